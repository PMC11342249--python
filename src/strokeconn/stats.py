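"""Covariate regression, residual-ratio correlation, and the aetiology ANOVA.

The behavioural analysis is deliberately two-step: first an OLS of each
behavioural score on the nuisance covariates (age, years post stroke,
lesion volume and — where defined — key-region damage), then a Pearson
correlation between the standardized residuals of that model and the
long-range fibre proportion.  The squared correlation is reported as the
additional variance the fibre ratio explains beyond the covariates.

The literal two-step differs slightly from a semi-partial correlation
because the ratio itself is not residualized; both modes are implemented.
``mode="literal"`` is the default; ``mode="semipartial"`` computes the
textbook part correlation — the raw score against the ratio residualized
on the same covariates — whose square equals the exact increment in model
R^2 when the ratio joins the covariate OLS (the Frisch-Waugh-Lovell
decomposition).  Correlating *residualized* score with residualized ratio
would instead give the partial correlation, whose square is that increment
divided by (1 - R^2) of the covariate model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import (
    AlignmentError,
    CollinearityError,
    DegenerateInputError,
    ValidationError,
)

__all__ = [
    "CovariateModelFit",
    "AnovaResult",
    "ols_residualize",
    "pearson_r",
    "residual_association",
    "anova_oneway",
    "merge_small_groups",
]


@dataclass(frozen=True)
class CovariateModelFit:
    """OLS of one behavioural measure on nuisance covariates.

    Carries everything the downstream correlation and the summary table
    need: coefficients with t/p, model F and p, multiple R, adjusted R^2,
    and standardized residuals (residual / sample SD of residuals, so their
    SD is 1 by construction).
    """

    measure: str
    covariate_names: tuple
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    fvalue: float
    f_pvalue: float
    multiple_r: float
    rsquared: float
    rsquared_adj: float
    residuals: pd.Series
    std_residuals: pd.Series
    nobs: int
    design: pd.DataFrame = field(repr=False)
    y: pd.Series = field(repr=False)
    studentized: bool = False


def _check_design(X: pd.DataFrame) -> None:
    vals = X.to_numpy(float)
    if not np.all(np.isfinite(vals)):
        raise ValidationError("covariate design contains non-finite values")
    const = [c for c in X.columns if np.ptp(X[c].to_numpy(float)) == 0]
    if const:
        raise ValidationError(
            f"constant covariate column(s): {const}; remove them (an "
            "intercept is added automatically)"
        )
    design = np.column_stack([np.ones(len(X)), vals])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        # name columns whose removal restores full rank
        offending = []
        for j, col in enumerate(X.columns):
            others = np.delete(design, j + 1, axis=1)
            if np.linalg.matrix_rank(others) == np.linalg.matrix_rank(design):
                offending.append(col)
        raise CollinearityError(offending or list(X.columns))


def ols_residualize(
    behaviour: pd.Series,
    covariates: pd.DataFrame,
    measure: str = "",
    studentized: bool = False,
) -> CovariateModelFit:
    """Regress a behavioural score on covariates; keep standardized residuals.

    Subjects with a missing score or covariate are dropped (complete case).
    ``studentized=True`` switches the residual scaling to internally
    studentized residuals (residual / (s * sqrt(1 - h_ii))); the default
    divides by the sample SD of the residuals.
    """
    measure = measure or str(behaviour.name or "score")
    df = covariates.copy()
    df["_y"] = behaviour
    df = df.dropna()
    y = df["_y"]
    X = df.drop(columns="_y")
    n, k = X.shape
    if n <= k + 1:
        raise ValidationError(
            f"{measure}: {n} subjects cannot identify {k} covariates + intercept"
        )
    _check_design(X)
    res = sm.OLS(y.to_numpy(float), sm.add_constant(X.to_numpy(float))).fit()
    names = ["intercept"] + list(X.columns)
    resid = pd.Series(res.resid, index=df.index, name=f"resid_{measure}")
    sd = resid.std(ddof=1)
    if sd < 1e-12:
        warnings.warn(
            f"{measure}: residual SD ~ 0 (perfect covariate fit); "
            "standardized residuals set to 0",
            stacklevel=2,
        )
        std_resid = resid * 0.0
    elif studentized:
        infl = res.get_influence()
        std_resid = pd.Series(infl.resid_studentized_internal, index=df.index)
    else:
        std_resid = resid / sd
    std_resid.name = f"std_resid_{measure}"
    return CovariateModelFit(
        measure=measure,
        covariate_names=tuple(X.columns),
        params=pd.Series(res.params, index=names),
        bse=pd.Series(res.bse, index=names),
        tvalues=pd.Series(res.tvalues, index=names),
        pvalues=pd.Series(res.pvalues, index=names),
        fvalue=float(res.fvalue),
        f_pvalue=float(res.f_pvalue),
        multiple_r=float(np.sqrt(res.rsquared)),
        rsquared=float(res.rsquared),
        rsquared_adj=float(res.rsquared_adj),
        residuals=resid,
        std_residuals=std_resid,
        nobs=int(res.nobs),
        design=X,
        y=y,
        studentized=studentized,
    )


def pearson_r(x, y):
    """Product-moment correlation with a two-tailed p (t transform, n-2 df)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("pearson_r expects two equal-length 1-d vectors")
    if len(x) < 3:
        raise ValidationError(f"need >= 3 observations, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("correlation undefined for a constant vector")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def residual_association(
    fits: Mapping[str, CovariateModelFit],
    ratios: pd.Series,
    q_level: float = 0.05,
    mode: str = "literal",
) -> pd.DataFrame:
    """Correlate each measure's standardized residuals with the fibre ratio.

    Returns one row per measure: r, delta_r2 (= r^2 exactly), raw p, BH
    p across the measure family, and the significance flag.  ``mode``
    selects the literal two-step ("literal": standardized score residuals
    against the raw ratio) or the part correlation ("semipartial": raw
    score against the ratio residualized on that measure's covariates).
    """
    from .lsm import benjamini_hochberg  # local import avoids cycle at import time

    if not fits:
        raise ValidationError("no covariate model fits supplied")
    if mode not in ("literal", "semipartial"):
        raise ValidationError(f"unknown association mode {mode!r}")
    rows = []
    for m, fit in fits.items():
        idx = fit.std_residuals.index
        missing = idx.difference(ratios.index)
        if len(missing) > 0:
            raise AlignmentError(
                f"{m}: {len(missing)} subjects in the model fit have no "
                f"fibre ratio (e.g. {list(missing[:3])})"
            )
        g = ratios.loc[idx].to_numpy(float)
        if mode == "semipartial":
            X = sm.add_constant(fit.design.to_numpy(float))
            beta, *_ = np.linalg.lstsq(X, g, rcond=None)
            r, p = pearson_r(fit.y.to_numpy(float), g - X @ beta)
        else:
            r, p = pearson_r(fit.std_residuals.to_numpy(), g)
        rows.append((m, len(idx), r, r * r, p))
    out = pd.DataFrame(rows, columns=["measure", "n", "r", "delta_r2", "p_raw"])
    sig, q = benjamini_hochberg(out["p_raw"].to_numpy(), q_level)
    out["p_fdr"] = q
    out["significant"] = sig
    out["family_size"] = len(out)
    out["mode"] = mode
    return out


@dataclass(frozen=True)
class AnovaResult:
    """Classical one-way ANOVA of the fibre ratio across groups."""

    fvalue: float
    pvalue: float
    df_between: int
    df_within: int
    group_means: pd.Series
    group_sizes: pd.Series


def merge_small_groups(
    groups: pd.Series, min_size: int = 2, other_label: str = "other"
) -> pd.Series:
    """Pool groups with fewer than ``min_size`` members into ``other_label``.

    Keeps a cohort with a rare aetiology analysable instead of failing the
    whole run; warns so the pooling is auditable.
    """
    counts = groups.value_counts()
    small = counts[counts < min_size].index.tolist()
    if not small:
        return groups
    pooled = groups.where(~groups.isin(small), other_label)
    counts = pooled.value_counts()
    target = other_label
    if counts.get(other_label, 0) < min_size:
        # pooling did not reach min_size; fold into the largest group
        target = counts.drop(other_label, errors="ignore").idxmax()
        pooled = pooled.where(pooled != other_label, target)
    warnings.warn(
        f"groups {small} have < {min_size} members; merged into "
        f"{target!r} for the ANOVA",
        stacklevel=2,
    )
    return pooled


def anova_oneway(values: pd.Series, groups: pd.Series) -> AnovaResult:
    """One-way ANOVA decomposition of ``values`` by ``groups``."""
    df = pd.DataFrame({"v": values, "g": groups}).dropna()
    sizes = df["g"].value_counts()
    if len(sizes) < 2:
        raise ValidationError(f"need >= 2 groups, got {len(sizes)}")
    small = sizes[sizes < 2]
    if len(small) > 0:
        raise ValidationError(
            f"group(s) with < 2 members: {small.index.tolist()}; "
            "within-group variance undefined"
        )
    if np.ptp(df["v"].to_numpy(float)) == 0:
        raise DegenerateInputError("values are constant; ANOVA undefined")
    arrays = [sub["v"].to_numpy(float) for _, sub in df.groupby("g")]
    f, p = sps.f_oneway(*arrays)
    return AnovaResult(
        fvalue=float(f),
        pvalue=float(p),
        df_between=len(arrays) - 1,
        df_within=len(df) - len(arrays),
        group_means=df.groupby("g")["v"].mean(),
        group_sizes=sizes.sort_index(),
    )
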