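"""Statsmodels-style front end: build once, ``fit()``, inspect results.

:class:`LongRangeModel` bundles the staged behavioural analysis — aetiology
ANOVA, per-measure lesion-symptom mapping, key-damage covariate, covariate
OLS, residual-ratio correlation with FDR — into a single fitted object.
The individual stages remain available as plain functions in
:mod:`strokeconn.lsm` and :mod:`strokeconn.stats`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .atlas import ROIAtlas, compute_distance_bands
from .connectome import (
    Connectome,
    fibre_length_profile,
    symmetrize_and_normalize,
    threshold_connectome,
)
from .errors import AlignmentError, ValidationError
from .lsm import KeyDamageScore, LSMResult, key_damage_score, roi_lsm
from .stats import (
    AnovaResult,
    CovariateModelFit,
    anova_oneway,
    merge_small_groups,
    ols_residualize,
    residual_association,
)

__all__ = ["LongRangeModel", "LongRangeResults", "compute_profiles"]

BASE_COVARIATES = ("age", "years_post_stroke", "lesion_volume")


def compute_profiles(
    connectomes: Mapping[str, Connectome],
    atlas: ROIAtlas,
    percentile: float = 0.20,
    percentile_method: str = "nearest-rank",
    ratio_mode: str = "edges",
) -> pd.DataFrame:
    """Run the connectome correction pipeline for every subject.

    Returns one row per subject: band counts, long:short ratio and the
    percentile cutoff applied.
    """
    bands = compute_distance_bands(atlas)
    rows = []
    for sid, raw in connectomes.items():
        norm = symmetrize_and_normalize(raw, atlas)
        thresh = threshold_connectome(norm, percentile, method=percentile_method)
        p = fibre_length_profile(thresh, bands, mode=ratio_mode)
        rows.append(
            (sid, p.n_short, p.n_medium, p.n_long, p.long_short_ratio,
             p.threshold_cutoff)
        )
    return pd.DataFrame(
        rows,
        columns=["subject_id", "n_short", "n_medium", "n_long",
                 "long_short_ratio", "threshold_cutoff"],
    ).set_index("subject_id")


class LongRangeModel:
    """Behavioural outcomes versus the long-range fibre proportion.

    Parameters
    ----------
    subjects : DataFrame indexed by subject id with ``age``,
        ``years_post_stroke``, ``lesion_volume``, optionally ``aetiology``,
        and one column per behavioural measure.
    ratios : Series of long:short fibre ratios per subject.
    damage : DataFrame, subjects x regions damage fractions.
    measures : behavioural columns to analyse.
    atlas : optional; restricts LSM candidates to ``candidate_hemisphere``.
    """

    def __init__(
        self,
        subjects: pd.DataFrame,
        ratios: pd.Series,
        damage: pd.DataFrame,
        measures: Sequence[str],
        atlas: Optional[ROIAtlas] = None,
        candidate_hemisphere: Optional[str] = "L",
        min_affected: int = 10,
        q_lsm: float = 0.05,
        q_association: float = 0.05,
        association_mode: str = "literal",
        studentized: bool = False,
    ):
        missing = [m for m in measures if m not in subjects.columns]
        if missing:
            raise ValidationError(f"measures not in subject table: {missing}")
        common = subjects.index.intersection(ratios.index).intersection(damage.index)
        if len(common) == 0:
            raise AlignmentError("subjects, ratios and damage share no subject ids")
        dropped = len(subjects) - len(common)
        if dropped:
            warnings.warn(
                f"{dropped} subjects dropped for missing ratio or damage data",
                stacklevel=2,
            )
        self.subjects = subjects.loc[common]
        self.ratios = ratios.loc[common]
        self.damage = damage.loc[common]
        self.measures = list(measures)
        self.atlas = atlas
        if atlas is not None and candidate_hemisphere is not None:
            cand = atlas.hemisphere_region_ids(candidate_hemisphere)
            self.candidate_regions = [r for r in cand if r in damage.columns]
            if not self.candidate_regions:
                raise ValidationError(
                    f"no {candidate_hemisphere}-hemisphere atlas regions in "
                    "the damage matrix"
                )
        else:
            self.candidate_regions = None
        self.min_affected = min_affected
        self.q_lsm = q_lsm
        self.q_association = q_association
        self.association_mode = association_mode
        self.studentized = studentized

    @classmethod
    def from_cohort(cls, cohort, percentile: Optional[float] = None, **kwargs):
        """Build from a :class:`~strokeconn.simulate.SyntheticCohort`.

        Uses the cohort's precomputed profiles unless ``percentile`` asks
        for a different threshold, in which case the connectome stage is
        re-run.
        """
        if percentile is None or percentile == cohort.truth.percentile:
            ratios = cohort.profiles["long_short_ratio"]
        else:
            ratios = compute_profiles(
                cohort.connectomes, cohort.atlas, percentile
            )["long_short_ratio"]
        from .simulate import MEASURES

        return cls(
            subjects=cohort.subjects,
            ratios=ratios,
            damage=cohort.damage,
            measures=[m for m in MEASURES if m in cohort.subjects.columns],
            atlas=cohort.atlas,
            **kwargs,
        )

    def fit(self) -> "LongRangeResults":
        """Run every stage and return the results object."""
        anova = None
        if "aetiology" in self.subjects.columns:
            groups = merge_small_groups(self.subjects["aetiology"])
            anova = anova_oneway(self.ratios, groups)

        lsm_results: Dict[str, LSMResult] = {}
        key_scores: Dict[str, KeyDamageScore] = {}
        fits: Dict[str, CovariateModelFit] = {}
        for m in self.measures:
            lsm = roi_lsm(
                self.damage,
                self.subjects[m],
                min_affected=self.min_affected,
                q_level=self.q_lsm,
                candidate_regions=self.candidate_regions,
                measure=m,
            )
            lsm_results[m] = lsm
            key = key_damage_score(self.damage, lsm.significant_regions, measure=m)
            key_scores[m] = key
            covs = self.subjects[list(BASE_COVARIATES)].copy()
            if key.defined:
                covs["key_damage"] = key.values
            fits[m] = ols_residualize(
                self.subjects[m], covs, measure=m, studentized=self.studentized
            )
        associations = residual_association(
            fits, self.ratios, q_level=self.q_association,
            mode=self.association_mode,
        )
        return LongRangeResults(
            model=self,
            anova=anova,
            lsm=lsm_results,
            key_damage=key_scores,
            model_fits=fits,
            associations=associations,
        )


@dataclass
class LongRangeResults:
    """Fitted results: every stage's output plus reporting helpers."""

    model: LongRangeModel
    anova: Optional[AnovaResult]
    lsm: Dict[str, LSMResult]
    key_damage: Dict[str, KeyDamageScore]
    model_fits: Dict[str, CovariateModelFit]
    associations: pd.DataFrame

    def modelfit_table(self) -> pd.DataFrame:
        """Covariate-model statistics, one column per measure.

        Mirrors the conventional reporting layout: model F/p, multiple R,
        adjusted R^2, then per-covariate t and p; 'N/A' where the
        key-damage covariate was undefined (no LSM-significant regions).
        """
        rows: Dict[str, Dict[str, object]] = {}
        covariates = list(BASE_COVARIATES) + ["key_damage"]
        for m, fit in self.model_fits.items():
            col = {
                "F": fit.fvalue,
                "F_p": fit.f_pvalue,
                "multiple_R": fit.multiple_r,
                "adj_R2": fit.rsquared_adj,
                "n": fit.nobs,
            }
            for c in covariates:
                if c in fit.covariate_names:
                    col[f"t_{c}"] = fit.tvalues[c]
                    col[f"p_{c}"] = fit.pvalues[c]
                else:
                    col[f"t_{c}"] = "N/A"
                    col[f"p_{c}"] = "N/A"
            rows[m] = col
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Plain-text report of every stage."""
        lines = ["Long-range fibre proportion analysis", "=" * 52]
        lines.append(
            f"subjects: {len(self.model.subjects)}   "
            f"measures: {', '.join(self.model.measures)}"
        )
        if self.anova is not None:
            a = self.anova
            lines += [
                "",
                "One-way ANOVA: fibre ratio ~ stroke aetiology",
                f"  F({a.df_between}, {a.df_within}) = {a.fvalue:.3f}, "
                f"p = {a.pvalue:.3f}",
            ]
            for g, mean in a.group_means.items():
                lines.append(
                    f"    {g}: mean ratio {mean:.3f} (n={a.group_sizes[g]})"
                )
        lines += ["", "Lesion-symptom mapping (one-tailed, BH-FDR)"]
        for m, res in self.lsm.items():
            sig = res.significant_regions
            lines.append(
                f"  {m}: {len(res.table)} regions tested, "
                f"{len(res.excluded)} excluded, "
                f"{len(sig)} significant at q<={res.q_level:g}"
                + (f" -> key damage over {[int(r) for r in sig]}" if len(sig)
                   else " -> key-damage covariate dropped")
            )
        lines += ["", "Covariate models (OLS)"]
        mft = self.modelfit_table()
        lines.append(mft.to_string(float_format=lambda v: f"{v:.4g}"))
        lines += [
            "",
            "Residual correlation with long-range fibre proportion "
            f"(mode={self.associations['mode'].iloc[0]}, "
            f"BH family of {self.associations['family_size'].iloc[0]})",
        ]
        tab = self.associations.drop(columns=["mode", "family_size"])
        lines.append(tab.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        lines.append(
            "delta_r2 is the additional behavioural variance explained by "
            "the fibre ratio beyond the covariates."
        )
        return "\n".join(lines)

    def plot_associations(self, path=None):
        """Scatter of standardized residuals vs the fibre ratio per measure."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        n = len(self.model_fits)
        fig, axes = plt.subplots(1, n, figsize=(4 * n, 3.5), squeeze=False)
        for ax, (m, fit) in zip(axes.ravel(), self.model_fits.items()):
            g = self.model.ratios.loc[fit.std_residuals.index]
            ax.scatter(g, fit.std_residuals, s=12, alpha=0.7)
            row = self.associations.set_index("measure").loc[m]
            ax.set_title(f"{m}: r={row['r']:.3f}, p_fdr={row['p_fdr']:.3g}")
            ax.set_xlabel("long:short fibre ratio")
            ax.set_ylabel("standardized residual")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig
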