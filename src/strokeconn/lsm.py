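"""ROI-level univariate lesion-symptom mapping (LSM).

For each candidate region, the behavioural score is regressed on that
region's damage fraction (proportion of the region's voxels inside the
lesion).  Because a lesion can only plausibly hurt performance, the test is
one-tailed on a negative slope.  Regions lesioned in too few subjects are
excluded before testing (standard ROI-LSM practice: a slope estimated from
a handful of affected subjects is noise), and the Benjamini-Hochberg
step-up rule controls the false discovery rate across tested regions.

The per-subject "key damage" covariate is the mean damage fraction over the
LSM-significant region set for a given behavioural measure.  When no region
survives FDR the covariate is undefined and downstream models drop it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import AlignmentError, DegenerateInputError, ValidationError

__all__ = [
    "LSMResult",
    "KeyDamageScore",
    "roi_lsm",
    "benjamini_hochberg",
    "key_damage_score",
    "validate_damage_matrix",
]


def validate_damage_matrix(damage: pd.DataFrame) -> pd.DataFrame:
    """Check a subjects x regions damage-fraction matrix.

    Entries must be finite fractions in [0, 1]; columns are region ids.
    """
    vals = damage.to_numpy(float)
    if not np.all(np.isfinite(vals)):
        raise ValidationError("damage matrix contains non-finite entries")
    if np.any(vals < 0) or np.any(vals > 1):
        i, j = np.argwhere((vals < 0) | (vals > 1))[0]
        raise ValidationError(
            f"damage fraction out of [0, 1] for subject {damage.index[i]!r}, "
            f"region {damage.columns[j]!r}"
        )
    return damage


@dataclass(frozen=True)
class LSMResult:
    """Per-region LSM statistics for one behavioural measure.

    ``table`` has one row per *tested* region: slope, t, one-tailed p,
    BH-adjusted q and a significance flag at ``q <= q_level``.  ``excluded``
    lists candidate regions removed before testing, with the reason.
    """

    measure: str
    table: pd.DataFrame
    excluded: pd.DataFrame
    q_level: float
    n_subjects: int

    @property
    def significant_regions(self) -> np.ndarray:
        return self.table.loc[self.table["significant"], "region_id"].to_numpy()

    @property
    def tested_regions(self) -> np.ndarray:
        return self.table["region_id"].to_numpy()


@dataclass(frozen=True)
class KeyDamageScore:
    """Per-subject mean damage over a significant-region set.

    ``defined`` is False exactly when the region set is empty, in which
    case ``values`` is None and downstream covariate models omit the term.
    """

    measure: str
    regions: tuple
    defined: bool
    values: Optional[pd.Series]


def benjamini_hochberg(p_values, q_level: float = 0.05):
    """BH step-up FDR control.

    Returns ``(significant, q_values)``: boolean rejection flags at level
    ``q_level`` and monotone adjusted p-values.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        raise ValidationError("empty p-value vector")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must be finite and in [0, 1]")
    if not 0 < q_level < 1:
        raise ValidationError(f"q level must be in (0, 1), got {q_level}")
    reject, q, _, _ = multipletests(p, alpha=q_level, method="fdr_bh")
    return reject, q


def roi_lsm(
    damage: pd.DataFrame,
    behaviour: pd.Series,
    min_affected: int = 10,
    q_level: float = 0.05,
    candidate_regions: Optional[Sequence] = None,
    measure: str = "",
) -> LSMResult:
    """Mass-univariate region-level lesion-symptom mapping.

    Parameters
    ----------
    damage : DataFrame, subjects x regions, fractions in [0, 1].
    behaviour : Series indexed by subject; NaNs dropped (complete case).
    min_affected : exclude regions with fewer subjects having damage > 0.
    q_level : BH-FDR level for the significance flag.
    candidate_regions : region ids to test (default: all damage columns;
        a typical restriction is the lesioned hemisphere).
    """
    validate_damage_matrix(damage)
    behaviour = behaviour.dropna()
    common = damage.index.intersection(behaviour.index)
    if len(common) == 0:
        raise AlignmentError("no subjects shared between damage matrix and behaviour")
    dmg = damage.loc[common]
    y = behaviour.loc[common].to_numpy(float)
    if np.ptp(y) == 0:
        raise DegenerateInputError(
            f"behaviour {measure or behaviour.name!r} is constant; LSM undefined"
        )
    if candidate_regions is None:
        candidate_regions = list(dmg.columns)
    else:
        missing = [r for r in candidate_regions if r not in dmg.columns]
        if missing:
            raise ValidationError(f"candidate regions not in damage matrix: {missing}")

    rows, excluded = [], []
    for region in candidate_regions:
        x = dmg[region].to_numpy(float)
        n_affected = int(np.count_nonzero(x > 0))
        if n_affected < min_affected:
            excluded.append((region, f"affected in {n_affected} < {min_affected} subjects"))
            continue
        if np.ptp(x) == 0:
            excluded.append((region, "constant damage fraction"))
            continue
        fit = sps.linregress(x, y)
        with np.errstate(divide="ignore"):
            # a perfect linear relation has zero residual SE; t is +/-inf
            t = fit.slope / fit.stderr if fit.stderr > 0 else np.sign(fit.slope) * np.inf
        # one-tailed: damage should lower the score, so small p <=> t << 0
        p_one = float(sps.t.cdf(t, df=len(y) - 2))
        rows.append((region, n_affected, fit.slope, t, p_one))

    if not rows:
        raise DegenerateInputError(
            "all candidate regions excluded before testing "
            f"(min_affected={min_affected})"
        )
    table = pd.DataFrame(
        rows, columns=["region_id", "n_affected", "slope", "t", "p_one_tailed"]
    )
    sig, q = benjamini_hochberg(table["p_one_tailed"].to_numpy(), q_level)
    table["q_value"] = q
    table["significant"] = sig
    excluded_df = pd.DataFrame(excluded, columns=["region_id", "reason"])
    return LSMResult(
        measure=measure or str(behaviour.name or ""),
        table=table,
        excluded=excluded_df,
        q_level=q_level,
        n_subjects=len(common),
    )


def key_damage_score(
    damage: pd.DataFrame,
    significant_regions: Iterable,
    measure: str = "",
) -> KeyDamageScore:
    """Average damage over a significant-region set, per subject.

    An empty set yields an *undefined* score (mirrors dropping the covariate
    for measures whose LSM finds nothing), never a silent zero.
    """
    regions = tuple(significant_regions)
    missing = [r for r in regions if r not in damage.columns]
    if missing:
        raise ValidationError(f"regions not present in damage matrix: {missing}")
    if not regions:
        return KeyDamageScore(measure=measure, regions=(), defined=False, values=None)
    validate_damage_matrix(damage[list(regions)])
    values = damage[list(regions)].mean(axis=1)
    values.name = f"key_damage_{measure}" if measure else "key_damage"
    return KeyDamageScore(measure=measure, regions=regions, defined=True, values=values)
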