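"""Single-subject structural connectomes and the long-range fibre proportion.

A raw connectome is the region x region streamline-count matrix produced by
probabilistic tractography (one file per subject; directionality is a
tractography artefact).  The correction pipeline is:

1. ``symmetrize_and_normalize`` — average the two seeding directions and
   divide each pair's count by the sum of the two region volumes, removing
   the size bias of larger seed/target regions.
2. ``threshold_connectome`` — zero out connections below the subject's 20th
   percentile of nonzero weights, treating the weakest tail as possibly
   spurious streamlines.
3. ``fibre_length_profile`` — count surviving connections per centroid
   distance band and form the long:short ratio, the "proportion of
   long-range fibres" carried into the behavioural analysis.

The percentile population is the subject's own nonzero upper-triangle
weights: including structural zeros would drive the cutoff to zero for any
sparse matrix and disable the step entirely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .atlas import LONG, MEDIUM, SHORT, DistanceBands, ROIAtlas
from .errors import DegenerateInputError, UndefinedRatioError, ValidationError

__all__ = [
    "Connectome",
    "FibreLengthProfile",
    "symmetrize_and_normalize",
    "threshold_connectome",
    "fibre_length_profile",
    "nearest_rank_cutoff",
]

STAGES = ("raw", "normalized", "thresholded")


@dataclass(frozen=True)
class Connectome:
    """One subject's region x region connectivity matrix.

    ``stage`` records provenance: ``raw`` (tractography counts, possibly
    asymmetric, nonzero diagonal tolerated), ``normalized`` (symmetric,
    volume-corrected, zero diagonal) or ``thresholded`` (percentile-cleaned;
    ``threshold_cutoff`` holds the applied cutoff).
    """

    weights: np.ndarray
    region_ids: np.ndarray
    stage: str
    subject_id: str = ""
    threshold_cutoff: Optional[float] = None

    def __post_init__(self):
        w = np.asarray(self.weights, float)
        ids = np.asarray(self.region_ids, int)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValidationError(f"connectome matrix must be square, got {w.shape}")
        if w.shape[0] != len(ids):
            raise ValidationError(
                f"{w.shape[0]} matrix rows but {len(ids)} region ids"
            )
        if len(np.unique(ids)) != len(ids):
            raise ValidationError("connectome region ids are not unique")
        if self.stage not in STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}; expected {STAGES}")
        if not np.all(np.isfinite(w)):
            i, j = np.argwhere(~np.isfinite(w))[0]
            raise ValidationError(
                f"non-finite weight at region pair ({ids[i]}, {ids[j]})"
            )
        if np.any(w < 0):
            i, j = np.argwhere(w < 0)[0]
            raise ValidationError(
                f"negative weight at region pair ({ids[i]}, {ids[j]})"
            )
        if self.stage in ("normalized", "thresholded"):
            if not np.allclose(w, w.T):
                raise ValidationError(f"{self.stage} connectome must be symmetric")
            if np.any(np.diagonal(w) != 0):
                raise ValidationError(f"{self.stage} connectome must have zero diagonal")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "region_ids", ids)

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)


@dataclass(frozen=True)
class FibreLengthProfile:
    """Surviving-connection counts per distance band for one subject.

    ``long_short_ratio`` is n_long / n_short in the default edge-count mode;
    in weight-sum mode it is the ratio of summed surviving weights.  The
    weight sums are always reported for inspection.
    """

    subject_id: str
    n_short: int
    n_medium: int
    n_long: int
    long_short_ratio: float
    mode: str = "edges"
    weight_short: float = 0.0
    weight_medium: float = 0.0
    weight_long: float = 0.0
    threshold_cutoff: Optional[float] = None

    @property
    def n_total(self) -> int:
        return self.n_short + self.n_medium + self.n_long


def symmetrize_and_normalize(raw: Connectome, atlas: ROIAtlas) -> Connectome:
    """Average the two seeding directions and correct for region volumes.

    ``w[i, j] = ((raw[i, j] + raw[j, i]) / 2) / (vol_i + vol_j)`` with the
    diagonal zeroed (self-connections carry no pair meaning).
    """
    if raw.stage != "raw":
        raise ValidationError(f"expected a raw connectome, got stage {raw.stage!r}")
    if set(raw.region_ids.tolist()) != set(atlas.region_ids.tolist()):
        raise ValidationError(
            "connectome region ids do not match the atlas "
            f"(subject {raw.subject_id!r})"
        )
    vols = atlas.volumes_for(raw.region_ids)
    sym = (raw.weights + raw.weights.T) / 2.0
    w = sym / (vols[:, None] + vols[None, :])
    np.fill_diagonal(w, 0.0)
    return Connectome(
        weights=w,
        region_ids=raw.region_ids,
        stage="normalized",
        subject_id=raw.subject_id,
    )


def nearest_rank_cutoff(values: np.ndarray, percentile: float) -> float:
    """Nearest-rank percentile: the ceil(p*n)-th order statistic.

    For ``percentile = 0`` this degenerates to the minimum, so a strict
    "below cutoff" removal set is empty — thresholding at 0 is a no-op.
    """
    v = np.sort(np.asarray(values, float))
    k = max(math.ceil(percentile * len(v)), 1)
    return float(v[k - 1])


def threshold_connectome(
    c: Connectome,
    percentile: float = 0.20,
    method: str = "nearest-rank",
) -> Connectome:
    """Zero out weights strictly below the subject's percentile cutoff.

    The cutoff is taken over the subject's *nonzero* upper-triangle weights.
    ``method`` is ``"nearest-rank"`` (default; exactly reproducible order
    statistic) or ``"linear"`` (interpolated percentile).  Weights equal to
    the cutoff survive ("lower than" is strict).
    """
    if c.stage != "normalized":
        raise ValidationError(
            f"thresholding expects a normalized connectome, got {c.stage!r}"
        )
    if not 0.0 <= percentile < 1.0:
        raise ValidationError(f"percentile must be in [0, 1), got {percentile}")
    iu = np.triu_indices(c.n_regions, k=1)
    upper = c.weights[iu]
    nonzero = upper[upper > 0]
    if nonzero.size == 0:
        raise DegenerateInputError(
            f"connectome for subject {c.subject_id!r} has no nonzero "
            "connections; percentile cutoff is undefined"
        )
    if method == "nearest-rank":
        cutoff = nearest_rank_cutoff(nonzero, percentile)
    elif method == "linear":
        cutoff = float(np.quantile(nonzero, percentile))
    else:
        raise ValidationError(f"unknown percentile method {method!r}")
    w = c.weights.copy()
    w[w < cutoff] = 0.0
    return Connectome(
        weights=w,
        region_ids=c.region_ids,
        stage="thresholded",
        subject_id=c.subject_id,
        threshold_cutoff=cutoff,
    )


def fibre_length_profile(
    c: Connectome,
    bands: DistanceBands,
    mode: str = "edges",
) -> FibreLengthProfile:
    """Count surviving connections per band and form the long:short ratio.

    ``mode="edges"`` (default) counts surviving nonzero connections;
    ``mode="weights"`` ratios the summed surviving weights instead.  A zero
    denominator (no surviving short-range connections) raises
    :class:`UndefinedRatioError` rather than returning inf/NaN.
    """
    if c.stage != "thresholded":
        raise ValidationError(
            f"fibre profile expects a thresholded connectome, got {c.stage!r}"
        )
    if mode not in ("edges", "weights"):
        raise ValidationError(f"unknown ratio mode {mode!r}")
    if not np.array_equal(bands.region_ids, c.region_ids):
        bands = bands.reorder(c.region_ids)
    iu = np.triu_indices(c.n_regions, k=1)
    w = c.weights[iu]
    b = bands.band[iu]
    surviving = w > 0
    counts = {
        band: int(np.count_nonzero(surviving & (b == band)))
        for band in (SHORT, MEDIUM, LONG)
    }
    sums = {band: float(w[surviving & (b == band)].sum()) for band in (SHORT, MEDIUM, LONG)}
    if mode == "edges":
        num, den = counts[LONG], counts[SHORT]
    else:
        num, den = sums[LONG], sums[SHORT]
    if den == 0:
        raise UndefinedRatioError(
            f"subject {c.subject_id!r} has no surviving short-range "
            f"connections; long:short ratio undefined (mode={mode})"
        )
    return FibreLengthProfile(
        subject_id=c.subject_id,
        n_short=counts[SHORT],
        n_medium=counts[MEDIUM],
        n_long=counts[LONG],
        long_short_ratio=float(num) / float(den),
        mode=mode,
        weight_short=sums[SHORT],
        weight_medium=sums[MEDIUM],
        weight_long=sums[LONG],
        threshold_cutoff=c.threshold_cutoff,
    )
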