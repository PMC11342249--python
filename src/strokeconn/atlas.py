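"""Region-of-interest atlas and centroid-distance banding.

An atlas is the fixed frame of an analysis: integer region labels, a
hemisphere tag, a centroid in millimetres (MNI-convention axes: x increases
to the right, so left-hemisphere centroids have negative x) and a grey- or
white-matter volume in mm^3.  Connections are classified as short-, medium-
or long-range by where the Euclidean distance between the two region
centroids falls in the quartiles of *all* unordered pair distances of the
atlas.  The quartile cutoffs are therefore an atlas property, identical for
every subject analysed against it.

Banding convention (ties documented and tested): a pair is *short* when its
distance is <= the first-quartile cutoff, *long* when strictly greater than
the third-quartile cutoff, and *medium* otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import ValidationError

__all__ = [
    "ROIAtlas",
    "DistanceBands",
    "compute_distance_bands",
    "SHORT",
    "MEDIUM",
    "LONG",
]

SHORT, MEDIUM, LONG = 0, 1, 2
BAND_NAMES = {SHORT: "short", MEDIUM: "medium", LONG: "long"}

ATLAS_COLUMNS = [
    "region_id",
    "name",
    "hemisphere",
    "centroid_x",
    "centroid_y",
    "centroid_z",
    "volume_mm3",
]

_HEMISPHERES = {"L", "R", "midline"}


@dataclass(frozen=True)
class ROIAtlas:
    """A parcellation table: one row per region.

    Parameters
    ----------
    table : pandas.DataFrame
        Columns ``region_id, name, hemisphere, centroid_x, centroid_y,
        centroid_z, volume_mm3``.  Region ids must be unique integers,
        centroids finite, volumes strictly positive, and there must be at
        least 4 regions (quartile banding needs >= 4 distinct pairs).
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        missing = [c for c in ATLAS_COLUMNS if c not in t.columns]
        if missing:
            raise ValidationError(f"atlas table missing columns: {missing}")
        if len(t) < 4:
            raise ValidationError(
                f"atlas needs >= 4 regions for quartile banding, got {len(t)}"
            )
        ids = t["region_id"].to_numpy()
        if len(np.unique(ids)) != len(ids):
            raise ValidationError("atlas region_ids are not unique")
        cent = t[["centroid_x", "centroid_y", "centroid_z"]].to_numpy(float)
        if not np.all(np.isfinite(cent)):
            raise ValidationError("atlas centroids contain non-finite values")
        vols = t["volume_mm3"].to_numpy(float)
        if not np.all(np.isfinite(vols)) or np.any(vols <= 0):
            raise ValidationError("atlas volumes must be finite and > 0")
        bad = set(t["hemisphere"]) - _HEMISPHERES
        if bad:
            raise ValidationError(
                f"unknown hemisphere labels {sorted(bad)}; expected {_HEMISPHERES}"
            )
        # normalise dtypes and index without mutating the caller's frame
        t = t.copy()
        t["region_id"] = t["region_id"].astype(int)
        object.__setattr__(self, "table", t.reset_index(drop=True))

    # -- accessors ---------------------------------------------------------
    @property
    def region_ids(self) -> np.ndarray:
        return self.table["region_id"].to_numpy()

    @property
    def centroids(self) -> np.ndarray:
        return self.table[["centroid_x", "centroid_y", "centroid_z"]].to_numpy(float)

    @property
    def volumes(self) -> np.ndarray:
        return self.table["volume_mm3"].to_numpy(float)

    @property
    def n_regions(self) -> int:
        return len(self.table)

    def hemisphere_region_ids(self, hemisphere: str) -> np.ndarray:
        return self.table.loc[
            self.table["hemisphere"] == hemisphere, "region_id"
        ].to_numpy()

    def volumes_for(self, region_ids) -> np.ndarray:
        """Volumes aligned to an arbitrary ordering of region ids."""
        lut = dict(zip(self.region_ids.tolist(), self.volumes.tolist()))
        try:
            return np.array([lut[int(r)] for r in region_ids], float)
        except KeyError as e:  # pragma: no cover - message path
            raise ValidationError(f"region id {e.args[0]} not in atlas") from None

    # -- io ----------------------------------------------------------------
    @classmethod
    def from_csv(cls, path) -> "ROIAtlas":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.12g")


@dataclass(frozen=True)
class DistanceBands:
    """Quartile banding of centroid distances for one atlas.

    ``distance`` and ``band`` are square matrices aligned to ``region_ids``;
    the diagonal of ``band`` is -1 (self-pairs are never banded).
    """

    region_ids: np.ndarray
    distance: np.ndarray
    band: np.ndarray
    q1_cutoff: float
    q3_cutoff: float
    degenerate: bool = field(default=False)

    def reorder(self, region_ids) -> "DistanceBands":
        """Return a copy with rows/columns aligned to ``region_ids``."""
        want = np.asarray(region_ids, int)
        if set(want.tolist()) != set(self.region_ids.tolist()):
            raise ValidationError("requested region ids do not match this atlas")
        pos = {int(r): i for i, r in enumerate(self.region_ids)}
        idx = np.array([pos[int(r)] for r in want])
        return DistanceBands(
            region_ids=want,
            distance=self.distance[np.ix_(idx, idx)],
            band=self.band[np.ix_(idx, idx)],
            q1_cutoff=self.q1_cutoff,
            q3_cutoff=self.q3_cutoff,
            degenerate=self.degenerate,
        )

    def pair_table(self) -> pd.DataFrame:
        """Long-format table of unordered pairs with distance and band name."""
        n = len(self.region_ids)
        iu, ju = np.triu_indices(n, k=1)
        return pd.DataFrame(
            {
                "region_a": self.region_ids[iu],
                "region_b": self.region_ids[ju],
                "distance_mm": self.distance[iu, ju],
                "band": [BAND_NAMES[b] for b in self.band[iu, ju]],
            }
        )


def compute_distance_bands(atlas: ROIAtlas) -> DistanceBands:
    """Classify every unordered region pair as short/medium/long range.

    Distances are Euclidean between centroids (mm).  The Q1/Q3 cutoffs are
    the 25th/75th percentiles (linear interpolation) of the population of
    all unordered pair distances.  Short: d <= Q1; long: d > Q3; medium
    otherwise.  All pair distances equal (e.g. duplicated centroids) is
    permitted but flagged ``degenerate`` and warned about: every pair then
    lands in the short band.
    """
    cond = pdist(atlas.centroids)
    q1, q3 = np.quantile(cond, [0.25, 0.75])
    dist = squareform(cond)
    band = np.full(dist.shape, MEDIUM, dtype=int)
    band[dist <= q1] = SHORT
    band[dist > q3] = LONG
    np.fill_diagonal(band, -1)
    degenerate = bool(np.all(cond == cond[0]))
    if degenerate:
        warnings.warn(
            "all pairwise centroid distances are equal; distance banding is "
            "degenerate (every pair classified short)",
            stacklevel=2,
        )
    return DistanceBands(
        region_ids=atlas.region_ids.copy(),
        distance=dist,
        band=band,
        q1_cutoff=float(q1),
        q3_cutoff=float(q3),
        degenerate=degenerate,
    )
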