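"""Readers, writers and run configuration.

All tabular interchange is plain text: connectome matrices are TSV with a
header row and column of region ids (one file per subject), everything else
is CSV.  Floats are written with 12 significant digits so a written table
round-trips through its reader bit-for-bit at that precision.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .atlas import ROIAtlas
from .connectome import Connectome
from .errors import ValidationError
from .simulate import MEASURES, SyntheticCohort

__all__ = [
    "read_connectome_tsv",
    "write_connectome_tsv",
    "read_damage_csv",
    "write_damage_csv",
    "read_subjects_csv",
    "damage_from_nifti",
    "RunConfig",
    "write_cohort",
    "FLOAT_FORMAT",
]

FLOAT_FORMAT = "%.12g"


# ---------------------------------------------------------------------------
# connectome matrices


def read_connectome_tsv(path, subject_id: Optional[str] = None) -> Connectome:
    """Read a square region x region matrix with region-id headers."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as e:
        raise ValidationError(f"{path.name}: ragged or malformed TSV ({e})") from e
    if df.shape[0] != df.shape[1]:
        raise ValidationError(
            f"{path.name}: matrix is {df.shape[0]}x{df.shape[1]}, not square"
        )
    try:
        rows = [int(r) for r in df.index]
        cols = [int(c) for c in df.columns]
    except (TypeError, ValueError):
        raise ValidationError(f"{path.name}: headers must be integer region ids")
    if rows != cols:
        raise ValidationError(f"{path.name}: row and column region ids differ")
    vals = df.to_numpy(float)
    if np.any(~np.isfinite(vals)):
        i, j = np.argwhere(~np.isfinite(vals))[0]
        raise ValidationError(
            f"{path.name}: non-finite entry at row {rows[i]}, column {cols[j]}"
        )
    if np.any(vals < 0):
        i, j = np.argwhere(vals < 0)[0]
        raise ValidationError(
            f"{path.name}: negative entry at row {rows[i]}, column {cols[j]}"
        )
    return Connectome(
        weights=vals,
        region_ids=np.array(rows),
        stage="raw",
        subject_id=subject_id or path.stem,
    )


def write_connectome_tsv(conn: Connectome, path) -> None:
    df = pd.DataFrame(conn.weights, index=conn.region_ids, columns=conn.region_ids)
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# damage matrices and subject tables


def read_damage_csv(path) -> pd.DataFrame:
    """Subjects x regions damage-fraction CSV (columns = integer region ids)."""
    df = pd.read_csv(path, index_col=0)
    try:
        df.columns = [int(c) for c in df.columns]
    except (TypeError, ValueError):
        raise ValidationError(f"{Path(path).name}: damage columns must be region ids")
    from .lsm import validate_damage_matrix

    return validate_damage_matrix(df)


def write_damage_csv(damage: pd.DataFrame, path) -> None:
    damage.to_csv(path, float_format=FLOAT_FORMAT)


def read_subjects_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    required = {"age", "years_post_stroke", "lesion_volume"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"subject table missing columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# NIfTI damage extraction


def damage_from_nifti(lesion_mask_path, label_atlas_path) -> pd.Series:
    """Per-region damage fractions from a binary lesion mask + label volume.

    fraction(r) = lesioned voxels with label r / total voxels with label r.
    Both images must share grid shape and affine; the mask must be binary.
    """
    import nibabel as nib

    mask_img = nib.load(str(lesion_mask_path))
    atlas_img = nib.load(str(label_atlas_path))
    if mask_img.shape != atlas_img.shape:
        raise ValidationError(
            f"grid mismatch: mask {mask_img.shape} vs atlas {atlas_img.shape}"
        )
    if not np.allclose(mask_img.affine, atlas_img.affine, atol=1e-4):
        raise ValidationError("affine mismatch between lesion mask and label atlas")
    mask = np.asarray(mask_img.dataobj)
    labels = np.asarray(atlas_img.dataobj).astype(int)
    uniq = np.unique(mask)
    if not np.all(np.isin(uniq, [0, 1])):
        raise ValidationError(
            f"lesion mask must be binary; found values {uniq[:5].tolist()}"
        )
    region_ids = np.unique(labels)
    region_ids = region_ids[region_ids != 0]
    fractions = {}
    for r in region_ids:
        in_region = labels == r
        fractions[int(r)] = float(mask[in_region].sum() / in_region.sum())
    return pd.Series(fractions, name="damage_fraction")


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run.

    A run writes this next to its outputs so every number is traceable to
    the exact settings that produced it.
    """

    out_dir: str = "results"
    matrix_dir: Optional[str] = None
    atlas_path: Optional[str] = None
    subjects_path: Optional[str] = None
    damage_path: Optional[str] = None
    simulate: bool = False
    seed: int = 0
    n_subjects: int = 87
    n_regions_per_hemisphere: int = 20
    percentile: float = 0.20
    percentile_method: str = "nearest-rank"
    ratio_mode: str = "edges"
    min_affected: int = 10
    q_lsm: float = 0.05
    q_association: float = 0.05
    association_mode: str = "literal"
    measures: Sequence[str] = field(default_factory=lambda: list(MEASURES))
    candidate_hemisphere: str = "L"

    def validate(self) -> "RunConfig":
        if not 0.0 <= self.percentile < 1.0:
            raise ValidationError(f"percentile must be in [0, 1): {self.percentile}")
        for name in ("q_lsm", "q_association"):
            q = getattr(self, name)
            if not 0.0 < q < 1.0:
                raise ValidationError(f"{name} must be in (0, 1): {q}")
        if self.ratio_mode not in ("edges", "weights"):
            raise ValidationError(f"ratio_mode must be edges|weights: {self.ratio_mode}")
        if self.association_mode not in ("literal", "semipartial"):
            raise ValidationError(
                f"association_mode must be literal|semipartial: {self.association_mode}"
            )
        if self.min_affected < 1:
            raise ValidationError(f"min_affected must be >= 1: {self.min_affected}")
        if not self.simulate:
            for p in ("matrix_dir", "atlas_path", "subjects_path", "damage_path"):
                if getattr(self, p) is None:
                    raise ValidationError(
                        f"config requires {p} unless simulate is true"
                    )
        return self

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data).validate()

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# cohort export


def write_cohort(cohort: SyntheticCohort, out_dir) -> Dict[str, str]:
    """Write a simulated cohort in the exact formats the pipeline consumes."""
    out = Path(out_dir)
    (out / "connectomes").mkdir(parents=True, exist_ok=True)
    cohort.atlas.to_csv(out / "atlas.csv")
    cohort.subjects.to_csv(out / "subjects.csv", float_format=FLOAT_FORMAT)
    write_damage_csv(cohort.damage, out / "damage.csv")
    for sid, conn in cohort.connectomes.items():
        write_connectome_tsv(conn, out / "connectomes" / f"{sid}.tsv")
    truth_doc = cohort.truth.to_dict()
    truth_doc["planted_regions"] = {
        m: list(r) for m, r in cohort.planted_regions.items()
    }
    truth_doc["realized_beta_ratio"] = dict(cohort.realized_beta_ratio)
    with open(out / "ground_truth.yaml", "w") as fh:
        yaml.safe_dump(truth_doc, fh, sort_keys=True)
    return {
        "atlas": str(out / "atlas.csv"),
        "subjects": str(out / "subjects.csv"),
        "damage": str(out / "damage.csv"),
        "connectomes": str(out / "connectomes"),
        "ground_truth": str(out / "ground_truth.yaml"),
    }
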