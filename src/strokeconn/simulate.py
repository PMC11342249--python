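"""Synthetic cohorts with known ground truth.

No public accession exists for the kind of clinical cohort this pipeline
analyses, so every stage is exercised on simulated data that emulates its
essential structure:

* a mirrored two-hemisphere atlas on the millimetre scale of a human brain
  (total extent ~140 mm);
* distance-dependent connectivity decay (expected streamline count falls
  exponentially with inter-centroid distance);
* contiguous left-hemisphere lesions whose damage fraction decays with
  distance from a lesion seed region, and which preferentially attenuate
  long-range connections (metabolically vulnerable fibres);
* behavioural scores generated as a linear function of age, years post
  stroke, lesion volume, key-region damage and the long-range fibre
  proportion, plus Gaussian noise, clipped to each instrument's scale.

Defaults mirror the cohort structure of the chronic left-hemisphere stroke
literature this package targets: n = 87, age ~ N(60.5, 11.2) within
[29, 80], years post stroke right-skewed with mean ~3.9, aetiology mix
57:23:7 (ischaemic : haemorrhagic : other), and four behavioural measures
on their native scales (WAB-AQ 0-100, PNT % correct, PPTT 0-52, WAIS
matrix reasoning scaled score 1-19).

The ratio effect can be planted either as a raw regression coefficient
(``ratio_effect_mode="beta"``) or as a target partial correlation
(``"partial_r"``): in the latter case the coefficient is solved per cohort
from the realized design so that the population correlation between
covariate-residualized behaviour and the raw ratio equals the target.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .atlas import DistanceBands, ROIAtlas, compute_distance_bands
from .connectome import (
    Connectome,
    fibre_length_profile,
    symmetrize_and_normalize,
    threshold_connectome,
)
from .errors import ValidationError

__all__ = [
    "MeasureTruth",
    "GroundTruth",
    "SyntheticCohort",
    "default_truth",
    "null_truth",
    "generate_atlas",
    "generate_lesion",
    "generate_connectome",
    "generate_behaviour",
    "simulate_cohort",
]

MEASURES = ("wab_aq", "pnt", "pptt", "matrix_reasoning")


@dataclass(frozen=True)
class MeasureTruth:
    """Generative parameters for one behavioural measure.

    ``n_key_regions`` plants that many "critical" left-hemisphere regions
    whose mean damage enters the score with coefficient ``beta_key``
    (0 regions mirrors measures for which lesion mapping finds nothing).
    ``ratio_effect`` is a coefficient when ``ratio_effect_mode="beta"`` or
    a target partial correlation when ``"partial_r"``.
    """

    intercept: float
    beta_age: float
    beta_ypo: float
    beta_lesion_volume: float
    beta_key: float
    noise_sd: float
    clip: Optional[Tuple[float, float]]
    n_key_regions: int
    ratio_effect: float
    ratio_effect_mode: str = "partial_r"

    def __post_init__(self):
        if self.ratio_effect_mode not in ("beta", "partial_r"):
            raise ValidationError(
                f"ratio_effect_mode must be 'beta' or 'partial_r', "
                f"got {self.ratio_effect_mode!r}"
            )
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.noise_sd == 0 and self.ratio_effect_mode == "partial_r":
            raise ValidationError(
                "partial_r planting needs noise_sd > 0 (a noise-free score "
                "has correlation 1 with its own linear predictor)"
            )


@dataclass(frozen=True)
class GroundTruth:
    """Full generative configuration for a cohort; stored alongside it.

    Regenerating with the same configuration (including ``seed``) is
    bit-identical: all randomness flows through one PCG64 generator.
    """

    seed: int
    n_subjects: int = 87
    n_regions_per_hemisphere: int = 20
    decay_mm: float = 45.0
    base_count: float = 5000.0
    dispersion: Optional[float] = 4.0
    long_range_attenuation: float = 2.5
    lesion_extent_mm: Tuple[float, float] = (25.0, 55.0)
    lesion_severity_beta: Tuple[float, float] = (2.0, 1.2)
    lesion_severity_max: float = 0.95
    damage_floor: float = 0.01
    aetiology_weights: Tuple[int, int, int] = (57, 23, 7)
    age_mean: float = 60.52
    age_sd: float = 11.24
    age_range: Tuple[float, float] = (29.0, 80.0)
    ypo_mean: float = 3.87
    ypo_sd: float = 3.98
    percentile: float = 0.20
    clip_scores: bool = True
    measures: Dict[str, MeasureTruth] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["measures"] = {m: asdict(t) for m, t in self.measures.items()}
        return d


def _default_measures() -> Dict[str, MeasureTruth]:
    return {
        "wab_aq": MeasureTruth(
            intercept=95.0, beta_age=-0.35, beta_ypo=0.8,
            beta_lesion_volume=-0.08, beta_key=-35.0, noise_sd=10.0,
            clip=(0.0, 100.0), n_key_regions=3, ratio_effect=0.331,
        ),
        "pnt": MeasureTruth(
            intercept=95.0, beta_age=-0.45, beta_ypo=1.2,
            beta_lesion_volume=-0.10, beta_key=-35.0, noise_sd=11.0,
            clip=(0.0, 100.0), n_key_regions=2, ratio_effect=0.254,
        ),
        "pptt": MeasureTruth(
            intercept=44.0, beta_age=0.0, beta_ypo=0.1,
            beta_lesion_volume=-0.12, beta_key=0.0, noise_sd=3.2,
            clip=(0.0, 52.0), n_key_regions=0, ratio_effect=0.297,
        ),
        "matrix_reasoning": MeasureTruth(
            intercept=12.0, beta_age=-0.08, beta_ypo=0.03,
            beta_lesion_volume=-0.01, beta_key=0.0, noise_sd=2.5,
            clip=(1.0, 19.0), n_key_regions=0, ratio_effect=0.402,
        ),
    }


def default_truth(seed: int, **overrides) -> GroundTruth:
    """The standard planted-effect cohort configuration."""
    measures = overrides.pop("measures", _default_measures())
    return GroundTruth(seed=seed, measures=measures, **overrides)


def null_truth(seed: int, **overrides) -> GroundTruth:
    """Global-null configuration: behaviour carries no lesion or ratio signal.

    Age and years-post-stroke effects are retained (they are independent of
    the lesion), but beta_key, beta_lesion_volume and the ratio effect are
    zero and no critical regions are planted, so any downstream detection
    is a false positive.  Used for type-I-error calibration.
    """
    measures = {
        m: replace(
            t,
            beta_key=0.0,
            beta_lesion_volume=0.0,
            n_key_regions=0,
            ratio_effect=0.0,
            ratio_effect_mode="beta",
        )
        for m, t in _default_measures().items()
    }
    return GroundTruth(seed=seed, measures=measures, **overrides)


@dataclass(frozen=True)
class SyntheticCohort:
    """A generated cohort plus everything needed to score recovery."""

    atlas: ROIAtlas
    bands: DistanceBands
    subjects: pd.DataFrame
    damage: pd.DataFrame
    connectomes: Dict[str, Connectome]
    profiles: pd.DataFrame
    truth: GroundTruth
    planted_regions: Dict[str, Tuple[int, ...]]
    key_damage_true: pd.DataFrame
    realized_beta_ratio: Dict[str, float]

    @property
    def ratios(self) -> pd.Series:
        return self.profiles["long_short_ratio"]


# ---------------------------------------------------------------------------
# atlas


def generate_atlas(n_regions_per_hemisphere: int, seed=None, rng=None) -> ROIAtlas:
    """Two mirrored hemispheric boxes of uniformly placed centroids.

    Left-hemisphere x in [-70, -10] mm, right is the sign-flipped mirror;
    y in [-85, 60], z in [-40, 55] (roughly MNI brain extent).  Volumes are
    log-normal around ~3.5 cm^3 per region.
    """
    if n_regions_per_hemisphere < 4:
        raise ValidationError(
            f"need >= 4 regions per hemisphere, got {n_regions_per_hemisphere}"
        )
    rng = rng if rng is not None else np.random.default_rng(seed)
    n = n_regions_per_hemisphere
    left = np.column_stack(
        [
            rng.uniform(-70.0, -10.0, n),
            rng.uniform(-85.0, 60.0, n),
            rng.uniform(-40.0, 55.0, n),
        ]
    )
    right = left * np.array([-1.0, 1.0, 1.0])
    volumes = rng.lognormal(mean=np.log(3500.0), sigma=0.45, size=2 * n)
    rows = []
    for i in range(n):
        rows.append((i + 1, f"L_region_{i + 1:02d}", "L", *left[i], volumes[i]))
    for i in range(n):
        rows.append((n + i + 1, f"R_region_{i + 1:02d}", "R", *right[i], volumes[n + i]))
    return ROIAtlas(
        pd.DataFrame(
            rows,
            columns=[
                "region_id", "name", "hemisphere",
                "centroid_x", "centroid_y", "centroid_z", "volume_mm3",
            ],
        )
    )


# ---------------------------------------------------------------------------
# lesions


def generate_lesion(atlas: ROIAtlas, truth: GroundTruth, rng) -> pd.Series:
    """One subject's per-region damage fractions.

    A lesion seed region is drawn among left-hemisphere regions (weighted
    toward the hemisphere's centre, like middle-cerebral-artery territory
    strokes), and damage decays exponentially with centroid distance from
    the seed, truncated below ``damage_floor`` to give lesions compact
    support.  Right-hemisphere damage is identically zero.
    """
    left_mask = atlas.table["hemisphere"].to_numpy() == "L"
    left_idx = np.flatnonzero(left_mask)
    cent = atlas.centroids
    centre = cent[left_idx].mean(axis=0)
    d_centre = np.linalg.norm(cent[left_idx] - centre, axis=1)
    # concentrate seeds centrally: these cohorts are dominated by
    # middle-cerebral-artery territory (peri-Sylvian) strokes
    w = np.exp(-d_centre / 15.0)
    seed_region = rng.choice(left_idx, p=w / w.sum())
    # severity skewed high: chronic aphasia cohorts have substantial core
    # damage (typical key-region damage fractions ~0.3-0.5, SD ~0.3)
    severity = rng.beta(*truth.lesion_severity_beta) * truth.lesion_severity_max
    extent = rng.uniform(*truth.lesion_extent_mm)
    d_seed = np.linalg.norm(cent - cent[seed_region], axis=1)
    damage = severity * np.exp(-d_seed / extent)
    damage[~left_mask] = 0.0
    damage[damage < truth.damage_floor] = 0.0
    return pd.Series(np.clip(damage, 0.0, 1.0), index=atlas.region_ids)


# ---------------------------------------------------------------------------
# connectomes


def generate_connectome(
    atlas: ROIAtlas,
    lesion_damage,
    decay_mm: float = 45.0,
    base_count: float = 5000.0,
    seed=None,
    rng=None,
    dispersion: Optional[float] = 4.0,
    long_range_attenuation: float = 2.5,
    bands: Optional[DistanceBands] = None,
    subject_id: str = "",
) -> Connectome:
    """Raw streamline-count matrix for one subject.

    Expected count for pair (i, j):

        mu = base_count * exp(-d_ij / decay_mm) * (1 - damage_i) * (1 - damage_j)

    with an extra ``exp(-long_range_attenuation * lesion_load)`` factor for
    pairs beyond the atlas Q3 distance (lesions hit long fibres hardest);
    ``lesion_load`` is the volume-weighted mean damage fraction over the
    lesioned (damage > 0) regions' hemisphere, so it is not diluted by the
    intact hemisphere.  Counts are
    drawn as overdispersed nonnegative integers (gamma-Poisson with shape
    ``dispersion``), independently per seeding direction, so the raw matrix
    is asymmetric like real tractography output.  ``dispersion=None`` turns
    noise off (counts are the rounded means).
    """
    if decay_mm <= 0:
        raise ValidationError(f"decay_mm must be > 0, got {decay_mm}")
    rng = rng if rng is not None else np.random.default_rng(seed)
    if bands is None:
        bands = compute_distance_bands(atlas)
    dmg = (
        lesion_damage.reindex(atlas.region_ids).to_numpy(float)
        if isinstance(lesion_damage, pd.Series)
        else np.asarray(lesion_damage, float)
    )
    if dmg.shape != (atlas.n_regions,):
        raise ValidationError("lesion_damage must align with the atlas regions")
    hemi = atlas.table["hemisphere"].to_numpy()
    lesioned_hemis = set(hemi[dmg > 0])
    load_mask = np.isin(hemi, sorted(lesioned_hemis)) if lesioned_hemis else slice(None)
    lesion_load = float(
        np.average(dmg[load_mask], weights=atlas.volumes[load_mask])
        if lesioned_hemis
        else 0.0
    )
    mu = (
        base_count
        * np.exp(-bands.distance / decay_mm)
        * np.outer(1.0 - dmg, 1.0 - dmg)
    )
    long_pairs = bands.distance > bands.q3_cutoff
    mu = np.where(
        long_pairs, mu * np.exp(-long_range_attenuation * lesion_load), mu
    )
    np.fill_diagonal(mu, 0.0)
    if dispersion is None:
        counts = np.round(mu)
    else:
        p = dispersion / (dispersion + mu)
        counts = rng.negative_binomial(dispersion, p).astype(float)
    np.fill_diagonal(counts, 0.0)
    return Connectome(
        weights=counts,
        region_ids=atlas.region_ids,
        stage="raw",
        subject_id=subject_id,
    )


# ---------------------------------------------------------------------------
# behaviour


def _solve_beta_for_partial_r(
    target_r: float, noise_sd: float, g: np.ndarray, X: np.ndarray
) -> float:
    """Coefficient on the ratio that yields a target residual correlation.

    With y = X b + beta_g * g + sigma * eps and g~ the part of g orthogonal
    to [1, X], the population correlation between the covariate residuals
    of y and the raw ratio g is

        rho = kappa * c / sqrt(c^2 + sigma^2),   c = beta_g * sd(g~),
        kappa = sd(g~) / sd(g),

    which inverts to c = sigma * (rho/kappa) / sqrt(1 - (rho/kappa)^2).
    """
    if target_r == 0.0:
        return 0.0
    Xc = np.column_stack([np.ones(len(g)), X])
    beta, *_ = np.linalg.lstsq(Xc, g, rcond=None)
    g_res = g - Xc @ beta
    sd_res, sd_g = g_res.std(), g.std()
    if sd_res <= 0 or sd_g <= 0:
        raise ValidationError("ratio has no variance after residualization")
    kappa = sd_res / sd_g
    rho = target_r / kappa
    if abs(rho) >= 0.999:
        raise ValidationError(
            f"target partial correlation {target_r} unattainable: the ratio "
            f"is too collinear with the covariates (kappa={kappa:.3f})"
        )
    c = noise_sd * rho / np.sqrt(1.0 - rho * rho)
    return float(c / sd_res)


def generate_behaviour(
    subjects: pd.DataFrame,
    ratios: pd.Series,
    key_true: Dict[str, Optional[pd.Series]],
    truth: GroundTruth,
    rng,
) -> Tuple[pd.DataFrame, Dict[str, float]]:
    """Behavioural scores for all measures plus the realized ratio betas.

    score = intercept + beta_age*age + beta_ypo*ypo + beta_lv*lesion_volume
            + beta_key*key_damage + beta_ratio*(ratio - mean(ratio)) + noise,
    clipped to the instrument's scale when ``truth.clip_scores``.  The ratio
    term is centred so the intercept stays the expected score at the
    cohort-mean fibre ratio regardless of the planted effect size; slopes
    and correlations are unaffected by the centring.
    """
    idx = subjects.index
    if not ratios.index.equals(idx):
        raise ValidationError("ratios not aligned with the subject table")
    age = subjects["age"].to_numpy(float)
    ypo = subjects["years_post_stroke"].to_numpy(float)
    lv = subjects["lesion_volume"].to_numpy(float)
    g = ratios.to_numpy(float)
    scores, realized = {}, {}
    for m, t in truth.measures.items():
        cols = [age, ypo, lv]
        linear = (
            t.intercept + t.beta_age * age + t.beta_ypo * ypo
            + t.beta_lesion_volume * lv
        )
        key = key_true.get(m)
        if t.beta_key != 0.0 and key is not None:
            linear = linear + t.beta_key * key.reindex(idx).to_numpy(float)
            cols.append(key.reindex(idx).to_numpy(float))
        if t.ratio_effect_mode == "beta":
            beta_g = t.ratio_effect
        else:
            beta_g = _solve_beta_for_partial_r(
                t.ratio_effect, t.noise_sd, g, np.column_stack(cols)
            )
        y = linear + beta_g * (g - g.mean()) + rng.normal(0.0, t.noise_sd, len(idx))
        if truth.clip_scores and t.clip is not None:
            y = np.clip(y, *t.clip)
        scores[m] = y
        realized[m] = beta_g
    return pd.DataFrame(scores, index=idx), realized


# ---------------------------------------------------------------------------
# whole cohorts


def select_planted_regions(atlas: ROIAtlas, k: int) -> Tuple[int, ...]:
    """The k left-hemisphere regions nearest the left-hemisphere centre.

    Central regions are the ones lesions most often reach, so planting the
    critical set there gives lesion-symptom mapping a fair target.  Nested
    by construction: the first 2 of 3 are the same regions for every k.
    """
    left = atlas.table[atlas.table["hemisphere"] == "L"]
    cent = left[["centroid_x", "centroid_y", "centroid_z"]].to_numpy(float)
    d = np.linalg.norm(cent - cent.mean(axis=0), axis=1)
    order = left["region_id"].to_numpy()[np.argsort(d, kind="stable")]
    return tuple(int(r) for r in order[:k])


def simulate_cohort(truth: GroundTruth) -> SyntheticCohort:
    """Generate a full cohort: atlas, lesions, connectomes, behaviour.

    All randomness flows through one generator seeded with ``truth.seed``,
    so regeneration is bit-identical.  The per-subject fibre ratios used to
    generate behaviour are the *measured* ones — the connectome pipeline
    (normalize, threshold at ``truth.percentile``, band counts) applied to
    the generated raw matrices — so planted effects refer to the quantity
    the analysis actually computes.
    """
    rng = np.random.default_rng(truth.seed)
    atlas = generate_atlas(truth.n_regions_per_hemisphere, rng=rng)
    bands = compute_distance_bands(atlas)
    n = truth.n_subjects
    subject_ids = [f"sub-{i + 1:03d}" for i in range(n)]

    age = np.clip(rng.normal(truth.age_mean, truth.age_sd, n), *truth.age_range)
    # right-skewed years post stroke (gamma matched to mean/SD), chronic stage
    shape = (truth.ypo_mean / truth.ypo_sd) ** 2
    scale = truth.ypo_sd**2 / truth.ypo_mean
    ypo = np.maximum(rng.gamma(shape, scale, n), 0.25)
    aet_p = np.array(truth.aetiology_weights, float)
    aetiology = rng.choice(
        ["ischaemic", "haemorrhagic", "other"], size=n, p=aet_p / aet_p.sum()
    )
    sex = rng.choice(["M", "F"], size=n, p=[52 / 87, 35 / 87])

    damage = pd.DataFrame(
        [generate_lesion(atlas, truth, rng) for _ in range(n)],
        index=pd.Index(subject_ids, name="subject_id"),
    )
    lesion_volume = (damage.to_numpy() * atlas.volumes[None, :]).sum(axis=1) / 1000.0

    connectomes, prof_rows = {}, []
    for sid in subject_ids:
        raw = generate_connectome(
            atlas,
            damage.loc[sid],
            decay_mm=truth.decay_mm,
            base_count=truth.base_count,
            rng=rng,
            dispersion=truth.dispersion,
            long_range_attenuation=truth.long_range_attenuation,
            bands=bands,
            subject_id=sid,
        )
        connectomes[sid] = raw
        thresh = threshold_connectome(
            symmetrize_and_normalize(raw, atlas), truth.percentile
        )
        p = fibre_length_profile(thresh, bands)
        prof_rows.append(
            (sid, p.n_short, p.n_medium, p.n_long, p.long_short_ratio,
             p.threshold_cutoff)
        )
    profiles = pd.DataFrame(
        prof_rows,
        columns=["subject_id", "n_short", "n_medium", "n_long",
                 "long_short_ratio", "threshold_cutoff"],
    ).set_index("subject_id")

    subjects = pd.DataFrame(
        {
            "age": age,
            "years_post_stroke": ypo,
            "sex": sex,
            "aetiology": aetiology,
            "lesion_volume": lesion_volume,
        },
        index=pd.Index(subject_ids, name="subject_id"),
    )

    planted = {
        m: select_planted_regions(atlas, t.n_key_regions)
        for m, t in truth.measures.items()
    }
    key_true = {
        m: (damage[list(regs)].mean(axis=1) if regs else None)
        for m, regs in planted.items()
    }
    scores, realized = generate_behaviour(
        subjects, profiles["long_short_ratio"], key_true, truth, rng
    )
    subjects = pd.concat([subjects, scores], axis=1)

    key_df = pd.DataFrame(
        {m: (s if s is not None else np.nan) for m, s in key_true.items()},
        index=subjects.index,
    )
    return SyntheticCohort(
        atlas=atlas,
        bands=bands,
        subjects=subjects,
        damage=damage,
        connectomes=connectomes,
        profiles=profiles,
        truth=truth,
        planted_regions=planted,
        key_damage_true=key_df,
        realized_beta_ratio=realized,
    )
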