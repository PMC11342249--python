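"""End-to-end orchestration: inputs -> every stage -> audited CSV outputs.

Stage order follows the analysis design: aetiology ANOVA first (confound
check), then lesion-symptom mapping per measure, then the covariate OLS,
then the residual-ratio correlations.  Each run writes its resolved
configuration and a provenance record next to the outputs; rerunning with
the same configuration and seed is byte-identical.
"""

from __future__ import annotations

import logging
import platform
from pathlib import Path
from typing import Dict, Optional

import pandas as pd

from . import __version__
from .atlas import ROIAtlas
from .errors import StrokeconnError
from .io import (
    FLOAT_FORMAT,
    RunConfig,
    read_connectome_tsv,
    read_damage_csv,
    read_subjects_csv,
)
from .model import LongRangeModel, LongRangeResults, compute_profiles
from .simulate import default_truth, simulate_cohort

log = logging.getLogger("strokeconn")

__all__ = ["run_all", "load_inputs", "write_results"]


def load_inputs(config: RunConfig):
    """Load (or simulate) atlas, subjects, damage and raw connectomes."""
    if config.simulate:
        cohort = simulate_cohort(
            default_truth(
                config.seed,
                n_subjects=config.n_subjects,
                n_regions_per_hemisphere=config.n_regions_per_hemisphere,
                percentile=config.percentile,
            )
        )
        return cohort.atlas, cohort.subjects, cohort.damage, cohort.connectomes
    atlas = ROIAtlas.from_csv(config.atlas_path)
    subjects = read_subjects_csv(config.subjects_path)
    damage = read_damage_csv(config.damage_path)
    connectomes = {}
    matrix_dir = Path(config.matrix_dir)
    for path in sorted(matrix_dir.glob("*.tsv")):
        connectomes[path.stem] = read_connectome_tsv(path)
    if not connectomes:
        raise StrokeconnError(f"no .tsv connectome matrices found in {matrix_dir}")
    return atlas, subjects, damage, connectomes


def write_results(
    results: LongRangeResults,
    profiles: pd.DataFrame,
    config: RunConfig,
    out_dir: Path,
) -> Dict[str, str]:
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    profiles.to_csv(out_dir / "profiles.csv", float_format=FLOAT_FORMAT)
    paths["profiles"] = str(out_dir / "profiles.csv")

    if results.anova is not None:
        a = results.anova
        anova_df = pd.DataFrame(
            {
                "group": a.group_means.index,
                "mean_ratio": a.group_means.to_numpy(),
                "n": a.group_sizes.reindex(a.group_means.index).to_numpy(),
                "F": a.fvalue,
                "p": a.pvalue,
                "df_between": a.df_between,
                "df_within": a.df_within,
            }
        )
        anova_df.to_csv(out_dir / "anova.csv", index=False, float_format=FLOAT_FORMAT)
        paths["anova"] = str(out_dir / "anova.csv")

    for m, lsm in results.lsm.items():
        p = out_dir / f"lsm_{m}.csv"
        lsm.table.to_csv(p, index=False, float_format=FLOAT_FORMAT)
        lsm.excluded.to_csv(
            out_dir / f"lsm_{m}_excluded.csv", index=False, float_format=FLOAT_FORMAT
        )
        paths[f"lsm_{m}"] = str(p)

    results.modelfit_table().to_csv(out_dir / "modelfit.csv", float_format=FLOAT_FORMAT)
    paths["modelfit"] = str(out_dir / "modelfit.csv")

    results.associations.to_csv(
        out_dir / "associations.csv", index=False, float_format=FLOAT_FORMAT
    )
    paths["associations"] = str(out_dir / "associations.csv")

    config.to_yaml(out_dir / "resolved_config.yaml")
    paths["config"] = str(out_dir / "resolved_config.yaml")
    with open(out_dir / "provenance.txt", "w") as fh:
        fh.write(
            f"strokeconn {__version__}\n"
            f"python {platform.python_version()}\n"
            f"seed {config.seed}\n"
        )
    return paths


def run_all(config: RunConfig) -> LongRangeResults:
    """Run the full pipeline per ``config`` and write all outputs."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    stage = "load inputs"
    try:
        atlas, subjects, damage, connectomes = load_inputs(config)
        log.info(
            "loaded %d subjects, %d regions, %d connectomes",
            len(subjects), atlas.n_regions, len(connectomes),
        )
        stage = "connectome metrics"
        profiles = compute_profiles(
            connectomes,
            atlas,
            percentile=config.percentile,
            percentile_method=config.percentile_method,
            ratio_mode=config.ratio_mode,
        )
        log.info(
            "profiles computed for %d subjects (percentile %.2f, mode %s)",
            len(profiles), config.percentile, config.ratio_mode,
        )

        # stages communicate through the interchange format: the profiles
        # table is written and read back, so a run-all is exactly the
        # composition of the stage commands on the same files
        profiles.to_csv(out_dir / "profiles.csv", float_format="%.12g")
        profiles = pd.read_csv(out_dir / "profiles.csv", index_col=0)

        stage = "behavioural analysis"
        model = LongRangeModel(
            subjects=subjects,
            ratios=profiles["long_short_ratio"],
            damage=damage,
            measures=[m for m in config.measures if m in subjects.columns],
            atlas=atlas,
            candidate_hemisphere=config.candidate_hemisphere,
            min_affected=config.min_affected,
            q_lsm=config.q_lsm,
            q_association=config.q_association,
            association_mode=config.association_mode,
        )
        results = model.fit()
        for m, lsm in results.lsm.items():
            log.info(
                "LSM %s: %d tested, %d excluded, %d significant",
                m, len(lsm.table), len(lsm.excluded),
                len(lsm.significant_regions),
            )
        stage = "write outputs"
        write_results(results, profiles, config, out_dir)
    except StrokeconnError as e:
        raise StrokeconnError(f"pipeline failed at stage '{stage}': {e}") from e
    return results
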