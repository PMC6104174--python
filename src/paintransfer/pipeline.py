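"""End-to-end pipeline driver: simulate -> fit -> predict -> diff -> map -> report.

Every random operation draws from a sub-stream of the single top-level seed,
so identical configurations produce byte-identical tabular outputs. A manifest
of every artifact with SHA-256 checksums is written alongside the report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .config import PipelineConfig
from .differences import DifferenceMetrics, compute_difference_metrics
from .maps import CorrelationReport, PairVectors, build_pair_vectors, correlate_all
from .plsr import PLSRModel, VoxelStatMap, fit_individual, group_predictive_map
from .simulate import GroundTruth, IndividualDataset, generate_cohort
from .transfer import PairwiseErrorMatrix, WithinBetweenReport, compare_within_between, \
    pairwise_predict

logger = logging.getLogger(__name__)


@dataclass
class RunReport:
    """Everything a run computed, plus where it was written."""

    config: PipelineConfig
    datasets: list[IndividualDataset]
    ground_truth: GroundTruth
    models: list[PLSRModel]
    errors: PairwiseErrorMatrix
    comparison: WithinBetweenReport | None
    differences: DifferenceMetrics
    pair_vectors: PairVectors
    group_map: VoxelStatMap | None
    correlations: CorrelationReport | None
    summary: dict
    out_dir: Path | None = None
    manifest: dict | None = None


def analyze_cohort(config: PipelineConfig, datasets=None, ground_truth=None):
    """Run the analysis stages in memory; generation is skipped when a cohort
    is passed in. Returns a RunReport without any files written."""
    config.validate()
    cohort_cfg = config.resolved_cohort()
    if datasets is None:
        logger.info("simulate: %d individuals, %d trials, grid %s, seed %d",
                    cohort_cfg.n_individuals, cohort_cfg.n_trials,
                    cohort_cfg.grid_shape, cohort_cfg.seed)
        datasets, ground_truth = generate_cohort(cohort_cfg)

    logger.info("fit: SIMPLS per individual (r2>=%.2f, cap %d)",
                config.r2_threshold, config.max_components)
    models = [
        fit_individual(ds, config.r2_threshold, config.max_components)
        for ds in datasets
    ]
    n = len(models)
    if n >= 3:
        group_map = group_predictive_map(models, alpha=config.alphas[0])
    else:
        logger.warning("fewer than 3 individuals: group map skipped")
        group_map = None

    logger.info("predict: %d x %d pairwise scheme", n, n)
    errors = pairwise_predict(models, datasets, within_mode=config.within_mode)
    comparison = compare_within_between(errors, test_variant=config.test_variant) \
        if n >= 3 else None

    logger.info("diff: %s Bhattacharyya estimator", config.estimator)
    diffs = compute_difference_metrics(datasets, estimator=config.estimator)
    pairs = build_pair_vectors(errors, diffs)

    if len(pairs.mae) >= 3:
        logger.info("map: correlations across %d between-individual pairs", len(pairs.mae))
        correlations = correlate_all(pairs, alphas=config.alphas)
    else:
        logger.warning("fewer than 3 between-individual pairs: correlations skipped")
        correlations = None

    summary = {
        "n_individuals": len(datasets),
        "n_trials_per_individual": int(datasets[0].n_trials),
        "n_prediction_pairs": len(datasets) ** 2,
        "n_between_pairs": len(pairs.mae),
        "n_within_pairs": len(datasets),
        "mae_between_mean": float(pairs.mae.mean()),
        "mae_between_sd": float(pairs.mae.std(ddof=1)) if len(pairs.mae) > 1 else 0.0,
        "mpb_between_mean": float(pairs.mpb.mean()),
        "mpb_between_sd": float(pairs.mpb.std(ddof=1)) if len(pairs.mpb) > 1 else 0.0,
        "mae_within_mean": float(errors.within("mae").mean()),
        "mpb_within_mean": float(errors.within("mpb").mean()),
    }
    if comparison is not None:
        summary["mae_within_between_p"] = comparison.mae.p_value
        summary["mpb_within_between_p"] = comparison.mpb.p_value
    if correlations is not None:
        summary.update({
            "r_dist_pain_mae": correlations.r_dist_pain_mae,
            "p_dist_pain_mae": correlations.p_dist_pain_mae,
            "r_diff_pain_mpb": correlations.r_diff_pain_mpb,
            "p_diff_pain_mpb": correlations.p_diff_pain_mpb,
            "dist_bold_mae_significant_voxels": {
                str(a): int(m.significant.sum())
                for a, m in correlations.dist_bold_mae_maps.items()
            },
            "diff_bold_mpb_significant_voxels": {
                str(a): int(m.significant.sum())
                for a, m in correlations.diff_bold_mpb_maps.items()
            },
        })
    if group_map is not None:
        summary["group_map_significant_voxels"] = int(group_map.significant.sum())
    return RunReport(config, datasets, ground_truth, models, errors, comparison,
                     diffs, pairs, group_map, correlations, summary)


def _write_outputs(report: RunReport, out_dir: Path) -> None:
    cfg = report.config
    grid = cfg.resolved_cohort().grid_shape
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts = []

    io.write_config(cfg, out_dir / "config.yaml")
    artifacts.append(out_dir / "config.yaml")

    data_dir = out_dir / "data"
    data_dir.mkdir(exist_ok=True)
    for ds in report.datasets:
        p = data_dir / f"{ds.individual_id}_ratings.csv"
        io.write_ratings_table(ds, p)
        artifacts.append(p)
    mask = np.ones(grid, dtype=bool)
    io.save_mask(mask, out_dir / "mask.nii")
    artifacts.append(out_dir / "mask.nii")

    model_dir = out_dir / "models"
    for m in report.models:
        io.save_model(m, grid, model_dir)
        artifacts += [model_dir / f"{m.individual_id}_coef.nii",
                      model_dir / f"{m.individual_id}_model.json"]

    ids = report.errors.ids
    for name, mat in (("mae", report.errors.mae), ("mpb", report.errors.mpb),
                      ("dist_pain", report.differences.dist_pain),
                      ("diff_pain", report.differences.diff_pain)):
        p = out_dir / f"{name}_matrix.csv"
        io.write_matrix(mat, ids, p)
        artifacts.append(p)
    report.pair_vectors.pair_index.to_csv(out_dir / "pair_index.csv", index=False)
    artifacts.append(out_dir / "pair_index.csv")

    maps_dir = out_dir / "maps"
    maps_dir.mkdir(exist_ok=True)
    if report.group_map is not None:
        io.save_volume(report.group_map.statistic, maps_dir / "group_t.nii", grid_shape=grid)
        io.save_volume(report.group_map.p_value, maps_dir / "group_p.nii", grid_shape=grid)
        io.save_volume(report.group_map.significant.astype(float),
                       maps_dir / "group_sig.nii", grid_shape=grid)
        artifacts += [maps_dir / "group_t.nii", maps_dir / "group_p.nii",
                      maps_dir / "group_sig.nii"]
    if report.correlations is not None:
        for label, maps in (("dist_bold_mae", report.correlations.dist_bold_mae_maps),
                            ("diff_bold_mpb", report.correlations.diff_bold_mpb_maps)):
            first = next(iter(maps.values()))
            io.save_volume(first.statistic, maps_dir / f"{label}_r.nii", grid_shape=grid)
            io.save_volume(first.p_value, maps_dir / f"{label}_p.nii", grid_shape=grid)
            artifacts += [maps_dir / f"{label}_r.nii", maps_dir / f"{label}_p.nii"]
            for a, m in maps.items():
                p = maps_dir / f"{label}_sig_alpha_{a:g}.nii"
                io.save_volume(m.significant.astype(float), p, grid_shape=grid)
                artifacts.append(p)

    # KDE curves as (grid, density) tables
    if report.comparison is not None:
        for metric in ("mae", "mpb"):
            comp = getattr(report.comparison, metric)
            for group in ("between", "within"):
                dens = getattr(comp, f"{group}_density")
                p = out_dir / f"{metric}_{group}_density.csv"
                pd.DataFrame({"grid": dens.grid, "density": dens.density}).to_csv(p, index=False)
                artifacts.append(p)

    (out_dir / "report.json").write_text(json.dumps(report.summary, indent=2))
    artifacts.append(out_dir / "report.json")
    report.manifest = io.write_manifest(artifacts, out_dir / "manifest.json")
    report.out_dir = out_dir


def run_pipeline(config: PipelineConfig, out_dir=None) -> RunReport:
    """Execute the full pipeline; write all artifacts when out_dir is given."""
    try:
        report = analyze_cohort(config)
    except Exception as exc:  # annotate with the failing stage for the CLI
        raise type(exc)(f"pipeline failed: {exc}") from exc
    if out_dir is not None:
        _write_outputs(report, Path(out_dir))
    return report
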