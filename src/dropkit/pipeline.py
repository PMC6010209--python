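"""End-to-end orchestration of the correction stages.

Fixed stage order: UMI error correction first (barcode merging compares
gene-UMI sets, which should be error-free), then cellular-barcode merging,
then collision adjustment (sizes change under merging), then cell quality
classification.  Every stage can be disabled through the configuration and
disabling a stage never changes the output of earlier stages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from dropkit import cb_correction, cell_quality, umi_correction
from dropkit.config import RunConfig
from dropkit.diagnostics import run_report
from dropkit.records import CountMatrix, Dataset, read_whitelist
from dropkit.umi_distribution import (
    UmiDistribution,
    adjust_counts,
    build_collision_table,
    estimate_umi_distribution,
)

logger = logging.getLogger("dropkit")


@dataclass
class PipelineResult:
    matrix: CountMatrix
    data: Dataset
    merge_plan: cb_correction.MergePlan | None
    umi_audit: pd.DataFrame | None
    thresholds: cell_quality.SizeThresholds | None
    scores: pd.Series | None
    cell_table: pd.DataFrame | None
    report: dict
    config: RunConfig


def run_pipeline(cfg: RunConfig, data: Dataset) -> PipelineResult:
    stages: dict = {}
    umi_audit = None
    dist = estimate_umi_distribution(data) if len(data) else None

    # 1. UMI sequence error correction
    if cfg.umi_method != "none" and len(data):
        before = len(data)
        if cfg.umi_method == "bayesian":
            try:
                qm = umi_correction.train_quality_model(
                    data, cfg.umi_k_quantiles, dist=dist
                )
            except ValueError:
                logger.warning(
                    "no quality-model training pairs; falling back to cluster filtering"
                )
                data = umi_correction.filter_dataset(data, "cluster")
                qm = None
            if qm is not None:
                prior = umi_correction.AdjacencyPrior(data.umi_length, cfg.umi_dp_step)
                data, umi_audit = umi_correction.bayesian_filter(
                    data,
                    dist,
                    qm,
                    prior,
                    max_iterations=cfg.umi_max_iterations,
                    collect_audit=True,
                )
        else:
            data = umi_correction.filter_dataset(data, cfg.umi_method)
        stages["umi_correction"] = {
            "method": cfg.umi_method,
            "removed_molecules": before - len(data),
        }

    # 2. cellular barcode merging
    plan = None
    if cfg.cb_method != "none" and len(data):
        comps = cb_correction.build_compositions(data)
        table = build_collision_table(dist) if cfg.collision_adjustment != "none" else None
        if cfg.cb_method == "poisson":
            plan = cb_correction.merge_poisson(
                comps, dist, table, cfg.cb_max_hamming, cfg.merge_alpha
            )
        elif cfg.cb_method == "simple":
            plan = cb_correction.merge_simple(comps, cfg.cb_max_hamming)
        else:
            wl = read_whitelist(cfg.cb_whitelist)
            plan = cb_correction.merge_known_barcodes(
                comps, wl, dist, table, cfg.cb_max_hamming
            )
        data = cb_correction.apply_merge(data, plan)
        stages["cb_merge"] = {"method": cfg.cb_method, "n_merges": len(plan)}

    # 3. collision adjustment of the count matrix
    matrix = CountMatrix.from_dataset(data)
    if cfg.collision_adjustment != "none" and len(data):
        if cfg.collision_adjustment == "uniform":
            adj_dist = UmiDistribution.uniform_pool(data.umi_length)
        else:
            adj_dist = estimate_umi_distribution(data)
        table = build_collision_table(adj_dist)
        matrix = adjust_counts(matrix, table)
        stages["collision_adjustment"] = {"method": cfg.collision_adjustment}

    # 4. cell quality classification
    thresholds = scores = cell_table = None
    if cfg.quality_enabled and len(data):
        sizes = data.cell_sizes()
        try:
            if cfg.manual_thresholds is not None:
                thresholds = cell_quality.SizeThresholds(*cfg.manual_thresholds)
            else:
                thresholds = cell_quality.size_thresholds(sizes.to_numpy())
            mito = None
            if cfg.mito_genes:
                with open(cfg.mito_genes) as fh:
                    mito = {line.strip() for line in fh if line.strip()}
            features = cell_quality.extract_features(data, mito)
            labels = cell_quality.initial_labels(sizes, thresholds)
            clf = cell_quality.train_quality_classifier(
                features, labels, random_state=cfg.seed
            )
            scores = cell_quality.score_cells(clf, features)
            genes_per_cell = (
                data.df.loc[~data.df["intergenic"]].groupby("cb")["gene"].nunique()
            )
            cell_table = cell_quality.filter_cells(
                scores,
                sizes,
                thresholds,
                genes_per_cell,
                cfg.quality_keep_hi,
                cfg.quality_drop_lo,
                cfg.quality_min_genes,
            )
            stages["cell_quality"] = {
                "t_l": thresholds.t_l,
                "t_u": thresholds.t_u,
                "n_kept": int(cell_table["kept"].sum()),
            }
        except ValueError as exc:
            logger.warning("cell quality stage skipped: %s", exc)
            stages["cell_quality"] = {"skipped": str(exc)}

    report = run_report(data, stages, seed=cfg.seed, config=cfg.to_dict())
    return PipelineResult(
        matrix, data, plan, umi_audit, thresholds, scores, cell_table, report, cfg
    )
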