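"""End-to-end orchestration of the dosage-imbalance DE pipeline.

Stages: TMM normalization -> NB dispersion estimation -> QL F-tests for the
KD and OE contrasts -> MAS ranking -> Cross-MAS partition -> candidate pool
-> Spearman/directionality panel selection -> PCA + logistic-regression
discriminability of the panel vs the whole transcriptome.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, glmql, normalization, prioritize
from .io import (
    CountMatrix,
    PipelineConfig,
    SampleTable,
    check_consistency,
    write_deg_table,
    write_table,
)
from .mas import CrossMasPartition, crossmas_partition

logger = logging.getLogger("crossmas")


@dataclass
class PipelineResult:
    config: PipelineConfig
    counts: CountMatrix
    samples: SampleTable
    norm: normalization.NormalizationResult
    logcpm: pd.DataFrame                # genes x samples, log2-CPM
    dispersions: glmql.DispersionModel
    deg_kd: pd.DataFrame
    deg_oe: pd.DataFrame
    partition: CrossMasPartition
    pool: list[str]
    rho: pd.Series
    panel: pd.DataFrame
    report_panel: classify.ClassificationReport | None
    report_all: classify.ClassificationReport
    retained_genes: tuple[str, ...] = field(default_factory=tuple)


def run_pipeline(
    counts: CountMatrix, samples: SampleTable, config: PipelineConfig | None = None
) -> PipelineResult:
    """Run every stage on a count matrix + sample table."""
    config = config or PipelineConfig()
    check_consistency(counts, samples)
    # align metadata order with count matrix columns
    cond_of = dict(zip(samples.sample_ids, samples.conditions))
    samples = SampleTable(
        counts.sample_ids,
        tuple(cond_of[s] for s in counts.sample_ids),
        labels=samples.labels,
    )

    t0 = time.perf_counter()
    # drop genes with zero counts everywhere (cannot be fit)
    keep = counts.counts.sum(axis=1) > 0
    if not keep.all():
        logger.info("dropping %d all-zero genes", int((~keep).sum()))
        counts_fit = CountMatrix(
            tuple(g for g, k in zip(counts.gene_ids, keep) if k),
            counts.sample_ids,
            counts.counts[keep],
        )
    else:
        counts_fit = counts

    norm = normalization.tmm_factors(
        counts_fit, trim_m=config.trim_m, trim_a=config.trim_a
    )
    logcpm = pd.DataFrame(
        normalization.cpm_matrix(
            counts_fit, norm, log2=True, prior_count=config.log_prior_count
        ),
        index=list(counts_fit.gene_ids),
        columns=list(counts_fit.sample_ids),
    )
    logger.info("normalization done in %.1fs", time.perf_counter() - t0)

    design, _ = glmql.build_design(samples)
    offsets = np.log(norm.effective_lib_sizes)
    t0 = time.perf_counter()
    disp = glmql.estimate_dispersions(counts_fit, design, offsets)
    logger.info(
        "dispersions done in %.1fs (common=%.4g, prior_df=%.3g)",
        time.perf_counter() - t0, disp.common_dispersion, disp.prior_df,
    )

    t0 = time.perf_counter()
    deg = {}
    for contrast in ("kd", "oe"):
        deg[contrast] = glmql.ql_ftest(
            counts_fit, design, offsets, disp, contrast,
            lfc_threshold=config.lfc_threshold, alpha=config.alpha,
            mas_M=config.mas_M, mas_A=config.mas_A,
        )
    logger.info("QL F-tests done in %.1fs", time.perf_counter() - t0)

    partition = crossmas_partition(
        deg["kd"], deg["oe"], config.driver_gene, cfg=config
    )
    pool = prioritize.candidate_pool(partition, config.top_k_per_set)
    rho = prioritize.spearman_with_driver(logcpm, config.driver_gene, pool) \
        if pool else pd.Series(dtype=float)
    panel = prioritize.select_panel(
        pool, rho, deg["kd"], deg["oe"], partition, config
    )

    report_all = classify.evaluate_features(
        logcpm, samples, genes=None, n_components=config.n_components,
        feature_set_label="all_genes",
    )
    report_panel = None
    if len(panel) >= config.n_components:
        report_panel = classify.evaluate_features(
            logcpm, samples, genes=list(panel["gene_id"]),
            n_components=config.n_components, feature_set_label="panel",
        )

    return PipelineResult(
        config=config,
        counts=counts,
        samples=samples,
        norm=norm,
        logcpm=logcpm,
        dispersions=disp,
        deg_kd=deg["kd"],
        deg_oe=deg["oe"],
        partition=partition,
        pool=pool,
        rho=rho,
        panel=panel,
        report_panel=report_panel,
        report_all=report_all,
        retained_genes=counts_fit.gene_ids,
    )


def write_outputs(result: PipelineResult, outdir: str | Path) -> None:
    """Write every stage's artifact as TSV/JSON under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    norm_frame = pd.DataFrame(
        {
            "sample_id": list(result.counts.sample_ids),
            "factor": result.norm.factors,
            "lib_size": result.counts.library_sizes,
        }
    )
    write_table(norm_frame, outdir / "norm_factors.tsv")
    write_deg_table(result.deg_kd, outdir / "deg_kd.tsv")
    write_deg_table(result.deg_oe, outdir / "deg_oe.tsv")
    write_table(result.partition.detail, outdir / "crossmas_partition.tsv")
    panel = result.panel.rename(
        columns={"log2fc": "log2FC", "p_bh": "FDR"}
    )
    write_table(panel, outdir / "panel.tsv")

    reports = [classify.report_to_dict(result.report_all)]
    if result.report_panel is not None:
        reports.append(classify.report_to_dict(result.report_panel))
    with open(outdir / "classification_report.json", "w") as fh:
        json.dump(reports, fh, indent=2, sort_keys=True)
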