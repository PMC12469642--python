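"""Candidate pooling and dosage-sensitive panel selection.

From the Cross-MAS partition, the top-k genes of each *unique* set form a
candidate pool. Candidates are then filtered by (i) absolute Spearman
correlation with the dosage-driver gene across all samples (log2-CPM scale)
and (ii) directionality agreement with driver dosage: only genes
downregulated under driver knockdown (source kd_only_down, log2FC < 0) or
upregulated under driver overexpression (source oe_only_up, log2FC > 0)
are retained, i.e. genes whose expression tracks the driver positively.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io import PipelineConfig, ValidationError
from .mas import CrossMasPartition

logger = logging.getLogger("crossmas")

PANEL_COLUMNS = ["gene_id", "source", "log2fc", "rho", "p_bh"]


def candidate_pool(partition: CrossMasPartition, k: int) -> list[str]:
    """First min(k, |set|) genes of each unique set, in set order
    (kd_only_up, kd_only_down, oe_only_up, oe_only_down)."""
    if k < 0:
        raise ValidationError("k must be >= 0")
    pool: list[str] = []
    for name in ("kd_only_up", "kd_only_down", "oe_only_up", "oe_only_down"):
        pool.extend(partition.sets()[name][:k])
    return pool


def spearman_with_driver(
    logexpr: pd.DataFrame, driver_gene: str, genes: list[str]
) -> pd.Series:
    """Spearman rho of each gene against the driver across all samples.

    ``logexpr`` is genes x samples (log2-CPM). Ties get average ranks. A
    zero-variance gene is reported as rho = 0 with a warning instead of NaN.
    """
    if driver_gene not in logexpr.index:
        raise ValidationError(f"driver gene {driver_gene!r} not in expression matrix")
    if logexpr.shape[1] < 3:
        raise ValidationError("Spearman correlation needs at least 3 samples")
    missing = [g for g in genes if g not in logexpr.index]
    if missing:
        raise ValidationError(f"genes not in expression matrix: {missing[:5]}")
    driver = logexpr.loc[driver_gene].to_numpy()
    out = {}
    for g in genes:
        x = logexpr.loc[g].to_numpy()
        if np.ptp(x) == 0 or np.ptp(driver) == 0:
            logger.warning("zero-variance expression for %r; rho set to 0", g)
            out[g] = 0.0
        else:
            out[g] = float(stats.spearmanr(x, driver).statistic)
    return pd.Series(out, name="rho")


def select_panel(
    pool: list[str],
    rho: pd.Series,
    kd: pd.DataFrame,
    oe: pd.DataFrame,
    partition: CrossMasPartition,
    cfg: PipelineConfig,
) -> pd.DataFrame:
    """Filter the pool to the final panel, sorted by |rho| descending.

    Keeps pool genes with |rho| strictly above the threshold whose source
    set agrees with driver dosage (kd_only_down or oe_only_up); the
    kd_only_up and oe_only_down sources are excluded by the directionality
    rule. Empty result is a warning, not an error.
    """
    source_of: dict[str, str] = {}
    for name, genes in partition.sets().items():
        for g in genes:
            source_of[g] = name
    kd_lfc = dict(zip(kd["gene_id"], kd["log2fc"]))
    kd_p = dict(zip(kd["gene_id"], kd["p_bh"]))
    oe_lfc = dict(zip(oe["gene_id"], oe["log2fc"]))
    oe_p = dict(zip(oe["gene_id"], oe["p_bh"]))

    rows = []
    for g in pool:
        if g == cfg.driver_gene:
            continue
        r = float(rho[g])
        if abs(r) <= cfg.rho_threshold:
            continue
        if cfg.require_positive_rho and r <= 0:
            continue
        src = source_of[g]
        if src == "kd_only_down":
            lfc, p_bh = kd_lfc[g], kd_p[g]
            assert lfc < 0, "kd_only_down member with non-negative log2FC"
            rows.append((g, "kd_down", lfc, r, p_bh))
        elif src == "oe_only_up":
            lfc, p_bh = oe_lfc[g], oe_p[g]
            assert lfc > 0, "oe_only_up member with non-positive log2FC"
            rows.append((g, "oe_up", lfc, r, p_bh))
        # kd_only_up / oe_only_down: excluded by directionality
    if not rows:
        logger.warning("panel selection produced an empty panel")
    panel = pd.DataFrame(rows, columns=PANEL_COLUMNS)
    if len(panel):
        panel = panel.sort_values(
            by=["rho", "gene_id"],
            key=lambda s: -s.abs() if s.name == "rho" else s,
        ).reset_index(drop=True)
    return panel
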