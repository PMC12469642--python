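"""Magnitude-Altitude scoring and the Cross-MAS partition.

A gene's Magnitude-Altitude Score combines effect size and significance:

    MAS = |log2FC|^M * |log10 p_BH|^A        (defaults M = A = 1)

Rank 1 is the gene with the largest MAS. Cross-MAS aggregates ranks across
the two contrasts (KD vs reference, OE vs reference): each gene's worst
(maximum) rank is taken and genes with the smallest worst rank are
preferred, which splits significant genes into contrast-unique and shared
up/down sets. The dosage-driver gene itself is removed before partitioning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import PipelineConfig, ValidationError


def mas_score(
    log2fc: np.ndarray | float,
    p_bh: np.ndarray | float,
    M: float = 1.0,
    A: float = 1.0,
) -> np.ndarray | float:
    """|log2fc|^M * |log10 p_bh|^A; p_bh must lie in (0, 1]."""
    lfc = np.asarray(log2fc, dtype=float)
    p = np.asarray(p_bh, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p_bh must lie in (0, 1]; floor p-values first")
    score = np.abs(lfc) ** M * np.abs(np.log10(p)) ** A
    return float(score) if np.isscalar(log2fc) and np.isscalar(p_bh) else score


def rank_by_mas(table: pd.DataFrame) -> pd.DataFrame:
    """Attach MAS ranks: descending MAS, ties by smaller p_bh, then larger
    |log2fc|, then lexicographic gene id (fully deterministic)."""
    order = sorted(
        range(len(table)),
        key=lambda i: (
            -table["mas"].iat[i],
            table["p_bh"].iat[i],
            -abs(table["log2fc"].iat[i]),
            table["gene_id"].iat[i],
        ),
    )
    ranks = np.empty(len(table), dtype=int)
    ranks[order] = np.arange(1, len(table) + 1)
    out = table.copy()
    out["rank"] = ranks
    return out


def significant_sets(
    table: pd.DataFrame, cfg: PipelineConfig
) -> tuple[set[str], set[str]]:
    """(up, down) gene sets at BH p < alpha and |log2FC| strictly above the
    fold-change threshold."""
    sig = table["p_bh"] < cfg.alpha
    up = set(table.loc[sig & (table["log2fc"] > cfg.lfc_threshold), "gene_id"])
    down = set(table.loc[sig & (table["log2fc"] < -cfg.lfc_threshold), "gene_id"])
    return up, down


@dataclass
class CrossMasPartition:
    """Six disjoint ordered gene lists plus a discordant overflow list.

    Unique sets are ordered by their own contrast's MAS rank (ascending);
    shared sets by the worst-of-two (max) rank, ties by the better (min)
    rank then gene id. ``detail`` holds per-gene ranks and set membership.
    """

    kd_only_up: list[str]
    kd_only_down: list[str]
    oe_only_up: list[str]
    oe_only_down: list[str]
    shared_up: list[str]
    shared_down: list[str]
    discordant: list[str] = field(default_factory=list)
    detail: pd.DataFrame = field(default_factory=pd.DataFrame)

    def sets(self) -> dict[str, list[str]]:
        return {
            "kd_only_up": self.kd_only_up,
            "kd_only_down": self.kd_only_down,
            "oe_only_up": self.oe_only_up,
            "oe_only_down": self.oe_only_down,
            "shared_up": self.shared_up,
            "shared_down": self.shared_down,
        }


def crossmas_partition(
    kd: pd.DataFrame,
    oe: pd.DataFrame,
    driver_gene: str,
    cfg: PipelineConfig | None = None,
) -> CrossMasPartition:
    """Partition significant genes into unique/shared up/down sets.

    Genes significant in both contrasts but in opposite directions go to the
    ``discordant`` list rather than being dropped silently.
    """
    cfg = cfg or PipelineConfig()
    if set(kd["gene_id"]) != set(oe["gene_id"]):
        raise ValidationError("KD and OE tables must cover the same genes")
    kd = kd[kd["gene_id"] != driver_gene]
    oe = oe[oe["gene_id"] != driver_gene]

    up_kd, down_kd = significant_sets(kd, cfg)
    up_oe, down_oe = significant_sets(oe, cfg)
    rank_kd = dict(zip(kd["gene_id"], kd["rank"]))
    rank_oe = dict(zip(oe["gene_id"], oe["rank"]))

    discordant = (up_kd & down_oe) | (down_kd & up_oe)
    sig_oe = up_oe | down_oe
    sig_kd = up_kd | down_kd

    def by_rank(genes: set[str], rank: dict[str, int]) -> list[str]:
        return sorted(genes, key=lambda g: (rank[g], g))

    def by_maxrank(genes: set[str]) -> list[str]:
        return sorted(
            genes,
            key=lambda g: (
                max(rank_kd[g], rank_oe[g]),
                min(rank_kd[g], rank_oe[g]),
                g,
            ),
        )

    part = CrossMasPartition(
        kd_only_up=by_rank(up_kd - sig_oe, rank_kd),
        kd_only_down=by_rank(down_kd - sig_oe, rank_kd),
        oe_only_up=by_rank(up_oe - sig_kd, rank_oe),
        oe_only_down=by_rank(down_oe - sig_kd, rank_oe),
        shared_up=by_maxrank(up_kd & up_oe),
        shared_down=by_maxrank(down_kd & down_oe),
        discordant=sorted(discordant),
    )
    rows = []
    for set_name, genes in list(part.sets().items()) + [("discordant", part.discordant)]:
        for g in genes:
            rows.append(
                {
                    "gene_id": g,
                    "set": set_name,
                    "rank_kd": rank_kd[g],
                    "rank_oe": rank_oe[g],
                    "max_rank": max(rank_kd[g], rank_oe[g]),
                }
            )
    part.detail = pd.DataFrame(
        rows, columns=["gene_id", "set", "rank_kd", "rank_oe", "max_rank"]
    )
    return part
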