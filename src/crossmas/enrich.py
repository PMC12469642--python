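"""Local hypergeometric over-representation analysis against GMT gene sets.

For each term, the p-value is the upper tail of the hypergeometric
distribution: the probability of drawing at least the observed overlap when
``query_size`` genes are sampled without replacement from a background of
``background_size`` genes containing ``term_size`` term members. BH
correction is applied across the tested terms.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .glmql import bh_adjust
from .io import ValidationError

logger = logging.getLogger("crossmas")

ENRICHMENT_COLUMNS = [
    "term",
    "overlap_count",
    "query_size",
    "term_size",
    "background_size",
    "p_raw",
    "p_bh",
    "overlap_genes",
]


def ora_hypergeometric(
    query: Iterable[str],
    sets: Mapping[str, set[str]],
    background: Iterable[str],
    min_term_size: int = 3,
    max_term_size: int = 2000,
) -> pd.DataFrame:
    """Over-representation of ``query`` in each GMT term.

    Query genes outside the background are dropped with a warning; terms
    are intersected with the background and tested only if their effective
    size falls in [min_term_size, max_term_size]. Zero-overlap terms get
    p = 1. Rows are sorted by p_raw, ties by term name.
    """
    background = set(background)
    if not background:
        raise ValidationError("background gene set is empty")
    query = set(query)
    outside = query - background
    if outside:
        logger.warning(
            "%d query gene(s) outside the background were dropped", len(outside)
        )
        query &= background

    N = len(background)
    n = len(query)
    rows = []
    for term, members in sets.items():
        eff = members & background
        K = len(eff)
        if not min_term_size <= K <= max_term_size:
            continue
        overlap = sorted(query & eff)
        k = len(overlap)
        p = 1.0 if k == 0 else float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, n, K, N, min(p, 1.0), overlap))
    frame = pd.DataFrame(
        rows,
        columns=[c for c in ENRICHMENT_COLUMNS if c != "p_bh"],
    )
    frame["p_bh"] = bh_adjust(frame["p_raw"].to_numpy()) if len(frame) else []
    frame = frame[ENRICHMENT_COLUMNS]
    return frame.sort_values(["p_raw", "term"]).reset_index(drop=True)
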