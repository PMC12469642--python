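#!/usr/bin/env python
"""Driver-correlated panel selection.

Takes the top genes of each contrast-unique Cross-MAS set, computes each
candidate's Spearman correlation with the driver gene on log2-CPM values,
and keeps dosage-concordant candidates (down in KD-only, up in OE-only)
whose |rho| clears the threshold.  Writes results/panel/panel.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from crossmas import (
    PipelineConfig,
    candidate_pool,
    cpm_matrix,
    crossmas_partition,
    read_counts,
    read_deg_table,
    read_metadata,
    select_panel,
    spearman_with_driver,
    tmm_factors,
)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cfg = PipelineConfig()
    counts = read_counts(ROOT / "data" / "counts.tsv")
    read_metadata(ROOT / "data" / "meta.tsv")  # validates sample sheet
    kd = read_deg_table(ROOT / "dge" / "deg_kd.tsv")
    oe = read_deg_table(ROOT / "dge" / "deg_oe.tsv")

    part = crossmas_partition(kd, oe, cfg.driver_gene, cfg=cfg)
    pool = candidate_pool(part, cfg.top_k_per_set)

    norm = tmm_factors(counts)
    logexpr = pd.DataFrame(
        cpm_matrix(counts, norm, log2=True, prior_count=cfg.log_prior_count),
        index=list(counts.gene_ids), columns=list(counts.sample_ids),
    )
    rho = spearman_with_driver(logexpr, cfg.driver_gene, pool)
    panel = select_panel(pool, rho, kd, oe, part, cfg)

    out = ROOT / "panel"
    out.mkdir(parents=True, exist_ok=True)
    panel.to_csv(out / "panel.tsv", sep="\t", index=False, float_format="%.17g")

    print(f"candidate pool: {len(pool)} genes")
    print(f"final panel: {len(panel)} genes "
          f"(|rho| > {cfg.rho_threshold}, dosage-concordant)")
    with np.printoptions(precision=3):
        print(panel[["gene_id", "source", "log2fc", "rho"]]
              .to_string(index=False))


if __name__ == "__main__":
    main()
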