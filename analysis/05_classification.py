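#!/usr/bin/env python
"""Condition discriminability of the panel vs the whole transcriptome.

PCA on log2-CPM (panel genes only, then all genes), multinomial logistic
regression on the leading principal components, training-set accuracy and
confusion matrices.  Writes results/classification/report.json.
"""

import json
from pathlib import Path

import pandas as pd

from crossmas import (
    PipelineConfig,
    cpm_matrix,
    evaluate_features,
    read_counts,
    read_metadata,
    report_to_dict,
    tmm_factors,
)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cfg = PipelineConfig()
    counts = read_counts(ROOT / "data" / "counts.tsv")
    samples = read_metadata(ROOT / "data" / "meta.tsv")
    panel = pd.read_csv(ROOT / "panel" / "panel.tsv", sep="\t")

    norm = tmm_factors(counts)
    logexpr = pd.DataFrame(
        cpm_matrix(counts, norm, log2=True, prior_count=cfg.log_prior_count),
        index=list(counts.gene_ids), columns=list(counts.sample_ids),
    )

    reports = []
    for label, genes in (("all_genes", None),
                         ("panel", list(panel["gene_id"]))):
        if label == "panel" and not genes:
            continue
        rep = evaluate_features(logexpr, samples, genes=genes,
                                n_components=cfg.n_components,
                                feature_set_label=label)
        reports.append(report_to_dict(rep))
        print(f"{label}: accuracy {rep.accuracy:.3f}, "
              f"PC variance fractions "
              f"{[round(float(f), 3) for f in rep.explained_variance_fractions]}")

    out = ROOT / "classification"
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(reports, indent=2) + "\n")


if __name__ == "__main__":
    main()
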