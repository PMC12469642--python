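#!/usr/bin/env python
"""Over-representation analysis of the panel against synthetic gene sets.

Because the data are simulated, gene sets are built from the ground-truth
classes (each planted class becomes a term, padded with random null genes)
plus pure-noise terms; the planted terms should enrich, the noise terms
should not.  Writes results/enrichment/enrichment.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from crossmas import ora_hypergeometric

ROOT = Path(__file__).resolve().parent.parent / "results"


def build_terms(truth: pd.DataFrame, rng: np.random.Generator) -> dict[str, set[str]]:
    null_genes = truth.loc[truth["class"] == "null", "gene_id"].to_numpy()
    terms: dict[str, set[str]] = {}
    for cls, grp in truth.groupby("class"):
        if cls in ("null", "driver"):
            continue
        members = set(grp["gene_id"])
        # pad with unrelated genes so terms look like curated pathways
        pad = rng.choice(null_genes, size=30, replace=False)
        terms[f"class_{cls}"] = members | set(pad)
    for i in range(5):
        terms[f"random_{i}"] = set(rng.choice(null_genes, size=40, replace=False))
    return terms


def main() -> None:
    # keep_default_na: the literal class label "null" must not parse as NaN
    truth = pd.read_csv(ROOT / "data" / "truth.tsv", sep="\t",
                        keep_default_na=False)
    panel = pd.read_csv(ROOT / "panel" / "panel.tsv", sep="\t")

    rng = np.random.default_rng(2024)
    terms = build_terms(truth, rng)
    background = set(truth["gene_id"])
    res = ora_hypergeometric(set(panel["gene_id"]), terms, background)

    out = ROOT / "enrichment"
    out.mkdir(parents=True, exist_ok=True)
    res.to_csv(out / "enrichment.tsv", sep="\t", index=False,
               float_format="%.6g")
    print(res.to_string(index=False))


if __name__ == "__main__":
    main()
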