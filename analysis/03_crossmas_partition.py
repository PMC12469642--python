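#!/usr/bin/env python
"""Cross-MAS partition of the two DEG lists.

Splits significant genes into contrast-unique (kd_only_up/down,
oe_only_up/down) and shared same-direction sets, ordered by MAS rank, and
writes the long-format partition table under results/crossmas/.
"""

from pathlib import Path

from crossmas import PipelineConfig, crossmas_partition, read_deg_table

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cfg = PipelineConfig()
    kd = read_deg_table(ROOT / "dge" / "deg_kd.tsv")
    oe = read_deg_table(ROOT / "dge" / "deg_oe.tsv")
    part = crossmas_partition(kd, oe, cfg.driver_gene, cfg=cfg)

    out = ROOT / "crossmas"
    out.mkdir(parents=True, exist_ok=True)
    part.detail.to_csv(out / "partition.tsv", sep="\t", index=False)

    for name, members in part.sets().items():
        print(f"{name:14s} {len(members):4d}")
    if part.discordant:
        print(f"discordant     {len(part.discordant):4d}")


if __name__ == "__main__":
    main()
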