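"""Synthetic three-condition RNA-seq experiments with planted truth.

The generator emulates a dosage-perturbation design: a reference condition
(WT), a driver-knockdown condition (KD) in which one designated driver gene
is expressed at a fraction of its baseline, and a driver-overexpression
condition (OE) in which it is elevated. Counts are negative-binomial with
gene-wise gamma-distributed dispersions, log-normal library sizes and
log-normal baseline abundances.

Planted gene classes
--------------------
``kd_up/kd_down/oe_up/oe_down``
    fixed log2 fold change of +/- ``planted_lfc_magnitude`` in exactly one
    contrast, zero effect in the other (clean truth for the unique sets of
    the Cross-MAS partition).
``shared_up/shared_down``
    the same fixed effect in both contrasts.
``dosage_tracking_kd`` / ``dosage_tracking_oe``
    genes wired to the driver's *realized per-sample dosage* (group factor
    times per-sample log-normal jitter). The kd-side class responds only
    when dosage falls below baseline (effect = min(dosage, 1)^exponent) and
    the oe-side class only when it rises above (max(dosage, 1)^exponent), so
    each class lands in exactly one contrast's unique set while, across the
    two classes, expression falls in KD, rises in OE and correlates with the
    driver sample-by-sample.
``null``
    no effect anywhere.

Effects are planted in genes with above-median baseline abundance (a
dosage-sensitive target must be expressed to be observable), and the driver
gene's baseline is pinned to the 90th percentile of drawn abundances so the
perturbation itself is measurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io import CountMatrix, SampleTable, ValidationError

PLANTED_CLASSES = (
    "kd_up",
    "kd_down",
    "oe_up",
    "oe_down",
    "shared_up",
    "shared_down",
    "dosage_tracking_kd",
    "dosage_tracking_oe",
)

TRUTH_COLUMNS = ["gene_id", "class", "true_lfc_kd", "true_lfc_oe"]


@dataclass
class SimulationConfig:
    """Generative parameters for one synthetic experiment."""

    n_genes: int = 2000
    n_per_group: int = 4
    lib_size_mean: float = 1e6
    lib_size_cv: float = 0.15
    baseline_log_mean_mu: float = 4.0   # natural-log scale of relative abundance
    baseline_log_mean_sigma: float = 2.0
    dispersion_mean: float = 0.1
    dispersion_shape: float = 2.0       # gamma shape of gene-wise dispersions
    driver_kd_factor: float = 0.25
    driver_oe_factor: float = 4.0
    class_counts: dict[str, int] = field(default_factory=dict)
    planted_lfc_magnitude: float = 1.5
    dosage_exponent: float = 1.0
    dosage_jitter_sd: float = 0.15      # per-sample log-normal jitter on dosage
    driver_gene: str = "Mecp2"
    condition_labels: tuple[str, str, str] = ("WT", "KD", "OE")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_per_group < 2:
            raise ValidationError("need n_genes >= 1 and n_per_group >= 2")
        for name in ("lib_size_mean", "dispersion_mean", "dispersion_shape",
                     "planted_lfc_magnitude", "dosage_exponent"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.lib_size_cv < 0 or self.dosage_jitter_sd < 0:
            raise ValidationError("coefficients of variation must be >= 0")
        # factor 1 on either side yields a null driver (useful for
        # calibration experiments)
        if not 0 < self.driver_kd_factor <= 1:
            raise ValidationError("driver_kd_factor must lie in (0, 1]")
        if self.driver_oe_factor < 1:
            raise ValidationError("driver_oe_factor must be >= 1")
        unknown = set(self.class_counts) - set(PLANTED_CLASSES)
        if unknown:
            raise ValidationError(f"unknown planted classes: {sorted(unknown)}")
        if any(v < 0 for v in self.class_counts.values()):
            raise ValidationError("class counts must be >= 0")
        # +1 for the driver gene itself
        if sum(self.class_counts.values()) + 1 > self.n_genes:
            raise ValidationError("class_counts (plus the driver) exceed n_genes")


def default_paperlike_config(seed: int = 0) -> SimulationConfig:
    """Study-scale defaults for the end-to-end pipeline.

    2000 genes, 4 replicates per condition, 4-fold driver knockdown and
    4-fold overexpression. The unique down-in-KD and up-in-OE signal is
    carried by 10 + 6 dosage-tracking genes (the panel the pipeline is
    expected to recover), static planted classes populate the remaining
    Cross-MAS sets, and planted genes stay well under 10% of the
    transcriptome so the majority-null assumption behind TMM holds.
    """
    return SimulationConfig(
        n_genes=2000,
        n_per_group=4,
        class_counts={
            "kd_up": 30,
            "kd_down": 0,
            "oe_up": 0,
            "oe_down": 25,
            "shared_up": 25,
            "shared_down": 25,
            "dosage_tracking_kd": 10,
            "dosage_tracking_oe": 6,
        },
        seed=seed,
    )


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[CountMatrix, SampleTable, pd.DataFrame]:
    """Draw one experiment; same config and seed give byte-identical output.

    Returns the count matrix, the sample table and a truth table with one
    row per gene (columns ``gene_id, class, true_lfc_kd, true_lfc_oe``).
    """
    rng = np.random.default_rng(config.seed)
    G = config.n_genes
    n = config.n_per_group
    ref, low, high = config.condition_labels

    sample_ids = tuple(
        f"{label}_{i + 1}" for label in config.condition_labels for i in range(n)
    )
    conditions = tuple(label for label in config.condition_labels for _ in range(n))
    samples = SampleTable(sample_ids, conditions, labels=config.condition_labels)

    # gene-level parameters
    base_log = rng.normal(config.baseline_log_mean_mu,
                          config.baseline_log_mean_sigma, size=G)
    dispersions = rng.gamma(
        config.dispersion_shape,
        config.dispersion_mean / config.dispersion_shape,
        size=G,
    )

    # library sizes: log-normal with the requested mean and CV
    sigma2 = np.log1p(config.lib_size_cv ** 2)
    lib_sizes = rng.lognormal(
        np.log(config.lib_size_mean) - sigma2 / 2, np.sqrt(sigma2), size=3 * n
    )

    # class assignment: driver pinned to a well-expressed baseline, planted
    # classes drawn among above-median genes
    gene_ids = np.array([f"Gene{i + 1:05d}" for i in range(G)], dtype=object)
    classes = np.array(["null"] * G, dtype=object)
    order_by_abund = np.argsort(base_log)
    driver_idx = order_by_abund[int(0.9 * (G - 1))]
    gene_ids[driver_idx] = config.driver_gene
    classes[driver_idx] = "driver"

    eligible = order_by_abund[(G + 1) // 2:]  # above-median baseline
    eligible = eligible[eligible != driver_idx]
    n_planted = sum(config.class_counts.get(c, 0) for c in PLANTED_CLASSES)
    if n_planted > len(eligible):
        raise ValidationError(
            "class_counts exceed the number of above-median genes available"
        )
    chosen = rng.choice(eligible, size=n_planted, replace=False)
    pos = 0
    for cls in PLANTED_CLASSES:
        k = config.class_counts.get(cls, 0)
        classes[chosen[pos:pos + k]] = cls
        pos += k

    # per-sample realized driver dosage
    group_factor = np.repeat(
        [1.0, config.driver_kd_factor, config.driver_oe_factor], n
    )
    jitter = rng.lognormal(0.0, config.dosage_jitter_sd, size=3 * n)
    dosage = group_factor * jitter

    # effect multipliers, genes x samples
    effects = np.ones((G, 3 * n))
    kd_cols = np.arange(n, 2 * n)
    oe_cols = np.arange(2 * n, 3 * n)
    m = 2.0 ** config.planted_lfc_magnitude
    static_effect = {
        "kd_up": (m, 1.0),
        "kd_down": (1.0 / m, 1.0),
        "oe_up": (1.0, m),
        "oe_down": (1.0, 1.0 / m),
        "shared_up": (m, m),
        "shared_down": (1.0 / m, 1.0 / m),
    }
    for cls, (f_kd, f_oe) in static_effect.items():
        idx = np.flatnonzero(classes == cls)
        effects[np.ix_(idx, kd_cols)] = f_kd
        effects[np.ix_(idx, oe_cols)] = f_oe
    idx = np.flatnonzero(classes == "dosage_tracking_kd")
    effects[idx, :] = np.minimum(dosage, 1.0) ** config.dosage_exponent
    idx = np.flatnonzero(classes == "dosage_tracking_oe")
    effects[idx, :] = np.maximum(dosage, 1.0) ** config.dosage_exponent
    effects[driver_idx, :] = dosage

    rel_abund = np.exp(base_log)
    rel_abund /= rel_abund.sum()
    mean = lib_sizes[None, :] * rel_abund[:, None] * effects

    # NB draw via gamma-Poisson mixture (vectorizes per-gene dispersion)
    shape = 1.0 / dispersions[:, None]
    lam = rng.gamma(shape, mean / shape)
    counts = rng.poisson(lam).astype(np.int64)

    exp_ = config.dosage_exponent
    lfc_kd = np.zeros(G)
    lfc_oe = np.zeros(G)
    for cls, (f_kd, f_oe) in static_effect.items():
        idx = classes == cls
        lfc_kd[idx] = np.log2(f_kd)
        lfc_oe[idx] = np.log2(f_oe)
    lfc_kd[classes == "dosage_tracking_kd"] = exp_ * np.log2(config.driver_kd_factor)
    lfc_oe[classes == "dosage_tracking_oe"] = exp_ * np.log2(config.driver_oe_factor)
    lfc_kd[classes == "driver"] = np.log2(config.driver_kd_factor)
    lfc_oe[classes == "driver"] = np.log2(config.driver_oe_factor)

    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "class": classes,
            "true_lfc_kd": lfc_kd,
            "true_lfc_oe": lfc_oe,
        }
    )
    matrix = CountMatrix(tuple(gene_ids), sample_ids, counts)
    return matrix, samples, truth
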