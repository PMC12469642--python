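"""Trimmed-mean-of-M-values (TMM) normalization and (log-)CPM matrices.

TMM estimates a per-sample scaling factor from pairwise log-ratios against a
reference sample, doubly trimmed by log-ratio (M) and average log-abundance
(A) and combined with inverse-variance weights, under the assumption that
most genes are not differentially expressed. Factors are rescaled to a unit
geometric mean; effective library sizes (raw size x factor) enter the GLM as
offsets and the CPM computation as denominators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .io import CountMatrix, ValidationError


@dataclass(frozen=True)
class NormalizationResult:
    factors: np.ndarray            # one positive factor per sample, geo-mean 1
    effective_lib_sizes: np.ndarray
    ref_sample: str

    def __post_init__(self) -> None:
        f = np.asarray(self.factors, dtype=float)
        if not np.all(np.isfinite(f)) or np.any(f <= 0):
            raise ValidationError("TMM factors must be finite and positive")
        if abs(np.exp(np.mean(np.log(f))) - 1.0) > 1e-12:
            raise ValidationError("TMM factors must have geometric mean 1")


def _choose_reference(counts: np.ndarray, lib_sizes: np.ndarray) -> int:
    """Sample whose upper quartile of nonzero CPM is closest to the mean."""
    uq = np.empty(counts.shape[1])
    for j in range(counts.shape[1]):
        nz = counts[counts[:, j] > 0, j] / lib_sizes[j] * 1e6
        uq[j] = np.quantile(nz, 0.75) if nz.size else 0.0
    return int(np.argmin(np.abs(uq - uq.mean())))


def _pair_factor(
    y: np.ndarray,
    y_ref: np.ndarray,
    n: float,
    n_ref: float,
    trim_m: float,
    trim_a: float,
    sample_name: str,
) -> float:
    """log2 scaling factor of one sample against the reference."""
    mask = (y > 0) & (y_ref > 0)
    if not mask.any():
        raise ValidationError(
            f"sample {sample_name!r} shares no positively expressed genes "
            "with the reference sample"
        )
    ys, yr = y[mask].astype(float), y_ref[mask].astype(float)
    p, p_ref = ys / n, yr / n_ref
    M = np.log2(p / p_ref)
    A = 0.5 * np.log2(p * p_ref)
    # asymptotic (delta-method) binomial variance of M
    w = (n - ys) / (n * ys) + (n_ref - yr) / (n_ref * yr)

    k = M.size
    lo_m = np.floor(k * trim_m) + 1
    hi_m = k - np.floor(k * trim_m)
    lo_a = np.floor(k * trim_a) + 1
    hi_a = k - np.floor(k * trim_a)
    rm = rankdata(M)
    ra = rankdata(A)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        return 0.0
    f = np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep])
    return float(f) if np.isfinite(f) else 0.0


def tmm_factors(
    counts: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05
) -> NormalizationResult:
    """TMM normalization factors, rescaled to geometric mean 1.

    ``trim_m`` and ``trim_a`` are the fractions trimmed from *each* tail of
    the M and A distributions (published defaults 30% and 5%).
    """
    Y = counts.counts
    lib = Y.sum(axis=0).astype(float)
    if np.any(lib <= 0):
        bad = counts.sample_ids[int(np.argmax(lib <= 0))]
        raise ValidationError(f"sample {bad!r} has zero library size")
    ref = _choose_reference(Y, lib)
    log2f = np.zeros(counts.n_samples)
    for j in range(counts.n_samples):
        if j == ref:
            continue
        log2f[j] = _pair_factor(
            Y[:, j], Y[:, ref], lib[j], lib[ref], trim_m, trim_a,
            counts.sample_ids[j],
        )
    factors = 2.0 ** log2f
    factors /= np.exp(np.mean(np.log(factors)))
    return NormalizationResult(
        factors=factors,
        effective_lib_sizes=lib * factors,
        ref_sample=counts.sample_ids[ref],
    )


def cpm_matrix(
    counts: CountMatrix,
    norm: NormalizationResult,
    log2: bool = False,
    prior_count: float = 1.0,
) -> np.ndarray:
    """Counts per million on effective library sizes; optionally log2.

    The log transform adds the prior count to the raw count before scaling:
    log2((count + prior) * 1e6 / effective_lib_size), so a zero count at an
    effective library size of 1e6 maps to log2(1) = 0 with prior 1.
    """
    eff = np.asarray(norm.effective_lib_sizes, dtype=float)
    if log2:
        if prior_count <= 0:
            raise ValidationError("prior_count must be positive for log-CPM")
        return np.log2((counts.counts + prior_count) * 1e6 / eff[None, :])
    return counts.counts * 1e6 / eff[None, :]
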