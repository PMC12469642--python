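# Methods

This note documents what the package computes, the parameter defaults and
their rationale, what the synthetic generator does and does not emulate,
and the numerical and design decisions that matter for reproducing or
auditing results.

## 1. Normalization (TMM)

Raw library sizes are the column sums of the count matrix. TMM factors are
computed pairwise against a reference sample — the sample whose
upper quartile of nonzero CPM is closest to the mean of those quartiles
across samples. For each sample–reference pair, genes with positive counts
in both samples contribute a log2 ratio of proportions (M-value) and a mean
log2 abundance (A-value). The most extreme 30% of genes in each tail by M
and 5% in each tail by A are discarded (rank-based double trimming), and
the factor is the weighted mean of the surviving M-values with inverse
asymptotic binomial variance weights

```
w = (N_s − y_s)/(N_s y_s) + (N_r − y_r)/(N_r y_r).
```

Factors are rescaled to geometric mean 1; effective library sizes are raw
depth × factor.

A note on sensitivity: because the weights depend on absolute counts, TMM
factors are *not* exactly invariant to rescaling all counts by a common
constant — two depth-scaled copies of the same data give factors that can
differ in the third decimal. This matches the behavior of the reference
implementation in the wider ecosystem (verified numerically to 7
significant digits against edgeR on shared input) and is an inherent
property of the weighting, not a defect of this implementation.

Log2-CPM is `log2((count + prior) · 10⁶ / effective library size)` with
prior count 1, so a zero count at effective depth 10⁶ maps to 0.

## 2. NB GLM and quasi-likelihood testing

Each gene's counts follow `NB(μ, φ)` with `Var = μ + φμ²` and
`log μ = Xβ + offset`, where X is intercept + KD indicator + OE indicator
and offsets are log effective library sizes. Coefficients are fitted by
iteratively reweighted least squares, vectorized across all genes
(batched 3×3 solves), with step-halving damping, a coefficient magnitude
cap of 50 (natural log) to keep all-zero groups finite, convergence
tolerance 1e-8, and at most 50 iterations. Below dispersion 1e-7 the
deviance switches to its Poisson limit to avoid cancellation.

Dispersion estimation follows the Cox-Reid adjusted profile likelihood:
the NB log-likelihood minus `½ log det(XᵀWX)`. A common dispersion is
maximized by golden-section search; genewise estimates use a 21-point
log-spaced grid on [1e-4, 10] with parabolic refinement; the trended
dispersion is a centered running median (span 0.3) of genewise estimates
ordered by average log-CPM.

Quasi-dispersions `s² = deviance / residual df` at the trended dispersion
are squeezed toward their own abundance trend by an empirical-Bayes
scaled-F moment fit (matching the mean and variance of log s² via digamma
/ trigamma identities, Newton solve for the prior df; an underdispersed
spread yields infinite prior df). Each contrast is tested by

```
F = (deviance_reduced − deviance_full) / s²_posterior  ~  F(1, df_res + df_prior)
```

(χ² when the prior df is infinite). Raw p-values are floored at the
smallest positive double; BH adjustment uses the standard step-up
procedure. Note BH is not idempotent — re-adjusting already-adjusted
p-values changes them — so adjusted p-values are computed exactly once per
contrast.

## 3. MAS, Cross-MAS and the panel

MAS = `|log2FC|^M · |log10 p_BH|^A` with M = A = 1. Ranks are ordinal
(1..G) over descending MAS; ties break by smaller adjusted p, then larger
|log2FC|, then gene id, so ranking is total and deterministic.

Significance for set membership is strict: `p_BH < α = 0.05` **and**
`|log2FC| > 1`. The driver gene itself is excluded from all sets. Unique
sets (significant in exactly one contrast) are ordered by that contrast's
MAS rank; shared same-direction sets by the worse (max) of the two ranks,
ties by the better rank then id. Genes significant in both contrasts with
*opposite* directions go to a separate discordant list rather than being
dropped silently.

The candidate pool takes the top k = 10 of each of the four unique sets
(fewer if a set is shorter). Spearman ρ against the driver is computed on
log2-CPM across all 12 samples (scipy, rank-then-Pearson; a zero-variance
gene reports ρ = 0 with a warning). The panel keeps pool genes with
|ρ| > 0.2 whose source set is dosage-concordant — `kd_only_down` or
`oe_only_up` — sorted by |ρ| descending. An empty panel is a warning, not
an error.

## 4. Classification and enrichment

PCA operates on gene-centered log2-CPM via SVD with a deterministic sign
convention (largest-magnitude loading positive). Multinomial logistic
regression (L2, λ = 1e-4, lbfgs) is fitted on the leading 2 components and
evaluated on the training samples themselves — with 12 samples the
resubstitution accuracy is a descriptive summary of separability, not an
estimate of generalization, and is reported as such.

Over-representation uses the hypergeometric upper tail
`P(X ≥ k) = hypergeom.sf(k−1, N, K, n)` over an explicit background, terms
restricted to sizes [3, 2000] after background intersection, zero-overlap
terms reported at p = 1, BH across the tested terms.

## 5. Synthetic generator

Counts are gamma-Poisson: `y ~ Poisson(Gamma(1/φ, φμ))`. Baseline gene
means are lognormal (log-mean 4, log-sd 2), library sizes lognormal around
10⁶ (CV 0.15), dispersions gamma with mean 0.1 and shape 2. Each sample
gets a driver dosage = group factor (KD 0.25, WT 1, OE 4) × lognormal
jitter (sd 0.15); the driver gene id replaces the gene at the 90th
abundance percentile so it is well-measured.

Planted classes: static contrast-specific and shared genes at
|log2FC| = 1.5, and two dosage-tracking classes whose effect follows the
per-sample dosage *one-sidedly* —

```
kd-side:  effect = min(dosage, 1)^exponent
oe-side:  effect = max(dosage, 1)^exponent
```

Tracking genes are planted at above-median baseline abundance so they are
measurable at 4 replicates.

Two generator design decisions deserve emphasis:

- **One-sided tracking classes.** A gene that tracked dosage on *both*
  sides would be significant in both contrasts, land in the shared (or
  discordant) Cross-MAS sets, and be structurally excluded from the panel,
  which draws only from contrast-unique sets. The biologically meaningful
  panel target is therefore genes that respond to one dosage extreme and
  stay flat at the other, and that is what the generator plants.
- **Default class counts.** The study-scale default plants kd_up 30,
  oe_down 25, shared up/down 25 each, tracking 10 + 6 — and deliberately
  zero static `kd_down` / `oe_up` genes. Any static gene in a
  dosage-concordant unique set carries the group-structure correlation
  with the driver (ρ ≈ 0.67 across a 4/4/4 design, far above the 0.2
  threshold) and would enter the panel alongside the tracking genes; with
  zero such genes the expected recovered panel is exactly the 16 planted
  tracking genes. These counts were fixed before the recovery experiments
  were run, not tuned afterward.

What the generator does *not* emulate: GC/length biases, batch effects,
outlier samples, correlated genes beyond the shared driver dosage, and
compositional effects other than those implied by the planted fold
changes. On raw proportions the planted 4× genes do inflate their group's
library size slightly; TMM absorbs this downstream.

## 6. Determinism and numerics

All randomness flows through `numpy.random.default_rng(seed)`; seeds stay
below 2³¹. Tables are written with 17-significant-digit floats and read
back with round-trip parsing, so every artifact is byte-identical across
runs and machines with the same library versions. Genes with zero total
count are dropped before model fitting. Sample metadata is aligned to
count-matrix column order, so row order in the sample sheet is irrelevant.

## 7. Limitations

- Resubstitution accuracy with n = 12 is descriptive only.
- The QL squeeze uses a running-median trend rather than a spline; with
  very few genes the trend is coarse.
- The F-test calibration was verified at the default simulation settings
  (2000 genes, 4 per group, dispersion ~0.1); strongly different regimes
  (n = 2, very large dispersion) were not profiled.
- TMM's exact values depend on sequencing depth through the weights (see
  §1); comparisons across depth-rescaled datasets should expect
  third-decimal differences.
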