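"""Negative-binomial GLMs with quasi-likelihood F-tests for count data.

Per gene, counts are modeled as NB(mean mu_gs, dispersion phi_g) with
log mu_gs = x_s' beta_g + offset_s, where the offsets are natural-log
effective library sizes (raw size x TMM factor) and the design has the
reference condition absorbed into the intercept plus one indicator per
perturbed condition (KD, OE).

Dispersion estimation follows the standard empirical-Bayes recipe for
small-replicate RNA-seq:

1. a common dispersion maximizing the summed Cox-Reid adjusted profile
   likelihood (APL) over genes;
2. gene-wise APL maximizers smoothed into a trended dispersion by a running
   median against average log-CPM;
3. quasi-dispersions (residual deviance / residual df at the trended
   dispersion), squeezed toward their own abundance trend by moment-matching
   a scaled-F model for the ratios (prior df estimated from the spread of
   log-ratios; infinite when they are underdispersed).

Each contrast is tested with a quasi-likelihood F statistic: the deviance
drop from the reduced model (contrast indicator removed) to the full model,
divided by the squeezed quasi-dispersion, referred to F(1, residual df +
prior df).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix, SampleTable, ValidationError
from .mas import mas_score, rank_by_mas

DISPERSION_FLOOR = 1e-8
_COEF_CAP = 50.0  # |natural-log coefficient| cap for degenerate genes


# ---------------------------------------------------------------------------
# design


def build_design(samples: SampleTable) -> tuple[np.ndarray, list[str]]:
    """Intercept + one indicator per non-reference condition.

    Columns are ("intercept", "kd", "oe") with the reference condition
    absorbed into the intercept.
    """
    n = len(samples.sample_ids)
    X = np.zeros((n, 3))
    X[:, 0] = 1.0
    for i, cond in enumerate(samples.conditions):
        if cond == samples.low:
            X[:, 1] = np.where(np.arange(n) == i, 1.0, X[:, 1])
        elif cond == samples.high:
            X[:, 2] = np.where(np.arange(n) == i, 1.0, X[:, 2])
    if np.linalg.matrix_rank(X) < 3:
        raise ValidationError("design matrix is rank-deficient")
    return X, ["intercept", "kd", "oe"]


# ---------------------------------------------------------------------------
# NB likelihood pieces (vectorized over genes)


def nb_deviance(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Residual deviance per gene; rows are genes, columns samples."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(mu, 1e-300)
    phi = np.asarray(phi, dtype=float).reshape(-1, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(np.maximum(y, 1e-300) / mu), 0.0)
    small = phi < 1e-7
    # Poisson limit is numerically safer than the NB formula at tiny phi
    pois = term1 - (y - mu)
    nb = term1 - (y + 1.0 / phi) * np.log1p(phi * (y - mu) / (1.0 + phi * mu))
    unit = np.where(np.broadcast_to(small, nb.shape), pois, nb)
    return 2.0 * unit.sum(axis=1)


def nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Exact NB log-likelihood per gene (gamma-Poisson parameterization)."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(mu, 1e-300)
    phi = np.maximum(np.asarray(phi, dtype=float).reshape(-1, 1), DISPERSION_FLOOR)
    r = 1.0 / phi
    ll = (
        special.gammaln(y + r)
        - special.gammaln(r)
        - special.gammaln(y + 1.0)
        + y * np.log(phi * mu)
        - (y + r) * np.log1p(phi * mu)
    )
    return ll.sum(axis=1)


@dataclass(frozen=True)
class GeneFit:
    coefficients: np.ndarray   # natural-log scale, one per design column
    fitted_means: np.ndarray
    deviance: float
    df_residual: int


def _fit_nb_matrix(
    Y: np.ndarray,
    X: np.ndarray,
    offsets: np.ndarray,
    phi: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """IRLS fit of every gene at fixed dispersion.

    Returns (beta (G,p), mu (G,n), deviance (G,)). Steps that increase the
    deviance are damped by halving; coefficients are capped at +/-50 on the
    natural-log scale so all-zero groups stay finite.
    """
    Y = np.asarray(Y, dtype=float)
    G, n = Y.shape
    p = X.shape[1]
    phi = np.maximum(np.asarray(phi, dtype=float), DISPERSION_FLOOR)
    if phi.ndim == 0:
        phi = np.full(G, float(phi))

    # start from weighted least squares on log counts
    z0 = np.log(np.maximum(Y, 0.5)) - offsets[None, :]
    beta = np.linalg.lstsq(X, z0.T, rcond=None)[0].T
    beta = np.clip(beta, -_COEF_CAP, _COEF_CAP)

    def mu_of(b: np.ndarray) -> np.ndarray:
        eta = b @ X.T + offsets[None, :]
        return np.exp(np.clip(eta, -700, 700))

    mu = mu_of(beta)
    dev = nb_deviance(Y, mu, phi)
    active = np.ones(G, dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        mu_a = np.maximum(mu[idx], 1e-8)
        w = mu_a / (1.0 + phi[idx, None] * mu_a)
        z = np.log(mu_a) - offsets[None, :] + (Y[idx] - mu_a) / mu_a
        XtWX = np.einsum("gn,np,nq->gpq", w, X, X)
        XtWz = np.einsum("gn,np,gn->gp", w, X, z)
        XtWX += 1e-12 * np.eye(p)[None, :, :]
        beta_new = np.linalg.solve(XtWX, XtWz[:, :, None])[:, :, 0]
        beta_new = np.clip(beta_new, -_COEF_CAP, _COEF_CAP)

        # damped update: halve the step while the deviance increases
        step = beta_new - beta[idx]
        frac = np.ones(len(idx))
        cand = beta[idx] + step
        for _half in range(12):
            mu_c = mu_of(cand)
            dev_c = nb_deviance(Y[idx], mu_c, phi[idx])
            worse = dev_c > dev[idx] + 1e-10
            if not worse.any():
                break
            frac[worse] *= 0.5
            cand = beta[idx] + frac[:, None] * step
        mu_c = mu_of(cand)
        dev_c = nb_deviance(Y[idx], mu_c, phi[idx])
        delta = np.max(np.abs(cand - beta[idx]), axis=1)
        beta[idx] = cand
        mu[idx] = mu_c
        dev[idx] = dev_c
        still = delta >= tol
        active[idx] = still
    return beta, mu, dev


def fit_nb_glm(
    y: np.ndarray, design: np.ndarray, offsets: np.ndarray, dispersion: float
) -> GeneFit:
    """Fit one gene's NB GLM at fixed dispersion (IRLS with damping)."""
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.shape[0] != design.shape[0]:
        raise ValidationError("y and design have incompatible shapes")
    if not np.all(np.isfinite(offsets)):
        raise ValidationError("offsets must be finite")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValidationError("design matrix is rank-deficient")
    beta, mu, dev = _fit_nb_matrix(
        y[None, :], design, np.asarray(offsets, dtype=float),
        np.array([max(dispersion, DISPERSION_FLOOR)]),
    )
    return GeneFit(
        coefficients=beta[0],
        fitted_means=mu[0],
        deviance=float(dev[0]),
        df_residual=design.shape[0] - design.shape[1],
    )


# ---------------------------------------------------------------------------
# dispersion estimation


@dataclass(frozen=True)
class DispersionModel:
    common_dispersion: float
    genewise_dispersion: np.ndarray
    trended_dispersion: np.ndarray
    ql_dispersion: np.ndarray       # squeezed quasi-dispersions
    ql_dispersion_raw: np.ndarray
    ql_trend: np.ndarray
    prior_df: float                 # may be inf
    ave_log_cpm: np.ndarray


def _apl(
    Y: np.ndarray, X: np.ndarray, offsets: np.ndarray, phi: np.ndarray
) -> np.ndarray:
    """Cox-Reid adjusted profile log-likelihood of phi, per gene."""
    beta, mu, _ = _fit_nb_matrix(Y, X, offsets, phi)
    phi_col = np.maximum(phi.reshape(-1, 1), DISPERSION_FLOOR)
    w = np.maximum(mu, 1e-8) / (1.0 + phi_col * np.maximum(mu, 1e-8))
    XtWX = np.einsum("gn,np,nq->gpq", w, X, X)
    sign, logdet = np.linalg.slogdet(XtWX + 1e-12 * np.eye(X.shape[1])[None])
    return nb_loglik(Y, mu, phi.reshape(-1)) - 0.5 * logdet


def _running_median(x_sorted_values: np.ndarray, span: float) -> np.ndarray:
    """Centered running median over an array already in covariate order."""
    s = pd.Series(x_sorted_values)
    window = max(3, int(np.ceil(span * len(s))))
    return s.rolling(window, center=True, min_periods=1).median().to_numpy()


def average_log_cpm(Y: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    """Mean log2 CPM per gene on effective library sizes (prior 0.5)."""
    eff = np.exp(offsets)
    return np.log2((Y + 0.5) * 1e6 / eff[None, :]).mean(axis=1)


def _fit_scaled_f(ratios: np.ndarray, df1: float) -> tuple[float, float]:
    """Moment-match ratios ~ scale * F(df1, df2) on the log scale.

    Returns (scale, df2); df2 = inf when the observed spread of log-ratios
    does not exceed the chi-square(df1)/df1 sampling noise.
    """
    z = np.log(np.maximum(ratios, 1e-300))
    e = z - special.digamma(df1 / 2) + np.log(df1 / 2)
    evar = np.var(e, ddof=1) - special.polygamma(1, df1 / 2)
    if evar <= 0:
        return float(np.exp(np.mean(e))), np.inf
    # solve trigamma(df2/2) = evar by Newton on df2/2
    x = 0.5 + 1.0 / evar  # decent starting point
    for _ in range(50):
        f = special.polygamma(1, x) - evar
        fp = special.polygamma(2, x)
        step = f / fp
        x_new = x - step
        if x_new <= 0:
            x_new = x / 2
        if abs(x_new - x) < 1e-10 * max(1.0, x):
            x = x_new
            break
        x = x_new
    df2 = 2 * x
    scale = float(np.exp(np.mean(e) + special.digamma(x) - np.log(x)))
    return scale, float(df2)


def estimate_dispersions(
    counts: CountMatrix | np.ndarray,
    design: np.ndarray,
    offsets: np.ndarray,
    grid_min: float = 1e-4,
    grid_max: float = 10.0,
    grid_size: int = 21,
    trend_span: float = 0.3,
) -> DispersionModel:
    """Common, trended and squeezed quasi-dispersions for all genes."""
    Y = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts)
    Y = Y.astype(float)
    if np.any(Y.sum(axis=1) <= 0):
        raise ValidationError("every retained gene must have positive total count")
    G, n = Y.shape
    p = design.shape[1]
    df_res = n - p
    if df_res < 2:
        raise ValidationError(
            "quasi-likelihood estimation needs at least 2 residual df"
        )
    offsets = np.asarray(offsets, dtype=float)

    grid = np.exp(np.linspace(np.log(grid_min), np.log(grid_max), grid_size))
    apl = np.empty((grid_size, G))
    for k, phi in enumerate(grid):
        apl[k] = _apl(Y, design, offsets, np.full(G, phi))

    # common dispersion: grid argmax of the summed APL + golden-section refine
    total = apl.sum(axis=1)
    k_best = int(np.argmax(total))
    lo = np.log(grid[max(k_best - 1, 0)])
    hi = np.log(grid[min(k_best + 1, grid_size - 1)])

    def total_apl(log_phi: float) -> float:
        return float(_apl(Y, design, offsets, np.full(G, np.exp(log_phi))).sum())

    gr = (np.sqrt(5) - 1) / 2
    a, b = lo, hi
    c, d = b - gr * (b - a), a + gr * (b - a)
    fc, fd = total_apl(c), total_apl(d)
    for _ in range(30):
        if b - a < 1e-4:
            break
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - gr * (b - a)
            fc = total_apl(c)
        else:
            a, c, fc = c, d, fd
            d = a + gr * (b - a)
            fd = total_apl(d)
    common = float(np.exp((a + b) / 2))

    # gene-wise maximizers with parabolic refinement in log-phi
    k_g = np.argmax(apl, axis=0)
    log_grid = np.log(grid)
    genewise = grid[k_g].astype(float)
    interior = (k_g > 0) & (k_g < grid_size - 1)
    ki = k_g[interior]
    y0 = apl[ki - 1, np.flatnonzero(interior)]
    y1 = apl[ki, np.flatnonzero(interior)]
    y2 = apl[ki + 1, np.flatnonzero(interior)]
    h = log_grid[1] - log_grid[0]
    denom = y0 - 2 * y1 + y2
    shift = np.where(np.abs(denom) > 1e-12, 0.5 * (y0 - y2) / denom, 0.0)
    shift = np.clip(shift, -1.0, 1.0)
    genewise[interior] = np.exp(log_grid[ki] + shift * h)

    # trended: running median of gene-wise values in abundance order
    alc = average_log_cpm(Y, offsets)
    order = np.argsort(alc, kind="stable")
    trended = np.empty(G)
    trended[order] = _running_median(genewise[order], trend_span)
    trended = np.maximum(trended, DISPERSION_FLOOR)

    # quasi-dispersions at the trended NB dispersion
    _, _, dev = _fit_nb_matrix(Y, design, offsets, trended)
    s2 = np.maximum(dev / df_res, 1e-10)
    ql_trend = np.empty(G)
    ql_trend[order] = _running_median(s2[order], trend_span)
    ql_trend = np.maximum(ql_trend, 1e-10)
    scale, prior_df = _fit_scaled_f(s2 / ql_trend, df1=float(df_res))
    target = ql_trend * scale
    if np.isinf(prior_df):
        squeezed = target.copy()
    else:
        squeezed = (df_res * s2 + prior_df * target) / (df_res + prior_df)
    return DispersionModel(
        common_dispersion=common,
        genewise_dispersion=genewise,
        trended_dispersion=trended,
        ql_dispersion=squeezed,
        ql_dispersion_raw=s2,
        ql_trend=target,
        prior_df=prior_df,
        ave_log_cpm=alc,
    )


# ---------------------------------------------------------------------------
# multiple testing


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size and (np.any(p <= 0) or np.any(p > 1) or not np.all(np.isfinite(p))):
        raise ValidationError("p-values must lie in (0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# QL F-test per contrast


def ql_ftest(
    counts: CountMatrix | np.ndarray,
    design: np.ndarray,
    offsets: np.ndarray,
    disp: DispersionModel,
    contrast: str,
    gene_ids: tuple[str, ...] | None = None,
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
    mas_M: float = 1.0,
    mas_A: float = 1.0,
) -> pd.DataFrame:
    """Quasi-likelihood F-test of one contrast ("kd" or "oe").

    The full model carries both condition indicators; the reduced model
    drops the tested one. Returns a DEG table with log2FC, raw and
    BH-adjusted p, MAS score, MAS rank, significance flag and direction.
    """
    if contrast not in ("kd", "oe"):
        raise ValidationError("contrast must be 'kd' or 'oe'")
    if isinstance(counts, CountMatrix):
        Y = counts.counts.astype(float)
        gene_ids = counts.gene_ids
    else:
        Y = np.asarray(counts, dtype=float)
        if gene_ids is None:
            gene_ids = tuple(f"g{i}" for i in range(Y.shape[0]))
    col = 1 if contrast == "kd" else 2
    n, p = design.shape
    df_res = n - p

    beta_full, _, dev_full = _fit_nb_matrix(Y, design, offsets, disp.trended_dispersion)
    reduced = np.delete(design, col, axis=1)
    _, _, dev_red = _fit_nb_matrix(Y, reduced, offsets, disp.trended_dispersion)

    F = np.maximum(dev_red - dev_full, 0.0) / np.maximum(disp.ql_dispersion, 1e-300)
    df2 = df_res + disp.prior_df
    if np.isinf(df2):
        p_raw = stats.chi2.sf(F, 1)
    else:
        p_raw = stats.f.sf(F, 1, df2)
    # floor so |log10 p| in the MAS stays finite
    tiny = np.finfo(float).tiny
    p_raw = np.clip(p_raw, tiny, 1.0)
    p_bh = bh_adjust(p_raw)

    log2fc = beta_full[:, col] / np.log(2.0)
    mas = mas_score(log2fc, p_bh, M=mas_M, A=mas_A)
    significant = (p_bh < alpha) & (np.abs(log2fc) > lfc_threshold)
    direction = np.where(
        ~significant, "ns", np.where(log2fc > 0, "up", "down")
    )
    table = pd.DataFrame(
        {
            "gene_id": list(gene_ids),
            "log2fc": log2fc,
            "p_raw": p_raw,
            "p_bh": p_bh,
            "mas": mas,
            "significant": significant,
            "direction": direction,
        }
    )
    return rank_by_mas(table)
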