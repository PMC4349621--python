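"""Low-expression filtering, size factors, variance-stabilizing
transformation, and empirical-Bayes batch adjustment.

The stage order is fixed: filter -> size factors -> VST -> batch
adjustment, and all samples (controls, grade 0, symptomatic) are included
throughout.

Model
-----
Counts are treated as negative-binomial with a parametric mean-dispersion
trend ``alpha(mu) = alpha0 + alpha1 / mu`` (an asymptotic dispersion plus
an extra-Poisson term), so the variance function is
``v(mu) = mu * (1 + alpha1) + alpha0 * mu**2``.  The VST is the closed-form
antiderivative of ``1/sqrt(v)``, affinely calibrated so that it approaches
``log2`` at large counts:

    vst(q) = log2( (1 + a1 + 2*a0*q + 2*sqrt(a0*q*(1 + a1 + a0*q))) / (4*a0) )

Batch adjustment is the parametric empirical-Bayes location/scale method
(ComBat): per-feature standardization against a batch-design fit, normal
prior on batch location effects, inverse-gamma prior on batch scale
effects, priors by method of moments, posterior means by iterated
conditional expectations, then back-transformation.  The covariate model
is intercept-only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class DispersionTrend:
    """Parameters of the dispersion trend ``alpha(mu) = alpha0 + alpha1/mu``."""

    alpha0: float  # asymptotic dispersion, > 0
    alpha1: float  # extra-Poisson term, >= 0

    def __post_init__(self) -> None:
        if self.alpha0 <= 0:
            raise ValueError("alpha0 must be positive")
        if self.alpha1 < 0:
            raise ValueError("alpha1 must be non-negative")

    def alpha(self, mu):
        return self.alpha0 + self.alpha1 / np.asarray(mu, dtype=float)

    def variance(self, mu):
        mu = np.asarray(mu, dtype=float)
        return mu * (1.0 + self.alpha1) + self.alpha0 * mu**2


def filter_low_expression(counts: pd.DataFrame, min_mean: float = 2.0) -> pd.DataFrame:
    """Keep miRNAs whose mean raw count across ALL samples is >= ``min_mean``.

    The boundary is inclusive: a mean of exactly ``min_mean`` survives
    (the removal rule is a strict "mean < min_mean").
    """
    return counts.loc[counts.mean(axis=1) >= min_mean]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors, log-centered to geometric mean 1.

    For each sample, the factor is the median over miRNAs (restricted to
    miRNAs positive in every sample) of count / per-miRNA geometric mean.
    If no miRNA is positive in all samples, falls back to per-sample
    positive-subset ratios with a warning.
    """
    mat = counts.to_numpy(dtype=float)
    if mat.shape[0] == 0:
        raise ValueError("empty count matrix")
    with np.errstate(divide="ignore"):
        logs = np.log(mat)
    log_geomeans = logs.mean(axis=1)
    usable = np.isfinite(log_geomeans)
    factors = np.empty(mat.shape[1])
    if usable.any():
        for j in range(mat.shape[1]):
            factors[j] = np.exp(np.median(logs[usable, j] - log_geomeans[usable]))
    else:
        warnings.warn(
            "no miRNA is positive in all samples; falling back to "
            "positive-subset median-of-ratios"
        )
        # per-miRNA geometric mean over its positive entries only
        pos_geo = np.array([
            logs[i][np.isfinite(logs[i])].mean() if np.isfinite(logs[i]).any()
            else np.nan
            for i in range(mat.shape[0])
        ])
        for j in range(mat.shape[1]):
            pos = (mat[:, j] > 0) & np.isfinite(pos_geo)
            if not pos.any():
                raise ValueError(f"sample {counts.columns[j]!r} has no positive counts")
            factors[j] = np.exp(np.median(logs[pos, j] - pos_geo[pos]))
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def _method_of_moments_dispersions(
    mat: np.ndarray, sf: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-miRNA MoM dispersion estimates on size-factor-normalized counts."""
    q = mat / sf
    mu = q.mean(axis=1)
    var = q.var(axis=1, ddof=1)
    s = np.mean(1.0 / sf)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (var - s * mu) / mu**2
    return mu, alpha


def fit_dispersion_trend(
    counts: pd.DataFrame,
    sf: pd.Series,
    n_iter: int = 10,
) -> DispersionTrend:
    """Fit ``alpha(mu) = alpha0 + alpha1/mu`` to per-miRNA MoM dispersions.

    Gamma-style iteratively reweighted least squares on the positive
    estimates (weights 1/fitted^2), with one outlier-trimming pass
    (ratio to fit outside [1e-4, 15] dropped).  Degenerate fits clamp
    ``alpha0`` to a small positive value with a warning.
    """
    if counts.shape[0] < 20:
        raise ValueError("need at least 20 miRNAs to fit a dispersion trend")
    mat = counts.to_numpy(dtype=float)
    sfv = sf.loc[counts.columns].to_numpy(dtype=float)
    mu, alpha = _method_of_moments_dispersions(mat, sfv)
    keep = np.isfinite(alpha) & (alpha > 0) & (mu > 0)
    if keep.sum() < 10:
        warnings.warn("too few positive dispersion estimates; using Poisson-like trend")
        return DispersionTrend(1e-8, 0.0)
    mu_f, a_f = mu[keep], alpha[keep]

    def irls(mu_v: np.ndarray, a_v: np.ndarray) -> np.ndarray:
        X = np.column_stack([np.ones_like(mu_v), 1.0 / mu_v])
        beta = np.array([np.median(a_v), 0.0])
        for _ in range(n_iter):
            fitted = np.clip(X @ beta, 1e-8, None)
            w = 1.0 / fitted**2
            WX = X * w[:, None]
            beta_new, *_ = np.linalg.lstsq(X.T @ WX, X.T @ (w * a_v), rcond=None)
            if np.allclose(beta_new, beta, rtol=1e-8, atol=1e-12):
                beta = beta_new
                break
            beta = beta_new
        return beta

    beta = irls(mu_f, a_f)
    fitted = np.clip(np.column_stack([np.ones_like(mu_f), 1.0 / mu_f]) @ beta, 1e-8, None)
    ratio = a_f / fitted
    trimmed = (ratio > 1e-4) & (ratio < 15)
    if trimmed.sum() >= 10 and not trimmed.all():
        beta = irls(mu_f[trimmed], a_f[trimmed])
    alpha0, alpha1 = float(beta[0]), float(beta[1])
    if alpha0 <= 0:
        warnings.warn("degenerate dispersion fit (alpha0 <= 0); clamping")
        alpha0 = 1e-8
    if alpha1 < 0:
        alpha1 = 0.0
    return DispersionTrend(alpha0, alpha1)


def vst(
    counts: pd.DataFrame,
    sf: pd.Series,
    trend: DispersionTrend,
) -> pd.DataFrame:
    """Closed-form variance-stabilizing transform of normalized counts.

    Strictly monotone in counts; approaches ``log2(q)`` as ``q -> inf``.
    """
    q = counts.to_numpy(dtype=float) / sf.loc[counts.columns].to_numpy(dtype=float)
    a0, a1 = trend.alpha0, trend.alpha1
    inner = 1.0 + a1 + 2.0 * a0 * q + 2.0 * np.sqrt(a0 * q * (1.0 + a1 + a0 * q))
    values = np.log2(inner / (4.0 * a0))
    out = pd.DataFrame(values, index=counts.index, columns=counts.columns)
    out.attrs["vst_applied"] = True
    out.attrs["batch_corrected"] = False
    return out


# ---------------------------------------------------------------------------
# Empirical-Bayes batch adjustment (parametric ComBat, intercept-only model)
# ---------------------------------------------------------------------------

def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2.0 * s2 + m**2) / s2

def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m**3) / s2


def _it_sol(
    s_data: np.ndarray,
    gamma_hat: np.ndarray,
    delta_hat: np.ndarray,
    gamma_bar: float,
    tau2: float,
    a: float,
    b: float,
    conv: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Iterated conditional posterior means for one batch's (gamma*, delta*)."""
    n = s_data.shape[1]
    gamma_old = gamma_hat.copy()
    delta_old = delta_hat.copy()
    for _ in range(500):
        gamma_new = (n * tau2 * gamma_hat + delta_old * gamma_bar) / (n * tau2 + delta_old)
        sum2 = ((s_data - gamma_new[:, None]) ** 2).sum(axis=1)
        delta_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)
        change = max(
            np.abs(gamma_new - gamma_old).max() / np.abs(gamma_old).clip(1e-12).max(),
            np.abs(delta_new - delta_old).max() / np.abs(delta_old).clip(1e-12).max(),
        )
        gamma_old, delta_old = gamma_new, delta_new
        if change < conv:
            break
    return gamma_old, delta_old


def combat_adjust(expr: pd.DataFrame, batch: pd.Series) -> pd.DataFrame:
    """Parametric empirical-Bayes location/scale batch adjustment.

    ``expr`` is a feature x sample matrix on VST scale; ``batch`` labels
    every sample.  Requires >= 2 batches with >= 2 samples each; a single
    batch is a no-op.  The per-feature grand mean is preserved up to
    numerical tolerance.
    """
    batch = batch.loc[expr.columns]
    if batch.isna().any():
        raise ValueError("missing batch label")
    levels = list(pd.unique(batch))
    if len(levels) == 1:
        out = expr.copy()
        out.attrs.update(expr.attrs)
        out.attrs["batch_corrected"] = True
        return out
    sizes = batch.value_counts()
    small = sizes[sizes < 2]
    if len(small):
        raise ValueError(
            f"batch(es) with fewer than 2 samples: {sorted(small.index)} "
            "(scale effect not estimable)"
        )
    X = expr.to_numpy(dtype=float)
    n_genes, n = X.shape
    masks = [(batch == lev).to_numpy() for lev in levels]
    n_b = np.array([m.sum() for m in masks])

    batch_means = np.column_stack([X[:, m].mean(axis=1) for m in masks])  # genes x B
    grand_mean = batch_means @ (n_b / n)
    # residuals against the batch design
    resid = np.empty_like(X)
    for k, m in enumerate(masks):
        resid[:, m] = X[:, m] - batch_means[:, [k]]
    var_pooled = np.clip((resid**2).mean(axis=1), 1e-12, None)

    s_data = (X - grand_mean[:, None]) / np.sqrt(var_pooled)[:, None]

    adjusted = np.empty_like(s_data)
    for k, m in enumerate(masks):
        sub = s_data[:, m]
        gamma_hat = sub.mean(axis=1)
        delta_hat = np.clip(sub.var(axis=1, ddof=1), 1e-12, None)
        gamma_bar = gamma_hat.mean()
        tau2 = gamma_hat.var(ddof=1)
        d_s2 = delta_hat.var(ddof=1)
        if d_s2 < 1e-20 or tau2 < 1e-20:
            # degenerate (e.g. noise-free data): no information to shrink with,
            # use the point estimates directly
            gamma_star = np.full_like(gamma_hat, gamma_bar) if tau2 < 1e-20 else gamma_hat
            delta_star = delta_hat
        else:
            a, b = _aprior(delta_hat), _bprior(delta_hat)
            gamma_star, delta_star = _it_sol(
                sub, gamma_hat, delta_hat, gamma_bar, tau2, a, b
            )
        adjusted[:, m] = (sub - gamma_star[:, None]) / np.sqrt(delta_star)[:, None]

    out_values = adjusted * np.sqrt(var_pooled)[:, None] + grand_mean[:, None]
    out = pd.DataFrame(out_values, index=expr.index, columns=expr.columns)
    out.attrs.update(expr.attrs)
    out.attrs["batch_corrected"] = True
    return out


def normalize_counts(
    counts: pd.DataFrame,
    batch: pd.Series | None,
    min_mean: float = 2.0,
) -> tuple[pd.DataFrame, pd.Series, DispersionTrend]:
    """Full normalization: filter -> size factors -> VST -> batch adjustment.

    Returns the expression matrix, the size factors and the fitted trend.
    ``batch`` may be None only when batch adjustment is to be skipped
    explicitly (single-batch data should still pass its labels).
    """
    filtered = filter_low_expression(counts, min_mean=min_mean)
    sf = size_factors(filtered)
    trend = fit_dispersion_trend(filtered, sf)
    expr = vst(filtered, sf, trend)
    if batch is not None:
        expr = combat_adjust(expr, batch)
    return expr, sf, trend
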