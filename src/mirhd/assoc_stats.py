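"""Inferential statistics: moderated differential expression, Vonsattel
grade ANOVA with Tukey HSD and compact letter display, ROC/AUC, CAG
residualization, per-miRNA clinical-feature regressions, and correlation
clustering.

Differential expression uses per-feature ordinary least squares with
empirical-Bayes variance moderation: residual variances are shrunk toward
a common prior, with the prior degrees of freedom ``d0`` and prior
variance ``s0^2`` estimated by matching moments of the log residual
variances to a scaled-F model (digamma/trigamma moment equations).  The
moderated t statistic ``b / (s_post * sqrt(v))`` is referred to a t
distribution with ``d0 + d_res`` degrees of freedom.

Clinical features (age of onset, disease duration, age at death,
Hadzi-Vonsattel striatal and cortical scores) are residualized on CAG
repeat length before association, excluding samples with CAG > 55 or
missing CAG; onset uses a logarithmic model ``ln(onset) ~ CAG``, the
other features a linear one.  Feature regressions deliberately include no
further covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

CLINICAL_FEATURES = ("onset", "duration", "death_age", "striatal", "cortical")

#: metadata column backing each residualizable clinical feature
FEATURE_COLUMNS = {
    "onset": "onset_age",
    "duration": "duration",
    "death_age": "age_death",
    "striatal": "hv_striatal",
    "cortical": "hv_cortical",
}


# ---------------------------------------------------------------------------
# Empirical-Bayes moderated differential expression
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y by Newton iteration."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Estimate (d0, s0^2) of the scaled-F model for residual variances.

    Matches the mean and variance of ``log(s2)``:
    ``var(log s2) - trigamma(df/2)`` estimates ``trigamma(d0/2)``.
    Returns ``d0 = inf`` when the observed spread is at or below the
    sampling spread (no evidence of variance heterogeneity).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = z.var(ddof=1) if len(z) > 1 else 0.0
    target = e_var - special.polygamma(1, df / 2.0)
    if target <= 0:
        # no excess spread: infinite prior df, plain pooled variance
        return np.inf, float(s2[ok].mean())
    d0 = 2.0 * _trigamma_inverse(target)
    s0_sq = np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return float(d0), float(s0_sq)


def moderated_de(
    expr: pd.DataFrame,
    condition: pd.Series,
    covariates: pd.DataFrame | None = None,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Moderated-t differential expression, case level vs reference level.

    ``condition`` must have exactly two levels; the contrast is
    ``HD - control`` when those labels are present, otherwise second level
    minus first in sorted order.  ``covariates`` (e.g. age at death) are
    numeric columns aligned to the samples.  ``prior_df`` overrides the
    estimated d0 (0 recovers the ordinary t-test; ``inf`` a pooled-variance
    z-like test).

    Returns a frame with log2_fold_change, average_expression,
    moderated_t, p_value, q_value (BH over all rows) and residual_df.
    """
    condition = condition.loc[expr.columns]
    levels = sorted(condition.unique())
    if len(levels) != 2:
        raise ValueError(f"condition must have two levels, got {levels}")
    if "HD" in levels and "control" in levels:
        case, ref = "HD", "control"
    else:
        ref, case = levels
    design_cols = {"intercept": np.ones(expr.shape[1]),
                   "condition": (condition == case).to_numpy(float)}
    if covariates is not None:
        covariates = covariates.loc[expr.columns]
        if covariates.isna().any().any():
            raise ValueError("covariates must be complete")
        for col in covariates.columns:
            design_cols[col] = covariates[col].to_numpy(float)
    X = np.column_stack(list(design_cols.values()))
    names = list(design_cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(f"collinear design matrix (columns: {names})")
    Y = expr.to_numpy(dtype=float)
    n, p = X.shape
    df_res = n - p
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = Y @ X @ XtX_inv.T  # genes x p
    resid = Y - beta @ X.T
    s2 = (resid**2).sum(axis=1) / df_res
    v_cond = XtX_inv[1, 1]

    if prior_df is None:
        d0, s0_sq = fit_f_dist(s2, df_res)
    elif prior_df == 0:
        d0, s0_sq = 0.0, 1.0
    elif np.isinf(prior_df):
        d0, s0_sq = np.inf, float(s2.mean())
    else:
        d0 = float(prior_df)
        _, s0_sq = fit_f_dist(s2, df_res)

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df_res * s2) / (d0 + df_res)
        df_total = d0 + df_res
    t = beta[:, 1] / np.sqrt(s2_post * v_cond)
    p_val = 2.0 * stats.t.sf(np.abs(t), df_total)
    out = pd.DataFrame(
        {
            "log2_fold_change": beta[:, 1],
            "average_expression": Y.mean(axis=1),
            "moderated_t": t,
            "p_value": p_val,
            "residual_df": df_res,
        },
        index=expr.index,
    )
    out["q_value"] = bh_fdr(out["p_value"].to_numpy())
    out.attrs["prior_df"] = d0
    out.attrs["prior_var"] = s0_sq
    out.attrs["contrast"] = f"{case} vs {ref}"
    return out


def bh_fdr(p_values: np.ndarray | Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with enforced monotonicity.

    NaN p-values propagate as NaN and are excluded from the ranking; the
    family size is the number of non-NaN entries.  Ties and equal p-values
    keep stable input order in the ranking.
    """
    p = np.asarray(p_values, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return q
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    qv = np.empty(m)
    qv[order] = np.minimum(ranked, 1.0)
    q[ok] = qv
    return q


# ---------------------------------------------------------------------------
# Vonsattel-grade machinery: ANOVA, Tukey HSD, compact letter display
# ---------------------------------------------------------------------------

def grade_anova(
    expr: pd.DataFrame,
    groups: pd.Series,
) -> pd.Series:
    """Per-miRNA one-way fixed-effects ANOVA F-test p-values.

    ``groups`` labels each sample (e.g. control, 0, 2, 3, 4).  Every group
    must have at least 2 samples and there must be at least 2 groups.
    """
    groups = groups.loc[expr.columns]
    levels = pd.unique(groups)
    sizes = groups.value_counts()
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    if (sizes < 2).any():
        small = sorted(sizes[sizes < 2].index.astype(str))
        raise ValueError(f"group(s) with fewer than 2 samples: {small}")
    Y = expr.to_numpy(dtype=float)
    n = Y.shape[1]
    k = len(levels)
    grand = Y.mean(axis=1)
    ss_between = np.zeros(Y.shape[0])
    ss_within = np.zeros(Y.shape[0])
    for lev in levels:
        m = (groups == lev).to_numpy()
        gm = Y[:, m].mean(axis=1)
        ss_between += m.sum() * (gm - grand) ** 2
        ss_within += ((Y[:, m] - gm[:, None]) ** 2).sum(axis=1)
    df1, df2 = k - 1, n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df1) / (ss_within / df2)
    p = stats.f.sf(f, df1, df2)
    return pd.Series(p, index=expr.index, name="anova_p")


def tukey_hsd(
    values: pd.Series | np.ndarray,
    groups: pd.Series | Sequence,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All-pairs Tukey(-Kramer) comparisons for a one-way layout.

    Returns one row per unordered group pair with the mean difference, the
    studentized-range-adjusted p-value and a significance flag at
    ``alpha``.  With zero pooled within-group variance, p is 0 for unequal
    means and 1 for equal means (with a warning).
    """
    values = np.asarray(values, dtype=float)
    groups = pd.Series(list(groups))
    levels = list(pd.unique(groups))
    k = len(levels)
    if k < 2:
        raise ValueError("need at least 2 groups")
    means, ns, ss = {}, {}, 0.0
    for lev in levels:
        x = values[(groups == lev).to_numpy()]
        if len(x) < 2:
            raise ValueError(f"group {lev!r} has fewer than 2 samples")
        means[lev], ns[lev] = x.mean(), len(x)
        ss += ((x - x.mean()) ** 2).sum()
    df = len(values) - k
    s2 = ss / df
    rows = []
    for g1, g2 in combinations(levels, 2):
        diff = means[g1] - means[g2]
        if s2 <= 0:
            warnings.warn("zero within-group variance in Tukey HSD")
            p = 1.0 if diff == 0 else 0.0
        else:
            se = np.sqrt(s2 / 2.0 * (1.0 / ns[g1] + 1.0 / ns[g2]))
            q_stat = abs(diff) / se
            p = float(stats.studentized_range.sf(q_stat, k, df))
        rows.append(
            {"group1": g1, "group2": g2, "mean_diff": diff,
             "p_adjusted": p, "significant": p < alpha}
        )
    return pd.DataFrame(rows)


def compact_letter_display(
    significant: Mapping[frozenset, bool],
    group_order: Sequence,
) -> dict:
    """Insert-and-absorb compact letter display.

    ``significant`` maps each unordered group pair to whether it differs
    significantly.  Two groups share at least one letter iff their pair is
    non-significant; letter sets are minimal under absorption.  Letters are
    assigned a, b, c, ... in ``group_order`` of first use.
    """
    groups = list(group_order)
    columns: list[set] = [set(groups)]
    sig_pairs = [
        tuple(sorted(pair, key=groups.index))
        for pair, is_sig in significant.items()
        if is_sig
    ]
    for g1, g2 in sorted(sig_pairs, key=lambda p: (groups.index(p[0]), groups.index(p[1]))):
        hit = [c for c in columns if g1 in c and g2 in c]
        for col in hit:
            columns.remove(col)
            for new in (col - {g1}, col - {g2}):
                if new and not any(new <= other for other in columns):
                    columns = [c for c in columns if not (c < new)]
                    columns.append(new)
    # order columns by the earliest group they contain, then assign letters
    columns.sort(key=lambda c: min(groups.index(g) for g in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in groups}
    for i, col in enumerate(columns):
        for g in groups:
            if g in col:
                letters[g] += alphabet[i % len(alphabet)]
    return letters


def grade_association(
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    de_set: Sequence[str] | None = None,
    alpha: float = 0.05,
    pairwise_adjust: str = "tukey",
) -> pd.DataFrame:
    """Dual-ANOVA grade association with Tukey pairwise tests and letters.

    Two one-way ANOVAs are run per miRNA: one across grades 0-4 with the
    controls as their own group, and one in HD brains only (grades 0-4).
    A miRNA is grade-associated when its BH q-value is below ``alpha`` in
    BOTH runs (the FDR family is ``de_set`` for each run).  Pairwise
    adjusted p-values use the studentized range by default, or Bonferroni
    with ``pairwise_adjust='bonferroni'``.
    """
    if de_set is not None:
        expr = expr.loc[[m for m in de_set if m in expr.index]]
    labels = samples.loc[expr.columns].apply(
        lambda r: "control" if r["condition"] == "control" else str(int(r["grade"])),
        axis=1,
    )
    hd_mask = (samples.loc[expr.columns, "condition"] == "HD").to_numpy()
    p_with = grade_anova(expr, labels)
    p_hd = grade_anova(expr.loc[:, hd_mask], labels[hd_mask])
    q_with = bh_fdr(p_with.to_numpy())
    q_hd = bh_fdr(p_hd.to_numpy())

    group_order = [g for g in ("control", "0", "2", "3", "4") if g in set(labels)]
    rows = []
    for i, mirna in enumerate(expr.index):
        pairs = tukey_hsd(expr.loc[mirna].to_numpy(), labels, alpha=alpha)
        if pairwise_adjust == "bonferroni":
            raw = _pairwise_t_pvalues(expr.loc[mirna].to_numpy(), labels)
            pairs["p_adjusted"] = np.minimum(raw * len(raw), 1.0)
            pairs["significant"] = pairs["p_adjusted"] < alpha
        sig = {
            frozenset((r.group1, r.group2)): bool(r.significant)
            for r in pairs.itertuples()
        }
        letters = compact_letter_display(sig, group_order)
        rows.append(
            {
                "mirna_id": mirna,
                "anova_p_with_controls": p_with.iloc[i],
                "anova_q_with_controls": q_with[i],
                "anova_p_hd_only": p_hd.iloc[i],
                "anova_q_hd_only": q_hd[i],
                "significant_both": (q_with[i] < alpha) and (q_hd[i] < alpha),
                "letters": ";".join(f"{g}:{letters[g]}" for g in group_order),
                "pairwise": pairs,
            }
        )
    return pd.DataFrame(rows).set_index("mirna_id")


def _pairwise_t_pvalues(values: np.ndarray, groups: pd.Series) -> np.ndarray:
    """Unadjusted pooled-variance pairwise t p-values (Bonferroni input)."""
    levels = list(pd.unique(groups))
    k = len(levels)
    stats_ = {lev: values[(groups == lev).to_numpy()] for lev in levels}
    df = len(values) - k
    s2 = sum(((x - x.mean()) ** 2).sum() for x in stats_.values()) / df
    out = []
    for g1, g2 in combinations(levels, 2):
        x, y = stats_[g1], stats_[g2]
        se = np.sqrt(s2 * (1.0 / len(x) + 1.0 / len(y)))
        t = abs(x.mean() - y.mean()) / se
        out.append(2.0 * stats.t.sf(t, df))
    return np.asarray(out)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def roc_auc(
    scores: Sequence[float] | np.ndarray,
    labels: Sequence[int] | np.ndarray,
) -> tuple[float, tuple[float, float]]:
    """AUC with a DeLong-type 95% confidence interval.

    AUC is the Mann-Whitney U statistic divided by ``n1 * n0`` with ties
    counted one half.  The CI uses the variance of the per-observation
    placement values, clipped to [0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos, neg = scores[labels], scores[~labels]
    n1, n0 = len(pos), len(neg)
    if n1 == 0 or n0 == 0:
        raise ValueError("both label classes must be present")
    # placements: for each positive, fraction of negatives it beats (ties 1/2)
    diff = pos[:, None] - neg[None, :]
    psi = np.where(diff > 0, 1.0, np.where(diff < 0, 0.0, 0.5))
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    auc = float(psi.mean())
    s10 = v10.var(ddof=1) if n1 > 1 else 0.0
    s01 = v01.var(ddof=1) if n0 > 1 else 0.0
    se = np.sqrt(s10 / n1 + s01 / n0)
    z = stats.norm.ppf(0.975)
    ci = (float(max(0.0, auc - z * se)), float(min(1.0, auc + z * se)))
    return auc, ci


# ---------------------------------------------------------------------------
# CAG residualization and feature regressions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResidualModel:
    """OLS fit of a clinical feature on CAG repeat length."""

    model: str            # "log_onset_on_cag" or "linear_on_cag"
    intercept: float
    slope: float
    slope_se: float
    n_fit: int
    cag_max: int


def cag_residualize(
    feature_values: pd.Series,
    cag: pd.Series,
    model: str,
    cag_max: int = 55,
    samples: Sequence[str] | None = None,
) -> tuple[pd.Series, ResidualModel]:
    """Residualize a clinical feature on CAG length.

    The fit uses every sample with a present CAG <= ``cag_max`` and a
    present feature value (onset must additionally be positive under the
    log model); samples above the CAG cutoff or with missing CAG are
    excluded and get NaN residuals.  ``samples`` restricts which residuals
    are returned (the fitting set may be larger, e.g. a reference cohort).
    Residuals are orthogonal to [1, CAG] within the fitting set.
    """
    if model not in ("log_onset_on_cag", "linear_on_cag"):
        raise ValueError(f"unknown model {model!r}")
    feature_values = feature_values.astype(float)
    cag = cag.astype(float).loc[feature_values.index]
    y = feature_values.copy()
    if model == "log_onset_on_cag":
        if (y.dropna() <= 0).any():
            raise ValueError("non-positive onset under log model")
        y = np.log(y)
    fit_mask = y.notna() & cag.notna() & (cag <= cag_max)
    if fit_mask.sum() < 3:
        raise ValueError(f"fewer than 3 usable fitting points ({int(fit_mask.sum())})")
    x = cag[fit_mask].to_numpy()
    yy = y[fit_mask].to_numpy()
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, yy, rcond=None)
    resid_fit = yy - X @ beta
    dof = len(x) - 2
    sigma2 = (resid_fit**2).sum() / dof if dof > 0 else np.nan
    sxx = ((x - x.mean()) ** 2).sum()
    slope_se = float(np.sqrt(sigma2 / sxx)) if sxx > 0 else np.nan
    fit = ResidualModel(model, float(beta[0]), float(beta[1]), slope_se,
                        int(fit_mask.sum()), cag_max)
    residuals = pd.Series(np.nan, index=feature_values.index, name="residual")
    residuals[fit_mask] = resid_fit
    if samples is not None:
        residuals = residuals.loc[list(samples)]
    return residuals, fit


def residualize_features(
    analysis: pd.DataFrame,
    reference: pd.DataFrame | None = None,
    cag_max: int = 55,
) -> tuple[pd.DataFrame, dict[str, ResidualModel]]:
    """CAG-adjust all five clinical features for the analysis samples.

    Models are fitted on ``reference`` (e.g. the large neuropathology
    cohort) when given, otherwise on the analysis samples themselves;
    residuals are returned for the analysis samples only.
    """
    fit_on = reference if reference is not None else analysis
    out = {}
    fits = {}
    for feature, column in FEATURE_COLUMNS.items():
        model = "log_onset_on_cag" if feature == "onset" else "linear_on_cag"
        combined = pd.concat(
            [fit_on[[column, "cag"]],
             analysis.loc[~analysis.index.isin(fit_on.index), [column, "cag"]]]
        )
        resid, fit = cag_residualize(
            combined[column], combined["cag"], model,
            cag_max=cag_max, samples=list(analysis.index),
        )
        out[feature] = resid
        fits[feature] = fit
    return pd.DataFrame(out), fits


def feature_regression(
    expr: pd.DataFrame,
    residualized_feature: pd.Series,
    de_set: Sequence[str],
    feature_name: str = "feature",
) -> pd.DataFrame:
    """Per-miRNA simple linear regression of expression on a CAG-adjusted
    clinical feature, in symptomatic HD brains.

    ``de_set`` defines both the tested miRNAs and the BH family size.
    Samples with a missing residual are dropped.  No covariates.
    """
    feat = residualized_feature.loc[expr.columns]
    keep = feat.notna()
    feat = feat[keep]
    if feat.nunique() <= 1:
        raise ValueError(f"feature {feature_name!r} is constant")
    sub = expr.loc[[m for m in de_set if m in expr.index], keep.index[keep]]
    x = feat.to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(x), x])
    XtX_inv = np.linalg.inv(X.T @ X)
    Y = sub.to_numpy(dtype=float)
    beta = Y @ X @ XtX_inv.T
    resid = Y - beta @ X.T
    df = len(x) - 2
    s2 = (resid**2).sum(axis=1) / df
    se = np.sqrt(s2 * XtX_inv[1, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[:, 1] / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    out = pd.DataFrame(
        {
            "feature": feature_name,
            "beta": beta[:, 1],
            "p": p,
            "n_samples": len(x),
        },
        index=sub.index,
    )
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out


def multivariate_feature_regression(
    expr: pd.DataFrame,
    striatal_resid: pd.Series,
    cortical_resid: pd.Series,
) -> pd.DataFrame:
    """Striatal-score association adjusted for cortical score.

    Per-miRNA OLS on [1, striatal residual, cortical residual]; reports the
    striatal partial slope and its p-value.  Errors if the two residual
    features are essentially collinear (|r| > 0.999).
    """
    s = striatal_resid.loc[expr.columns]
    c = cortical_resid.loc[expr.columns]
    keep = s.notna() & c.notna()
    s, c = s[keep].to_numpy(float), c[keep].to_numpy(float)
    if len(s) < 4:
        raise ValueError("too few samples with both residual features")
    r = np.corrcoef(s, c)[0, 1]
    if abs(r) > 0.999:
        raise ValueError(f"striatal and cortical residuals are collinear (r={r:.4f})")
    X = np.column_stack([np.ones_like(s), s, c])
    XtX_inv = np.linalg.inv(X.T @ X)
    Y = expr.loc[:, keep.index[keep]].to_numpy(dtype=float)
    beta = Y @ X @ XtX_inv.T
    resid = Y - beta @ X.T
    df = len(s) - 3
    s2 = (resid**2).sum(axis=1) / df
    se = np.sqrt(s2 * XtX_inv[1, 1])
    t = beta[:, 1] / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return pd.DataFrame(
        {"beta_striatal": beta[:, 1], "p_striatal": p, "n_samples": len(s)},
        index=expr.index,
    )


# ---------------------------------------------------------------------------
# Correlation clustering
# ---------------------------------------------------------------------------

def correlation_cluster(
    expr: pd.DataFrame,
    residualized_features: pd.DataFrame,
    p_threshold: float = 0.05,
) -> tuple[pd.DataFrame, list[str], list[str], np.ndarray, np.ndarray]:
    """Pearson correlation of miRNA expression to CAG-adjusted features,
    filtered to miRNAs with at least one nominal p < ``p_threshold``, then
    hierarchically clustered (Euclidean distance, complete linkage) on rows
    and columns independently.

    Returns the reordered coefficient matrix, row and column leaf orders,
    and the two linkage matrices.
    """
    common = [s for s in expr.columns if s in residualized_features.index]
    if len(common) < 3:
        raise ValueError("fewer than 3 samples for correlation clustering")
    feats = residualized_features.loc[common]
    coef = pd.DataFrame(index=expr.index, columns=feats.columns, dtype=float)
    pmat = pd.DataFrame(index=expr.index, columns=feats.columns, dtype=float)
    for feature in feats.columns:
        fvals = feats[feature]
        ok = fvals.notna()
        if ok.sum() < 3:
            coef[feature] = np.nan
            pmat[feature] = np.nan
            continue
        x = fvals[ok].to_numpy(float)
        for mirna in expr.index:
            r, p = stats.pearsonr(expr.loc[mirna, ok.index[ok]].to_numpy(float), x)
            coef.loc[mirna, feature] = r
            pmat.loc[mirna, feature] = p
    keep = (pmat < p_threshold).any(axis=1)
    coef = coef.loc[keep].fillna(0.0)
    if coef.shape[0] < 2:
        return coef, list(coef.index), list(coef.columns), np.empty((0, 4)), np.empty((0, 4))
    row_linkage = hierarchy.linkage(pdist(coef.to_numpy(), metric="euclidean"),
                                    method="complete")
    col_linkage = hierarchy.linkage(pdist(coef.to_numpy().T, metric="euclidean"),
                                    method="complete")
    row_order = [coef.index[i] for i in hierarchy.leaves_list(row_linkage)]
    col_order = [coef.columns[i] for i in hierarchy.leaves_list(col_linkage)]
    ordered = coef.loc[row_order, col_order]
    return ordered, row_order, col_order, row_linkage, col_linkage
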