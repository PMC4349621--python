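"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's own code paths: plain loops, literal
formula transcriptions, and exhaustive scans, so that agreement with the
package is evidence rather than tautology.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


# --- quantifier rules, applied literally -----------------------------------

def brute_force_assign(alignments, matures, window=4, max_len=27):
    """Literal application of the three counting rules to one read.

    ``alignments``: list of (chrom, strand, start, end, read_len).
    ``matures``: list of (mature_id, chrom, strand, start, end).
    Returns ("discarded_long" | "assigned" | "discarded_multi_mature" |
    "unassigned", mature_id_or_None).
    """
    if not alignments:
        return "unassigned", None
    if alignments[0][4] > max_len:
        return "discarded_long", None
    hits = set()
    for chrom, strand, start, end, _len in alignments:
        five = start if strand == "+" else end
        for mid, mchrom, mstrand, mstart, mend in matures:
            if mchrom != chrom or mstrand != strand:
                continue
            overlap = start <= mend and mstart <= end
            m5 = mstart if mstrand == "+" else mend
            if overlap and abs(five - m5) <= window:
                hits.add(mid)
    if len(hits) == 1:
        return "assigned", hits.pop()
    if len(hits) >= 2:
        return "discarded_multi_mature", None
    return "unassigned", None


# --- normalization ---------------------------------------------------------

def median_of_ratios(matrix: np.ndarray) -> np.ndarray:
    """Literal median-of-ratios size factors (then log-centered)."""
    n_genes, n_samples = matrix.shape
    geo = np.array([
        np.exp(np.mean(np.log(matrix[i]))) if (matrix[i] > 0).all() else np.nan
        for i in range(n_genes)
    ])
    factors = np.empty(n_samples)
    for j in range(n_samples):
        ratios = [matrix[i, j] / geo[i] for i in range(n_genes) if np.isfinite(geo[i])]
        factors[j] = np.median(ratios)
    return factors / np.exp(np.mean(np.log(factors)))


# --- multiple testing ------------------------------------------------------

def bh_stepup(p: np.ndarray) -> np.ndarray:
    """Literal Benjamini-Hochberg step-up."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        q[i] = val
        prev = val
    return q


# --- ROC -------------------------------------------------------------------

def trapezoid_auc(scores, labels) -> float:
    """AUC by trapezoidal integration of the empirical ROC curve."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    tpr, fpr = [], []
    n1, n0 = labels.sum(), (~labels).sum()
    for t in thresholds:
        pred = scores >= t
        tpr.append((pred & labels).sum() / n1)
        fpr.append((pred & ~labels).sum() / n0)
    return float(np.trapezoid(tpr, fpr))


# --- hierarchical clustering ----------------------------------------------

def complete_linkage_heights(X: np.ndarray) -> list[float]:
    """Merge heights of a naive complete-linkage agglomeration.

    Euclidean distances; at each step merge the pair of clusters with the
    smallest maximum inter-point distance.  Returns the n-1 merge heights
    in merge order.
    """
    clusters = [[i] for i in range(len(X))]

    def d(a, b):
        return max(
            float(np.linalg.norm(X[i] - X[j])) for i in a for j in b
        )

    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in combinations(range(len(clusters)), 2):
            dist = d(clusters[a], clusters[b])
            if best is None or dist < best[0]:
                best = (dist, a, b)
        dist, a, b = best
        heights.append(dist)
        merged = clusters[a] + clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(merged)
    return heights


# --- compact letter display validity ---------------------------------------

def cld_is_valid(letters: dict, significant: dict) -> bool:
    """Share-a-letter iff the pair is non-significant."""
    groups = list(letters)
    for a, b in combinations(groups, 2):
        share = bool(set(letters[a]) & set(letters[b]))
        sig = significant.get(frozenset((a, b)), False)
        if sig and share:
            return False
        if not sig and not share:
            return False
    return True
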