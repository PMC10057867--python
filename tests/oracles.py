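"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a quantity from its textbook definition by
direct enumeration or dense scanning, sharing no code with the
implementation under test.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm


def minkowski_matrix(X: np.ndarray, p: float) -> np.ndarray:
    diff = np.abs(X[:, None, :] - X[None, :, :])
    return (diff**p).sum(axis=2) ** (1.0 / p)


def lof_brute(X, k: int, p: float = 2.0) -> np.ndarray:
    """Classical Local Outlier Factor by direct O(n²) enumeration."""
    X = np.asarray(X, dtype=float)
    n = len(X)
    D = minkowski_matrix(X, p)
    neighbors = []
    kdist = np.empty(n)
    for i in range(n):
        order = np.argsort(D[i])
        order = order[order != i][:k]
        neighbors.append(order)
        kdist[i] = D[i, order[-1]]
    lrd = np.empty(n)
    for i in range(n):
        reach = np.maximum(kdist[neighbors[i]], D[i, neighbors[i]])
        lrd[i] = 1.0 / (reach.mean() + 1e-10)  # duplicate-point cap convention
    lof = np.empty(n)
    for i in range(n):
        lof[i] = lrd[neighbors[i]].mean() / lrd[i]
    return lof


def silhouette_brute(X, labels) -> float:
    """Mean silhouette from the definition; singleton clusters score 0."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    D = minkowski_matrix(X, 2.0)
    s = []
    for i in range(len(X)):
        same = (labels == labels[i]) & (np.arange(len(X)) != i)
        if not same.any():
            s.append(0.0)
            continue
        a = D[i, same].mean()
        b = min(
            D[i, labels == other].mean() for other in np.unique(labels) if other != labels[i]
        )
        s.append((b - a) / max(a, b))
    return float(np.mean(s))


def complete_linkage_partitions(X) -> dict[int, set[frozenset]]:
    """Exhaustive complete-linkage agglomeration.

    Returns the partition (set of frozensets of row indices) left after
    each merge, keyed by the number of clusters.
    """
    X = np.asarray(X, dtype=float)
    n = len(X)
    D = minkowski_matrix(X, 2.0)
    clusters: list[frozenset] = [frozenset([i]) for i in range(n)]
    partitions = {n: set(clusters)}
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = max(D[i, j] for i in clusters[a] for j in clusters[b])
                if best is None or d < best[0]:
                    best = (d, a, b)
        _, a, b = best
        merged = clusters[a] | clusters[b]
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)] + [merged]
        partitions[len(clusters)] = set(clusters)
    return partitions


def speciation_scan_oracle(d1, dc, f1: float, n_grid: int = 100_001) -> float:
    """Fine-grid scan inversion of the speciation-index equation.

    Builds the log(dN/dlnF) polylines of both channels through their
    populated bins, evaluates the channel-1 level at ``f1``, scans a
    dense log-intensity grid over the channel-c support from low to
    high, and linearly refines the first sign change.
    """

    def nodes(curve):
        pos = curve.density > 0
        u = np.log(curve.support[pos])
        w = np.log(curve.density[pos] * curve.support[pos])
        return u, w

    u1, w1 = nodes(d1)
    uc, wc = nodes(dc)
    uq = np.log(f1)
    # constant end extension of the channel-1 polyline (np.interp default)
    target = np.interp(uq, u1, w1)
    if target > wc.max() + 1e-9 or target < wc.min() - 1e-9:
        raise ValueError("oracle: level outside the target curve's range")
    target = float(np.clip(target, wc.min(), wc.max()))

    us = np.linspace(uc[0], uc[-1], n_grid)
    ws = np.interp(us, uc, wc)
    diff = ws - target
    for i in range(n_grid - 1):
        if diff[i] == 0.0:
            return float(f1 / np.exp(us[i]))
        if diff[i] * diff[i + 1] < 0:
            t = diff[i] / (diff[i] - diff[i + 1])
            u_star = us[i] + t * (us[i + 1] - us[i])
            return float(f1 / np.exp(u_star))
    if diff[-1] == 0.0:
        return float(f1 / np.exp(us[-1]))
    raise ValueError("oracle: no crossing on the grid")


def ovo_vote_oracle(classes, pair_probs, thresholds) -> list[str]:
    """Naive per-row tally of thresholded one-vs-one votes."""
    n = len(next(iter(pair_probs.values())))
    out = []
    for i in range(n):
        votes = {c: 0 for c in classes}
        prob = {c: 0.0 for c in classes}
        for (a, b), p in pair_probs.items():
            if p[i] >= thresholds[(a, b)]:
                votes[b] += 1
                prob[b] += p[i]
            else:
                votes[a] += 1
                prob[a] += 1.0 - p[i]
        best = max(votes.values())
        cands = [c for c in classes if votes[c] == best]
        best_p = max(prob[c] for c in cands)
        cands = [c for c in cands if prob[c] == best_p]
        out.append(min(cands))
    return out


def bayes_accuracy_two_gaussians(mu_delta: float) -> float:
    """Optimal accuracy for two equal-prior Gaussians N(0, I) and
    N(Δ·e₁, I): Φ(Δ/2)."""
    return float(norm.cdf(mu_delta / 2.0))
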