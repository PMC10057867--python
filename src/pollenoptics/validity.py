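"""Internal cluster-validity indices and the cluster-count vote.

The cluster count is chosen by letting a fixed set of ten internal
validity indices each vote for its preferred k on the hierarchical
partitions, with the majority (ties to the smaller k) winning:

=================  ==========================================
silhouette          maximize
Calinski–Harabasz   maximize
Davies–Bouldin      minimize
Dunn                maximize
C-index             minimize
McClain–Rao         minimize
gap statistic       Tibshirani one-standard-error rule
Ball–Hall           largest drop between successive k
Hartigan            smallest k with H(k) <= 10
Xie–Beni            minimize
=================  ==========================================

The index set and every decision rule are frozen so the vote is
reproducible; a k whose partition degenerates (fewer than k non-empty
clusters) is skipped.
"""

from __future__ import annotations

from collections import Counter
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import calinski_harabasz_score, davies_bouldin_score, silhouette_score

from .simulate import as_rng

HARTIGAN_CUTOFF = 10.0
GAP_N_REFERENCES = 10


def _centroids(X, labels):
    labs = np.unique(labels)
    return labs, np.array([X[labels == l].mean(axis=0) for l in labs])


def total_within_ss(X, labels) -> float:
    """Total within-cluster sum of squared distances to centroids."""
    labs, cents = _centroids(X, labels)
    w = 0.0
    for l, c in zip(labs, cents):
        w += float(((X[labels == l] - c) ** 2).sum())
    return w


def dunn_index(X, labels) -> float:
    """min inter-cluster point distance / max intra-cluster diameter."""
    D = squareform(pdist(X))
    labels = np.asarray(labels)
    labs = np.unique(labels)
    max_diam = 0.0
    for l in labs:
        idx = np.where(labels == l)[0]
        if len(idx) > 1:
            max_diam = max(max_diam, D[np.ix_(idx, idx)].max())
    min_sep = np.inf
    for i, a in enumerate(labs):
        for b in labs[i + 1:]:
            ia, ib = np.where(labels == a)[0], np.where(labels == b)[0]
            min_sep = min(min_sep, D[np.ix_(ia, ib)].min())
    if max_diam == 0:
        return np.inf
    return float(min_sep / max_diam)


def _same_label_pairs(labels) -> np.ndarray:
    """Condensed-form (pdist-ordered) mask of same-cluster pairs."""
    labels = np.asarray(labels)
    iu = np.triu_indices(len(labels), k=1)
    return labels[iu[0]] == labels[iu[1]]


def c_index(X, labels) -> float:
    """(S_w − S_min) / (S_max − S_min) over within-cluster pair distances."""
    d = pdist(X)
    same = _same_label_pairs(labels)
    n_w = int(same.sum())
    if n_w == 0:
        return np.nan
    s_w = float(d[same].sum())
    d_sorted = np.sort(d)
    s_min = float(d_sorted[:n_w].sum())
    s_max = float(d_sorted[-n_w:].sum())
    if s_max == s_min:
        return 0.0
    return (s_w - s_min) / (s_max - s_min)


def mcclain_rao_index(X, labels) -> float:
    """Mean within-pair distance over mean between-pair distance."""
    d = pdist(X)
    same = _same_label_pairs(labels)
    n_w, n_b = int(same.sum()), int((~same).sum())
    if n_w == 0 or n_b == 0:
        return np.nan
    return float((d[same].mean()) / (d[~same].mean()))


def ball_hall_index(X, labels) -> float:
    """Mean over clusters of per-cluster mean squared centroid distance."""
    labs, cents = _centroids(X, labels)
    vals = []
    for l, c in zip(labs, cents):
        pts = X[labels == l]
        vals.append(float(((pts - c) ** 2).sum()) / len(pts))
    return float(np.mean(vals))


def xie_beni_index(X, labels) -> float:
    """Within-cluster SS over n × squared minimum centroid separation."""
    labs, cents = _centroids(X, labels)
    if len(labs) < 2:
        return np.nan
    sep = pdist(cents) ** 2
    return float(total_within_ss(X, labels) / (len(X) * sep.min()))


def _labels_for_range(X, ks: Sequence[int], metric: str, method: str) -> dict[int, np.ndarray]:
    Z = scipy_linkage(X, method=method, metric=metric)
    return {k: fcluster(Z, t=k, criterion="maxclust") for k in ks}


def gap_statistic(
    X, ks: Sequence[int], rng=None, n_references: int = GAP_N_REFERENCES,
    metric: str = "euclidean", method: str = "complete",
) -> tuple[np.ndarray, np.ndarray]:
    """Gap(k) = E*[log W_k] − log W_k with uniform bounding-box references.

    Returns (gap values, standard errors s_k), aligned with ``ks``.
    """
    X = np.asarray(X, dtype=float)
    rng = as_rng(rng)
    ks = list(ks)
    labels = _labels_for_range(X, ks, metric, method)
    log_w = np.array([np.log(max(total_within_ss(X, labels[k]), 1e-300)) for k in ks])
    lo, hi = X.min(axis=0), X.max(axis=0)
    ref_log_w = np.empty((n_references, len(ks)))
    for b in range(n_references):
        ref = rng.uniform(lo, hi, size=X.shape)
        ref_labels = _labels_for_range(ref, ks, metric, method)
        ref_log_w[b] = [np.log(max(total_within_ss(ref, ref_labels[k]), 1e-300)) for k in ks]
    gap = ref_log_w.mean(axis=0) - log_w
    s = ref_log_w.std(axis=0) * np.sqrt(1.0 + 1.0 / n_references)
    return gap, s


def optimal_k_vote(
    X,
    k_range: Sequence[int] = range(2, 9),
    metric: str = "euclidean",
    method: str = "complete",
    rng=None,
) -> tuple[int, dict[str, int]]:
    """Majority vote of the ten validity indices over ``k_range``.

    Returns ``(winning k, per-index votes)``; ties go to the smaller k.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    ks = [k for k in k_range if 2 <= k <= n - 1]
    if not ks:
        raise ValueError("k_range contains no feasible k")
    rng = as_rng(rng)

    # Partitions for ks, plus k±1 neighbours needed by elbow-style rules.
    extra = sorted({1, max(ks) + 1} | set(k - 1 for k in ks if k - 1 >= 1))
    all_ks = sorted(set(ks) | {k for k in extra if k <= n})
    labels = _labels_for_range(X, all_ks, metric, method)
    valid = {k for k in ks if len(np.unique(labels[k])) == k}

    def best(metric_by_k: dict[int, float], maximize: bool) -> int | None:
        items = [(k, v) for k, v in metric_by_k.items() if np.isfinite(v)]
        if not items:
            return None
        key = (lambda kv: (-kv[1], kv[0])) if maximize else (lambda kv: (kv[1], kv[0]))
        return sorted(items, key=key)[0][0]

    votes: dict[str, int] = {}

    per_k = {k: labels[k] for k in valid}
    votes_spec = {
        "silhouette": ({k: silhouette_score(X, l) for k, l in per_k.items()}, True),
        "calinski_harabasz": ({k: calinski_harabasz_score(X, l) for k, l in per_k.items()}, True),
        "davies_bouldin": ({k: davies_bouldin_score(X, l) for k, l in per_k.items()}, False),
        "dunn": ({k: dunn_index(X, l) for k, l in per_k.items()}, True),
        "c_index": ({k: c_index(X, l) for k, l in per_k.items()}, False),
        "mcclain_rao": ({k: mcclain_rao_index(X, l) for k, l in per_k.items()}, False),
        "xie_beni": ({k: xie_beni_index(X, l) for k, l in per_k.items()}, False),
    }
    for name, (vals, maximize) in votes_spec.items():
        k = best(vals, maximize)
        if k is not None:
            votes[name] = k

    # Ball–Hall: largest drop BH(k−1) − BH(k).
    bh = {k: ball_hall_index(X, labels[k]) for k in all_ks if k in labels}
    bh_drop = {k: bh[k - 1] - bh[k] for k in valid if (k - 1) in bh}
    k = best(bh_drop, True)
    if k is not None:
        votes["ball_hall"] = k

    # Hartigan: smallest k with H(k) <= cutoff, else argmin H.
    w = {k: total_within_ss(X, labels[k]) for k in all_ks}
    hart = {
        k: (w[k] / w[k + 1] - 1.0) * (n - k - 1)
        for k in valid if (k + 1) in w and w[k + 1] > 0
    }
    if hart:
        small = sorted(k for k, h in hart.items() if h <= HARTIGAN_CUTOFF)
        votes["hartigan"] = small[0] if small else best(hart, False)

    # Gap statistic: smallest k with Gap(k) >= Gap(k+1) − s(k+1).
    gap_ks = sorted(valid | ({max(ks) + 1} if max(ks) + 1 <= n else set()))
    gap, s = gap_statistic(X, gap_ks, rng=rng, metric=metric, method=method)
    gap_by_k = dict(zip(gap_ks, gap))
    s_by_k = dict(zip(gap_ks, s))
    chosen = None
    for k in sorted(valid):
        if k + 1 in gap_by_k and gap_by_k[k] >= gap_by_k[k + 1] - s_by_k[k + 1]:
            chosen = k
            break
    if chosen is None:
        chosen = best({k: gap_by_k[k] for k in valid if k in gap_by_k}, True)
    if chosen is not None:
        votes["gap"] = chosen

    counts = Counter(votes.values())
    top = max(counts.values())
    winner = min(k for k, c in counts.items() if c == top)
    return winner, votes
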