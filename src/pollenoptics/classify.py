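"""Per-size-cluster species classification of optical signatures.

Within each size cluster a one-vs-one (OvO) scheme trains one binary
logistic regression per unordered class pair on the 6-element optical
signatures (log-transformed, then standardized — the entries are
positive ratios spanning decades).  Each pair's decision threshold is
tuned on held-out folds to maximize the macro F1-score over a fixed
probability grid; at prediction time every pair casts a thresholded
vote and the majority wins (ties: highest sum of winning-pair
probabilities, then lexicographic class order).  Generalization is
assessed with repeated stratified 10-fold cross-validation, reported as
per-class recall and confusion matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedKFold

logger = logging.getLogger(__name__)

UNCLASSIFIED = "unclassified"

#: default decision-threshold grid: 0.05 .. 0.95 in steps of 0.05
DEFAULT_THRESHOLD_GRID = tuple(float(t) for t in np.round(np.arange(0.05, 0.951, 0.05), 2))


def _valid_rows(X: np.ndarray) -> np.ndarray:
    """Signatures usable as features: finite and strictly positive."""
    return np.isfinite(X).all(axis=1) & (X > 0).all(axis=1)


@dataclass
class PairClassifier:
    """One binary logistic model with its tuned decision threshold.

    ``classes`` is the (lexicographically ordered) pair (a, b); the
    model's probability refers to class b.
    """

    classes: tuple[str, str]
    model: LogisticRegression
    threshold: float


@dataclass
class OvOModel:
    """A fitted one-vs-one ensemble for one size cluster."""

    classes_: tuple[str, ...]
    pairs: dict[tuple[str, str], PairClassifier]
    log_mean: np.ndarray
    log_scale: np.ndarray
    cluster_id: int | None = None

    def transform(self, X) -> np.ndarray:
        Z = (np.log(np.asarray(X, dtype=float)) - self.log_mean) / self.log_scale
        return Z


def _tune_threshold(
    y: np.ndarray,
    rows: np.ndarray,
    pair: tuple[str, str],
    grid: Sequence[float],
    inner_folds: int,
    seed: int,
) -> float:
    """Pick the F1-maximizing threshold from pooled inner-fold predictions.

    Ties go to the threshold closest to 0.5, then the smaller one.
    """
    a, b = pair
    yv_all, pv_all = [], []
    skf = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    yb = (y == b).astype(int)
    for tr, va in skf.split(rows, yb):
        clf = LogisticRegression(max_iter=2000)
        clf.fit(rows[tr], yb[tr])
        pv_all.append(clf.predict_proba(rows[va])[:, list(clf.classes_).index(1)])
        yv_all.append(y[va])
    yv = np.concatenate(yv_all)
    pv = np.concatenate(pv_all)
    best = (-np.inf, np.inf, np.inf)  # (f1, |t-0.5|, t)
    best_t = 0.5
    for t in grid:
        pred = np.where(pv >= t, b, a)
        f1 = f1_score(yv, pred, labels=[a, b], average="macro", zero_division=0)
        key = (-f1, abs(t - 0.5), t)
        if key < (-best[0], best[1], best[2]):
            best = (f1, abs(t - 0.5), t)
            best_t = float(t)
    return best_t


def train_ovo(
    X,
    labels,
    seed: int = 0,
    threshold_grid: Sequence[float] = DEFAULT_THRESHOLD_GRID,
    inner_folds: int = 3,
    cluster_id: int | None = None,
) -> OvOModel:
    """Fit one thresholded binary logistic model per class pair.

    With a single-element threshold grid no inner split is made and the
    scheme reduces to plain OvO voting at that threshold.  Rows with
    non-finite or non-positive signature entries are rejected (logged).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels).astype(str)
    ok = _valid_rows(X)
    if not ok.all():
        logger.info("train_ovo: rejecting %d invalid signature rows", int((~ok).sum()))
    X, y = X[ok], y[ok]
    classes = tuple(sorted(np.unique(y)))
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    counts = {c: int((y == c).sum()) for c in classes}
    tune = len(threshold_grid) > 1
    min_needed = inner_folds if tune else 1
    for c, n in counts.items():
        if n < min_needed:
            raise ValueError(f"class {c!r} has {n} rows; needs at least {min_needed}")

    logX = np.log(X)
    mean = logX.mean(axis=0)
    scale = logX.std(axis=0)
    scale[scale == 0] = 1.0
    Z = (logX - mean) / scale

    rng = np.random.default_rng(seed)
    pairs: dict[tuple[str, str], PairClassifier] = {}
    for a, b in combinations(classes, 2):
        sel = (y == a) | (y == b)
        rows, ysub = Z[sel], y[sel]
        pair_seed = int(rng.integers(2**31))
        if tune:
            t = _tune_threshold(ysub, rows, (a, b), threshold_grid, inner_folds, pair_seed)
        else:
            t = float(threshold_grid[0])
        clf = LogisticRegression(max_iter=2000)
        clf.fit(rows, (ysub == b).astype(int))
        pairs[(a, b)] = PairClassifier(classes=(a, b), model=clf, threshold=t)
    return OvOModel(
        classes_=classes, pairs=pairs, log_mean=mean, log_scale=scale, cluster_id=cluster_id
    )


def aggregate_votes(
    classes: Sequence[str],
    pair_probs: Mapping[tuple[str, str], np.ndarray],
    thresholds: Mapping[tuple[str, str], float],
) -> np.ndarray:
    """Combine pairwise thresholded decisions into final labels.

    ``pair_probs[(a, b)]`` is the probability of class b per row.  Each
    pair votes b when its probability meets its threshold, else a; the
    label with most votes wins, ties broken by the larger sum of
    winning-pair probabilities, then lexicographically.
    """
    classes = list(classes)
    some = next(iter(pair_probs.values()))
    n = len(some)
    votes = {c: np.zeros(n) for c in classes}
    probsum = {c: np.zeros(n) for c in classes}
    for (a, b), p_b in pair_probs.items():
        win_b = p_b >= thresholds[(a, b)]
        votes[b] += win_b
        votes[a] += ~win_b
        probsum[b] += np.where(win_b, p_b, 0.0)
        probsum[a] += np.where(win_b, 0.0, 1.0 - p_b)
    order = sorted(classes)
    vote_mat = np.stack([votes[c] for c in order])
    prob_mat = np.stack([probsum[c] for c in order])
    winners = [
        order[min(range(len(order)), key=lambda j: (-vote_mat[j, i], -prob_mat[j, i], order[j]))]
        for i in range(n)
    ]
    return np.array(winners, dtype=object)


def predict(model: OvOModel, X) -> np.ndarray:
    """Predict labels; rows with invalid signatures get ``unclassified``."""
    X = np.asarray(X, dtype=float)
    out = np.full(len(X), UNCLASSIFIED, dtype=object)
    ok = _valid_rows(X)
    if not ok.any():
        return out
    Z = model.transform(X[ok])
    pair_probs = {}
    thresholds = {}
    for (a, b), pc in model.pairs.items():
        idx = list(pc.model.classes_).index(1)
        pair_probs[(a, b)] = pc.model.predict_proba(Z)[:, idx]
        thresholds[(a, b)] = pc.threshold
    out[ok] = aggregate_votes(model.classes_, pair_probs, thresholds)
    return out


@dataclass
class ClassifierReport:
    """Cross-validated confusion counts and per-class recall.

    ``confusion`` rows are true classes (each row sums to
    support × repeats, plus an ``unclassified`` column when needed);
    ``recall`` is diagonal / row sum.
    """

    confusion: pd.DataFrame
    recall: pd.Series
    folds: int
    repeats: int
    seed: int
    cluster_id: int | None = None

    def check(self) -> None:
        assert ((self.recall >= 0) & (self.recall <= 1)).all()
        assert (self.confusion.to_numpy() >= 0).all()


def evaluate_cv(
    X,
    labels,
    folds: int = 10,
    repeats: int = 5,
    seed: int = 0,
    threshold_grid: Sequence[float] = DEFAULT_THRESHOLD_GRID,
    inner_folds: int = 3,
    cluster_id: int | None = None,
) -> ClassifierReport:
    """Repeated stratified k-fold evaluation of the OvO scheme.

    Thresholds are tuned inside the training folds only; confusion
    counts accumulate over repeats.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels).astype(str)
    ok = _valid_rows(X)
    X, y = X[ok], y[ok]
    classes = sorted(np.unique(y))
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    min_count = min(int((y == c).sum()) for c in classes)
    if min_count < folds:
        raise ValueError(
            f"smallest class has {min_count} members < {folds} folds; use fewer folds"
        )

    cols = classes + [UNCLASSIFIED]
    confusion = pd.DataFrame(0, index=classes, columns=cols, dtype=int)
    rskf = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
    rng = np.random.default_rng(seed)
    for tr, te in rskf.split(X, y):
        model = train_ovo(
            X[tr], y[tr], seed=int(rng.integers(2**31)),
            threshold_grid=threshold_grid, inner_folds=inner_folds,
        )
        pred = predict(model, X[te])
        for yt, yp in zip(y[te], pred):
            confusion.loc[yt, yp] += 1

    if confusion[UNCLASSIFIED].sum() == 0:
        confusion = confusion.drop(columns=[UNCLASSIFIED])
    support = confusion.sum(axis=1)
    diag = pd.Series(
        [confusion.loc[c, c] if c in confusion.columns else 0 for c in classes], index=classes
    )
    recall = diag / support
    report = ClassifierReport(
        confusion=confusion, recall=recall, folds=folds, repeats=repeats,
        seed=seed, cluster_id=cluster_id,
    )
    report.check()
    return report


def per_cluster_classify(
    signatures: pd.DataFrame,
    rosters: Mapping[int, Sequence[str]],
    feature_columns: Sequence[str],
    seed: int = 0,
    folds: int = 10,
    repeats: int = 5,
    threshold_grid: Sequence[float] = DEFAULT_THRESHOLD_GRID,
    inner_folds: int = 3,
) -> dict[int, ClassifierReport]:
    """Train and evaluate one OvO model per size cluster.

    ``signatures`` needs a ``label`` column, a ``cluster`` column
    (NaN/absent cluster means the row is roster-assigned, e.g. the
    non-pollen classes), and the feature columns.  ``rosters`` maps each
    cluster id to the labels evaluated in it; a label appears in a
    cluster when either the roster lists it or its own rows carry that
    cluster id.  Empty or single-class clusters are skipped with a
    warning.
    """
    reports: dict[int, ClassifierReport] = {}
    rng = np.random.default_rng(seed)
    for cluster_id, roster in sorted(rosters.items()):
        in_cluster = signatures["cluster"] == cluster_id
        by_roster = signatures["label"].isin(roster) & signatures["cluster"].isna()
        sub = signatures[in_cluster | by_roster]
        n_classes = sub["label"].nunique()
        if len(sub) == 0 or n_classes < 2:
            logger.warning(
                "cluster %s: skipped (%d rows, %d classes)", cluster_id, len(sub), n_classes
            )
            continue
        reports[cluster_id] = evaluate_cv(
            sub[list(feature_columns)].to_numpy(),
            sub["label"].to_numpy(),
            folds=folds, repeats=repeats, seed=int(rng.integers(2**31)),
            threshold_grid=threshold_grid, inner_folds=inner_folds,
            cluster_id=cluster_id,
        )
    return reports
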