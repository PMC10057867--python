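"""Stage 1 of the analysis: size-based pre-processing and clustering.

Per species session, frames contaminated by ambient particles,
aggregates or debris are removed with a Local Outlier Factor filter
whose parameters are tuned by a silhouette-scored grid search.  The
surviving frames are oversampled into cumulative size distributions
(random frames summed until every occupied size bin holds at least 20
particles — the count needed for stable mean scattering properties),
row-normalized, checked for clustering tendency with the Hopkins
statistic, and clustered with complete-linkage agglomeration; a voting
scheme over internal validity indices picks the cluster count.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial import cKDTree
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score
from sklearn.neighbors import LocalOutlierFactor

from .instrument import Frame, InstrumentConfig, frame_to_size_distribution, sum_frames
from .simulate import Session, as_rng

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Local Outlier Factor
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LOFParams:
    """LOF settings: neighbourhood size, Minkowski metric order, and the
    score above which a row is declared an outlier (LOF ≈ 1 for inliers)."""

    n_neighbors: int = 20
    minkowski_p: int = 2
    score_threshold: float = 1.5

    def __post_init__(self) -> None:
        if self.n_neighbors < 1:
            raise ValueError("n_neighbors must be >= 1")
        if self.minkowski_p < 1:
            raise ValueError("minkowski_p must be >= 1")
        if self.score_threshold <= 1.0:
            raise ValueError("score_threshold must be > 1")


def default_lof_grid() -> list[LOFParams]:
    return [LOFParams(n, p) for n in (5, 10, 20, 35) for p in (1, 2)]


def lof_scores(X, params: LOFParams) -> np.ndarray:
    """Classical LOF score per row (higher = more outlying).

    Duplicate points with degenerate (infinite) local reachability
    density follow the sklearn convention: their density is capped so
    scores stay finite.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < params.n_neighbors + 1:
        raise ValueError(
            f"need at least n_neighbors+1={params.n_neighbors + 1} rows, got {X.shape[0]}"
        )
    lof = LocalOutlierFactor(n_neighbors=params.n_neighbors, p=params.minkowski_p)
    with warnings.catch_warnings():
        # duplicate rows (common in sparse count frames) get capped
        # reachability densities; that convention is intended here
        warnings.filterwarnings("ignore", message="Duplicate values")
        lof.fit(X)
    return -lof.negative_outlier_factor_


def lof_inlier_mask(X, params: LOFParams) -> np.ndarray:
    return lof_scores(X, params) <= params.score_threshold


def silhouette(X, labels) -> float:
    """Mean silhouette of a labelling (singleton clusters score 0).

    Raises ``ValueError`` when fewer than two labels are present.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette needs at least two clusters")
    return float(silhouette_score(X, labels))


def tune_lof(
    X,
    grid: Sequence[LOFParams] | None = None,
    rng=None,
    n_folds: int = 5,
    subsample: float = 0.8,
) -> LOFParams:
    """Pick the LOF parameters whose inlier/outlier split silhouettes best.

    For each grid point the rows are repeatedly subsampled (``n_folds``
    random 80 % draws), LOF is run on the subsample, and the silhouette
    of the resulting two-way partition is computed; the grid point with
    the best mean silhouette wins.  Degenerate all-inlier or all-outlier
    partitions score −1.  Ties go to the smallest neighbourhood, then
    the smallest Minkowski order.
    """
    X = np.asarray(X, dtype=float)
    if grid is None:
        grid = default_lof_grid()
    grid = list(grid)
    if not grid:
        raise ValueError("empty LOF grid")
    rng = as_rng(rng)
    n = X.shape[0]
    m = max(2, int(round(subsample * n)))
    folds = [rng.choice(n, size=m, replace=False) for _ in range(n_folds)]

    results: list[tuple[float, int, int, LOFParams]] = []
    for params in grid:
        if params.n_neighbors + 1 > m:
            continue  # not enough rows for this neighbourhood
        scores = []
        for idx in folds:
            sub = X[idx]
            outlier = lof_scores(sub, params) > params.score_threshold
            if outlier.all() or (~outlier).all():
                scores.append(-1.0)
            else:
                scores.append(silhouette(sub, outlier.astype(int)))
        results.append((float(np.mean(scores)), params.n_neighbors, params.minkowski_p, params))
    if not results:
        raise ValueError("no feasible grid point for this dataset size")
    results.sort(key=lambda r: (-r[0], r[1], r[2]))
    return results[0][3]


def filter_session(
    session: Session,
    grid: Sequence[LOFParams] | None = None,
    rng=None,
    params: LOFParams | None = None,
) -> tuple[list[Frame], np.ndarray, LOFParams, float]:
    """LOF-filter a session on its channel-1 count rows.

    Returns (inlier frames, inlier mask, chosen params, silhouette of
    the final split; NaN when the split is degenerate).
    """
    X = np.array([f.counts[0] for f in session.frames], dtype=float)
    if params is None:
        params = tune_lof(X, grid=grid, rng=rng)
    mask = lof_inlier_mask(X, params)
    if mask.all() or (~mask).all():
        sil = float("nan")
    else:
        sil = silhouette(X, mask.astype(int))
    kept = [f for f, m in zip(session.frames, mask) if m]
    logger.info(
        "LOF filter %s: kept %d/%d frames (n_neighbors=%d, p=%d, silhouette=%.3f)",
        session.species, len(kept), len(mask), params.n_neighbors, params.minkowski_p, sil,
    )
    return kept, mask, params, sil


# ---------------------------------------------------------------------------
# Oversampling into cumulative distributions
# ---------------------------------------------------------------------------


def oversample_cumulative(
    frames: Sequence[Frame],
    n_draws: int = 30,
    min_per_bin: int = 20,
    rng=None,
    budget_factor: int = 10,
) -> tuple[list[Frame], np.ndarray]:
    """Sum randomly drawn frames (with replacement) into cumulative ones.

    Each draw keeps adding frames until every *occupied* channel-1 size
    bin holds at least ``min_per_bin`` counts, or until
    ``budget_factor × len(frames)`` frames have been used, in which case
    the row is flagged (returned mask True = flagged).  A bin counts as
    occupied when the whole session holds at least ``min_per_bin``
    counts in it: a bin the session itself cannot fill (a stray debris
    count) would otherwise force every draw into the budget cap and
    collapse all rows onto the scaled session mean.  Counts are
    conserved: each cumulative frame is an exact sum of its
    constituents, on all four channels.
    """
    if len(frames) == 0:
        raise ValueError("cannot oversample an empty session")
    rng = as_rng(rng)
    session_total = np.sum([f.counts[0] for f in frames], axis=0)
    occupied = session_total >= min_per_bin
    if not occupied.any():
        occupied = session_total > 0
    budget = budget_factor * len(frames)

    cumulative: list[Frame] = []
    flagged = np.zeros(n_draws, dtype=bool)
    for i in range(n_draws):
        total = np.zeros_like(frames[0].counts)
        used = 0
        while used < budget:
            f = frames[rng.integers(len(frames))]
            total = total + f.counts
            used += 1
            if np.all(total[0][occupied] >= min_per_bin):
                break
        else:
            pass
        if not np.all(total[0][occupied] >= min_per_bin):
            flagged[i] = True
        cumulative.append(Frame(timestamp=float(i), counts=total))
    if flagged.any():
        logger.warning("oversampling: %d/%d draws hit the frame budget", int(flagged.sum()), n_draws)
    return cumulative, flagged


@dataclass
class CumulativeDataset:
    """Cumulative size distributions, one row per oversampling draw.

    ``matrix`` is (n_species × n_draws, 19) channel-1 counts (or row
    shares after :meth:`normalized`); ``frames`` keeps the full
    four-channel cumulative frames for the speciation stage.
    """

    matrix: np.ndarray
    species: np.ndarray
    frames: list[Frame]
    flagged: np.ndarray
    normalized: bool = False
    zero_rows: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.zero_rows is None:
            self.zero_rows = np.zeros(len(self.matrix), dtype=bool)
        if not self.normalized:
            m = self.matrix
            if np.any(m < 0) or not np.allclose(m, np.round(m)):
                raise ValueError("un-normalized cumulative rows must be non-negative integers")

    def normalized_copy(self) -> "CumulativeDataset":
        m, zero = row_normalize(self.matrix)
        return CumulativeDataset(
            matrix=m, species=self.species, frames=self.frames,
            flagged=self.flagged, normalized=True, zero_rows=zero,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=[f"size_bin{b}" for b in range(1, 20)])
        df.insert(0, "species", self.species)
        df["flagged"] = self.flagged
        return df


def build_cumulative_dataset(
    inlier_frames: Mapping[str, Sequence[Frame]],
    n_draws: int = 30,
    min_per_bin: int = 20,
    rng=None,
    budget_factor: int = 10,
) -> CumulativeDataset:
    """Oversample every species and concatenate the rows (30 draws × 12
    species → 360 rows in the study layout)."""
    rng = as_rng(rng)
    rows, labels, all_frames, flags = [], [], [], []
    for name, frames in inlier_frames.items():
        cum, flagged = oversample_cumulative(frames, n_draws, min_per_bin, rng, budget_factor)
        for f, fl in zip(cum, flagged):
            rows.append(f.counts[0].astype(float))
            labels.append(name)
            all_frames.append(f)
            flags.append(fl)
    return CumulativeDataset(
        matrix=np.array(rows), species=np.array(labels), frames=all_frames,
        flagged=np.array(flags),
    )


def row_normalize(M) -> tuple[np.ndarray, np.ndarray]:
    """Divide each row by its sum; zero rows are left zero and flagged.

    Returns ``(normalized matrix, zero-row mask)``.
    """
    M = np.asarray(M, dtype=float)
    if np.any(M < 0):
        raise ValueError("rows must be non-negative")
    sums = M.sum(axis=1)
    zero = sums == 0
    out = M.copy()
    out[~zero] = M[~zero] / sums[~zero, None]
    return out, zero


# ---------------------------------------------------------------------------
# Clustering tendency, hierarchical clustering, projection
# ---------------------------------------------------------------------------


def hopkins(X, sample_fraction: float = 0.1, rng=None) -> float:
    """Hopkins clustering-tendency statistic in [0, 1].

    ``m`` sample points are drawn from the data and ``m`` reference
    points uniformly from the data's bounding box; ``H = Σu / (Σu + Σw)``
    where ``u`` are reference-to-nearest-data distances and ``w`` are
    sample-to-nearest-other-data distances.  H ≈ 0.5 for spatially
    random data, → 1 for strongly clustered data.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 10:
        raise ValueError("hopkins needs at least 10 rows")
    rng = as_rng(rng)
    m = max(10, int(round(sample_fraction * n)))
    m = min(m, n - 1)
    tree = cKDTree(X)

    lo, hi = X.min(axis=0), X.max(axis=0)
    ref = rng.uniform(lo, hi, size=(m, X.shape[1]))
    u, _ = tree.query(ref, k=1)

    idx = rng.choice(n, size=m, replace=False)
    w, _ = tree.query(X[idx], k=2)  # nearest other point = second neighbour
    w = w[:, 1]

    denom = u.sum() + w.sum()
    if denom == 0:
        return 0.5
    return float(u.sum() / denom)


@dataclass
class ClusterModel:
    """A fitted agglomeration: merge tree, chosen k, and row labels."""

    linkage: np.ndarray
    k: int
    labels: np.ndarray
    metric: str = "euclidean"
    method: str = "complete"

    def cut(self, k: int) -> np.ndarray:
        return fcluster(self.linkage, t=k, criterion="maxclust")

    def majority_cluster(self, species: Sequence[str]) -> dict[str, int]:
        """Per-species majority cluster label."""
        species = np.asarray(species)
        out: dict[str, int] = {}
        for name in pd.unique(species):
            labs, counts = np.unique(self.labels[species == name], return_counts=True)
            out[name] = int(labs[np.argmax(counts)])
        return out


def hierarchical_cluster(
    X, k: int, metric: str = "euclidean", method: str = "complete"
) -> ClusterModel:
    """Agglomerative clustering cut at ``k`` clusters (complete linkage
    with Euclidean distances by default)."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not (1 <= k <= n):
        raise ValueError(f"k must lie in 1..{n}, got {k}")
    Z = scipy_linkage(X, method=method, metric=metric)
    labels = fcluster(Z, t=k, criterion="maxclust")
    return ClusterModel(linkage=Z, k=k, labels=labels, metric=metric, method=method)


def pca_project(X, n_components: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Centered (not rescaled) PCA projection.

    Component signs are fixed by making each loading vector's
    largest-magnitude entry positive.  Returns ``(coordinates,
    explained-variance shares)``.
    """
    X = np.asarray(X, dtype=float)
    if n_components > min(X.shape[0] - 1, X.shape[1]):
        raise ValueError("n_components too large for this dataset")
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    comps = pca.components_
    for i in range(n_components):
        j = int(np.argmax(np.abs(comps[i])))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
            coords[:, i] = -coords[:, i]
    return coords, pca.explained_variance_ratio_


def session_size_distribution(session_or_frames, cfg: InstrumentConfig):
    """Session-wide number size distribution (channel-1 counts summed)."""
    frames = session_or_frames.frames if isinstance(session_or_frames, Session) else session_or_frames
    return frame_to_size_distribution(sum_frames(list(frames)), cfg)
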