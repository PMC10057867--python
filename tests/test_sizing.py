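import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pollenoptics.instrument import Frame
from pollenoptics.simulate import ContaminationModel, simulate_session
from pollenoptics.sizing import (
    LOFParams,
    build_cumulative_dataset,
    filter_session,
    hierarchical_cluster,
    hopkins,
    lof_scores,
    oversample_cumulative,
    pca_project,
    row_normalize,
    silhouette,
    tune_lof,
)

from oracles import complete_linkage_partitions, lof_brute, silhouette_brute


def _random_frames(rng, n, lam=40.0):
    frames = []
    for i in range(n):
        counts = np.zeros((4, 19), dtype=int)
        counts[0] = rng.poisson(lam / 19, 19)
        frames.append(Frame(10.0 * i, counts))
    return frames


class TestLOF:
    @pytest.mark.parametrize("p", [1, 2])
    @pytest.mark.parametrize("n,dim,k", [(8, 2, 2), (12, 3, 3), (10, 19, 4)])
    def test_matches_brute_force_oracle(self, rng, n, dim, k, p):
        X = rng.normal(size=(n, dim))
        got = lof_scores(X, LOFParams(n_neighbors=k, minkowski_p=p))
        expected = lof_brute(X, k, p)
        assert np.allclose(got, expected, rtol=1e-6)

    def test_far_point_scores_much_higher(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0], [100.0]])
        scores = lof_scores(X, LOFParams(n_neighbors=2))
        assert scores[4] > 10 * scores[:4].max()
        assert np.allclose(scores, lof_brute(X, 2, 2), rtol=1e-6)

    def test_regular_simplex_is_perfectly_homogeneous(self):
        X = np.eye(4)  # vertices of a regular simplex
        scores = lof_scores(X, LOFParams(n_neighbors=2))
        assert np.allclose(scores, 1.0)

    def test_two_dense_blobs_score_near_one(self, rng):
        X = np.vstack([rng.normal(0, 0.1, (30, 2)), rng.normal(10, 0.1, (30, 2))])
        scores = lof_scores(X, LOFParams(n_neighbors=5))
        # the bulk of both blobs is locally homogeneous (blob fringes
        # can legitimately score higher)
        assert np.median(scores) < 1.1
        assert (scores < 1.5).mean() > 0.9
        assert np.allclose(scores, lof_brute(X, 5, 2), rtol=1e-6)

    def test_needs_enough_rows(self):
        with pytest.raises(ValueError):
            lof_scores(np.zeros((3, 2)), LOFParams(n_neighbors=5))


class TestTuneLOF:
    def test_single_element_grid_returned(self, rng):
        X = rng.normal(size=(40, 3))
        only = LOFParams(n_neighbors=7, minkowski_p=1)
        assert tune_lof(X, [only], rng=rng) == only

    def test_planted_outliers_recovered(self, rng):
        X = np.vstack([rng.normal(0, 1, (60, 4)), rng.normal(30, 1, (5, 4))])
        params = tune_lof(X, rng=rng)
        mask = lof_scores(X, params) > params.score_threshold
        assert set(np.where(mask)[0]) == {60, 61, 62, 63, 64}

    def test_filter_reduces_aggregate_peak_mass(self, cfg, registry):
        # after outlier removal the 40 µm aggregate peak of an
        # olive-like session must lose volume share
        from pollenoptics.sizing import session_size_distribution

        session = simulate_session(
            registry["Olea euopaea"], ContaminationModel(), 231, cfg,
            np.random.default_rng(23),
        )
        before = session_size_distribution(session, cfg).to_volume()
        kept, mask, _, _ = filter_session(session, rng=np.random.default_rng(1))
        after = session_size_distribution(kept, cfg).to_volume()
        agg_bin = np.argmin(np.abs(before.bin_centers - 40.0))
        share_before = before.counts[agg_bin] / before.total()
        share_after = after.counts[agg_bin] / after.total()
        assert share_after < share_before


class TestSilhouette:
    def test_hand_computed_value(self):
        X = np.array([[0.0], [1.0], [5.0], [6.0]])
        labels = [0, 0, 1, 1]
        assert silhouette(X, labels) == pytest.approx(79 / 99)
        assert silhouette_brute(X, labels) == pytest.approx(79 / 99)

    def test_far_separated_tight_pairs_approach_one(self):
        X = np.array([[0.0], [0.01], [100.0], [100.01]])
        assert silhouette(X, [0, 0, 1, 1]) > 0.99

    def test_matches_oracle_on_random_labelings(self, rng):
        X = rng.normal(size=(12, 3))
        for _ in range(5):
            labels = rng.integers(0, 3, 12)
            if len(np.unique(labels)) < 2:
                continue
            assert silhouette(X, labels) == pytest.approx(
                silhouette_brute(X, labels), rel=1e-6
            )

    def test_random_labels_on_one_blob_near_zero(self, rng):
        X = rng.normal(size=(200, 2))
        labels = rng.integers(0, 2, 200)
        assert abs(silhouette(X, labels)) < 0.1

    def test_single_cluster_is_an_error(self, rng):
        with pytest.raises(ValueError):
            silhouette(rng.normal(size=(5, 2)), [1, 1, 1, 1, 1])


class TestOversampling:
    def test_single_frame_repeats_to_a_multiple(self, rng):
        counts = np.zeros((4, 19), dtype=int)
        counts[0, 5] = 3
        frame = Frame(0.0, counts)
        cum, flagged = oversample_cumulative([frame], n_draws=4, min_per_bin=20, rng=rng)
        assert not flagged.any()
        for c in cum:
            assert c.counts[0, 5] % 3 == 0 and c.counts[0, 5] >= 20

    def test_stopping_rule_on_unflagged_rows(self, rng):
        frames = _random_frames(rng, 50)
        cum, flagged = oversample_cumulative(frames, n_draws=10, min_per_bin=20, rng=rng)
        session_total = np.sum([f.counts[0] for f in frames], axis=0)
        occupied = session_total >= 20
        for c, fl in zip(cum, flagged):
            if not fl:
                assert np.all(c.counts[0][occupied] >= 20)

    def test_twelve_species_thirty_draws_gives_360_rows(self, rng):
        sessions = {f"sp{i}": _random_frames(rng, 30) for i in range(12)}
        ds = build_cumulative_dataset(sessions, n_draws=30, min_per_bin=20, rng=rng)
        assert ds.matrix.shape == (360, 19)
        assert len(ds.frames) == 360

    def test_empty_input_rejected(self, rng):
        with pytest.raises(ValueError):
            oversample_cumulative([], rng=rng)


class TestRowNormalize:
    def test_example_row(self):
        M, zero = row_normalize([[1.0, 1.0, 2.0]])
        assert np.allclose(M, [[0.25, 0.25, 0.5]])
        assert not zero.any()

    def test_idempotent_and_zero_rows_flagged(self):
        M, zero = row_normalize([[0.25, 0.25, 0.5], [0.0, 0.0, 0.0]])
        M2, _ = row_normalize(M)
        assert np.allclose(M, M2)
        assert list(zero) == [False, True]

    @given(
        rows=st.lists(
            st.lists(st.floats(0.0, 1e6), min_size=3, max_size=3), min_size=1, max_size=8
        )
    )
    def test_nonzero_rows_sum_to_one(self, rows):
        M, zero = row_normalize(rows)
        sums = M.sum(axis=1)
        assert np.allclose(sums[~zero], 1.0, atol=1e-9)


class TestHopkins:
    def test_uniform_data_near_half(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(size=(400, 2))
        vals = [hopkins(X, rng=np.random.default_rng(i)) for i in range(10)]
        assert abs(np.mean(vals) - 0.5) < 0.08

    def test_tight_clusters_near_one(self, rng):
        centers = rng.uniform(0, 100, (5, 3))
        X = np.vstack([c + rng.normal(0, 0.01, (40, 3)) for c in centers])
        assert hopkins(X, rng=rng) > 0.9

    def test_near_duplicates_drive_h_to_one(self, rng):
        # every point duplicated at a few well-separated spots: the
        # real-to-real distances w vanish while u stays finite
        centers = rng.uniform(0, 100, (5, 2))
        X = np.repeat(centers, 10, axis=0) + rng.normal(0, 1e-9, (50, 2))
        assert hopkins(X, rng=rng) > 0.999

    def test_column_shuffling_reduces_clustering_tendency(self, rng):
        centers = rng.uniform(0, 10, (4, 6))
        X = np.vstack([c + rng.normal(0, 0.05, (30, 6)) for c in centers])
        h = hopkins(X, rng=np.random.default_rng(1))
        shuffled = X.copy()
        for row in shuffled:
            rng.shuffle(row)
        h_shuffled = hopkins(shuffled, rng=np.random.default_rng(1))
        assert h_shuffled < h


class TestHierarchicalClustering:
    def test_k_equals_n_gives_singletons(self, rng):
        X = rng.normal(size=(6, 2))
        model = hierarchical_cluster(X, k=6)
        assert len(np.unique(model.labels)) == 6

    def test_k_beyond_n_rejected(self, rng):
        with pytest.raises(ValueError):
            hierarchical_cluster(rng.normal(size=(4, 2)), k=5)

    @pytest.mark.parametrize("n", [6, 9, 12])
    def test_matches_exhaustive_agglomeration_oracle(self, rng, n):
        X = rng.normal(size=(n, 3))
        oracle = complete_linkage_partitions(X)
        for k in range(1, n + 1):
            model = hierarchical_cluster(X, k)
            got = {
                frozenset(np.where(model.labels == lab)[0])
                for lab in np.unique(model.labels)
            }
            assert got == oracle[k]

    def test_cut_reproduces_labels(self, rng):
        X = rng.normal(size=(20, 4))
        model = hierarchical_cluster(X, 4)
        assert np.array_equal(model.cut(4), model.labels)


class TestPCA:
    def test_line_explains_all_variance(self):
        t = np.linspace(0, 1, 30)
        X = np.outer(t, [1.0, 2.0, 3.0])
        coords, evr = pca_project(X, 2)
        assert evr[0] == pytest.approx(1.0, abs=1e-12)

    def test_explained_variance_shares_bounded(self, rng):
        X = rng.normal(size=(40, 6))
        _, evr = pca_project(X, 3)
        assert evr.sum() <= 1.0 + 1e-12

    def test_sign_convention_is_deterministic(self, rng):
        X = rng.normal(size=(25, 5))
        c1, _ = pca_project(X)
        c2, _ = pca_project(X[::-1][::-1])  # same data, fresh call
        assert np.allclose(c1, c2)

    def test_pairwise_distances_preserved_in_full_projection(self, rng):
        from scipy.spatial.distance import pdist

        X = rng.normal(size=(10, 3))
        coords, _ = pca_project(X, 3)
        assert np.allclose(pdist(coords), pdist(X), rtol=1e-9)
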