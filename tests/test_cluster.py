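"""Activity vectors, model seeds, k-means, silhouette, Rand index, and
the end-to-end recovery of generated cluster labels."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import silhouette_samples

from stndecide.cluster import (
    assign_by_correlation,
    build_activity_vectors,
    embed_2d,
    kmeans_fit,
    make_model_seeds,
    rand_index,
    silhouette,
    spatial_silhouette,
    stability_grid,
)
from stndecide.cluster.vectors import VECTOR_ORDER


def _epoch_block(vec, epoch, choice):
    """The 5 coherence values of one (epoch, choice) cell of a seed."""
    e = ("early", "late", "peri").index(epoch)
    c = ("pref", "other").index(choice)
    return vec[e * 10 + c * 5:e * 10 + c * 5 + 5]


class TestSeeds:
    def test_vector_order_has_thirty_labels(self):
        assert len(VECTOR_ORDER) == 30
        assert VECTOR_ORDER[0] == "early_pref_c1" and VECTOR_ORDER[-1] == "peri_other_c5"

    def test_early_brake_seed_flat_and_decreasing(self):
        s2 = make_model_seeds().vectors[1]
        for epoch in ("early", "late", "peri"):
            block = np.r_[
                _epoch_block(s2, epoch, "pref"), _epoch_block(s2, epoch, "other")
            ]
            assert block.max() - block.min() == pytest.approx(0.0)
        means = [
            np.mean(np.r_[_epoch_block(s2, e, "pref"), _epoch_block(s2, e, "other")])
            for e in ("early", "late", "peri")
        ]
        assert means[0] > means[1] > means[2]

    def test_gating_seed_choice_free_then_selective(self):
        s3 = make_model_seeds().vectors[2]
        for epoch in ("early", "late"):
            assert np.allclose(
                _epoch_block(s3, epoch, "pref"), _epoch_block(s3, epoch, "other")
            )
        late = _epoch_block(s3, "late", "pref")
        assert np.all(np.diff(late) > 0)  # coherence-monotone
        assert _epoch_block(s3, "peri", "pref").mean() > _epoch_block(
            s3, "peri", "other"
        ).mean()

    def test_pooling_seed_choice_separated(self):
        s1 = make_model_seeds().vectors[0]
        diff = _epoch_block(s1, "late", "pref") - _epoch_block(s1, "late", "other")
        assert np.all(diff > 0)

    def test_arbitrary_seed_orthogonal_to_models(self):
        seeds = make_model_seeds().vectors
        s4 = seeds[3]
        for s in seeds[:3]:
            sc = s - s.mean()
            assert abs(s4 @ sc) < 1e-9


class TestKMeans:
    def test_distinct_points_zero_inertia(self):
        X = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        m = kmeans_fit(X, 3, distance="sq-euclidean", init=X.copy(), seed=0)
        assert m.inertia == pytest.approx(0.0)
        assert len(set(m.assignments)) == 3

    def test_k_equals_one(self):
        X = np.random.default_rng(0).normal(size=(20, 5))
        m = kmeans_fit(X, 1, distance="sq-euclidean", init="random", n_reps=3, seed=1)
        assert set(m.assignments) == {1}

    def test_matches_sklearn_inertia_on_euclidean(self):
        from sklearn.cluster import KMeans

        X = np.random.default_rng(2).normal(size=(120, 6))
        mine = kmeans_fit(X, 4, distance="sq-euclidean", init="random",
                          n_reps=20, seed=3)
        sk = KMeans(n_clusters=4, n_init=20, random_state=3).fit(X)
        assert mine.inertia == pytest.approx(sk.inertia_, rel=0.02)

    def test_correlation_affine_invariance(self):
        """Correlation-distance clustering ignores per-vector shift/scale."""
        rng = np.random.default_rng(4)
        X = rng.normal(size=(60, 30))
        shifts = rng.normal(0, 5, size=(60, 1))
        scales = rng.uniform(0.5, 3.0, size=(60, 1))
        m1 = kmeans_fit(X, 3, distance="correlation", init="random",
                        n_reps=30, seed=5)
        m2 = kmeans_fit(scales * X + shifts, 3, distance="correlation",
                        init="random", n_reps=30, seed=5)
        assert rand_index(m1.assignments, m2.assignments) == pytest.approx(1.0)

    def test_deterministic_given_seed(self):
        X = np.random.default_rng(6).normal(size=(50, 8))
        a = kmeans_fit(X, 3, init="random", n_reps=10, seed=7)
        b = kmeans_fit(X, 3, init="random", n_reps=10, seed=7)
        assert np.array_equal(a.assignments, b.assignments)


class TestSilhouette:
    def test_hand_computed_example(self):
        # points {0, 0.1} in A and {10, 10.1} in B, Euclidean distance:
        # for point 0: d_intra = 0.1, d_inter = (10 + 10.1)/2 = 10.05
        X = np.array([[0.0], [0.1], [10.0], [10.1]])
        labels = [1, 1, 2, 2]
        s = silhouette(X, labels, distance="euclidean")
        assert s[0] == pytest.approx((10.05 - 0.1) / 10.05, abs=1e-9)

    def test_coincident_clusters_score_zero(self):
        X = np.ones((6, 3))
        s = silhouette(X, [1, 1, 1, 2, 2, 2], distance="euclidean")
        assert np.allclose(s, 0.0)

    def test_bounded_and_matches_sklearn(self):
        rng = np.random.default_rng(8)
        X = np.r_[rng.normal(0, 1, (30, 4)), rng.normal(4, 1, (30, 4))]
        labels = np.r_[np.ones(30), 2 * np.ones(30)]
        mine = silhouette(X, labels, distance="euclidean")
        assert np.all((-1 <= mine) & (mine <= 1))
        ref = silhouette_samples(X, labels, metric="euclidean")
        assert np.allclose(mine, ref, atol=1e-9)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            silhouette(np.ones((4, 2)), [1, 1, 1, 1])


class TestRandIndex:
    def test_identical_partitions(self):
        assert rand_index([1, 1, 2, 2], [1, 1, 2, 2]) == 1.0

    def test_enumerated_example(self):
        # pairs of {1,1,2,2} vs {1,2,1,2}: only (1,4)?? enumerate: agree on
        # pairs (1,2)x ... exactly 2 of 6 pairs agree
        assert rand_index([1, 1, 2, 2], [1, 2, 1, 2]) == pytest.approx(2 / 6)

    def test_relabeling_invariance(self):
        a = [1, 1, 2, 3, 3, 2]
        b = [7, 7, 9, 5, 5, 9]  # same partition, different labels
        assert rand_index(a, b) == 1.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(1, 4), min_size=2, max_size=30),
        st.randoms(use_true_random=False),
    )
    def test_symmetry_and_bounds(self, a, rnd):
        b = [rnd.randint(1, 4) for _ in a]
        r_ab = rand_index(a, b)
        assert r_ab == pytest.approx(rand_index(b, a))
        assert 0.0 <= r_ab <= 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            rand_index([1, 2], [1, 2, 3])


class TestAssignByCorrelation:
    def test_centroid_itself_and_shift_invariance(self):
        C = np.vstack([np.sin(np.arange(30)), np.cos(np.arange(30)),
                       np.linspace(-1, 1, 30)])
        assert assign_by_correlation(C[1], C) == 2
        assert assign_by_correlation(C[1] + 5.0, C) == 2

    def test_scale_invariance_with_small_noise(self):
        rng = np.random.default_rng(9)
        C = rng.normal(size=(4, 30))
        v = 0.5 * C[1] + 1e-8 * rng.normal(size=30)
        assert assign_by_correlation(v, C) == 2

    def test_constant_vector_rejected(self):
        C = np.random.default_rng(10).normal(size=(3, 30))
        with pytest.raises(ValueError):
            assign_by_correlation(np.ones(30), C)


class TestSpatialSilhouette:
    def test_segregated_blocks_score_high(self):
        rng = np.random.default_rng(11)
        loc = np.r_[
            rng.normal(0, 0.2, (20, 3)), rng.normal(5, 0.2, (20, 3))
        ]
        labels = np.r_[np.ones(20), 2 * np.ones(20)]
        assert spatial_silhouette(loc, labels) > 0.5

    def test_permuted_labels_score_near_zero(self):
        rng = np.random.default_rng(12)
        loc = rng.uniform(0, 4, (60, 3))
        labels = rng.integers(1, 4, 60)
        assert spatial_silhouette(loc, labels) < 0.15

    def test_identical_locations_score_zero(self):
        loc = np.ones((8, 3))
        assert spatial_silhouette(loc, [1, 1, 1, 1, 2, 2, 2, 2]) == 0.0


class TestEmbed:
    def test_deterministic_and_shaped(self):
        X = np.random.default_rng(13).normal(size=(40, 30))
        a = embed_2d(X, seed=1)
        b = embed_2d(X, seed=1)
        assert a.shape == (40, 2)
        assert np.allclose(a, b)

    def test_separated_clusters_stay_separated(self, recording_vectors):
        X, y, _ = recording_vectors
        Y = embed_2d(X, seed=2)
        within, between = [], []
        for c in np.unique(y):
            m = y == c
            within.append(np.mean([np.linalg.norm(p - q)
                                   for p in Y[m][:10] for q in Y[m][:10]]))
            between.append(np.mean([np.linalg.norm(p - q)
                                    for p in Y[m][:10] for q in Y[~m][:10]]))
        assert np.mean(within) < np.mean(between)


class TestEndToEndRecovery:
    def test_model_seeded_recovery(self, recording_vectors):
        X, y, _ = recording_vectors
        m = kmeans_fit(X, 4, distance="correlation", init=make_model_seeds(), seed=0)
        assert rand_index(m.assignments, y) >= 0.95

    def test_seeded_matches_random_seeded(self, recording_vectors):
        X, y, _ = recording_vectors
        seeded = kmeans_fit(X, 4, distance="correlation",
                            init=make_model_seeds(), seed=0)
        random = kmeans_fit(X, 4, distance="correlation", init="random",
                            n_reps=100, seed=1)
        assert rand_index(seeded.assignments, random.assignments) >= 0.95

    def test_half_separation_still_recovers(self):
        from stndecide.cluster.vectors import vector_matrix
        from stndecide.synth import generate_recording_dataset

        spikes, trials, templates = generate_recording_dataset(
            15, seed=77, separation=0.5
        )
        vec = build_activity_vectors(spikes, trials)
        X = vector_matrix(vec)
        truth = {t.neuron_id: t.true_cluster for t in templates}
        y = np.array([truth[n] for n in vec.index])
        m = kmeans_fit(X, 4, distance="correlation", init=make_model_seeds(), seed=0)
        assert rand_index(m.assignments, y) >= 0.9

    def test_structured_data_more_stable_than_blob(self, recording_vectors):
        X, _, _ = recording_vectors
        rng = np.random.default_rng(14)
        blob = rng.normal(size=X.shape)
        rep_real = stability_grid(
            X, representations=("raw30",), distances=("correlation",),
            ks=(4,), n_runs=8, n_reps=20, seed=1,
        )
        rep_blob = stability_grid(
            blob, representations=("raw30",), distances=("correlation",),
            ks=(4,), n_runs=8, n_reps=20, seed=1,
        )
        real_rand = rep_real.table["mean_rand"].iloc[0]
        blob_rand = rep_blob.table["mean_rand"].iloc[0]
        assert real_rand > blob_rand

    def test_stability_grid_ranks_true_k_highly(self, recording_vectors):
        """k=4 (the generated number of clusters) is maximally stable
        under raw vectors + correlation, and over-clustering (k >= 5)
        is strictly less stable with worse silhouettes."""
        X, _, _ = recording_vectors
        rep = stability_grid(
            X, representations=("raw30",), distances=("correlation",),
            ks=(4, 5, 6), n_runs=6, n_reps=30, seed=2,
        )
        t = rep.table.set_index("k")
        assert t.loc[4, "mean_rand"] >= 0.95
        assert t.loc[4, "mean_rand"] >= t.loc[5, "mean_rand"]
        assert t.loc[4, "mean_rand"] >= t.loc[6, "mean_rand"]
        assert t.loc[4, "mean_silhouette"] > t.loc[5, "mean_silhouette"]
        assert rep.chosen["mean_rand"] == rep.table["mean_rand"].max()

    def test_single_run_flags_undefined_rand(self, recording_vectors):
        X, _, _ = recording_vectors
        rep = stability_grid(
            X, representations=("raw30",), distances=("correlation",),
            ks=(4,), n_runs=1, n_reps=5, seed=3,
        )
        assert np.isnan(rep.table["mean_rand"].iloc[0])
        assert any("undefined" in f for f in rep.flags)


class TestActivityVectors:
    def test_thirty_entries_and_preferred_label(self, small_recording):
        spikes, trials, templates = small_recording
        vec = build_activity_vectors(spikes, trials)
        vcols = [c for c in vec.columns if c.startswith("v")]
        assert len(vcols) == 30
        assert set(vec["preferred_label"]) <= {"contra", "ipsi"}

    def test_preferred_side_has_larger_peri_activity(self, small_recording):
        spikes, trials, templates = small_recording
        vec = build_activity_vectors(spikes, trials)
        # peri-saccade preferred block (v21..v25) >= other block (v26..v30)
        pref = vec[[f"v{i:02d}" for i in range(21, 26)]].mean(axis=1)
        other = vec[[f"v{i:02d}" for i in range(26, 31)]].mean(axis=1)
        assert (pref >= other).all()

    def test_missing_condition_raises_with_name(self, small_recording):
        spikes, trials, templates = small_recording
        broken = trials[
            ~((trials["signed_coh"] > 0.5) & (trials["choice"] == "contra"))
        ]
        with pytest.raises(ValueError, match="condition"):
            build_activity_vectors(spikes, broken)
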