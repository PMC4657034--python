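import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from scipy.stats import spearmanr

from flyvep.design import canonical_columns
from flyvep.exceptions import (
    ConfigurationError,
    LabellingError,
    UndefinedCorrelationError,
)
from flyvep.similarity import (
    DistanceMatrix,
    classical_scaling,
    distance_matrix,
    genotype_means,
    hull_separation,
    mds_embed,
    Embedding2D,
)


def _table(X, labels):
    df = pd.DataFrame(X, columns=canonical_columns())
    df.insert(0, "genotype", labels)
    df.insert(0, "fly_id", [f"f{i}" for i in range(len(labels))])
    return df


def procrustes_rmse(A, B):
    """RMSE after optimal translation/rotation/reflection/scaling."""
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    U, s, Vt = np.linalg.svd(B.T @ A)
    R = U @ Vt
    scale = s.sum() / (B ** 2).sum()
    return float(np.sqrt(np.mean((A - scale * (B @ R)) ** 2)))


class TestGenotypeMeans:
    def test_single_fly_per_genotype_returns_that_fly(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(3, 64))
        means = genotype_means(_table(X, ["g1", "g2", "g3"]))
        np.testing.assert_allclose(means.to_numpy(), X)
        assert list(means.index) == ["g1", "g2", "g3"]

    def test_identical_flies_average_to_common_vector(self):
        X = np.tile(np.arange(64.0), (20, 1))
        means = genotype_means(_table(X, ["g"] * 20))
        np.testing.assert_allclose(means.to_numpy()[0], np.arange(64.0))

    def test_row_shuffle_invariance(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(12, 64))
        labels = np.array(["a", "b", "c"] * 4)
        t = _table(X, labels)
        perm = rng.permutation(12)
        m1 = genotype_means(t).sort_index()
        m2 = genotype_means(t.iloc[perm].reset_index(drop=True)).sort_index()
        pd.testing.assert_frame_equal(m1, m2)

    def test_label_length_mismatch_raises(self):
        with pytest.raises(LabellingError):
            genotype_means(np.zeros((3, 64)), labels=["a", "b"])


class TestDistanceMatrix:
    def test_identical_means_give_zero_matrix(self):
        M = np.tile(np.arange(64.0), (4, 1))
        D = distance_matrix(M)
        np.testing.assert_allclose(D.d, 0.0)

    def test_single_feature_difference_closed_form(self):
        M = np.zeros((2, 64))
        M[1, 10] = 3.0
        D = distance_matrix(M)
        assert D.d[0, 1] == pytest.approx(3.0)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(2)
        M = rng.normal(size=(5, 64))
        D = distance_matrix(M).d
        for i in range(5):
            for j in range(5):
                expected = np.sqrt(np.sum((M[i] - M[j]) ** 2))
                assert abs(D[i, j] - expected) < 1e-12

    def test_metric_axioms(self):
        rng = np.random.default_rng(3)
        D = distance_matrix(rng.normal(size=(6, 64))).d
        np.testing.assert_allclose(D, D.T)
        np.testing.assert_allclose(np.diag(D), 0.0)
        for i in range(6):
            for j in range(6):
                for k in range(6):
                    assert D[i, j] <= D[i, k] + D[k, j] + 1e-9

    def test_correlation_metric_and_constant_vector_error(self):
        rng = np.random.default_rng(4)
        M = rng.normal(size=(3, 64))
        D = distance_matrix(M, metric="correlation")
        assert np.all(D.d >= 0)
        M[0] = 5.0
        with pytest.raises(UndefinedCorrelationError):
            distance_matrix(M, metric="correlation")


class TestMDS:
    def test_equilateral_triangle_embeds_exactly(self):
        labels = ["a", "b", "c"]
        D = DistanceMatrix(labels, 1.0 - np.eye(3))
        emb = mds_embed(D, dims=2, seed=0)
        dists = np.linalg.norm(
            emb.coords[:, None, :] - emb.coords[None, :, :], axis=2
        )
        off = dists[~np.eye(3, dtype=bool)]
        assert np.all(np.abs(off - 1.0) < 1e-4)
        assert emb.converged

    def test_planted_2d_configuration_recovered(self):
        rng = np.random.default_rng(5)
        truth = rng.normal(size=(10, 2))
        diff = truth[:, None, :] - truth[None, :, :]
        D = DistanceMatrix(list(range(10)), np.sqrt((diff ** 2).sum(-1)))
        emb = mds_embed(D, dims=2, seed=0)
        assert procrustes_rmse(truth, emb.coords) < 1e-3

    def test_two_points_separated_by_their_distance(self):
        D = DistanceMatrix(["a", "b"], np.array([[0.0, 2.7], [2.7, 0.0]]))
        emb = mds_embed(D, dims=2, seed=0)
        assert np.linalg.norm(emb.coords[0] - emb.coords[1]) == pytest.approx(2.7)

    def test_rank_correlation_of_distances_preserved(self):
        # random 10-genotype panels: mean response vectors live on the
        # generator's low-dimensional parameter manifold, so a 2-D
        # embedding preserves the distance ranking
        from flyvep.synth import GenotypeSpec, tuning_surface

        def random_panel(seed):
            rng = np.random.default_rng(seed)
            specs = [
                GenotypeSpec(
                    name=f"g{i}",
                    gain=float(rng.uniform(4, 9)),
                    tf_peak_hz=float(rng.uniform(3, 12)),
                    tf_bandwidth_oct=float(rng.uniform(1.0, 2.0)),
                    sf_cutoff_cpd=float(rng.uniform(0.4, 1.3)),
                    low_sf_boost=float(rng.uniform(1.0, 2.5)),
                )
                for i in range(10)
            ]
            return np.array(
                [tuning_surface(s).amplitude.ravel() for s in specs]
            )

        ok = 0
        for seed in range(10):
            D = distance_matrix(random_panel(seed))
            emb = mds_embed(D, dims=2, seed=seed)
            iu = np.triu_indices(10, 1)
            emb_d = np.linalg.norm(
                emb.coords[:, None, :] - emb.coords[None, :, :], axis=2
            )
            rho = spearmanr(D.d[iu], emb_d[iu]).statistic
            ok += rho > 0.9
        assert ok >= 9

    def test_dims_must_be_below_point_count(self):
        D = DistanceMatrix(["a", "b", "c"], 1.0 - np.eye(3))
        with pytest.raises(ConfigurationError):
            mds_embed(D, dims=3)

    def test_classical_scaling_exact_for_euclidean_input(self):
        rng = np.random.default_rng(7)
        truth = rng.normal(size=(6, 2))
        diff = truth[:, None, :] - truth[None, :, :]
        coords = classical_scaling(np.sqrt((diff ** 2).sum(-1)), dims=2)
        assert procrustes_rmse(truth, coords) < 1e-9


class TestHullSeparation:
    def _embedding(self, coords, labels):
        return Embedding2D(labels=labels, coords=np.asarray(coords, float),
                           stress=0.0, converged=True)

    def test_translated_clusters_are_separated(self):
        coords = [[0, 0], [1, 0], [0, 1], [10, 10], [11, 10], [10, 11]]
        labels = [f"g{i}" for i in range(6)]
        cmap = {l: ("A" if i < 3 else "B") for i, l in enumerate(labels)}
        rep = hull_separation(self._embedding(coords, labels), cmap)
        assert rep["separated"]

    def test_nested_cluster_is_not_separated(self):
        coords = [[0, 0], [10, 0], [5, 10], [5, 3], [5, 4], [6, 4]]
        labels = [f"g{i}" for i in range(6)]
        cmap = {l: ("A" if i < 3 else "B") for i, l in enumerate(labels)}
        rep = hull_separation(self._embedding(coords, labels), cmap)
        assert not rep["separated"]
        assert any(rep["containment"][l] for l in labels[3:])

    def test_outlier_reported_outside_both_hulls(self):
        coords = [[0, 0], [1, 0], [0, 1], [1, 1],
                  [10, 10], [11, 10], [10, 11], [11, 11],
                  [30, -30]]
        labels = [f"c{i}" for i in range(4)] + [f"p{i}" for i in range(4)] + ["x"]
        cmap = {**{f"c{i}": "ctrl" for i in range(4)},
                **{f"p{i}": "pd" for i in range(4)}, "x": "outlier"}
        rep = hull_separation(self._embedding(coords, labels), cmap)
        assert rep["containment"]["x"] == []
        assert rep["separated"]

    def test_collinear_class_handled_as_segment(self):
        coords = [[0, 0], [1, 0], [2, 0], [1.0, 0.0], [5, 5], [6, 5], [5, 6]]
        labels = ["a1", "a2", "a3", "b_on_segment", "b1", "b2", "b3"]
        cmap = {"a1": "A", "a2": "A", "a3": "A",
                "b_on_segment": "B", "b1": "B", "b2": "B", "b3": "B"}
        rep = hull_separation(self._embedding(coords, labels), cmap)
        assert "A" in rep["containment"]["b_on_segment"]

    def test_missing_class_map_entry_raises(self):
        with pytest.raises(LabellingError):
            hull_separation(self._embedding([[0, 0], [1, 1]], ["a", "b"]),
                            {"a": "A"})


class TestEndToEndDistances:
    def test_noiseless_pipeline_distances_match_surface_distances(
        self, noiseless_spec
    ):
        # the distance matrix computed from extracted features equals the
        # one computed directly from the generating surfaces x mean gains
        from flyvep.spectral import feature_matrix
        from flyvep.synth import simulate_cohort, tuning_surface

        specs = [
            replace(noiseless_spec, name="gA"),
            replace(noiseless_spec, name="gB", gain=8.0),
            replace(noiseless_spec, name="gC", tf_peak_hz=3.0),
        ]
        cohort = simulate_cohort(specs, n_flies=2, n_reps=1, seed=3)
        table = feature_matrix(cohort)
        D_pipeline = distance_matrix(genotype_means(table)).d

        expected_means = []
        for s in specs:
            gains = [g for f, g in cohort.fly_gains.items()
                     if cohort.fly_genotype[f] == s.name]
            expected_means.append(
                tuning_surface(s).amplitude.ravel() * np.mean(gains)
            )
        D_truth = distance_matrix(np.array(expected_means)).d
        assert np.max(np.abs(D_pipeline - D_truth)) < 1e-6
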