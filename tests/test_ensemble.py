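"""Subspace construction, kNN fitting/voting and the ensemble rules."""

import numpy as np
import pytest

from dtiknn import (
    ConfigError,
    InputError,
    KNNConfig,
    KNNModel,
    MAJORITY,
    SubspaceEnsemble,
    SubspacePair,
    UNANIMITY,
    build_subspaces,
    fit_ensemble,
    fit_subspace_knn,
    partition_descriptors,
    select_k,
)
from oracles import brute_knn_predict, brute_knn_scores, brute_select_k


def random_xy(rng, n=80, d=12, separated=False):
    x = rng.standard_normal((n, d))
    y = rng.integers(0, 2, size=n)
    if separated:
        x[y == 1] += 3.0
    return x, y


class TestBuildSubspaces:
    def test_grid_size_default(self):
        part = partition_descriptors(1444, 7)
        subs = build_subspaces(7, 10, part)
        assert len(subs) == 49

    def test_full_scale_dimensions(self):
        part = partition_descriptors(1444, 7)
        subs = build_subspaces(7, 10, part)
        sizes = [s.n_features for s in subs]
        assert sizes.count(406) == 42  # 200 protein + 206 drug
        assert sizes.count(408) == 7  # last drug group absorbs the remainder
        for s in subs:
            assert (np.diff(s.feature_indices) > 0).all()
            assert s.feature_indices[-1] < 1444 + 1400

    def test_degenerate_single_subspace(self):
        part = partition_descriptors(30, 1)
        subs = build_subspaces(1, 4, part)
        assert len(subs) == 1
        np.testing.assert_array_equal(subs[0].feature_indices, np.arange(30 + 80))

    def test_group_count_mismatch(self):
        with pytest.raises(ConfigError):
            build_subspaces(7, 10, partition_descriptors(100, 5))


class TestSelectK:
    def test_singleton_candidate(self, rng):
        x, y = random_xy(rng)
        assert select_k(x, y, [3]) == 3

    def test_matches_exhaustive_oracle(self, rng):
        for weighting in ("distance", "uniform"):
            x, y = random_xy(rng, n=40, d=3, separated=True)
            ks = [1, 3, 5, 7, 9]
            assert select_k(x, y, ks, weighting=weighting) == brute_select_k(
                x, y, ks, weighting
            )

    def test_single_class_errors(self, rng):
        x = rng.standard_normal((10, 2))
        with pytest.raises(InputError):
            select_k(x, np.ones(10, dtype=int), [1, 3])

    def test_separated_blobs_pick_a_sensible_k(self, rng):
        x, y = random_xy(rng, n=60, d=4, separated=True)
        k = select_k(x, y)
        assert 1 <= k <= 59 and k % 2 == 1


def _subspace(d):
    return SubspacePair(1, 1, np.arange(d))


class TestFitSubspaceKNN:
    def test_k1_training_identity(self, rng):
        x, y = random_xy(rng, n=30, d=5)
        model = fit_subspace_knn((x, y), _subspace(5), KNNConfig(k=1))
        labels, scores = model.predict(x)
        np.testing.assert_array_equal(labels, y)
        np.testing.assert_array_equal(scores, y.astype(float))

    def test_minmax_scaling_bounds(self, rng):
        x, y = random_xy(rng, n=30, d=5)
        x[:, 2] = 4.2  # degenerate feature
        model = fit_subspace_knn((x, y), _subspace(5), KNNConfig(k=3))
        assert model.training_vectors.min() >= 0.0
        assert model.training_vectors.max() <= 1.0
        assert (model.training_vectors[:, 2] == 0.0).all()

    def test_single_class_errors(self, rng):
        x = rng.standard_normal((10, 3))
        with pytest.raises(InputError):
            fit_subspace_knn((x, np.zeros(10, dtype=int)), _subspace(3), KNNConfig(k=1))

    @pytest.mark.parametrize("weighting", ["distance", "uniform"])
    def test_matches_brute_force_oracle(self, rng, weighting):
        x, y = random_xy(rng, n=60, d=8)
        model = fit_subspace_knn((x, y), _subspace(8), KNNConfig(k=5, weighting=weighting))
        queries = rng.standard_normal((25, 8))
        labels, _ = model.predict(queries)
        expected = brute_knn_predict(
            model.training_vectors, model.labels, model.transform(queries), 5, weighting
        )
        np.testing.assert_array_equal(labels, expected)


def _identity_model(points, labels, k, weighting="distance"):
    return KNNModel(
        np.asarray(points, dtype=float),
        np.asarray(labels, dtype=int),
        k,
        weighting,
        np.zeros(np.shape(points)[1]),
        np.ones(np.shape(points)[1]),
    )


class TestPredictSingle:
    def test_query_on_training_point(self):
        m = _identity_model([[0.0], [5.0]], [1, 0], 1)
        labels, scores = m.predict([[0.0]])
        assert labels[0] == 1 and scores[0] == 1.0

    def test_inverse_distance_hand_arithmetic(self):
        # neighbors at distances (1, 1, 2) with labels (1, 1, 0):
        # score = (1 + 1) / (1 + 1 + 0.5) = 0.8
        m = _identity_model([[0.0], [2.0], [3.0], [50.0]], [1, 1, 0, 0], 3)
        labels, scores = m.predict([[1.0]])
        assert labels[0] == 1
        assert scores[0] == pytest.approx(0.8)

    def test_uniform_tie_breaks_negative(self):
        m = _identity_model([[0.0], [2.0]], [1, 0], 2, weighting="uniform")
        labels, scores = m.predict([[1.0]])
        assert scores[0] == 0.5 and labels[0] == 0

    def test_zero_distance_neighbors_dominate(self):
        # one exact match (label 0) outweighs two very close positives
        m = _identity_model([[0.0], [1e-3], [2e-3]], [0, 1, 1], 3)
        labels, scores = m.predict([[0.0]])
        assert labels[0] == 0 and scores[0] == 0.0

    def test_dimension_mismatch(self):
        m = _identity_model([[0.0, 0.0]], [1], 1)
        with pytest.raises(InputError):
            m.predict([[1.0]])


def _forced_vote_ensemble(votes_for_query):
    """A 1-feature-per-classifier grid whose votes on the zero query are
    exactly ``votes_for_query``."""
    n = len(votes_for_query)
    n_pca = int(round(n**0.5))
    subs, clfs = [], []
    for m, vote in enumerate(votes_for_query):
        subs.append(SubspacePair(m // n_pca + 1, m % n_pca + 1, np.array([m])))
        clfs.append(_identity_model([[0.0], [9.0]], [vote, 1 - vote], 1))
    return SubspaceEnsemble(subs, clfs, n_pca)


class TestPredictEnsemble:
    def test_48_of_49_positive(self):
        ens = _forced_vote_ensemble([1] * 48 + [0])
        q = np.zeros((1, 49))
        lab_u, votes = ens.predict(q, vote_rule=UNANIMITY)
        lab_m, _ = ens.predict(q, vote_rule=MAJORITY)
        assert votes.sum() == 48
        assert lab_u[0] == 0 and lab_m[0] == 1

    def test_all_positive(self):
        ens = _forced_vote_ensemble([1] * 49)
        q = np.zeros((1, 49))
        assert ens.predict(q, vote_rule=UNANIMITY)[0][0] == 1
        assert ens.predict(q, vote_rule=MAJORITY)[0][0] == 1

    def test_exact_half_majority_breaks_negative(self):
        ens = _forced_vote_ensemble([1, 1, 0, 0])
        assert ens.predict(np.zeros((1, 4)), vote_rule=MAJORITY)[0][0] == 0

    def test_incomplete_grid_rejected(self):
        with pytest.raises(ConfigError):
            _forced_vote_ensemble([1, 0, 1])  # 3 is not a square


@pytest.fixture(scope="module")
def trained(small_pipeline):
    p = small_pipeline
    ens = fit_ensemble((p["x"], p["y"]), p["subspaces"], KNNConfig())
    return p, ens


class TestEnsembleOnData:
    def test_grid_completeness(self, trained):
        p, ens = trained
        assert ens.n_classifiers == p["spec"].n_pca ** 2

    def test_vote_monotonicity(self, trained):
        p, ens = trained
        lab_u, _ = ens.predict(p["x"], vote_rule=UNANIMITY)
        lab_m, _ = ens.predict(p["x"], vote_rule=MAJORITY)
        assert np.all(lab_u <= lab_m)  # unanimity positives subset of majority

    def test_unanimity_is_vote_intersection(self, trained):
        p, ens = trained
        lab_u, votes = ens.predict(p["x"], vote_rule=UNANIMITY)
        np.testing.assert_array_equal(lab_u, votes.min(axis=1))

    def test_deterministic_refit(self, trained):
        p, ens = trained
        ens2 = fit_ensemble((p["x"], p["y"]), p["subspaces"], KNNConfig())
        assert [c.k for c in ens.classifiers] == [c.k for c in ens2.classifiers]
        np.testing.assert_array_equal(
            ens.predict(p["x"])[1], ens2.predict(p["x"])[1]
        )

    def test_bundle_round_trip(self, trained, tmp_path):
        p, ens = trained
        ens.save(tmp_path / "bundle")
        back = SubspaceEnsemble.load(tmp_path / "bundle")
        assert back.vote_rule == ens.vote_rule
        l1, v1 = ens.predict(p["x"])
        l2, v2 = back.predict(p["x"])
        np.testing.assert_array_equal(l1, l2)
        np.testing.assert_array_equal(v1, v2)


def test_subspace_knn_oracle_on_pipeline_subspaces(small_pipeline, rng):
    """Each subspace classifier agrees with the exhaustive-distance oracle on
    held-out queries, for both weightings."""
    p = small_pipeline
    x, y = p["x"], p["y"]
    queries = x[::3] + 0.01 * rng.standard_normal(x[::3].shape)
    for weighting in ("distance", "uniform"):
        for sub in p["subspaces"]:
            model = fit_subspace_knn((x, y), sub, KNNConfig(k=3, weighting=weighting))
            got, _ = model.predict(queries[:, sub.feature_indices])
            want = brute_knn_predict(
                model.training_vectors,
                model.labels,
                model.transform(queries[:, sub.feature_indices]),
                3,
                weighting,
            )
            np.testing.assert_array_equal(got, want)
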