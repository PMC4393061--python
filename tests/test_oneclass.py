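"""Nearest-neighbor ranking, clustering, and the one-class algorithm."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist

from rnadual.features import FeatureMatrix
from rnadual.fixtures import FixtureSpec, make_gaussian_classes
from rnadual.oneclass import (
    LogisticScorer,
    NeuralScorer,
    cluster,
    cognitive_one_class,
    leave_one_negative,
    make_large_sigma_patterns,
    nn_rank,
    persistence_ranking,
    roc_threshold,
    split_by_rank,
    triangle_annotation,
)


def fm_of(arr, ids=None):
    arr = np.atleast_2d(np.asarray(arr, dtype=float))
    ids = ids or [f"g{i}" for i in range(arr.shape[0])]
    return FeatureMatrix(values=pd.DataFrame(
        arr, index=ids, columns=[f"f{j}" for j in range(arr.shape[1])]))


class TestNNRank:
    def test_duplicate_of_verified_ranks_first(self):
        fm = fm_of([[0.0], [5.0], [0.0], [9.0]])
        rank = nn_rank(fm, ["g0", "g1"])
        assert rank.index[0] == "g2" and rank.iloc[0] == 0.0

    def test_single_feature_ordering(self):
        fm = fm_of([[0.0], [1.0], [3.0]])
        rank = nn_rank(fm, ["g0"])
        assert list(rank.index) == ["g1", "g2"]

    def test_agrees_with_bruteforce_on_random_matrices(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            X = rng.normal(size=(20, 5))
            fm = fm_of(X)
            verified = [f"g{i}" for i in range(6)]
            rank = nn_rank(fm, verified)
            expected = cdist(X[6:], X[:6]).min(axis=1)
            got = rank.sort_index(key=lambda ix: ix.str.slice(1).astype(int))
            assert np.allclose(got.to_numpy(), expected)

    def test_empty_verified_rejected(self):
        with pytest.raises(ValueError):
            nn_rank(fm_of([[0.0]]), [])


class TestSplitByRank:
    def test_splits(self):
        ranking = pd.Series(range(10), index=[f"g{i}" for i in range(10)])
        close, far = split_by_rank(ranking, 4)
        assert close == [f"g{i}" for i in range(4)]
        assert far == [f"g{i}" for i in range(4, 10)]
        assert split_by_rank(ranking, 0) == ([], list(ranking.index))
        assert split_by_rank(ranking, 10) == (list(ranking.index), [])

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            split_by_rank(pd.Series([1.0], index=["a"]), 2)


class TestCluster:
    @pytest.mark.parametrize("method", ["hierarchical", "kmedoids"])
    def test_recovers_separated_clouds(self, method):
        rng = np.random.default_rng(10)
        a = rng.normal(0, 1, size=(20, 3))
        b = rng.normal(10, 1, size=(20, 3))
        fm = fm_of(np.vstack([a, b]))
        labels = cluster(fm, k=2, method=method)
        first, second = labels.iloc[:20], labels.iloc[20:]
        assert first.nunique() == 1 and second.nunique() == 1
        assert first.iloc[0] != second.iloc[0]

    def test_k1_single_cluster(self):
        fm = fm_of(np.eye(4))
        assert cluster(fm, k=1).nunique() == 1

    def test_duplicated_rows_co_cluster(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(10, 3))
        X[7] = X[3]
        labels = cluster(fm_of(X), k=3)
        assert labels.iloc[7] == labels.iloc[3]

    def test_k_exceeding_rows_rejected(self):
        with pytest.raises(ValueError):
            cluster(fm_of(np.eye(3)), k=4)


class TestLeaveOneNegative:
    def test_far_outlier_leaves_rest_with_verified(self):
        rng = np.random.default_rng(14)
        cloud = rng.normal(size=(24, 5))
        outlier = np.full((1, 5), 10.0)
        fm = fm_of(np.vstack([cloud, outlier]))
        verified = [f"g{i}" for i in range(12)]
        report = leave_one_negative(fm, verified, seed=0)
        assert len(report) == 13
        # when the outlier is the presumed negative, the remaining
        # same-cloud candidates side with the verified class
        assert report.loc["g24", "fraction_with_verified"] >= 0.9

    def test_too_few_candidates_rejected(self):
        fm = fm_of(np.eye(3))
        with pytest.raises(ValueError):
            leave_one_negative(fm, ["g0", "g1"], seed=0)


class TestLargeSigmaPatterns:
    def test_per_descriptor_clearance(self):
        rng = np.random.default_rng(15)
        P = rng.normal(size=(12, 6))
        syn = make_large_sigma_patterns(P, 20, 5.0, seed=3)
        clearance = np.abs(syn[:, None, :] - P[None]).min(axis=1)
        assert clearance.min() >= 5.0

    def test_seed_reproducible_and_count(self):
        P = np.zeros((3, 4))
        a = make_large_sigma_patterns(P, 3, 2.0, seed=7)
        b = make_large_sigma_patterns(P, 3, 2.0, seed=7)
        assert a.shape == (3, 4)
        assert np.array_equal(a, b)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            make_large_sigma_patterns(np.zeros((2, 2)), 0, 1.0, seed=0)
        with pytest.raises(ValueError):
            make_large_sigma_patterns(np.zeros((2, 2)), 1, 0.0, seed=0)


class TestRocThreshold:
    def test_perfect_separation_tie_break(self):
        t = roc_threshold(np.array([0.1, 0.2, 0.8, 0.9]), np.array([0, 0, 1, 1]))
        assert 0.2 < t <= 0.8

    def test_constant_scores(self):
        t = roc_threshold(np.array([0.5] * 4), np.array([0, 1, 0, 1]))
        assert t == 0.5

    def test_agrees_with_bruteforce_scan(self):
        rng = np.random.default_rng(16)
        for _ in range(10):
            scores = rng.uniform(size=30).round(2)
            labels = (rng.uniform(size=30) < 0.5).astype(int)
            if labels.min() == labels.max():
                continue
            t = roc_threshold(scores, labels)
            pos, neg = scores[labels == 1], scores[labels == 0]

            def j(th):
                return np.mean(pos >= th) + np.mean(neg < th) - 1

            best = max(j(th) for th in np.unique(scores))
            assert j(t) == pytest.approx(best)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_threshold(np.array([0.1, 0.9]), np.array([1, 1]))


class TestCognitiveOneClass:
    def test_max_iter_zero_returns_initial_sets(self):
        fm, _ = make_gaussian_classes(FixtureSpec(n_classes=1, per_class=10,
                                                  dimensions=3, seed=0))
        sets = cognitive_one_class(fm, list(fm.values.index[:3]), max_iter=0, seed=0)
        assert sets.history == []
        assert len(sets.P) == 3 and len(sets.S) == 7 and sets.N == []

    def test_empty_initial_p_rejected(self):
        fm, _ = make_gaussian_classes(FixtureSpec(n_classes=1, per_class=5,
                                                  dimensions=2, seed=0))
        with pytest.raises(ValueError):
            cognitive_one_class(fm, [], seed=0)

    def test_no_progress_parameters_rejected(self):
        fm, _ = make_gaussian_classes(FixtureSpec(n_classes=1, per_class=5,
                                                  dimensions=2, seed=0))
        with pytest.raises(ValueError):
            cognitive_one_class(fm, list(fm.values.index[:2]), n=0, m=0, seed=0)

    def test_disjointness_recorded_every_iteration(self):
        fm, _ = make_gaussian_classes(FixtureSpec(n_classes=2, per_class=30,
                                                  dimensions=5, seed=1))
        P0 = [g for g in fm.values.index if g.startswith("c0_")][:8]
        sets = cognitive_one_class(fm, P0, seed=1)
        all_ids = set(fm.values.index)
        for rec in sets.history:
            p, n_, s = set(rec.P), set(rec.N), set(rec.S)
            assert not (p & n_ or p & s or n_ & s)
            assert p | n_ | s == all_ids

    def test_deterministic_under_seed(self):
        fm, _ = make_gaussian_classes(FixtureSpec(n_classes=2, per_class=25,
                                                  dimensions=5, seed=2))
        P0 = [g for g in fm.values.index if g.startswith("c0_")][:8]
        a = cognitive_one_class(fm, P0, seed=11)
        b = cognitive_one_class(fm, P0, seed=11)
        assert a.P == b.P and a.N == b.N and a.S == b.S
        assert [r.__dict__ for r in a.history] == [r.__dict__ for r in b.history]

    def test_single_class_monotone_growth_after_first_iteration(self):
        hits = 0
        for seed in range(10):
            fm, _ = make_gaussian_classes(FixtureSpec(n_classes=1, per_class=40,
                                                      dimensions=8, seed=seed))
            sets = cognitive_one_class(fm, list(fm.values.index[:10]), seed=seed)
            sizes = [len(r.P) for r in sets.history]
            if all(b >= a for a, b in zip(sizes[1:], sizes[2:])):
                hits += 1
        assert hits >= 9

    def test_logistic_scorer_satisfies_contract(self):
        fm, _ = make_gaussian_classes(FixtureSpec(n_classes=1, per_class=20,
                                                  dimensions=4, seed=3))
        sets = cognitive_one_class(
            fm, list(fm.values.index[:6]),
            scorer_factory=lambda s: LogisticScorer(seed=s), seed=3,
        )
        assert set(sets.P) | set(sets.N) | set(sets.S) == set(fm.values.index)


class TestPersistenceRanking:
    def test_counts_iterations_in_n(self):
        fm, _ = make_gaussian_classes(FixtureSpec(n_classes=2, per_class=25,
                                                  dimensions=5, seed=4))
        P0 = [g for g in fm.values.index if g.startswith("c0_")][:8]
        sets = cognitive_one_class(fm, P0, seed=4)
        ranking = persistence_ranking(sets.history)
        recount = {}
        for rec in sets.history:
            for g in rec.N:
                recount[g] = recount.get(g, 0) + 1
        assert ranking.sum() == sum(recount.values())
        assert all(ranking[g] == c for g, c in recount.items())
        never_in_n = set(fm.values.index) - set(recount)
        assert not (set(ranking.index) & never_in_n)

    def test_empty_history_rejected(self):
        with pytest.raises(ValueError):
            persistence_ranking([])


def test_triangle_annotation(loop_double, triangle):
    from rnadual.multigraph import Multigraph

    note = triangle_annotation(triangle)
    assert note["has_triangle"] and not note["triangle_with_degree_3_or_4"]
    dense = Multigraph(range(3), [(0, 1), (1, 2), (0, 2), (0, 1)])
    note2 = triangle_annotation(dense)
    assert note2["has_triangle"] and note2["triangle_with_degree_3_or_4"]
    assert not triangle_annotation(loop_double)["has_triangle"]
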