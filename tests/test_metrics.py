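import itertools
import math

import numpy as np
import pytest

from clustex import (
    ClusterResult,
    Partition,
    ValidationError,
    adjusted_rand_index,
    boundary_box,
    cluster_mse,
    ji,
    rank_scores,
    result_mse,
    summarize_result,
    validation_indices,
)
from clustex.metrics import INDEX_NAMES, IndexScores

from helpers import (
    ari_pair_counting,
    make_matrix,
    mse_pairwise,
    set_partitions,
    silhouette_brute,
)


class TestClusterMSE:
    def test_two_point_hand_example(self):
        m = make_matrix([[0.0, 0.0], [2.0, 2.0]])
        assert cluster_mse({"g0", "g1"}, m) == pytest.approx(1.0)

    def test_identical_profiles_and_singletons_are_zero(self):
        m = make_matrix([[1.0, 2.0], [1.0, 2.0], [9.0, 9.0]])
        assert cluster_mse({"g0", "g1"}, m) == pytest.approx(0.0)
        assert cluster_mse({"g2"}, m) == pytest.approx(0.0)

    def test_empty_cluster_and_unknown_gene_error(self):
        m = make_matrix([[1.0, 2.0]])
        with pytest.raises(ValidationError):
            cluster_mse(set(), m)
        with pytest.raises(ValidationError):
            cluster_mse({"nope"}, m)

    def test_matches_pairwise_identity_on_random_clusters(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            X = rng.normal(size=(rng.integers(2, 7), rng.integers(1, 5)))
            m = make_matrix(X)
            assert cluster_mse(set(m.gene_ids), m) == pytest.approx(mse_pairwise(X))


class TestResultMSE:
    def test_weighted_mean_example(self):
        # clusters with (MSE, N) = (1.0, 2) and (0.0, 2) -> 0.5
        m = make_matrix([[0.0, 0.0], [2.0, 2.0], [5.0, 5.0], [5.0, 5.0]])
        res = [{"g0", "g1"}, {"g2", "g3"}]
        assert result_mse(res, m) == pytest.approx(0.5)

    def test_total_squared_error_identity(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(12, 4))
        m = make_matrix(X)
        clusters = [set(m.gene_ids[:3]), set(m.gene_ids[3:8]), set(m.gene_ids[8:])]
        total_sse = sum(
            ((m.profiles(sorted(c)) - m.profiles(sorted(c)).mean(0)) ** 2).sum()
            for c in clusters
        )
        assert result_mse(clusters, m) == pytest.approx(total_sse / (4 * 12))

    def test_no_clusters_error(self):
        with pytest.raises(ValidationError):
            result_mse([], make_matrix([[1.0]]))


class TestBoundaryBoxAndJI:
    def test_degenerate_and_interpolated_percentiles(self):
        m = make_matrix([[float(v)] for v in range(11)])
        box = boundary_box(set(m.gene_ids), m)
        np.testing.assert_allclose([box.lower[0], box.upper[0]], [0.1, 9.9])
        same = make_matrix([[3.0], [3.0]])
        b2 = boundary_box({"g0", "g1"}, same)
        assert b2.lower[0] == b2.upper[0] == 3.0

    def test_single_cluster_has_zero_ji(self):
        m = make_matrix([[1.0, 2.0], [1.5, 2.5]])
        assert ji([{"g0", "g1"}], m) == 0.0

    def test_counts_overlap_genes_per_definition(self):
        # B spans values 0..10; g1 lies outside, g2 inside B's box
        m = make_matrix(
            [[20.0], [5.0]] + [[float(v)] for v in range(11)],
            gene_ids=["g1", "g2"] + [f"b{v}" for v in range(11)],
        )
        clusters = [{"g1", "g2"}, {f"b{v}" for v in range(11)}]
        # B's box is [0.1, 9.9]; no gene of B lies inside A's box ([5.15, 19.85])?
        # g2=5 is inside B, g1=20 is not; B members b6..b9 fall inside A's box.
        val = ji(clusters, m)
        overlap = 1 + sum(1 for v in range(11) if 5.15 <= v <= 19.85)
        assert val == pytest.approx(overlap / 13)

    def test_two_separated_clusters_have_zero_ji(self):
        m = make_matrix([[0.0, 0.0], [0.1, 0.1], [5.0, 5.0], [5.1, 5.1]])
        assert ji([{"g0", "g1"}, {"g2", "g3"}], m) == 0.0

    def test_invariant_to_cluster_order_and_outside_genes(self):
        rng = np.random.default_rng(3)
        m = make_matrix(rng.normal(size=(20, 3)))
        a = set(m.gene_ids[:6])
        b = set(m.gene_ids[6:12])
        assert ji([a, b], m) == ji([b, a], m)


class TestAdjustedRandIndex:
    def test_identity_and_label_invariance(self):
        p = Partition({"a": 0, "b": 0, "c": 1}, K=2)
        q = Partition({"a": 1, "b": 1, "c": 0}, K=2)
        assert adjusted_rand_index(p, p) == pytest.approx(1.0)
        assert adjusted_rand_index(p, q) == pytest.approx(1.0)

    def test_crossed_pairs_give_minus_half(self):
        p = Partition.from_clusters([{"1", "2"}, {"3", "4"}])
        q = Partition.from_clusters([{"1", "3"}, {"2", "4"}])
        assert adjusted_rand_index(p, q) == pytest.approx(-0.5)

    def test_mismatched_universes_rejected(self):
        p = Partition({"a": 0}, K=1)
        q = Partition({"b": 0}, K=1)
        with pytest.raises(ValidationError):
            adjusted_rand_index(p, q)

    @pytest.mark.parametrize("n", [4, 5])
    def test_matches_pair_counting_oracle_on_all_partitions(self, n):
        items = [f"g{i}" for i in range(n)]
        parts = [
            Partition.from_clusters([set(b) for b in blocks])
            for blocks in set_partitions(items)
        ]
        labelings = [[p.labels[g] for g in items] for p in parts]
        for (pa, la), (pb, lb) in itertools.product(zip(parts, labelings), repeat=2):
            expected = ari_pair_counting(la, lb)
            assert adjusted_rand_index(pa, pb) == pytest.approx(expected, abs=1e-12)


class TestValidationIndices:
    def test_silhouette_matches_brute_force(self):
        rng = np.random.default_rng(11)
        X = np.concatenate([rng.normal(0, 0.2, (8, 3)), rng.normal(4, 0.2, (8, 3))])
        m = make_matrix(X)
        clusters = [set(m.gene_ids[:8]), set(m.gene_ids[8:])]
        labels = np.array([0] * 8 + [1] * 8)
        scores = validation_indices(clusters, m)
        assert scores.values["silhouette"] == pytest.approx(
            silhouette_brute(X, labels), abs=1e-9
        )

    def test_separated_blobs_beat_merged_cluster(self):
        rng = np.random.default_rng(5)
        X = np.concatenate([rng.normal(0, 0.1, (10, 2)), rng.normal(5, 0.1, (10, 2))])
        m = make_matrix(X)
        ids = m.gene_ids
        two = validation_indices([set(ids[:10]), set(ids[10:])], m)
        # splitting one blob arbitrarily is a worse 2-cluster solution
        bad = validation_indices([set(ids[:5]) | set(ids[10:]), set(ids[5:10])], m)
        assert two.values["silhouette"] > bad.values["silhouette"]
        assert two.values["DB"] < bad.values["DB"]
        assert two.values["CH"] > bad.values["CH"]
        assert two.values["WB"] < bad.values["WB"]

    def test_zero_scatter_gives_zero_db(self):
        m = make_matrix([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0], [5.0, 5.0]])
        scores = validation_indices([{"g0", "g1"}, {"g2", "g3"}], m)
        assert scores.values["DB"] == pytest.approx(0.0)

    def test_single_cluster_yields_nan_sentinels_not_crash(self):
        m = make_matrix(np.arange(8.0).reshape(4, 2))
        scores = validation_indices([set(m.gene_ids)], m)
        for name in ("DB", "silhouette", "CH", "WB"):
            assert math.isnan(scores.values[name])
        assert math.isfinite(scores.values["BH"])

    def test_deterministic_for_duplicate_input(self):
        rng = np.random.default_rng(2)
        m = make_matrix(rng.normal(size=(12, 3)))
        clusters = [set(m.gene_ids[:6]), set(m.gene_ids[6:])]
        assert validation_indices(clusters, m).values == validation_indices(clusters, m).values


class TestRankScores:
    def _scores(self, db_values):
        return [
            IndexScores(f"m{i}", {"DB": v}) for i, v in enumerate(db_values)
        ]

    def test_two_tied_best_among_eight_get_1_5(self):
        scores = self._scores([0.1, 0.1, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8])
        report = rank_scores(scores)
        assert report.ranks["DB"]["m0"] == report.ranks["DB"]["m1"] == 1.5

    def test_extremes_are_1_and_8(self):
        scores = self._scores([0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8])
        report = rank_scores(scores)
        assert report.ranks["DB"]["m0"] == 1.0
        assert report.ranks["DB"]["m7"] == 8.0

    def test_all_identical_rank_4_5(self):
        report = rank_scores(self._scores([0.2] * 8))
        assert all(r == 4.5 for r in report.ranks["DB"].values())

    def test_smaller_db_is_better_direction(self):
        report = rank_scores(self._scores([0.9, 0.5, 0.1]))
        assert [report.ranks["DB"][m] for m in ("m0", "m1", "m2")] == [3.0, 2.0, 1.0]

    def test_larger_better_indices_rank_inverted(self):
        scores = [IndexScores("a", {"CH": 10.0}), IndexScores("b", {"CH": 20.0})]
        report = rank_scores(scores)
        assert report.ranks["CH"]["b"] == 1.0

    def test_nan_ranks_worst(self):
        scores = [
            IndexScores("a", {"silhouette": 0.5}),
            IndexScores("b", {"silhouette": float("nan")}),
        ]
        assert rank_scores(scores).ranks["silhouette"]["b"] == 2.0

    def test_ranks_form_tie_averaged_permutation(self):
        rng = np.random.default_rng(9)
        n = 6
        scores = [
            IndexScores(f"m{i}", {name: float(rng.integers(0, 4)) for name in INDEX_NAMES})
            for i in range(n)
        ]
        report = rank_scores(scores)
        for index in INDEX_NAMES:
            assert sum(report.ranks[index].values()) == pytest.approx(n * (n + 1) / 2)

    def test_final_score_is_mean_of_seven(self):
        scores = [
            IndexScores("a", {name: 1.0 for name in INDEX_NAMES}),
            IndexScores("b", {name: 2.0 for name in INDEX_NAMES}),
        ]
        report = rank_scores(scores)
        # direction-aware: a is best on smaller-better, worst on larger-better
        expected_a = np.mean([2.0 if n in ("BIC", "silhouette", "CH") else 1.0 for n in INDEX_NAMES])
        assert report.final["a"] == pytest.approx(expected_a)


def test_summarize_result_populates_all_fields():
    m = make_matrix([[0.0, 0.0], [0.2, 0.2], [5.0, 5.0], [5.2, 5.2], [99.0, -99.0]])
    res = summarize_result([{"g0", "g1"}, {"g2", "g3"}], [m], n_retained=5)
    assert isinstance(res, ClusterResult)
    assert res.K == 2
    assert res.pag == pytest.approx(80.0)
    assert res.ji == 0.0
    assert res.overall_mse == pytest.approx(result_mse(res, m))
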