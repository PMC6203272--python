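import itertools

import numpy as np
import pytest

from clustex import (
    FuzzyCPM,
    Partition,
    SeedConfig,
    SimulationConfig,
    ValidationError,
    align_partitions,
    build_cpm,
    dtb_binarize,
    generate,
    kmeans_pool,
    multi_dataset_seed_pool,
)

from helpers import make_matrix


@pytest.fixture(scope="module")
def noise_free():
    return generate(SimulationConfig(sigma=0.0, seed=123))


class TestKmeansPool:
    def test_k_one_yields_single_all_gene_seed(self):
        m = make_matrix(np.random.default_rng(0).normal(size=(20, 3)))
        pool = kmeans_pool(m, SeedConfig(k_grid=(1,), seed=0))
        assert len(pool) == 1 and pool[0].genes == frozenset(m.gene_ids)

    def test_pool_size_is_sum_of_k(self):
        m = make_matrix(np.random.default_rng(1).normal(size=(30, 3)))
        pool = kmeans_pool(m, SeedConfig(k_grid=(2, 3), seed=0))
        assert len(pool) == 5

    def test_recovers_planted_sets_at_zero_noise(self, noise_free):
        clustered = sorted(g for g, lab in noise_free.truth.items() if lab != 0)
        m = noise_free.matrix.subset(clustered)
        pool = kmeans_pool(m, SeedConfig(k_grid=(3,), seed=0))
        found = sorted(sorted(s.genes) for s in pool)
        expected = sorted(sorted(c) for c in noise_free.truth_clusters())
        assert found == expected

    def test_oversized_k_skipped(self):
        m = make_matrix(np.random.default_rng(2).normal(size=(5, 2)))
        pool = kmeans_pool(m, SeedConfig(k_grid=(2, 50), seed=0))
        assert {len(p.genes) for p in pool} and len(pool) == 2  # only K=2 ran

    def test_deterministic_given_seed(self):
        m = make_matrix(np.random.default_rng(3).normal(size=(40, 4)))
        cfg = SeedConfig(k_grid=(2, 4), seed=9)
        a = [s.genes for s in kmeans_pool(m, cfg)]
        b = [s.genes for s in kmeans_pool(m, cfg)]
        assert a == b


class TestAlignPartitions:
    def test_recovers_label_swap(self):
        ref = Partition({"a": 0, "b": 0, "c": 1, "d": 1}, K=2)
        other = Partition({"a": 1, "b": 1, "c": 0, "d": 0}, K=2)
        assert align_partitions(ref, other).labels == ref.labels

    def test_identity_on_identical_partitions(self):
        ref = Partition({"a": 0, "b": 1, "c": 2}, K=3)
        assert align_partitions(ref, ref).labels == ref.labels

    def test_differing_k_rejected(self):
        with pytest.raises(ValidationError):
            align_partitions(Partition({"a": 0}, K=1), Partition({"a": 1}, K=2))

    def test_matches_exhaustive_permutation_oracle(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(12)]
        for _ in range(10):
            ref = Partition({g: int(rng.integers(0, 3)) for g in genes}, K=3)
            other = Partition({g: int(rng.integers(0, 3)) for g in genes}, K=3)
            aligned = align_partitions(ref, other)
            agree = sum(aligned.labels[g] == ref.labels[g] for g in genes)
            best = max(
                sum(perm[other.labels[g]] == ref.labels[g] for g in genes)
                for perm in itertools.permutations(range(3))
            )
            assert agree == best


class TestBuildCPM:
    def test_identical_partitions_give_binary_cpm(self):
        p = Partition({"a": 0, "b": 1, "c": 1}, K=2)
        cpm = build_cpm([p, p, p])
        assert set(np.unique(cpm.memberships)) <= {0.0, 1.0}

    def test_single_disagreement_becomes_half_half(self):
        p = Partition({"a": 0, "b": 1, "c": 1}, K=3)
        q = Partition({"a": 0, "b": 2, "c": 1}, K=3)
        cpm = build_cpm([p, q])
        row_b = cpm.memberships[cpm.gene_ids.index("b")]
        np.testing.assert_allclose(row_b, [0.0, 0.5, 0.5])

    def test_rows_sum_to_one_for_random_inputs(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(15)]
        parts = [
            Partition({g: int(rng.integers(0, 4)) for g in genes}, K=4)
            for _ in range(5)
        ]
        cpm = build_cpm(parts)
        np.testing.assert_allclose(cpm.memberships.sum(axis=1), 1.0)

    def test_empty_list_rejected(self):
        with pytest.raises(ValidationError):
            build_cpm([])


class TestDTBBinarize:
    def test_margin_rule(self):
        cpm = FuzzyCPM(["a"], np.array([[0.8, 0.2]]))
        seeds = dtb_binarize(cpm, 0.3)
        assert len(seeds) == 1 and seeds[0].genes == frozenset({"a"})

    def test_exact_tie_stays_unassigned_even_at_delta_zero(self):
        cpm = FuzzyCPM(["a"], np.array([[0.5, 0.5]]))
        assert dtb_binarize(cpm, 0.0) == []

    def test_delta_one_excludes_any_competing_mass(self):
        cpm = FuzzyCPM(["a", "b"], np.array([[0.9, 0.1], [1.0, 0.0]]))
        seeds = dtb_binarize(cpm, 1.0)
        assert seeds == []  # even membership 1 has margin exactly 1, not > 1

    def test_invalid_delta_rejected(self):
        cpm = FuzzyCPM(["a"], np.array([[1.0]]))
        with pytest.raises(ValidationError):
            dtb_binarize(cpm, 1.5)

    def test_clusters_disjoint_and_monotone_in_delta(self):
        rng = np.random.default_rng(8)
        raw = rng.dirichlet(np.ones(4), size=30)
        cpm = FuzzyCPM([f"g{i}" for i in range(30)], raw)
        previous = None
        for delta in (0.0, 0.2, 0.4, 0.6):
            seeds = dtb_binarize(cpm, delta)
            all_genes = [g for s in seeds for g in s.genes]
            assert len(all_genes) == len(set(all_genes))
            assigned = set(all_genes)
            if previous is not None:
                assert assigned <= previous  # larger delta only sheds genes
            previous = assigned


class TestMultiDatasetSeedPool:
    def test_identical_datasets_reproduce_single_dataset_seeds_at_delta_zero(self):
        # three well-separated blobs: the K=3 optimum is unique, so every
        # k-means run (and hence the consensus) lands on the same partition
        rng = np.random.default_rng(5)
        X = np.concatenate(
            [rng.normal(c, 0.05, size=(13, 4)) for c in (0.0, 5.0, 10.0)]
        )[:40]
        m1 = make_matrix(X, dataset_id="d1")
        m2 = make_matrix(X, dataset_id="d2")
        cfg = SeedConfig(k_grid=(3,), delta_grid=(0.0,), seed=0)
        single = {s.genes for s in kmeans_pool(m1, SeedConfig(k_grid=(3,), seed=0))}
        multi = {s.genes for s in multi_dataset_seed_pool([m1, m2], cfg)}
        assert multi == single

    def test_consensus_recovers_planted_clusters_across_noisy_replicates(self):
        ds1 = generate(SimulationConfig(sigma=0.4, seed=21))
        ds2 = generate(SimulationConfig(sigma=0.4, seed=22))
        m1, m2 = ds1.matrix, ds2.matrix
        m1.dataset_id, m2.dataset_id = "a", "b"
        clustered = sorted(g for g, lab in ds1.truth.items() if lab != 0)
        cfg = SeedConfig(k_grid=(3,), delta_grid=(0.0,), seed=0)
        pool = multi_dataset_seed_pool([m1.subset(clustered), m2.subset(clustered)], cfg)
        found = sorted(sorted(s.genes) for s in pool)
        expected = sorted(sorted(c) for c in ds1.truth_clusters())
        assert found == expected

    def test_empty_intersection_names_datasets(self):
        m1 = make_matrix([[1.0, 2.0]], gene_ids=["a"], dataset_id="left")
        m2 = make_matrix([[1.0, 2.0]], gene_ids=["b"], dataset_id="right")
        with pytest.raises(ValidationError, match="left.*right"):
            multi_dataset_seed_pool([m1, m2], SeedConfig(k_grid=(2,)))
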