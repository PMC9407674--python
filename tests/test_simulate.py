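"""Synthetic generators: lineage networks, validity panel, ddG tables."""

import math

import networkx as nx
import numpy as np
import pytest

from classdiv import (
    CloneNetworkSpec,
    DdgGeneratorSpec,
    STANDARD_THERMO,
    SimilarityModel,
    ValidationError,
    class_diversity,
    edit_distance,
    hill_diversity,
    make_clonal_repertoire,
    make_clone_network,
    make_ddg_table,
    make_random_kmers,
    make_two_clone,
    make_unrelated_set,
    make_validity_quartet,
    parse_skempi_like,
    reference_counts,
)
from classdiv.simulate import truncated_exponential_mean

RT = STANDARD_THERMO.RT


class TestReferenceCounts:
    def test_sum_and_minimum(self):
        counts = reference_counts(34, 752)
        assert counts.sum() == 752 and counts.size == 34
        assert counts.min() >= 1
        assert counts[0] == counts.max()  # dominant ancestor

    def test_infeasible_rejected(self):
        with pytest.raises(ValidationError):
            reference_counts(10, 5)


class TestCloneNetwork:
    def test_default_spec_dimensions(self):
        synth = make_clone_network(CloneNetworkSpec(seed=0))
        rep = synth.repertoire
        assert rep.n_unique == 34 and rep.total_count == 752
        assert all(len(s) == 17 for s in rep.sequences)

    def test_connected_through_distance_one_edges(self):
        synth = make_clone_network(CloneNetworkSpec(seed=0))
        graph = nx.Graph()
        graph.add_nodes_from(synth.repertoire.sequences)
        graph.add_edges_from(synth.edges)
        assert nx.is_connected(graph)

    def test_edges_audit_against_distance_oracle(self):
        synth = make_clone_network(CloneNetworkSpec(n_unique=12, seed=1))
        seqs = synth.repertoire.sequences
        expected = {
            frozenset((a, b))
            for i, a in enumerate(seqs)
            for b in seqs[i + 1 :]
            if edit_distance(a, b) == 1
        }
        assert {frozenset(e) for e in synth.edges} == expected

    def test_single_node_network(self):
        synth = make_clone_network(
            CloneNetworkSpec(n_unique=1, total_count=10, seed=2)
        )
        assert synth.repertoire.n_unique == 1 and synth.edges == []

    def test_impossible_spec_rejected(self):
        with pytest.raises(ValidationError):
            make_clone_network(
                CloneNetworkSpec(
                    n_unique=500, total_count=1000, cdr3_length=3, seed=0
                )
            )

    def test_seed_determinism(self):
        a = make_clone_network(CloneNetworkSpec(seed=5)).repertoire
        b = make_clone_network(CloneNetworkSpec(seed=5)).repertoire
        assert a == b


class TestTwoClone:
    def test_count_multiset_matches_reference(self):
        spec = CloneNetworkSpec(seed=3)
        one = make_clone_network(
            CloneNetworkSpec(seed=3, n_mutable_positions=6)
        ).repertoire
        two = make_two_clone(spec).repertoire
        assert sorted(one.counts.tolist()) == sorted(two.counts.tolist())
        assert two.n_unique == 34 and two.total_count == 752

    def test_cross_clone_distance_bound(self):
        synth = make_two_clone(CloneNetworkSpec(seed=3))
        truth = synth.ground_truth
        length = 17
        seqs = synth.repertoire.sequences
        # recover block membership from the seed sequences
        seed_a = truth["seed_sequence"]
        block_a = [s for s in seqs if edit_distance(s, seed_a) <= 6]
        block_b = [s for s in seqs if s not in block_a]
        assert len(block_a) == 17 and len(block_b) == 17
        min_cross = min(
            edit_distance(a, b) for a in block_a for b in block_b
        )
        assert min_cross >= math.ceil(length / 2)

    def test_isomorphic_halves_preserve_distances(self):
        # the relabelled block must reproduce the replaced nodes' distance
        # structure exactly (stronger than subgraph isomorphism)
        two = make_two_clone(CloneNetworkSpec(seed=4))
        replaced = two.ground_truth["replaced_nodes"]
        block_b = two.ground_truth["block_b"]
        assert len(replaced) == len(block_b) == 17
        for i in range(17):
            for j in range(i + 1, 17):
                assert edit_distance(block_b[i], block_b[j]) == edit_distance(
                    replaced[i], replaced[j]
                )

    def test_higher_class_diversity_than_one_clone(self):
        model = SimilarityModel()
        quartet = make_validity_quartet(CloneNetworkSpec(seed=3))
        one = quartet["one-clone"].repertoire
        two = quartet["two-clone"].repertoire
        assert hill_diversity(one, 0) == hill_diversity(two, 0)
        assert class_diversity(two, 0, model) > class_diversity(one, 0, model)


class TestUnrelatedAndRandom:
    def test_min_pairwise_distance_audit(self):
        synth = make_unrelated_set(seed=0)
        seqs = synth.repertoire.sequences
        assert all(
            edit_distance(a, b) >= 2
            for i, a in enumerate(seqs)
            for b in seqs[i + 1 :]
        )

    def test_single_sequence_trivially_satisfies(self):
        assert make_unrelated_set(n=1, seed=1).repertoire.n_unique == 1

    def test_unrelated_more_diverse_than_clone_at_same_counts(self):
        counts = reference_counts(34, 752)
        unrelated = make_unrelated_set(seed=2, counts=counts).repertoire
        clone = make_clone_network(CloneNetworkSpec(seed=2)).repertoire
        model = SimilarityModel()
        assert class_diversity(unrelated, 0, model) > class_diversity(
            clone, 0, model
        )

    def test_random_kmers_uniform_letters(self):
        synth = make_random_kmers(n=400, length=10, seed=3)
        letters = "".join(synth.repertoire.sequences)
        counts = np.array([letters.count(a) for a in "ACDEFGHIKLMNPQRSTVWY"])
        n = counts.sum()
        se = math.sqrt(0.05 * 0.95 / n)
        assert np.all(np.abs(counts / n - 0.05) < 4 * se)

    def test_random_kmers_expected_pairwise_hamming(self, rng):
        synth = make_random_kmers(n=60, length=17, seed=4)
        seqs = synth.repertoire.sequences
        dists = [
            sum(x != y for x, y in zip(a, b))
            for i, a in enumerate(seqs)
            for b in seqs[i + 1 :]
        ]
        expected = 17 * 19 / 20
        se = np.std(dists, ddof=1) / math.sqrt(len(dists))
        assert abs(np.mean(dists) - expected) < 4 * se + 0.05

    def test_zero_sequences_rejected(self):
        with pytest.raises(ValidationError):
            make_random_kmers(n=0)


class TestValidityQuartet:
    def test_shared_count_multiset_and_class_ordering(self):
        model = SimilarityModel()
        quartet = make_validity_quartet(CloneNetworkSpec(seed=0))
        counts = [
            sorted(s.repertoire.counts.tolist()) for s in quartet.values()
        ]
        assert all(c == counts[0] for c in counts)
        d0s = {
            name: class_diversity(s.repertoire, 0, model)
            for name, s in quartet.items()
        }
        assert d0s["one-clone"] < d0s["two-clone"] < d0s["unrelated"]
        assert d0s["unrelated"] <= d0s["random"]


class TestClonalRepertoire:
    def test_determinism_and_ground_truth(self):
        a = make_clonal_repertoire(n_clones=3, seed=11)
        b = make_clonal_repertoire(n_clones=3, seed=11)
        assert a.repertoire == b.repertoire
        assert a.ground_truth["min_cross_clone_distance_bound"] >= 9

    def test_sequence_diversity_is_sum_of_clone_uniques(self):
        synth = make_clonal_repertoire(n_clones=4, n_unique_per_clone=15, seed=12)
        assert synth.repertoire.n_unique == 60

    def test_class_diversity_scales_with_clone_number(self):
        model = SimilarityModel()
        values = {}
        for k in (4, 8):
            rep = make_clonal_repertoire(
                n_clones=k, n_unique_per_clone=15, within_clone_decay=0.5,
                seed=13,
            ).repertoire
            values[k] = class_diversity(rep, 0, model)
            assert k <= values[k] <= 4 * k  # a tight clone is a few classes
        assert values[8] == pytest.approx(2 * values[4], rel=0.2)

    def test_two_blocks_are_nearly_additive(self):
        model = SimilarityModel()
        synth = make_clonal_repertoire(n_clones=2, n_unique_per_clone=12, seed=14)
        rep = synth.repertoire
        seeds = synth.ground_truth["clone_seeds"]
        blocks = []
        for seed_seq in seeds:
            members = [
                (s, int(c))
                for s, c in rep.to_pairs()
                if edit_distance(s, seed_seq) <= 4
            ]
            from classdiv import collapse_and_normalize

            blocks.append(collapse_and_normalize(members))
        assert sum(b.n_unique for b in blocks) == rep.n_unique
        total = class_diversity(rep, 0, model)
        parts = sum(class_diversity(b, 0, model) for b in blocks)
        assert total == pytest.approx(parts, rel=1e-2)


class TestDdgTable:
    def test_parse_round_trip_recovers_ddg(self):
        df, _ = make_ddg_table(DdgGeneratorSpec(n_records=50, seed=0))
        parsed = parse_skempi_like(df)
        regenerated = np.sort([r.abs_ddg for r in parsed.singles])
        rng = np.random.default_rng(0)
        del rng
        assert len(parsed.singles) == 50
        assert np.all(regenerated <= 3.2 + 1e-9)

    def test_truncated_mean_formula_matches_samples(self):
        spec = DdgGeneratorSpec(n_records=20000, seed=1)
        df, truth = make_ddg_table(spec)
        parsed = parse_skempi_like(df)
        noncore = np.array(
            [r.abs_ddg for r in parsed.singles if r.region == "noncore"]
        )
        expected = truth["noncore_mean_truncated"]
        se = noncore.std(ddof=1) / math.sqrt(noncore.size)
        assert abs(noncore.mean() - expected) < 4 * se

    def test_fold_one_gives_all_zero(self):
        df, truth = make_ddg_table(
            DdgGeneratorSpec(core_fold=1.0, noncore_fold=1.0, n_records=20, seed=2)
        )
        parsed = parse_skempi_like(df)
        assert all(r.abs_ddg == pytest.approx(0.0, abs=1e-12) for r in parsed.singles)
        assert truth["implied_s"] == pytest.approx(1.0)

    def test_core_untruncated_mean_is_rt_ln_fold(self):
        _, truth = make_ddg_table(DdgGeneratorSpec(seed=3))
        assert truth["core_mean_untruncated"] == pytest.approx(
            RT * math.log(13), abs=1e-12
        )

    def test_truncated_exponential_mean_limits(self):
        assert truncated_exponential_mean(1.0, 1e9) == pytest.approx(1.0)
        assert truncated_exponential_mean(1.0, 0.01) < 0.01
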