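import numpy as np
import pytest

from dropquant.baselines import (
    directional_cluster_count,
    min_dominating_set_size,
    naive_eqclass_gene_counts,
)
from dropquant.pug_dedup import (
    PUG,
    PUGVertex,
    brute_force_cover,
    build_pug,
    dominating_set_pug,
    greedy_cover,
    hamming,
    label_arborescences,
    pug_to_dot,
    validate_covering,
)


def random_pug(rng, max_vertices=8, tx_pool=("t1", "t2", "t3", "t4")):
    """A random small cell table and its PUG (UMIs over a 2-letter alphabet
    so Hamming-1 pairs are common)."""
    table = {}
    for _ in range(int(rng.integers(2, max_vertices + 1))):
        umi = "".join("AC"[i] for i in rng.integers(0, 2, 4))
        T = tuple(sorted(rng.choice(tx_pool, size=int(rng.integers(1, 3)), replace=False)))
        key = (umi, T)
        if key not in table:
            table[key] = int(rng.integers(1, 9))
    return table, build_pug(table)


class TestBuildPug:
    def test_directed_edge_when_count_dominates(self):
        pug = build_pug({("ACGT", ("t1",)): 5, ("ACGA", ("t1",)): 1})
        assert pug.directed == {(0, 1)}
        assert pug.bidirected == set()

    def test_bidirected_edge_when_counts_balanced(self):
        pug = build_pug({("ACGT", ("t1",)): 3, ("ACGA", ("t1",)): 2})
        assert pug.directed == set()
        assert pug.bidirected == {(0, 1)}

    def test_no_edge_without_transcript_overlap(self):
        pug = build_pug({("ACGT", ("t1",)): 5, ("ACGA", ("t2",)): 1})
        assert pug.directed == set() and pug.bidirected == set()

    def test_same_umi_different_classes_joined_at_distance_zero(self):
        pug = build_pug({("ACGT", ("t1", "t2")): 5, ("ACGT", ("t2",)): 1})
        assert pug.bidirected == {(0, 1)}

    def test_inconsistent_umi_lengths_error(self):
        with pytest.raises(ValueError, match="UMI lengths"):
            build_pug({("ACGT", ("t1",)): 1, ("ACG", ("t1",)): 1})

    def test_hamming_requires_equal_lengths(self):
        with pytest.raises(ValueError):
            hamming("ACGT", "ACG")


class TestGreedyCover:
    def test_single_vertex(self):
        pug = build_pug({("ACGT", ("t1",)): 1})
        cov = greedy_cover(pug)
        validate_covering(pug, cov)
        assert len(cov) == 1

    def test_distinct_umis_disjoint_classes_stay_separate(self):
        # one molecule per transcript, UMIs far apart: two molecules
        pug = build_pug({("AAAA", ("t1",)): 2, ("CCCC", ("t2",)): 2})
        cov = greedy_cover(pug)
        validate_covering(pug, cov)
        assert len(cov) == 2

    def test_bidirected_path_collapses_to_one(self):
        table = {("AAAA", ("t1",)): 1, ("AAAT", ("t1",)): 1, ("AATT", ("t1",)): 1}
        pug = build_pug(table)
        cov = greedy_cover(pug)
        validate_covering(pug, cov)
        assert len(cov) == 1
        assert brute_force_cover(pug) == 1

    def test_shared_umi_across_overlapping_classes_is_one_molecule(self):
        """One UMI seen in classes {t1,t2} and {t2} (same gene): one pre-PCR
        molecule, while the per-class naive counter reports two."""
        table = {("ACGT", ("t1", "t2")): 3, ("ACGT", ("t2",)): 2}
        t2g = {"t1": "g1", "t2": "g1"}
        pug = build_pug(table)
        cov = greedy_cover(pug)
        validate_covering(pug, cov)
        unique, ambiguous = label_arborescences(cov, t2g)
        assert len(cov) == 1 and unique == {"g1": 1} and not ambiguous
        assert naive_eqclass_gene_counts(table, t2g) == {"g1": 2.0}

    def test_monochromatic_components_collapse_to_one_per_component(self, rng):
        # all vertices share t1 and every edge is bi-directed (equal counts)
        table = {}
        for i in range(6):
            umi = format(i, "04b").replace("0", "A").replace("1", "C")
            table[(umi, ("t1",))] = 1
        pug = build_pug(table)
        cov = greedy_cover(pug)
        validate_covering(pug, cov)
        und = pug.undirected_neighbors()
        n_components = 0
        seen = set()
        for v in range(len(pug.vertices)):
            if v not in seen:
                n_components += 1
                stack = [v]
                seen.add(v)
                while stack:
                    x = stack.pop()
                    for w in und[x]:
                        if w not in seen:
                            seen.add(w)
                            stack.append(w)
        assert len(cov) == n_components

    def test_every_iteration_terminates_and_covers(self, rng):
        for _ in range(50):
            _table, pug = random_pug(rng)
            cov = greedy_cover(pug)
            validate_covering(pug, cov)


class TestBruteForce:
    def test_empty_graph(self):
        assert brute_force_cover(PUG([], set(), set())) == 0

    def test_two_isolated_vertices(self):
        pug = build_pug({("AAAA", ("t1",)): 1, ("CCCC", ("t2",)): 1})
        assert brute_force_cover(pug) == 2

    def test_size_guard(self):
        vertices = [
            PUGVertex(f"{i:04d}".replace("0", "A").replace("1", "C"), frozenset({"t"}), 1)
            for i in range(13)
        ]
        with pytest.raises(ValueError, match="limited"):
            brute_force_cover(PUG(vertices, set(), set()))

    def test_greedy_never_beats_exact_minimum(self, rng):
        matches = 0
        n = 200
        for _ in range(n):
            _table, pug = random_pug(rng)
            cov = greedy_cover(pug)
            validate_covering(pug, cov)
            opt = brute_force_cover(pug)
            assert len(cov) >= opt
            matches += len(cov) == opt
        assert matches / n >= 0.9


class TestLabeling:
    def test_single_gene_feasible_set_increments_gene(self):
        pug = build_pug({("AAAA", ("t1",)): 1})
        unique, amb = label_arborescences(greedy_cover(pug), {"t1": "gA"})
        assert unique == {"gA": 1} and amb == []

    def test_multi_transcript_single_gene_counts_once(self):
        pug = build_pug({("AAAA", ("t1", "t2")): 1})
        unique, amb = label_arborescences(greedy_cover(pug), {"t1": "gA", "t2": "gA"})
        assert unique == {"gA": 1} and amb == []

    def test_multi_gene_feasible_set_is_ambiguous(self):
        pug = build_pug({("AAAA", ("t1", "t2")): 1})
        unique, amb = label_arborescences(greedy_cover(pug), {"t1": "gA", "t2": "gB"})
        assert not unique and amb == [frozenset({"gA", "gB"})]


class TestDirectionalEquivalence:
    def test_matches_directional_clustering_on_single_transcript_data(self, rng):
        """On single-transcript tables the covering size equals an
        independently coded directional UMI clustering."""
        for _ in range(30):
            counts = {}
            for _ in range(int(rng.integers(3, 9))):
                u = "".join("ACGT"[i] for i in rng.integers(0, 4, 5))
                counts[u] = counts.get(u, 0) + int(rng.integers(1, 50))
                if rng.random() < 0.7:
                    pos = int(rng.integers(5))
                    e = u[:pos] + "ACGT"[int(rng.integers(4))] + u[pos + 1 :]
                    if e != u:
                        counts[e] = counts.get(e, 0) + int(rng.integers(1, 5))
            pug = build_pug({(u, ("t1",)): c for u, c in counts.items()})
            cov = greedy_cover(pug)
            validate_covering(pug, cov)
            assert len(cov) == directional_cluster_count(counts)


class TestDominatingSetReduction:
    def test_star_graph_has_covering_one(self):
        edges = [(0, i) for i in range(1, 5)]
        pug = dominating_set_pug(5, edges)
        assert brute_force_cover(pug) == 1 == min_dominating_set_size(5, edges)

    def test_reduction_matches_exhaustive_dominating_set(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 9))
            edges = [
                (i, j)
                for i in range(n)
                for j in range(i + 1, n)
                if rng.random() < 0.4
            ]
            assert brute_force_cover(dominating_set_pug(n, edges)) == (
                min_dominating_set_size(n, edges)
            )


def test_dot_output_mentions_vertices_and_edges():
    pug = build_pug({("ACGT", ("t1",)): 5, ("ACGA", ("t1",)): 1})
    dot = pug_to_dot(pug)
    assert "n0 -> n1" in dot and "ACGT" in dot and dot.startswith("digraph")
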