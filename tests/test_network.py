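"""Haplotype network (goeBURST MST), group steps, K2P and NJ."""

import itertools
import math

import numpy as np
import pytest

from coihap.haplotypes import HaplotypeTable, collapse_haplotypes
from coihap.network import (
    DistanceMatrix,
    goeburst_mst,
    group_min_steps,
    group_mst_path_steps,
    hamming_matrix,
    k2p_distance,
    k2p_matrix,
    mst_total_weight,
    neighbor_joining,
)
from coihap.seqio import Alignment, SequenceRecord


def table_from(seq_counts):
    """HaplotypeTable from (id, seq, count) triples."""
    haps = [(i, s, c, [i]) for i, s, c in seq_counts]
    return HaplotypeTable(haps, sum(c for _, _, c in seq_counts))


def brute_force_mst_weight(dm: DistanceMatrix) -> float:
    """Minimum spanning-tree weight by exhaustive edge-subset enumeration."""
    n = len(dm.ids)
    edges = [
        (i, j, dm.d[i, j]) for i, j in itertools.combinations(range(n), 2)
    ]
    best = math.inf
    for subset in itertools.combinations(edges, n - 1):
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        ok = True
        for i, j, _ in subset:
            ri, rj = find(i), find(j)
            if ri == rj:
                ok = False
                break
            parent[ri] = rj
        if ok:
            best = min(best, sum(w for _, _, w in subset))
    return best


class TestHamming:
    def test_f1_haplotype_distances(self, f1):
        table = collapse_haplotypes(f1)
        dm = hamming_matrix(table)
        assert dm[("s1", "s2")] == 1
        assert dm[("s1", "s3")] == 1
        assert dm[("s2", "s3")] == 2

    def test_single_difference(self):
        dm = hamming_matrix(table_from([("a", "ACGT", 1), ("b", "ACGA", 1)]))
        assert dm[("a", "b")] == 1


class TestGoeburstMST:
    def test_single_haplotype(self):
        t = table_from([("a", "ACGT", 5)])
        G = goeburst_mst(t, hamming_matrix(t))
        assert G.number_of_nodes() == 1 and G.number_of_edges() == 0

    def test_path_fixture(self):
        # 4 haplotypes on a line: consecutive d=1, else larger
        t = table_from([
            ("a", "AAAA", 1), ("b", "AAAC", 1), ("c", "AACC", 1),
            ("d", "ACCC", 1),
        ])
        dm = hamming_matrix(t)
        G = goeburst_mst(t, dm)
        assert mst_total_weight(G) == 3 == brute_force_mst_weight(dm)
        degs = sorted(d for _, d in G.degree)
        assert degs == [1, 1, 2, 2]

    def test_star_fixture_hub_wins_ties(self):
        # hub with count 50, five satellites at d=1 from hub, d=2 pairwise
        base = "AAAAAAAA"
        sats = []
        for i in range(5):
            s = list(base)
            s[i] = "C"
            sats.append(("sat%d" % i, "".join(s), 1))
        t = table_from([("hub", base, 50)] + sats)
        dm = hamming_matrix(t)
        G = goeburst_mst(t, dm)
        assert mst_total_weight(G) == 5 == brute_force_mst_weight(dm)
        assert G.degree["hub"] == 5  # star through the hub

    def test_matches_brute_force_on_random_matrices(self, rng):
        for _ in range(4):
            n = 6
            sym = rng.integers(1, 9, size=(n, n))
            d = np.triu(sym, 1)
            d = d + d.T
            dm = DistanceMatrix([f"h{i}" for i in range(n)], d.astype(float))
            t = table_from([(f"h{i}", "A" * 4, 1) for i in range(n)])
            G = goeburst_mst(t, dm)
            assert mst_total_weight(G) == brute_force_mst_weight(dm)

    def test_deterministic_under_tiebreak_preserving_relabel(self):
        t1 = table_from([("a", "AAAA", 3), ("b", "AAAC", 2), ("c", "AACC", 1)])
        G1 = goeburst_mst(t1, hamming_matrix(t1))
        G2 = goeburst_mst(t1, hamming_matrix(t1))
        assert sorted(G1.edges) == sorted(G2.edges)


class TestGroupSteps:
    def test_min_pairwise_definition(self):
        t = table_from([
            ("a", "AAAA", 1), ("b", "AAAC", 1), ("c", "ACCC", 1),
            ("d", "CCCC", 1),
        ])
        dm = hamming_matrix(t)
        groups = {"a": "G1", "b": "G1", "c": "G2", "d": "G2"}
        steps = group_min_steps(dm, groups)
        assert steps[("G1", "G2")] == 2  # b vs c
        assert steps[("G1", "G1")] == 0

    def test_unknown_label_rejected(self):
        t = table_from([("a", "AAAA", 1), ("b", "AAAC", 1)])
        dm = hamming_matrix(t)
        with pytest.raises(ValueError):
            group_min_steps(dm, {"a": "G1"})

    def test_mst_path_at_least_min_hamming(self):
        t = table_from([
            ("a", "AAAA", 1), ("b", "AACC", 1), ("c", "CCCC", 1),
        ])
        dm = hamming_matrix(t)
        G = goeburst_mst(t, dm)
        groups = {"a": "G1", "b": "G2", "c": "G3"}
        mins = group_min_steps(dm, groups)
        paths = group_mst_path_steps(G, groups)
        for pair, v in paths.items():
            assert v >= mins[pair] - 1e-9


class TestK2P:
    def test_identical_sequences(self):
        assert k2p_distance("ACGT", "ACGT") == 0.0

    def test_closed_form_transitions_only(self):
        # P=0.1, Q=0: d = -1/2 ln(0.8)
        a = "A" * 10
        b = "G" + "A" * 9
        expected = -0.5 * math.log(1 - 2 * 0.1) - 0.25 * math.log(1.0)
        assert k2p_distance(a, b) == pytest.approx(expected)
        assert expected == pytest.approx(0.1116, abs=5e-4)

    def test_transitions_corrected_more_than_transversions(self):
        # at equal p-distance the K2P correction is larger for transitions
        # (-1/2 ln(1-2P) grows faster than -1/2 ln(1-Q) - 1/4 ln(1-2Q))
        ts = k2p_distance("A" * 10, "G" + "A" * 9)  # transition
        tv = k2p_distance("A" * 10, "C" + "A" * 9)  # transversion
        assert ts > tv
        assert ts > k2p_distance("A" * 10, "A" * 10)

    def test_saturation_hits_ceiling(self):
        d = k2p_distance("AC", "CA", ceiling=10.0)
        assert d == 10.0


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        # d(ab)=3, d(ac)=5, d(bc)=6 -> la=1, lb=2, lc=4
        dm = DistanceMatrix(
            ["a", "b", "c"],
            np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0]], float),
        )
        tree = neighbor_joining(dm)
        assert tree.path_length("a", "b") == pytest.approx(3)
        assert tree.path_length("a", "c") == pytest.approx(5)
        assert tree.path_length("b", "c") == pytest.approx(6)

    def test_additive_five_taxon_exact_recovery(self):
        dm = DistanceMatrix(list("ABCDE"), np.array([
            [0, 5, 9, 12, 13], [5, 0, 10, 13, 14], [9, 10, 0, 7, 8],
            [12, 13, 7, 0, 5], [13, 14, 8, 5, 0]], float))
        tree = neighbor_joining(dm)
        for u, v in itertools.combinations("ABCDE", 2):
            assert abs(tree.path_length(u, v) - dm[(u, v)]) < 1e-9

    def test_random_additive_matrices_recovered(self, rng):
        # random caterpillar trees with positive branch lengths
        for _ in range(3):
            bl = rng.uniform(0.5, 3.0, size=7)
            # tree: (A,B)x, (x,C)y, (y,(D,E))
            dA, dB, dC, dD, dE, dx, dy = bl
            ids = list("ABCDE")
            coords = {
                "A": dA, "B": dB, "C": dC + dx, "D": dD + dx + dy,
                "E": dE + dx + dy,
            }
            d = np.zeros((5, 5))
            pathpairs = {
                ("A", "B"): dA + dB, ("A", "C"): dA + dx + dC,
                ("A", "D"): dA + dx + dy + dD, ("A", "E"): dA + dx + dy + dE,
                ("B", "C"): dB + dx + dC, ("B", "D"): dB + dx + dy + dD,
                ("B", "E"): dB + dx + dy + dE, ("C", "D"): dC + dy + dD,
                ("C", "E"): dC + dy + dE, ("D", "E"): dD + dE,
            }
            for (u, v), val in pathpairs.items():
                i, j = ids.index(u), ids.index(v)
                d[i, j] = d[j, i] = val
            dm = DistanceMatrix(ids, d)
            tree = neighbor_joining(dm)
            for (u, v), val in pathpairs.items():
                assert abs(tree.path_length(u, v) - val) < 1e-9

    def test_identical_rows_give_zero_length_cherry(self):
        dm = DistanceMatrix(
            ["a", "b", "c"],
            np.array([[0, 0, 4], [0, 0, 4], [4, 4, 0]], float),
        )
        tree = neighbor_joining(dm)
        assert tree.path_length("a", "b") == pytest.approx(0.0)

    def test_agrees_with_skbio_on_additive_matrix(self):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj

        d = np.array([
            [0, 5, 9, 12, 13], [5, 0, 10, 13, 14], [9, 10, 0, 7, 8],
            [12, 13, 7, 0, 5], [13, 14, 8, 5, 0]], float)
        ids = list("ABCDE")
        ours = neighbor_joining(DistanceMatrix(ids, d))
        theirs = sk_nj(SkDM(d, ids))
        for u, v in itertools.combinations(ids, 2):
            sk_len = theirs.find(u).distance(theirs.find(v))
            assert abs(ours.path_length(u, v) - sk_len) < 1e-9

    def test_newick_is_parseable_with_branch_lengths(self, f1):
        table = collapse_haplotypes(f1)
        dm = k2p_matrix(table.ids, table.seqs)
        nwk = neighbor_joining(dm).newick()
        from io import StringIO

        from Bio import Phylo

        tree = Phylo.read(StringIO(nwk), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == sorted(table.ids)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0]], float))
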