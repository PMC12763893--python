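"""Alignment, K2P distance, clustering, NJ trees and NG86 Ka/Ks."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skbio import DistanceMatrix

import telandscape as tl
from telandscape.seqcompare import (
    DEFAULT_SCORES,
    SaturationError,
    _k2p_matrix_from_columns,
    bipartitions,
)

# Independently evaluated closed form (30-digit arithmetic):
# K(0.1, 0.05) = -1/2 ln((1 - 0.25) * sqrt(0.9)) = 0.170181165140347...
K_01_005 = 0.17018117


def brute_force_global_score(a: str, b: str, scores=DEFAULT_SCORES) -> float:
    """Exhaustive enumeration of all global alignments (affine gaps: a gap
    of length L costs open + (L-1)*extend); independent of the aligner."""
    match, mismatch, gap_open, gap_extend = scores

    def rec(i: int, j: int, prev: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = -math.inf
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            if a[i] == "N" or b[j] == "N":
                s = 0.0
            best = max(best, s + rec(i + 1, j + 1, "d"))
        if i < len(a):
            s = gap_extend if prev == "u" else gap_open
            best = max(best, s + rec(i + 1, j, "u"))
        if j < len(b):
            s = gap_extend if prev == "l" else gap_open
            best = max(best, s + rec(i, j + 1, "l"))
        return best

    return rec(0, 0, "")


class TestAlignPair:
    def test_identical(self):
        aln = tl.align_pair("ACGT", "ACGT")
        assert aln.identity == 1.0 and aln.matches == 4 and aln.mismatches == 0

    def test_single_transversion(self):
        aln = tl.align_pair("ACGT", "ACGA")
        assert aln.identity == 0.75
        assert (aln.transitions, aln.transversions) == (0, 1)

    def test_single_transition(self):
        aln = tl.align_pair("ACGT", "ACAT")
        assert (aln.transitions, aln.transversions) == (1, 0)

    @pytest.mark.parametrize(
        "a,b",
        [
            ("ACGT", "ACGA"),
            ("ACGTA", "AGTA"),
            ("AAAA", "TTTT"),
            ("ACGTAC", "TACG"),
            ("AC", "ACGTAC"),
            ("ANGT", "ACGT"),
        ],
    )
    def test_global_score_matches_exhaustive_enumeration(self, a, b):
        assert tl.align_pair(a, b).score == pytest.approx(brute_force_global_score(a, b))

    def test_local_finds_embedded_repeat(self):
        aln = tl.align_pair("TTTTACGTACGTTTTT", "ACGTACGT", mode="local")
        assert aln.identity == 1.0
        assert aln.coverage_b == 1.0

    def test_empty_sequence_raises(self):
        with pytest.raises(ValueError):
            tl.align_pair("", "ACGT")

    def test_column_accounting_invariant(self):
        aln = tl.align_pair("ACGTACGGTT", "ACTTACGT")
        n_cols = len(aln.aligned_a)
        n_gapless = sum(
            1
            for x, y in zip(aln.aligned_a, aln.aligned_b)
            if x != "-" and y != "-" and x != "N" and y != "N"
        )
        assert aln.matches + aln.mismatches == n_gapless
        assert aln.transitions + aln.transversions == aln.mismatches


class TestK2P:
    def test_zero(self):
        assert tl.k2p_distance(0.0, 0.0) == 0.0

    def test_closed_form_value(self):
        assert tl.k2p_distance(0.1, 0.05) == pytest.approx(K_01_005, abs=1e-7)

    def test_saturation_boundary(self):
        with pytest.raises(SaturationError):
            tl.k2p_distance(0.45, 0.10)  # 1 - 2P - Q = 0
        with pytest.raises(SaturationError):
            tl.k2p_distance(0.0, 0.5)

    @settings(max_examples=200, derandomize=True)
    @given(
        p=st.floats(0.0, 0.4),
        q=st.floats(0.0, 0.4),
        dp=st.floats(0.001, 0.05),
    )
    def test_monotone_and_bounded_below_by_p_distance(self, p, q, dp):
        if 1 - 2 * (p + dp) - (q + dp) <= 0 or 1 - 2 * (q + dp) <= 0:
            return
        k = tl.k2p_distance(p, q)
        assert tl.k2p_distance(p + dp, q) > k
        assert tl.k2p_distance(p, q + dp) > k
        assert k >= p + q - 1e-12

    def test_from_alignment(self):
        # 10 comparable columns: 1 transition, 1 transversion
        aln = tl.align_pair("AAAAAAAAGT", "AAAAAAAAAA")
        assert tl.k2p_from_alignment(aln) == pytest.approx(
            tl.k2p_distance(0.1, 0.1)
        )


def has_split(splits, taxa, side):
    side = frozenset(side)
    return side in splits or (frozenset(taxa) - side) in splits


def random_dna(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


class TestGreedyCluster:
    def test_identical_pair_one_cluster(self):
        seq = random_dna(np.random.default_rng(0), 1200)
        clusters = tl.greedy_cluster([("a", seq), ("b", seq)])
        assert len(clusters) == 1 and clusters[0].size == 2

    def test_unrelated_pair_two_singletons(self):
        rng = np.random.default_rng(1)
        clusters = tl.greedy_cluster(
            [("a", random_dna(rng, 1200)), ("b", random_dna(rng, 1200))]
        )
        assert len(clusters) == 2

    def test_planted_two_families_recovered(self):
        rng = np.random.default_rng(2)
        c1, c2 = random_dna(rng, 2000), random_dna(rng, 1500)
        frags = [("c1", c1)]
        frags += [(f"a{i}", tl.mutate_copy(c1, 0.1, 2.0, seed=i)) for i in range(10)]
        frags += [(f"b{i}", tl.mutate_copy(c2, 0.1, 2.0, seed=50 + i)) for i in range(5)]
        clusters = tl.greedy_cluster(frags)
        assert len(clusters) == 2
        assert sorted(c.size for c in clusters) == [5, 11]
        for cluster in clusters:  # centroid is the longest member
            assert all(
                len(cluster.centroid_seq) >= len(dict(frags)[m]) for m in cluster.members
            )

    def test_output_is_a_partition_and_respects_min_length(self):
        rng = np.random.default_rng(3)
        frags = [(f"f{i}", random_dna(rng, int(n))) for i, n in enumerate(rng.integers(800, 1600, 8))]
        clusters = tl.greedy_cluster(frags, min_length=1000)
        members = [m for c in clusters for m in c.members]
        eligible = [fid for fid, seq in frags if len(seq) > 1000]
        assert sorted(members) == sorted(eligible)


class TestCoverageFilter:
    def test_threshold_is_strict(self):
        rng = np.random.default_rng(4)
        ref = random_dna(rng, 1000)
        # fragments of the reference at controlled coverages
        items = [
            ("ref", "L2", ref),
            ("c79", "L2", ref[:790]),
            ("c81", "L2", ref[:810]),
        ]
        kept = {cid for cid, _, _ in tl.coverage_filter(items)}
        assert kept == {"ref", "c81"}  # L2 threshold 0.80, strict

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        ref = random_dna(rng, 1000)
        items = [("r", "Rex-Babar", ref), ("x", "Rex-Babar", ref[:500])]
        once = tl.coverage_filter(items)
        assert tl.coverage_filter(once) == once

    def test_unknown_superfamily_uses_fallback(self):
        rng = np.random.default_rng(6)
        ref = random_dna(rng, 1000)
        items = [("r", "Mystery", ref), ("x", "Mystery", ref[:200])]
        kept = {cid for cid, _, _ in tl.coverage_filter(items)}
        assert kept == {"r"}  # 0.20 coverage fails the 0.30 fallback


class TestNJTree:
    def test_three_taxa_closed_form(self):
        # d(A,B)=3, d(A,C)=5, d(B,C)=6 -> a=1, b=2, c=4
        m = DistanceMatrix([[0, 3, 5], [3, 0, 6], [5, 6, 0]], ids=list("ABC"))
        tree = tl.nj_tree(m, bootstrap_replicates=0)
        lengths = {leaf.name: leaf.length for leaf in tree.tips()}
        assert lengths["A"] == pytest.approx(1.0)
        assert lengths["B"] == pytest.approx(2.0)
        assert lengths["C"] == pytest.approx(4.0)

    def test_additive_four_taxon_split_recovered(self):
        # tree ((A:1,B:2):3,(C:1.5,D:2.5)) -> additive matrix
        m = DistanceMatrix(
            [
                [0, 3, 5.5, 6.5],
                [3, 0, 6.5, 7.5],
                [5.5, 6.5, 0, 4],
                [6.5, 7.5, 4, 0],
            ],
            ids=list("ABCD"),
        )
        tree = tl.nj_tree(m, bootstrap_replicates=0)
        assert frozenset("AB") in bipartitions(tree) or frozenset("CD") in bipartitions(tree)
        # path lengths reproduce the matrix to machine tolerance
        dists = tree.tip_tip_distances()
        for i, j in itertools.combinations("ABCD", 2):
            assert dists[i, j] == pytest.approx(m[i, j], abs=1e-9)

    def test_clock_tree_topology_recovered(self):
        """An ultrametric 8-leaf caterpillar-of-cherries matrix is recovered."""
        # balanced tree: cherries (t0,t1),(t2,t3),(t4,t5),(t6,t7)
        leaves = [f"t{i}" for i in range(8)]

        def dist(i, j):
            if i == j:
                return 0.0
            if i // 2 == j // 2:
                return 2.0
            if i // 4 == j // 4:
                return 4.0
            return 6.0

        m = DistanceMatrix(
            [[dist(i, j) for j in range(8)] for i in range(8)], ids=leaves
        )
        tree = tl.nj_tree(m, bootstrap_replicates=0)
        splits = bipartitions(tree)
        for pair in ({"t0", "t1"}, {"t2", "t3"}, {"t4", "t5"}, {"t6", "t7"}):
            assert has_split(splits, leaves, pair)

    def test_too_few_labels_raises(self):
        with pytest.raises(ValueError):
            tl.nj_tree(DistanceMatrix([[0, 1], [1, 0]], ids=["A", "B"]))

    def test_bootstrap_support_on_clean_signal(self):
        """Strongly separated clades get high bootstrap support."""
        rng = np.random.default_rng(8)
        c1, c2 = random_dna(rng, 600), random_dna(rng, 600)
        seqs = {f"a{i}": tl.mutate_copy(c1, 0.02, 2.0, seed=i) for i in range(3)}
        seqs |= {f"b{i}": tl.mutate_copy(c2, 0.02, 2.0, seed=10 + i) for i in range(3)}
        ref = "a0"
        labels, cols = tl.star_alignment(seqs, ref)
        m = _k2p_matrix_from_columns(labels, cols)
        tree = tl.nj_tree(m, alignment=(labels, cols), bootstrap_replicates=30, seed=1)
        supports = [
            node.support
            for node in tree.non_tips(include_self=False)
            if getattr(node, "support", None) is not None
        ]
        assert supports and max(supports) >= 90


class TestKaKsNG86:
    def test_identical_sequences(self):
        ka, ks, ratio = tl.kaks_ng86("ATGAAACCC", "ATGAAACCC")
        assert ka == 0.0 and ks == 0.0 and ratio is None

    def test_single_synonymous_change(self):
        # one Phe TTT->TTC codon in a context long enough that pS < 3/4
        base = "ATGGAAGACCTGATCAAGCGA"
        ka, ks, _ = tl.kaks_ng86(base + "TTT", base + "TTC")
        assert ka == 0.0 and ks > 0.0

    def test_single_codon_pair_saturates_per_error_contract(self):
        with pytest.raises(SaturationError):
            tl.kaks_ng86("TTT", "TTC")

    def test_symmetry(self):
        rng = np.random.default_rng(12)
        codons = [
            c for c in ("".join(p) for p in itertools.product("ACGT", repeat=3))
            if c not in ("TAA", "TAG", "TGA")
        ]
        a = "".join(rng.choice(codons) for _ in range(60))
        b = tl.mutate_copy(a, 0.05, 2.0, seed=1)
        b = "".join(  # revert codons that mutated into stops
            a[i : i + 3] if b[i : i + 3] in ("TAA", "TAG", "TGA") else b[i : i + 3]
            for i in range(0, len(a), 3)
        )
        assert tl.kaks_ng86(a, b) == tl.kaks_ng86(b, a)

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            tl.kaks_ng86("ATGTAAAAA", "ATGTAAAAG")

    def test_neutral_simulation_gives_ratio_near_one(self):
        """Codon pairs diverged under equal per-site rates have Ka/Ks ~ 1
        (copies that mutated into stop codons revert that codon)."""
        ratios = [neutral_pair_ratio(seed) for seed in range(20)]
        ratios = [r for r in ratios if r is not None]
        assert abs(np.mean(ratios) - 1.0) < 0.15


STOPS = ("TAA", "TAG", "TGA")


def neutral_pair_ratio(seed: int, n_codons: int = 300, k: float = 0.15) -> float | None:
    """Independent neutral oracle: evolve a random coding sequence under a
    uniform-rate (kappa=1) substitution process and return its NG86 Ka/Ks."""
    rng = np.random.default_rng(seed)
    codons = [
        "".join(p) for p in itertools.product("ACGT", repeat=3) if "".join(p) not in STOPS
    ]
    seq = "".join(rng.choice(codons) for _ in range(n_codons))
    copy = tl.mutate_copy(seq, k, 1.0, seed=10_000 + seed)
    # revert any codon that mutated into a stop (kept identical in both)
    out = [
        seq[i : i + 3] if copy[i : i + 3] in STOPS else copy[i : i + 3]
        for i in range(0, len(seq), 3)
    ]
    _, _, ratio = tl.kaks_ng86(seq, "".join(out))
    return ratio
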