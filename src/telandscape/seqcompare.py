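"""Sequence-level computation.

Pairwise affine-gap alignment, Kimura two-parameter (K2P) distances,
greedy centroid clustering of long TE fragments, per-superfamily
alignment-coverage filtering, neighbor-joining trees with star-alignment
bootstrap support, and Nei-Gojobori (1986) Ka/Ks.

The K2P distance treats transitions (A<->G, C<->T) and transversions as
separate processes:  K = -1/2 ln((1-2P-Q) sqrt(1-2Q))  with P the
transition and Q the transversion proportion over ungapped, non-N
columns.  It is the standard proxy for the age of a TE copy relative to
its family consensus.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable
import skbio
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

DEFAULT_SCORES = (1.0, -1.0, -5.0, -1.0)  # match, mismatch, gap open, gap extend

#: Per-superfamily alignment-coverage thresholds against the star
#: reference (the longest centroid of the superfamily); a centroid is
#: kept when its coverage is strictly higher than the threshold.
DEFAULT_COVERAGE_THRESHOLDS: dict[str, float] = {
    "L2": 0.80,
    "Rex-Babar": 0.30,
    "RTE-BovB": 0.60,
    "TcMar-Tc1": 0.30,
    "hAT-Ac": 0.30,
    "hAT-Charlie": 0.30,
}
FALLBACK_COVERAGE_THRESHOLD = 0.30


class SaturationError(ValueError):
    """Raised when a distance estimator leaves its admissible domain."""


@dataclass(frozen=True)
class PairwiseAlignment:
    """Column statistics of one optimal pairwise alignment."""

    aligned_a: str
    aligned_b: str
    score: float
    matches: int
    mismatches: int
    transitions: int
    transversions: int
    gap_columns: int
    identity: float
    coverage_a: float
    coverage_b: float

    def __len__(self) -> int:
        return len(self.aligned_a)


def is_transition(x: str, y: str) -> bool:
    return (x in PURINES and y in PURINES) or (x in PYRIMIDINES and y in PYRIMIDINES)


def _make_aligner(mode: str, scores: tuple[float, float, float, float]) -> Align.PairwiseAligner:
    match, mismatch, gap_open, gap_extend = scores
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    # N vs anything is neutral (scores 0), so N columns never drive the
    # optimum and are excluded from the match/mismatch tallies below.
    matrix = substitution_matrices.Array(alphabet="ACGTN", dims=2)
    for x in "ACGT":
        for y in "ACGT":
            matrix[x, y] = match if x == y else mismatch
    for x in "ACGTN":
        matrix[x, "N"] = 0.0
        matrix["N", x] = 0.0
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def align_pair(
    a: str,
    b: str,
    mode: str = "global",
    scores: tuple[float, float, float, float] = DEFAULT_SCORES,
) -> PairwiseAlignment:
    """Optimal affine-gap pairwise alignment of two DNA sequences.

    ``mode`` is "global" (Needleman-Wunsch) or "local" (Smith-Waterman).
    A gap of length L costs ``open + (L-1) * extend``.  Identity is
    matches divided by the length of the shorter input (the CD-HIT
    convention), so a short sequence fully contained in a longer one has
    identity 1.
    """
    if not a or not b:
        raise ValueError("align_pair requires non-empty sequences")
    if mode not in ("global", "local"):
        raise ValueError(f"mode must be 'global' or 'local', got {mode!r}")
    a, b = a.upper(), b.upper()
    aligner = _make_aligner(mode, scores)
    alignment = aligner.align(a, b)[0]
    ga, gb = str(alignment[0]), str(alignment[1])
    matches = mismatches = transitions = transversions = gap_columns = 0
    for x, y in zip(ga, gb):
        if x == "-" or y == "-":
            gap_columns += 1
        elif x == "N" or y == "N":
            continue
        elif x == y:
            matches += 1
        else:
            mismatches += 1
            if is_transition(x, y):
                transitions += 1
            else:
                transversions += 1
    aligned_cols = sum(1 for x, y in zip(ga, gb) if x != "-" and y != "-")
    shorter = min(len(a), len(b))
    return PairwiseAlignment(
        aligned_a=ga,
        aligned_b=gb,
        score=float(alignment.score),
        matches=matches,
        mismatches=mismatches,
        transitions=transitions,
        transversions=transversions,
        gap_columns=gap_columns,
        identity=matches / shorter,
        coverage_a=aligned_cols / len(a),
        coverage_b=aligned_cols / len(b),
    )


def k2p_distance(P: float, Q: float) -> float:
    """Kimura two-parameter distance from transition/transversion proportions.

    K = -1/2 ln((1 - 2P - Q) sqrt(1 - 2Q)), in substitutions per site.
    Raises :class:`SaturationError` outside the admissible region.
    """
    if P < 0 or Q < 0:
        raise ValueError("P and Q must be non-negative")
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(f"saturated: P={P}, Q={Q}")
    return -0.5 * math.log(w1 * math.sqrt(w2))


def k2p_from_alignment(aln: PairwiseAlignment) -> float:
    """K2P distance over the ungapped, non-N columns of an alignment."""
    n = aln.matches + aln.mismatches
    if n == 0:
        raise ValueError("alignment has no comparable columns")
    return k2p_distance(aln.transitions / n, aln.transversions / n)


def k2p_between(a: str, b: str, mode: str = "global") -> float:
    """Align two sequences and return their K2P distance."""
    return k2p_from_alignment(align_pair(a, b, mode=mode))


def k2p_proportions(target_k: float, kappa: float) -> tuple[float, float]:
    """Expected (P, Q) after evolving a site to K2P distance ``target_k``.

    ``kappa`` is the transition/transversion rate ratio alpha/beta of the
    Kimura model (total transversion rate 2*beta).  Inverts the model's
    transition probabilities, so ``k2p_distance(P, Q) == target_k``
    exactly in expectation.
    """
    if target_k < 0:
        raise ValueError("target_k must be >= 0")
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    # alpha*t + 2*beta*t = K; alpha/beta = kappa
    bt = target_k / (kappa + 2.0)
    at = kappa * bt
    P = 0.25 + 0.25 * math.exp(-4.0 * bt) - 0.5 * math.exp(-2.0 * (at + bt))
    Q = 0.5 - 0.5 * math.exp(-4.0 * bt)
    if 1.0 - 2.0 * P - Q <= 0:
        raise SaturationError(f"saturation at target_k={target_k}")
    return P, Q


# ---------------------------------------------------------------------------
# Greedy centroid clustering


@dataclass
class Cluster:
    """A greedy identity cluster represented by its longest member."""

    centroid_id: str
    centroid_seq: str
    members: list[str] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.members)


def greedy_cluster(
    fragments: Sequence[tuple[str, str]],
    identity_threshold: float = 0.70,
    min_length: int = 1000,
) -> list[Cluster]:
    """Greedy incremental clustering of (id, sequence) fragments.

    Fragments longer than ``min_length`` are sorted by length descending
    (ties by id); each joins the first existing cluster whose centroid it
    matches at identity strictly above ``identity_threshold`` (local
    alignment, matches / shorter length), otherwise it founds a new
    cluster.  The centroid is always the longest member, because longer
    fragments are seen first.
    """
    kept = [(fid, seq) for fid, seq in fragments if len(seq) > min_length]
    kept.sort(key=lambda item: (-len(item[1]), item[0]))
    clusters: list[Cluster] = []
    for fid, seq in kept:
        placed = False
        for cluster in clusters:
            aln = align_pair(seq, cluster.centroid_seq, mode="local")
            if aln.identity > identity_threshold:
                cluster.members.append(fid)
                placed = True
                break
        if not placed:
            clusters.append(Cluster(centroid_id=fid, centroid_seq=seq, members=[fid]))
    return clusters


def coverage_filter(
    centroids: Sequence[tuple[str, str, str]],
    thresholds: Mapping[str, float] | None = None,
) -> list[tuple[str, str, str]]:
    """Filter centroids by alignment coverage against a star reference.

    ``centroids`` are (centroid_id, superfamily, sequence) triples.  Per
    superfamily, every centroid is globally aligned to the longest
    centroid (the star reference); coverage is the fraction of the
    reference's columns that the centroid occupies with aligned
    (non-gap-pair) residues, so short or poorly alignable centroids score
    low.  A centroid is retained when its coverage is strictly higher
    than the superfamily's threshold.  Idempotent: the reference survives
    (coverage 1.0) so re-filtering changes nothing.
    """
    thresholds = dict(DEFAULT_COVERAGE_THRESHOLDS if thresholds is None else thresholds)
    by_sf: dict[str, list[tuple[str, str, str]]] = {}
    for item in centroids:
        by_sf.setdefault(item[1], []).append(item)
    kept: list[tuple[str, str, str]] = []
    for sf, items in by_sf.items():
        threshold = thresholds.get(sf, FALLBACK_COVERAGE_THRESHOLD)
        reference = max(items, key=lambda item: (len(item[2]), item[0]))[2]
        for item in items:
            if item[2] == reference:
                coverage = 1.0
            else:
                coverage = align_pair(item[2], reference, mode="global").coverage_b
            if coverage > threshold:
                kept.append(item)
    kept.sort(key=lambda item: (item[1], item[0]))
    return kept


# ---------------------------------------------------------------------------
# Star alignment, neighbor joining, bootstrap


def star_alignment(sequences: Mapping[str, str], reference_id: str) -> tuple[list[str], np.ndarray]:
    """Project every sequence onto the reference's coordinates.

    Each sequence is globally aligned to the reference; reference columns
    keep the aligned character (or '-') from each sequence.  Returns the
    label list (reference first) and a (n, len(reference)) character
    matrix.  A light-weight stand-in for a full MSA that supports column
    resampling.
    """
    reference = sequences[reference_id]
    labels = [reference_id] + sorted(k for k in sequences if k != reference_id)
    matrix = np.full((len(labels), len(reference)), "-", dtype="<U1")
    matrix[0] = list(reference)
    for i, label in enumerate(labels[1:], start=1):
        aln = align_pair(sequences[label], reference, mode="global")
        col = 0
        for x, y in zip(aln.aligned_a, aln.aligned_b):
            if y != "-":
                matrix[i, col] = x
                col += 1
    return labels, matrix


def _k2p_matrix_from_columns(labels: Sequence[str], matrix: np.ndarray) -> DistanceMatrix:
    n = len(labels)
    dists = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        a, b = matrix[i], matrix[j]
        ok = (a != "-") & (b != "-") & (a != "N") & (b != "N")
        total = int(ok.sum())
        if total == 0:
            d = 0.0
        else:
            ts = tv = 0
            for x, y in zip(a[ok], b[ok]):
                if x != y:
                    if is_transition(x, y):
                        ts += 1
                    else:
                        tv += 1
            try:
                d = k2p_distance(ts / total, tv / total)
            except SaturationError:
                d = 5.0  # saturation cap
        dists[i, j] = dists[j, i] = d
    return DistanceMatrix(dists, ids=list(labels))


def bipartitions(tree: skbio.TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an (un)rooted tree, each encoded as the
    leaf set on one side, canonicalized to the side not containing the
    lexicographically smallest taxon."""
    taxa = frozenset(leaf.name for leaf in tree.tips())
    anchor = min(taxa)
    splits: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        clade = frozenset(leaf.name for leaf in node.tips())
        side = taxa - clade if anchor in clade else clade
        if 1 < len(side) < len(taxa) - 1:
            splits.add(side)
    return splits


def nj_tree(
    matrix: DistanceMatrix,
    alignment: tuple[Sequence[str], np.ndarray] | None = None,
    bootstrap_replicates: int = 100,
    seed: int | None = None,
) -> skbio.TreeNode:
    """Neighbor-joining tree from a K2P distance matrix.

    When ``alignment`` (labels, column matrix from :func:`star_alignment`)
    is given, bootstrap support is computed by resampling alignment
    columns with replacement ``bootstrap_replicates`` times, rebuilding
    the K2P matrix and NJ tree, and scoring each internal bipartition by
    the percentage of replicates that contain it (stored in
    ``node.support``, 0-100).
    """
    if matrix.shape[0] < 3:
        raise ValueError("neighbor joining needs at least 3 labels")
    tree = _skbio_nj(matrix)
    if alignment is not None and bootstrap_replicates > 0:
        labels, columns = alignment
        rng = np.random.default_rng(seed)
        counts: dict[frozenset[str], int] = {}
        n_cols = columns.shape[1]
        for _ in range(bootstrap_replicates):
            idx = rng.integers(0, n_cols, size=n_cols)
            rep_matrix = _k2p_matrix_from_columns(labels, columns[:, idx])
            for split in bipartitions(_skbio_nj(rep_matrix)):
                counts[split] = counts.get(split, 0) + 1
        taxa = frozenset(leaf.name for leaf in tree.tips())
        anchor = min(taxa)
        for node in tree.non_tips(include_self=False):
            clade = frozenset(leaf.name for leaf in node.tips())
            side = taxa - clade if anchor in clade else clade
            if 1 < len(side) < len(taxa) - 1:
                node.support = round(100.0 * counts.get(side, 0) / bootstrap_replicates)
    return tree


# ---------------------------------------------------------------------------
# Nei-Gojobori (1986) Ka/Ks

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_STOPS = frozenset(_STANDARD.stop_codons)


def _translate(codon: str) -> str:
    return "*" if codon in _STOPS else _STANDARD.forward_table[codon]


def _synonymous_sites(codon: str) -> float:
    """Fraction-weighted number of synonymous sites in a codon (0..3)."""
    if codon in _STOPS:
        return 0.0
    aa = _translate(codon)
    total = 0.0
    for pos in range(3):
        syn = 0
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            mutant = codon[:pos] + nt + codon[pos + 1 :]
            if mutant not in _STOPS and _translate(mutant) == aa:
                syn += 1
        total += syn / 3.0
    return total


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous substitution counts between two codons,
    averaged over all mutational pathways (orders of the differing sites)."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    sd_total = nd_total = 0.0
    n_paths = 0
    for order in itertools.permutations(diff):
        current = c1
        sd = nd = 0.0
        for pos in order:
            nxt = current[:pos] + c2[pos] + current[pos + 1 :]
            if current in _STOPS or nxt in _STOPS:
                # steps through a stop codon are counted nonsynonymous
                nd += 1
            elif _translate(current) == _translate(nxt):
                sd += 1
            else:
                nd += 1
            current = nxt
        sd_total += sd
        nd_total += nd
        n_paths += 1
    return sd_total / n_paths, nd_total / n_paths


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        raise SaturationError(f"proportion {p} >= 3/4, Jukes-Cantor correction undefined")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def kaks_ng86(seq_a: str, seq_b: str) -> tuple[float, float, float | None]:
    """Nei-Gojobori (1986) Ka, Ks and their ratio for a gapless codon pair.

    Site counts are averaged over both sequences; substitution counts are
    averaged over all shortest mutational pathways per codon; pS and pN
    receive the Jukes-Cantor multiple-hit correction.  Returns
    ``(ka, ks, ratio)`` with ``ratio None`` when Ks = 0.  Symmetric in
    its arguments.
    """
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal length")
    if len(seq_a) % 3 != 0:
        raise ValueError("sequence length must be divisible by 3")
    codons_a = [seq_a[i : i + 3] for i in range(0, len(seq_a), 3)]
    codons_b = [seq_b[i : i + 3] for i in range(0, len(seq_b), 3)]
    for name, codons in (("first", codons_a[:-1]), ("second", codons_b[:-1])):
        if any(c in _STOPS for c in codons):
            raise ValueError(f"internal stop codon in {name} sequence")
    s_sites = 0.5 * (
        sum(_synonymous_sites(c) for c in codons_a) + sum(_synonymous_sites(c) for c in codons_b)
    )
    n_sites = 3.0 * len(codons_a) - s_sites
    sd = nd = 0.0
    for c1, c2 in zip(codons_a, codons_b):
        s, n = _pathway_counts(c1, c2)
        sd += s
        nd += n
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ks = _jukes_cantor(ps) + 0.0  # normalize -0.0
    ka = _jukes_cantor(pn) + 0.0
    ratio = ka / ks if ks > 0 else None
    return ka, ks, ratio
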