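"""TE-gene overlap anatomy.

Merges redundant TE fragments into a non-redundant interval set, splits
genes into exons / introns / 500 bp flanks, and summarizes how many
merged TE regions fall in each region and how many bases they cover.
All coordinates are 0-based half-open; overlap is strand-insensitive
(strand only decides which flank is upstream).
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_formats import GeneModel, RMFragment


@dataclass(frozen=True)
class IntervalSet:
    """Per-sequence sorted, disjoint intervals (touching intervals merged)."""

    intervals: Mapping[str, tuple[tuple[int, int], ...]]

    def total_length(self) -> int:
        return sum(e - s for ivs in self.intervals.values() for s, e in ivs)

    def count(self) -> int:
        return sum(len(ivs) for ivs in self.intervals.values())

    def on(self, seq_id: str) -> tuple[tuple[int, int], ...]:
        return self.intervals.get(seq_id, ())


def reduce_intervals(intervals: Iterable[tuple[str, int, int]]) -> IntervalSet:
    """Minimal disjoint cover of the union of the input intervals.

    Overlapping and abutting intervals are merged (GenomicRanges
    ``reduce`` semantics).  ``start >= end`` is an error.
    """
    by_seq: dict[str, list[tuple[int, int]]] = {}
    for seq_id, start, end in intervals:
        if start >= end:
            raise ValueError(f"invalid interval ({seq_id}, {start}, {end})")
        by_seq.setdefault(seq_id, []).append((start, end))
    merged: dict[str, tuple[tuple[int, int], ...]] = {}
    for seq_id, ivs in by_seq.items():
        ivs.sort()
        out: list[tuple[int, int]] = []
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:  # overlap or touch
                cur_e = max(cur_e, e)
            else:
                out.append((cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((cur_s, cur_e))
        merged[seq_id] = tuple(out)
    return IntervalSet(intervals=merged)


def reduce_fragments(fragments: Iterable[RMFragment]) -> IntervalSet:
    return reduce_intervals((f.seq_id, f.start, f.end) for f in fragments)


@dataclass(frozen=True)
class GeneSubregions:
    """A gene decomposed into the regions the overlap analysis reports on.

    Exons and introns partition the gene body exactly; the flanks are
    ``flank`` bp outside the gene boundaries (strand-aware: upstream of a
    minus-strand gene lies at higher coordinates), clipped to the
    sequence so they may be shorter at contig edges.
    """

    gene_id: str
    seq_id: str
    strand: str
    whole: tuple[int, int]
    exons: tuple[tuple[int, int], ...]
    introns: tuple[tuple[int, int], ...]
    upstream: tuple[int, int] | None
    downstream: tuple[int, int] | None


def build_subregions(gene: GeneModel, seq_length: int, flank: int = 500) -> GeneSubregions:
    left = (max(0, gene.start - flank), gene.start) if gene.start > 0 else None
    right = (gene.end, min(seq_length, gene.end + flank)) if gene.end < seq_length else None
    if gene.strand == "-":
        upstream, downstream = right, left
    else:
        upstream, downstream = left, right
    return GeneSubregions(
        gene_id=gene.gene_id,
        seq_id=gene.seq_id,
        strand=gene.strand,
        whole=(gene.start, gene.end),
        exons=gene.exons,
        introns=gene.introns,
        upstream=upstream,
        downstream=downstream,
    )


def _overlap_with(te_ivs: Sequence[tuple[int, int]], region: tuple[int, int]) -> tuple[int, int]:
    """(number of TE intervals intersecting region, intersected bases)."""
    rs, re = region
    if not te_ivs or rs >= re:
        return 0, 0
    starts = [s for s, _ in te_ivs]
    # first interval that could overlap: the one before the insertion point
    i = max(0, bisect_right(starts, rs) - 1)
    n = bp = 0
    for s, e in te_ivs[i:]:
        if s >= re:
            break
        ov = min(e, re) - max(s, rs)
        if ov > 0:
            n += 1
            bp += ov
    return n, bp


def _multi_overlap(te_ivs: Sequence[tuple[int, int]], regions: Sequence[tuple[int, int]]) -> tuple[int, int]:
    """Overlap against a disjoint multi-part region (e.g. all exons): a TE
    interval touching several parts counts once; bases add up."""
    seen = 0
    bp = 0
    touched: set[int] = set()
    for region in regions:
        rs, re = region
        starts = [s for s, _ in te_ivs]
        i = max(0, bisect_right(starts, rs) - 1)
        for j in range(i, len(te_ivs)):
            s, e = te_ivs[j]
            if s >= re:
                break
            ov = min(e, re) - max(s, rs)
            if ov > 0:
                touched.add(j)
                bp += ov
    seen = len(touched)
    return seen, bp


@dataclass
class GeneOverlap:
    """Per-gene overlap statistics for one TE superfamily."""

    gene_id: str
    superfamily: str
    gene_length: int
    n_te_regions: int = 0
    overlap_bp: int = 0
    subregions: dict[str, tuple[int, int, int]] = field(default_factory=dict)
    # subregions maps name -> (n_te_regions, overlap_bp, region_length)

    @property
    def gene_fraction(self) -> float:
        return self.overlap_bp / self.gene_length if self.gene_length else 0.0


def overlap_summary(
    te_set: IntervalSet,
    regions: Sequence[GeneSubregions],
    superfamily: str = "all",
) -> list[GeneOverlap]:
    """Intersect a merged TE interval set with genes and their subregions.

    A merged TE region overlapping several genes increments each gene's
    count (gene-centric accounting).  For multi-part subregions (exons,
    introns) an interval touching several parts counts once.
    """
    out: list[GeneOverlap] = []
    for sub in regions:
        te_ivs = te_set.on(sub.seq_id)
        n, bp = _overlap_with(te_ivs, sub.whole)
        rec = GeneOverlap(
            gene_id=sub.gene_id,
            superfamily=superfamily,
            gene_length=sub.whole[1] - sub.whole[0],
            n_te_regions=n,
            overlap_bp=bp,
        )
        for name, parts in (
            ("exons", sub.exons),
            ("introns", sub.introns),
            ("upstream", (sub.upstream,) if sub.upstream else ()),
            ("downstream", (sub.downstream,) if sub.downstream else ()),
        ):
            parts = tuple(p for p in parts if p is not None)
            pn, pbp = _multi_overlap(te_ivs, parts)
            rec.subregions[name] = (pn, pbp, sum(e - s for s, e in parts))
        out.append(rec)
    return out


def fragment_count_distribution(summaries: Sequence[GeneOverlap]) -> dict[int, int]:
    """Histogram of genes by their number of overlapping merged TE regions.

    Genes with zero regions appear under key 0.
    """
    hist: dict[int, int] = {}
    for rec in summaries:
        hist[rec.n_te_regions] = hist.get(rec.n_te_regions, 0) + 1
    return hist
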