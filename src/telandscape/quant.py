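"""TE content census and comparative statistics.

Per-species, per-superfamily base-pair totals and genome fractions,
cross-species log2 fold-change of TE content, core/unique superfamily
partitioning (UpSet-style intersection cells), and bp-weighted Kimura
divergence landscapes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import RMFragment
from .overlap import reduce_intervals


@dataclass(frozen=True)
class SuperfamilyCensus:
    species_id: str
    superfamily: str
    te_order: str
    total_bp: int
    fragment_count: int
    genome_fraction: float


def census(
    fragments: Sequence[RMFragment],
    assembly_size: int,
    level: str = "superfamily",
    merge: bool = False,
    include_non_te: bool = False,
) -> list[SuperfamilyCensus]:
    """Total bp and fragment count per TE class for one species.

    ``merge=False`` (default) adds raw fragment lengths, so overlapping
    annotations are double-counted; ``merge=True`` measures the disjoint
    union per class.  ``level`` groups by superfamily or by order.
    Simple repeats / low-complexity / satellite records (te_order
    "Other") are excluded unless ``include_non_te``.
    """
    if assembly_size <= 0:
        raise ValueError("assembly_size must be positive")
    if level not in ("superfamily", "order"):
        raise ValueError(f"level must be 'superfamily' or 'order', got {level!r}")
    groups: dict[tuple[str, str], list[RMFragment]] = {}
    for frag in fragments:
        if frag.te_order == "Other" and not include_non_te:
            continue
        key = (
            (frag.superfamily or "Unknown", frag.te_order)
            if level == "superfamily"
            else (frag.te_order, frag.te_order)
        )
        groups.setdefault(key, []).append(frag)
    out: list[SuperfamilyCensus] = []
    for (name, order), frags in sorted(groups.items()):
        if merge:
            total = reduce_intervals(
                (f.seq_id, f.start, f.end) for f in frags
            ).total_length()
        else:
            total = sum(f.length for f in frags)
        out.append(
            SuperfamilyCensus(
                species_id=frags[0].species_id,
                superfamily=name,
                te_order=order,
                total_bp=total,
                fragment_count=len(frags),
                genome_fraction=total / assembly_size,
            )
        )
    return out


def census_table(censuses: Iterable[SuperfamilyCensus]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (c.species_id, c.superfamily, c.te_order, c.total_bp, c.fragment_count, c.genome_fraction)
            for c in censuses
        ],
        columns=["species_id", "superfamily", "te_order", "total_bp", "fragment_count", "genome_fraction"],
    )


def logfc_bp(census_ref: SuperfamilyCensus, census_other: SuperfamilyCensus) -> float:
    """log2(reference bp / other bp) for one superfamily.

    Positive values mean the superfamily is amplified in the reference
    species.  Returns NaN when the superfamily is absent (0 bp) in the
    other species.
    """
    if census_ref.superfamily != census_other.superfamily:
        raise ValueError(
            f"superfamily mismatch: {census_ref.superfamily} vs {census_other.superfamily}"
        )
    if census_other.total_bp == 0:
        return math.nan
    # difference of logs, so swapping the roles negates the value exactly
    return math.log2(census_ref.total_bp) - math.log2(census_other.total_bp)


def logfc_table(
    censuses_by_species: Mapping[str, Sequence[SuperfamilyCensus]],
    reference_species: str,
) -> pd.DataFrame:
    """Fold-change of every superfamily in the reference vs each other species."""
    ref = {c.superfamily: c for c in censuses_by_species[reference_species]}
    rows = []
    for species, censuses in censuses_by_species.items():
        if species == reference_species:
            continue
        for c in censuses:
            if c.superfamily in ref:
                rows.append((c.superfamily, species, logfc_bp(ref[c.superfamily], c)))
    return pd.DataFrame(rows, columns=["superfamily", "other_species", "logfc"])


@dataclass(frozen=True)
class CoreSetPartition:
    """UpSet-style partition of superfamilies by the species owning them."""

    species: tuple[str, ...]
    cells: Mapping[frozenset[str], frozenset[str]]  # species subset -> superfamilies

    @property
    def core(self) -> frozenset[str]:
        return self.cells.get(frozenset(self.species), frozenset())

    def unique_to(self, species_id: str) -> frozenset[str]:
        return self.cells.get(frozenset({species_id}), frozenset())

    def cell_counts(self) -> dict[frozenset[str], int]:
        return {subset: len(sfs) for subset, sfs in self.cells.items()}


def core_partition(
    censuses_by_species: Mapping[str, Sequence[SuperfamilyCensus]],
    presence_threshold: int = 1,
    min_bp: int = 0,
) -> CoreSetPartition:
    """Partition observed superfamilies into species-subset cells.

    A superfamily is present in a species when its fragment count is at
    least ``presence_threshold`` and its total bp at least ``min_bp``.
    Every superfamily lands in exactly the cell of the species subset
    where it is present; empty cells are omitted.  The core set is the
    all-species cell.
    """
    species = tuple(censuses_by_species)
    if len(species) < 2:
        raise ValueError("core_partition needs at least 2 species")
    present_in: dict[str, set[str]] = {}
    for sp, censuses in censuses_by_species.items():
        for c in censuses:
            if c.fragment_count >= presence_threshold and c.total_bp >= min_bp:
                present_in.setdefault(c.superfamily, set()).add(sp)
    cells: dict[frozenset[str], set[str]] = {}
    for sf, owners in present_in.items():
        cells.setdefault(frozenset(owners), set()).add(sf)
    return CoreSetPartition(
        species=species,
        cells={k: frozenset(v) for k, v in cells.items()},
    )


@dataclass(frozen=True)
class DivergenceHistogram:
    """bp- (or copy-) weighted histogram of Kimura distances.

    Bins are percent-divergence intervals [0,1), [1,2), ..., [49,50);
    mass at or above ``max_bin`` goes to an overflow bin whose lower
    edge is ``max_bin``.  ``no_divergence`` tallies the bp of fragments
    lacking a divergence value.
    """

    species_id: str
    superfamily: str
    bin_edges: tuple[float, ...]
    mass: tuple[float, ...]
    overflow: float
    no_divergence: float

    def mode_bin(self) -> int:
        """Lower edge of the heaviest bin (ignores the overflow bin)."""
        return int(np.argmax(self.mass))

    def total_mass(self) -> float:
        return float(sum(self.mass) + self.overflow)


def divergence_landscape(
    fragments: Sequence[RMFragment],
    bin_width: float = 1.0,
    max_bin: float = 50.0,
    weight: str = "bp",
) -> DivergenceHistogram:
    """Repeat landscape: fragment mass binned by percent Kimura divergence.

    Each fragment contributes its length (``weight="bp"``, the
    RepeatMasker-landscape convention) or one count (``weight="copies"``)
    to the bin containing its divergence.
    """
    if weight not in ("bp", "copies"):
        raise ValueError(f"weight must be 'bp' or 'copies', got {weight!r}")
    n_bins = int(round(max_bin / bin_width))
    edges = tuple(i * bin_width for i in range(n_bins + 1))
    mass = np.zeros(n_bins)
    overflow = 0.0
    no_div = 0.0
    species = fragments[0].species_id if fragments else ""
    superfamilies = {f.superfamily for f in fragments}
    for frag in fragments:
        w = frag.length if weight == "bp" else 1
        if frag.divergence_pct is None:
            no_div += w
            continue
        idx = int(frag.divergence_pct // bin_width)
        if idx >= n_bins:
            overflow += w
        else:
            mass[idx] += w
    return DivergenceHistogram(
        species_id=species,
        superfamily=superfamilies.pop() if len(superfamilies) == 1 else "multiple",
        bin_edges=edges,
        mass=tuple(mass),
        overflow=overflow,
        no_divergence=no_div,
    )


def landscape_table(histograms: Iterable[DivergenceHistogram]) -> pd.DataFrame:
    rows = []
    for h in histograms:
        for lo, m in zip(h.bin_edges[:-1], h.mass):
            rows.append((h.species_id, h.superfamily, lo, lo + (h.bin_edges[1] - h.bin_edges[0]), m))
        rows.append((h.species_id, h.superfamily, h.bin_edges[-1], math.inf, h.overflow))
    return pd.DataFrame(rows, columns=["species", "superfamily", "bin_lo", "bin_hi", "mass"])
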