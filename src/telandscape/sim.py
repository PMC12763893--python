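"""Synthetic multi-species genome generator with exhaustive ground truth.

Emulates what the comparative TE pipeline consumes: per species, a
genome FASTA, a gene annotation (GFF3) and a RepeatMasker-style ``.out``
repeat table, where TE copies descend from per-superfamily consensus
sequences through a Kimura two-parameter substitution process with a
controlled target distance ("burst age"), a configurable fraction of
copies lands inside gene introns, and tandem arrays are embedded inside
chosen TE copies.

The genome is a fixed-length i.i.d. uniform ACGT background; genes are
placed first, then TE copies paint over free intronic or intergenic
space (no coordinate shifting, no nested insertions, no indels), so the
ground truth tiles the emitted sequence exactly and every downstream
census can be checked against it to the base pair.

The divergence column of the emitted ``.out`` carries the realized
Kimura-corrected percent divergence of each copy against its consensus
(the quantity the divergence landscapes bin), not the raw mismatch
percentage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_formats import (
    ClassificationTable,
    GeneModel,
    RMFragment,
    write_fasta,
    write_gff3,
    write_repeatmasker_out,
)
from .seqcompare import SaturationError, is_transition, k2p_distance, k2p_proportions

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Superfamily:
    name: str
    te_order: str
    consensus_length: int


@dataclass(frozen=True)
class Burst:
    """One amplification event: n copies of a superfamily at a target age."""

    species_id: str
    superfamily: str
    n_copies: int
    target_k: float
    kappa: float = 2.0


@dataclass(frozen=True)
class TandemPlant:
    """Embed tandem arrays (motif of ``period`` bp repeated ``copies``
    times, with optional per-base substitution noise) inside ``n_regions``
    TE copies of a superfamily."""

    superfamily: str
    period: int
    copies: int
    n_regions: int
    noise: float = 0.0


@dataclass
class SimConfig:
    seed: int = 0
    n_species: int = 2
    genome_length: int = 1_000_000
    superfamilies: Sequence[Superfamily] = field(
        default_factory=lambda: (
            Superfamily("L2", "LINE", 2000),
            Superfamily("Rex-Babar", "LINE", 1500),
            Superfamily("TcMar-Tc1", "DNA", 1300),
        )
    )
    bursts: Sequence[Burst] = field(default_factory=tuple)
    n_genes: int = 20
    exons_per_gene: tuple[int, int] = (2, 6)
    exon_length: tuple[int, int] = (100, 300)
    intron_length: tuple[int, int] = (500, 1500)
    tandem_plants: Sequence[TandemPlant] = field(default_factory=tuple)
    fraction_te_in_genes: float = 0.3
    fraction_fragmented: float = 0.0

    def __post_init__(self) -> None:
        if self.genome_length <= 0 or self.n_species <= 0:
            raise ValueError("genome_length and n_species must be positive")
        if not 0.0 <= self.fraction_te_in_genes <= 1.0:
            raise ValueError("fraction_te_in_genes must be in [0,1]")
        if not 0.0 <= self.fraction_fragmented <= 1.0:
            raise ValueError("fraction_fragmented must be in [0,1]")
        for burst in self.bursts:
            if burst.target_k < 0 or burst.kappa <= 0:
                raise ValueError("burst target_k must be >= 0 and kappa > 0")

    @property
    def species_ids(self) -> tuple[str, ...]:
        return tuple(f"sp{i + 1}" for i in range(self.n_species))

    def classification(self) -> ClassificationTable:
        return ClassificationTable({sf.name: sf.te_order for sf in self.superfamilies})


@dataclass(frozen=True)
class TruthFragment:
    fragment_id: str
    species_id: str
    seq_id: str
    start: int
    end: int
    strand: str
    superfamily: str
    te_order: str
    target_k: float
    realized_divergence_pct: float
    realized_mismatch_pct: float
    in_gene: bool


@dataclass(frozen=True)
class TruthTandem:
    species_id: str
    seq_id: str
    start: int
    end: int
    period: int
    copies: int
    motif: str
    host_fragment_id: str


@dataclass
class SimTruth:
    fragments: list[TruthFragment] = field(default_factory=list)
    genes: dict[str, list[GeneModel]] = field(default_factory=dict)
    tandems: list[TruthTandem] = field(default_factory=list)

    def bp_by_superfamily(self, species_id: str) -> dict[str, int]:
        totals: dict[str, int] = {}
        for frag in self.fragments:
            if frag.species_id == species_id:
                totals[frag.superfamily] = totals.get(frag.superfamily, 0) + (frag.end - frag.start)
        return totals

    def count_by_superfamily(self, species_id: str) -> dict[str, int]:
        counts: dict[str, int] = {}
        for frag in self.fragments:
            if frag.species_id == species_id:
                counts[frag.superfamily] = counts.get(frag.superfamily, 0) + 1
        return counts


@dataclass
class SimResult:
    config: SimConfig
    sequences: dict[str, dict[str, str]]  # species -> {seq_id: sequence}
    fragments: dict[str, list[RMFragment]]  # species -> emitted .out records
    genes: dict[str, list[GeneModel]]
    truth: SimTruth
    consensus: dict[str, str]  # superfamily -> consensus sequence

    def write(self, outdir: str | Path) -> dict[str, dict[str, Path]]:
        """Emit genome.fa / genes.gff3 / repeats.out per species plus
        truth.json and the classification table; byte-identical for an
        identical config."""
        outdir = Path(outdir)
        paths: dict[str, dict[str, Path]] = {}
        for sp in self.config.species_ids:
            spdir = outdir / sp
            spdir.mkdir(parents=True, exist_ok=True)
            fasta = spdir / "genome.fa"
            gff = spdir / "genes.gff3"
            rm_out = spdir / "repeats.out"
            write_fasta(self.sequences[sp], fasta)
            write_gff3(self.genes[sp], gff)
            write_repeatmasker_out(self.fragments[sp], rm_out)
            paths[sp] = {"fasta": fasta, "gff3": gff, "out": rm_out}
        truth_doc = {
            "fragments": [asdict(f) for f in self.truth.fragments],
            "genes": {
                sp: [
                    {
                        "gene_id": g.gene_id,
                        "seq_id": g.seq_id,
                        "start": g.start,
                        "end": g.end,
                        "strand": g.strand,
                        "exons": list(map(list, g.exons)),
                    }
                    for g in genes
                ]
                for sp, genes in self.truth.genes.items()
            },
            "tandems": [asdict(t) for t in self.truth.tandems],
        }
        (outdir / "truth.json").write_text(json.dumps(truth_doc, indent=1))
        self.config.classification().to_tsv(outdir / "classification.tsv")
        return paths


def mutate_copy(consensus: str, target_k: float, kappa: float, seed: int) -> str:
    """Diverge a consensus by a K2P process to expected distance ``target_k``.

    Per site, a transition happens with the model's expected transition
    proportion P and a transversion (either of the two, equiprobable)
    with proportion Q, where ``k2p_distance(P, Q) == target_k``.  Same
    length as the consensus; no indels.
    """
    if not consensus:
        raise ValueError("consensus must be non-empty")
    P, Q = k2p_proportions(target_k, kappa)  # raises SaturationError when too large
    rng = np.random.default_rng(seed)
    transitions = {"A": "G", "G": "A", "C": "T", "T": "C"}
    transversions = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}
    u = rng.random(len(consensus))
    pick = rng.integers(0, 2, size=len(consensus))
    out = []
    for i, base in enumerate(consensus):
        if u[i] < P:
            out.append(transitions[base])
        elif u[i] < P + Q:
            out.append(transversions[base][pick[i]])
        else:
            out.append(base)
    return "".join(out)


def observed_divergence(copy: str, consensus: str) -> tuple[float, float]:
    """(Kimura-corrected percent divergence, raw mismatch percent) of a
    same-length copy against its consensus."""
    n = len(consensus)
    ts = tv = 0
    for x, y in zip(copy, consensus):
        if x != y:
            if is_transition(x, y):
                ts += 1
            else:
                tv += 1
    mismatch_pct = 100.0 * (ts + tv) / n
    try:
        k = k2p_distance(ts / n, tv / n)
    except SaturationError:
        k = 0.5  # cap; only reachable at extreme ages
    return 100.0 * k, mismatch_pct


class _FreeSpace:
    """Disjoint free segments supporting uniform placement of a block."""

    def __init__(self, segments: Sequence[tuple[int, int]]):
        self.segments: list[tuple[int, int]] = [tuple(s) for s in segments if s[1] > s[0]]

    def capacity(self, length: int) -> int:
        return sum(max(0, e - s - length + 1) for s, e in self.segments)

    def place(self, length: int, rng: np.random.Generator) -> tuple[int, int] | None:
        """Pick a start uniformly over all admissible positions; split the
        chosen segment.  Returns (start, end) or None when nothing fits."""
        weights = [max(0, e - s - length + 1) for s, e in self.segments]
        total = sum(weights)
        if total == 0:
            return None
        r = int(rng.integers(0, total))
        for idx, w in enumerate(weights):
            if r < w:
                s, e = self.segments[idx]
                start = s + r
                end = start + length
                self.segments[idx : idx + 1] = [
                    seg for seg in ((s, start), (end, e)) if seg[1] > seg[0]
                ]
                return start, end
            r -= w
        return None  # pragma: no cover

    def remove_all(self, start: int, end: int) -> None:
        out = []
        for s, e in self.segments:
            if e <= start or s >= end:
                out.append((s, e))
            else:
                if s < start:
                    out.append((s, start))
                if e > end:
                    out.append((end, e))
        self.segments = out


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def _place_genes(config: SimConfig, species: str, rng: np.random.Generator) -> list[GeneModel]:
    free = _FreeSpace([(0, config.genome_length)])
    genes: list[GeneModel] = []
    for i in range(config.n_genes):
        n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        exon_lens = rng.integers(config.exon_length[0], config.exon_length[1] + 1, size=n_exons)
        intron_lens = rng.integers(
            config.intron_length[0], config.intron_length[1] + 1, size=max(0, n_exons - 1)
        )
        gene_len = int(exon_lens.sum() + intron_lens.sum())
        placed = free.place(gene_len + 1000, rng)  # 500 bp buffer each side
        if placed is None:
            raise ValueError(
                f"gene placement exceeds genome capacity for {species} "
                f"(gene {i + 1} of {config.n_genes})"
            )
        start = placed[0] + 500
        exons = []
        pos = start
        for j, el in enumerate(exon_lens):
            exons.append((pos, pos + int(el)))
            pos += int(el)
            if j < len(intron_lens):
                pos += int(intron_lens[j])
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneModel(
                gene_id=f"{species}_g{i + 1:04d}",
                seq_id=f"{species}_chr1",
                start=start,
                end=pos,
                strand=strand,
                exons=tuple(exons),
            )
        )
    genes.sort(key=lambda g: g.start)
    return genes


def simulate_genome(config: SimConfig, outdir: str | Path | None = None) -> SimResult:
    """Run the full simulation; optionally write all per-species files.

    Placement: genes first, then for every burst each TE copy goes into
    free intron space with probability ``fraction_te_in_genes`` (falling
    back to intergenic space when no intron fits) and free intergenic
    space otherwise, uniformly at random, never overlapping genes'
    exons or previously placed copies.  Raises before writing anything
    when the requested insertions exceed capacity.
    """
    master = np.random.default_rng(config.seed)
    consensus: dict[str, str] = {}
    sf_order: dict[str, str] = {}
    for sf in config.superfamilies:
        consensus[sf.name] = _random_sequence(master, sf.consensus_length)
        sf_order[sf.name] = sf.te_order

    sequences: dict[str, dict[str, str]] = {}
    fragments: dict[str, list[RMFragment]] = {}
    genes_by_sp: dict[str, list[GeneModel]] = {}
    truth = SimTruth()

    for sp in config.species_ids:
        rng = np.random.default_rng(master.integers(0, 2**31))
        seq_id = f"{sp}_chr1"
        background = np.array(list(_random_sequence(rng, config.genome_length)))
        genes = _place_genes(config, sp, rng)
        genes_by_sp[sp] = genes
        truth.genes[sp] = genes

        intron_free = _FreeSpace(
            [iv for g in genes for iv in g.introns]
        )
        gene_spans = [(g.start, g.end) for g in genes]
        intergenic = _FreeSpace([(0, config.genome_length)])
        for s, e in gene_spans:
            intergenic.remove_all(s, e)

        sp_fragments: list[tuple[TruthFragment, str]] = []
        counter = 0
        for burst in config.bursts:
            if burst.species_id != sp:
                continue
            cons = consensus[burst.superfamily]
            for _ in range(burst.n_copies):
                counter += 1
                copy = mutate_copy(
                    cons, burst.target_k, burst.kappa, seed=int(rng.integers(0, 2**31))
                )
                in_gene = rng.random() < config.fraction_te_in_genes
                placed = None
                if in_gene:
                    placed = intron_free.place(len(copy), rng)
                if placed is None:
                    in_gene = False
                    placed = intergenic.place(len(copy), rng)
                if placed is None:
                    raise ValueError(
                        f"TE insertions exceed genome capacity for {sp} "
                        f"(burst {burst.superfamily}, K={burst.target_k})"
                    )
                start, end = placed
                strand = "+" if rng.random() < 0.8 else "-"
                emitted = copy if strand == "+" else revcomp(copy)
                background[start:end] = list(emitted)
                div_pct, mismatch_pct = observed_divergence(copy, cons)
                frag = TruthFragment(
                    fragment_id=f"{sp}_te{counter:05d}",
                    species_id=sp,
                    seq_id=seq_id,
                    start=start,
                    end=end,
                    strand=strand,
                    superfamily=burst.superfamily,
                    te_order=sf_order[burst.superfamily],
                    target_k=burst.target_k,
                    realized_divergence_pct=div_pct,
                    realized_mismatch_pct=mismatch_pct,
                    in_gene=in_gene,
                )
                sp_fragments.append((frag, emitted))

        # Tandem arrays overwrite a window inside chosen TE copies,
        # preferring copies that landed in genes (so gene-overlap driven
        # tandem statistics see them).
        for plant in config.tandem_plants:
            hosts = [
                (i, f)
                for i, (f, _) in enumerate(sp_fragments)
                if f.superfamily == plant.superfamily
                and (f.end - f.start) >= plant.period * plant.copies
            ]
            hosts.sort(key=lambda item: (not item[1].in_gene, item[1].fragment_id))
            if len(hosts) < plant.n_regions:
                raise ValueError(
                    f"not enough {plant.superfamily} copies of length >= "
                    f"{plant.period * plant.copies} to host tandem arrays in {sp}"
                )
            motif = _random_sequence(rng, plant.period)
            for i, frag in hosts[: plant.n_regions]:
                array_len = plant.period * plant.copies
                offset = int(rng.integers(0, frag.end - frag.start - array_len + 1))
                array = (motif * plant.copies)
                if plant.noise > 0:
                    arr = np.array(list(array))
                    flip = rng.random(len(arr)) < plant.noise
                    alphabet = np.array(list("ACGT"))
                    repl = alphabet[rng.integers(0, 4, size=int(flip.sum()))]
                    arr[flip] = repl
                    array = "".join(arr)
                a_start = frag.start + offset
                background[a_start : a_start + array_len] = list(array)
                truth.tandems.append(
                    TruthTandem(
                        species_id=sp,
                        seq_id=seq_id,
                        start=a_start,
                        end=a_start + array_len,
                        period=plant.period,
                        copies=plant.copies,
                        motif=motif,
                        host_fragment_id=frag.fragment_id,
                    )
                )

        sequences[sp] = {seq_id: "".join(background)}
        truth.fragments.extend(f for f, _ in sp_fragments)

        # Emit .out records; the optional fragmenter splits a fraction of
        # copies into two abutting records to exercise interval merging.
        records: list[RMFragment] = []
        for frag, _ in sp_fragments:
            pieces: list[tuple[int, int, str]]
            if (
                config.fraction_fragmented > 0
                and frag.end - frag.start >= 200
                and rng.random() < config.fraction_fragmented
            ):
                cut = int(rng.integers(frag.start + 50, frag.end - 50))
                pieces = [
                    (frag.start, cut, f"{frag.fragment_id}a"),
                    (cut, frag.end, f"{frag.fragment_id}b"),
                ]
            else:
                pieces = [(frag.start, frag.end, frag.fragment_id)]
            for s, e, fid in pieces:
                records.append(
                    RMFragment(
                        species_id=sp,
                        seq_id=frag.seq_id,
                        start=s,
                        end=e,
                        strand=frag.strand,
                        family_name=f"{frag.superfamily}-1",
                        superfamily=frag.superfamily,
                        te_order=frag.te_order,
                        divergence_pct=round(frag.realized_divergence_pct, 2),
                        fragment_id=fid,
                    )
                )
        records.sort(key=lambda r: (r.seq_id, r.start))
        fragments[sp] = records

    result = SimResult(
        config=config,
        sequences=sequences,
        fragments=fragments,
        genes=genes_by_sp,
        truth=truth,
        consensus=consensus,
    )
    if outdir is not None:
        result.write(outdir)
    return result
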