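"""Readers and writers for the annotation formats the pipeline touches.

All coordinates are normalized at the I/O boundary to a single internal
convention: 0-based, half-open ``[start, end)``.  RepeatMasker ``.out``
tables and GFF3 are 1-based inclusive on disk and are converted on read
and write; nothing downstream ever sees 1-based coordinates.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Recognized TE orders.  Anything else maps to "Unknown".
TE_ORDERS = ("LINE", "SINE", "LTR", "DNA", "RC", "Other", "Unknown")

#: RepeatMasker classes that are repeats but not transposable elements.
#: They are retained on read with te_order="Other" and excluded from TE
#: analyses by default.
NON_TE_CLASSES = frozenset(
    {"simple_repeat", "low_complexity", "satellite", "rrna", "trna", "snrna", "scrna"}
)


@dataclass(frozen=True)
class RMFragment:
    """One annotated TE fragment on a genome sequence.

    ``divergence_pct`` is the percent mismatch to the family consensus as
    reported by the annotator (``None`` when the annotation carries no
    divergence column).
    """

    species_id: str
    seq_id: str
    start: int
    end: int
    strand: str
    family_name: str
    superfamily: str
    te_order: str
    divergence_pct: float | None = None
    fragment_id: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid fragment interval [{self.start}, {self.end}) for {self.fragment_id!r}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """A gene with its exon chain; introns are the gaps between exons."""

    gene_id: str
    seq_id: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        exons = tuple(sorted(tuple(e) for e in self.exons))
        object.__setattr__(self, "exons", exons)
        for s, e in exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(
                    f"exon ({s},{e}) outside gene {self.gene_id} span [{self.start},{self.end})"
                )
        for (_, e0), (s1, _) in zip(exons, exons[1:]):
            if s1 < e0 + 1:
                raise ValueError(f"overlapping/abutting exons in gene {self.gene_id}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (e0, s1) for (_, e0), (s1, _) in zip(self.exons, self.exons[1:])
        )


class ClassificationTable:
    """Total mapping superfamily -> TE order, case-normalized.

    Lookup keys are lower-cased but the original capitalization of the
    first-seen name is preserved for reporting (hyphens are significant:
    hAT-Charlie and hAT-Ac are distinct superfamilies).
    """

    def __init__(self, mapping: Mapping[str, str] | None = None) -> None:
        self._order: dict[str, str] = {}
        self._canonical: dict[str, str] = {}
        if mapping:
            for sf, order in mapping.items():
                self.add(sf, order)

    def add(self, superfamily: str, te_order: str) -> None:
        order = te_order if te_order in TE_ORDERS else "Unknown"
        key = superfamily.strip().lower()
        self._order[key] = order
        self._canonical.setdefault(key, superfamily.strip())

    def order_of(self, superfamily: str) -> str:
        return self._order.get(superfamily.strip().lower(), "Unknown")

    def canonical(self, superfamily: str) -> str:
        return self._canonical.get(superfamily.strip().lower(), superfamily.strip())

    def __contains__(self, superfamily: str) -> bool:
        return superfamily.strip().lower() in self._order

    def __len__(self) -> int:
        return len(self._order)

    def items(self) -> Iterable[tuple[str, str]]:
        for key, order in self._order.items():
            yield self._canonical[key], order

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ClassificationTable":
        table = cls()
        with open(path) as fh:
            reader = csv.reader(fh, delimiter="\t")
            header = next(reader, None)
            if header and header[0].lower() not in ("superfamily", "family"):
                # no header row
                if len(header) >= 2:
                    table.add(header[0], header[1])
            for row in reader:
                if len(row) >= 2 and row[0].strip():
                    table.add(row[0], row[1])
        return table

    def to_tsv(self, path: str | Path) -> None:
        rows = [("superfamily", "te_order")] + sorted(self.items())
        write_table(rows, path, header=None)


def _split_class_family(token: str) -> tuple[str, str]:
    """Split a RepeatMasker class/family token into (order, superfamily).

    "LINE/L2" -> ("LINE", "L2"); a bare "LINE" -> ("LINE", "LINE").
    Trailing "?" qualifiers (uncertain classifications) are stripped.
    """
    token = token.strip().rstrip("?")
    if "/" in token:
        order, superfamily = token.split("/", 1)
        return order.rstrip("?"), superfamily
    return token, token


# RepeatMasker .out header (three lines, reproduced structurally).
_RM_HEADER = (
    "   SW   perc perc perc  query      position in query           matching"
    "       repeat              position in  repeat\n"
    "score   div. del. ins.  sequence    begin     end    (left)    repeat"
    "       class/family         begin  end (left)   ID\n"
    "\n"
)


def read_repeatmasker_out(
    path: str | Path,
    species_id: str,
    classification: ClassificationTable | None = None,
) -> list[RMFragment]:
    """Parse a RepeatMasker ``.out`` table into fragments.

    The dialect: three header lines, then whitespace-separated columns
    ``score div del ins seq begin end (left) strand family class/family
    rbegin rend (left) id [*]``.  ``begin``/``end`` are 1-based inclusive
    and are converted to 0-based half-open; strand ``C`` maps to ``-``;
    a trailing ``*`` (overlap flag) is tolerated and ignored.
    """
    fragments: list[RMFragment] = []
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines, start=1):
        fields = line.split()
        if not fields:
            continue
        # Skip the two header lines (they start with "SW"/"score").
        if fields[0] in ("SW", "score"):
            continue
        if len(fields) < 14:
            raise ValueError(f"{path}: line {lineno}: expected >=14 columns, got {len(fields)}")
        try:
            div = float(fields[1])
            begin = int(fields[5])
            end = int(fields[6])
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: malformed numeric column: {exc}") from exc
        strand = fields[8]
        if strand == "C":
            strand = "-"
        elif strand != "+":
            raise ValueError(f"{path}: line {lineno}: unknown strand {strand!r}")
        family_name = fields[9]
        order, superfamily = _split_class_family(fields[10])
        if order.lower() in NON_TE_CLASSES:
            te_order, superfamily = "Other", order
        elif classification is not None and superfamily in classification:
            te_order = classification.order_of(superfamily)
            superfamily = classification.canonical(superfamily)
        else:
            te_order = order if order in TE_ORDERS else "Unknown"
        frag_id = fields[14] if len(fields) > 14 else f"{species_id}:{lineno}"
        fragments.append(
            RMFragment(
                species_id=species_id,
                seq_id=fields[4],
                start=begin - 1,
                end=end,
                strand=strand,
                family_name=family_name,
                superfamily=superfamily,
                te_order=te_order,
                divergence_pct=div,
                fragment_id=frag_id,
            )
        )
    return fragments


def write_repeatmasker_out(fragments: Sequence[RMFragment], path: str | Path) -> None:
    """Write fragments back to the RepeatMasker ``.out`` dialect."""
    with open(path, "w") as fh:
        fh.write(_RM_HEADER)
        for frag in fragments:
            strand = "C" if frag.strand == "-" else "+"
            class_family = (
                frag.te_order
                if frag.superfamily == frag.te_order
                else f"{frag.te_order}/{frag.superfamily}"
            )
            div = 0.0 if frag.divergence_pct is None else frag.divergence_pct
            fh.write(
                f"  225 {div:5.2f}  0.00  0.00  {frag.seq_id} "
                f"{frag.start + 1} {frag.end} ({0}) {strand} "
                f"{frag.family_name} {class_family} 1 {frag.length} (0) {frag.fragment_id}\n"
            )


def _parse_gff_attributes(token: str) -> dict[str, str]:
    attrs = {}
    for item in token.strip().split(";"):
        if "=" in item:
            key, value = item.split("=", 1)
            attrs[key.strip()] = value.strip()
    return attrs


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models (gene + exon features) from a GFF3 file.

    Exon ``Parent`` attributes may point at the gene directly or at an
    mRNA whose ``Parent`` is the gene.  Orphan exons are skipped with a
    warning; an exon outside its gene's span is an error.
    """
    genes: dict[str, dict] = {}
    mrna_parent: dict[str, str] = {}
    exon_rows: list[tuple[str, int, int, str]] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                continue
            seq_id, _, ftype, start, end, _, strand, _, attr_token = cols[:9]
            attrs = _parse_gff_attributes(attr_token)
            start0, end0 = int(start) - 1, int(end)
            if ftype == "gene":
                gid = attrs.get("ID", f"gene{len(genes)}")
                genes[gid] = {
                    "seq_id": seq_id,
                    "start": start0,
                    "end": end0,
                    "strand": strand,
                    "exons": [],
                }
            elif ftype == "mRNA":
                if "ID" in attrs and "Parent" in attrs:
                    mrna_parent[attrs["ID"]] = attrs["Parent"]
            elif ftype == "exon":
                exon_rows.append((attrs.get("Parent", ""), start0, end0, seq_id))
    models: list[GeneModel] = []
    for parent, start0, end0, seq_id in exon_rows:
        gid = mrna_parent.get(parent, parent)
        if gid not in genes:
            logger.warning("orphan exon (%s:%d-%d) with parent %r skipped", seq_id, start0, end0, parent)
            continue
        gene = genes[gid]
        if not (gene["start"] <= start0 < end0 <= gene["end"]):
            raise ValueError(
                f"exon ({start0},{end0}) outside gene {gid} span "
                f"[{gene['start']},{gene['end']})"
            )
        gene["exons"].append((start0, end0))
    for gid, gene in genes.items():
        if not gene["exons"]:
            # gene feature without exon children: treat the whole span as one exon
            gene["exons"] = [(gene["start"], gene["end"])]
        models.append(
            GeneModel(
                gene_id=gid,
                seq_id=gene["seq_id"],
                start=gene["start"],
                end=gene["end"],
                strand=gene["strand"],
                exons=tuple(gene["exons"]),
            )
        )
    return models


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in genes:
            fh.write(
                f"{gene.seq_id}\ttelandscape\tgene\t{gene.start + 1}\t{gene.end}\t.\t"
                f"{gene.strand}\t.\tID={gene.gene_id}\n"
            )
            for i, (s, e) in enumerate(gene.exons, start=1):
                fh.write(
                    f"{gene.seq_id}\ttelandscape\texon\t{s + 1}\t{e}\t.\t"
                    f"{gene.strand}\t.\tID={gene.gene_id}.exon{i};Parent={gene.gene_id}\n"
                )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into ``{seq_id: uppercase sequence}``.

    Duplicate identifiers are an error.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"duplicate FASTA identifier {record.id!r} in {path}")
        sequences[record.id] = str(record.seq).upper()
    return sequences


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=seq_id, description="") for seq_id, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def write_newick(tree, path: str | Path) -> None:
    """Write a tree (scikit-bio TreeNode) as Newick with branch lengths."""
    tree.write(str(path), format="newick")


def write_table(rows: Iterable[Sequence], path: str | Path, header: Sequence[str] | None = None) -> None:
    """Write rows as a TSV file, optionally with a header row."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        if header is not None:
            writer.writerow(header)
        for row in rows:
            writer.writerow(row)


def read_table(path: str | Path, header: bool = True) -> tuple[list[str] | None, list[list[str]]]:
    """Read a TSV back as (header, rows of strings)."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        rows = list(reader)
    if header and rows:
        return rows[0], rows[1:]
    return None, rows
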