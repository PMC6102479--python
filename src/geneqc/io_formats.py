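"""Plain-text format I/O: FASTA and GFF3 references, SAM alignments, TSV report.

Coordinate convention
---------------------
GFF3 and SAM store 1-based inclusive coordinates and :class:`GeneModel` /
:class:`AlignmentRecord` keep them that way.  Everything downstream works on
the 0-based half-open projection exposed as :attr:`GeneModel.span0` (and on
half-open aligned blocks derived from CIGAR strings), so the inclusive/
exclusive conversion happens exactly once, here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from Bio import SeqIO

__all__ = [
    "FormatError",
    "EmptyAnnotationError",
    "GenomeSequence",
    "GeneModel",
    "AlignmentRecord",
    "ReportRow",
    "REPORT_COLUMNS",
    "read_fasta",
    "read_gff_genes",
    "stream_sam_alignments",
    "write_report",
    "read_report",
]


class FormatError(ValueError):
    """An input file violates its format contract."""


class EmptyAnnotationError(ValueError):
    """The annotation contains no features of the requested type(s)."""


_NON_ACGTN = re.compile(r"[^ACGTN]")


@dataclass(frozen=True)
class GenomeSequence:
    """One reference contig; sequence uppercased, ambiguity codes mapped to N."""

    contig_id: str
    sequence: str

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.sequence)


@dataclass(frozen=True)
class GeneModel:
    """An annotated genomic region ("gene" in the broad sense: any region
    a read can be attributed to — gene, transcript or exon)."""

    gene_id: str
    contig: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )

    @property
    def span0(self) -> tuple[int, int]:
        """0-based half-open genomic span."""
        return self.start - 1, self.end

    @property
    def length(self) -> int:
        return self.end - self.start + 1


#: sentinel contig value for unmapped alignment records
UNMAPPED = None


@dataclass(frozen=True)
class AlignmentRecord:
    """One SAM alignment line (mandatory columns plus the NH / AS tags)."""

    read_id: str
    flags: int
    contig: str | None  # None when unmapped
    pos: int  # 1-based leftmost mapped position (0 when unmapped)
    cigar: str
    nh: int | None = None
    align_score: int | None = None

    @property
    def is_unmapped(self) -> bool:
        return self.contig is None

    @property
    def is_secondary(self) -> bool:
        return bool(self.flags & 0x100)

    @property
    def is_supplementary(self) -> bool:
        return bool(self.flags & 0x800)

    @property
    def mate_index(self) -> int | None:
        """1 / 2 for paired-end mates, None for single-end reads."""
        if self.flags & 0x40:
            return 1
        if self.flags & 0x80:
            return 2
        return None

    @property
    def unit_id(self) -> str:
        """Countable alignment unit: a single-end read, or one mate of a pair."""
        mate = self.mate_index
        return self.read_id if mate is None else f"{self.read_id}/{mate}"


@dataclass(frozen=True)
class ReportRow:
    """One line of the final report (column order fixed by REPORT_COLUMNS)."""

    gene_id: str
    d1: float
    d2: float
    d3: float
    d_score: float
    category: str
    alt_likelihood: float


REPORT_COLUMNS = (
    "Gene ID",
    "D1",
    "D2",
    "D3",
    "D-score",
    "Category",
    "Alternative likelihood",
)


def read_fasta(path: str | Path) -> dict[str, GenomeSequence]:
    """Read a (multi-)FASTA file into a mapping contig_id -> GenomeSequence.

    Record ids are the first whitespace-delimited header token; sequences are
    uppercased and any character outside {A,C,G,T,N} becomes N.
    """
    contigs: dict[str, GenomeSequence] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in contigs:
            raise FormatError(f"duplicate contig id {record.id!r} in {path}")
        seq = _NON_ACGTN.sub("N", str(record.seq).upper())
        if not seq:
            raise FormatError(f"contig {record.id!r} has an empty sequence")
        contigs[record.id] = GenomeSequence(record.id, seq)
    if not contigs:
        raise FormatError(f"no FASTA records found in {path}")
    return contigs


_GFF_ID = re.compile(r"(?:^|;)\s*ID=([^;]+)")


def read_gff_genes(
    path: str | Path, feature_types: Iterable[str] = ("gene",)
) -> list[GeneModel]:
    """Read GFF3 features of the requested type(s) as GeneModels.

    gene_id comes from the ID attribute, falling back to ``contig:start-end``.
    Coordinates stay 1-based inclusive (GFF3 native).
    """
    wanted = set(feature_types)
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.startswith("##FASTA"):
                break
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            contig, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = cols
            if ftype not in wanted:
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end < start:
                raise FormatError(f"{path}:{lineno}: end {end} < start {start}")
            match = _GFF_ID.search(attrs)
            gene_id = match.group(1).strip() if match else f"{contig}:{start}-{end}"
            if gene_id in seen:
                raise FormatError(f"{path}:{lineno}: duplicate gene id {gene_id!r}")
            seen.add(gene_id)
            if strand not in "+-.":
                strand = "."
            genes.append(GeneModel(gene_id, contig, start, end, strand))
    if not genes:
        raise EmptyAnnotationError(
            f"no features of type(s) {sorted(wanted)} in {path}"
        )
    return genes


def _parse_int_tag(fields: Sequence[str], tag: str) -> int | None:
    prefix = f"{tag}:i:"
    for field in fields:
        if field.startswith(prefix):
            try:
                return int(field[len(prefix):])
            except ValueError:
                return None
    return None


def stream_sam_alignments(path: str | Path) -> Iterator[AlignmentRecord]:
    """Stream AlignmentRecords from a SAM text file.

    Header lines (``@``) are skipped; unmapped records (flag 0x4 or ``*``
    reference) are yielded with ``contig=None``; NH and AS tags are parsed
    when present.
    """
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            if line.startswith("@"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 11:
                raise FormatError(
                    f"{path}:{lineno}: SAM record has {len(cols)} columns (< 11)"
                )
            read_id = cols[0]
            try:
                flags = int(cols[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer FLAG {cols[1]!r}") from exc
            unmapped = bool(flags & 0x4) or cols[2] == "*"
            try:
                pos = int(cols[3])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer POS {cols[3]!r}") from exc
            if not unmapped and pos < 1:
                raise FormatError(f"{path}:{lineno}: mapped record with POS {pos} < 1")
            tags = cols[11:]
            yield AlignmentRecord(
                read_id=read_id,
                flags=flags,
                contig=None if unmapped else cols[2],
                pos=0 if unmapped else pos,
                cigar=cols[5],
                nh=_parse_int_tag(tags, "NH"),
                align_score=_parse_int_tag(tags, "AS"),
            )


def _fmt(value: float) -> str:
    """Render a float with 6 decimals, trailing zeros stripped (228.0 -> '228')."""
    text = f"{value:.6f}".rstrip("0").rstrip(".")
    return text if text not in ("", "-0") else "0"


def write_report(rows: Sequence[ReportRow], path: str | Path) -> None:
    """Write the final tab-separated per-gene report."""
    if not rows:
        raise ValueError("refusing to write an empty report")
    with open(path, "w") as handle:
        handle.write("\t".join(REPORT_COLUMNS) + "\n")
        for row in rows:
            handle.write(
                "\t".join(
                    (
                        row.gene_id,
                        _fmt(row.d1),
                        _fmt(row.d2),
                        _fmt(row.d3),
                        _fmt(row.d_score),
                        row.category,
                        _fmt(row.alt_likelihood),
                    )
                )
                + "\n"
            )


def read_report(path: str | Path) -> list[ReportRow]:
    """Parse a report written by :func:`write_report` (round-trip helper)."""
    rows: list[ReportRow] = []
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if tuple(header) != REPORT_COLUMNS:
            raise FormatError(f"unexpected report header {header!r}")
        for line in handle:
            gene_id, d1, d2, d3, d_score, category, alt = line.rstrip("\n").split("\t")
            rows.append(
                ReportRow(gene_id, float(d1), float(d2), float(d3),
                          float(d_score), category, float(alt))
            )
    return rows
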