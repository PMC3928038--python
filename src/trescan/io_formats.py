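"""Shared coordinate model and readers/writers for the flat formats the
pipeline touches.

All coordinates are 0-based half-open internally.  BED input is taken
verbatim; refFlat txStart is already 0-based.  Readers that accept 1-based
peak-table dialects convert at the boundary via an explicit ``one_based``
flag.  Contig name matching throughout the package is exact and
case-sensitive — no "chr" aliasing.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "FormatError",
    "CoordinateError",
    "GenomicInterval",
    "Peak",
    "GeneModel",
    "SequenceSet",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_refflat",
    "write_refflat",
    "read_peak_table",
    "extract_sequences",
]

STRANDS = ("+", "-", ".")


class FormatError(ValueError):
    """A file does not conform to its declared flat format."""


class CoordinateError(ValueError):
    """An interval refers to coordinates absent from the genome."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic span; ``.`` means unstranded."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("interval chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class Peak:
    """A called binding peak with its condition label."""

    interval: GenomicInterval
    score: float = 0.0
    condition: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError(f"peak score must be >= 0, got {self.score}")


@dataclass(frozen=True)
class GeneModel:
    """Transcript anatomy: span, CDS bounds and exon list (all half-open)."""

    gene_id: str
    interval: GenomicInterval
    cds_start: int
    cds_end: int
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not self.cds_start <= self.cds_end:
            raise ValueError(f"gene {self.gene_id}: cds_start > cds_end")
        prev_end = self.interval.start
        for ex in self.exons:
            if ex.chrom != self.interval.chrom:
                raise ValueError(f"gene {self.gene_id}: exon on wrong contig")
            if ex.start < prev_end:
                raise ValueError(
                    f"gene {self.gene_id}: exons overlap or are unsorted"
                )
            prev_end = ex.end
        if self.exons and (
            self.exons[0].start < self.interval.start
            or self.exons[-1].end > self.interval.end
        ):
            raise ValueError(f"gene {self.gene_id}: exons outside gene span")

    @property
    def tss(self) -> int:
        """Strand-dependent transcription start: txStart on +, txEnd on -."""
        if self.interval.strand == "+":
            return self.interval.start
        return self.interval.end  # one past the last transcribed base

    @property
    def strand(self) -> str:
        return self.interval.strand


class SequenceSet(dict):
    """Mapping contig -> uppercase DNA string over {A,C,G,T,N}."""

    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.items()}


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> SequenceSet:
    """Read a (possibly wrapped, possibly lowercase) FASTA file.

    Sequences are uppercased; ``N`` is preserved.  Raises
    :class:`FormatError` on malformed headers or empty records.
    """
    path = Path(path)
    text = path.read_text()
    if text.strip() and not text.lstrip().startswith(">"):
        first = text.lstrip().splitlines()[0]
        raise FormatError(f"{path}: expected FASTA header, got {first[:40]!r}")
    seqs = SequenceSet()
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: record with empty header")
        if len(rec.seq) == 0:
            raise FormatError(f"{path}: empty record {rec.id!r}")
        if rec.id in seqs:
            raise FormatError(f"{path}: duplicate contig {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in seqs.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# BED

def read_bed(
    path: str | Path, condition_label: str = "", one_based: bool = False
) -> list[Peak]:
    """Read BED3/BED5(+) intervals as :class:`Peak` records.

    Coordinates are kept verbatim (0-based half-open) unless ``one_based``
    requests conversion of a 1-based inclusive dialect.  A missing score
    column yields score 0.
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom = cols[0]
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if one_based:
                start -= 1
            if start >= end:
                raise FormatError(
                    f"{path}:{lineno}: start >= end ({start} >= {end})"
                )
            name = cols[3] if len(cols) > 3 else ""
            score = 0.0
            if len(cols) > 4 and cols[4] not in (".", ""):
                try:
                    score = float(cols[4])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: bad score {cols[4]!r}") from exc
            strand = cols[5] if len(cols) > 5 and cols[5] in STRANDS else "."
            peaks.append(
                Peak(
                    GenomicInterval(chrom, start, end, strand),
                    score=score,
                    condition=condition_label,
                    name=name,
                )
            )
    return peaks


def write_bed(peaks: Iterable[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name or '.'}"
                f"\t{p.score:g}\t{iv.strand}\n"
            )


def read_peak_table(
    path: str | Path,
    condition_label: str = "",
    chrom_col: int = 0,
    start_col: int = 1,
    end_col: int = 2,
    score_col: int | None = None,
    one_based: bool = False,
    skip_header: bool = True,
) -> list[Peak]:
    """Tolerant reader for peak tables that list peaks by start/end position
    with arbitrary extra columns (nearest gene, strand, distance...).

    Only chrom/start/end/score are kept; the column layout is configurable
    because published peak tables do not share a fixed dialect.
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            needed = max(chrom_col, start_col, end_col, score_col or 0)
            if len(cols) <= needed:
                raise FormatError(f"{path}:{lineno}: expected >= {needed + 1} columns")
            try:
                start, end = int(cols[start_col]), int(cols[end_col])
            except ValueError:
                if skip_header and lineno == 1:
                    continue  # header row
                raise FormatError(f"{path}:{lineno}: non-integer coordinate")
            if one_based:
                start -= 1
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end")
            score = 0.0
            if score_col is not None:
                try:
                    score = float(cols[score_col])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: bad score") from exc
            peaks.append(
                Peak(
                    GenomicInterval(cols[chrom_col], start, end),
                    score=score,
                    condition=condition_label,
                )
            )
    return peaks


# ---------------------------------------------------------------------------
# refFlat

def read_refflat(path: str | Path) -> list[GeneModel]:
    """Read refFlat gene models (geneName, name, chrom, strand, txStart,
    txEnd, cdsStart, cdsEnd, exonCount, exonStarts, exonEnds)."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 11:
                raise FormatError(f"{path}:{lineno}: fewer than 11 refFlat columns")
            gene_name, _tx_name, chrom, strand = cols[0], cols[1], cols[2], cols[3]
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: bad strand {strand!r}")
            try:
                tx_start, tx_end = int(cols[4]), int(cols[5])
                cds_start, cds_end = int(cols[6]), int(cols[7])
                exon_count = int(cols[8])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer field") from exc
            ex_starts = [int(x) for x in cols[9].rstrip(",").split(",") if x]
            ex_ends = [int(x) for x in cols[10].rstrip(",").split(",") if x]
            if len(ex_starts) != exon_count or len(ex_ends) != exon_count:
                raise FormatError(
                    f"{path}:{lineno}: exonCount {exon_count} does not match "
                    f"exon lists ({len(ex_starts)}/{len(ex_ends)})"
                )
            exons = tuple(
                GenomicInterval(chrom, s, e, strand)
                for s, e in zip(ex_starts, ex_ends)
            )
            try:
                genes.append(
                    GeneModel(
                        gene_id=gene_name,
                        interval=GenomicInterval(chrom, tx_start, tx_end, strand),
                        cds_start=cds_start,
                        cds_end=cds_end,
                        exons=exons,
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return genes


def write_refflat(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            iv = g.interval
            starts = ",".join(str(e.start) for e in g.exons) + ","
            ends = ",".join(str(e.end) for e in g.exons) + ","
            fh.write(
                "\t".join(
                    [
                        g.gene_id,
                        g.gene_id,
                        iv.chrom,
                        iv.strand,
                        str(iv.start),
                        str(iv.end),
                        str(g.cds_start),
                        str(g.cds_end),
                        str(len(g.exons)),
                        starts,
                        ends,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Sequence extraction

def extract_sequences(
    intervals: Sequence[GenomicInterval], genome: Mapping[str, str]
) -> list[str]:
    """Plus-strand sequence for each interval (scanning handles strands).

    Raises :class:`CoordinateError` for unknown contigs or out-of-bounds
    spans, naming the offending interval.
    """
    out: list[str] = []
    for iv in intervals:
        seq = genome.get(iv.chrom)
        if seq is None:
            raise CoordinateError(
                f"unknown contig {iv.chrom!r} for interval "
                f"{iv.chrom}:{iv.start}-{iv.end}"
            )
        if iv.end > len(seq):
            raise CoordinateError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds contig "
                f"length {len(seq)}"
            )
        out.append(seq[iv.start : iv.end])
    return out
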