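"""Sequences, genomic intervals, and gene models.

External coordinates are 1-based inclusive (the convention used in genome
catalogs); internal slicing is 0-based half-open. The conversion happens in
exactly one place, :meth:`GenomicInterval.to_slice` /
:meth:`GenomicInterval.from_slice` — nothing else does coordinate
arithmetic by hand.

FASTA reading and writing are delegated to Biopython's ``SeqIO``; this
module adds the validation contract (uppercase, ``ACGTN`` alphabet with
error positions, unique record ids) that the downstream assay-design code
relies on. ``N`` is allowed in genomic sequence but forbidden in primers,
which are synthesized oligos.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Sequence, TextIO, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

GENOME_ALPHABET = frozenset("ACGTN")
PRIMER_ALPHABET = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FastaError(ValueError):
    """Malformed FASTA input (empty file, duplicate ids, bad characters)."""


def _validate_sequence(seq: str, record_id: str = "") -> str:
    """Uppercase *seq* and verify it is a non-empty ACGTN string.

    Raises :class:`FastaError` naming the 1-based position of the first
    offending character.
    """
    seq = seq.upper()
    if not seq:
        raise FastaError(f"record '{record_id}': empty sequence")
    for pos, ch in enumerate(seq, start=1):
        if ch not in GENOME_ALPHABET:
            raise FastaError(
                f"record '{record_id}': invalid character {ch!r} at position {pos}"
            )
    return seq


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence over the ``ACGTN`` alphabet."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SequenceRecord requires a non-empty id")
        object.__setattr__(self, "seq", _validate_sequence(self.seq, self.id))

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "SequenceRecord":
        return SequenceRecord(self.id, reverse_complement(self.seq))


def reverse_complement(seq: str) -> str:
    """Reverse complement of an ``ACGTN`` string (involution)."""
    seq = seq.upper()
    for pos, ch in enumerate(seq, start=1):
        if ch not in GENOME_ALPHABET:
            raise ValueError(f"invalid character {ch!r} at position {pos}")
    return seq.translate(_COMPLEMENT)[::-1]


def parse_fasta(source: Union[str, Path, TextIO]) -> List[SequenceRecord]:
    """Parse multi-record FASTA into :class:`SequenceRecord` objects.

    Sequences are uppercased; record order is preserved. Empty input and
    duplicate ids are errors, as are characters outside ``ACGTN``.
    """
    if isinstance(source, str) and ("\n" in source or source.lstrip().startswith(">") or not source.strip()):
        handle: TextIO = io.StringIO(source)
        close = False
    elif isinstance(source, (str, Path)):
        handle = open(source)
        close = True
    else:
        handle = source  # type: ignore[assignment]
        close = False
    try:
        records: List[SequenceRecord] = []
        seen = set()
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise FastaError(f"duplicate record id '{rec.id}'")
            seen.add(rec.id)
            records.append(SequenceRecord(rec.id, str(rec.seq)))
        if not records:
            raise FastaError("no FASTA records found")
        return records
    finally:
        if close:
            handle.close()


def write_fasta(records: Iterable[SequenceRecord], dest: Union[str, Path, TextIO]) -> None:
    """Write records as FASTA, wrapped at 70 columns."""
    bio = [_BioRecord(Seq(r.seq), id=r.id, description="") for r in records]
    if isinstance(dest, (str, Path)):
        with open(dest, "w") as fh:
            SeqIO.write(bio, fh, "fasta")
    else:
        SeqIO.write(bio, dest, "fasta")


_COORD_RE = re.compile(r"^\s*(\S+?)\s*:\s*([\d,]+)\s*-\s*([\d,]+)\s*$")


@dataclass(frozen=True)
class GenomicInterval:
    """1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    def to_slice(self) -> slice:
        """0-based half-open slice selecting this interval."""
        return slice(self.start - 1, self.end)

    @classmethod
    def from_slice(cls, chrom: str, start0: int, end0: int, strand: str = "+") -> "GenomicInterval":
        """Build from a 0-based half-open range."""
        return cls(chrom, start0 + 1, end0, strand)

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start <= other.end and other.start <= self.end

    def __str__(self) -> str:
        return f"{self.chrom}: {self.start}-{self.end}"


def parse_coordinate(text: str) -> GenomicInterval:
    """Parse ``"<chrom>: <start>-<end>"`` into an interval (strand ``+``)."""
    m = _COORD_RE.match(text)
    if not m:
        raise ValueError(f"malformed coordinate string: {text!r}")
    chrom, start, end = m.group(1), int(m.group(2).replace(",", "")), int(m.group(3).replace(",", ""))
    return GenomicInterval(chrom, start, end)


def interval_span(interval: GenomicInterval) -> int:
    """Number of bases covered, ``end - start + 1``."""
    return interval.span


@dataclass(frozen=True)
class GeneModel:
    """An exon/intron gene structure on one chromosome.

    Exons are 1-based inclusive intervals, non-overlapping and sorted by
    coordinate; introns are the gaps between consecutive exons.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple

    def __post_init__(self) -> None:
        exons = tuple(self.exons)
        if not exons:
            raise ValueError("gene model needs at least one exon")
        for a, b in zip(exons, exons[1:]):
            if b.start <= a.end:
                raise ValueError("exons must be sorted and non-overlapping")
        for e in exons:
            if e.chrom != self.chrom:
                raise ValueError("all exons must lie on the gene's chromosome")
        object.__setattr__(self, "exons", exons)

    @property
    def introns(self) -> tuple:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            out.append(GenomicInterval(self.chrom, a.end + 1, b.start - 1, self.strand))
        return tuple(out)

    @property
    def extent(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.exons[0].start, self.exons[-1].end, self.strand)

    @property
    def exon_lengths(self) -> tuple:
        return tuple(e.span for e in self.exons)

    def spliced_length(self) -> int:
        return sum(self.exon_lengths)

    def cdna_junctions(self) -> tuple:
        """cDNA positions (1-based) of the last base of each exon but the last."""
        out, total = [], 0
        for e in self.exons[:-1]:
            total += e.span
            out.append(total)
        return tuple(out)

    def spliced_sequence(self, chrom_seq: str) -> str:
        """Concatenate exon sequence (reverse-complemented for ``-`` genes)."""
        parts = [chrom_seq[e.to_slice()] for e in self.exons]
        cdna = "".join(parts)
        return reverse_complement(cdna) if self.strand == "-" else cdna

    def genomic_span_of_cdna_interval(self, start: int, end: int) -> int:
        """Genomic bp spanned by cDNA positions [start, end] (1-based, + genes).

        Differs from ``end - start + 1`` by the summed lengths of introns
        falling inside the interval — the quantity that separates a spliced
        amplicon from its genomic counterpart.
        """
        if self.strand != "+":
            raise NotImplementedError("genomic projection implemented for + strand models")
        g_start = self._cdna_to_genomic(start)
        g_end = self._cdna_to_genomic(end)
        return g_end - g_start + 1

    def _cdna_to_genomic(self, pos: int) -> int:
        if pos < 1 or pos > self.spliced_length():
            raise ValueError(f"cDNA position {pos} outside transcript")
        offset = pos
        for e in self.exons:
            if offset <= e.span:
                return e.start + offset - 1
            offset -= e.span
        raise AssertionError("unreachable")


def read_gene_model_bed(source: Union[str, Path, TextIO], strand: str = "+") -> GeneModel:
    """Read a 4-column BED-like exon annotation (chrom, start0, end, name).

    All rows must share one gene name; exons are sorted by coordinate.
    """
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        text = Path(source).read_text()
    elif isinstance(source, str):
        text = source
    else:
        text = source.read()
    exons, names, chroms = [], set(), set()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        chrom, start0, end, name = line.split("\t")[:4]
        exons.append(GenomicInterval(chrom, int(start0) + 1, int(end), strand))
        names.add(name)
        chroms.add(chrom)
    if not exons:
        raise ValueError("no exon rows in BED input")
    if len(names) != 1 or len(chroms) != 1:
        raise ValueError("BED input must describe a single gene on one chromosome")
    exons.sort(key=lambda e: e.start)
    return GeneModel(names.pop(), chroms.pop(), strand, tuple(exons))


def write_gene_model_bed(model: GeneModel, dest: Union[str, Path, TextIO]) -> None:
    lines = [
        f"{e.chrom}\t{e.start - 1}\t{e.end}\t{model.gene_id}" for e in model.exons
    ]
    text = "\n".join(lines) + "\n"
    if isinstance(dest, (str, Path)):
        Path(dest).write_text(text)
    else:
        dest.write(text)
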