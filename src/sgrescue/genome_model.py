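"""Reference genomes, coding sequences and genomic coordinates.

This module is the coordinate backbone shared by the simulator, the mosaic
caller, the SNV-space enumerator and the breakpoint clustering code.  All
in-memory coordinates are 1-based inclusive (the SAM/VCF convention);
BED-like interval files on disk are 0-based half-open and converted at the
I/O boundary.

Translation uses the standard nuclear genetic code only.  ``N`` bases are
permitted in a reference, but any operation that would have to interpret an
``N`` inside a coding sequence raises instead of guessing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

VALID_BASES = frozenset("ACGTN")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

__all__ = [
    "ReferenceGenome",
    "CodingSequence",
    "GenomicPosition",
    "FastaFormatError",
    "CdsValidationError",
    "read_fasta",
    "write_fasta",
    "extract_cds",
    "genomic_to_cds_pos",
    "cds_to_genomic_pos",
    "read_cds_table",
    "write_cds_table",
    "revcomp",
    "translate_cds",
]


class FastaFormatError(ValueError):
    """Raised when a FASTA file is malformed or uses a non-ACGTN alphabet."""


class CdsValidationError(ValueError):
    """Raised when a putative coding sequence violates a CDS invariant."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN alphabet)."""
    return str(Seq(seq).reverse_complement())


def translate_cds(cds_seq: str) -> str:
    """Translate a full CDS (standard code), returning the protein without
    the terminal stop."""
    if "N" in cds_seq:
        raise CdsValidationError("CDS contains N bases; refusing to translate")
    aa = str(Seq(cds_seq).translate(table=1))
    return aa[:-1] if aa.endswith("*") else aa


@dataclass(frozen=True)
class GenomicPosition:
    """A 1-based coordinate on a named chromosome."""

    chrom: str
    pos: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")


@dataclass
class ReferenceGenome:
    """An ordered set of named uppercase DNA sequences (alphabet ACGTN)."""

    chromosomes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, seq in self.chromosomes.items():
            if not name:
                raise ValueError("chromosome names must be non-empty")
            if len(seq) < 1:
                raise ValueError(f"chromosome {name!r} is empty")
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(
                    f"chromosome {name!r} has invalid characters {sorted(bad)}"
                )

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chromosomes

    def length(self, chrom: str) -> int:
        return len(self.chromosomes[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of ``chrom`` between 1-based inclusive ``start``/``end``."""
        if start < 1 or end > self.length(chrom) or start > end:
            raise ValueError(
                f"interval {chrom}:{start}-{end} outside chromosome bounds "
                f"(length {self.length(chrom)})"
            )
        return self.chromosomes[chrom][start - 1 : end]

    def base(self, gpos: GenomicPosition) -> str:
        return self.fetch(gpos.chrom, gpos.pos, gpos.pos)


@dataclass
class CodingSequence:
    """A genome-anchored CDS: strand, exon segments, spliced sequence and
    protein.

    ``segments`` are 1-based inclusive ``(start, end)`` genomic intervals in
    transcript (5'->3') order — ascending genomic order on ``+``, descending
    on ``-``.  The spliced ``cds_seq`` must start with ATG and end with a
    stop codon; ``protein`` is its standard-code translation without the
    stop.
    """

    name: str
    chrom: str
    strand: str
    segments: list[tuple[int, int]]
    cds_seq: str
    protein: str

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise CdsValidationError(f"strand must be '+' or '-', got {self.strand!r}")
        self._validate_segments()
        n = len(self.cds_seq)
        if n < 6:
            raise CdsValidationError(f"CDS length {n} < 6")
        if n % 3 != 0:
            raise CdsValidationError(f"CDS length {n} not divisible by 3")
        if sum(e - s + 1 for s, e in self.segments) != n:
            raise CdsValidationError("segment lengths do not sum to CDS length")
        if not self.cds_seq.startswith("ATG"):
            raise CdsValidationError("CDS does not start with ATG")
        if self.cds_seq[-3:] not in STOP_CODONS:
            raise CdsValidationError("CDS does not end with a stop codon")
        if len(self.protein) != n // 3 - 1:
            raise CdsValidationError("protein length != CDS length / 3 - 1")

    def _validate_segments(self) -> None:
        if not self.segments:
            raise CdsValidationError("CDS has no segments")
        for s, e in self.segments:
            if s > e:
                raise CdsValidationError(f"segment start {s} > end {e}")
        genomic_sorted = sorted(self.segments)
        for (s1, e1), (s2, e2) in zip(genomic_sorted, genomic_sorted[1:]):
            if e1 >= s2:
                raise CdsValidationError("segments overlap")
        expected = genomic_sorted if self.strand == "+" else genomic_sorted[::-1]
        if list(self.segments) != expected:
            raise CdsValidationError(
                "segments not in transcript order for strand " + self.strand
            )

    def __len__(self) -> int:
        return len(self.cds_seq)

    @property
    def n_codons(self) -> int:
        return len(self.cds_seq) // 3

    def codon(self, codon_index: int) -> str:
        """1-based codon (codon 1 is the ATG)."""
        i = (codon_index - 1) * 3
        return self.cds_seq[i : i + 3]


def read_fasta(path: str | Path) -> ReferenceGenome:
    """Read a (multi-record) FASTA into a :class:`ReferenceGenome`.

    Sequences are uppercased.  A record using characters outside ACGTN
    raises :class:`FastaFormatError` naming the offending line.
    """
    path = Path(path)
    records: dict[str, str] = {}
    with open(path) as fh:
        first = fh.read(1)
        if first != ">":
            raise FastaFormatError(f"{path}: line 1: expected FASTA header '>'")
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FastaFormatError(f"{path}: duplicate record name {rec.id!r}")
        seq = str(rec.seq).upper()
        bad = set(seq) - VALID_BASES
        if bad:
            raise FastaFormatError(
                f"{path}: record {rec.id!r}, line {_find_bad_line(path, bad)}: "
                f"invalid characters {sorted(bad)}"
            )
        records[rec.id] = seq
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    return ReferenceGenome(records)


def _find_bad_line(path: Path, bad: set[str]) -> int:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                continue
            if set(line.strip().upper()) & bad:
                return lineno
    return -1


def write_fasta(genome: ReferenceGenome, path: str | Path, width: int = 60) -> None:
    """Write the genome as FASTA with fixed line width."""
    with open(path, "w") as fh:
        for name, seq in genome.chromosomes.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def extract_cds(
    genome: ReferenceGenome,
    chrom: str,
    strand: str,
    segments: Sequence[tuple[int, int]],
    name: str = "cds",
) -> CodingSequence:
    """Splice a CDS out of ``genome`` and validate it.

    ``segments`` are 1-based inclusive intervals in transcript order (for
    ``-`` strand, descending genomic coordinates).  The spliced sequence is
    reverse-complemented per segment on the minus strand.
    """
    parts = []
    for s, e in segments:
        seq = genome.fetch(chrom, s, e)
        parts.append(seq if strand == "+" else revcomp(seq))
    cds_seq = "".join(parts)
    if "N" in cds_seq:
        raise CdsValidationError(f"CDS {name!r} contains N bases")
    protein = translate_cds(cds_seq)
    if "*" in protein:
        raise CdsValidationError(f"CDS {name!r} has an internal stop codon")
    return CodingSequence(
        name=name,
        chrom=chrom,
        strand=strand,
        segments=[tuple(seg) for seg in segments],
        cds_seq=cds_seq,
        protein=protein,
    )


def genomic_to_cds_pos(cds: CodingSequence, gpos: GenomicPosition) -> int | None:
    """Map a genomic position to its 1-based offset in the spliced CDS.

    Returns ``None`` for positions outside the CDS segments (or on another
    chromosome).  On the minus strand, transcript order runs against the
    genomic coordinate.
    """
    if gpos.chrom != cds.chrom:
        return None
    offset = 0
    for s, e in cds.segments:
        if s <= gpos.pos <= e:
            if cds.strand == "+":
                return offset + (gpos.pos - s + 1)
            return offset + (e - gpos.pos + 1)
        offset += e - s + 1
    return None


def cds_to_genomic_pos(cds: CodingSequence, cds_pos: int) -> GenomicPosition:
    """Inverse of :func:`genomic_to_cds_pos` (1-based CDS offset to genome)."""
    if not 1 <= cds_pos <= len(cds.cds_seq):
        raise ValueError(f"CDS position {cds_pos} outside 1..{len(cds.cds_seq)}")
    remaining = cds_pos
    for s, e in cds.segments:
        seg_len = e - s + 1
        if remaining <= seg_len:
            if cds.strand == "+":
                return GenomicPosition(cds.chrom, s + remaining - 1)
            return GenomicPosition(cds.chrom, e - remaining + 1)
        remaining -= seg_len
    raise AssertionError("unreachable")  # pragma: no cover


def write_cds_table(cds_list: Iterable[CodingSequence], path: str | Path) -> None:
    """Write a 6-column CDS annotation table (0-based half-open on disk).

    Columns: name, chrom, strand, comma-separated segment starts (0-based),
    comma-separated segment ends (half-open), frame placeholder.
    """
    with open(path, "w") as fh:
        fh.write("#name\tchrom\tstrand\tseg_starts\tseg_ends\tframe\n")
        for cds in cds_list:
            starts = ",".join(str(s - 1) for s, _ in cds.segments)
            ends = ",".join(str(e) for _, e in cds.segments)
            fh.write(f"{cds.name}\t{cds.chrom}\t{cds.strand}\t{starts}\t{ends}\t0\n")


def read_cds_table(path: str | Path, genome: ReferenceGenome) -> list[CodingSequence]:
    """Read the 6-column CDS table back, re-splicing against ``genome``."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 6:
                raise ValueError(f"{path}: line {lineno}: expected 6 columns")
            name, chrom, strand, starts_s, ends_s, _frame = fields
            starts = [int(x) + 1 for x in starts_s.split(",")]
            ends = [int(x) for x in ends_s.split(",")]
            segments = list(zip(starts, ends))
            out.append(extract_cds(genome, chrom, strand, segments, name=name))
    return out
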