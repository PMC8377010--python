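"""Synthetic patient cohorts with mosaic clonal events.

The study data this package targets (ultra-deep targeted sequencing of a
single locus in bone-marrow/blood DNA) is access-restricted, so this module
generates cohorts with the same statistical structure: per-patient sets of
low-cell-fraction clones carrying coding SNVs/indels, one patient with a
mosaic heterozygous deletion shifting SNP B-allele frequencies, and one
patient with a reciprocal translocation producing soft-clipped junction
reads with inter-chromosomal mates.

Read geometry mirrors the emulated library: paired-end 130+130 reads on
200 bp fragments, PCR duplicates carried as SAM duplicate-flagged records,
and uniform strand-independent sequencing errors (which makes the caller's
binomial error null exact by construction).

Key quantitative conventions
----------------------------
- a heterozygous somatic SNV in cell fraction ``f`` has expected VAF ``f/2``;
- a heterozygous deletion in cell fraction ``f`` shifts the deleted allele's
  BAF at constitutional het SNPs to ``(1-f)/(2-f)``;
- depth regimes: ``locus_capture`` ~2807x and ``cdna_capture`` ~26873x mean
  deduplicated depth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .genome_model import (
    CodingSequence,
    GenomicPosition,
    ReferenceGenome,
    STOP_CODONS,
    revcomp,
    write_cds_table,
    write_fasta,
)

__all__ = [
    "ClonalEvent",
    "PatientSpec",
    "CohortSpec",
    "DEFAULT_SPECTRUM",
    "DEPTH_REGIMES",
    "READ_LENGTH",
    "FRAGMENT_LENGTH",
    "simulate_reference",
    "expected_baf",
    "simulate_het_snp_counts",
    "simulate_patient_reads",
    "make_sam_header",
    "write_sam",
    "build_cohort_specs",
    "simulate_cohort",
]

READ_LENGTH = 130
FRAGMENT_LENGTH = 200

#: Mean deduplicated target depths of the two capture designs.
DEPTH_REGIMES = {"locus_capture": 2807, "cdna_capture": 26873}

#: Six-class substitution spectrum (pyrimidine-reference convention).
#: The C>T share follows the dominant-transition spectrum of hematopoietic
#: somatic mutations; the division of the remainder is this package's choice.
DEFAULT_SPECTRUM = {
    "C>A": 0.080,
    "C>G": 0.060,
    "C>T": 0.511,
    "T>A": 0.065,
    "T>C": 0.180,
    "T>G": 0.104,
}

_BASES = np.array(["A", "C", "G", "T"])
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
]


@dataclass
class ClonalEvent:
    """One acquired clonal event present in a ``cell_fraction`` of cells.

    ``kind`` is one of ``snv``, ``indel``, ``het_deletion``,
    ``translocation``.  SNV/indel events carry VCF-style left-anchored
    ``chrom/pos/ref/alt``; deletions an interval on one haplotype;
    translocations one junction position per chromosome.
    """

    kind: str
    cell_fraction: float
    chrom: str | None = None
    pos: int | None = None
    ref: str | None = None
    alt: str | None = None
    start: int | None = None
    end: int | None = None
    chrom2: str | None = None
    pos2: int | None = None
    orientation: str = "head_tail"

    def __post_init__(self) -> None:
        if not 0 < self.cell_fraction <= 1:
            raise ValueError(f"cell_fraction must be in (0,1], got {self.cell_fraction}")
        if self.kind == "snv":
            if len(self.ref) != 1 or len(self.alt) != 1 or self.ref == self.alt:
                raise ValueError("snv ref/alt must be single distinct bases")
        elif self.kind == "indel":
            if len(self.ref) == len(self.alt):
                raise ValueError("indel alleles must differ in length")
        elif self.kind == "het_deletion":
            if self.start is None or self.end is None or self.start > self.end:
                raise ValueError("het_deletion needs a valid [start, end] interval")
        elif self.kind == "translocation":
            if None in (self.chrom, self.pos, self.chrom2, self.pos2):
                raise ValueError("translocation needs two (chrom, pos) junctions")
        else:
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass
class PatientSpec:
    """Everything needed to simulate one patient's aligned reads."""

    id: str
    age: float
    events: list[ClonalEvent]
    mean_depth: int
    seed: int
    error_rate: float = 1e-3
    duplicate_rate: float = 0.1
    het_snp_positions: list[GenomicPosition] = field(default_factory=list)
    regions: list[tuple[str, int, int]] = field(default_factory=list)
    group: str = "affected"

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError("age must be >= 0")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if not 0 <= self.error_rate <= 0.05:
            raise ValueError("error_rate must be in [0, 0.05]")
        if not 0 <= self.duplicate_rate < 1:
            raise ValueError("duplicate_rate must be in [0, 1)")
        event_pos = {(e.chrom, e.pos) for e in self.events if e.pos is not None}
        for g in self.het_snp_positions:
            if (g.chrom, g.pos) in event_pos:
                raise ValueError(f"het SNP at {g.chrom}:{g.pos} collides with an event")


@dataclass
class CohortSpec:
    """Cohort-level simulation parameters."""

    n_patients: int = 26
    spectrum_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SPECTRUM)
    )
    vaf_range: tuple[float, float] = (0.0025, 0.28)
    depth_regime: str = "cdna_capture"
    seed: int = 0
    error_rate: float = 1e-3
    duplicate_rate: float = 0.1

    def __post_init__(self) -> None:
        total = sum(self.spectrum_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"spectrum weights sum to {total}, expected 1")
        lo, hi = self.vaf_range
        if not 0 < lo <= hi <= 1:
            raise ValueError(f"invalid vaf_range {self.vaf_range}")
        if self.depth_regime not in DEPTH_REGIMES:
            raise ValueError(f"unknown depth_regime {self.depth_regime!r}")


# ---------------------------------------------------------------------------
# Reference simulation


def simulate_reference(
    seed: int,
    chrom_lengths: dict[str, int],
    cds_layout: dict,
) -> tuple[ReferenceGenome, CodingSequence]:
    """Simulate a random reference embedding one valid CDS.

    ``cds_layout`` keys: ``name``, ``chrom``, ``start`` (1-based genomic
    start of the CDS footprint), ``n_coding_nt`` (spliced length including
    the stop codon, divisible by 3), optional ``strand`` (default ``+``).
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    name = cds_layout["name"]
    chrom = cds_layout["chrom"]
    start = cds_layout["start"]
    n_nt = cds_layout["n_coding_nt"]
    strand = cds_layout.get("strand", "+")
    if n_nt % 3 != 0 or n_nt < 6:
        raise ValueError("n_coding_nt must be >= 6 and divisible by 3")
    if chrom not in chrom_lengths:
        raise ValueError(f"CDS chromosome {chrom!r} not in chrom_lengths")
    if start < 1 or start + n_nt - 1 > chrom_lengths[chrom]:
        raise ValueError(
            f"CDS of {n_nt} nt at {chrom}:{start} does not fit in chromosome "
            f"of length {chrom_lengths[chrom]}"
        )

    chroms = {}
    for cname, ln in chrom_lengths.items():
        chroms[cname] = "".join(rng.choice(_BASES, size=ln))

    n_mid = n_nt // 3 - 2
    codons = ["ATG"]
    codons += list(rng.choice(_NON_STOP_CODONS, size=n_mid))
    codons.append(str(rng.choice(sorted(STOP_CODONS))))
    cds_seq = "".join(codons)
    embedded = cds_seq if strand == "+" else revcomp(cds_seq)
    s = chroms[chrom]
    chroms[chrom] = s[: start - 1] + embedded + s[start + n_nt - 1 :]

    genome = ReferenceGenome(chroms)
    end = start + n_nt - 1
    segments = [(start, end)]
    from .genome_model import extract_cds

    cds = extract_cds(genome, chrom, strand, segments, name=name)
    return genome, cds


# ---------------------------------------------------------------------------
# BAF arithmetic


def expected_baf(f: float, allele: str = "deleted") -> float:
    """Expected allele fraction at a constitutional het SNP inside a
    heterozygous deletion present in cell fraction ``f``.

    Copy number of the deleted allele is ``1-f`` against ``1`` for the
    retained allele, giving ``(1-f)/(2-f)`` and ``1/(2-f)`` respectively
    (the two sum to 1).
    """
    if not 0 <= f <= 1:
        raise ValueError(f"cell fraction must be in [0, 1], got {f}")
    if allele == "deleted":
        return (1.0 - f) / (2.0 - f)
    if allele == "retained":
        return 1.0 / (2.0 - f)
    raise ValueError("allele must be 'deleted' or 'retained'")


def simulate_het_snp_counts(
    f: float,
    depth: int,
    n_snps: int,
    rng: np.random.Generator,
    positions: list[int] | None = None,
    chrom: str = "chr20s",
) -> pd.DataFrame:
    """Count-level shortcut for BAF studies: binomial allele counts at
    ``n_snps`` het SNPs inside a deletion of cell fraction ``f``.

    The B allele is the deleted one.  Columns: chrom, pos, a_count, b_count.
    """
    p_b = expected_baf(f, "deleted")
    depths = np.full(n_snps, depth)
    b = rng.binomial(depths, p_b)
    pos = positions if positions is not None else list(range(1000, 1000 + n_snps * 100, 100))
    return pd.DataFrame(
        {"chrom": chrom, "pos": pos, "a_count": depths - b, "b_count": b}
    )


# ---------------------------------------------------------------------------
# Read simulation


def make_sam_header(genome: ReferenceGenome) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [
                {"SN": name, "LN": len(seq)}
                for name, seq in genome.chromosomes.items()
            ],
        }
    )


def _compress_cigar(ref_positions: list[int | None]) -> tuple[int, str]:
    """Turn a per-base reference-position map into (1-based start, CIGAR).

    ``None`` entries are unaligned bases: soft clips at either end, ``I`` in
    the middle; jumps in reference position become ``D``.
    """
    n = len(ref_positions)
    lo = 0
    while lo < n and ref_positions[lo] is None:
        lo += 1
    hi = n
    while hi > lo and ref_positions[hi - 1] is None:
        hi -= 1
    if lo == hi:
        raise ValueError("read has no aligned bases")
    ops: list[tuple[str, int]] = []
    if lo:
        ops.append(("S", lo))
    prev = None
    for rp in ref_positions[lo:hi]:
        if rp is None:
            op = ("I", 1)
        elif prev is not None and prev[0] is not None and rp > prev[0] + 1:
            ops.append(("D", rp - prev[0] - 1))
            op = ("M", 1)
        else:
            op = ("M", 1)
        if ops and ops[-1][0] == op[0] and op[0] in "MI":
            ops[-1] = (op[0], ops[-1][1] + 1)
        else:
            ops.append(op)
        prev = (rp,) if rp is not None else prev
    if hi < n:
        ops.append(("S", n - hi))
    cigar = "".join(f"{ln}{op}" for op, ln in ops)
    return ref_positions[lo], cigar


@dataclass
class _Read:
    qname: str
    chrom: str
    pos: int  # 1-based leftmost aligned
    cigar: str
    seq: str
    flag: int
    mate_chrom: str
    mate_pos: int


def _pair_flags(r1_chrom: str, r2_chrom: str) -> tuple[int, int]:
    proper = 0x2 if r1_chrom == r2_chrom else 0
    f1 = 0x1 | proper | 0x20 | 0x40  # paired, mate-reverse, first in pair
    f2 = 0x1 | proper | 0x10 | 0x80  # paired, reverse, second in pair
    return f1, f2


def _plain_read(chromseq: str, chrom: str, start: int, subs: dict[int, str]) -> tuple[str, str]:
    """Reference-matching read of READ_LENGTH at 1-based ``start`` with
    point substitutions ``{genomic_pos: base}`` applied."""
    seq = chromseq[start - 1 : start - 1 + READ_LENGTH]
    if subs:
        chars = list(seq)
        for p, b in subs.items():
            off = p - start
            if 0 <= off < READ_LENGTH:
                chars[off] = b
        seq = "".join(chars)
    return seq, f"{READ_LENGTH}M"


def _derivative_read(
    genome: ReferenceGenome, ev: ClonalEvent, der: int, d_start0: int
) -> tuple[str, int, str, str]:
    """One read from a derivative chromosome of a reciprocal translocation.

    ``der`` 1 joins chromA[1..posA] to chromB[posB..]; ``der`` 2 joins
    chromB[1..posB] to chromA[posA+1..].  Returns (chrom, pos, cigar, seq);
    junction-spanning reads anchor on the prefix side with a trailing soft
    clip, so their last aligned base is exactly the junction position.
    """
    a_seq = genome.chromosomes[ev.chrom]
    b_seq = genome.chromosomes[ev.chrom2]
    pos_a, pos_b = ev.pos, ev.pos2
    if der == 1:
        prefix_len = pos_a
        prefix_chrom, prefix_seq = ev.chrom, a_seq
        suffix_chrom, suffix_seq, suffix_ref_start = ev.chrom2, b_seq, pos_b
    else:
        prefix_len = pos_b
        prefix_chrom, prefix_seq = ev.chrom2, b_seq
        suffix_chrom, suffix_seq, suffix_ref_start = ev.chrom, a_seq, pos_a + 1
    d_end0 = d_start0 + READ_LENGTH  # exclusive
    if d_end0 <= prefix_len:
        seq = prefix_seq[d_start0:d_end0]
        return prefix_chrom, d_start0 + 1, f"{READ_LENGTH}M", seq
    if d_start0 >= prefix_len:
        off = d_start0 - prefix_len
        seq = suffix_seq[suffix_ref_start - 1 + off : suffix_ref_start - 1 + off + READ_LENGTH]
        return suffix_chrom, suffix_ref_start + off, f"{READ_LENGTH}M", seq
    k = prefix_len - d_start0
    seq = prefix_seq[d_start0:prefix_len] + suffix_seq[
        suffix_ref_start - 1 : suffix_ref_start - 1 + READ_LENGTH - k
    ]
    return prefix_chrom, d_start0 + 1, f"{k}M{READ_LENGTH - k}S", seq


def _mutant_chrom(chromseq: str, ev: ClonalEvent) -> tuple[str, list]:
    """Mutant chromosome sequence for an indel plus a base->ref-pos map."""
    p = ev.pos  # anchor, 1-based; ref/alt VCF-style
    if len(ev.ref) > len(ev.alt):  # deletion
        d = len(ev.ref) - len(ev.alt)
        mut = chromseq[:p] + chromseq[p + d :]
        ref_of = lambda m: m + 1 if m < p else m + 1 + d  # noqa: E731
    else:  # insertion
        ins = ev.alt[len(ev.ref) :]
        d = len(ins)
        mut = chromseq[:p] + ins + chromseq[p:]
        ref_of = lambda m: m + 1 if m < p else (None if m < p + d else m + 1 - d)  # noqa: E731
    return mut, ref_of


def _indel_read(mut: str, ref_of, m_start0: int) -> tuple[int, str, str]:
    seq = mut[m_start0 : m_start0 + READ_LENGTH]
    positions = [ref_of(m) for m in range(m_start0, m_start0 + len(seq))]
    pos, cigar = _compress_cigar(positions)
    return pos, cigar, seq


def simulate_patient_reads(
    spec: PatientSpec, genome: ReferenceGenome
) -> tuple[list[_Read], pd.DataFrame]:
    """Simulate one patient's paired-end records plus their truth rows.

    Returns unsorted read records (see :func:`write_sam` for output) and a
    truth table with the realized events, cell fractions and the expected
    VAF/BAF each implies.  Deterministic for a fixed ``spec.seed``.
    """
    if not spec.regions:
        raise ValueError("PatientSpec.regions must name at least one target region")
    rng = np.random.default_rng(spec.seed)
    for ev in spec.events:
        for c, p in ((ev.chrom, ev.pos), (ev.chrom2, ev.pos2)):
            if c is not None and c not in genome:
                raise ValueError(f"event chromosome {c!r} not in reference")
            if c is not None and p is not None and not 1 <= p <= genome.length(c):
                raise ValueError(f"event position {c}:{p} outside reference")

    reads: list[_Read] = []
    het_by_chrom: dict[str, dict[int, str]] = {}
    for g in spec.het_snp_positions:
        alt = _COMPLEMENT[genome.base(g)]
        het_by_chrom.setdefault(g.chrom, {})[g.pos] = alt

    for ridx, (chrom, rstart, rend) in enumerate(spec.regions):
        chromseq = genome.chromosomes[chrom]
        region_len = rend - rstart + 1
        if region_len < FRAGMENT_LENGTH:
            raise ValueError(f"region {chrom}:{rstart}-{rend} shorter than a fragment")
        n_frags = max(1, round(spec.mean_depth * region_len / (2 * READ_LENGTH)))
        starts = rng.integers(rstart, rend - FRAGMENT_LENGTH + 2, size=n_frags)
        ends = starts + FRAGMENT_LENGTH - 1

        hap_b = rng.random(n_frags) < 0.5
        for ev in spec.events:
            if ev.kind == "het_deletion" and ev.chrom == chrom:
                overlap = (starts <= ev.end) & (ends >= ev.start)
                p_b = expected_baf(ev.cell_fraction, "deleted")
                hap_b[overlap] = rng.random(int(overlap.sum())) < p_b

        sub_events = [
            ev
            for ev in spec.events
            if ev.kind == "snv" and ev.chrom == chrom and rstart <= ev.pos <= rend
        ]
        sub_masks = {
            id(ev): rng.random(n_frags) < ev.cell_fraction / 2 for ev in sub_events
        }
        indel_events = [
            ev
            for ev in spec.events
            if ev.kind == "indel" and ev.chrom == chrom and rstart <= ev.pos <= rend
        ]
        indel_masks = {
            id(ev): rng.random(n_frags) < ev.cell_fraction / 2 for ev in indel_events
        }
        indel_cache = {id(ev): _mutant_chrom(chromseq, ev) for ev in indel_events}
        trans = next(
            (
                ev
                for ev in spec.events
                if ev.kind == "translocation" and chrom in (ev.chrom, ev.chrom2)
            ),
            None,
        )
        if trans is not None:
            junction = trans.pos if chrom == trans.chrom else trans.pos2
            der = 1 if chrom == trans.chrom else 2
            crosses = (starts <= junction) & (ends > junction)
            chimeric = crosses & (rng.random(n_frags) < trans.cell_fraction / 2)
        else:
            chimeric = np.zeros(n_frags, dtype=bool)

        het_subs = het_by_chrom.get(chrom, {})
        for i in range(n_frags):
            s = int(starts[i])
            qname = f"{spec.id}:{ridx}:{i}"
            if chimeric[i]:
                c1, p1, cg1, sq1 = _derivative_read(genome, trans, der, s - 1)
                c2, p2, cg2, sq2 = _derivative_read(
                    genome, trans, der, s - 1 + FRAGMENT_LENGTH - READ_LENGTH
                )
            else:
                active_indel = next(
                    (ev for ev in indel_events if indel_masks[id(ev)][i]), None
                )
                if active_indel is not None:
                    mut, ref_of = indel_cache[id(active_indel)]
                    p1, cg1, sq1 = _indel_read(mut, ref_of, s - 1)
                    p2, cg2, sq2 = _indel_read(
                        mut, ref_of, s - 1 + FRAGMENT_LENGTH - READ_LENGTH
                    )
                    c1 = c2 = chrom
                else:
                    subs: dict[int, str] = {}
                    if hap_b[i] and het_subs:
                        for p, b in het_subs.items():
                            if s <= p <= s + FRAGMENT_LENGTH - 1:
                                subs[p] = b
                    for ev in sub_events:
                        if sub_masks[id(ev)][i] and s <= ev.pos <= s + FRAGMENT_LENGTH - 1:
                            subs[ev.pos] = ev.alt
                    sq1, cg1 = _plain_read(chromseq, chrom, s, subs)
                    sq2, cg2 = _plain_read(
                        chromseq, chrom, s + FRAGMENT_LENGTH - READ_LENGTH, subs
                    )
                    c1 = c2 = chrom
                    p1, p2 = s, s + FRAGMENT_LENGTH - READ_LENGTH
            f1, f2 = _pair_flags(c1, c2)
            reads.append(_Read(qname, c1, p1, cg1, sq1, f1, c2, p2))
            reads.append(_Read(qname, c2, p2, cg2, sq2, f2, c1, p1))

    _apply_errors(reads, spec.error_rate, rng)
    _add_duplicates(reads, spec.duplicate_rate, rng)
    truth = _truth_rows(spec)
    return reads, truth


def _apply_errors(reads: list[_Read], error_rate: float, rng: np.random.Generator) -> None:
    if error_rate <= 0 or not reads:
        return
    counts = rng.binomial(READ_LENGTH, error_rate, size=len(reads))
    for i in np.nonzero(counts)[0]:
        r = reads[i]
        chars = list(r.seq)
        for off in rng.integers(0, len(chars), size=counts[i]):
            old = chars[off]
            choices = [b for b in "ACGT" if b != old]
            chars[off] = choices[rng.integers(0, 3)]
        r.seq = "".join(chars)


def _add_duplicates(reads: list[_Read], duplicate_rate: float, rng: np.random.Generator) -> None:
    if duplicate_rate <= 0 or not reads:
        return
    n_pairs = len(reads) // 2
    n_dup = round(duplicate_rate * n_pairs)
    if n_dup == 0:
        return
    picks = rng.choice(n_pairs, size=n_dup, replace=False)
    for j in picks:
        for r in (reads[2 * j], reads[2 * j + 1]):
            d = dataclasses.replace(r, qname=r.qname + ":dup", flag=r.flag | 0x400)
            reads.append(d)


def _truth_rows(spec: PatientSpec) -> pd.DataFrame:
    rows = []
    for ev in spec.events:
        rows.append(
            {
                "patient": spec.id,
                "kind": ev.kind,
                "chrom": ev.chrom,
                "pos": ev.pos,
                "ref": ev.ref,
                "alt": ev.alt,
                "start": ev.start,
                "end": ev.end,
                "chrom2": ev.chrom2,
                "pos2": ev.pos2,
                "cell_fraction": ev.cell_fraction,
                "expected_vaf": (
                    ev.cell_fraction / 2 if ev.kind in ("snv", "indel") else np.nan
                ),
                "expected_baf": (
                    expected_baf(ev.cell_fraction, "deleted")
                    if ev.kind == "het_deletion"
                    else np.nan
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "patient", "kind", "chrom", "pos", "ref", "alt", "start", "end",
            "chrom2", "pos2", "cell_fraction", "expected_vaf", "expected_baf",
        ],
    )


def write_sam(
    reads: list[_Read], genome: ReferenceGenome, path: str | Path
) -> None:
    """Write records as a coordinate-sorted, headered SAM file."""
    header = make_sam_header(genome)
    order = {name: i for i, name in enumerate(genome.chromosomes)}
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for r in sorted(reads, key=lambda r: (order[r.chrom], r.pos)):
            a = pysam.AlignedSegment(header)
            a.query_name = r.qname
            a.flag = r.flag
            a.reference_id = order[r.chrom]
            a.reference_start = r.pos - 1
            a.mapping_quality = 60
            a.cigarstring = r.cigar
            a.query_sequence = r.seq
            a.query_qualities = pysam.qualitystring_to_array("I" * len(r.seq))
            a.next_reference_id = order[r.mate_chrom]
            a.next_reference_start = r.mate_pos - 1
            a.template_length = 0
            out.write(a)


def reads_to_segments(
    reads: list[_Read], genome: ReferenceGenome
) -> tuple[pysam.AlignmentHeader, list[pysam.AlignedSegment]]:
    """In-memory pysam records (coordinate-sorted), for pipeline use without
    touching disk."""
    header = make_sam_header(genome)
    order = {name: i for i, name in enumerate(genome.chromosomes)}
    segs = []
    for r in sorted(reads, key=lambda r: (order[r.chrom], r.pos)):
        a = pysam.AlignedSegment(header)
        a.query_name = r.qname
        a.flag = r.flag
        a.reference_id = order[r.chrom]
        a.reference_start = r.pos - 1
        a.mapping_quality = 60
        a.cigarstring = r.cigar
        a.query_sequence = r.seq
        a.query_qualities = pysam.qualitystring_to_array("I" * len(r.seq))
        a.next_reference_id = order[r.mate_chrom]
        a.next_reference_start = r.mate_pos - 1
        segs.append(a)
    return header, segs


# ---------------------------------------------------------------------------
# Cohort assembly


def _spawn_seed(master_seed: int, index: int) -> int:
    # SeedSequence mixing keeps per-patient streams independent across both
    # patients and master seeds (plain master+index arithmetic makes cohort
    # k's patient i+1 identical to cohort k+1's patient i); result < 2^31.
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0]) % (
        2**31 - 1
    )


def _sample_event_positions(
    rng: np.random.Generator,
    cds: CodingSequence,
    genome: ReferenceGenome,
    weights: dict[str, float],
    n: int,
    used: set[int],
) -> list[tuple[int, str, str]]:
    """Sample ``n`` distinct coding SNV (pos, ref, alt) triples following the
    six-class substitution spectrum (pyrimidine-reference convention)."""
    classes = list(weights)
    probs = np.array([weights[c] for c in classes])
    probs = probs / probs.sum()
    chromseq = genome.chromosomes[cds.chrom]
    lo = min(s for s, _ in cds.segments)
    hi = max(e for _, e in cds.segments)
    by_base: dict[str, list[int]] = {"C": [], "T": [], "G": [], "A": []}
    for p in range(lo, hi + 1):
        by_base[chromseq[p - 1]].append(p)
    out = []
    for _ in range(n):
        for _attempt in range(200):
            cls = classes[rng.choice(len(classes), p=probs)]
            pyr_ref, pyr_alt = cls[0], cls[2]
            if rng.random() < 0.5:
                ref, alt = pyr_ref, pyr_alt
            else:
                ref, alt = _COMPLEMENT[pyr_ref], _COMPLEMENT[pyr_alt]
            pool = by_base[ref]
            if not pool:
                continue
            pos = pool[rng.integers(0, len(pool))]
            if pos in used:
                continue
            used.add(pos)
            out.append((pos, ref, alt))
            break
    return out


def build_cohort_specs(
    spec: CohortSpec,
    genome: ReferenceGenome,
    cds: CodingSequence,
    include_deletion_patient: bool = True,
    include_translocation_patient: bool = True,
    partner_chrom: str | None = None,
) -> list[PatientSpec]:
    """Expand a :class:`CohortSpec` into concrete per-patient specs.

    Ages follow a right-skewed distribution (mean ~15 y); per-patient clone
    counts are Poisson with an age-increasing rate so older patients carry
    more clones; clone VAFs are log-uniform over ``vaf_range``.  One patient
    carries a mosaic heterozygous deletion (cell fraction 0.37) over the
    locus with informative het SNPs; one carries a reciprocal translocation
    (cell fraction 0.1) with its partner junction on ``partner_chrom``.
    """
    rng = np.random.default_rng(spec.seed)
    depth = DEPTH_REGIMES[spec.depth_regime]
    lo_vaf, hi_vaf = spec.vaf_range
    cds_lo = min(s for s, _ in cds.segments)
    cds_hi = max(e for _, e in cds.segments)
    pad = (FRAGMENT_LENGTH - READ_LENGTH) + READ_LENGTH  # one read length of context
    region = (
        cds.chrom,
        max(1, cds_lo - pad),
        min(genome.length(cds.chrom), cds_hi + pad),
    )
    if partner_chrom is None:
        partner_chrom = next(
            (c for c in genome.chromosomes if c != cds.chrom), None
        )

    patients = []
    for i in range(spec.n_patients):
        prng = np.random.default_rng(_spawn_seed(spec.seed, 1000 + i))
        age = float(np.clip(prng.gamma(2.0, 7.7), 0.47, 52.2))
        n_clones = min(8, prng.poisson(0.5 + 0.1 * age))
        used: set[int] = set()
        events = []
        triples = _sample_event_positions(
            prng, cds, genome, spec.spectrum_weights, n_clones, used
        )
        for pos, ref, alt in triples:
            vaf = float(np.exp(prng.uniform(np.log(lo_vaf), np.log(hi_vaf))))
            events.append(
                ClonalEvent(
                    "snv", cell_fraction=min(1.0, 2 * vaf),
                    chrom=cds.chrom, pos=pos, ref=ref, alt=alt,
                )
            )
        regions = [region]
        if include_deletion_patient and i == 0:
            events.append(
                ClonalEvent(
                    "het_deletion", cell_fraction=0.37,
                    chrom=cds.chrom, start=region[1], end=region[2],
                )
            )
        if (
            include_translocation_patient
            and i == 1
            and partner_chrom is not None
        ):
            junction_a = (cds_lo + cds_hi) // 2
            while junction_a in used:
                junction_a += 1
            used.add(junction_a)
            junction_b = genome.length(partner_chrom) // 2
            events.append(
                ClonalEvent(
                    "translocation", cell_fraction=0.1,
                    chrom=cds.chrom, pos=junction_a,
                    chrom2=partner_chrom, pos2=junction_b,
                )
            )
            blo = max(1, junction_b - 400)
            bhi = min(genome.length(partner_chrom), junction_b + 400)
            regions = [region, (partner_chrom, blo, bhi)]
        # every patient gets informative het SNPs in the captured locus but
        # outside the coding sequence (intron/flank-like), so constitutional
        # variation does not masquerade as somatic calls over the CDS
        snp_pool = [
            p
            for p in (cds_lo - 100, cds_lo - 50, cds_hi + 50, cds_hi + 100)
            if region[1] <= p <= region[2] and p not in used
        ]
        het_snps = [GenomicPosition(cds.chrom, p) for p in snp_pool]
        patients.append(
            PatientSpec(
                id=f"P{i + 1:02d}",
                age=age,
                events=events,
                mean_depth=depth,
                seed=_spawn_seed(spec.seed, i),
                error_rate=spec.error_rate,
                duplicate_rate=spec.duplicate_rate,
                het_snp_positions=het_snps,
                regions=regions,
            )
        )
    return patients


def simulate_cohort(
    spec: CohortSpec,
    genome: ReferenceGenome,
    cds: CodingSequence,
    out_dir: str | Path,
    **build_kwargs,
) -> pd.DataFrame:
    """Simulate a full cohort to ``out_dir``: reference FASTA, CDS table,
    one sorted SAM per patient, truth TSV and cohort metadata TSV.

    Returns the combined truth table.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(genome, out / "reference.fa")
    write_cds_table([cds], out / "cds.tsv")
    patients = build_cohort_specs(spec, genome, cds, **build_kwargs)
    truths = []
    meta = []
    for p in patients:
        reads, truth = simulate_patient_reads(p, genome)
        write_sam(reads, genome, out / f"{p.id}.sam")
        truths.append(truth)
        meta.append(
            {
                "patient": p.id,
                "age": round(p.age, 2),
                "group": p.group,
                "depth_regime": spec.depth_regime,
                "mean_depth": p.mean_depth,
            }
        )
    truth = pd.concat(truths, ignore_index=True)
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    pd.DataFrame(meta).to_csv(out / "cohort.tsv", sep="\t", index=False)
    return truth
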