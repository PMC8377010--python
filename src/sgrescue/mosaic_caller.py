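"""Duplicate-aware pileup and low-VAF somatic mutation calling.

The screening design re-implemented here: remove PCR duplicates, pile up
deduplicated reads over the target coding sequence at ultra-deep coverage,
and call an alternative allele as a somatic mosaic mutation when

1. its variant allele frequency (VAF) reaches the regime threshold
   (``vaf_min`` = 0.5% for the ~2807x locus-capture design, 0.25% for the
   ~26,873x cDNA-capture design),
2. it is supported by at least ``min_alt_reads`` deduplicated reads, and
3. the one-sided binomial tail probability of its read count under the
   per-base error rate ``epsilon`` survives a Bonferroni correction over
   (number of sites x 3 alternative alleles).

This transparent binomial-error caller stands in for black-box germline
callers: with the uniform error model of the synthetic cohorts its null is
exact, which makes type-I behaviour testable.

Calls are annotated with their coding consequence and protein change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pysam
from scipy.stats import binom

from .consequence import annotate_consequence
from .genome_model import CodingSequence, ReferenceGenome

__all__ = [
    "CallerConfig",
    "PileupSite",
    "VariantCall",
    "dedup",
    "pileup",
    "call_variants",
    "call_sam",
    "write_vcf",
    "write_calls_tsv",
    "read_calls_tsv",
]

logger = logging.getLogger(__name__)

#: VAF thresholds of the two capture regimes.
VAF_MIN_BY_MODE = {"locus": 0.005, "cdna": 0.0025}


@dataclass
class CallerConfig:
    """Thresholds of the mosaic screening step.

    ``vaf_min``: minimum VAF to consider a call somatic (0.005 or 0.0025
    depending on capture regime).  ``error_rate``: per-base sequencing error
    rate of the binomial null.  ``alpha``: family-wise significance level,
    Bonferroni-corrected over sites x 3 alternative alleles.
    ``min_alt_reads``: suppresses singleton errors at extreme depth.
    """

    vaf_min: float = 0.005
    error_rate: float = 1e-3
    alpha: float = 0.05
    multiple_testing: str = "bonferroni"
    min_alt_reads: int = 3
    min_mapq: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.vaf_min < 1:
            raise ValueError("vaf_min must be in (0, 1)")
        if not 0 < self.error_rate < self.vaf_min:
            raise ValueError("error_rate must be in (0, vaf_min)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.multiple_testing != "bonferroni":
            raise ValueError("only bonferroni multiple-testing is supported")

    @classmethod
    def for_mode(cls, mode: str, **kwargs) -> "CallerConfig":
        """Preset for ``locus`` (VAF >= 0.5%) or ``cdna`` (VAF >= 0.25%)."""
        return cls(vaf_min=VAF_MIN_BY_MODE[mode], **kwargs)


@dataclass
class PileupSite:
    """Per-position allele counts from deduplicated, CIGAR-walked reads.

    ``depth`` counts aligned (M/=/X) read bases; indel alleles are keyed by
    their VCF-style left-anchored (ref, alt) strings and anchored at the
    base before the event.
    """

    chrom: str
    pos: int
    ref_base: str
    depth: int = 0
    allele_counts: dict = field(default_factory=dict)

    def alt_alleles(self) -> list[tuple[str, str, int]]:
        """(ref, alt, count) for every non-reference allele observed."""
        out = []
        for key, count in self.allele_counts.items():
            if isinstance(key, str):
                if key != self.ref_base and key in "ACGT":
                    out.append((self.ref_base, key, count))
            else:
                ref, alt = key
                out.append((ref, alt, count))
        return out


@dataclass
class VariantCall:
    """One called mosaic mutation candidate."""

    chrom: str
    pos: int
    ref: str
    alt: str
    alt_count: int
    depth: int
    vaf: float
    p_error: float
    consequence: str
    protein_change: str


def _open_records(sam: str | Path | Iterable) -> Iterator[pysam.AlignedSegment]:
    if isinstance(sam, (str, Path)):
        with pysam.AlignmentFile(str(sam), "r") as fh:
            yield from fh
    else:
        yield from sam


def dedup(reads: Iterable[pysam.AlignedSegment]) -> Iterator[pysam.AlignedSegment]:
    """Drop duplicate-flagged records, preserving order (idempotent)."""
    for r in reads:
        if not r.is_duplicate:
            yield r


def pileup(
    reads: str | Path | Iterable,
    genome: ReferenceGenome,
    region: tuple[str, int, int],
    min_mapq: int = 1,
    remove_duplicates: bool = True,
) -> list[PileupSite]:
    """Pile up reads over ``region`` = (chrom, start, end), 1-based inclusive.

    Walks each record's CIGAR: M/=/X bases are counted toward depth and the
    observed base's allele count; I and D events are counted as indel
    alleles anchored at the preceding reference base; soft-clipped bases
    contribute nothing.  Records below ``min_mapq`` or unmapped are skipped;
    duplicate-flagged records are removed first unless told otherwise.
    """
    chrom, start, end = region
    refseq = genome.chromosomes[chrom]
    sites = {
        p: PileupSite(chrom, p, refseq[p - 1]) for p in range(start, end + 1)
    }
    stream = _open_records(reads)
    if remove_duplicates:
        stream = dedup(stream)
    n_skipped = 0
    for rec in stream:
        if rec.is_unmapped or rec.mapping_quality < min_mapq:
            n_skipped += 1
            continue
        if rec.reference_name != chrom:
            continue
        seq = rec.query_sequence
        if rec.cigartuples is None:
            continue
        consumed_q = sum(
            ln for op, ln in rec.cigartuples if op in (0, 1, 4, 7, 8)
        )
        if seq is None or consumed_q != len(seq):
            logger.warning("CIGAR/sequence length mismatch for %s; skipped", rec.query_name)
            continue
        qpos = 0
        rpos = rec.reference_start + 1  # 1-based
        for op, ln in rec.cigartuples:
            if op in (0, 7, 8):  # M, =, X
                for k in range(ln):
                    p = rpos + k
                    if start <= p <= end:
                        site = sites[p]
                        site.depth += 1
                        base = seq[qpos + k]
                        site.allele_counts[base] = site.allele_counts.get(base, 0) + 1
                qpos += ln
                rpos += ln
            elif op == 1:  # I — anchored at previous reference base
                anchor = rpos - 1
                if start <= anchor <= end:
                    ref = refseq[anchor - 1]
                    alt = ref + seq[qpos : qpos + ln]
                    key = (ref, alt)
                    site = sites[anchor]
                    site.allele_counts[key] = site.allele_counts.get(key, 0) + 1
                qpos += ln
            elif op == 2:  # D — anchored at previous reference base
                anchor = rpos - 1
                if start <= anchor <= end:
                    ref = refseq[anchor - 1 : anchor + ln]
                    alt = refseq[anchor - 1]
                    key = (ref, alt)
                    site = sites[anchor]
                    site.allele_counts[key] = site.allele_counts.get(key, 0) + 1
                rpos += ln
            elif op == 3:  # N
                rpos += ln
            elif op == 4:  # S
                qpos += ln
            # H (5) and P (6) consume nothing
    if n_skipped:
        logger.info("skipped %d unmapped/low-MAPQ records", n_skipped)
    return [sites[p] for p in range(start, end + 1)]


def call_variants(
    sites: list[PileupSite],
    cfg: CallerConfig,
    cds: CodingSequence,
    genome: ReferenceGenome,
) -> list[VariantCall]:
    """Apply the three-part calling rule to every alternative allele.

    An allele is called iff VAF >= ``cfg.vaf_min``, its read count >=
    ``cfg.min_alt_reads``, and the one-sided binomial tail
    P(X >= count | depth, error_rate) is below ``alpha`` Bonferroni-corrected
    over (number of sites x 3).  Zero-depth sites are skipped.
    """
    n_tests = 3 * len(sites)
    threshold = cfg.alpha / n_tests if n_tests else cfg.alpha
    calls = []
    for site in sites:
        if site.depth == 0:
            logger.debug("zero-depth site %s:%d skipped", site.chrom, site.pos)
            continue
        for ref, alt, count in site.alt_alleles():
            if count == 0:
                continue
            vaf = count / site.depth
            if vaf < cfg.vaf_min or count < cfg.min_alt_reads:
                continue
            p_err = float(binom.sf(count - 1, site.depth, cfg.error_rate))
            if p_err >= threshold:
                continue
            csq, pchange = annotate_consequence(
                genome, cds, site.chrom, site.pos, ref, alt
            )
            calls.append(
                VariantCall(
                    chrom=site.chrom,
                    pos=site.pos,
                    ref=ref,
                    alt=alt,
                    alt_count=count,
                    depth=site.depth,
                    vaf=vaf,
                    p_error=p_err,
                    consequence=csq,
                    protein_change=pchange,
                )
            )
    return calls


def call_sam(
    sam: str | Path | Iterable,
    genome: ReferenceGenome,
    cds: CodingSequence,
    cfg: CallerConfig | None = None,
    region: tuple[str, int, int] | None = None,
) -> list[VariantCall]:
    """End-to-end: dedup -> pileup -> call over the CDS footprint (or an
    explicit region)."""
    cfg = cfg or CallerConfig()
    if region is None:
        lo = min(s for s, _ in cds.segments)
        hi = max(e for _, e in cds.segments)
        region = (cds.chrom, lo, hi)
    sites = pileup(sam, genome, region, min_mapq=cfg.min_mapq)
    return call_variants(sites, cfg, cds, genome)


# ---------------------------------------------------------------------------
# Output formats


def write_vcf(
    calls: list[VariantCall], genome: ReferenceGenome, path: str | Path
) -> None:
    """Write calls as VCF 4.2 with INFO fields VAF, DP, AC, PERR, CSQ."""
    header = pysam.VariantHeader()
    for name, seq in genome.chromosomes.items():
        header.contigs.add(name, length=len(seq))
    header.info.add("VAF", 1, "Float", "Variant allele frequency")
    header.info.add("DP", 1, "Integer", "Deduplicated depth")
    header.info.add("AC", "A", "Integer", "Alternative allele read count")
    header.info.add("PERR", 1, "Float", "Binomial tail p under the error model")
    header.info.add("CSQ", 1, "String", "Consequence class and protein change")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for c in sorted(calls, key=lambda c: (c.chrom, c.pos)):
            rec = out.new_record(
                contig=c.chrom,
                start=c.pos - 1,
                alleles=(c.ref, c.alt),
            )
            rec.info["VAF"] = c.vaf
            rec.info["DP"] = c.depth
            rec.info["AC"] = c.alt_count
            rec.info["PERR"] = c.p_error
            csq = c.consequence + (f"|{c.protein_change}" if c.protein_change else "")
            rec.info["CSQ"] = csq
            out.write(rec)


_TSV_COLUMNS = [
    "chrom", "pos", "ref", "alt", "alt_count", "depth", "vaf",
    "p_error", "consequence", "protein_change",
]


def write_calls_tsv(calls: list[VariantCall], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame([vars(c) for c in calls], columns=_TSV_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def read_calls_tsv(path: str | Path):
    import pandas as pd

    return pd.read_csv(
        path, sep="\t", dtype={"chrom": str}, keep_default_na=False,
        na_values=[""],
    )
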