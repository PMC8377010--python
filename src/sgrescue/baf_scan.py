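"""Mosaic heterozygous-deletion detection from B-allele frequencies.

At a constitutional heterozygous SNP the two alleles are balanced (BAF 0.5)
in diploid cells.  A heterozygous deletion present in a cell fraction ``f``
removes one allele's copy in those cells, shifting the deleted allele's
expected BAF to ``(1-f)/(2-f)``.  This module tests each SNP for deviation
from 0.5 with an exact two-sided binomial test (Bonferroni over SNPs),
groups runs of consecutive deviating SNPs into segments, and inverts the
BAF relation to estimate the affected cell fraction:

    f_hat = (1 - 2*BAF_minor) / (1 - BAF_minor)

The minor-allele convention (min(BAF, 1-BAF)) makes results independent of
which allele the upstream genotyper labelled "B" — phase is unobservable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy.stats import binomtest

__all__ = [
    "HetSNP",
    "BafSegment",
    "compute_baf",
    "detect_deviation",
    "estimate_cell_fraction",
    "scan_snp_table",
    "read_het_snps_vcf",
    "write_segments_tsv",
]


@dataclass
class HetSNP:
    """Allele counts at one constitutional heterozygous SNP."""

    chrom: str
    pos: int
    a_count: int
    b_count: int
    baf: float
    p_dev: float


@dataclass
class BafSegment:
    """A run of consecutive BAF-deviating SNPs with its cell-fraction
    estimate."""

    chrom: str
    start: int
    end: int
    snp_positions: list[int]
    mean_minor_baf: float
    cell_fraction: float
    p_min: float
    deviating: bool

    @property
    def n_snps(self) -> int:
        return len(self.snp_positions)


def compute_baf(chrom: str, pos: int, a_count: int, b_count: int) -> HetSNP:
    """BAF = b/(a+b) and exact two-sided binomial p-value against 0.5."""
    n = a_count + b_count
    if n < 1:
        raise ValueError(f"zero total allele count at {chrom}:{pos}")
    baf = b_count / n
    p = binomtest(b_count, n, 0.5, alternative="two-sided").pvalue
    return HetSNP(chrom, pos, a_count, b_count, baf, float(p))


def estimate_cell_fraction(minor_baf: float) -> float:
    """Invert the deletion-BAF relation for the minor allele.

    For a deletion in fraction ``f`` of cells the minor-allele BAF is
    ``(1-f)/(2-f)``; solving for ``f`` gives ``(1-2b)/(1-b)``.
    """
    if not 0 <= minor_baf <= 0.5:
        raise ValueError(
            f"minor-allele BAF must be in [0, 0.5], got {minor_baf} "
            "(pass min(baf, 1-baf))"
        )
    return (1.0 - 2.0 * minor_baf) / (1.0 - minor_baf)


def detect_deviation(
    snps: list[HetSNP],
    alpha: float = 0.05,
    multiple_testing: str = "bonferroni",
    min_snps: int = 2,
) -> list[BafSegment]:
    """Group runs of significantly-deviating SNPs into deletion candidates.

    A SNP deviates when its exact binomial p-value is below
    ``alpha / n_snps`` (Bonferroni).  Maximal runs of at least ``min_snps``
    consecutive deviating SNPs (minor allele below 0.5 throughout, by
    construction of the minor-allele convention) become segments with a
    pooled cell-fraction estimate from the mean minor-allele BAF.
    """
    if multiple_testing != "bonferroni":
        raise ValueError("only bonferroni multiple-testing is supported")
    if min_snps < 1:
        raise ValueError("min_snps must be >= 1")
    snps = sorted(snps, key=lambda s: (s.chrom, s.pos))
    n = len(snps)
    if n == 0:
        return []
    cutoff = alpha / n
    segments: list[BafSegment] = []
    run: list[HetSNP] = []

    def flush(run: list[HetSNP]) -> None:
        if len(run) >= min_snps:
            minor = [min(s.baf, 1 - s.baf) for s in run]
            mean_minor = sum(minor) / len(minor)
            segments.append(
                BafSegment(
                    chrom=run[0].chrom,
                    start=run[0].pos,
                    end=run[-1].pos,
                    snp_positions=[s.pos for s in run],
                    mean_minor_baf=mean_minor,
                    cell_fraction=estimate_cell_fraction(min(mean_minor, 0.5)),
                    p_min=min(s.p_dev for s in run),
                    deviating=True,
                )
            )

    for s in snps:
        if s.p_dev < cutoff:
            if run and run[-1].chrom != s.chrom:
                flush(run)
                run = []
            run.append(s)
        else:
            flush(run)
            run = []
    flush(run)
    return segments


def scan_snp_table(
    table: pd.DataFrame,
    alpha: float = 0.05,
    min_snps: int = 2,
) -> tuple[list[HetSNP], list[BafSegment]]:
    """Run the full scan on a table with columns chrom, pos, a_count,
    b_count."""
    snps = [
        compute_baf(str(r.chrom), int(r.pos), int(r.a_count), int(r.b_count))
        for r in table.itertuples()
    ]
    return snps, detect_deviation(snps, alpha=alpha, min_snps=min_snps)


def read_het_snps_vcf(path: str | Path) -> pd.DataFrame:
    """Read constitutional het SNPs with allelic depths (FORMAT/AD) from a
    VCF into the chrom/pos/a_count/b_count table the scan consumes."""
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for sample in rec.samples.values():
                ad = sample.get("AD")
                if ad is None or len(ad) < 2:
                    continue
                rows.append(
                    {
                        "chrom": rec.chrom,
                        "pos": rec.pos,
                        "a_count": int(ad[0]),
                        "b_count": int(ad[1]),
                    }
                )
                break
    return pd.DataFrame(rows, columns=["chrom", "pos", "a_count", "b_count"])


def write_segments_tsv(segments: list[BafSegment], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "n_snps": s.n_snps,
                "mean_minor_baf": s.mean_minor_baf,
                "cell_fraction": s.cell_fraction,
                "p": s.p_min,
            }
            for s in segments
        ],
        columns=["chrom", "start", "end", "n_snps", "mean_minor_baf", "cell_fraction", "p"],
    ).to_csv(path, sep="\t", index=False)
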