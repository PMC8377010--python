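"""Translocation breakpoint localization from soft-clipped chimeric reads.

Reads spanning a translocation junction align to one chromosome up to the
breakpoint and carry the partner chromosome's sequence as a soft clip
(CIGAR ``S``).  The procedure:

1. extract every MAPQ>=1 read on the source chromosome whose CIGAR contains
   a soft clip and compute its *last aligned position* (alignment start plus
   the reference-consuming CIGAR lengths, minus one);
2. cluster these putative breakpoints by position (book-ended merge:
   adjacent positions join one cluster);
3. retain clusters whose distinct mate-chromosome set is exactly
   {same-chromosome, partner} — junction-spanning fragments produce both
   same-chromosome and inter-chromosomal mates at the true breakpoint,
   while a third mate chromosome marks an artifact.

Reference-consuming CIGAR operations are M, D, N, = and X; I, S, H and P
advance the reference by nothing.  (A widespread shell recipe for this step
recognizes only M and D; aligners may emit =/X/N, so the full set is used
here.  On M/D-only CIGARs the two agree exactly.)

Coordinates reported are 1-based last-aligned positions.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
import pysam

__all__ = [
    "ClipEndpoint",
    "BreakpointCluster",
    "last_aligned_pos",
    "extract_endpoints",
    "cluster_endpoints",
    "filter_clusters",
    "locate_breakpoints",
    "write_clusters_tsv",
]

logger = logging.getLogger(__name__)

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
REF_CONSUMING = frozenset("MDN=X")


@dataclass
class ClipEndpoint:
    """A soft-clipped read's candidate breakpoint."""

    chrom: str
    last_aligned_pos: int
    cigar: str
    mate_chrom: str  # "=" for same-chromosome mates
    mapq: int


@dataclass
class BreakpointCluster:
    """A positional cluster of clip endpoints."""

    chrom: str
    start: int
    end: int
    n_endpoints: int
    mate_chroms: frozenset
    n_interchromosomal_mates: int
    retained: bool = False


def last_aligned_pos(pos: int, cigar: str) -> int:
    """1-based position of the final reference-consuming base of an
    alignment starting at 1-based ``pos``.

    Adds the lengths of M/D/N/=/X operations and subtracts one; I, S, H and
    P consume no reference.
    """
    if not cigar or cigar == "*":
        raise ValueError(f"cannot compute end of unaligned CIGAR {cigar!r}")
    consumed = 0
    matched = 0
    for m in _CIGAR_RE.finditer(cigar):
        matched += len(m.group(0))
        if m.group(2) in REF_CONSUMING:
            consumed += int(m.group(1))
    if matched != len(cigar):
        raise ValueError(f"malformed CIGAR {cigar!r}")
    if consumed == 0:
        raise ValueError(f"CIGAR {cigar!r} consumes no reference")
    return pos + consumed - 1


def extract_endpoints(
    records: Iterable[pysam.AlignedSegment],
    source_chrom: str,
    min_mapq: int = 1,
) -> list[ClipEndpoint]:
    """One endpoint per soft-clipped, MAPQ-passing record on
    ``source_chrom``.

    The mate chromosome is kept as "=" when the mate maps to the same
    chromosome, mirroring the SAM RNEXT convention.
    """
    out = []
    n_unmapped = 0
    for rec in records:
        if rec.is_unmapped:
            n_unmapped += 1
            continue
        if rec.reference_name != source_chrom:
            continue
        if rec.mapping_quality < min_mapq:
            continue
        cigar = rec.cigarstring
        if cigar is None or "S" not in cigar:
            continue
        if rec.next_reference_id < 0:
            mate = "*"
        elif rec.next_reference_name == rec.reference_name:
            mate = "="
        else:
            mate = rec.next_reference_name
        out.append(
            ClipEndpoint(
                chrom=source_chrom,
                last_aligned_pos=last_aligned_pos(rec.reference_start + 1, cigar),
                cigar=cigar,
                mate_chrom=mate,
                mapq=rec.mapping_quality,
            )
        )
    if n_unmapped:
        logger.info("skipped %d unmapped records", n_unmapped)
    return out


def cluster_endpoints(
    endpoints: list[ClipEndpoint], max_gap: int = 1
) -> list[BreakpointCluster]:
    """Merge endpoints whose positions differ by at most ``max_gap``.

    The default of 1 reproduces the book-ended merge of adjacent 1-bp
    intervals (``bedtools merge -d 0`` semantics on the endpoint stream).
    """
    if not endpoints:
        return []
    chroms = {e.chrom for e in endpoints}
    if len(chroms) > 1:
        raise ValueError(f"endpoints span multiple chromosomes: {sorted(chroms)}")
    eps = sorted(endpoints, key=lambda e: e.last_aligned_pos)
    clusters = []
    current = [eps[0]]
    for e in eps[1:]:
        if e.last_aligned_pos - current[-1].last_aligned_pos <= max_gap:
            current.append(e)
        else:
            clusters.append(_make_cluster(current))
            current = [e]
    clusters.append(_make_cluster(current))
    return clusters


def _make_cluster(members: list[ClipEndpoint]) -> BreakpointCluster:
    mates = frozenset(e.mate_chrom for e in members)
    n_inter = sum(1 for e in members if e.mate_chrom not in ("=", "*"))
    return BreakpointCluster(
        chrom=members[0].chrom,
        start=members[0].last_aligned_pos,
        end=members[-1].last_aligned_pos,
        n_endpoints=len(members),
        mate_chroms=mates,
        n_interchromosomal_mates=n_inter,
    )


def filter_clusters(
    clusters: list[BreakpointCluster],
    partner_chrom: str,
) -> list[BreakpointCluster]:
    """Set ``retained`` on clusters whose distinct mate-chromosome set is
    exactly {"=", partner}: both same-chromosome and partner mates present,
    and no third chromosome."""
    wanted = frozenset({"=", partner_chrom})
    for c in clusters:
        c.retained = c.mate_chroms == wanted
    return clusters


def locate_breakpoints(
    sam: str | Path | Iterable,
    chrom_a: str,
    chrom_b: str,
    min_mapq: int = 1,
    max_gap: int = 1,
) -> dict[str, list[BreakpointCluster]]:
    """Run the extract -> cluster -> filter chain on both chromosomes, each
    with the other as translocation partner.

    Returns {chromosome: clusters}, every cluster carrying its window,
    endpoint support and inter-chromosomal mate count.  An empty retained
    set is a diagnostic outcome, not an error.
    """
    if isinstance(sam, (str, Path)):
        with pysam.AlignmentFile(str(sam), "r") as fh:
            records = list(fh)
    else:
        records = list(sam)
    result: dict[str, list[BreakpointCluster]] = {}
    for source, partner in ((chrom_a, chrom_b), (chrom_b, chrom_a)):
        eps = extract_endpoints(records, source, min_mapq=min_mapq)
        by_pos = cluster_endpoints(eps, max_gap=max_gap) if eps else []
        result[source] = filter_clusters(by_pos, partner)
        if not any(c.retained for c in result[source]):
            logger.info("no retained breakpoint cluster on %s", source)
    return result


def write_clusters_tsv(
    result: dict[str, list[BreakpointCluster]], path: str | Path
) -> None:
    rows = []
    for chrom, clusters in result.items():
        for c in clusters:
            rows.append(
                {
                    "chrom": chrom,
                    "window_start": c.start,
                    "window_end": c.end,
                    "n_endpoints": c.n_endpoints,
                    "mate_set": ",".join(sorted(c.mate_chroms)),
                    "n_interchrom_mates": c.n_interchromosomal_mates,
                    "retained": c.retained,
                }
            )
    pd.DataFrame(
        rows,
        columns=[
            "chrom", "window_start", "window_end", "n_endpoints",
            "mate_set", "n_interchrom_mates", "retained",
        ],
    ).to_csv(path, sep="\t", index=False)
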