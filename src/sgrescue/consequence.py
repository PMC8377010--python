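"""Consequence classification of variants against a coding sequence.

Shared by the mosaic caller (annotating genomic calls) and the SNV-space
enumerator (classifying every possible coding substitution).  Classes:

- ``synonymous``   — codon change preserving the amino acid (including
  stop-to-stop changes in the terminal codon)
- ``missense``     — amino-acid substitution
- ``nonsense``     — amino acid to stop (stop-gain)
- ``stop_loss``    — terminal stop codon to an amino acid
- ``start_loss``   — any change destroying the initiator ATG
- ``frameshift``   — indel whose length difference is not a multiple of 3
- ``inframe_indel``— indel with length difference divisible by 3
- ``noncoding``    — outside the CDS segments

``protein_change`` follows the usual one-letter convention, e.g. ``N106S``,
``M1L``, ``Q93*``, with ``*`` for stop.
"""

from __future__ import annotations

from Bio.Seq import Seq

from .genome_model import (
    CodingSequence,
    GenomicPosition,
    ReferenceGenome,
    STOP_CODONS,
    genomic_to_cds_pos,
)

__all__ = ["classify_cds_snv", "annotate_consequence", "NONSYNONYMOUS_CLASSES"]

#: SNV classes counted as non-synonymous in dN/dS site counting.
NONSYNONYMOUS_CLASSES = frozenset({"missense", "nonsense", "stop_loss", "start_loss"})

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _aa(codon: str) -> str:
    return str(Seq(codon).translate(table=1))


def classify_cds_snv(cds: CodingSequence, cds_pos: int, alt: str) -> tuple[str, str]:
    """Classify a single-base substitution given in CDS coordinates.

    ``cds_pos`` is the 1-based offset in the spliced CDS and ``alt`` the
    substituted base *on the coding strand*.  Returns
    ``(consequence, protein_change)``.
    """
    seq = cds.cds_seq
    if not 1 <= cds_pos <= len(seq):
        raise ValueError(f"CDS position {cds_pos} outside 1..{len(seq)}")
    ref = seq[cds_pos - 1]
    if alt == ref:
        raise ValueError(f"alt base equals reference base {ref!r} at CDS {cds_pos}")
    if "N" in (ref, alt):
        raise ValueError("cannot classify substitutions involving N")

    codon_index = (cds_pos - 1) // 3 + 1
    within = (cds_pos - 1) % 3
    ref_codon = cds.codon(codon_index)
    alt_codon = ref_codon[:within] + alt + ref_codon[within + 1 :]

    if codon_index == 1:
        # The initiator is the only ATG-coded Met; any change destroys it.
        return "start_loss", f"M1{_aa(alt_codon)}"
    ref_aa = _aa(ref_codon)
    alt_aa = _aa(alt_codon)
    change = f"{ref_aa}{codon_index}{alt_aa}"
    if ref_codon in STOP_CODONS:
        if alt_codon in STOP_CODONS:
            return "synonymous", change
        return "stop_loss", change
    if alt_aa == ref_aa:
        return "synonymous", change
    if alt_aa == "*":
        return "nonsense", change
    return "missense", change


def annotate_consequence(
    genome: ReferenceGenome,
    cds: CodingSequence,
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
) -> tuple[str, str]:
    """Classify a genomic variant (VCF-style alleles) against ``cds``.

    SNVs use codon comparison; indels are classified by frame effect only.
    ``ref`` must match the reference sequence at ``pos`` (left-anchored for
    indels).  Returns ``(consequence, protein_change)``.
    """
    actual = genome.fetch(chrom, pos, pos + len(ref) - 1)
    if actual != ref:
        raise ValueError(
            f"reference mismatch at {chrom}:{pos}: expected {ref!r}, found {actual!r}"
        )

    if len(ref) == 1 and len(alt) == 1:
        cds_pos = genomic_to_cds_pos(cds, GenomicPosition(chrom, pos))
        if cds_pos is None:
            return "noncoding", ""
        alt_cs = alt if cds.strand == "+" else alt.translate(_COMPLEMENT)
        return classify_cds_snv(cds, cds_pos, alt_cs)

    # Indel: coding iff any altered base (deleted span, or the insertion
    # anchor) falls inside a CDS segment.
    if len(ref) > len(alt):  # deletion of ref[len(alt):]
        affected = range(pos + len(alt), pos + len(ref))
    else:  # insertion between pos and pos+1
        affected = range(pos, pos + 1)
    hit = None
    for p in affected:
        cp = genomic_to_cds_pos(cds, GenomicPosition(chrom, p))
        if cp is not None:
            hit = cp
            break
    if hit is None:
        return "noncoding", ""
    delta = len(alt) - len(ref)
    codon_index = (hit - 1) // 3 + 1
    ref_aa = _aa(cds.codon(codon_index))
    if delta % 3 != 0:
        return "frameshift", f"{ref_aa}{codon_index}fs"
    return "inframe_indel", f"{ref_aa}{codon_index}delins"
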