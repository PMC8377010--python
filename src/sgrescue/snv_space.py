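"""Exhaustive SNV-space enumeration, dN/dS and score-background comparison.

For a CDS of length L there are exactly 3L possible single-nucleotide
variants.  Enumerating and classifying all of them gives the neutral
expectation for selection statistics:

- the *expected* non-synonymous/synonymous ratio ``N/S`` is the ratio of
  possible non-synonymous to possible synonymous SNVs (simple unweighted
  site counting; no transition/transversion bias);
- the observed-count ratio normalized by the expected ratio is dN/dS, with
  1 indicating neutrality and >1 positive selection for protein-altering
  variants;
- a deleteriousness score table (e.g. CADD, consumed as data) supports an
  unpaired t-test of observed variants' scores against the full space.

Nonsense, stop-loss and start-loss changes count as non-synonymous, so
dN/dS of the whole space is exactly 1 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .consequence import NONSYNONYMOUS_CLASSES, classify_cds_snv
from .genome_model import CodingSequence, cds_to_genomic_pos

__all__ = [
    "SnvSpace",
    "enumerate_snvs",
    "expected_ns_ratio",
    "observed_dnds",
    "dnds_from_counts",
    "score_background_test",
    "read_score_table",
    "attach_scores",
]

_ALL_BASES = "ACGT"


@dataclass
class SnvSpace:
    """All 3L possible SNVs of a CDS with their consequence classes.

    ``records`` columns: cds_pos, chrom, genomic_pos, ref, alt, codon_index,
    consequence, protein_change (ref/alt on the coding strand).
    """

    cds_name: str
    records: pd.DataFrame

    @property
    def size(self) -> int:
        return len(self.records)

    @property
    def class_counts(self) -> dict[str, int]:
        return self.records["consequence"].value_counts().to_dict()


def enumerate_snvs(cds: CodingSequence) -> SnvSpace:
    """Enumerate and classify every possible SNV of ``cds`` (3 per base)."""
    if "N" in cds.cds_seq:
        raise ValueError("CDS contains N bases; enumeration refuses to guess")
    rows = []
    for cds_pos in range(1, len(cds.cds_seq) + 1):
        ref = cds.cds_seq[cds_pos - 1]
        g = cds_to_genomic_pos(cds, cds_pos)
        for alt in _ALL_BASES:
            if alt == ref:
                continue
            csq, pchange = classify_cds_snv(cds, cds_pos, alt)
            rows.append(
                {
                    "cds_pos": cds_pos,
                    "chrom": g.chrom,
                    "genomic_pos": g.pos,
                    "ref": ref,
                    "alt": alt,
                    "codon_index": (cds_pos - 1) // 3 + 1,
                    "consequence": csq,
                    "protein_change": pchange,
                }
            )
    return SnvSpace(cds.name, pd.DataFrame(rows))


def _split_ns(consequences: pd.Series) -> tuple[int, int]:
    n = int(consequences.isin(NONSYNONYMOUS_CLASSES).sum())
    s = int((consequences == "synonymous").sum())
    return n, s


def expected_ns_ratio(space: SnvSpace, exclude_start_loss: bool = False) -> float:
    """Possible non-synonymous over possible synonymous SNVs (neutral
    expectation for the observed N/S count ratio)."""
    records = space.records
    if exclude_start_loss:
        records = records[records["consequence"] != "start_loss"]
    n, s = _split_ns(records["consequence"])
    if s == 0:
        raise ValueError("degenerate CDS: no synonymous SNV possible")
    return n / s


def observed_dnds(
    observed: pd.DataFrame,
    space: SnvSpace,
    exclude_start_loss: bool = False,
) -> float:
    """(observed N / observed S) normalized by the space's possible-site
    ratio.

    ``observed`` needs a ``consequence`` column using the same classes as
    the space (indels are not part of dN/dS and must be excluded by the
    caller).  With the whole space as input the result is exactly 1.
    """
    obs = observed
    if exclude_start_loss:
        obs = obs[obs["consequence"] != "start_loss"]
    n_obs, s_obs = _split_ns(obs["consequence"])
    return dnds_from_counts(n_obs, s_obs, space, exclude_start_loss=exclude_start_loss)


def dnds_from_counts(
    n_obs: int,
    s_obs: int,
    space: SnvSpace,
    exclude_start_loss: bool = False,
) -> float:
    """dN/dS from pre-tabulated observed class counts."""
    if s_obs == 0:
        raise ValueError(
            "no observed synonymous SNV; dN/dS undefined "
            "(a pseudocount option would be needed, and is off by default)"
        )
    exp_ratio = expected_ns_ratio(space, exclude_start_loss=exclude_start_loss)
    return (n_obs / s_obs) / exp_ratio


def read_score_table(path: str | Path) -> dict[tuple[int, str, str], float]:
    """Read a 4-column TSV (cds_pos, ref, alt, score) into a lookup table."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["cds_pos", "ref", "alt", "score"],
    )
    table = {
        (int(r.cds_pos), str(r.ref), str(r.alt)): float(r.score)
        for r in df.itertuples()
    }
    if any(not np.isfinite(v) for v in table.values()):
        raise ValueError("score table contains non-finite scores")
    return table


def attach_scores(
    records: pd.DataFrame, table: dict[tuple[int, str, str], float]
) -> pd.DataFrame:
    """Add a ``score`` column by (cds_pos, ref, alt) lookup."""
    out = records.copy()
    out["score"] = [
        table.get((int(r.cds_pos), r.ref, r.alt)) for r in records.itertuples()
    ]
    return out


def score_background_test(
    observed: pd.DataFrame,
    space: SnvSpace,
    table: dict[tuple[int, str, str], float],
    welch: bool = False,
) -> dict:
    """Unpaired t-test of observed variants' scores vs the full SNV space.

    Returns mean_obs, mean_all, t, df and the two-sided p-value.
    Equal-variance Student's t by default; Welch via ``welch=True``.
    Every observed SNV must have a score in ``table``.
    """
    from .cohort_report import unpaired_t

    obs_scores = []
    missing = []
    for r in observed.itertuples():
        key = (int(r.cds_pos), r.ref, r.alt)
        if key not in table:
            missing.append(key)
        else:
            obs_scores.append(table[key])
    if missing:
        raise ValueError(f"missing scores for observed SNVs: {missing}")
    if len(obs_scores) < 2:
        raise ValueError("need at least 2 observed scored SNVs")
    all_scores = [
        table[(int(r.cds_pos), r.ref, r.alt)]
        for r in space.records.itertuples()
        if (int(r.cds_pos), r.ref, r.alt) in table
    ]
    res = unpaired_t(obs_scores, all_scores, welch=welch)
    res["mean_obs"] = float(np.mean(obs_scores))
    res["mean_all"] = float(np.mean(all_scores))
    return res
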