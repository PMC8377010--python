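"""Cohort-level aggregation: per-patient summaries, mutation classification,
substitution spectrum, and count-versus-age correlation.

Percentages are rendered to one decimal place in reports while raw
fractions stay available in machine output.  The substitution spectrum uses
the standard pyrimidine-reference six-class convention (C>A, C>G, C>T, T>A,
T>C, T>G): substitutions with a purine reference are complemented into
their pyrimidine class (G>A becomes C>T).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SPECTRUM_CLASSES",
    "pct1",
    "summarize_patients",
    "classify_mutation_table",
    "substitution_spectrum",
    "correlate_count_age",
    "correlate",
    "unpaired_t",
    "make_report",
]

SPECTRUM_CLASSES = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def pct1(count: int, total: int) -> float:
    """Percentage truncated (not rounded) to one decimal place, the
    fixed-point display convention of clinical cohort tables
    (17/26 -> 65.3, 31/56 -> 55.3)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return (1000 * count // total) / 10


def summarize_patients(
    calls_by_patient: dict[str, pd.DataFrame],
    metadata: pd.DataFrame,
) -> pd.DataFrame:
    """One summary row per patient: mutation count, cumulative and maximum
    VAF, and per-class counts.

    ``calls_by_patient`` maps patient id to a call table (columns including
    vaf and consequence; possibly empty).  ``metadata`` needs columns
    patient, age and optionally group.  Rows are ordered by patient id.
    """
    if metadata["patient"].duplicated().any():
        dupes = metadata.loc[metadata["patient"].duplicated(), "patient"].tolist()
        raise ValueError(f"duplicate patient ids: {dupes}")
    meta = metadata.set_index("patient")
    rows = []
    for pid in sorted(meta.index):
        calls = calls_by_patient.get(pid)
        if calls is None or len(calls) == 0:
            n, cum, mx, classes = 0, 0.0, 0.0, {}
        else:
            n = len(calls)
            cum = float(calls["vaf"].sum())
            mx = float(calls["vaf"].max())
            classes = calls["consequence"].value_counts().to_dict()
        row = {
            "patient": pid,
            "age": float(meta.loc[pid, "age"]),
            "group": meta.loc[pid].get("group", "affected"),
            "n_mutations": n,
            "cumulative_vaf": cum,
            "max_vaf": mx,
        }
        row.update({f"n_{k}": v for k, v in classes.items()})
        rows.append(row)
    return pd.DataFrame(rows).fillna(0)


def _is_snv(ref: str, alt: str) -> bool:
    return len(ref) == 1 and len(alt) == 1 and ref in "ACGT" and alt in "ACGT"


def classify_mutation_table(calls: pd.DataFrame) -> dict:
    """Counts and 1-d.p. percentages over SNV/non-SNV and consequence
    classes.  Empty input yields zero counts and no percentages."""
    total = len(calls)
    out: dict = {"n_total": total, "counts": {}, "percentages": {}}
    if total == 0:
        return out
    n_snv = int(
        sum(_is_snv(str(r.ref), str(r.alt)) for r in calls.itertuples())
    )
    counts = calls["consequence"].value_counts().to_dict()
    counts["snv"] = n_snv
    counts["non_snv"] = total - n_snv
    out["counts"] = counts
    out["percentages"] = {k: pct1(v, total) for k, v in counts.items()}
    return out


def substitution_spectrum(calls: pd.DataFrame) -> dict[str, float]:
    """Six-class fractions of an SNV table (pyrimidine-reference
    convention).  Non-SNV rows raise."""
    if len(calls) == 0:
        return {c: 0.0 for c in SPECTRUM_CLASSES}
    counts = {c: 0 for c in SPECTRUM_CLASSES}
    for r in calls.itertuples():
        ref, alt = str(r.ref), str(r.alt)
        if not _is_snv(ref, alt):
            raise ValueError(f"non-SNV row in spectrum input: {ref}>{alt}")
        if ref in "GA":
            ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        counts[f"{ref}>{alt}"] += 1
    total = sum(counts.values())
    return {c: counts[c] / total for c in SPECTRUM_CLASSES}


def correlate(x, y) -> dict:
    """Pearson r with a two-tailed p-value from the t-approximation
    (t = r*sqrt((n-2)/(1-r^2)) on n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the variables")
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p_two_sided": float(p), "n": n}


def correlate_count_age(summaries: pd.DataFrame) -> dict:
    """Pearson correlation of per-patient mutation count against age."""
    return correlate(summaries["age"], summaries["n_mutations"])


def unpaired_t(group_a, group_b, welch: bool = False) -> dict:
    """Two-sample unpaired t-test (equal-variance Student's t by default,
    Welch-Satterthwaite when ``welch``); two-tailed p."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = np.concatenate([a, b])
    if np.allclose(pooled, pooled[0]):
        raise ValueError("all values identical; t undefined")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    df = res.df if hasattr(res, "df") else (len(a) + len(b) - 2)
    return {"t": float(res.statistic), "df": float(df), "p": float(res.pvalue)}


def make_report(
    calls_by_patient: dict[str, pd.DataFrame],
    metadata: pd.DataFrame,
) -> dict:
    """Full cohort report: group sizes, carrier fraction, classification
    table, spectrum, and the count~age / cumulative-VAF~age correlations.

    Deterministic for fixed inputs: regeneration is byte-identical.
    """
    summaries = summarize_patients(calls_by_patient, metadata)
    all_calls = [df for df in calls_by_patient.values() if df is not None and len(df)]
    calls = (
        pd.concat(all_calls, ignore_index=True)
        if all_calls
        else pd.DataFrame(columns=["ref", "alt", "vaf", "consequence"])
    )
    snv_mask = [
        _is_snv(str(r.ref), str(r.alt)) for r in calls.itertuples()
    ]
    snvs = calls[snv_mask] if len(calls) else calls
    n_patients = len(summaries)
    n_carriers = int((summaries["n_mutations"] > 0).sum())
    report = {
        "group_sizes": summaries["group"].value_counts().to_dict(),
        "n_patients": n_patients,
        "n_carriers": n_carriers,
        "carrier_fraction": n_carriers / n_patients if n_patients else np.nan,
        "carrier_pct": pct1(n_carriers, n_patients) if n_patients else np.nan,
        "classification": classify_mutation_table(calls),
        "spectrum": substitution_spectrum(snvs) if len(snvs) else None,
        "mean_vaf": float(calls["vaf"].mean()) if len(calls) else None,
    }
    try:
        report["count_age_correlation"] = correlate_count_age(summaries)
    except ValueError:
        report["count_age_correlation"] = None
    try:
        carriers = summaries[summaries["n_mutations"] > 0]
        report["cumulative_vaf_age_correlation"] = correlate(
            carriers["age"], carriers["cumulative_vaf"]
        )
    except ValueError:
        report["cumulative_vaf_age_correlation"] = None
    return report


def write_report_json(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
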