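"""Simulate a small synthetic patient cohort and inspect its truth table.

The generator emulates ultra-deep targeted sequencing of a single coding
locus: each patient carries a set of low-cell-fraction clones (somatic SNVs
with VAF = cell_fraction / 2), one patient a mosaic heterozygous deletion
(cell fraction 0.37) and one a reciprocal translocation (cell fraction 0.1).
"""

import tempfile
from pathlib import Path

from sgrescue import CohortSpec, simulate_cohort, simulate_reference

genome, cds = simulate_reference(
    seed=7,
    chrom_lengths={"chr20s": 4000, "chr16s": 3000},
    cds_layout={"name": "EIF6s", "chrom": "chr20s", "start": 1501, "n_coding_nt": 738},
)
print(f"reference: {list(genome.chromosomes)}  CDS length {len(cds.cds_seq)} nt, "
      f"protein {len(cds.protein)} aa")

out = Path(tempfile.mkdtemp(prefix="sgr_cohort_"))
spec = CohortSpec(n_patients=6, depth_regime="locus_capture", seed=1)
truth = simulate_cohort(spec, genome, cds, out)

print(f"\nwrote {truth['patient'].nunique()} patients to {out}")
print("\ntruth table (one row per clonal event):")
cols = ["patient", "kind", "pos", "ref", "alt", "cell_fraction",
        "expected_vaf", "expected_baf"]
print(truth[cols].to_string(index=False))
print("\nexpected_vaf = cell_fraction/2 for heterozygous somatic SNVs;")
print("expected_baf = (1-f)/(2-f) for het SNPs inside the mosaic deletion.")
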