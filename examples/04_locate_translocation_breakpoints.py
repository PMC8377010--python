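"""Localize a reciprocal translocation from soft-clipped chimeric reads.

Reads spanning the junction align up to the breakpoint and carry the
partner chromosome's sequence as a soft clip; their last aligned positions
pile up exactly at the junction.  Clusters are retained only when their
mates point to both the same chromosome and the partner (and nowhere else).
"""

from sgrescue import ClonalEvent, PatientSpec, locate_breakpoints
from sgrescue import simulate_patient_reads, simulate_reference
from sgrescue.synthetic_cohort import reads_to_segments

genome, cds = simulate_reference(
    7, {"chr20s": 4000, "chr16s": 3000},
    {"name": "EIF6s", "chrom": "chr20s", "start": 1501, "n_coding_nt": 738},
)

junction = {"chr20s": 1900, "chr16s": 1500}
event = ClonalEvent(
    "translocation", cell_fraction=0.1,
    chrom="chr20s", pos=junction["chr20s"],
    chrom2="chr16s", pos2=junction["chr16s"],
)
patient = PatientSpec(
    id="P02", age=9.0, events=[event], mean_depth=1800, seed=5,
    regions=[("chr20s", 1500, 2300), ("chr16s", 1100, 1900)],
)
reads, _ = simulate_patient_reads(patient, genome)
_, segments = reads_to_segments(reads, genome)

result = locate_breakpoints(segments, "chr20s", "chr16s")
for chrom, clusters in result.items():
    for c in clusters:
        if c.retained:
            print(f"{chrom}: window {c.start}-{c.end}  "
                  f"{c.n_endpoints} clipped reads  "
                  f"{c.n_interchromosomal_mates} inter-chromosomal mates  "
                  f"(true junction {junction[chrom]})")
print("\nEach retained window should contain the true junction base; mate")
print("evidence from both chromosomes distinguishes it from clipping noise.")
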