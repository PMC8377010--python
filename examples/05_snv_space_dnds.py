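"""Enumerate the exhaustive SNV space of a CDS; dN/dS and score enrichment.

A 738-nt CDS admits exactly 2214 possible SNVs.  Their consequence-class
partition gives the neutral expectation: dN/dS of observed variants is the
observed non-synonymous/synonymous count ratio normalized by the
possible-site ratio (1 = neutral).  A deleteriousness score table supports
an unpaired t-test of observed variants against the whole space.
"""

import numpy as np

from sgrescue import enumerate_snvs, expected_ns_ratio, simulate_reference
from sgrescue.snv_space import dnds_from_counts, score_background_test

genome, cds = simulate_reference(
    7, {"chr20s": 4000, "chr16s": 3000},
    {"name": "EIF6s", "chrom": "chr20s", "start": 1501, "n_coding_nt": 738},
)

space = enumerate_snvs(cds)
print(f"SNV space: {space.size} possible SNVs (3 x {len(cds.cds_seq)})")
print("class counts:", space.class_counts)
ratio = expected_ns_ratio(space)
print(f"expected (possible-site) N/S ratio: {ratio:.3f}")

# observed consequence-class counts of a screened cohort: 31 missense +
# 10 nonsense + 1 start-loss vs 4 synonymous among 46 SNVs
dnds = dnds_from_counts(n_obs=42, s_obs=4, space=space)
print(f"\ndN/dS of observed classes (42 non-syn vs 4 syn): {dnds:.2f}")
print("values > 1 indicate positive selection for protein-altering variants")

# synthetic deleteriousness scores: non-synonymous SNVs score higher
rng = np.random.default_rng(0)
table = {}
for r in space.records.itertuples():
    base = 22.0 if r.consequence != "synonymous" else 8.0
    table[(int(r.cds_pos), r.ref, r.alt)] = float(rng.normal(base, 4.0))
observed = space.records[space.records.consequence == "missense"].sample(
    40, random_state=1
)
res = score_background_test(observed, space, table)
print(f"\nscore background test: mean(observed) {res['mean_obs']:.2f} vs "
      f"mean(space) {res['mean_all']:.2f}; t = {res['t']:.2f}, "
      f"p = {res['p']:.2e} (df {res['df']:.0f})")
print("a positive t with small p means observed variants are predicted more")
print("deleterious than the background of all possible SNVs.")
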