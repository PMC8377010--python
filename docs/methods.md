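# Methods

This note documents the models, parameter choices and numerical conventions
behind `sgrescue`, and what the synthetic cohorts do and do not establish
about real data.

## Coordinates and sequence model

All in-memory coordinates are 1-based inclusive (SAM/VCF convention).  The
6-column CDS annotation table is 0-based half-open on disk and converted at
the I/O boundary.  A `CodingSequence` stores exon segments in transcript
order (descending genomic order on the minus strand); the spliced sequence
must begin with ATG, end with TAA/TAG/TGA, contain no internal stop, and
have length divisible by 3.  Translation uses the standard nuclear code
only.  `N` bases are tolerated in references but any consequence or
enumeration operation that would have to interpret one raises instead of
guessing.

## Mosaic caller

The caller is a transparent substitute for black-box germline callers: the
screening design, not caller internals, is what matters here, and a
self-contained binomial model makes the null exactly testable.

Pipeline: drop duplicate-flagged records → pile up CIGAR-walked bases
(M/=/X count toward depth and allele counts; I/D are recorded as VCF-style
left-anchored indel alleles at the preceding base; soft clips contribute
nothing; records with MAPQ < 1 are skipped, reusing the one mapping-quality
threshold the breakpoint procedure defines) → test every alternative
allele.

An allele with count *k* at depth *n* is called iff

1. *k*/*n* ≥ `vaf_min` — 0.005 in locus-capture mode (≈2807× mean depth),
   0.0025 in cDNA-capture mode (≈26,873×);
2. *k* ≥ `min_alt_reads` (default 3) — suppresses singleton errors at
   extreme depth; the threshold is a config knob, not an inferred value;
3. P(X ≥ k | n, ε) < α / (3 × n_sites), with ε = 10⁻³ per base and
   α = 0.05.  Bonferroni over sites × 3 alternative alleles is used rather
   than FDR because the screening regime reports hard cut-offs, and the
   correction is parameter-free.  The generator distributes errors
   uniformly over the three non-reference bases, so testing each allele
   against the full ε is (three-fold) conservative; the family-wise
   guarantee holds a fortiori.

Mate pairs overlap by 70 bp under the default read geometry, so read-level
allele counts at one site are pairwise correlated; VAF estimates remain
unbiased but their sampling variance is up to twice the naive binomial
value.  Real pipelines share this property unless they clip overlaps.

Consequence classes: synonymous, missense, nonsense (stop-gain), stop-loss,
start-loss (any change in codon 1 — ATG is the only Met codon), frameshift
and in-frame indel (by length mod 3), noncoding.  The classifier is
verified against a brute-force oracle that translates full mutant CDS
copies.

## BAF deletion scan

For a heterozygous deletion in cell fraction *f*, allele copy numbers at a
constitutional het SNP are 1 (retained) and 1 − *f* (deleted), giving the
deleted allele an expected BAF of (1 − f)/(2 − f).  Each SNP is tested
against BAF 0.5 with an exact two-sided binomial test (depths span two
orders of magnitude, so the exact test is preferred to a normal
approximation); SNPs deviate when p < α/n_SNPs, and maximal runs of at
least `min_snps = 2` consecutive deviating SNPs become segments.  The run
rule is this package's explicit operationalization of "sharp BAF
deviation"; no CBS/HMM segmentation is attempted.  Segments are described
by the minor allele, min(BAF, 1 − BAF), so the unobservable phase labelling
cannot flip results, and the cell fraction is estimated by the algebraic
inverse f̂ = (1 − 2·BAF)/(1 − BAF) of the mean minor BAF.

Power note: at depth 2000 and f = 0.1 the expected BAF (0.474) lies ~2.3
binomial SD from 0.5, so the Bonferroni run rule misses many replicates;
detection is reliable from f ≈ 0.25 upward at these depths.  Estimates
conditional on detection are slightly biased outward at small f (selection
on exceedances).

## Breakpoint clustering

A read spanning a translocation junction aligns up to the breakpoint and
carries the partner sequence as a soft clip, so its *last aligned position*
(alignment start + Σ lengths of reference-consuming CIGAR ops − 1) marks
the junction.  The full reference-consuming set {M, D, N, =, X} is used; a
widespread shell recipe for this step recognizes only M and D, and the
equivalence test against a literal re-interpreter of that recipe therefore
uses fixtures without N/=/X.  Endpoints merge when book-ended
(`max_gap = 1`, reproducing `bedtools merge -d 0` on adjacent 1-bp
intervals); a cluster is retained iff its distinct mate-chromosome set is
exactly {same-chromosome, partner} — junction-spanning fragments produce
both mate types at the true breakpoint, and any third chromosome marks an
artifact.  Clip side (leading vs trailing S) is recorded for diagnostics
but not used for filtering.  Both chromosomes are processed symmetrically,
each with the other as partner.

## SNV space and dN/dS

All 3L SNVs of a CDS are enumerated and classified with the same logic as
the caller.  Nonsense, stop-loss and start-loss count as non-synonymous in
both the observed and the possible-site tally, which keeps the whole
space's dN/dS at exactly 1.  Site counting is simple and unweighted
(Nei–Gojobori-style, no transition/transversion bias, no rate variation);
codon-model maximum-likelihood dN/dS is out of scope.  Because published
dN/dS values from web calculators rarely document their site-counting
scheme, reproduction of any specific published value is
methodology-sensitive; an `exclude_start_loss` flag covers the ambiguity of
whether initiator-loss variants are counted.  Indels never enter dN/dS.

Deleteriousness scores (e.g. CADD) are consumed as an external
(pos, ref, alt) → score table; computing such scores is out of scope.  The
background comparison is a two-sample unpaired t-test of observed variants'
scores against the full space, equal-variance Student's t by default with
Welch–Satterthwaite available by flag (figure-legend conventions rarely
specify which; the default is documented rather than guessed).

## Cohort report

Carrier fraction, per-class percentages, the pyrimidine-reference six-class
substitution spectrum (purine-reference substitutions are complemented), and
Pearson correlations with two-tailed p-values from the t-approximation
t = r·√((n−2)/(1−r²)).  Percentages are **truncated** (not rounded) to one
decimal place — the fixed-point display convention of clinical cohort
tables (17/26 → 65.3) — while raw fractions remain in machine output.
Reports are deterministic and byte-identical on regeneration.

## Synthetic cohorts

The generator emulates ultra-deep targeted capture of a small locus:
paired-end 130+130 reads on fixed 200 bp fragments, per-base uniform
strand-independent sequencing errors (default 10⁻³), PCR duplicates emitted
with the SAM duplicate flag (default rate 0.1; duplicate *marking* is out
of scope, duplicate *handling* is in scope), and mean deduplicated depths
of 2807× (locus capture) or 26,873× (cDNA capture).  Somatic SNV/indel
clones are injected into a Bernoulli(f/2) share of overlapping fragments;
heterozygous deletions re-weight haplotype sampling so the deleted allele's
BAF is (1 − f)/(2 − f); reciprocal translocations are simulated from two
derivative chromosomes, with junction-spanning reads soft-clipped on the
anchor side so their last aligned base is exactly the junction coordinate
(the partner-side junction base appears on both derivatives — a simulator
convention that pins both windows to the stated coordinates).

Cohort assembly: ages follow a right-skewed Gamma(2, 7.7) clipped to
[0.47, 52.2] years (mean ≈ 15); clone counts are Poisson(0.5 + 0.1·age),
giving a mean of ~2 clones and a positive count–age correlation; clone
VAFs are log-uniform over [0.0025, 0.28].  The default substitution
spectrum fixes C>T at 0.511 (the dominant spontaneous-deamination
transition class of hematopoietic somatic mutations) and divides the
remainder as {C>A 0.08, C>G 0.06, T>A 0.065, T>C 0.18, T>G 0.104} — a
package choice, config-exposed.  One patient carries a 0.37-cell-fraction
heterozygous deletion over the locus; one carries a 0.1-cell-fraction
reciprocal translocation.  Constitutional het SNPs are placed in the
captured flanks *outside* the CDS (intron-like), so constitutional
variation does not masquerade as somatic calls.

Per-patient random streams derive from the master seed via
`numpy.random.SeedSequence([master, index])`.  Plain `master + index`
arithmetic was rejected because it makes cohort *k*'s patient *i*+1 share a
stream with cohort *k*+1's patient *i*, correlating replicates across
master seeds.

**What the simulations do not model:** base-quality variation, GC bias,
strand bias, indel sequencing-error modes, alignment errors or read
mapping (reads are emitted pre-aligned), clone phylogenies, and germline
callers' artifact spectra.  Passing tests therefore establish the
statistical correctness of the pipeline under its own error model, not
robustness to alignment- or chemistry-specific artifacts of any particular
instrument.

## Problem sizes in the test-suite and acceptance script

Simulation-backed properties run at sizes chosen to make the checks sharp
but cheap: null calibration over 200 patients at depth 800 on a ~300 bp
target; clone recovery over 40 seeds at depth 2000; breakpoint recovery
over 50 random junctions at depth 300; BAF recovery over 50 seeds using
the generator's count-level SNP simulator (binomial draws at the expected
BAF), with a read-level cross-check at one seed; the acceptance script's
end-to-end cohort uses 26 patients at the 2807× locus regime.

## Stand-in locus

No public sequence accompanies the restricted cohort data this package's
analyses are designed around, and the build environment has no access to
sequence databases, so examples, tests and the acceptance script use a
**synthetic stand-in CDS**: 738 coding nucleotides (245-residue protein,
the length of human eIF6) with uniform non-stop codon usage, generated
deterministically from a seed.  Quantities that depend only on counts and
thresholds are unaffected; the expected N/S site ratio (and hence the
absolute dN/dS value, ~3.2–3.5 across seeds for the published observed
counts of 42 non-synonymous vs 4 synonymous) shifts by a few percent with
the codon composition of the CDS used.  Substituting the real CDS via
`read_fasta`/`read_cds_table` reproduces the exact published site ratio.
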