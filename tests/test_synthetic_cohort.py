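"""Synthetic-cohort generator: determinism, event injection, BAF/VAF
arithmetic, duplicates and translocation junction signatures."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sgrescue import (
    ClonalEvent,
    CohortSpec,
    GenomicPosition,
    PatientSpec,
    build_cohort_specs,
    expected_baf,
    simulate_patient_reads,
    simulate_reference,
)
from sgrescue.cohort_report import substitution_spectrum
from sgrescue.synthetic_cohort import (
    DEFAULT_SPECTRUM,
    simulate_het_snp_counts,
    write_sam,
)


class TestSimulateReference:
    def test_same_seed_identical_genome(self):
        args = (
            {"chrA": 2000},
            {"name": "x", "chrom": "chrA", "start": 501, "n_coding_nt": 300},
        )
        g1, c1 = simulate_reference(42, *args)
        g2, c2 = simulate_reference(42, *args)
        assert g1.chromosomes == g2.chromosomes
        assert c1.cds_seq == c2.cds_seq

    def test_738_nt_cds_gives_245_residue_protein(self, sim_cds):
        assert len(sim_cds.cds_seq) == 738
        assert len(sim_cds.protein) == 245

    def test_cds_not_fitting_raises(self):
        with pytest.raises(ValueError):
            simulate_reference(
                1,
                {"chrA": 100},
                {"name": "x", "chrom": "chrA", "start": 1, "n_coding_nt": 300},
            )


class TestExpectedBaf:
    def test_no_deletion_is_balanced(self):
        assert expected_baf(0.0) == 0.5

    def test_full_fraction_removes_deleted_allele(self):
        assert expected_baf(1.0, "deleted") == 0.0

    def test_37_percent_deletion(self):
        assert expected_baf(0.37) == pytest.approx(0.63 / 1.63, abs=1e-12)
        assert expected_baf(0.37) == pytest.approx(0.3865, abs=5e-5)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            expected_baf(1.5)

    @given(st.floats(0.0, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_deleted_and_retained_fractions_sum_to_one(self, f):
        assert expected_baf(f, "deleted") + expected_baf(f, "retained") == pytest.approx(
            1.0, abs=1e-12
        )


class TestSimulatePatientReads:
    def test_deterministic_sam_output(self, sim_genome, tmp_path):
        spec = PatientSpec(
            id="P", age=5, events=[], mean_depth=300, seed=9,
            regions=[("chr20s", 1500, 2100)],
        )
        for name in ("a.sam", "b.sam"):
            reads, _ = simulate_patient_reads(spec, sim_genome)
            write_sam(reads, sim_genome, tmp_path / name)
        assert (tmp_path / "a.sam").read_bytes() == (tmp_path / "b.sam").read_bytes()

    def test_snv_alt_fraction_tracks_half_cell_fraction(self, sim_genome):
        """Realized alt-read fraction of a 4% clone stays within 4 binomial
        SD of f/2 = 2% in every one of 20 seeds, and is unbiased on average."""
        pos, f = 1600, 0.04
        ref = sim_genome.base(GenomicPosition("chr20s", pos))
        alt = "A" if ref != "A" else "G"
        ev = ClonalEvent("snv", f, chrom="chr20s", pos=pos, ref=ref, alt=alt)
        fracs = []
        for seed in range(20):
            spec = PatientSpec(
                id="P", age=5, events=[ev], mean_depth=1500, seed=seed,
                error_rate=0.0, duplicate_rate=0.0,
                regions=[("chr20s", 1400, 1800)],
            )
            reads, _ = simulate_patient_reads(spec, sim_genome)
            # count fragments once (first-in-pair only): overlapping mates
            # share the fragment's haplotype, so per-read counts would be
            # pairwise correlated and break the binomial SD below
            n = alt_count = 0
            for r in reads:
                off = pos - r.pos
                if r.flag & 0x40 and r.cigar == "130M" and 0 <= off < 130:
                    n += 1
                    alt_count += r.seq[off] == alt
            frac = alt_count / n
            sd = np.sqrt(0.02 * 0.98 / n)
            assert abs(frac - 0.02) < 4 * sd
            fracs.append(frac)
        pooled_sd = np.sqrt(0.02 * 0.98 / (n * 20))
        assert abs(np.mean(fracs) - 0.02) < 2 * pooled_sd

    def test_zero_duplicate_rate_emits_no_duplicates(self, sim_genome):
        spec = PatientSpec(
            id="P", age=5, events=[], mean_depth=200, seed=1, duplicate_rate=0.0,
            regions=[("chr20s", 1500, 2000)],
        )
        reads, _ = simulate_patient_reads(spec, sim_genome)
        assert not any(r.flag & 0x400 for r in reads)

    def test_duplicate_fraction_matches_rate(self, sim_genome):
        spec = PatientSpec(
            id="P", age=5, events=[], mean_depth=500, seed=1, duplicate_rate=0.2,
            regions=[("chr20s", 1500, 2200)],
        )
        reads, _ = simulate_patient_reads(spec, sim_genome)
        n_dup = sum(bool(r.flag & 0x400) for r in reads)
        n_orig = len(reads) - n_dup
        assert n_dup / n_orig == pytest.approx(0.2, abs=0.01)

    def test_translocation_produces_softclips_with_partner_mates(self, sim_genome):
        ev = ClonalEvent(
            "translocation", 0.3, chrom="chr20s", pos=1900,
            chrom2="chr16s", pos2=1500,
        )
        spec = PatientSpec(
            id="P", age=5, events=[ev], mean_depth=400, seed=2,
            regions=[("chr20s", 1600, 2200), ("chr16s", 1200, 1800)],
        )
        reads, _ = simulate_patient_reads(spec, sim_genome)
        chimeric = [
            r for r in reads
            if "S" in r.cigar and r.chrom == "chr20s" and r.mate_chrom == "chr16s"
        ]
        assert chimeric, "no junction-spanning read with a partner-chromosome mate"

    def test_event_outside_reference_raises(self, sim_genome):
        ev = ClonalEvent("snv", 0.1, chrom="chr20s", pos=99999, ref="A", alt="G")
        spec = PatientSpec(
            id="P", age=5, events=[ev], mean_depth=100, seed=1,
            regions=[("chr20s", 1500, 2000)],
        )
        with pytest.raises(ValueError):
            simulate_patient_reads(spec, sim_genome)


class TestEventValidation:
    def test_cell_fraction_bounds(self):
        with pytest.raises(ValueError):
            ClonalEvent("snv", 0.0, chrom="c", pos=1, ref="A", alt="G")

    def test_snv_alleles_must_differ(self):
        with pytest.raises(ValueError):
            ClonalEvent("snv", 0.5, chrom="c", pos=1, ref="A", alt="A")

    def test_indel_alleles_must_differ_in_length(self):
        with pytest.raises(ValueError):
            ClonalEvent("indel", 0.5, chrom="c", pos=1, ref="AT", alt="GC")

    def test_het_snp_event_collision_rejected(self):
        ev = ClonalEvent("snv", 0.5, chrom="c", pos=10, ref="A", alt="G")
        with pytest.raises(ValueError):
            PatientSpec(
                id="P", age=1, events=[ev], mean_depth=10, seed=0,
                het_snp_positions=[GenomicPosition("c", 10)],
                regions=[("c", 1, 300)],
            )


class TestCohortAssembly:
    def test_spectrum_weights_must_sum_to_one(self):
        bad = dict(DEFAULT_SPECTRUM)
        bad["C>T"] += 0.1
        with pytest.raises(ValueError):
            CohortSpec(spectrum_weights=bad)

    def test_generated_snv_spectrum_recovers_weights(self, sim_genome, sim_cds):
        """Over >=2000 simulated SNV events, empirical substitution-class
        frequencies match the generator weights within 3 standard errors."""
        import pandas as pd

        spec = CohortSpec(n_patients=40, depth_regime="locus_capture", seed=3)
        rows = []
        seed = 3
        while len(rows) < 2000:
            spec = CohortSpec(n_patients=40, depth_regime="locus_capture", seed=seed)
            patients = build_cohort_specs(
                spec, sim_genome, sim_cds,
                include_deletion_patient=False,
                include_translocation_patient=False,
            )
            for p in patients:
                for ev in p.events:
                    if ev.kind == "snv":
                        rows.append({"ref": ev.ref, "alt": ev.alt})
            seed += 1
        table = pd.DataFrame(rows)
        spectrum = substitution_spectrum(table)
        n = len(table)
        for cls, w in DEFAULT_SPECTRUM.items():
            se = np.sqrt(w * (1 - w) / n)
            assert abs(spectrum[cls] - w) <= 3 * se, (cls, spectrum[cls], w)

    def test_count_level_snp_simulator_matches_expected_baf(self, rng):
        t = simulate_het_snp_counts(0.37, depth=5000, n_snps=50, rng=rng)
        baf = (t.b_count / (t.a_count + t.b_count)).mean()
        assert baf == pytest.approx(expected_baf(0.37), abs=0.01)
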