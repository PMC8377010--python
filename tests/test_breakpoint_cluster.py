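"""Soft-clip breakpoint clustering, including equivalence with a literal
re-execution oracle of the shell recipe the procedure is based on
(samtools view -q 1 | cut | grep S | awk M/D-sum | sort | merge | grep)."""

import re

import pysam
import pytest

from sgrescue import (
    ClonalEvent,
    PatientSpec,
    cluster_endpoints,
    extract_endpoints,
    filter_clusters,
    last_aligned_pos,
    locate_breakpoints,
    simulate_patient_reads,
)
from sgrescue.breakpoint_cluster import ClipEndpoint
from sgrescue.synthetic_cohort import make_sam_header, reads_to_segments


class TestLastAlignedPos:
    @pytest.mark.parametrize(
        "pos,cigar,expected",
        [
            (100, "50M", 149),
            (100, "30M5I20M10S", 149),  # I and S consume no reference
            (100, "10S40M2D8M", 149),   # D consumes reference
            (100, "60M70S", 159),
            (1, "1M", 1),
        ],
    )
    def test_reference_consuming_ops(self, pos, cigar, expected):
        assert last_aligned_pos(pos, cigar) == expected

    def test_n_equals_x_consume_reference(self):
        assert last_aligned_pos(100, "10M5N10M") == 124
        assert last_aligned_pos(100, "10=2X8=") == 119

    @pytest.mark.parametrize("cigar", ["", "*", "abc", "10M5"])
    def test_malformed_cigar_raises(self, cigar):
        with pytest.raises(ValueError):
            last_aligned_pos(100, cigar)

    @pytest.mark.parametrize("core", ["50M", "20M3D30M", "10M2I38M"])
    @pytest.mark.parametrize("lead,trail", [(0, 10), (7, 0), (5, 5)])
    def test_invariant_to_added_soft_clips(self, core, lead, trail):
        base = last_aligned_pos(200, core)
        padded = (f"{lead}S" if lead else "") + core + (f"{trail}S" if trail else "")
        assert last_aligned_pos(200, padded) == base


def _segment(header, chrom, pos, cigar, mate_chrom, mapq=60, name="r", flag=0x1):
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.flag = flag
    a.reference_id = header.get_tid(chrom)
    a.reference_start = pos - 1
    a.mapping_quality = mapq
    a.cigarstring = cigar
    n = sum(int(ln) for ln, op in re.findall(r"(\d+)([MIS=X])", cigar))
    a.query_sequence = "A" * n
    a.next_reference_id = header.get_tid(mate_chrom)
    a.next_reference_start = 0
    return a


@pytest.fixture()
def header(sim_genome):
    return make_sam_header(sim_genome)


class TestExtractEndpoints:
    def test_read_without_softclip_excluded(self, header):
        recs = [_segment(header, "chr20s", 100, "130M", "chr20s")]
        assert extract_endpoints(recs, "chr20s") == []

    def test_mapq_zero_excluded(self, header):
        recs = [_segment(header, "chr20s", 100, "60M70S", "chr16s", mapq=0)]
        assert extract_endpoints(recs, "chr20s") == []

    def test_partner_mate_recorded(self, header):
        recs = [_segment(header, "chr20s", 100, "60M70S", "chr16s")]
        (ep,) = extract_endpoints(recs, "chr20s")
        assert ep.last_aligned_pos == 159
        assert ep.mate_chrom == "chr16s"

    def test_same_chrom_mate_is_equals_sign(self, header):
        recs = [_segment(header, "chr20s", 100, "60M70S", "chr20s")]
        (ep,) = extract_endpoints(recs, "chr20s")
        assert ep.mate_chrom == "="


def _ep(pos, mate="=", chrom="c"):
    return ClipEndpoint(chrom, pos, "60M70S", mate, 60)


class TestClusterEndpoints:
    def test_bookended_positions_merge(self):
        clusters = cluster_endpoints([_ep(200), _ep(200), _ep(201)])
        assert len(clusters) == 1
        c = clusters[0]
        assert (c.start, c.end, c.n_endpoints) == (200, 201, 3)

    def test_distant_positions_split(self):
        clusters = cluster_endpoints([_ep(200), _ep(250)], max_gap=1)
        assert len(clusters) == 2

    def test_empty_input(self):
        assert cluster_endpoints([]) == []

    def test_mixed_chromosomes_rejected(self):
        with pytest.raises(ValueError):
            cluster_endpoints([_ep(1, chrom="a"), _ep(2, chrom="b")])


class TestFilterClusters:
    def _cluster(self, mates):
        (c,) = cluster_endpoints([_ep(100, m) for m in mates])
        return c

    def test_same_plus_partner_retained(self):
        c = self._cluster(["=", "chr16s"])
        filter_clusters([c], "chr16s")
        assert c.retained

    def test_third_chromosome_rejected(self):
        c = self._cluster(["=", "chr16s", "chr5"])
        filter_clusters([c], "chr16s")
        assert not c.retained

    def test_same_chromosome_only_rejected(self):
        c = self._cluster(["=", "="])
        filter_clusters([c], "chr16s")
        assert not c.retained

    def test_partner_only_rejected(self):
        c = self._cluster(["chr16s"])
        filter_clusters([c], "chr16s")
        assert not c.retained


# ---------------------------------------------------------------------------
# Literal re-execution oracle of the shell recipe


def shell_recipe_oracle(records, source_chrom, partner_chrom):
    """Step-by-step interpreter of the published command string:

    samtools view -q 1 <bam> <chrom> | cut -f3,4,6-8 | grep S
      | awk '{pos=$2; split($3,a,"[IMDSH]"); split($3,b,"[0-9]*");
              for i: if (b[i] ~ /[MD]/) pos += a[i-1]; print ... pos-1 ...}'
      | sort -k2,2n | bedtools merge -d 0 -c 5,6 -o distinct,distinct
      | grep -E '=,PARTNER|PARTNER,=' | grep -v -E '=,PARTNER,|PARTNER,=,'

    Returns retained (start, end, distinct-mate-string) tuples.  The awk's
    printed value is start + sum(M, D) - 1, i.e. the 1-based last aligned
    position, so no coordinate shift is needed against the module.  Only M
    and D are treated as reference-consuming, as the awk does; fixtures must
    therefore avoid N/=/X.
    """
    rows = []
    for r in records:
        if r.is_unmapped or r.reference_name != source_chrom:
            continue
        if r.mapping_quality < 1:  # samtools view -q 1
            continue
        cigar = r.cigarstring or "*"
        rnext = (
            "=" if r.next_reference_id == r.reference_id else r.next_reference_name
        )
        line = f"{r.reference_name}\t{r.reference_start + 1}\t{cigar}\t{rnext}"
        if "S" not in line:  # grep S on the cut fields
            continue
        pos = r.reference_start + 1  # awk: pos=$2
        for ln, op in re.findall(r"(\d+)([MIDSH])", cigar):
            if op in "MD":
                pos += int(ln)
        rows.append((pos - 1, rnext))  # awk prints pos-1
    rows.sort(key=lambda t: t[0])
    # bedtools merge on book-ended 1-bp endpoint intervals
    merged = []
    for p, mate in rows:
        if merged and p - merged[-1][1] <= 1:
            merged[-1][1] = p
            merged[-1][2].add(mate)
        else:
            merged.append([p, p, {mate}])
    out = []
    for start, end, mates in merged:
        distinct = ",".join(sorted(mates))
        hit = f"=,{partner_chrom}" in distinct or f"{partner_chrom},=" in distinct
        excl = f"=,{partner_chrom}," in distinct or f"{partner_chrom},=," in distinct
        if hit and not excl:
            out.append((start, end, distinct))
    return out


def _translocation_reads(sim_genome, seed, cell_fraction=0.3, depth=300):
    ev = ClonalEvent(
        "translocation", cell_fraction, chrom="chr20s", pos=1900,
        chrom2="chr16s", pos2=1500,
    )
    spec = PatientSpec(
        id="T", age=5, events=[ev], mean_depth=depth, seed=seed,
        regions=[("chr20s", 1600, 2200), ("chr16s", 1200, 1800)],
    )
    reads, _ = simulate_patient_reads(spec, sim_genome)
    _, segs = reads_to_segments(reads, sim_genome)
    return segs


def test_module_matches_shell_recipe_oracle(sim_genome):
    """Retained windows and mate sets equal the literal interpreter's,
    field by field, on a simulated translocation SAM (M/S-only CIGARs)."""
    segs = _translocation_reads(sim_genome, seed=21)
    for source, partner in (("chr20s", "chr16s"), ("chr16s", "chr20s")):
        result = locate_breakpoints(segs, "chr20s", "chr16s")[source]
        mine = [
            (c.start, c.end, ",".join(sorted(c.mate_chroms)))
            for c in result
            if c.retained
        ]
        assert mine == shell_recipe_oracle(segs, source, partner)


class TestLocateBreakpoints:
    def test_junction_recovered_on_both_chromosomes(self, sim_genome):
        segs = _translocation_reads(sim_genome, seed=3)
        result = locate_breakpoints(segs, "chr20s", "chr16s")
        for chrom, junction in (("chr20s", 1900), ("chr16s", 1500)):
            retained = [c for c in result[chrom] if c.retained]
            assert any(c.start <= junction <= c.end for c in retained), chrom
            assert all(c.end - c.start + 1 <= 130 for c in retained)

    def test_reads_on_one_chromosome_leave_partner_empty(self, sim_genome, header):
        recs = [_segment(header, "chr20s", 100, "60M70S", "chr16s")]
        result = locate_breakpoints(recs, "chr20s", "chr16s")
        assert result["chr16s"] == []

    def test_null_patient_has_no_retained_clusters(self, sim_genome):
        """Specificity: patients without a translocation produce no retained
        cluster in >=95% of 40 seeds."""
        n_hit = 0
        for seed in range(40):
            spec = PatientSpec(
                id="N", age=5, events=[], mean_depth=200, seed=seed,
                regions=[("chr20s", 1600, 2200), ("chr16s", 1200, 1800)],
            )
            reads, _ = simulate_patient_reads(spec, sim_genome)
            _, segs = reads_to_segments(reads, sim_genome)
            result = locate_breakpoints(segs, "chr20s", "chr16s")
            if any(c.retained for cs in result.values() for c in cs):
                n_hit += 1
        assert n_hit / 40 <= 0.05
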