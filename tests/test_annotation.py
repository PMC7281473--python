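"""GTF parsing, exon-overlap filtering and family grouping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from retinomimic.annotation import (
    GenomicInterval,
    GtfParseError,
    TEInstance,
    filter_exon_overlaps,
    group_families,
    intervals_overlap,
    read_gtf,
    write_custom_gtf,
    write_gtf,
)


def make_te(iid, chrom, start, end, strand="+", name="REP1", family="FAM_A"):
    return TEInstance(
        GenomicInterval(chrom, start, end, strand, "repeat"), name, family, iid
    )


def brute_force_filter(repeats, exons):
    """O(n*m) pairwise overlap oracle."""
    retained, discarded = [], []
    for te in repeats:
        if any(intervals_overlap(te.interval, ex) for ex in exons):
            discarded.append(te)
        else:
            retained.append(te)
    return retained, discarded


class TestGtfIO:
    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.gtf"
        path.write_text("")
        assert read_gtf(path) == []

    def test_toy_hand_parse(self, tmp_path):
        path = tmp_path / "toy.gtf"
        path.write_text(
            'chr1\tsrc\texon\t100\t200\t.\t+\t.\tgene_id "G1";\n'
            'chr2\tsrc\trepeat\t500\t650\t.\t-\t.\tgene_id "T1"; family "FAM_A";\n'
        )
        records = read_gtf(path)
        assert len(records) == 2
        ex, rep = records
        assert (ex.chrom, ex.start, ex.end, ex.strand, ex.feature_type) == (
            "chr1", 100, 200, "+", "exon",
        )
        assert rep.attributes["family"] == "FAM_A"
        assert (rep.start, rep.end) == (500, 650)

    def test_end_before_start_reports_line(self, tmp_path):
        path = tmp_path / "bad.gtf"
        path.write_text(
            'chr1\tsrc\texon\t100\t200\t.\t+\t.\tgene_id "G1";\n'
            'chr1\tsrc\texon\t300\t250\t.\t+\t.\tgene_id "G2";\n'
        )
        with pytest.raises(GtfParseError, match="line 2"):
            read_gtf(path)

    def test_wrong_field_count_rejected(self, tmp_path):
        path = tmp_path / "bad.gtf"
        path.write_text("chr1\texon\t100\t200\n")
        with pytest.raises(GtfParseError, match="9 tab-separated"):
            read_gtf(path)

    def test_roundtrip_identity(self, tmp_path):
        genes = [GenomicInterval("chr1", 1000, 5000, "+", "gene", {"gene_id": "G1"})]
        exons = [
            GenomicInterval("chr1", 1000, 1200, "+", "exon", {"gene_id": "G1"}),
            GenomicInterval("chr1", 4000, 4500, "+", "exon", {"gene_id": "G1"}),
        ]
        repeats = [make_te("T1", "chr1", 2000, 2300), make_te("T2", "chr2", 10, 90, "-")]
        path = tmp_path / "custom.gtf"
        write_custom_gtf(genes, exons, repeats, path)
        back = read_gtf(path)
        assert len(back) == 5
        reps = [r for r in back if r.feature_type == "repeat"]
        assert {r.attributes["instance_id"] for r in reps} == {"T1", "T2"}
        assert [(r.start, r.end) for r in back[:3]] == [(1000, 5000), (1000, 1200), (4000, 4500)]

    def test_byte_stable_output(self, tmp_path):
        genes = [GenomicInterval("chr1", 1, 100, "+", "gene", {"gene_id": "G"})]
        exons = [GenomicInterval("chr1", 1, 50, "+", "exon", {"gene_id": "G"})]
        reps = [make_te(f"T{i}", "chr1", 200 + 10 * i, 205 + 10 * i) for i in range(3)]
        p1, p2 = tmp_path / "a.gtf", tmp_path / "b.gtf"
        write_custom_gtf(genes, exons, reps, p1)
        write_custom_gtf(genes, exons, list(reversed(reps)), p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestExonOverlapFilter:
    def test_no_exons_keeps_everything(self):
        reps = [make_te("T1", "chr1", 10, 20), make_te("T2", "chr2", 5, 9)]
        retained, log = filter_exon_overlaps(reps, [])
        assert len(retained) == 2 and log == []

    def test_one_based_inclusive_boundary(self):
        exon = GenomicInterval("chr1", 150, 300, "+", "exon")
        overlapping = make_te("T1", "chr1", 100, 200)
        adjacent = make_te("T2", "chr1", 100, 149)
        touching_end = make_te("T3", "chr1", 300, 400)
        past_end = make_te("T4", "chr1", 301, 400)
        retained, log = filter_exon_overlaps(
            [overlapping, adjacent, touching_end, past_end], [exon]
        )
        assert {t.instance_id for t in retained} == {"T2", "T4"}
        assert {d["instance_id"] for d in log} == {"T1", "T3"}
        assert "overlaps exon chr1:150-300" in log[0]["reason"]

    def test_strand_agnostic(self):
        exon = GenomicInterval("chr1", 100, 200, "+", "exon")
        minus = make_te("T1", "chr1", 150, 160, strand="-")
        retained, log = filter_exon_overlaps([minus], [exon])
        assert retained == [] and len(log) == 1

    @pytest.mark.filterwarnings("ignore:repeat chromosomes absent")
    def test_different_chromosome_retained(self):
        exon = GenomicInterval("chr1", 100, 200, "+", "exon")
        retained, _ = filter_exon_overlaps([make_te("T1", "chr2", 100, 200)], [exon])
        assert len(retained) == 1

    def test_chrom_alias_map(self):
        exon = GenomicInterval("chr1", 100, 200, "+", "exon")
        te = make_te("T1", "1", 150, 160)
        retained, _ = filter_exon_overlaps([te], [exon], chrom_aliases={"1": "chr1"})
        assert retained == []

    def test_unmatched_chromosome_warns(self):
        exon = GenomicInterval("chr1", 100, 200, "+", "exon")
        with pytest.warns(UserWarning, match="chrUn"):
            filter_exon_overlaps([make_te("T1", "chrUn", 1, 5)], [exon])

    @pytest.mark.filterwarnings("ignore:repeat chromosomes absent")
    def test_matches_brute_force_on_random_annotations(self, rng):
        for _ in range(50):
            n_ex, n_rep = rng.integers(0, 40, size=2)
            chroms = ["chr1", "chr2", "chr3"]
            exons = [
                GenomicInterval(
                    chroms[rng.integers(3)],
                    int(s := rng.integers(1, 5000)),
                    int(s + rng.integers(0, 500)),
                    "+",
                    "exon",
                )
                for _ in range(n_ex)
            ]
            reps = [
                make_te(
                    f"T{i}",
                    chroms[rng.integers(3)],
                    int(s := rng.integers(1, 5000)),
                    int(s + rng.integers(0, 500)),
                )
                for i in range(n_rep)
            ]
            retained, log = filter_exon_overlaps(reps, exons)
            oracle_ret, oracle_disc = brute_force_filter(reps, exons)
            assert [t.instance_id for t in retained] == [t.instance_id for t in oracle_ret]
            assert [d["instance_id"] for d in log] == [t.instance_id for t in oracle_disc]
            # partition: retained + discarded = input, disjoint
            assert len(retained) + len(log) == n_rep


class TestFamilyGrouping:
    def test_hand_count(self):
        reps = [
            make_te("T1", "chr1", 1, 5, name="R1"),
            make_te("T2", "chr1", 10, 15, name="R2"),
            make_te("T3", "chr1", 20, 25, name="R1"),
        ]
        fams, meta = group_families(reps, {"R1": "A", "R2": "B"})
        assert {f.name: f.size for f in fams} == {"A": 2, "B": 1}
        assert meta.size == 3

    def test_empty_input(self):
        fams, meta = group_families([])
        assert fams == [] and meta.size == 0

    def test_single_family_equals_metagene(self):
        reps = [make_te(f"T{i}", "chr1", 10 * i + 1, 10 * i + 5) for i in range(4)]
        fams, meta = group_families(reps)
        assert len(fams) == 1
        assert fams[0].member_ids == meta.member_ids

    def test_strict_unresolved_name(self):
        reps = [make_te("T1", "chr1", 1, 5, name="UNKNOWN")]
        with pytest.raises(KeyError):
            group_families(reps, {"R1": "A"}, strict=True)
        fams, meta = group_families(reps, {"R1": "A"}, strict=False)
        assert fams == [] and meta.size == 0

    def test_partition_property(self, rng):
        reps = [
            make_te(f"T{i}", "chr1", 10 * i + 1, 10 * i + 5, family=f"F{rng.integers(5)}")
            for i in range(60)
        ]
        fams, meta = group_families(reps)
        all_members = [m for f in fams for m in f.member_ids]
        assert sorted(all_members) == sorted(meta.member_ids)
        assert len(set(all_members)) == len(all_members) == 60


@settings(derandomize=True, max_examples=200, deadline=None)
@given(
    a_start=st.integers(1, 300),
    a_len=st.integers(0, 100),
    b_start=st.integers(1, 300),
    b_len=st.integers(0, 100),
)
def test_overlap_convention_matches_half_open(a_start, a_len, b_start, b_len):
    """1-based inclusive overlap agrees with half-open [start, end+1) math."""
    a = GenomicInterval("chr1", a_start, a_start + a_len)
    b = GenomicInterval("chr1", b_start, b_start + b_len)
    half_open = max(a.start, b.start) < min(a.end + 1, b.end + 1)
    assert intervals_overlap(a, b) == half_open
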