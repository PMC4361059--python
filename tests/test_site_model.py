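"""Domain types, pileup-TSV and BED parsing, VCF round trips."""

import math

import pytest
from hypothesis import given, strategies as st

from polyclone.errors import FormatError, ValidationError
from polyclone.io import (
    read_bed_mask,
    read_pileup_table,
    read_vcf,
    write_bed,
    write_pileup_table,
    write_vcf,
)
from polyclone.sites import (
    AlleleCounts,
    GenomeMask,
    LesionCallSet,
    ReadEvidence,
    SitePileup,
    TargetRegion,
    VariantCall,
)

HEADER = "\t".join(
    ["chrom", "pos", "ref", "tri_context"]
    + [f"tumor_{b}_{s}" for b in "ACGT" for s in ("fwd", "rev")]
    + [f"normal_{b}_{s}" for b in "ACGT" for s in ("fwd", "rev")]
    + ["low_mapability", "near_repeat", "known_variant", "tumor_reads", "normal_reads"]
)


def _row(chrom="chr1", pos=10, ref="C", ctx="ACG", tumor=None, normal=None,
         flags=(0, 0, 0), reads=(".", ".")):
    tumor = tumor or {}
    normal = normal or {}
    t = [str(tumor.get(f"{b}_{s}", 0)) for b in "ACGT" for s in ("fwd", "rev")]
    n = [str(normal.get(f"{b}_{s}", 0)) for b in "ACGT" for s in ("fwd", "rev")]
    return "\t".join([chrom, str(pos), ref, ctx] + t + n + [str(f) for f in flags] + list(reads))


class TestPileupTable:
    def test_depth_is_sum_of_strand_counts(self, tmp_path):
        path = tmp_path / "p.tsv"
        row = _row(tumor={"C_fwd": 48, "C_rev": 42, "T_fwd": 5, "T_rev": 5},
                   normal={"C_fwd": 50, "C_rev": 50})
        path.write_text(HEADER + "\n" + row + "\n")
        sites = read_pileup_table(path)
        assert len(sites) == 1
        assert sites[0].tumor.depth == 100
        assert sites[0].tumor.count("T") == 10
        assert sites[0].pos == 10

    def test_header_only_file_yields_empty_sequence(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text(HEADER + "\n")
        assert read_pileup_table(path) == []

    def test_context_mismatch_is_validation_error_with_line_number(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text(HEADER + "\n" + _row(ref="C", ctx="ATG") + "\n")
        with pytest.raises(ValidationError, match="line 2"):
            read_pileup_table(path)

    def test_missing_column_is_format_error(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text("chrom\tpos\n" + "chr1\t5\n")
        with pytest.raises(FormatError, match="missing required columns"):
            read_pileup_table(path)

    def test_negative_count_names_the_field(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text(HEADER + "\n" + _row(tumor={"C_fwd": -3}) + "\n")
        with pytest.raises(ValidationError, match="tumor_C_fwd"):
            read_pileup_table(path)

    def test_round_trip_with_read_evidence(self, tmp_path, rng):
        sites = []
        for i in range(50):
            pos = i + 1
            ref = "ACGT"[rng.integers(0, 4)]
            ctx = "ACGT"[rng.integers(0, 4)] + ref + "ACGT"[rng.integers(0, 4)]
            nt = int(rng.integers(0, 6))
            reads = [
                ReadEvidence(
                    base="ACGT"[rng.integers(0, 4)],
                    base_quality=int(rng.integers(0, 61)),
                    end_distance=int(rng.integers(0, 38)),
                    strand="+" if rng.random() < 0.5 else "-",
                    confirmed=bool(rng.random() < 0.5),
                )
                for _ in range(nt)
            ]
            counts = {b: (0, 0) for b in "ACGT"}
            for r in reads:
                f, rv = counts[r.base]
                counts[r.base] = (f + (r.strand == "+"), rv + (r.strand == "-"))
            sites.append(
                SitePileup(
                    chrom="chr1", pos=pos, ref_base=ref, tri_context=ctx,
                    tumor=AlleleCounts.from_dict(counts),
                    normal=AlleleCounts.from_dict({"A": (3, 2)}),
                    tumor_reads=reads, normal_reads=None,
                    low_mapability=bool(rng.random() < 0.2),
                    near_repeat=bool(rng.random() < 0.2),
                    known_variant=bool(rng.random() < 0.2),
                )
            )
        path = tmp_path / "rt.tsv"
        write_pileup_table(sites, path)
        back = read_pileup_table(path)
        assert back == sites


class TestBedMask:
    def test_overlapping_regions_merge(self, tmp_path):
        path = tmp_path / "m.bed"
        path.write_text("chr1\t10\t20\nchr1\t15\t30\n")
        mask = read_bed_mask(path)
        assert mask.regions == [TargetRegion("chr1", 10, 30)]

    def test_one_based_membership_convention(self, tmp_path):
        path = tmp_path / "m.bed"
        path.write_text("chr1\t10\t20\n")
        mask = read_bed_mask(path)
        assert mask.contains("chr1", 11)
        assert mask.contains("chr1", 20)
        assert not mask.contains("chr1", 10)
        assert not mask.contains("chr1", 21)
        assert not mask.contains("chr2", 11)

    def test_empty_bed_matches_nothing(self, tmp_path):
        path = tmp_path / "m.bed"
        path.write_text("")
        mask = read_bed_mask(path)
        assert not mask.contains("chr1", 1)
        assert len(mask) == 0

    def test_start_ge_end_rejected(self, tmp_path):
        path = tmp_path / "m.bed"
        path.write_text("chr1\t20\t10\n")
        with pytest.raises(ValidationError):
            read_bed_mask(path)

    def test_flank_widens_before_merge(self, tmp_path):
        path = tmp_path / "m.bed"
        path.write_text("chr1\t100\t110\n")
        mask = read_bed_mask(path, flank=10)
        assert mask.contains("chr1", 95)
        assert mask.contains("chr1", 120)
        assert not mask.contains("chr1", 90)

    def test_variant_position_matches_bed_region(self):
        # a variant at 1-based pos p lies inside BED region [p-1, p)
        p = 137
        mask = GenomeMask([TargetRegion("chr1", p - 1, p)])
        assert mask.contains("chr1", p)
        assert not mask.contains("chr1", p - 1)
        assert not mask.contains("chr1", p + 1)


def _random_call(rng, pos):
    ref, alt = rng.choice(["A", "C", "G", "T"], size=2, replace=False)
    source = "primary" if rng.random() < 0.5 else "subclonal"
    tags = frozenset(
        t for t in ("STRAND_BIAS", "LOW_DEPTH", "NEAR_REPEAT", "TAIL_BIAS")
        if rng.random() < 0.2
    )
    from polyclone.sites import PRIMARY_FAIL_TAGS, SUBCLONAL_FAIL_TAGS

    fail = PRIMARY_FAIL_TAGS if source == "primary" else SUBCLONAL_FAIL_TAGS
    return VariantCall(
        chrom="chr1", pos=pos, ref=str(ref), alt=str(alt),
        vaf_tumor=round(float(rng.random()), 5),
        vaf_normal=round(float(rng.random()) * 0.02, 5),
        fisher_p=round(float(rng.random()), 6) if rng.random() < 0.8 else None,
        tags=tags,
        source=source,
        consequence=["synonymous", "missense", "truncating", "non_coding"][rng.integers(0, 4)],
        gene=f"GENE{rng.integers(1, 5):03d}" if rng.random() < 0.7 else None,
        passed=not (tags & fail),
    )


class TestVcf:
    def test_pass_call_writes_pass_filter(self, tmp_path):
        cs = LesionCallSet(
            lesion_id="L1", patient_id="P1",
            calls=[VariantCall("chr1", 5, "C", "T", 0.5, 0.0, fisher_p=1e-8)],
        )
        path = tmp_path / "c.vcf"
        write_vcf(cs, path)
        lines = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert len(lines) == 1
        assert lines[0].split("\t")[6] == "PASS"

    def test_tagged_call_writes_tag_filter(self, tmp_path):
        call = VariantCall("chr1", 5, "C", "T", 0.5, 0.0,
                           tags=frozenset({"STRAND_BIAS"}), passed=False)
        cs = LesionCallSet(lesion_id="L1", patient_id="P1", calls=[call])
        path = tmp_path / "c.vcf"
        write_vcf(cs, path)
        line = [l for l in path.read_text().splitlines() if not l.startswith("#")][0]
        assert "STRAND_BIAS" in line.split("\t")[6]

    def test_round_trip_of_100_random_calls(self, tmp_path, rng):
        calls = [_random_call(rng, pos) for pos in range(1, 101)]
        cs = LesionCallSet(lesion_id="L7", patient_id="P3", histology="adenoma",
                           calls=calls)
        path = tmp_path / "rt.vcf"
        write_vcf(cs, path)
        back = read_vcf(path)
        assert back.lesion_id == "L7"
        assert back.patient_id == "P3"
        assert back.histology == "adenoma"
        assert len(back.calls) == len(calls)
        by_key = {c.key: c for c in back.calls}
        for orig in calls:
            got = by_key[orig.key]
            assert math.isclose(got.vaf_tumor, orig.vaf_tumor, rel_tol=1e-5, abs_tol=1e-6)
            assert math.isclose(got.vaf_normal, orig.vaf_normal, rel_tol=1e-5, abs_tol=1e-6)
            if orig.fisher_p is None:
                assert got.fisher_p is None
            else:
                assert math.isclose(got.fisher_p, orig.fisher_p, rel_tol=1e-5, abs_tol=1e-6)
            assert got.tags == orig.tags
            assert got.source == orig.source
            assert got.consequence == orig.consequence
            assert got.gene == orig.gene
            assert got.passed == orig.passed


class TestInvariants:
    def test_allele_counts_reject_negative(self):
        with pytest.raises(ValidationError, match="c_fwd"):
            AlleleCounts(c_fwd=-1)

    def test_variant_call_rejects_ref_eq_alt(self):
        with pytest.raises(ValidationError):
            VariantCall("chr1", 1, "C", "C", 0.5, 0.0)

    def test_site_pileup_checks_read_list_depth(self):
        with pytest.raises(ValidationError, match="read list"):
            SitePileup(
                chrom="chr1", pos=1, ref_base="C", tri_context="ACG",
                tumor=AlleleCounts(c_fwd=2), normal=AlleleCounts(),
                tumor_reads=[ReadEvidence("C", 30, 10, "+")],
            )

    def test_call_set_rejects_duplicate_keys(self):
        c = VariantCall("chr1", 5, "C", "T", 0.5, 0.0)
        with pytest.raises(ValidationError, match="duplicate"):
            LesionCallSet(lesion_id="L", patient_id="P", calls=[c, c])

    @given(st.integers(0, 60), st.integers(0, 100))
    def test_read_evidence_accepts_legal_ranges(self, q, d):
        r = ReadEvidence("A", q, d, "+")
        assert r.base_quality == q

    def test_read_evidence_rejects_bad_quality(self):
        with pytest.raises(ValidationError):
            ReadEvidence("A", 61, 0, "+")
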