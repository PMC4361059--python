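"""Primary caller: genotyping, Fisher tests, bias tags, filter cascade."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from polyclone.primary import (
    apply_primary_filters,
    call_genotype,
    call_lesion_primary,
    call_primary_somatic,
    fisher_exact_two_sided,
    strand_bias_p,
    tail_distance_bias_tag,
)
from polyclone.sites import (
    LOW_DEPTH,
    LOW_MAPABILITY,
    STRAND_BIAS,
    AlleleCounts,
    ReadEvidence,
    SitePileup,
)

from oracles import fisher_oracle, ranksum_less_oracle


def _site(tumor, normal, ref="C", ctx="ACA", pos=100, **kwargs):
    return SitePileup(
        chrom="chr1", pos=pos, ref_base=ref, tri_context=ctx[0] + ref + ctx[2],
        tumor=AlleleCounts.from_dict(tumor), normal=AlleleCounts.from_dict(normal),
        **kwargs,
    )


class TestGenotype:
    @pytest.mark.parametrize(
        "counts,expected_gt,expected_frac",
        [
            ({"C": (48, 47), "T": (3, 2)}, "hom_ref", 0.05),
            ({"C": (25, 25), "T": (25, 25)}, "het", 0.5),
            ({"T": (50, 50)}, "hom_alt", 1.0),
            ({"C": (30, 30), "T": (9, 9), "G": (1, 1)}, "het", 0.225),
        ],
    )
    def test_threshold_genotyping(self, counts, expected_gt, expected_frac):
        gt = call_genotype(AlleleCounts.from_dict(counts), "C")
        assert gt.genotype == expected_gt
        assert gt.alt_fraction == pytest.approx(expected_frac)

    def test_zero_depth_is_no_call(self):
        gt = call_genotype(AlleleCounts(), "C")
        assert gt.genotype == "no_call"


class TestFisher:
    def test_balanced_table_p_one(self):
        assert fisher_exact_two_sided(5, 5, 5, 5) == pytest.approx(1.0)

    def test_extreme_table_matches_enumeration(self):
        # both tails of the maximally-skewed 10+10 table
        assert fisher_exact_two_sided(0, 10, 10, 0) == pytest.approx(2 / 184756, rel=1e-9)

    def test_small_diagonal_table(self):
        assert fisher_exact_two_sided(3, 0, 0, 3) == pytest.approx(0.1, rel=1e-9)

    def test_zero_margins_return_one(self):
        assert fisher_exact_two_sided(0, 0, 0, 0) == 1.0
        assert fisher_exact_two_sided(0, 0, 3, 4) == 1.0
        assert fisher_exact_two_sided(0, 3, 0, 4) == 1.0

    @given(st.tuples(*[st.integers(0, 12)] * 4))
    def test_agrees_with_hypergeometric_enumeration(self, table):
        a, b, c, d = table
        assert fisher_exact_two_sided(a, b, c, d) == pytest.approx(
            fisher_oracle(a, b, c, d), rel=1e-8, abs=1e-12
        )


class TestStrandBias:
    def test_balanced_ratios_give_p_one(self):
        counts = AlleleCounts.from_dict({"C": (50, 50), "T": (10, 10)})
        assert strand_bias_p(counts, "C", "T") == pytest.approx(1.0)

    def test_one_strand_alt_rejected_below_alpha(self):
        counts = AlleleCounts.from_dict({"C": (50, 50), "T": (20, 0)})
        p = strand_bias_p(counts, "C", "T")
        assert p < 0.001
        assert p == pytest.approx(fisher_oracle(50, 50, 20, 0), rel=1e-8)

    def test_tiny_counts_not_significant(self):
        counts = AlleleCounts.from_dict({"C": (5, 5), "T": (1, 1)})
        assert strand_bias_p(counts, "C", "T") > 0.05

    def test_no_alt_reads_is_undefined(self):
        counts = AlleleCounts.from_dict({"C": (50, 50)})
        assert strand_bias_p(counts, "C", "T") is None


def _reads(alt_dists, ref_dists, alt="T", ref="C"):
    reads = [ReadEvidence(alt, 35, d, "+") for d in alt_dists]
    reads += [ReadEvidence(ref, 35, d, "-") for d in ref_dists]
    return reads


class TestTailBias:
    def test_deep_alt_reads_untagged(self, rng):
        reads = _reads([30, 33, 37, 31], list(rng.integers(0, 38, size=60)))
        assert not tail_distance_bias_tag(reads, "T")

    def test_end_clustered_alt_reads_tagged(self, rng):
        alt_d = list(rng.integers(0, 4, size=10))
        ref_d = list(rng.integers(0, 38, size=90))
        reads = _reads(alt_d, ref_d)
        assert tail_distance_bias_tag(reads, "T")
        # permutation oracle agrees the enrichment is real at the 0.005 level
        assert ranksum_less_oracle(np.array(alt_d), np.array(ref_d)) < 0.005

    def test_single_alt_read_untagged(self):
        assert not tail_distance_bias_tag(_reads([0], [20] * 50), "T")

    def test_missing_evidence_untagged(self):
        assert not tail_distance_bias_tag(None, "T")

    def test_decision_matches_permutation_oracle(self, rng):
        # random datasets: rank-sum decision at alpha agrees with a
        # Monte-Carlo permutation test away from the boundary
        for trial in range(5):
            alt_d = list(rng.integers(0, 38, size=8))
            ref_d = list(rng.integers(0, 38, size=50))
            p_perm = ranksum_less_oracle(np.array(alt_d), np.array(ref_d), seed=trial)
            tagged = tail_distance_bias_tag(_reads(alt_d, ref_d), "T")
            if p_perm < 0.002:
                assert tagged
            elif p_perm > 0.02:
                assert not tagged


class TestSomaticCandidates:
    def test_het_tumor_clean_normal_is_called(self):
        site = _site({"C": (25, 25), "T": (25, 25)}, {"C": (50, 50)})
        call = call_primary_somatic(site)
        assert call is not None
        assert (call.ref, call.alt) == ("C", "T")
        assert call.vaf_tumor == pytest.approx(0.5)
        assert call.vaf_normal == 0.0
        assert call.fisher_p < 1e-10

    def test_identical_genotypes_not_called(self):
        site = _site({"C": (50, 50)}, {"C": (50, 50)})
        assert call_primary_somatic(site) is None

    def test_subthreshold_tumor_fraction_not_called(self):
        site = _site({"C": (48, 47), "T": (3, 2)}, {"C": (50, 50)})
        assert call_primary_somatic(site) is None

    def test_germline_het_not_called(self):
        site = _site({"C": (25, 25), "T": (25, 25)}, {"C": (25, 25), "T": (25, 25)})
        assert call_primary_somatic(site) is None

    def test_label_swap_finds_normal_private_variant(self):
        # the inverse analysis: variant carried by the normal only
        site = _site({"C": (50, 50)}, {"C": (25, 25), "T": (25, 25)})
        assert call_primary_somatic(site) is None
        call = call_primary_somatic(site.swapped())
        assert call is not None and call.vaf_tumor == pytest.approx(0.5)


class TestFilterCascade:
    def test_low_depth_filtered(self):
        site = _site({"C": (3, 2), "T": (2, 2)}, {"C": (50, 50)})
        call = call_primary_somatic(site)
        out = apply_primary_filters(call, site)
        assert LOW_DEPTH in out.tags and not out.passed

    def test_low_depth_in_normal_also_filtered(self):
        site = _site({"C": (25, 25), "T": (25, 25)}, {"C": (5, 4)})
        out = apply_primary_filters(call_primary_somatic(site), site)
        assert LOW_DEPTH in out.tags and not out.passed

    def test_one_strand_alt_filtered(self):
        site = _site({"C": (40, 40), "T": (20, 0)}, {"C": (50, 50)})
        out = apply_primary_filters(call_primary_somatic(site), site)
        assert STRAND_BIAS in out.tags and not out.passed

    def test_low_mapability_filtered(self):
        site = _site({"C": (25, 25), "T": (25, 25)}, {"C": (50, 50)},
                     low_mapability=True)
        out = apply_primary_filters(call_primary_somatic(site), site)
        assert LOW_MAPABILITY in out.tags and not out.passed

    def test_clean_site_passes_with_no_tags(self):
        site = _site({"C": (25, 25), "T": (25, 25)}, {"C": (50, 50)})
        out = apply_primary_filters(call_primary_somatic(site), site)
        assert out.passed and out.tags == frozenset()

    def test_depth_exactly_ten_passes(self):
        site = _site({"C": (3, 2), "T": (3, 2)}, {"C": (5, 5)})
        out = apply_primary_filters(call_primary_somatic(site), site)
        assert LOW_DEPTH not in out.tags

    def test_filter_monotonicity(self, noisy_patient):
        # a stricter depth filter never increases the passed-call count
        sites = noisy_patient.lesions["P1_L1"]
        loose = sum(c.passed for c in call_lesion_primary(sites, min_depth=10))
        strict = sum(c.passed for c in call_lesion_primary(sites, min_depth=60))
        assert strict <= loose


class TestRecoveryOnCleanData:
    def test_all_clonal_truth_recovered_and_nothing_else(self, clean_patient):
        # error-free, artifact-free, all-clonal: passed calls == truth, exactly
        for lid, sites in clean_patient.lesions.items():
            passed = {c.key for c in call_lesion_primary(sites) if c.passed}
            assert passed == clean_patient.truth.somatic_keys(lid)

    def test_inverse_direction_is_silent_on_clean_data(self, clean_patient):
        sites = [s.swapped() for s in clean_patient.lesions["P1_L1"]]
        calls = call_lesion_primary(sites)
        assert sum(c.passed for c in calls) == 0
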