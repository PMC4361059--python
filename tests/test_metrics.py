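"""Burden indices, substitution spectrum, CpG summaries, spectrum comparison."""

import pytest

from polyclone.errors import ConfigError, ValidationError
from polyclone.metrics import (
    compare_spectra,
    count_aa_changing,
    inverse_analysis,
    is_cpg_dimer,
    lesion_metrics,
    mutational_index,
    spectrum_summary,
    substitution_class,
)
from polyclone.primary import call_lesion_primary
from polyclone.sites import LesionCallSet, VariantCall

# Published per-lesion burden table: (amino-acid-changing count, index,
# inverse count, inverse index) over a 30 Mb effective exome target.
BURDEN_TABLE = [
    (56, 1.87, 2, 0.07),
    (93, 3.10, 3, 0.10),
    (84, 2.80, 4, 0.13),
    (35, 1.17, 2, 0.07),
    (45, 1.50, 6, 0.20),
    (74, 2.47, 4, 0.13),
    (130, 4.33, 4, 0.13),
    (74, 2.47, 9, 0.30),
    (33, 1.10, 7, 0.23),
    (155, 5.17, 14, 0.47),
    (33, 1.10, 5, 0.17),
    (25, 0.83, 8, 0.27),
    (58, 1.93, 9, 0.30),
]


class TestMutationalIndex:
    @pytest.mark.parametrize("count,index", [(c, i) for c, i, _, _ in BURDEN_TABLE]
                             + [(c, i) for _, _, c, i in BURDEN_TABLE])
    def test_reproduces_published_count_index_pairs(self, count, index):
        assert mutational_index(count, 30) == index

    def test_zero_mutations(self):
        assert mutational_index(0, 30) == 0.0

    def test_half_up_rounding(self):
        # 0.125 rounds up to 0.13, not banker's 0.12
        assert mutational_index(15, 120) == 0.13

    def test_linearity_before_rounding(self):
        for n in (7, 31, 88):
            assert 2 * n / 30 == pytest.approx(2 * (n / 30))
            assert mutational_index(2 * n, 30) == pytest.approx(2 * n / 30, abs=0.005)

    def test_nonpositive_target_rejected(self):
        with pytest.raises(ConfigError):
            mutational_index(10, 0)


class TestSubstitutionClass:
    @pytest.mark.parametrize("ref,alt,expected", [
        ("G", "A", "C>T"), ("C", "T", "C>T"), ("A", "C", "T>G"),
        ("A", "G", "T>C"), ("T", "A", "T>A"), ("G", "C", "C>G"),
        ("G", "T", "C>A"), ("A", "T", "T>A"),
    ])
    def test_complement_collapse(self, ref, alt, expected):
        assert substitution_class(ref, alt) == expected

    def test_all_twelve_collapse_to_six(self):
        classes = {
            substitution_class(r, a)
            for r in "ACGT" for a in "ACGT" if r != a
        }
        assert classes == {"C>A", "C>G", "C>T", "T>A", "T>C", "T>G"}

    def test_invalid_base_rejected(self):
        with pytest.raises(ValidationError):
            substitution_class("N", "A")


class TestCpgDimer:
    @pytest.mark.parametrize("ctx,ref,expected", [
        ("ACG", "C", True),
        ("CGT", "G", True),
        ("ACT", "C", False),
        ("AGT", "G", False),
        ("TCG", "C", True),
    ])
    def test_dimer_detection(self, ctx, ref, expected):
        assert is_cpg_dimer(ctx, ref, "T" if ref == "C" else "A") is expected

    def test_malformed_context_rejected(self):
        with pytest.raises(ValidationError):
            is_cpg_dimer("AAG", "C", "T")


def _call(pos, ref, alt, passed=True, chrom="chr1"):
    return VariantCall(chrom=chrom, pos=pos, ref=ref, alt=alt,
                       vaf_tumor=0.3, vaf_normal=0.0, passed=passed)


_RC = {"A": "T", "C": "G", "G": "C", "T": "A"}


class TestSpectrumSummary:
    def test_cpg_fraction(self):
        calls = [_call(1, "C", "T"), _call(2, "C", "T"), _call(3, "C", "T"),
                 _call(4, "C", "T")]
        contexts = {("chr1", 1): "ACG", ("chr1", 2): "TCG", ("chr1", 3): "CCG",
                    ("chr1", 4): "ACA"}
        sp = spectrum_summary(calls, contexts)
        assert sp.cpg_fraction_of_cg_transitions == pytest.approx(0.75)
        assert sp.class_fractions["C>T"] == 1.0

    def test_single_class_fraction_one(self):
        calls = [_call(i, "T", "G") for i in range(1, 6)]
        sp = spectrum_summary(calls, contexts={})
        assert sp.class_fractions["T>G"] == 1.0
        assert sp.cpg_fraction_of_cg_transitions is None

    def test_empty_call_set_flagged(self):
        sp = spectrum_summary([], contexts={})
        assert sp.empty and sp.n_total == 0

    def test_reverse_complement_invariance(self, rng):
        calls, contexts = [], {}
        for pos in range(1, 80):
            ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
            ctx = str(rng.choice(list("ACGT"))) + str(ref) + str(rng.choice(list("ACGT")))
            calls.append(_call(pos, str(ref), str(alt)))
            contexts[("chr1", pos)] = ctx
        rc_calls = [_call(c.pos, _RC[c.ref], _RC[c.alt]) for c in calls]
        rc_contexts = {
            k: "".join(_RC[b] for b in reversed(ctx)) for k, ctx in contexts.items()
        }
        a = spectrum_summary(calls, contexts)
        b = spectrum_summary(rc_calls, rc_contexts)
        assert a.class_counts == b.class_counts
        assert a.n_cg_transitions_cpg == b.n_cg_transitions_cpg

    def test_simulated_spectrum_is_cpg_transition_heavy(self, noisy_patient):
        # generator draws half of somatic events as CpG C>T transitions
        truth_calls = [
            _call(v.pos, v.ref, v.alt, chrom=v.chrom)
            for v in noisy_patient.truth.somatic["P1_L1"]
        ]
        sp = spectrum_summary(truth_calls, noisy_patient.contexts())
        assert sp.class_fractions["C>T"] > 0.5
        assert sp.cpg_fraction_of_cg_transitions > 0.5


class TestCompareSpectra:
    def _sp(self, cpg, non):
        calls = [_call(i + 1, "C", "T") for i in range(cpg + non)]
        ctx = {("chr1", i + 1): ("ACG" if i < cpg else "ACA") for i in range(cpg + non)}
        return spectrum_summary(calls, ctx)

    def test_identical_proportions_p_one(self):
        assert compare_spectra(self._sp(5, 5), self._sp(5, 5)) == pytest.approx(1.0)

    def test_opposite_composition_matches_enumeration(self):
        p = compare_spectra(self._sp(10, 0), self._sp(0, 10))
        assert p == pytest.approx(2 / 184756, rel=1e-9)

    def test_tiny_identical_sets(self):
        assert compare_spectra(self._sp(1, 1), self._sp(1, 1)) == pytest.approx(1.0)

    def test_no_transitions_is_undefined(self):
        calls = [_call(1, "T", "G")]
        sp = spectrum_summary(calls, {})
        assert compare_spectra(sp, self._sp(3, 3)) is None


class TestLesionMetricsAndInverse:
    def test_count_uses_unique_passed_aa_changing_keys(self):
        calls = [
            _call(1, "C", "T").with_(consequence="missense"),
            _call(2, "C", "T").with_(consequence="truncating"),
            _call(3, "C", "T").with_(consequence="synonymous"),
            _call(4, "C", "T").with_(consequence="missense", passed=False),
        ]
        cs = LesionCallSet("L", "P", calls=calls)
        assert count_aa_changing(cs) == 2
        m = lesion_metrics(cs, target_mb=30, n_inverse=14)
        assert m.mut_index == 0.07
        assert m.inverse_index == 0.47

    def test_inverse_is_silent_on_clean_data(self, clean_patient):
        sites = clean_patient.lesions["P1_L1"]
        n, idx = inverse_analysis(sites, transcripts=clean_patient.transcripts)
        assert n == 0 and idx == 0.0

    def test_double_swap_restores_forward_metrics(self, clean_patient):
        sites = clean_patient.lesions["P1_L2"]
        forward = {c.key for c in call_lesion_primary(sites) if c.passed}
        double = [s.swapped().swapped() for s in sites]
        again = {c.key for c in call_lesion_primary(double) if c.passed}
        assert forward == again
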