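"""Simulate a paired tumor/normal cohort and inspect its ground truth.

Each patient gets one normal sample and several synchronous lesions;
somatic mutations are private to a lesion by default, so the cohort
reproduces the "no recurrent mutation between sibling lesions"
structure that downstream heterogeneity reports measure.
"""

from polyclone.simulate import SimParams, simulate_cohort

params = SimParams(n_patients=2, lesions_per_patient=3, seed=1)
cohort = simulate_cohort(params)

for sim in cohort:
    print(f"patient {sim.patient_id}: {len(sim.transcripts)} genes, "
          f"{len(sim.truth.germline)} germline SNPs")
    for lid, variants in sim.truth.somatic.items():
        n_sub = sum(v.clonality == "subclonal" for v in variants)
        n_aa = sum(v.consequence in ("missense", "truncating") for v in variants)
        print(f"  {lid}: {len(variants)} somatic "
              f"({n_sub} subclonal, {n_aa} amino-acid changing)")

# Counts per lesion land in the tens, the per-lesion range a multi-lesion
# exome study reports; subclonal events dominate, as in real adenomas.
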