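"""Primary somatic calling: genotype comparison plus the filter cascade.

Calls are emitted where the tumor genotype differs from a homozygous-
reference normal, then filtered on depth (< 10), strand-bias
probability (< 0.001) and low mapability; tail-distance bias is
annotated but never filters.
"""

from collections import Counter

from polyclone.primary import call_lesion_primary
from polyclone.simulate import SimParams, simulate_patient

sim = simulate_patient(SimParams(seed=1), 0)
sites = sim.lesions["P1_L1"]
calls = call_lesion_primary(sites)

tags = Counter(tag for c in calls for tag in c.tags)
print(f"{len(calls)} candidate calls, {sum(c.passed for c in calls)} passed")
print("filter tags:", dict(tags))

truth = sim.truth.somatic_keys("P1_L1")
passed = {c.key for c in calls if c.passed}
clonal = {(v.chrom, v.pos, v.ref, v.alt)
          for v in sim.truth.somatic["P1_L1"] if v.clonality == "clonal"}
print(f"clonal truth recovered: {len(clonal & passed)}/{len(clonal)}")
print(f"passed calls that are true somatic events: {len(passed & truth)}/{len(passed)}")

# The genotype-threshold caller sees every clonal (50% VAF) mutation but,
# by construction, only the upper tail of the subclonal ones - detecting
# the rest is the subclonal caller's job (example 03).
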