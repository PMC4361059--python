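# polyclone

Somatic mutation analysis for **multiple synchronous colorectal lesions**
sequenced against a shared matched normal: paired tumor/normal SNV calling
with an explicit filter cascade, minimum-evidence subclonal detection, a
deep-amplicon validation rule, per-lesion mutation-burden and
substitution-spectrum metrics, and cross-lesion heterogeneity reports.

The package is aimed at researchers studying intra-patient tumor
heterogeneity — the situation where one endoscopic procedure yields a
carcinoma plus several adenomas or polyps, and the question is whether
those lesions share mutations (one clonal origin) or not (independent
origins). Because raw multi-lesion exome data is rarely at hand, the
package ships a synthetic cohort generator that emulates the paired-exome
data structure end to end, with ground truth for every stage.

## The model

For one genomic site with reference allele R and candidate alternate A,
each sample contributes strand-resolved counts `(n_R+, n_R-, n_A+, n_A-)`.

**Primary (clonal) caller.** Each sample is genotyped from its alternate
allele fraction `f = n_A / depth` with fixed thresholds (hom-ref below
0.10, het up to 0.85, hom-alt above). A somatic candidate requires a
hom-ref normal and a non-reference tumor genotype; the call is annotated
with the two-sided Fisher exact probability of the 2×2 table
(ref, alt) × (tumor, normal). The filter cascade then removes calls with

- depth < 10 in either sample (`LOW_DEPTH`),
- Fisher strand-bias probability < 0.001 on (ref fwd, ref rev) ×
  (alt fwd, alt rev) (`STRAND_BIAS`),
- positions in low-mapability regions (`LOW_MAPABILITY`),

and annotates (without filtering) tail-distance bias — a one-sided
rank-sum test for alternate evidence clustering near read ends
(`TAIL_BIAS`).

**Subclonal caller.** A minimum-evidence rule on per-read records: at
least 2 mutant reads that are high-quality (Q ≥ 20), independently
confirmed by a second alignment, and ≥ 5 bp from the nearer read end —
with *absolutely no* mutant read of any quality in the matched normal.
Candidates near DNA repeats, at known germline variant positions, or
supported only by read-end evidence are removed. Its detection
probability is the binomial tail P(X ≥ 2), X ~ Bin(depth, VAF); at 100X
this is ≈ 0.96 for VAF 0.05, which is what makes a 5% subclonal floor
realistic at exome depth.

**Validation rule.** At amplicon depth (~600X), a call is *validated*
when the tumor shows ≥ 5 mutant reads comprising ≥ 1% of reads and the
normal shows none; coverage < 20 in either sample makes the position not
evaluable. Concordance is the validated fraction among primary calls
with mutational percentage (tumor VAF) above 15%.

**Metrics.** The *mutational index* is the count of unique, passed,
amino-acid-changing mutations divided by the effective exome target size
(default 30 Mb), rounded half-up to 2 decimals. The *inverse analysis*
re-runs the primary pipeline with tumor and normal swapped — a
noise-floor control. The substitution spectrum collapses SNVs onto the
six pyrimidine-reference classes {C>A, C>G, C>T, T>A, T>C, T>G} and
reports the fraction of C>T/G>A transitions at CpG dimers; two spectra
are compared with a Fisher test on their (CpG, non-CpG) composition.

**Heterogeneity.** A *recurrent mutation* is an identical
(chrom, pos, ref, alt) key in two lesions of the same patient; gene-level
recurrence (different variants, same gene) is reported separately, and
calls are labeled clonal/subclonal at a configurable VAF threshold
(default 0.25, half the diploid heterozygous expectation).

## Worked example

```python
from polyclone.simulate import SimParams, simulate_patient
from polyclone.primary import call_lesion_primary
from polyclone.consequence import annotate_calls
from polyclone.metrics import inverse_analysis, lesion_metrics
from polyclone.sites import LesionCallSet

sim = simulate_patient(SimParams(seed=1), 0)   # 1 normal + 3 lesions, 99X
for lid, sites in sim.lesions.items():
    calls = annotate_calls(call_lesion_primary(sites), sim.transcripts)
    cs = LesionCallSet(lid, sim.patient_id, calls=calls)
    n_inv, inv_idx = inverse_analysis(sites, transcripts=sim.transcripts)
    m = lesion_metrics(cs, target_mb=30, n_inverse=n_inv)
    print(f"{lid}: {m.n_aa_changing} AA-changing, index {m.mut_index:.2f}; "
          f"inverse {n_inv} ({inv_idx:.2f}/Mb)")
```

prints

```
P1_L1: 23 AA-changing, index 0.77; inverse 0 (0.00/Mb)
P1_L2: 18 AA-changing, index 0.60; inverse 0 (0.00/Mb)
P1_L3: 23 AA-changing, index 0.77; inverse 0 (0.00/Mb)
```

— each lesion carries its own amino-acid-changing burden, while the
swapped (normal-as-tumor) control finds nothing: the asymmetry a genuine
tumor/normal comparison should show. The `examples/` directory has one
short script per capability (simulation, both callers, burden metrics,
amplicon validation, spectrum and heterogeneity, and the end-to-end
pipeline); `polyclone run-all --seed 1 --out-dir out/` produces the same
reports from the shell.

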