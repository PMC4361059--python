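# Methods

This note documents the models, thresholds, and design decisions behind
`polyclone`, and what the synthetic cohort does and does not show about
real data.

## Calling models

### Primary (clonal) caller

Genotypes are assigned per sample from the alternate allele fraction of
the most frequent non-reference base: hom-ref below `het_min` (0.10),
het between `het_min` and `hom_alt_min` (0.85), hom-alt above. Fixed
fraction thresholds were chosen over a likelihood-based genotyper
deliberately: they are deterministic, transparent, directly testable,
and at ≥ 10X depth they separate the three diploid genotypes cleanly.
Zero depth yields a no-call sentinel. Only the somatic direction is a
candidate: normal hom-ref, tumor non-reference. Loss-of-heterozygosity
directions are ignored; the pipeline reports somatic point mutations
only.

The tumor-normal Fisher exact probability (two-sided, on the
(ref, alt) × (tumor, normal) count table) is annotated on every call but
not thresholded by default — any cutoff is a config choice, default
none. The Fisher routine wraps `scipy.stats.fisher_exact`; the test
suite checks it exhaustively against an independent integer
hypergeometric enumeration for every 2×2 table with total ≤ 30
(46,376 tables, agreement to 1e-9).

Filter cascade (disqualifying): `LOW_DEPTH` when either sample is below
10 reads; `STRAND_BIAS` when the two-sided Fisher probability of the
(ref fwd, ref rev) × (alt fwd, alt rev) table is below 0.001;
`LOW_MAPABILITY` from the mapability mask. `TAIL_BIAS` — a one-sided
Mann-Whitney comparison of end distances between alternate- and
reference-supporting reads at α = 0.005, requiring ≥ 2 alternate reads —
is annotate-only, since the modeled pipeline lists it among tags, not
filters. Depth < 10 acts simultaneously as filter and tag.

### Subclonal (minimum-evidence) caller

A qualified mutant read has the candidate base with base quality ≥ 20,
carries the independent-alignment confirmation flag, and lies ≥ 5 bp
from the nearer read end. A call requires ≥ 2 qualified tumor reads and
**zero** mutant reads of any quality in the normal. "High quality" and
"minimum evidence" are fixed here at Q20 and 2 reads (both
configurable); "near the read end" at < 5 bp; repeat proximity is
delegated to the repeat BED with a 10 bp flank applied at mask load.
These are explicit, adjustable stand-ins for operational constants the
modeled procedure does not define numerically. Independent re-alignment
is abstracted to the per-read `confirmed` flag: alignment itself is out
of scope, but the decision rule — independent confirmation required — is
preserved. The "minimum value of 2" is read as ≥ 2 qualified mutant
reads (rather than a combined aligner score).

Sites whose strand counts show no alternate reads return no call
without consulting per-read evidence: the two-read minimum cannot be
met, and this lets the generator and the caller skip per-read records
at the ~80–90% of sites that are pure reference. A site that *does*
carry alternate counts but lacks read records is a hard error directing
the user to the count-based primary caller.

Detection probability is the exact binomial tail
`P(X >= min_reads), X ~ Binomial(depth, VAF)`; at VAF 0.05 and 100X it
is 0.9629, which quantifies the caller's ~5% VAF floor at exome depth.

### Consequence classification

Toy transcripts (ordered CDS intervals, 0-based half-open, plus the
spliced CDS sequence validated for ATG start, terminal stop and length
divisible by 3) replace a full annotation engine at desk scale. A SNV
maps strand-aware to its codon; translation uses the standard genetic
code (Biopython). Labels: `synonymous`, `missense`, `truncating` (stop
gained, stop lost, or start lost), `non_coding`. When a variant hits
several transcripts the most severe label (truncating > missense >
synonymous > non_coding) and its gene are reported. No splice-site, UTR
or regulatory annotation; standard code only.

### Validation rule and concordance

Validated: tumor mutant reads ≥ 5 **and** mutant fraction ≥ 1% **and**
zero mutant reads in the normal; not evaluable when either sample is
below 20X. "Independent mutant reads" is treated as the raw mutant
count — amplicon duplicate structure is out of scope. Concordance is
computed per variant (the fraction validated among evaluable primary
calls with tumor VAF above the 0.15 MP threshold); a per-gene roll-up
(`gene_concordance_rate`) is available since a per-gene reading of the
rate is also defensible. With no call above threshold the rate is
undefined (`None`), never 0.

Note an emergent property of the strict zero-in-normal clause: at ~600X
amplicon depth with a 1e-3 sequencing error rate, the normal draws at
least one error read at the mutant base with probability ~0.18, so even
true mutations validate at only ~80–90% — strict rules on deep data are
conservative by construction.

### Metrics and heterogeneity

The mutational index is `round_half_up(n / target_mb, 2)` with
`target_mb` defaulting to 30 — the effective exome target implied by
the published count/index ratios (56/1.87, 155/5.17, 130/4.33 ≈ 30.0);
all 26 published pairs reproduce exactly under half-up rounding, which
is why banker's rounding is not used. Only unique, passed,
amino-acid-changing (chrom, pos, ref, alt) keys enter the count. The
inverse analysis re-runs the identical primary pipeline on role-swapped
pileups.

Spectrum classes are the six complement-collapsed substitution classes;
CpG membership uses the reference trinucleotide (C with 3' G, or G with
5' C) and is summarized as the CpG fraction of C>T/G>A transitions.
The summary is invariant under reverse-complementing the entire input
(property-tested). The pooled-vs-per-sample ambiguity in "fraction of
transitions at CpG" is resolved by reporting per lesion; pooling is a
one-liner over the per-class counts.

Recurrence is defined on exact variant keys; gene-level recurrence is a
separate column, because independent lesions can converge on the same
driver gene without sharing one variant. Clonality defaults to a 0.25
VAF threshold (half the diploid het expectation), closed on the clonal
side; the threshold is a reporting convention, not an inference.

## Synthetic cohort

The generator emulates the paired multi-lesion exome structure the
pipeline is built for. Defaults are the study-like conditions used
throughout the tests:

| parameter | default | rationale |
|---|---|---|
| depth (tumor & normal) | NB, mean 99 | ~99X mean target coverage; overdispersion 0.013 puts most samples in ~78–141X |
| n_sites | 5,000 | desk-scale target; per-lesion event counts land in the published 25–155 range |
| somatic_rate | 0.01 /site/lesion | ~50 somatic events per lesion |
| clonal_vaf | 0.5 | diploid heterozygous somatic mutation |
| subclonal_vaf_range | [0.05, 0.25] | down to the 5% detection floor |
| fraction_subclonal | 0.6 | a majority of adenoma mutations are subclonal |
| shared_fraction | 0 | independent lesions; no recurrent mutation between siblings |
| germline_rate | 0.002 | het:hom 4:1, present in normal and all lesions |
| error_rate | 1e-3 | ~Q30 post-filter base error |
| artifact rates | 5e-4 each | all-one-strand sites (VAF 0.2) and read-end-only sites |
| amplicon_depth_mean | 600 | deep targeted re-sequencing |
| cpg_ct_fraction / ct_fraction | 0.5 / 0.2 | C>T/G>A-dominated spectrum, ~70% of transitions at CpG |

Mechanics worth knowing:

- **Reference and genes.** Each patient gets a random reference with
  embedded toy genes (ATG … stop, 1–3 exons, both strands, ~60% of the
  target coding) so consequence classification has real structure. The
  reference is padded so every position has a full trinucleotide
  context.
- **Shared-fraction semantics.** Somatic events are drawn per patient;
  each event goes to all lesions with probability `s`, otherwise to one
  lesion uniformly, and the pool size is scaled so the expected
  per-lesion count stays `somatic_rate × n_sites`. For two lesions this
  makes the expected truth-set Jaccard equal `s`, which is what the
  recovery tests estimate.
- **Counts.** Mutant-site alternate reads are Binomial(depth, VAF);
  remaining reads error to a uniform other base at `error_rate`; strand
  assignment is Bernoulli(0.5) except at strand-bias artifact sites,
  where alternate reads pile onto one strand. Read-end artifact reads
  get end distances inside the exclusion zone. Artifact reads carry
  confirmed, mutation-grade qualities so only the *targeted* filter
  removes them.
- **Read evidence.** Per-read records (quality, end distance, strand,
  confirmation) are attached wherever either sample carries alternate
  counts; true-mutation reads are confirmed with Q25–40, error reads
  get Q5–35 and a coin-flip confirmation. Normal-sample read records
  are generated from a per-site seed so they are identical in every
  lesion's pileup pair.
- **Determinism.** A single global seed spawns per-patient seeds by
  fixed arithmetic (`seed·100003 + index·7919 + 1 mod 2³¹−1`), so tests
  can target one patient; same seed ⇒ bit-identical cohort.

**What the generator does not model:** purity (true VAF is the observed
expectation, not decomposed into purity × CCF), copy number, indels,
multi-allelic sites, PCR duplicates, mapping artifacts beyond the two
injected classes, and FASTQ-level read simulation. Passing tests
therefore demonstrate that the decision rules and statistics behave as
specified under binomial sampling with realistic depths, error and
artifact structure — not that the pipeline is robust to every alignment
pathology of real exomes.

## Numerical and interface choices

- Coordinates: variants are 1-based (VCF); interval masks are 0-based
  half-open (BED). A variant at position p is inside BED region
  [p−1, p); mask membership tests `start < p <= end`.
- Ties in "best alternate base" break in fixed A<C<G<T order.
- Fisher with an all-zero margin returns p = 1 by convention; strand
  bias with zero alternate reads is undefined (None), not 1.
- Rank-sum tail test requires ≥ 2 alternate reads; ties-only inputs are
  untagged.
- Rounding of indices is decimal half-up (not float banker's), to 2
  decimals.
- VCF round trips use htslib via pysam; floats survive to ~7
  significant digits, so call-set equality after a round trip is exact
  on all fields except floats, which agree to 1e-5 relative.
- The `run-all` manifest records config, seed, package version and a
  SHA-256 per output; stages are pure functions of (inputs, config) and
  re-runs are byte-identical.
- Problem sizes in the test suite (5,000-site patients, 10,000-site
  recovery experiments, 200-patient truth cohorts) are the package's
  desk-scale defaults: large enough for 3-standard-error statistical
  checks, small enough to iterate on quickly.

## Known limitations

- The primary caller's fixed genotype thresholds ignore base qualities;
  at depths well below 10 the het/hom boundaries are noisy (such calls
  are filtered anyway).
- The subclonal caller's specificity relies on the confirmation flag
  and the matched normal; with error rates far above 1e-3 or an
  unmatched normal it will admit noise.
- Concordance on synthetic amplicons inherits the strict zero-in-normal
  clause (see above); interpreting it as caller accuracy would be
  wrong — it measures the joint behavior of caller and validation rule.
- Single-lesion patients skip the comparison stage; heterogeneity
  statistics need ≥ 2 lesions by definition.
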