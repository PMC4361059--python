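"""Primary somatic caller: genotype thresholds, Fisher comparison, filters.

This is the clonal-variant stage of the pipeline. Each sample is
genotyped from its allele-fraction at the site using fixed thresholds
(a deterministic, transparent stand-in for a likelihood-based
genotyper); a somatic candidate is a site where the normal is
homozygous reference and the tumor genotype differs. Candidates get a
two-sided Fisher exact probability on the tumor/normal ref-alt counts
and then pass through the filter cascade: depth < 10 in either sample,
strand-bias probability < 0.001, or low-mapability regions disqualify
a call; tail-distance bias is annotated but does not filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from scipy import stats

from polyclone.sites import (
    LOW_DEPTH,
    LOW_MAPABILITY,
    PRIMARY_FAIL_TAGS,
    STRAND_BIAS,
    TAIL_BIAS,
    AlleleCounts,
    ReadEvidence,
    SitePileup,
    VariantCall,
)

#: Default allele-fraction genotype thresholds.
HET_MIN = 0.10
HOM_ALT_MIN = 0.85
#: Default filter thresholds.
MIN_DEPTH = 10
STRAND_BIAS_ALPHA = 0.001
TAIL_BIAS_ALPHA = 0.005


@dataclass(frozen=True, slots=True)
class GenotypeCall:
    """Threshold genotype of one sample at one site."""

    genotype: str  # "hom_ref" | "het" | "hom_alt" | "no_call"
    alt_base: Optional[str]
    alt_fraction: float


def call_genotype(
    counts: AlleleCounts,
    ref_base: str,
    het_min: float = HET_MIN,
    hom_alt_min: float = HOM_ALT_MIN,
) -> GenotypeCall:
    """Genotype one sample by the fraction of its top non-reference base.

    Below ``het_min`` the site is hom_ref, above ``hom_alt_min`` hom_alt,
    between them het. Zero depth yields the no-call sentinel.
    """
    depth = counts.depth
    if depth == 0:
        return GenotypeCall("no_call", None, 0.0)
    alt = counts.best_alt(ref_base)
    if alt is None:
        return GenotypeCall("hom_ref", None, 0.0)
    frac = counts.count(alt) / depth
    if frac < het_min:
        return GenotypeCall("hom_ref", alt, frac)
    if frac > hom_alt_min:
        return GenotypeCall("hom_alt", alt, frac)
    return GenotypeCall("het", alt, frac)


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact probability of the 2x2 table [[a, b], [c, d]].

    Sums hypergeometric probabilities of all tables with the observed
    margins whose probability does not exceed that of the observed
    table. All-zero margins return 1 by convention.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("Fisher table entries must be non-negative")
    if (a + b == 0 and c + d == 0) or (a + c == 0 and b + d == 0):
        return 1.0
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(min(p, 1.0))


def strand_bias_p(counts: AlleleCounts, ref_base: str, alt_base: str) -> Optional[float]:
    """Fisher two-sided p for strand imbalance of alt versus ref reads.

    The 2x2 table is (ref fwd, ref rev) x (alt fwd, alt rev). Returns
    None when there are no alt reads (no bias assessable).
    """
    alt_f, alt_r = counts.fwd(alt_base), counts.rev(alt_base)
    if alt_f + alt_r == 0:
        return None
    return fisher_exact_two_sided(counts.fwd(ref_base), counts.rev(ref_base), alt_f, alt_r)


def tail_distance_bias_tag(
    tumor_reads: Optional[list[ReadEvidence]],
    alt_base: str,
    alpha: float = TAIL_BIAS_ALPHA,
) -> bool:
    """True when alt-supporting reads sit significantly nearer read ends.

    One-sided Wilcoxon rank-sum (Mann-Whitney) comparison of
    end-distance between alt- and ref-supporting reads; requires at
    least 2 alt reads and read-level evidence, otherwise untagged.
    """
    if not tumor_reads:
        return False
    alt_d = [r.end_distance for r in tumor_reads if r.base == alt_base]
    ref_d = [r.end_distance for r in tumor_reads if r.base != alt_base]
    if len(alt_d) < 2 or not ref_d:
        return False
    if len(set(alt_d + ref_d)) == 1:
        return False
    res = stats.mannwhitneyu(alt_d, ref_d, alternative="less")
    return bool(res.pvalue < alpha)


def call_primary_somatic(
    site: SitePileup,
    het_min: float = HET_MIN,
    hom_alt_min: float = HOM_ALT_MIN,
) -> Optional[VariantCall]:
    """Emit a somatic candidate when tumor and normal genotypes differ.

    Only the somatic direction is considered: the normal must be
    homozygous reference and the tumor must carry a non-reference
    genotype. The Fisher exact probability of the tumor/normal
    (ref, alt) count table is annotated on the call.
    """
    ref = site.ref_base
    gt_t = call_genotype(site.tumor, ref, het_min, hom_alt_min)
    gt_n = call_genotype(site.normal, ref, het_min, hom_alt_min)
    if gt_t.genotype in ("no_call", "hom_ref") or gt_n.genotype != "hom_ref":
        return None
    alt = gt_t.alt_base
    t_alt, n_alt = site.tumor.count(alt), site.normal.count(alt)
    t_depth, n_depth = site.tumor.depth, site.normal.depth
    p = fisher_exact_two_sided(t_depth - t_alt, t_alt, n_depth - n_alt, n_alt)
    return VariantCall(
        chrom=site.chrom,
        pos=site.pos,
        ref=ref,
        alt=alt,
        vaf_tumor=t_alt / t_depth,
        vaf_normal=(n_alt / n_depth) if n_depth else 0.0,
        fisher_p=p,
        source="primary",
    )


def apply_primary_filters(
    call: VariantCall,
    site: SitePileup,
    min_depth: int = MIN_DEPTH,
    strand_bias_alpha: float = STRAND_BIAS_ALPHA,
    tail_bias_alpha: float = TAIL_BIAS_ALPHA,
) -> VariantCall:
    """Tag and filter a primary candidate.

    LOW_DEPTH (either sample below ``min_depth``), STRAND_BIAS (Fisher
    strand probability below ``strand_bias_alpha``) and LOW_MAPABILITY
    disqualify the call; TAIL_BIAS is annotate-only.
    """
    tags = set(call.tags)
    if site.tumor.depth < min_depth or site.normal.depth < min_depth:
        tags.add(LOW_DEPTH)
    sb = strand_bias_p(site.tumor, call.ref, call.alt)
    if sb is not None and sb < strand_bias_alpha:
        tags.add(STRAND_BIAS)
    if site.low_mapability:
        tags.add(LOW_MAPABILITY)
    if tail_distance_bias_tag(site.tumor_reads, call.alt, tail_bias_alpha):
        tags.add(TAIL_BIAS)
    return call.with_(tags=frozenset(tags), passed=not (tags & PRIMARY_FAIL_TAGS))


def call_lesion_primary(
    sites: list[SitePileup],
    het_min: float = HET_MIN,
    hom_alt_min: float = HOM_ALT_MIN,
    min_depth: int = MIN_DEPTH,
    strand_bias_alpha: float = STRAND_BIAS_ALPHA,
    tail_bias_alpha: float = TAIL_BIAS_ALPHA,
) -> list[VariantCall]:
    """Run candidate generation plus the filter cascade over a lesion."""
    calls = []
    for site in sites:
        cand = call_primary_somatic(site, het_min, hom_alt_min)
        if cand is not None:
            calls.append(
                apply_primary_filters(cand, site, min_depth, strand_bias_alpha, tail_bias_alpha)
            )
    return calls
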