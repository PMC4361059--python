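"""Minimum-evidence subclonal caller.

Accepts a candidate on a small fixed number of independently confirmed,
high-quality mutant reads in the tumor with absolutely no evidence of
the same change in the matched normal — the evidence bar that lets the
pipeline see subclones down to ~5% VAF at exome depths, far below what
a genotype-threshold caller can resolve. Candidates near DNA repeats,
at known germline variant positions, or supported only by read-end
evidence are removed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from scipy import stats

from polyclone.errors import MissingEvidenceError
from polyclone.sites import (
    KNOWN_VARIANT,
    NEAR_REPEAT,
    READ_END_ONLY,
    SUBCLONAL_FAIL_TAGS,
    SitePileup,
    VariantCall,
)

#: Default evidence thresholds.
MIN_MUTANT_READS = 2
MIN_BASEQ = 20
END_EXCLUSION_BP = 5


@dataclass(frozen=True, slots=True)
class EvidenceSummary:
    """Read-level mutant evidence at one site for one alternate base."""

    qualified_mutant_reads: int
    total_mutant_reads: int
    normal_mutant_reads: int
    end_only: bool


def summarize_evidence(
    site: SitePileup,
    alt_base: str,
    min_baseq: int = MIN_BASEQ,
    end_exclusion_bp: int = END_EXCLUSION_BP,
) -> EvidenceSummary:
    """Count qualified mutant reads for ``alt_base`` at a site.

    A read qualifies when it reports the alternate base with base
    quality >= ``min_baseq``, carries independent-alignment confirmation,
    and sits at least ``end_exclusion_bp`` from the nearer read end.
    Normal mutant reads are counted with no quality bar at all — any
    evidence of the change in the normal disqualifies the site.
    ``end_only`` flags sites whose otherwise-qualified evidence all
    falls inside the end-exclusion zone.
    """
    if site.tumor_reads is None:
        raise MissingEvidenceError(
            f"{site.chrom}:{site.pos}: no read-level evidence; subclonal calling requires "
            "per-read records (use the primary caller for count-only input)"
        )
    qualified = 0
    total = 0
    quality_ok_any = False
    quality_and_end_ok = False
    for r in site.tumor_reads:
        if r.base != alt_base:
            continue
        total += 1
        if r.base_quality >= min_baseq and r.confirmed:
            quality_ok_any = True
            if r.end_distance >= end_exclusion_bp:
                quality_and_end_ok = True
                qualified += 1
    normal_mut = 0
    if site.normal_reads is not None:
        normal_mut = sum(1 for r in site.normal_reads if r.base == alt_base)
    else:
        normal_mut = site.normal.count(alt_base)
    end_only = total > 0 and quality_ok_any and not quality_and_end_ok
    return EvidenceSummary(
        qualified_mutant_reads=qualified,
        total_mutant_reads=total,
        normal_mutant_reads=normal_mut,
        end_only=end_only,
    )


def call_subclonal_site(
    site: SitePileup,
    min_baseq: int = MIN_BASEQ,
    end_exclusion_bp: int = END_EXCLUSION_BP,
    min_mutant_reads: int = MIN_MUTANT_READS,
) -> Optional[VariantCall]:
    """Emit a subclonal candidate on minimum qualified evidence.

    A call requires at least ``min_mutant_reads`` qualified mutant reads
    in the tumor and zero mutant reads of any quality in the normal.
    Sites whose strand counts show no alternate reads return None
    without consulting read-level evidence (the bar cannot be met).
    """
    ref = site.ref_base
    alt = site.tumor.best_alt(ref)
    if alt is None:
        return None
    summary = summarize_evidence(site, alt, min_baseq, end_exclusion_bp)
    if summary.qualified_mutant_reads < min_mutant_reads or summary.normal_mutant_reads > 0:
        return None
    depth = site.tumor.depth
    n_depth = site.normal.depth
    return VariantCall(
        chrom=site.chrom,
        pos=site.pos,
        ref=ref,
        alt=alt,
        vaf_tumor=summary.total_mutant_reads / depth if depth else 0.0,
        vaf_normal=summary.normal_mutant_reads / n_depth if n_depth else 0.0,
        source="subclonal",
    )


def apply_subclonal_filters(
    call: VariantCall,
    site: SitePileup,
    min_baseq: int = MIN_BASEQ,
    end_exclusion_bp: int = END_EXCLUSION_BP,
) -> VariantCall:
    """Remove candidates near repeats, at known variants, or end-only."""
    tags = set(call.tags)
    if site.near_repeat:
        tags.add(NEAR_REPEAT)
    if site.known_variant:
        tags.add(KNOWN_VARIANT)
    summary = summarize_evidence(site, call.alt, min_baseq, end_exclusion_bp)
    if summary.end_only:
        tags.add(READ_END_ONLY)
    return call.with_(tags=frozenset(tags), passed=not (tags & SUBCLONAL_FAIL_TAGS))


def call_lesion_subclonal(
    sites: list[SitePileup],
    min_baseq: int = MIN_BASEQ,
    end_exclusion_bp: int = END_EXCLUSION_BP,
    min_mutant_reads: int = MIN_MUTANT_READS,
) -> list[VariantCall]:
    """Run the minimum-evidence caller plus its exclusions over a lesion."""
    calls = []
    for site in sites:
        cand = call_subclonal_site(site, min_baseq, end_exclusion_bp, min_mutant_reads)
        if cand is not None:
            calls.append(apply_subclonal_filters(cand, site, min_baseq, end_exclusion_bp))
    return calls


def subclonal_sensitivity(vaf: float, depth: int, min_reads: int = MIN_MUTANT_READS) -> float:
    """P(at least ``min_reads`` mutant reads), X ~ Binomial(depth, vaf).

    The closed-form detection probability of the minimum-evidence rule
    at a given true VAF and depth; at VAF 0.05 and 100X it is ~0.96,
    which is what makes a 5% subclonal floor realistic at exome depth.
    """
    if not 0.0 <= vaf <= 1.0:
        raise ValueError(f"vaf {vaf} outside [0, 1]")
    if depth < 1:
        raise ValueError(f"depth {depth} must be >= 1")
    return float(stats.binom.sf(min_reads - 1, depth, vaf))
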