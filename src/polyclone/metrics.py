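"""Burden and spectrum metrics.

The mutational index is the count of unique amino-acid-changing passed
mutations divided by the effective exome target size in megabases,
rounded half-up to two decimals. The inverse analysis re-runs the full
primary pipeline with tumor and normal roles swapped — a noise-floor
control: mutations "private to the normal" can only be artifacts or
pipeline noise. The substitution spectrum collapses the twelve
possible SNV classes onto the six pyrimidine-reference classes, and
the CpG summary reports the fraction of C>T/G>A transitions falling in
a CpG dimer — the methyl-C deamination signature that dominates
colorectal lesions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

from polyclone.errors import ConfigError, ValidationError
from polyclone.sites import BASES, LesionCallSet, SitePileup, VariantCall

#: Effective exome target size (Mb) used for the index denominator.
TARGET_MB = 30.0

SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def mutational_index(n_mutations: int, target_mb: float = TARGET_MB) -> float:
    """Mutations per megabase of target, rounded half-up to 2 decimals."""
    if target_mb <= 0:
        raise ConfigError(f"target_mb must be > 0, got {target_mb}")
    if n_mutations < 0:
        raise ValidationError(f"n_mutations must be >= 0, got {n_mutations}")
    q = Decimal(n_mutations) / Decimal(str(target_mb))
    return float(q.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def substitution_class(ref: str, alt: str) -> str:
    """Collapse a substitution onto its pyrimidine-reference class."""
    if ref not in BASES or alt not in BASES:
        raise ValidationError(f"invalid bases {ref!r}>{alt!r}")
    if ref == alt:
        raise ValidationError(f"ref equals alt ({ref})")
    if ref in ("G", "A"):
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{ref}>{alt}"


def is_cpg_dimer(tri_context: str, ref: str, alt: str) -> bool:
    """True when the substitution sits in a CpG dinucleotide.

    For a C reference the 3' neighbor must be G; for a G reference the
    5' neighbor must be C. A/T references are never in a CpG dimer in
    the sense used for the transition spectrum.
    """
    if len(tri_context) != 3 or tri_context[1] != ref:
        raise ValidationError(
            f"tri_context {tri_context!r} middle base does not match ref {ref!r}"
        )
    if ref == "C":
        return tri_context[2] == "G"
    if ref == "G":
        return tri_context[0] == "C"
    return False


@dataclass(frozen=True)
class SpectrumSummary:
    """Collapsed substitution-class fractions plus the CpG transition share."""

    class_counts: dict[str, int]
    class_fractions: dict[str, float]
    n_total: int
    n_cg_transitions: int
    n_cg_transitions_cpg: int
    cpg_fraction_of_cg_transitions: Optional[float]
    empty: bool = False


def spectrum_summary(
    calls: LesionCallSet | Sequence[VariantCall],
    contexts: Optional[dict[tuple[str, int], str]] = None,
    passed_only: bool = True,
) -> SpectrumSummary:
    """Summarize the substitution spectrum of a call set.

    ``contexts`` maps (chrom, pos) to the reference trinucleotide; when
    None the call set must have been built from pileups and the context
    lookup is skipped only if empty. An empty call set yields an
    all-zero summary flagged ``empty``.
    """
    call_list = list(calls.calls if isinstance(calls, LesionCallSet) else calls)
    if passed_only:
        call_list = [c for c in call_list if c.passed]
    counts = {k: 0 for k in SUBSTITUTION_CLASSES}
    n_cg = n_cg_cpg = 0
    for c in call_list:
        klass = substitution_class(c.ref, c.alt)
        counts[klass] += 1
        if klass == "C>T":
            n_cg += 1
            if contexts is None:
                raise ValidationError(
                    f"no trinucleotide context available for {c.chrom}:{c.pos}"
                )
            ctx = contexts.get((c.chrom, c.pos))
            if ctx is None:
                raise ValidationError(f"missing context for {c.chrom}:{c.pos}")
            if is_cpg_dimer(ctx, c.ref, c.alt):
                n_cg_cpg += 1
    n_total = len(call_list)
    fractions = {
        k: (v / n_total if n_total else 0.0) for k, v in counts.items()
    }
    return SpectrumSummary(
        class_counts=counts,
        class_fractions=fractions,
        n_total=n_total,
        n_cg_transitions=n_cg,
        n_cg_transitions_cpg=n_cg_cpg,
        cpg_fraction_of_cg_transitions=(n_cg_cpg / n_cg) if n_cg else None,
        empty=n_total == 0,
    )


def compare_spectra(a: SpectrumSummary, b: SpectrumSummary) -> Optional[float]:
    """Fisher two-sided p comparing CpG composition of two call sets.

    2x2 table: (CpG, non-CpG) x (set A, set B) among C>T/G>A calls.
    Returns None when either set has no C>T/G>A calls.
    """
    from polyclone.primary import fisher_exact_two_sided

    if a.n_cg_transitions == 0 or b.n_cg_transitions == 0:
        return None
    return fisher_exact_two_sided(
        a.n_cg_transitions_cpg,
        a.n_cg_transitions - a.n_cg_transitions_cpg,
        b.n_cg_transitions_cpg,
        b.n_cg_transitions - b.n_cg_transitions_cpg,
    )


@dataclass(frozen=True)
class LesionMetrics:
    """Table-style per-lesion burden metrics."""

    lesion_id: str
    n_aa_changing: int
    mut_index: float
    n_inverse: Optional[int] = None
    inverse_index: Optional[float] = None


def count_aa_changing(calls: LesionCallSet | Sequence[VariantCall]) -> int:
    """Unique passed amino-acid-changing (chrom,pos,ref,alt) keys."""
    call_list = list(calls.calls if isinstance(calls, LesionCallSet) else calls)
    keys = {
        c.key
        for c in call_list
        if c.passed and c.consequence in ("missense", "truncating")
    }
    return len(keys)


def lesion_metrics(
    calls: LesionCallSet,
    target_mb: float = TARGET_MB,
    n_inverse: Optional[int] = None,
) -> LesionMetrics:
    n = count_aa_changing(calls)
    return LesionMetrics(
        lesion_id=calls.lesion_id,
        n_aa_changing=n,
        mut_index=mutational_index(n, target_mb),
        n_inverse=n_inverse,
        inverse_index=mutational_index(n_inverse, target_mb) if n_inverse is not None else None,
    )


def inverse_analysis(
    sites: Iterable[SitePileup],
    transcripts=None,
    target_mb: float = TARGET_MB,
    **primary_kwargs,
) -> tuple[int, float]:
    """Noise-floor control: the primary pipeline with sample roles swapped.

    Returns the count of passed amino-acid-changing calls found in the
    normal when it is treated as the tumor, and the corresponding
    per-Mb index.
    """
    from polyclone.consequence import annotate_calls
    from polyclone.primary import call_lesion_primary

    swapped = [s.swapped() for s in sites]
    calls = call_lesion_primary(swapped, **primary_kwargs)
    if transcripts is not None:
        calls = annotate_calls(calls, transcripts)
        n = len({c.key for c in calls if c.passed and c.consequence in ("missense", "truncating")})
    else:
        n = len({c.key for c in calls if c.passed})
    return n, mutational_index(n, target_mb)
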