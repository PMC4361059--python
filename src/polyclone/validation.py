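"""Deep-amplicon validation decision rule and concordance with the primary calls.

A variant re-sequenced at amplicon depth is *validated* when the tumor
shows at least 5 mutant reads making up at least 1% of reads at the
position while the matched normal shows none; positions with coverage
below 20 in either sample are not evaluable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from polyclone.sites import AlleleCounts, LesionCallSet

#: Default decision-rule thresholds.
MIN_COVERAGE = 20
MIN_MUTANT_READS = 5
MIN_MUTANT_FRACTION = 0.01
#: Default mutational-percentage threshold for concordance reporting.
MP_THRESHOLD = 0.15

VariantKey = tuple[str, int, str, str]


@dataclass(frozen=True, slots=True)
class ValidationResult:
    variant_key: VariantKey
    tumor_depth: int
    tumor_mutant_reads: int
    normal_depth: int
    normal_mutant_reads: int
    status: str  # "validated" | "not_validated" | "not_evaluable"


def validate_call(
    tumor: AlleleCounts,
    normal: AlleleCounts,
    alt_base: str,
    variant_key: Optional[VariantKey] = None,
    min_coverage: int = MIN_COVERAGE,
    min_mutant_reads: int = MIN_MUTANT_READS,
    min_mutant_fraction: float = MIN_MUTANT_FRACTION,
) -> ValidationResult:
    """Apply the amplicon validation rule to paired deep counts."""
    t_depth, n_depth = tumor.depth, normal.depth
    t_mut, n_mut = tumor.count(alt_base), normal.count(alt_base)
    if t_depth < min_coverage or n_depth < min_coverage:
        status = "not_evaluable"
    elif (
        t_mut >= min_mutant_reads
        and t_mut / t_depth >= min_mutant_fraction
        and n_mut == 0
    ):
        status = "validated"
    else:
        status = "not_validated"
    return ValidationResult(
        variant_key=variant_key if variant_key is not None else ("", 0, ".", "."),
        tumor_depth=t_depth,
        tumor_mutant_reads=t_mut,
        normal_depth=n_depth,
        normal_mutant_reads=n_mut,
        status=status,
    )


def concordance_rate(
    primary_calls: LesionCallSet,
    results: Iterable[ValidationResult],
    mp_threshold: float = MP_THRESHOLD,
) -> Optional[float]:
    """Fraction of high-MP primary calls confirmed by the secondary analysis.

    Among primary calls with tumor VAF (mutational percentage) above
    ``mp_threshold`` that have an evaluable validation result, the
    fraction with status ``validated``. Returns None when no call meets
    the denominator.
    """
    by_key: Mapping[VariantKey, ValidationResult] = {r.variant_key: r for r in results}
    n_eval = n_validated = 0
    for call in primary_calls:
        if call.vaf_tumor <= mp_threshold:
            continue
        res = by_key.get(call.key)
        if res is None or res.status == "not_evaluable":
            continue
        n_eval += 1
        if res.status == "validated":
            n_validated += 1
    if n_eval == 0:
        return None
    return n_validated / n_eval


def gene_concordance_rate(
    primary_calls: LesionCallSet,
    results: Iterable[ValidationResult],
    mp_threshold: float = MP_THRESHOLD,
) -> Optional[float]:
    """Per-gene roll-up: fraction of genes with any validated high-MP call."""
    by_key = {r.variant_key: r for r in results}
    genes_eval: dict[str, bool] = {}
    for call in primary_calls:
        if call.vaf_tumor <= mp_threshold or not call.gene:
            continue
        res = by_key.get(call.key)
        if res is None or res.status == "not_evaluable":
            continue
        genes_eval[call.gene] = genes_eval.get(call.gene, False) or res.status == "validated"
    if not genes_eval:
        return None
    return sum(genes_eval.values()) / len(genes_eval)
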