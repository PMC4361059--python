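"""Cross-lesion heterogeneity: overlap, clonality, and gene-level recurrence.

Synchronous lesions of one patient are compared on passed-call
identity. A *recurrent mutation* means the identical
(chrom, pos, ref, alt) key in two lesions; gene-level recurrence
(different variants hitting the same gene in different lesions) is
reported separately, because independent lesions can converge on the
same driver gene without sharing a single variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional

from polyclone.errors import ConfigError
from polyclone.sites import LesionCallSet, PatientCohort, VariantCall

#: Default VAF threshold separating clonal from subclonal calls
#: (half the diploid heterozygous expectation of 0.5).
CLONAL_VAF_THRESHOLD = 0.25

VariantKey = tuple[str, int, str, str]


def mutation_key(call: VariantCall) -> VariantKey:
    """Canonical identity of a mutation: (chrom, pos, ref, alt)."""
    return call.key


@dataclass(frozen=True)
class PairOverlap:
    lesion_a: str
    lesion_b: str
    shared: int
    union: int
    jaccard: float
    shared_keys: tuple[VariantKey, ...]


@dataclass(frozen=True)
class OverlapReport:
    patient_id: str
    pairs: tuple[PairOverlap, ...]

    @property
    def any_shared(self) -> bool:
        return any(p.shared > 0 for p in self.pairs)

    def pair(self, a: str, b: str) -> PairOverlap:
        for p in self.pairs:
            if {p.lesion_a, p.lesion_b} == {a, b}:
                return p
        raise KeyError((a, b))


def overlap_report(cohort: PatientCohort, passed_only: bool = True) -> OverlapReport:
    """Pairwise shared/union/Jaccard over lesion call keys."""
    if len(cohort.lesions) < 2:
        raise ConfigError(
            f"patient {cohort.patient_id}: overlap report needs >= 2 lesions"
        )
    keysets = {
        les.lesion_id: (les.passed_keys() if passed_only else {c.key for c in les})
        for les in cohort.lesions
    }
    pairs = []
    for a, b in combinations([l.lesion_id for l in cohort.lesions], 2):
        shared = keysets[a] & keysets[b]
        union = keysets[a] | keysets[b]
        pairs.append(
            PairOverlap(
                lesion_a=a,
                lesion_b=b,
                shared=len(shared),
                union=len(union),
                jaccard=(len(shared) / len(union)) if union else 0.0,
                shared_keys=tuple(sorted(shared)),
            )
        )
    return OverlapReport(patient_id=cohort.patient_id, pairs=tuple(pairs))


@dataclass(frozen=True, slots=True)
class ClonalityCall:
    variant_key: VariantKey
    vaf_tumor: float
    label: str  # "clonal" | "subclonal"


def classify_clonality(
    call: VariantCall, clonal_vaf_threshold: float = CLONAL_VAF_THRESHOLD
) -> ClonalityCall:
    """Label a call clonal or subclonal by its tumor VAF.

    The boundary is closed on the clonal side: a VAF exactly at the
    threshold is clonal.
    """
    label = "subclonal" if call.vaf_tumor < clonal_vaf_threshold else "clonal"
    return ClonalityCall(variant_key=call.key, vaf_tumor=call.vaf_tumor, label=label)


@dataclass(frozen=True)
class GeneHit:
    gene: str
    lesions_hit: tuple[str, ...]
    variants_per_lesion: dict[str, tuple[VariantKey, ...]]
    recurrent_gene: bool  # same gene hit in >= 2 lesions
    recurrent_variant: bool  # identical variant key in >= 2 lesions


def gene_multihit_report(cohort: PatientCohort, passed_only: bool = True) -> list[GeneHit]:
    """Per-gene table of distinct mutation keys per lesion.

    Distinguishes gene-level recurrence (different variants, same gene,
    different lesions) from variant-level recurrence (the same key in
    several lesions).
    """
    per_gene: dict[str, dict[str, set[VariantKey]]] = {}
    for les in cohort.lesions:
        for c in les.calls:
            if passed_only and not c.passed:
                continue
            if not c.gene:
                continue
            per_gene.setdefault(c.gene, {}).setdefault(les.lesion_id, set()).add(c.key)
    out = []
    for gene in sorted(per_gene):
        lesion_keys = per_gene[gene]
        all_keys: list[VariantKey] = [k for ks in lesion_keys.values() for k in ks]
        key_lesion_count: dict[VariantKey, int] = {}
        for lid, ks in lesion_keys.items():
            for k in ks:
                key_lesion_count[k] = key_lesion_count.get(k, 0) + 1
        out.append(
            GeneHit(
                gene=gene,
                lesions_hit=tuple(sorted(lesion_keys)),
                variants_per_lesion={
                    lid: tuple(sorted(ks)) for lid, ks in sorted(lesion_keys.items())
                },
                recurrent_gene=len(lesion_keys) >= 2,
                recurrent_variant=any(n >= 2 for n in key_lesion_count.values()),
            )
        )
    return out
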