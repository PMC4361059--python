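"""Domain types: per-site pileups, calls, call sets and interval masks.

Coordinate conventions follow the two named standards exactly: variant
positions are 1-based (VCF), interval tracks are 0-based half-open
(BED). A variant at 1-based position ``p`` falls inside BED region
``[p-1, p)``.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from polyclone.errors import ValidationError

BASES = ("A", "C", "G", "T")

# Filter / annotation tags.
LOW_DEPTH = "LOW_DEPTH"
STRAND_BIAS = "STRAND_BIAS"
TAIL_BIAS = "TAIL_BIAS"
LOW_MAPABILITY = "LOW_MAPABILITY"
NEAR_REPEAT = "NEAR_REPEAT"
KNOWN_VARIANT = "KNOWN_VARIANT"
READ_END_ONLY = "READ_END_ONLY"

ALL_TAGS = frozenset(
    {LOW_DEPTH, STRAND_BIAS, TAIL_BIAS, LOW_MAPABILITY, NEAR_REPEAT, KNOWN_VARIANT, READ_END_ONLY}
)

#: Tags that disqualify a primary-analysis call. TAIL_BIAS is annotate-only.
PRIMARY_FAIL_TAGS = frozenset({LOW_DEPTH, STRAND_BIAS, LOW_MAPABILITY})
#: Tags that disqualify a subclonal (minimum-evidence) call.
SUBCLONAL_FAIL_TAGS = frozenset({NEAR_REPEAT, KNOWN_VARIANT, READ_END_ONLY})

CONSEQUENCES = ("synonymous", "missense", "truncating", "non_coding", "unassigned")
SOURCES = ("primary", "subclonal")


@dataclass(frozen=True, slots=True)
class TargetRegion:
    """A 0-based half-open genomic interval (BED convention)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"region {self.chrom}:{self.start}-{self.end}: start must be < end"
            )
        if self.start < 0:
            raise ValidationError(f"region start {self.start} is negative")

    @property
    def length(self) -> int:
        return self.end - self.start


class GenomeMask:
    """Merged, sorted interval set with 1-based position membership.

    Membership for a 1-based position ``p`` tests ``start < p <= end``,
    i.e. the variant sits inside the half-open 0-based region.
    """

    def __init__(self, regions: Iterable[TargetRegion]):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for r in regions:
            by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            merged: list[list[int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self._starts[chrom] = [s for s, _ in merged]
            self._ends[chrom] = [e for _, e in merged]

    @property
    def regions(self) -> list[TargetRegion]:
        out = []
        for chrom in sorted(self._starts):
            out.extend(
                TargetRegion(chrom, s, e)
                for s, e in zip(self._starts[chrom], self._ends[chrom])
            )
        return out

    def total_bp(self) -> int:
        return sum(r.length for r in self.regions)

    def contains(self, chrom: str, pos: int) -> bool:
        """True if 1-based ``pos`` falls in a region of this mask."""
        starts = self._starts.get(chrom)
        if not starts:
            return False
        i = bisect.bisect_right(starts, pos - 1) - 1
        return i >= 0 and pos <= self._ends[chrom][i]

    def __len__(self) -> int:
        return sum(len(v) for v in self._starts.values())


@dataclass(frozen=True, slots=True)
class AlleleCounts:
    """Strand-resolved base counts at one site of one sample.

    Total depth is always the sum of the eight per-base strand counts.
    """

    a_fwd: int = 0
    a_rev: int = 0
    c_fwd: int = 0
    c_rev: int = 0
    g_fwd: int = 0
    g_rev: int = 0
    t_fwd: int = 0
    t_rev: int = 0

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            v = getattr(self, name)
            if v < 0:
                raise ValidationError(f"allele count {name} is negative ({v})")

    @classmethod
    def from_dict(cls, counts: dict[str, tuple[int, int]]) -> "AlleleCounts":
        """Build from {base: (fwd, rev)}; absent bases count zero."""
        kwargs = {}
        for base, (f, r) in counts.items():
            kwargs[f"{base.lower()}_fwd"] = f
            kwargs[f"{base.lower()}_rev"] = r
        return cls(**kwargs)

    def fwd(self, base: str) -> int:
        return getattr(self, f"{base.lower()}_fwd")

    def rev(self, base: str) -> int:
        return getattr(self, f"{base.lower()}_rev")

    def count(self, base: str) -> int:
        return self.fwd(base) + self.rev(base)

    @property
    def depth(self) -> int:
        return (
            self.a_fwd + self.a_rev + self.c_fwd + self.c_rev
            + self.g_fwd + self.g_rev + self.t_fwd + self.t_rev
        )

    def alt_depth(self, ref_base: str) -> int:
        """Reads carrying any base other than the reference."""
        return self.depth - self.count(ref_base)

    def best_alt(self, ref_base: str) -> Optional[str]:
        """Non-reference base with the highest count; None if no alt reads.

        Ties break in fixed A<C<G<T order so results are deterministic.
        """
        best, best_n = None, 0
        for b in BASES:
            if b == ref_base:
                continue
            n = self.count(b)
            if n > best_n:
                best, best_n = b, n
        return best

    def as_tuple(self) -> tuple[int, ...]:
        return (
            self.a_fwd, self.a_rev, self.c_fwd, self.c_rev,
            self.g_fwd, self.g_rev, self.t_fwd, self.t_rev,
        )


@dataclass(frozen=True, slots=True)
class ReadEvidence:
    """One read's observation at a site.

    ``confirmed`` is an independent-alignment agreement flag (the
    surrogate for re-alignment confirmation of the read); ``end_distance``
    is the distance in bp to the nearer read end.
    """

    base: str
    base_quality: int
    end_distance: int
    strand: str  # "+" or "-"
    confirmed: bool = True

    def __post_init__(self) -> None:
        if self.base not in BASES:
            raise ValidationError(f"read base {self.base!r} not one of A/C/G/T")
        if not 0 <= self.base_quality <= 60:
            raise ValidationError(f"base_quality {self.base_quality} outside [0, 60]")
        if self.end_distance < 0:
            raise ValidationError(f"end_distance {self.end_distance} is negative")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand {self.strand!r} must be '+' or '-'")


@dataclass(slots=True)
class SitePileup:
    """Paired tumor/normal observations at one 1-based genomic position.

    Read-level evidence lists are optional: the primary caller needs
    only the strand counts, the subclonal caller requires per-read
    records wherever alternate-allele counts are non-zero.
    """

    chrom: str
    pos: int
    ref_base: str
    tri_context: str
    tumor: AlleleCounts
    normal: AlleleCounts
    tumor_reads: Optional[list[ReadEvidence]] = None
    normal_reads: Optional[list[ReadEvidence]] = None
    low_mapability: bool = False
    near_repeat: bool = False
    known_variant: bool = False

    def __post_init__(self) -> None:
        if len(self.tri_context) != 3 or self.tri_context[1] != self.ref_base:
            raise ValidationError(
                f"{self.chrom}:{self.pos}: tri_context {self.tri_context!r} middle base "
                f"does not match ref_base {self.ref_base!r}"
            )
        if self.tumor_reads is not None and len(self.tumor_reads) != self.tumor.depth:
            raise ValidationError(
                f"{self.chrom}:{self.pos}: tumor read list length {len(self.tumor_reads)} "
                f"!= tumor depth {self.tumor.depth}"
            )
        if self.normal_reads is not None and len(self.normal_reads) != self.normal.depth:
            raise ValidationError(
                f"{self.chrom}:{self.pos}: normal read list length {len(self.normal_reads)} "
                f"!= normal depth {self.normal.depth}"
            )

    def swapped(self) -> "SitePileup":
        """Tumor and normal roles exchanged (the inverse analysis)."""
        return SitePileup(
            chrom=self.chrom,
            pos=self.pos,
            ref_base=self.ref_base,
            tri_context=self.tri_context,
            tumor=self.normal,
            normal=self.tumor,
            tumor_reads=self.normal_reads,
            normal_reads=self.tumor_reads,
            low_mapability=self.low_mapability,
            near_repeat=self.near_repeat,
            known_variant=self.known_variant,
        )


@dataclass(slots=True)
class VariantCall:
    """A called somatic SNV with its evidence summary and filter state."""

    chrom: str
    pos: int
    ref: str
    alt: str
    vaf_tumor: float
    vaf_normal: float
    fisher_p: Optional[float] = None
    tags: frozenset[str] = frozenset()
    source: str = "primary"
    consequence: str = "unassigned"
    gene: Optional[str] = None
    passed: bool = True

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValidationError(f"{self.chrom}:{self.pos}: ref equals alt ({self.ref})")
        if self.ref not in BASES or self.alt not in BASES:
            raise ValidationError(f"{self.chrom}:{self.pos}: ref/alt must be single A/C/G/T bases")
        if not 0.0 <= self.vaf_tumor <= 1.0 or not 0.0 <= self.vaf_normal <= 1.0:
            raise ValidationError(f"{self.chrom}:{self.pos}: VAF outside [0, 1]")
        if self.source not in SOURCES:
            raise ValidationError(f"unknown call source {self.source!r}")
        if self.consequence not in CONSEQUENCES:
            raise ValidationError(f"unknown consequence {self.consequence!r}")
        unknown = set(self.tags) - ALL_TAGS
        if unknown:
            raise ValidationError(f"unknown tags {sorted(unknown)}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def with_(self, **kwargs) -> "VariantCall":
        return replace(self, **kwargs)


@dataclass(slots=True)
class LesionCallSet:
    """All calls for one lesion versus its matched normal."""

    lesion_id: str
    patient_id: str
    histology: str = ""
    calls: list[VariantCall] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [c.key for c in self.calls]
        if len(keys) != len(set(keys)):
            seen, dups = set(), set()
            for k in keys:
                if k in seen:
                    dups.add(k)
                seen.add(k)
            raise ValidationError(f"duplicate call keys in {self.lesion_id}: {sorted(dups)[:5]}")

    @property
    def passed_calls(self) -> list[VariantCall]:
        return [c for c in self.calls if c.passed]

    def passed_keys(self) -> set[tuple[str, int, str, str]]:
        return {c.key for c in self.calls if c.passed}

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self):
        return iter(self.calls)


@dataclass(slots=True)
class PatientCohort:
    """One matched normal plus one or more lesion call sets."""

    patient_id: str
    lesions: list[LesionCallSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        for les in self.lesions:
            if les.patient_id != self.patient_id:
                raise ValidationError(
                    f"lesion {les.lesion_id} belongs to patient {les.patient_id}, "
                    f"not {self.patient_id}"
                )

    def __len__(self) -> int:
        return len(self.lesions)
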