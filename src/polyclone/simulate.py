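"""Synthetic paired-exome cohort generator.

Emulates the data structure of a multi-lesion colorectal study: each
patient contributes one normal sample and several synchronous lesions
sequenced against a shared desk-scale reference with toy gene models.
Somatic mutations are drawn independently per lesion (except an
optional shared fraction), split between clonal (~50% VAF) and
subclonal (5-25% VAF) events with a CpG-biased C>T spectrum; germline
SNPs appear in the normal and every lesion; read counts are binomial
in the true VAF on negative-binomial depths; sequencing error,
all-one-strand artifacts and read-end artifacts give the downstream
filters true positives to remove.

Per-read evidence records (base quality, end distance, strand,
independent-alignment confirmation) are attached to every site whose
strand counts carry at least one non-reference read in either sample;
all-reference sites omit the lists, which the callers treat as
count-only sites.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from polyclone.consequence import ToyTranscript, classify_consequence, revcomp
from polyclone.errors import ConfigError
from polyclone.sites import AlleleCounts, ReadEvidence, SitePileup, VariantCall

BASES = np.array(["A", "C", "G", "T"])
_STOPS = ("TAA", "TAG", "TGA")
_CODONS_NO_STOP = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]

#: Read half-length for a 75 bp read: distance to the nearer end is in [0, 37].
MAX_END_DISTANCE = 37


@dataclass(frozen=True)
class SimParams:
    """Study-condition parameters of the synthetic cohort.

    Defaults emulate the paired-exome design being modeled: ~99X mean
    target coverage with a spread reaching roughly 78-141X across
    samples, clonal somatic mutations at 50% VAF, subclonal ones at
    5-25%, per-lesion mutation counts in the tens (somatic_rate x
    n_sites ~ 50), independent mutation sets per lesion
    (shared_fraction 0), and deep (~600X) amplicon counts for the
    secondary validation analysis.
    """

    n_patients: int = 4
    lesions_per_patient: int = 3
    n_sites: int = 5000
    target_mb: float = 30.0
    depth_mean_tumor: float = 99.0
    depth_mean_normal: float = 99.0
    depth_overdispersion: float = 0.013
    clonal_vaf: float = 0.5
    subclonal_vaf_range: tuple[float, float] = (0.05, 0.25)
    fraction_subclonal: float = 0.6
    somatic_rate: float = 0.01
    shared_fraction: float = 0.0
    germline_rate: float = 0.002
    error_rate: float = 1e-3
    strand_bias_artifact_rate: float = 5e-4
    read_end_artifact_rate: float = 5e-4
    artifact_vaf: float = 0.2
    amplicon_depth_mean: float = 600.0
    cpg_ct_fraction: float = 0.5
    ct_fraction: float = 0.2
    gene_fraction: float = 0.6
    emit_read_evidence: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        rates = {
            "fraction_subclonal": self.fraction_subclonal,
            "somatic_rate": self.somatic_rate,
            "shared_fraction": self.shared_fraction,
            "germline_rate": self.germline_rate,
            "error_rate": self.error_rate,
            "strand_bias_artifact_rate": self.strand_bias_artifact_rate,
            "read_end_artifact_rate": self.read_end_artifact_rate,
            "artifact_vaf": self.artifact_vaf,
            "cpg_ct_fraction": self.cpg_ct_fraction,
            "ct_fraction": self.ct_fraction,
            "gene_fraction": self.gene_fraction,
            "clonal_vaf": self.clonal_vaf,
        }
        for name, v in rates.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.depth_mean_tumor <= 0 or self.depth_mean_normal <= 0:
            raise ConfigError("depth means must be > 0")
        if self.amplicon_depth_mean <= 0:
            raise ConfigError("amplicon_depth_mean must be > 0")
        lo, hi = self.subclonal_vaf_range
        if not (0.0 < lo <= hi < self.clonal_vaf):
            raise ConfigError(
                f"subclonal_vaf_range {self.subclonal_vaf_range} must lie within "
                f"(0, clonal_vaf={self.clonal_vaf})"
            )
        if self.n_sites < 100:
            raise ConfigError(f"n_sites must be >= 100, got {self.n_sites}")
        if self.n_patients < 1 or self.lesions_per_patient < 1:
            raise ConfigError("n_patients and lesions_per_patient must be >= 1")
        if self.depth_overdispersion < 0:
            raise ConfigError("depth_overdispersion must be >= 0")


@dataclass(frozen=True)
class TruthVariant:
    chrom: str
    pos: int
    ref: str
    alt: str
    true_vaf: float
    clonality: str  # "clonal" | "subclonal" | "germline_het" | "germline_hom"
    consequence: str = "unassigned"
    gene: Optional[str] = None
    shared: bool = False


@dataclass(frozen=True)
class ArtifactSite:
    pos: int
    alt: str
    kind: str  # "strand_bias" | "read_end"


@dataclass
class SimTruth:
    """Ground truth of one simulated patient."""

    patient_id: str
    chrom: str
    germline: list[TruthVariant]
    somatic: dict[str, list[TruthVariant]]  # lesion_id -> variants
    artifacts: dict[str, list[ArtifactSite]]
    depths: dict[str, np.ndarray] = field(default_factory=dict)

    def somatic_keys(self, lesion_id: str) -> set[tuple[str, int, str, str]]:
        return {(v.chrom, v.pos, v.ref, v.alt) for v in self.somatic[lesion_id]}


@dataclass
class PatientSim:
    """One simulated patient: truth, reference, gene models, pileups."""

    patient_id: str
    truth: SimTruth
    reference: str  # padded: index pos (1-based) directly
    transcripts: list[ToyTranscript]
    lesions: dict[str, list[SitePileup]]  # lesion_id -> paired pileups vs normal

    def contexts(self) -> dict[tuple[str, int], str]:
        chrom = self.truth.chrom
        return {
            (chrom, p): self.reference[p - 1:p + 2]
            for p in range(1, len(self.reference) - 1)
        }


def patient_seed(global_seed: int, patient_index: int) -> int:
    """Fixed arithmetic spawning per-patient seeds from the global seed."""
    return (int(global_seed) * 100003 + patient_index * 7919 + 1) % (2**31 - 1)


# ---------------------------------------------------------------------------
# Reference + gene model construction
# ---------------------------------------------------------------------------

def _build_reference(params: SimParams, rng: np.random.Generator, chrom: str):
    """Random reference with embedded toy genes.

    Returns (padded reference string, transcripts). The reference is
    padded with one T on each side so every simulated position 1..n has
    a full trinucleotide context; pad Ts cannot create spurious CpGs.
    """
    n = params.n_sites
    seq = rng.choice(BASES, size=n)
    transcripts = []
    cursor = int(rng.integers(10, 60))
    coding = 0
    gene_i = 0
    while coding < params.gene_fraction * n:
        n_codons = int(rng.integers(60, 200))
        cds_len = 3 * n_codons
        n_exons = int(rng.integers(1, 4))
        # split cds_len into n_exons parts of >= 9 bp
        cuts = np.sort(rng.choice(np.arange(9, cds_len - 8), size=n_exons - 1, replace=False)) if n_exons > 1 else np.array([], dtype=int)
        exon_lens = np.diff(np.concatenate(([0], cuts, [cds_len])))
        introns = rng.integers(10, 51, size=n_exons - 1)
        span = cds_len + int(introns.sum())
        if cursor + span >= n - 10:
            break
        strand = "+" if rng.random() < 0.5 else "-"
        body = "ATG" + "".join(rng.choice(_CODONS_NO_STOP, size=n_codons - 2)) + _STOPS[int(rng.integers(0, 3))]
        genomic_cds = body if strand == "+" else revcomp(body)
        intervals = []
        off = 0
        pos = cursor
        for k, el in enumerate(exon_lens):
            el = int(el)
            intervals.append((pos, pos + el))
            seq[pos:pos + el] = list(genomic_cds[off:off + el])
            off += el
            pos += el
            if k < n_exons - 1:
                pos += int(introns[k])
        gene_i += 1
        transcripts.append(
            ToyTranscript(
                gene=f"GENE{gene_i:03d}",
                chrom=chrom,
                strand=strand,
                cds_intervals=tuple(intervals),
                cds_seq=body,
            )
        )
        coding += cds_len
        cursor = pos + int(rng.integers(20, 100))
    ref = "T" + "".join(seq) + "T"
    return ref, transcripts


# ---------------------------------------------------------------------------
# Truth generation
# ---------------------------------------------------------------------------

def _draw_alt(rng: np.random.Generator, ref: str) -> str:
    alts = [b for b in "ACGT" if b != ref]
    return alts[int(rng.integers(0, 3))]


def _pick_event_site(rng, ref, kind, pools):
    """Pop a position from the requested pool, falling back to 'any'."""
    for pool_name in (kind, "any"):
        pool = pools[pool_name]
        while pool:
            i = int(rng.integers(0, len(pool)))
            pool[i], pool[-1] = pool[-1], pool[i]
            pos = pool.pop()
            if pos in pools["used"]:
                continue
            pools["used"].add(pos)
            return pos
    raise ConfigError("n_sites too small to place the requested variants")


def simulate_truth(params: SimParams, patient_index: int, seed: Optional[int] = None):
    """Generate reference, transcripts and ground-truth variants only.

    Cheap path used when read counts are not needed (e.g. overlap
    statistics over many patients). Deterministic given (params, seed).
    """
    pid = f"P{patient_index + 1}"
    chrom = f"chr{patient_index + 1}"
    p_seed = seed if seed is not None else patient_seed(params.seed, patient_index)
    rng = np.random.default_rng(p_seed)
    ref, transcripts = _build_reference(params, rng, chrom)
    n = params.n_sites

    # Candidate site pools (1-based positions).
    cpg_sites = [
        p for p in range(1, n + 1)
        if (ref[p] == "C" and ref[p + 1] == "G") or (ref[p] == "G" and ref[p - 1] == "C")
    ]
    cpg_set = set(cpg_sites)
    cg_noncpg = [p for p in range(1, n + 1) if ref[p] in "CG" and p not in cpg_set]
    pools = {
        "cpg": cpg_sites,
        "cg": cg_noncpg,
        "any": list(range(1, n + 1)),
        "used": set(),
    }

    # Germline SNPs, present in normal and all lesions.
    n_germ = rng.binomial(n, params.germline_rate)
    germline = []
    for _ in range(n_germ):
        pos = _pick_event_site(rng, ref, "any", pools)
        base = ref[pos]
        hom = rng.random() < 0.2
        germline.append(
            TruthVariant(
                chrom=chrom, pos=pos, ref=base, alt=_draw_alt(rng, base),
                true_vaf=1.0 if hom else 0.5,
                clonality="germline_hom" if hom else "germline_het",
            )
        )

    # Somatic events: drawn at patient level; shared with probability s,
    # otherwise assigned to one lesion uniformly. The pool size is scaled
    # so the expected per-lesion count stays somatic_rate * n_sites.
    L = params.lesions_per_patient
    s = params.shared_fraction
    m = params.somatic_rate * n
    n_events = rng.poisson(L * m / (1.0 + s * (L - 1)))
    lesion_ids = [f"{pid}_L{j + 1}" for j in range(L)]
    somatic: dict[str, list[TruthVariant]] = {lid: [] for lid in lesion_ids}
    for _ in range(n_events):
        u = rng.random()
        if u < params.cpg_ct_fraction:
            pos = _pick_event_site(rng, ref, "cpg", pools)
        elif u < params.cpg_ct_fraction + params.ct_fraction:
            pos = _pick_event_site(rng, ref, "cg", pools)
        else:
            pos = _pick_event_site(rng, ref, "any", pools)
        base = ref[pos]
        if u < params.cpg_ct_fraction + params.ct_fraction and base in "CG":
            alt = "T" if base == "C" else "A"
        else:
            # pool fallback can land on an A/T site; draw any alternate
            alt = _draw_alt(rng, base)
        shared = rng.random() < s
        targets = lesion_ids if shared else [lesion_ids[int(rng.integers(0, L))]]
        csq, gene = classify_consequence(
            VariantCall(chrom=chrom, pos=pos, ref=base, alt=alt,
                        vaf_tumor=0.5, vaf_normal=0.0),
            transcripts,
        )
        for lid in targets:
            if rng.random() < params.fraction_subclonal:
                lo, hi = params.subclonal_vaf_range
                vaf = float(rng.uniform(lo, hi))
                clonality = "subclonal"
            else:
                vaf = params.clonal_vaf
                clonality = "clonal"
            somatic[lid].append(
                TruthVariant(
                    chrom=chrom, pos=pos, ref=base, alt=alt, true_vaf=vaf,
                    clonality=clonality, consequence=csq, gene=gene, shared=shared,
                )
            )

    # Artifact sites (tumor-only), disjoint from true variants.
    artifacts: dict[str, list[ArtifactSite]] = {lid: [] for lid in lesion_ids}
    for lid in lesion_ids:
        for kind, rate in (
            ("strand_bias", params.strand_bias_artifact_rate),
            ("read_end", params.read_end_artifact_rate),
        ):
            for _ in range(rng.binomial(n, rate)):
                pos = _pick_event_site(rng, ref, "any", pools)
                artifacts[lid].append(ArtifactSite(pos=pos, alt=_draw_alt(rng, ref[pos]), kind=kind))

    truth = SimTruth(
        patient_id=pid, chrom=chrom, germline=germline,
        somatic=somatic, artifacts=artifacts,
    )
    return truth, ref, transcripts, rng


# ---------------------------------------------------------------------------
# Count + read-evidence generation
# ---------------------------------------------------------------------------

def _draw_depths(rng, mean: float, overdispersion: float, size: int) -> np.ndarray:
    """Negative-binomial depths with var = mean + d * mean^2 (Poisson at d=0)."""
    if overdispersion == 0:
        return rng.poisson(mean, size=size)
    k = 1.0 / overdispersion
    return rng.negative_binomial(k, k / (k + mean), size=size)


def _base_counts_to_reads(
    rng: np.random.Generator,
    counts: dict[str, tuple[int, int]],
    ref_base: str,
    true_alt: Optional[str],
    end_distance_lo: int = 0,
    end_distance_hi: int = MAX_END_DISTANCE,
    alt_end_hi: Optional[int] = None,
) -> list[ReadEvidence]:
    """Materialize per-read evidence consistent with strand counts.

    Reads on the true alternate (or reference) are confirmed with
    mutation-grade qualities; other non-reference reads are sequencing
    errors: lower, sometimes sub-threshold qualities and a coin-flip
    confirmation flag.
    """
    reads: list[ReadEvidence] = []
    for base, (n_fwd, n_rev) in counts.items():
        for strand, n_reads in (("+", n_fwd), ("-", n_rev)):
            if n_reads == 0:
                continue
            is_true = base == ref_base or base == true_alt
            if is_true:
                quals = rng.integers(25, 41, size=n_reads)
                confirmed = np.ones(n_reads, dtype=bool)
            else:
                quals = rng.integers(5, 36, size=n_reads)
                confirmed = rng.random(n_reads) < 0.5
            hi = alt_end_hi if (alt_end_hi is not None and base != ref_base) else end_distance_hi
            dists = rng.integers(end_distance_lo, hi + 1, size=n_reads)
            reads.extend(
                ReadEvidence(
                    base=base, base_quality=int(q), end_distance=int(d),
                    strand=strand, confirmed=bool(c),
                )
                for q, d, c in zip(quals, dists, confirmed)
            )
    return reads


def _sample_counts(
    rng: np.random.Generator,
    depth: int,
    ref_base: str,
    error_rate: float,
    alt: Optional[str] = None,
    vaf: float = 0.0,
    artifact: Optional[ArtifactSite] = None,
    artifact_vaf: float = 0.2,
) -> dict[str, tuple[int, int]]:
    """Strand-resolved base counts for one sample at one site."""
    per_base = {b: 0 for b in "ACGT"}
    remaining = depth
    if alt is not None and vaf > 0 and remaining:
        n_alt = rng.binomial(remaining, vaf)
        per_base[alt] += n_alt
        remaining -= n_alt
    if artifact is not None and remaining:
        n_art = rng.binomial(remaining, artifact_vaf)
        per_base[artifact.alt] += n_art
        remaining -= n_art
    if error_rate > 0 and remaining:
        n_err = rng.binomial(remaining, error_rate)
        if n_err:
            others = [b for b in "ACGT" if b != ref_base]
            split = rng.multinomial(n_err, [1 / 3] * 3)
            for b, k in zip(others, split):
                per_base[b] += int(k)
            remaining -= n_err
    per_base[ref_base] += remaining
    counts = {}
    for b, c in per_base.items():
        if artifact is not None and b == artifact.alt and artifact.kind == "strand_bias":
            # artifact reads pile onto one strand; true/error reads of the
            # same base are rare, fold them in
            counts[b] = (c, 0)
        else:
            f = rng.binomial(c, 0.5)
            counts[b] = (int(f), int(c - f))
    return counts


def simulate_patient(params: SimParams, patient_index: int = 0,
                     seed: Optional[int] = None) -> PatientSim:
    """Simulate one patient: truth plus per-lesion paired pileups.

    Deterministic given (params, patient seed). Germline variants
    appear in the normal and every lesion; somatic mutations are
    lesion-private unless shared; artifact sites inject all-one-strand
    or read-end alternate reads into the tumor only.
    """
    truth, ref, transcripts, rng = simulate_truth(params, patient_index, seed)
    n = params.n_sites
    chrom = truth.chrom
    pid = truth.patient_id
    lesion_ids = list(truth.somatic)

    germ_by_pos = {g.pos: g for g in truth.germline}
    som_by_pos = {
        lid: {v.pos: v for v in truth.somatic[lid]} for lid in lesion_ids
    }
    art_by_pos = {
        lid: {a.pos: a for a in truth.artifacts[lid]} for lid in lesion_ids
    }

    depth_n = _draw_depths(rng, params.depth_mean_normal, params.depth_overdispersion, n)
    truth.depths[f"{pid}_N"] = depth_n

    # Normal counts, shared across every lesion's pileup pair.
    normal_counts: list[dict[str, tuple[int, int]]] = []
    for i in range(n):
        pos = i + 1
        g = germ_by_pos.get(pos)
        normal_counts.append(
            _sample_counts(
                rng, int(depth_n[i]), ref[pos], params.error_rate,
                alt=g.alt if g else None, vaf=g.true_vaf if g else 0.0,
            )
        )

    lesions: dict[str, list[SitePileup]] = {}
    for li, lid in enumerate(lesion_ids):
        depth_t = _draw_depths(rng, params.depth_mean_tumor, params.depth_overdispersion, n)
        truth.depths[lid] = depth_t
        sites: list[SitePileup] = []
        for i in range(n):
            pos = i + 1
            ref_base = ref[pos]
            g = germ_by_pos.get(pos)
            v = som_by_pos[lid].get(pos)
            a = art_by_pos[lid].get(pos)
            if v is not None:
                alt, vaf = v.alt, v.true_vaf
            elif g is not None:
                alt, vaf = g.alt, g.true_vaf
            else:
                alt, vaf = None, 0.0
            t_counts = _sample_counts(
                rng, int(depth_t[i]), ref_base, params.error_rate,
                alt=alt, vaf=vaf, artifact=a, artifact_vaf=params.artifact_vaf,
            )
            n_counts = normal_counts[i]
            tumor = AlleleCounts.from_dict(t_counts)
            normal = AlleleCounts.from_dict(n_counts)
            t_reads = n_reads = None
            if params.emit_read_evidence and (
                tumor.alt_depth(ref_base) > 0 or normal.alt_depth(ref_base) > 0
            ):
                # Artifact reads masquerade as real evidence (confirmed,
                # mutation-grade quality) so that only the targeted filter
                # (strand bias or end-distance) removes them.
                true_alt = v.alt if v else (g.alt if g else (a.alt if a else None))
                site_rng = np.random.default_rng((seed if seed is not None else patient_seed(params.seed, patient_index), li + 1, pos))
                alt_end_hi = 4 if (a is not None and a.kind == "read_end") else None
                t_reads = _base_counts_to_reads(
                    site_rng, t_counts, ref_base,
                    true_alt=true_alt,
                    alt_end_hi=alt_end_hi,
                )
                n_rng = np.random.default_rng((seed if seed is not None else patient_seed(params.seed, patient_index), 0, pos))
                n_reads = _base_counts_to_reads(
                    n_rng, n_counts, ref_base,
                    true_alt=g.alt if g else None,
                )
            sites.append(
                SitePileup(
                    chrom=chrom, pos=pos, ref_base=ref_base,
                    tri_context=ref[pos - 1:pos + 2],
                    tumor=tumor, normal=normal,
                    tumor_reads=t_reads, normal_reads=n_reads,
                )
            )
        lesions[lid] = sites
    return PatientSim(
        patient_id=pid, truth=truth, reference=ref,
        transcripts=transcripts, lesions=lesions,
    )


def simulate_cohort(params: SimParams) -> list[PatientSim]:
    """Simulate all patients from the global seed."""
    return [
        simulate_patient(params, i, seed=patient_seed(params.seed, i))
        for i in range(params.n_patients)
    ]


def simulate_amplicon_counts(
    truth_vaf: float,
    params: SimParams,
    seed: int,
    ref_base: str = "C",
    alt_base: str = "T",
) -> tuple[AlleleCounts, AlleleCounts]:
    """Deep paired amplicon counts for one variant position.

    Tumor alternate reads are Binomial(depth, truth_vaf + error); the
    normal carries error reads only. Depths are Poisson around
    ``amplicon_depth_mean``.
    """
    if not 0.0 <= truth_vaf <= 1.0:
        raise ConfigError(f"truth_vaf {truth_vaf} outside [0, 1]")
    rng = np.random.default_rng(seed)
    e = params.error_rate / 3.0
    out = []
    for vaf in (truth_vaf, 0.0):
        depth = int(rng.poisson(params.amplicon_depth_mean))
        p_alt = vaf + (1.0 - vaf) * e
        n_alt = rng.binomial(depth, p_alt) if depth else 0
        n_ref = depth - n_alt
        f_alt = rng.binomial(n_alt, 0.5) if n_alt else 0
        f_ref = rng.binomial(n_ref, 0.5) if n_ref else 0
        out.append(
            AlleleCounts.from_dict({
                ref_base: (int(f_ref), int(n_ref - f_ref)),
                alt_base: (int(f_alt), int(n_alt - f_alt)),
            })
        )
    return out[0], out[1]


# ---------------------------------------------------------------------------
# Truth-table I/O
# ---------------------------------------------------------------------------

_TRUTH_COLS = ["chrom", "pos", "ref", "alt", "true_vaf", "clonality",
               "consequence", "gene", "shared"]


def write_truth_tables(truth: SimTruth, out_dir: str | os.PathLike) -> None:
    """One TSV per lesion plus a germline TSV; round-trip readable."""
    os.makedirs(out_dir, exist_ok=True)

    def _write(path, variants):
        with open(path, "w") as fh:
            fh.write("\t".join(_TRUTH_COLS) + "\n")
            for v in variants:
                fh.write(
                    f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{v.true_vaf!r}\t"
                    f"{v.clonality}\t{v.consequence}\t{v.gene or '.'}\t{int(v.shared)}\n"
                )

    _write(os.path.join(out_dir, f"{truth.patient_id}_germline.truth.tsv"), truth.germline)
    for lid, variants in truth.somatic.items():
        _write(os.path.join(out_dir, f"{lid}.truth.tsv"), variants)


def read_truth_table(path: str | os.PathLike) -> list[TruthVariant]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _TRUTH_COLS:
            from polyclone.errors import FormatError

            raise FormatError(f"{path}: unexpected truth-table header {header}")
        for line in fh:
            chrom, pos, ref, alt, vaf, clon, csq, gene, shared = line.rstrip("\n").split("\t")
            out.append(
                TruthVariant(
                    chrom=chrom, pos=int(pos), ref=ref, alt=alt,
                    true_vaf=float(vaf), clonality=clon, consequence=csq,
                    gene=None if gene == "." else gene, shared=bool(int(shared)),
                )
            )
    return out
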