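"""Readers and writers: pileup-TSV, BED masks, and VCF 4.2 output.

The pileup-TSV dialect carries one genomic site per row: chrom, 1-based
pos, ref base, reference trinucleotide, eight tumor strand counts
(A+,A-,C+,C-,G+,G-,T+,T-), eight normal strand counts, three 0/1 mask
flags, and two optional JSON-encoded read-evidence columns. Read
evidence is encoded compactly as ``[base, qual, end_distance, strand,
confirmed]`` records.
"""

from __future__ import annotations

import json
import math
import os
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd
import pysam

from polyclone.errors import FormatError, ValidationError
from polyclone.sites import (
    ALL_TAGS,
    PRIMARY_FAIL_TAGS,
    SUBCLONAL_FAIL_TAGS,
    AlleleCounts,
    GenomeMask,
    LesionCallSet,
    ReadEvidence,
    SitePileup,
    TargetRegion,
    VariantCall,
)

PILEUP_COLUMNS = (
    ["chrom", "pos", "ref", "tri_context"]
    + [f"tumor_{b}_{s}" for b in "ACGT" for s in ("fwd", "rev")]
    + [f"normal_{b}_{s}" for b in "ACGT" for s in ("fwd", "rev")]
    + ["low_mapability", "near_repeat", "known_variant"]
)
READ_COLUMNS = ["tumor_reads", "normal_reads"]


def _encode_reads(reads: Optional[list[ReadEvidence]]) -> str:
    if reads is None:
        return "."
    return json.dumps(
        [[r.base, r.base_quality, r.end_distance, r.strand, int(r.confirmed)] for r in reads],
        separators=(",", ":"),
    )


def _decode_reads(cell: str, line_no: int, col: str) -> Optional[list[ReadEvidence]]:
    if cell in (".", "", None) or (isinstance(cell, float) and math.isnan(cell)):
        return None
    try:
        records = json.loads(cell)
        return [
            ReadEvidence(base=b, base_quality=q, end_distance=d, strand=s, confirmed=bool(c))
            for b, q, d, s, c in records
        ]
    except (json.JSONDecodeError, TypeError, ValueError) as exc:
        raise FormatError(f"line {line_no}: cannot parse {col}: {exc}") from exc


def write_pileup_table(sites: Iterable[SitePileup], path: str | os.PathLike) -> None:
    """Write sites to the pileup-TSV dialect (with read-evidence columns)."""
    with open(path, "w") as fh:
        fh.write("\t".join(PILEUP_COLUMNS + READ_COLUMNS) + "\n")
        for s in sites:
            row = [s.chrom, str(s.pos), s.ref_base, s.tri_context]
            row += [str(x) for x in s.tumor.as_tuple()]
            row += [str(x) for x in s.normal.as_tuple()]
            row += [str(int(s.low_mapability)), str(int(s.near_repeat)), str(int(s.known_variant))]
            row += [_encode_reads(s.tumor_reads), _encode_reads(s.normal_reads)]
            fh.write("\t".join(row) + "\n")


def read_pileup_table(path: str | os.PathLike) -> list[SitePileup]:
    """Parse a pileup-TSV file into SitePileup records.

    Malformed rows are reported with their 1-based line number; missing
    columns raise a format error, negative counts a validation error
    naming the offending field.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "tri_context": str},
                         keep_default_na=False, na_values=[])
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - pandas parse failure detail
        raise FormatError(f"{path}: cannot parse as TSV: {exc}") from exc

    missing = [c for c in PILEUP_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns: {missing}")
    has_reads = all(c in df.columns for c in READ_COLUMNS)

    sites: list[SitePileup] = []
    count_cols = PILEUP_COLUMNS[4:20]
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # 1-based, after header
        rec = row._asdict()
        for col in count_cols:
            try:
                v = int(rec[col])
            except (TypeError, ValueError) as exc:
                raise FormatError(f"line {line_no}: column {col} is not an integer") from exc
            if v < 0:
                raise ValidationError(f"line {line_no}: negative count in column {col}")
        tumor = AlleleCounts(*(int(rec[c]) for c in count_cols[:8]))
        normal = AlleleCounts(*(int(rec[c]) for c in count_cols[8:]))
        try:
            site = SitePileup(
                chrom=str(rec["chrom"]),
                pos=int(rec["pos"]),
                ref_base=str(rec["ref"]),
                tri_context=str(rec["tri_context"]),
                tumor=tumor,
                normal=normal,
                tumor_reads=_decode_reads(rec["tumor_reads"], line_no, "tumor_reads") if has_reads else None,
                normal_reads=_decode_reads(rec["normal_reads"], line_no, "normal_reads") if has_reads else None,
                low_mapability=bool(int(rec["low_mapability"])),
                near_repeat=bool(int(rec["near_repeat"])),
                known_variant=bool(int(rec["known_variant"])),
            )
        except ValidationError as exc:
            raise ValidationError(f"line {line_no}: {exc}") from exc
        sites.append(site)
    return sites


def read_bed_mask(path: str | os.PathLike, flank: int = 0) -> GenomeMask:
    """Read a 3+ column BED into a merged interval mask.

    ``flank`` widens each region by that many bp on both sides before
    merging (used for the repeat track, where calls *near* a repeat are
    excluded).
    """
    regions: list[TargetRegion] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path} line {line_no}: BED requires >= 3 columns")
            chrom, start_s, end_s = parts[0], parts[1], parts[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path} line {line_no}: non-integer coordinates") from exc
            if start >= end:
                raise ValidationError(
                    f"{path} line {line_no}: start {start} >= end {end}"
                )
            regions.append(TargetRegion(chrom, max(0, start - flank), end + flank))
    return GenomeMask(regions)


def write_bed(regions: Sequence[TargetRegion], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")


# ---------------------------------------------------------------------------
# VCF 4.2
# ---------------------------------------------------------------------------

_VCF_INFO = [
    ("VAF_T", "1", "Float", "Tumor variant allele fraction"),
    ("VAF_N", "1", "Float", "Normal variant allele fraction"),
    ("FISHER_P", "1", "Float", "Two-sided Fisher exact p, tumor vs normal allele counts"),
    ("SOURCE", "1", "String", "Calling stage: primary or subclonal"),
    ("CSQ", "1", "String", "Coding consequence"),
    ("GENE", "1", "String", "Gene symbol of the most severe consequence"),
]


def _vcf_header(calls: LesionCallSet) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line("##source=polyclone")
    header.add_line(f"##polyclone_lesion_id={calls.lesion_id}")
    header.add_line(f"##polyclone_patient_id={calls.patient_id}")
    if calls.histology:
        header.add_line(f"##polyclone_histology={calls.histology}")
    contig_max: dict[str, int] = {}
    for c in calls.calls:
        contig_max[c.chrom] = max(contig_max.get(c.chrom, 0), c.pos)
    for chrom in sorted(contig_max):
        header.contigs.add(chrom, length=contig_max[chrom] + 1000)
    for tag in sorted(ALL_TAGS):
        header.filters.add(tag, None, None, f"polyclone filter/annotation tag {tag}")
    for name, number, typ, desc in _VCF_INFO:
        header.info.add(name, number, typ, desc)
    return header


def write_vcf(calls: LesionCallSet, path: str | os.PathLike) -> None:
    """Write a call set as VCF 4.2; FILTER is PASS or the tag names."""
    header = _vcf_header(calls)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for c in sorted(calls.calls, key=lambda c: (c.chrom, c.pos, c.alt)):
            rec = vcf.new_record(
                contig=c.chrom, start=c.pos - 1, stop=c.pos,
                alleles=(c.ref, c.alt), qual=None,
            )
            if c.tags:
                for tag in sorted(c.tags):
                    rec.filter.add(tag)
            else:
                rec.filter.add("PASS")
            rec.info["VAF_T"] = float(c.vaf_tumor)
            rec.info["VAF_N"] = float(c.vaf_normal)
            if c.fisher_p is not None:
                rec.info["FISHER_P"] = float(c.fisher_p)
            rec.info["SOURCE"] = c.source
            rec.info["CSQ"] = c.consequence
            if c.gene:
                rec.info["GENE"] = c.gene
            vcf.write(rec)


def read_vcf(path: str | os.PathLike) -> LesionCallSet:
    """Read a polyclone VCF back into a LesionCallSet.

    Floats survive the htslib text round trip to ~7 significant digits.
    """
    lesion_id = patient_id = ""
    histology = ""
    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec_line in str(vcf.header).splitlines():
            if rec_line.startswith("##polyclone_lesion_id="):
                lesion_id = rec_line.split("=", 1)[1]
            elif rec_line.startswith("##polyclone_patient_id="):
                patient_id = rec_line.split("=", 1)[1]
            elif rec_line.startswith("##polyclone_histology="):
                histology = rec_line.split("=", 1)[1]
        for rec in vcf:
            tags = frozenset(f for f in rec.filter.keys() if f != "PASS")
            info = rec.info
            source = info["SOURCE"]
            fail_tags = PRIMARY_FAIL_TAGS if source == "primary" else SUBCLONAL_FAIL_TAGS
            calls.append(
                VariantCall(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    vaf_tumor=float(info["VAF_T"]),
                    vaf_normal=float(info["VAF_N"]),
                    fisher_p=float(info["FISHER_P"]) if "FISHER_P" in info else None,
                    tags=tags,
                    source=source,
                    consequence=info["CSQ"],
                    gene=info.get("GENE"),
                    passed=not (tags & fail_tags),
                )
            )
    return LesionCallSet(lesion_id=lesion_id, patient_id=patient_id, histology=histology, calls=calls)
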