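"""Toy-transcript coding-consequence classification.

Classifies SNVs against small transcript models (ordered CDS intervals
plus the spliced CDS sequence) with the standard genetic code:
synonymous, missense, truncating (stop gained, stop lost or start
lost), or non-coding when the variant falls outside every CDS. This is
a desk-scale replacement for a full annotation engine; it exists so
burden metrics can be restricted to amino-acid-changing mutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from Bio.Seq import Seq

from polyclone.errors import ConfigError
from polyclone.sites import VariantCall

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: Severity order used when a variant hits several transcripts.
SEVERITY = {"truncating": 3, "missense": 2, "synonymous": 1, "non_coding": 0}


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


@dataclass(frozen=True)
class ToyTranscript:
    """A minimal transcript model: gene, strand, CDS intervals, CDS sequence.

    CDS intervals are 0-based half-open in genomic coordinates, stored
    in genomic order; the spliced CDS sequence is given 5'->3' in
    transcript orientation (already reverse-complemented for minus-
    strand genes). The CDS must start with ATG, end with a stop codon,
    and have length divisible by 3.
    """

    gene: str
    chrom: str
    strand: str
    cds_intervals: tuple[tuple[int, int], ...]
    cds_seq: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ConfigError(f"{self.gene}: strand must be '+' or '-'")
        total = sum(e - s for s, e in self.cds_intervals)
        if total != len(self.cds_seq):
            raise ConfigError(
                f"{self.gene}: CDS interval lengths ({total}) != sequence length "
                f"({len(self.cds_seq)})"
            )
        if len(self.cds_seq) % 3 != 0:
            raise ConfigError(f"{self.gene}: CDS length {len(self.cds_seq)} not divisible by 3")
        if not self.cds_seq.startswith("ATG"):
            raise ConfigError(f"{self.gene}: CDS does not start with ATG")
        if str(Seq(self.cds_seq[-3:]).translate()) != "*":
            raise ConfigError(f"{self.gene}: CDS does not end with a stop codon")
        for (s, e) in self.cds_intervals:
            if s >= e:
                raise ConfigError(f"{self.gene}: empty CDS interval ({s}, {e})")

    def cds_index(self, pos: int) -> Optional[int]:
        """Map a 1-based genomic position to a 0-based CDS index, or None."""
        p0 = pos - 1
        offset = 0
        for s, e in self.cds_intervals:
            if s <= p0 < e:
                plus_offset = offset + (p0 - s)
                if self.strand == "+":
                    return plus_offset
                return len(self.cds_seq) - 1 - plus_offset
            offset += e - s
        return None


def _classify_one(variant: VariantCall, tx: ToyTranscript) -> str:
    idx = tx.cds_index(variant.pos)
    if idx is None:
        return "non_coding"
    ref, alt = variant.ref, variant.alt
    if tx.strand == "-":
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    if tx.cds_seq[idx] != ref:
        raise ConfigError(
            f"{tx.gene}: CDS base {tx.cds_seq[idx]} at index {idx} does not match "
            f"variant ref {variant.ref} at {variant.chrom}:{variant.pos}"
        )
    codon_start = (idx // 3) * 3
    ref_codon = tx.cds_seq[codon_start:codon_start + 3]
    within = idx - codon_start
    alt_codon = ref_codon[:within] + alt + ref_codon[within + 1:]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if codon_start == 0 and alt_codon != "ATG":
        return "truncating"  # start lost
    if ref_aa == alt_aa:
        return "synonymous"
    if alt_aa == "*" or ref_aa == "*":
        return "truncating"  # stop gained / stop lost
    return "missense"


def classify_consequence(
    variant: VariantCall,
    transcripts: Sequence[ToyTranscript],
) -> tuple[str, Optional[str]]:
    """Most severe consequence of a SNV across transcripts, with its gene.

    Severity order: truncating > missense > synonymous > non_coding.
    Returns ("non_coding", None) when no transcript on the variant's
    chromosome covers the position.
    """
    best_label, best_gene = "non_coding", None
    for tx in transcripts:
        if tx.chrom != variant.chrom:
            continue
        label = _classify_one(variant, tx)
        if SEVERITY[label] > SEVERITY[best_label]:
            best_label, best_gene = label, tx.gene
    return best_label, best_gene


def is_amino_acid_changing(label: str) -> bool:
    """True for consequences that alter the protein (missense, truncating)."""
    if label not in SEVERITY and label != "unassigned":
        raise ValueError(f"unknown consequence label {label!r}")
    return label in ("missense", "truncating")


def annotate_calls(
    calls: Iterable[VariantCall],
    transcripts: Sequence[ToyTranscript],
) -> list[VariantCall]:
    """Return calls with consequence and gene fields filled in."""
    out = []
    for c in calls:
        label, gene = classify_consequence(c, transcripts)
        out.append(c.with_(consequence=label, gene=gene))
    return out


# ---------------------------------------------------------------------------
# Transcript table I/O (GFF-like TSV + spliced-CDS FASTA)
# ---------------------------------------------------------------------------

def write_transcripts(transcripts: Sequence[ToyTranscript], tsv_path, fasta_path) -> None:
    """Write transcripts as a GFF-like interval TSV plus a CDS FASTA."""
    with open(tsv_path, "w") as fh:
        fh.write("gene\tchrom\tstrand\tstart\tend\n")
        for tx in transcripts:
            for s, e in tx.cds_intervals:
                fh.write(f"{tx.gene}\t{tx.chrom}\t{tx.strand}\t{s}\t{e}\n")
    with open(fasta_path, "w") as fh:
        for tx in transcripts:
            fh.write(f">{tx.gene}\n{tx.cds_seq}\n")


def read_transcripts(tsv_path, fasta_path) -> list[ToyTranscript]:
    import pandas as pd

    seqs: dict[str, str] = {}
    name = None
    with open(fasta_path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = ""
            elif name is not None:
                seqs[name] += line
    df = pd.read_csv(tsv_path, sep="\t", dtype={"gene": str, "chrom": str, "strand": str})
    out = []
    for gene, grp in df.groupby("gene", sort=False):
        ivs = tuple(sorted((int(s), int(e)) for s, e in zip(grp["start"], grp["end"])))
        out.append(
            ToyTranscript(
                gene=gene,
                chrom=str(grp["chrom"].iloc[0]),
                strand=str(grp["strand"].iloc[0]),
                cds_intervals=ivs,
                cds_seq=seqs[gene],
            )
        )
    return out
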