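"""End-to-end orchestration: simulate -> call -> annotate -> metrics ->
validate -> compare, with a machine-readable run manifest.

Every stage is a pure function of (inputs, config); re-running with the
same config and seed reproduces every output file byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

from polyclone import __version__
from polyclone.config import PipelineConfig
from polyclone.consequence import annotate_calls, write_transcripts
from polyclone.errors import ConfigError
from polyclone.heterogeneity import (
    OverlapReport,
    classify_clonality,
    gene_multihit_report,
    overlap_report,
)
from polyclone.io import write_pileup_table, write_vcf
from polyclone.metrics import (
    LesionMetrics,
    count_aa_changing,
    inverse_analysis,
    lesion_metrics,
    spectrum_summary,
    SpectrumSummary,
)
from polyclone.primary import call_lesion_primary
from polyclone.sites import LesionCallSet, PatientCohort
from polyclone.simulate import PatientSim, simulate_amplicon_counts, simulate_cohort, write_truth_tables
from polyclone.subclonal import call_lesion_subclonal
from polyclone.validation import ValidationResult, concordance_rate, validate_call

logger = logging.getLogger("polyclone")


@dataclass
class LesionResult:
    lesion_id: str
    patient_id: str
    primary: LesionCallSet
    subclonal: LesionCallSet
    metrics: LesionMetrics
    spectrum: SpectrumSummary
    validation: list[ValidationResult] = field(default_factory=list)
    concordance: Optional[float] = None


@dataclass
class ReportBundle:
    config: PipelineConfig
    lesions: list[LesionResult]
    overlaps: list[OverlapReport]
    manifest: dict


def _analyze_lesion(sim: PatientSim, lesion_id: str, cfg: PipelineConfig,
                    val_seed: int) -> LesionResult:
    sites = sim.lesions[lesion_id]
    primary_calls = call_lesion_primary(
        sites,
        het_min=cfg.het_min,
        hom_alt_min=cfg.hom_alt_min,
        min_depth=cfg.min_depth,
        strand_bias_alpha=cfg.strand_bias_alpha,
        tail_bias_alpha=cfg.tail_bias_alpha,
    )
    subclonal_calls = call_lesion_subclonal(
        sites,
        min_baseq=cfg.min_baseq,
        end_exclusion_bp=cfg.end_exclusion_bp,
        min_mutant_reads=cfg.min_mutant_reads,
    )
    primary_calls = annotate_calls(primary_calls, sim.transcripts)
    subclonal_calls = annotate_calls(subclonal_calls, sim.transcripts)
    primary_set = LesionCallSet(
        lesion_id=lesion_id, patient_id=sim.patient_id, calls=primary_calls
    )
    subclonal_set = LesionCallSet(
        lesion_id=lesion_id, patient_id=sim.patient_id, calls=subclonal_calls
    )

    n_inv, _ = inverse_analysis(
        sites,
        transcripts=sim.transcripts,
        target_mb=cfg.target_mb,
        het_min=cfg.het_min,
        hom_alt_min=cfg.hom_alt_min,
        min_depth=cfg.min_depth,
        strand_bias_alpha=cfg.strand_bias_alpha,
        tail_bias_alpha=cfg.tail_bias_alpha,
    )
    metrics = lesion_metrics(primary_set, target_mb=cfg.target_mb, n_inverse=n_inv)
    spectrum = spectrum_summary(primary_set, contexts=sim.contexts())

    # Secondary analysis: deep amplicon counts around each passed primary
    # call, sampled at the call's *true* VAF (0 for a false positive).
    truth_vaf = {
        (v.chrom, v.pos, v.ref, v.alt): v.true_vaf
        for v in sim.truth.somatic[lesion_id]
    }
    results = []
    for i, call in enumerate(sorted(primary_set.passed_calls, key=lambda c: c.key)):
        tumor, normal = simulate_amplicon_counts(
            truth_vaf.get(call.key, 0.0), cfg.sim,
            seed=(val_seed + 7 * i) % (2**31 - 1),
            ref_base=call.ref, alt_base=call.alt,
        )
        results.append(
            validate_call(
                tumor, normal, call.alt, variant_key=call.key,
                min_coverage=cfg.val_min_coverage,
                min_mutant_reads=cfg.val_min_mutant_reads,
                min_mutant_fraction=cfg.val_min_mutant_fraction,
            )
        )
    conc = concordance_rate(primary_set, results, mp_threshold=cfg.mp_threshold)
    logger.info(
        "%s: %d primary (%d passed), %d subclonal (%d passed), %d AA-changing, "
        "inverse %d, concordance %s",
        lesion_id, len(primary_set), len(primary_set.passed_calls),
        len(subclonal_set), len(subclonal_set.passed_calls),
        metrics.n_aa_changing, n_inv,
        f"{conc:.3f}" if conc is not None else "NA",
    )
    return LesionResult(
        lesion_id=lesion_id,
        patient_id=sim.patient_id,
        primary=primary_set,
        subclonal=subclonal_set,
        metrics=metrics,
        spectrum=spectrum,
        validation=results,
        concordance=conc,
    )


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_reports(bundle: ReportBundle, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    cfg = bundle.config
    # Table-style burden metrics.
    with open(os.path.join(out_dir, "lesion_metrics.tsv"), "w") as fh:
        fh.write("lesion_id\tpatient_id\tn_aa_changing\tmut_index\t"
                 "n_inverse\tinverse_index\tconcordance\n")
        for r in bundle.lesions:
            m = r.metrics
            conc = f"{r.concordance:.4f}" if r.concordance is not None else "NA"
            fh.write(
                f"{r.lesion_id}\t{r.patient_id}\t{m.n_aa_changing}\t{m.mut_index:.2f}\t"
                f"{m.n_inverse}\t{m.inverse_index:.2f}\t{conc}\n"
            )
    # Spectrum report.
    with open(os.path.join(out_dir, "spectrum.tsv"), "w") as fh:
        classes = list(bundle.lesions[0].spectrum.class_fractions) if bundle.lesions else []
        fh.write("lesion_id\t" + "\t".join(classes) + "\tcpg_fraction_of_cg_transitions\n")
        for r in bundle.lesions:
            sp = r.spectrum
            cpg = (
                f"{sp.cpg_fraction_of_cg_transitions:.4f}"
                if sp.cpg_fraction_of_cg_transitions is not None else "NA"
            )
            fh.write(
                r.lesion_id + "\t"
                + "\t".join(f"{sp.class_fractions[k]:.4f}" for k in classes)
                + f"\t{cpg}\n"
            )
    # Heterogeneity report.
    with open(os.path.join(out_dir, "overlap.tsv"), "w") as fh:
        fh.write("patient_id\tlesion_a\tlesion_b\tshared\tunion\tjaccard\tshared_keys\n")
        for rep in bundle.overlaps:
            for p in rep.pairs:
                keys = ";".join("_".join(map(str, k)) for k in p.shared_keys) or "."
                fh.write(
                    f"{rep.patient_id}\t{p.lesion_a}\t{p.lesion_b}\t{p.shared}\t"
                    f"{p.union}\t{p.jaccard:.4f}\t{keys}\n"
                )
    # Clonality report.
    with open(os.path.join(out_dir, "clonality.tsv"), "w") as fh:
        fh.write("lesion_id\tchrom\tpos\tref\talt\tvaf_tumor\tlabel\n")
        for r in bundle.lesions:
            for c in r.primary.passed_calls:
                cl = classify_clonality(c, cfg.clonal_vaf_threshold)
                fh.write(
                    f"{r.lesion_id}\t{c.chrom}\t{c.pos}\t{c.ref}\t{c.alt}\t"
                    f"{c.vaf_tumor:.4f}\t{cl.label}\n"
                )
    # Per-lesion VCFs.
    for r in bundle.lesions:
        write_vcf(r.primary, os.path.join(out_dir, f"{r.lesion_id}.primary.vcf"))
        write_vcf(r.subclonal, os.path.join(out_dir, f"{r.lesion_id}.subclonal.vcf"))
    # Validation report.
    with open(os.path.join(out_dir, "validation.tsv"), "w") as fh:
        fh.write("lesion_id\tchrom\tpos\tref\talt\ttumor_depth\ttumor_mut\t"
                 "normal_depth\tnormal_mut\tstatus\n")
        for r in bundle.lesions:
            for v in r.validation:
                chrom, pos, ref, alt = v.variant_key
                fh.write(
                    f"{r.lesion_id}\t{chrom}\t{pos}\t{ref}\t{alt}\t{v.tumor_depth}\t"
                    f"{v.tumor_mutant_reads}\t{v.normal_depth}\t{v.normal_mutant_reads}\t"
                    f"{v.status}\n"
                )


def run_all(config: PipelineConfig, out_dir: str,
            write_inputs: bool = False) -> ReportBundle:
    """Run the whole pipeline on a simulated cohort and write reports.

    Stages: simulate -> primary calling -> subclonal calling ->
    consequence annotation -> metrics (including the inverse analysis)
    -> amplicon validation -> cross-lesion comparison. A cohort whose
    patients have a single lesion skips the comparison stage with a
    logged notice.
    """
    if config.target_mb <= 0:  # re-checked here so run_all rejects before staging
        raise ConfigError("target_mb must be > 0")
    stage = "simulate"
    try:
        sims = simulate_cohort(config.sim)
        if write_inputs:
            for sim in sims:
                pdir = os.path.join(out_dir, "inputs", sim.patient_id)
                os.makedirs(pdir, exist_ok=True)
                write_truth_tables(sim.truth, pdir)
                write_transcripts(
                    sim.transcripts,
                    os.path.join(pdir, "transcripts.tsv"),
                    os.path.join(pdir, "transcripts.fa"),
                )
                for lid, sites in sim.lesions.items():
                    write_pileup_table(sites, os.path.join(pdir, f"{lid}.pileup.tsv"))
        lesions: list[LesionResult] = []
        overlaps: list[OverlapReport] = []
        for sim in sims:
            stage = f"call/{sim.patient_id}"
            results = [
                _analyze_lesion(sim, lid, config,
                                val_seed=(config.seed * 9973 + i * 31 + 11) % (2**31 - 1))
                for i, lid in enumerate(sim.lesions)
            ]
            lesions.extend(results)
            stage = f"compare/{sim.patient_id}"
            if len(results) >= 2:
                cohort = PatientCohort(
                    patient_id=sim.patient_id,
                    lesions=[r.primary for r in results],
                )
                overlaps.append(overlap_report(cohort))
            else:
                logger.info("%s: single lesion, comparison stage skipped", sim.patient_id)
        stage = "report"
        manifest: dict = {
            "version": __version__,
            "seed": config.seed,
            "config": config.to_dict(),
        }
        bundle = ReportBundle(config=config, lesions=lesions, overlaps=overlaps,
                              manifest=manifest)
        _write_reports(bundle, out_dir)
        outputs = sorted(
            os.path.relpath(os.path.join(root, f), out_dir)
            for root, _, files in os.walk(out_dir)
            for f in files
            if f != "manifest.json"
        )
        manifest["outputs"] = {p: _sha256(os.path.join(out_dir, p)) for p in outputs}
        with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return bundle
    except ConfigError:
        raise
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
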