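"""End-to-end orchestration: variants -> peptides -> scoring -> summary.

`run_pipeline` executes the stages in order, writes one CSV per stage plus a
machine-readable JSON summary, and is byte-reproducible for a fixed config
and inputs (all outputs are deterministically ordered; no timestamps).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import yaml

from . import binding, expression, peptides, summary, transcripts, variants
from .errors import ConfigError, StageError

log = logging.getLogger("allopotential")


@dataclass
class PipelineConfig:
    recipient_vcf: str = ""
    donor_vcf: str = ""
    direction: str = "GVH"
    recipient_sample: Optional[str] = None
    donor_sample: Optional[str] = None
    gff3: Optional[str] = None
    genome_fasta: Optional[str] = None
    transcript_table: Optional[str] = None
    hla_alleles: List[str] = field(default_factory=list)
    matrix_paths: Dict[str, str] = field(default_factory=dict)
    pan_output: Optional[str] = None
    pan_columns: Dict[str, str] = field(default_factory=dict)
    expression_table: Optional[str] = None
    flank: int = 8
    presented_nM: float = 500.0
    strong_nM: float = 50.0
    auc_cutoff_nM: float = 100.0
    reu_threshold: float = 10.0
    dedup_counts: bool = True  # unique complexes for count statistics
    dedup_auc: bool = False  # duplicates retained for the rank-curve potential
    missing_as_unknown: bool = False
    seed: int = 0
    patient_id: str = "patient"

    def validate(self) -> None:
        if not self.recipient_vcf or not self.donor_vcf:
            raise ConfigError("recipient_vcf and donor_vcf are required")
        if self.direction not in ("GVH", "HVG"):
            raise ConfigError(f"direction must be GVH or HVG, got {self.direction!r}")
        if not (self.transcript_table or (self.gff3 and self.genome_fasta)):
            raise ConfigError("provide transcript_table or gff3 + genome_fasta")
        if not self.hla_alleles:
            raise ConfigError("hla_alleles is required")
        if not self.strong_nM < self.presented_nM:
            raise ConfigError("strong threshold must be below presented threshold")
        for t in ("presented_nM", "strong_nM", "auc_cutoff_nM"):
            if getattr(self, t) <= 0:
                raise ConfigError(f"{t} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        thresholds = raw.pop("thresholds", {})
        mapping = {
            "presented_nM": "presented_nM",
            "strong_nM": "strong_nM",
            "auc_cutoff_nM": "auc_cutoff_nM",
            "reu_threshold": "reu_threshold",
        }
        for k, attr in mapping.items():
            if k in thresholds:
                raw[attr] = thresholds[k]
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except (ConfigError,) as exc:
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc

        return wrapper

    return deco


@_stage("gvh-call")
def stage_directional(config: PipelineConfig) -> Tuple[variants.DirectionalVariantSet, dict]:
    recipient = variants.read_variant_calls(
        config.recipient_vcf, config.recipient_sample, config.missing_as_unknown
    )
    donor = variants.read_variant_calls(
        config.donor_vcf, config.donor_sample, config.missing_as_unknown
    )
    dset = variants.directional_set_from_calls(
        recipient, donor, config.direction, config.missing_as_unknown
    )
    log.info(
        "directional set %s: %d variants (recipient %d, donor %d)",
        config.direction,
        len(dset),
        len(recipient.variants),
        len(donor.variants),
    )
    return dset, {
        "recipient_load": recipient.report.as_dict(),
        "donor_load": donor.report.as_dict(),
        "n_recipient_variants": len(recipient.variants),
        "n_donor_variants": len(donor.variants),
        "n_directional": len(dset),
    }


@_stage("peptides")
def stage_peptides(config: PipelineConfig, dset) -> Tuple[list, peptides.PeptideBuildReport]:
    if config.transcript_table:
        models, load_report = transcripts.load_transcript_table(config.transcript_table)
    else:
        models, load_report = transcripts.load_transcript_models(
            config.gff3, config.genome_fasta
        )
    log.info("loaded %d transcript models (%d rejected)", load_report.n_loaded, len(load_report.rejected))
    nonamers, report = peptides.build_peptide_library(dset.variants, models, flank=config.flank)
    log.info(
        "peptide library: %d nonsynonymous consequences -> %d padded peptides -> %d nonamers",
        report.n_nonsynonymous,
        report.n_padded,
        report.n_nonamers,
    )
    return nonamers, report


@_stage("score")
def stage_score(config: PipelineConfig, nonamers) -> List[binding.BindingRecord]:
    genotype = binding.HlaGenotype(config.patient_id, tuple(config.hla_alleles))
    matrices = {a: binding.load_scoring_matrix(p) for a, p in config.matrix_paths.items()}
    records = binding.score_peptides(nonamers, genotype, matrices)
    log.info("scored %d peptide-allele pairs with the matrix predictor", len(records))
    return records


@_stage("parse-pan")
def stage_pan(config: PipelineConfig) -> List[binding.BindingRecord]:
    with open(config.pan_output) as fh:
        records = binding.parse_pan_predictor_output(fh, config.pan_columns or None)
    log.info("parsed %d pan-predictor records", len(records))
    return records


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute all stages, write per-stage outputs under ``outdir``, and
    return the JSON-able summary (also written as summary.json)."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary_doc: dict = {"config": {"direction": config.direction, "seed": config.seed}}

    dset, variant_stats = stage_directional(config)
    summary_doc["variants"] = variant_stats
    variants.write_variant_csv(dset.variants, outdir / "directional_variants.csv")
    variants.write_variant_vcf(dset.variants, outdir / "directional_variants.vcf")

    nonamers, pep_report = stage_peptides(config, dset)
    summary_doc["peptides"] = dict(pep_report.__dict__)
    _write_peptide_csvs(nonamers, outdir)

    smm_records = stage_score(config, nonamers)
    binding.write_binding_csv(smm_records, outdir / "binding_smm.csv")

    pan_records: List[binding.BindingRecord] = []
    if config.pan_output:
        pan_records = stage_pan(config)
        binding.write_binding_csv(pan_records, outdir / "binding_pan.csv")

    summary_doc["summary"] = _summarize(config, smm_records, pan_records, outdir)

    if config.expression_table:
        table = expression.load_expression_table(config.expression_table)
        presented = [
            r for r in smm_records if r.presentation is not binding.Presentation.NONE
        ]
        counts, unmapped = expression.count_expressed_antigen_genes(
            presented, table, config.reu_threshold
        )
        expression.write_tissue_counts(counts, outdir / "tissue_counts.csv")
        summary_doc["tissue"] = {
            "threshold_reu": config.reu_threshold,
            "counts": counts,
            "n_unmapped_genes": len(unmapped),
        }

    text = json.dumps(summary_doc, indent=2, sort_keys=True)
    (outdir / "summary.json").write_text(text + "\n")
    return summary_doc


def _write_peptide_csvs(nonamers, outdir: Path) -> None:
    padded_rows = {}
    nonamer_lines = []
    for nm in sorted(
        nonamers, key=lambda n: (n.parent.consequence.variant, n.parent.consequence.transcript_id, n.variant_pos)
    ):
        c = nm.parent.consequence
        v = c.variant
        key = (c.transcript_id, v, nm.parent.sequence)
        base = (
            f"{c.gene_id},{c.transcript_id},{v.chrom},{v.pos},{v.ref},{v.alt},"
            f"{c.protein_pos},{c.ref_aa},{c.alt_aa},{nm.parent.sequence},{nm.parent.variant_offset}"
        )
        padded_rows[key] = base
        nonamer_lines.append(f"{base},{nm.sequence},{nm.variant_pos}")
    header = "gene,transcript,chrom,pos,ref,alt,protein_pos,ref_aa,alt_aa,padded_peptide,variant_offset"
    with open(outdir / "peptides.csv", "w") as fh:
        fh.write(header + "\n")
        for line in padded_rows.values():
            fh.write(line + "\n")
    with open(outdir / "nonamers.csv", "w") as fh:
        fh.write(header + ",nonamer,variant_pos\n")
        for line in nonamer_lines:
            fh.write(line + "\n")


@_stage("summarize")
def _summarize(config, smm_records, pan_records, outdir: Path) -> dict:
    doc: dict = {}
    best_smm = binding.best_ic50_by_key(smm_records)
    vals = (
        list(best_smm.values()) if config.dedup_counts else [r.ic50_nM for r in smm_records]
    )
    doc["smm"] = {
        "n_records": len(smm_records),
        "n_unique_complexes": len(best_smm),
        "presented": sum(1 for v in vals if v < config.presented_nM),
        "strongly_presented": sum(1 for v in vals if v < config.strong_nM),
        "per_locus_presented": summary.per_locus_presented_counts(
            smm_records, config.presented_nM
        ),
    }
    auc_records = smm_records
    if config.dedup_auc:
        auc_records = [
            binding.BindingRecord.make(k[0], k[1], "SMM", v)
            for k, v in sorted(best_smm.items())
        ]
    auc = summary.compute_alloreactivity_potential(auc_records, config.auc_cutoff_nM)
    doc["alloreactivity_potential"] = {
        "auc_nM_peptide": auc.auc,
        "n_points": auc.n_points,
        "cutoff_nM": auc.cutoff_nM,
        "coefficients": list(auc.coefficients),
        "fit_rmse": auc.fit_rmse,
        "fallback": auc.fallback,
    }
    series = summary.rank_ic50_curve(auc_records, config.auc_cutoff_nM)
    try:
        summary.plot_rank_curve(auc, series, outdir / "rank_curve.png")
    except Exception:  # plotting is best-effort
        log.warning("rank-curve plot failed", exc_info=True)
    presented_smm = [r for r in smm_records if r.ic50_nM < config.presented_nM]
    if len(presented_smm) >= 3:
        fit = summary.fit_power_law(presented_smm)
        doc["power_law"] = {
            "exponent": fit.exponent,
            "intercept": fit.intercept,
            "r_squared": fit.r_squared,
            "n": fit.n,
        }
    if pan_records:
        best_pan = binding.best_ic50_by_key(pan_records)
        pvals = list(best_pan.values())
        doc["pan"] = {
            "n_records": len(pan_records),
            "n_unique_complexes": len(best_pan),
            "presented": sum(1 for v in pvals if v < config.presented_nM),
            "strongly_presented": sum(1 for v in pvals if v < config.strong_nM),
        }
        shared = binding.shared_complexes(smm_records, pan_records, config.presented_nM)
        doc["shared"] = {"n": len(shared)}
        if len(shared) >= 3:
            r, p, n = binding.correlate_predictions(shared, log_scale=False)
            doc["shared"]["pearson_r"] = r
            doc["shared"]["pearson_p"] = p
        with open(outdir / "shared_complexes.csv", "w") as fh:
            fh.write("peptide,allele,ic50_smm_nM,ic50_pan_nM\n")
            for c in sorted(shared, key=lambda c: c.key):
                fh.write(
                    f"{c.peptide},{c.allele},{c.ic50('SMM'):.6g},{c.ic50('PAN'):.6g}\n"
                )
    return doc
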