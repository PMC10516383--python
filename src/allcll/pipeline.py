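"""Single-sample orchestration and the integrated per-sample report.

Runs reconstruction -> annotation -> subset -> R110 -> CNA -> variants; any
stage failure degrades to an explicit "not evaluable" section rather than
aborting the report. Reports serialize deterministically (stable key order),
so a rerun on identical input is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import __version__
from .annotate import AnnotationConfig, airr_table, annotate_sequence
from .cna import CNAConfig, cna_table, call_cnas, compute_depths, normalize
from .light_chain import R110Result, analyze_light_chain
from .reconstruct import ReconstructionConfig, candidates_to_fasta, reconstruct
from .reference import ReferenceBundle
from .stereotypy import assign_subset, bundled_definitions
from .variants import VariantConfig, pileup_call, variant_table, write_vcf

NOT_EVALUABLE = "not evaluable"


def default_config() -> dict:
    with resources.files("allcll").joinpath("data/default_config.yaml").open() as fh:
        return yaml.safe_load(fh)


def load_config(path: str | Path | None = None) -> dict:
    config = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for block, values in user.items():
            config.setdefault(block, {}).update(values or {})
    return config


def config_digest(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]


def _module_configs(config: dict):
    return (ReconstructionConfig(**config["reconstruction"]),
            AnnotationConfig(**config["annotation"]),
            CNAConfig(**config["cna"]),
            VariantConfig(**config["variants"]),
            config.get("light_chain", {}).get("min_codon_support", 10))


def run_pipeline(alignments, bundle: ReferenceBundle,
                 genome: Mapping[str, str] | None = None,
                 normals: Sequence | None = None,
                 subset_definitions=None,
                 config: dict | None = None,
                 outdir: str | Path | None = None,
                 sample_id: str = "sample",
                 seed: int | None = None) -> dict:
    """Execute the full workflow on one sample and return the report dict."""
    config = config or default_config()
    recon_cfg, ann_cfg, cna_cfg, var_cfg, min_codon_support = _module_configs(config)
    if subset_definitions is None:
        definitions, subset_version = bundled_definitions()
    else:
        definitions, subset_version = subset_definitions

    report: dict = {
        "sample_id": sample_id,
        "run_metadata": {
            "tool_version": __version__,
            "reference_checksum": bundle.checksum(),
            "config_digest": config_digest(config),
            "seed": seed,
            "subset_definitions_version": subset_version,
        },
    }
    evaluable: dict[str, bool] = {}
    annotations = []

    # --- IG reconstruction + annotation -----------------------------------
    try:
        recon = reconstruct(alignments, bundle, recon_cfg)
        igh = [c for c in recon.candidates if c.locus == "IGH"]
        if igh:
            top = igh[0]
            ann = annotate_sequence(top.sequence, bundle, "IGH", candidate=top, config=ann_cfg)
            subset = assign_subset(ann, definitions)
            ann.subset_id = subset.subset_id
            annotations.append(ann)
            report["igh"] = {
                "v_call": ann.v.segment_name,
                "d_call": ann.d.segment_name if ann.d else None,
                "j_call": ann.j.segment_name,
                "cdr3_aa": ann.cdr3.aa_sequence if ann.cdr3 else None,
                "junction_aa": ann.cdr3.junction_aa if ann.cdr3 else None,
                "identity_pct": ann.shm.identity_pct,
                "shm_status": ann.shm.status,
                "borderline": ann.shm.borderline,
                "productive": ann.productive,
                "failure_reason": ann.failure_reason,
                "subset_id": subset.subset_id,
                "support": top.support,
                "score": round(top.score, 4),
            }
            evaluable["igh"] = True
        else:
            report["igh"] = {"status": "no rearrangement detected"}
            evaluable["igh"] = False
    except Exception as exc:  # degrade, never abort
        report["igh"] = {"status": NOT_EVALUABLE, "error": str(exc)}
        evaluable["igh"] = False
        recon = None

    # --- IGL / R110 --------------------------------------------------------
    try:
        if recon is not None:
            r110 = analyze_light_chain(recon.candidates, bundle, ann_cfg,
                                       min_codon_support=min_codon_support)
            igl_cands = [c for c in recon.candidates if c.locus == "IGL"]
            if igl_cands and r110.status not in ("no_rearrangement",):
                ann_igl = annotate_sequence(igl_cands[0].sequence, bundle, "IGL",
                                            candidate=igl_cands[0], config=ann_cfg)
                annotations.append(ann_igl)
        else:
            r110 = R110Result(status="no_rearrangement")
        report["iglv3_21"] = r110.to_dict()
        evaluable["iglv3_21"] = r110.status != "indeterminate"
    except Exception as exc:
        report["iglv3_21"] = {"status": NOT_EVALUABLE, "error": str(exc)}
        evaluable["iglv3_21"] = False

    # --- CNAs ---------------------------------------------------------------
    try:
        profile = compute_depths(alignments, bundle, sample_id, cna_cfg)
        norm = normalize(profile, bundle, normals, cna_cfg)
        cna_result = call_cnas(norm, bundle, cna_cfg)
        report["cnas"] = {
            "qc_pass": cna_result.qc_pass,
            "uniformity_metric": round(norm.uniformity_metric, 4),
            "normalization": norm.mode,
            "calls": [
                {"region": c.region, "state": c.state,
                 "median_log2": None if c.median_log2 is None else round(c.median_log2, 4),
                 "n_targets": c.n_targets,
                 "clonal_fraction": None if c.clonal_fraction_est is None
                 else round(c.clonal_fraction_est, 3)}
                for c in cna_result.calls],
        }
        evaluable["cnas"] = cna_result.qc_pass
        mean_cov = float(np.mean(list(profile.depths.values()))) if profile.depths else 0.0
    except Exception as exc:
        report["cnas"] = {"status": NOT_EVALUABLE, "error": str(exc)}
        evaluable["cnas"] = False
        cna_result = None
        norm = None
        mean_cov = 0.0

    # --- variants -----------------------------------------------------------
    variant_calls = []
    try:
        if genome is None:
            report["variants"] = {"status": NOT_EVALUABLE,
                                  "error": "no genomic reference supplied"}
            evaluable["variants"] = False
        else:
            variant_calls = pileup_call(alignments, genome, bundle, var_cfg)
            report["variants"] = {
                "n_pass": sum(c.status == "pass" for c in variant_calls),
                "n_low_confidence": sum(c.status == "low_confidence" for c in variant_calls),
                "n_filtered": sum(c.status == "filtered" for c in variant_calls),
                "calls": [
                    {"chrom": c.chrom, "pos": c.pos, "ref": c.ref, "alt": c.alt,
                     "gene": c.gene, "depth": c.depth, "alt_count": c.alt_count,
                     "vaf": round(c.vaf, 4), "status": c.status,
                     "filters": sorted(c.filters)}
                    for c in sorted(variant_calls, key=lambda c: (c.chrom, c.pos, c.alt))],
            }
            evaluable["variants"] = True
    except Exception as exc:
        report["variants"] = {"status": NOT_EVALUABLE, "error": str(exc)}
        evaluable["variants"] = False

    report["qc"] = {
        "mean_target_coverage": round(mean_cov, 2),
        "uniformity_metric": None if norm is None else round(norm.uniformity_metric, 4),
        "flags": sorted(k for k, ok in evaluable.items() if not ok),
    }
    report["evaluable"] = evaluable

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_report(report, outdir / "report.json")
        if annotations:
            airr_table(annotations).to_csv(outdir / "rearrangements.tsv", sep="\t", index=False)
        if recon is not None and recon.candidates:
            candidates_to_fasta(recon.candidates[:1], outdir / "clonal_rearrangement.fasta")
        if cna_result is not None:
            cna_table(cna_result).to_csv(outdir / "cna.tsv", sep="\t", index=False)
        if genome is not None:
            write_vcf(variant_calls, outdir / "variants.vcf",
                      {c: len(genome[c]) for c in genome})
            variant_table(variant_calls).to_csv(outdir / "variants.tsv", sep="\t", index=False)
    return report


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, sort_keys=True, indent=2) + "\n")
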