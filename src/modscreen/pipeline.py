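"""End-to-end orchestration: simulate/load -> filter -> GRM -> GWAS ->
assign -> GSEA -> report, with a manifest for reproducibility auditing.

Each stage communicates only through the declared file formats, so any
stage can be re-run piecewise from the written outputs. The manifest
records the config hash, seeds, per-stage row counts, every threshold
applied, and SHA-256 digests of all outputs; re-running an identical
config reproduces identical digests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict

import pandas as pd
import yaml

from . import __version__, association, gene_assignment, gsea, io_formats
from . import phenotype_stats, synthetic_data
from .errors import InvalidConfigError, ValidationError

log = logging.getLogger(__name__)

STAGE_FILES = ["assoc.tsv", "assignments.tsv", "gsea.tsv", "qq.tsv",
               "manifest.json"]


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(path: str) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise InvalidConfigError("config must be a mapping")
    known = {"simulation", "inputs", "maf_min", "max_missing", "p_cutoff",
             "window_bp", "n_perm", "seed", "weight_p", "min_lines",
             "gsea_min_genes", "gsea_p_adj_max"}
    unknown = set(cfg) - known
    if unknown:
        raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")
    if ("simulation" in cfg) == ("inputs" in cfg):
        raise InvalidConfigError(
            "config needs exactly one of 'simulation' or 'inputs'")
    return cfg


def run_screen(config_path: str, out_dir: str) -> dict:
    """Run the whole screen from a YAML config; returns the manifest."""
    cfg = load_config(config_path)
    os.makedirs(out_dir, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    maf_min = float(cfg.get("maf_min", 0.05))
    max_missing = float(cfg.get("max_missing", 0.20))
    p_cutoff = float(cfg.get("p_cutoff", 1e-4))
    window = int(cfg.get("window_bp", 1000))
    n_perm = int(cfg.get("n_perm", 1000))
    weight_p = float(cfg.get("weight_p", 1.0))
    min_lines = int(cfg.get("min_lines", 30))
    counts: dict = {}

    stage = "simulate/load"
    try:
        if "simulation" in cfg:
            sim = dict(cfg["simulation"])
            sim.setdefault("seed", seed)
            scfg = synthetic_data.config_from_dict(sim)
            geno, genes, sets, pheno, truth = \
                synthetic_data.simulate_screen(scfg)
            with open(os.path.join(out_dir, "ground_truth.json"), "w") as fh:
                json.dump(truth.to_json_dict(), fh, indent=1)
        else:
            inputs = cfg["inputs"]
            geno = io_formats.read_genotypes(inputs["genotypes"])
            genes = io_formats.read_annotation(inputs["annotation"])
            sets = io_formats.read_gene_sets(inputs["gene_sets"])
            pheno = io_formats.read_phenotypes(inputs["phenotypes"])
        counts["lines"] = geno.n_lines
        counts["variants_in"] = geno.n_variants
        counts["genes_annotated"] = len(genes)
        counts["gene_sets_in"] = len(sets)

        stage = "phenotype summary"
        summary = phenotype_stats.summarize_strains(pheno, sex_filter="F")
        counts["strains_summarized"] = len(summary)

        stage = "variant filtering"
        filtered, report = association.filter_variants(
            geno, maf_min=maf_min, max_missing=max_missing)
        counts["variants_filtered_out"] = report.n_input - report.n_retained
        counts["variants_tested"] = report.n_retained
        log.info("filters applied: maf_min=%g max_missing=%g; removed "
                 "non-biallelic=%d high-missing=%d low-maf=%d", maf_min,
                 max_missing, report.n_non_biallelic, report.n_high_missing,
                 report.n_low_maf)

        stage = "GRM"
        K = association.compute_grm(filtered)

        stage = "GWAS"
        assoc = association.run_gwas(summary, filtered, K,
                                     min_lines=min_lines)
        io_formats.write_assoc_results(assoc, os.path.join(out_dir,
                                                           "assoc.tsv"))

        stage = "QQ diagnostics"
        qq, lam_gc = association.qq_diagnostics(assoc)
        qq.to_csv(os.path.join(out_dir, "qq.tsv"), sep="\t", index=False,
                  float_format="%.6g")
        counts["lambda_gc"] = round(lam_gc, 4)

        stage = "gene assignment"
        assignments = gene_assignment.assign_variants(
            filtered.variants, genes, window=window)
        merged = assignments.merge(assoc[["variant_id", "p_wald"]],
                                   on="variant_id")
        merged.to_csv(os.path.join(out_dir, "assignments.tsv"), sep="\t",
                      index=False, float_format="%.12g")
        cands, inter = gene_assignment.candidate_genes(assignments, assoc,
                                                       p_cutoff=p_cutoff)
        cands.to_csv(os.path.join(out_dir, "candidates.tsv"), sep="\t",
                     index=False, float_format="%.12g")
        counts["candidate_genes"] = len(cands)
        counts["intergenic_hits"] = len(inter)
        log.info("candidate threshold applied: p < %g", p_cutoff)

        stage = "GSEA"
        ranked = gsea.rank_genes(assignments, assoc)
        counts["genes_ranked"] = len(ranked)
        results = gsea.permutation_significance(
            ranked, sets, n_perm=n_perm, seed=seed + 7919,
            weight_p=weight_p)
        counts["sets_tested"] = len(results)
        min_genes = int(cfg.get("gsea_min_genes", 4))
        p_adj_max = float(cfg.get("gsea_p_adj_max", 0.05))
        passing = gsea.filter_results(results, min_genes=min_genes,
                                      p_adj_max=p_adj_max)
        counts["sets_passing"] = len(passing)
        log.info("GSEA filters applied: ES > 0, n_genes >= %d, "
                 "p_adj < %g", min_genes, p_adj_max)
        full = gsea.results_to_frame(results)
        full["passes_filters"] = [r in passing for r in results]
        full.to_csv(os.path.join(out_dir, "gsea.tsv"), sep="\t",
                    index=False, float_format="%.12g")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage: {stage}") from exc

    manifest = {
        "tool": "modscreen",
        "version": __version__,
        "seed": seed,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "thresholds": {"maf_min": maf_min, "max_missing": max_missing,
                       "p_cutoff": p_cutoff, "window_bp": window,
                       "n_perm": n_perm, "weight_p": weight_p},
        "counts": counts,
        "digests": {},
    }
    for name in ("assoc.tsv", "assignments.tsv", "candidates.tsv",
                 "gsea.tsv", "qq.tsv"):
        fp = os.path.join(out_dir, name)
        if os.path.exists(fp):
            manifest["digests"][name] = _sha256(fp)
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def report(out_dir: str, p_cutoff: float = 1e-4) -> str:
    """Human-readable summary of a finished run, recounted from files."""
    for name in STAGE_FILES:
        fp = os.path.join(out_dir, name)
        if not os.path.exists(fp):
            raise ValidationError(f"missing stage file: {name}")
    with open(os.path.join(out_dir, "manifest.json")) as fh:
        manifest = json.load(fh)
    assoc = io_formats.read_assoc_results(os.path.join(out_dir, "assoc.tsv"))
    assign = pd.read_csv(os.path.join(out_dir, "assignments.tsv"), sep="\t")
    cands, _ = gene_assignment.candidate_genes(
        assign[["variant_id", "gene_id", "category", "distance_bp"]],
        assoc, p_cutoff=p_cutoff)
    gsea_df = pd.read_csv(os.path.join(out_dir, "gsea.tsv"), sep="\t")
    passing = gsea_df[gsea_df["passes_filters"]]
    lines = [
        "modscreen run summary",
        "=====================",
        f"variants tested: {len(assoc)}",
        f"genomic inflation lambda_GC: {manifest['counts']['lambda_gc']}",
        f"candidate genes (p < {p_cutoff:g}): {len(cands)}",
    ]
    if len(cands):
        lines.append("top candidates (min p ascending):")
        for row in cands.head(10).itertuples(index=False):
            lines.append(f"  {row.gene_id}  n_variants={row.n_variants}  "
                         f"min_p={row.min_p:.3g}")
    else:
        lines.append("no candidate genes below the cutoff")
    lines.append(f"gene sets passing filters: {len(passing)}")
    for row in passing.itertuples(index=False):
        lines.append(f"  {row.set_id}  ES={row.es:.3f}  "
                     f"p_adj={row.p_adjusted:.4g}  n={row.n_genes_present}")
    return "\n".join(lines)
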