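"""End-to-end orchestration: simulate/load -> QC -> EWAS -> DMR -> meQTL ->
genetic adjustment -> permutation tests -> annotation -> report.

A run is driven by a single YAML/TOML-style mapping (see ``run_pipeline``)
and writes every stage's table plus a manifest (config hash, seed, stage
row counts) into a run directory, so a Table-of-models summary can be
reconstructed from the logs alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .adjust import adjust_dmcs
from .annotation import assigned_gene_set, build_gene_features, map_regions_to_genes
from .dmr import call_regions, regions_to_frame, summarize_regions
from .ewas import compute_celltype_pc1, run_ewas
from .filtering import run_qc
from .io import (
    read_covariates,
    read_gene_models,
    read_genotypes,
    read_methylation_counts,
    write_results,
)
from .meqtl import enumerate_cis_pairs, filter_snps, scan_meqtl
from .permutation import permutation_test
from .report import model_summary_row, render_summary
from .simulate import config_from_dict, export_cohort, simulate_cohort
from .types import CELL_TYPES

log = logging.getLogger(__name__)

STAGES = ["simulate", "filter", "ewas", "dmr", "meqtl", "adjust", "permtest",
          "annotate", "report"]


def config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def synthetic_gene_models(mat, span: int = 20_000, step: int = 50_000) -> pd.DataFrame:
    """Deterministic protein-coding gene models tiled over the cohort's
    chromosomes, so annotation can be exercised on simulated data."""
    rows = []
    g = 0
    for chrom in pd.unique(mat.chrom):
        cpos = mat.pos[mat.chrom == chrom]
        start = (int(cpos.min()) // step) * step
        stop = int(cpos.max()) + step
        for x in range(start, stop, step):
            strand = "+" if g % 2 == 0 else "-"
            tss = x if strand == "+" else x + span
            rows.append(
                {
                    "gene_id": f"SYNG{g:05d}",
                    "symbol": f"SYNG{g:05d}",
                    "chrom": chrom,
                    "strand": strand,
                    "tss": tss,
                    "start": x,
                    "end": x + span,
                    "biotype": "protein_coding",
                }
            )
            g += 1
    return pd.DataFrame(rows)


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Execute all stages; returns the manifest (also written to disk).

    Config keys: ``simulate`` (SimulationConfig mapping) or ``inputs``
    (counts/vcf/covariates paths); ``seed``; ``qc`` (min_depth,
    min_samples); ``ewas`` (phenotypes, q_method, q_threshold); ``dmr``
    (max_gap, min_sites); ``meqtl`` (window, maf_min, info_min);
    ``adjust`` (folds, p_threshold); ``permtest`` (n_perm); ``annotate``
    (gene_models path; omit to use tiled synthetic models).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest: dict = {
        "version": __version__,
        "config_hash": config_hash(config),
        "seed": seed,
        "stages": {},
    }
    stage = "setup"
    try:
        # ------------------------------------------------ inputs
        if "simulate" in config:
            stage = "simulate"
            sim_cfg = dict(config["simulate"])
            sim_cfg.setdefault("seed", seed)
            mat, geno, covariates, truth = simulate_cohort(config_from_dict(sim_cfg))
            export_cohort(mat, geno, covariates, truth, out / "cohort",
                          overwrite=True)
            manifest["stages"]["simulate"] = {
                "n_sites": mat.n_sites, "n_samples": mat.n_samples,
                "n_snps": geno.n_snps,
            }
        else:
            inputs = config["inputs"]
            mat = read_methylation_counts(inputs["counts"])
            covariates = read_covariates(inputs["covariates"])
            geno = read_genotypes(inputs["vcf"]) if "vcf" in inputs else None
        if set(covariates["sample_id"]) != set(mat.samples):
            raise ValueError("sample sets of counts and covariates differ")

        # ------------------------------------------------ QC
        stage = "filter"
        qc_cfg = config.get("qc", {})
        filtered, qc_report = run_qc(
            mat,
            min_depth=int(qc_cfg.get("min_depth", 15)),
            min_samples=int(qc_cfg.get("min_samples", min(30, mat.n_samples))),
        )
        qc_report.to_frame().to_csv(out / "filter_report.tsv", sep="\t", index=False)
        manifest["stages"]["filter"] = {
            "n_input": qc_report.n_input, "n_tested": qc_report.n_after_depth,
            "n_filtered_out": qc_report.n_input - qc_report.n_after_depth,
        }

        # ------------------------------------------------ PC1 + EWAS
        stage = "ewas"
        ew = config.get("ewas", {})
        pc1, var_explained = compute_celltype_pc1(
            covariates[list(CELL_TYPES)].to_numpy()
        )
        covariates = covariates.copy()
        covariates["pc1"] = pc1
        manifest["pc1_variance_explained"] = round(var_explained, 4)
        results: dict[str, pd.DataFrame] = {}
        for phenotype in ew.get("phenotypes", ["acpa"]):
            results[phenotype] = run_ewas(
                filtered,
                covariates,
                phenotype=phenotype,
                q_method=ew.get("q_method", "storey"),
                q_threshold=float(ew.get("q_threshold", 0.01)),
            )
            write_results(results[phenotype], out / f"ewas_{phenotype}.tsv")
        primary = ew.get("phenotypes", ["acpa"])[0]
        site_results = results[primary]
        manifest["stages"]["ewas"] = {
            pheno: {
                "n_tested": int(r["estimable"].sum()),
                "n_non_estimable": int((~(r["estimable"] & r["converged"])).sum()),
                "n_dmc": int(r["dmc"].sum()),
            }
            for pheno, r in results.items()
        }

        # ------------------------------------------------ DMR
        stage = "dmr"
        dmr_cfg = config.get("dmr", {})
        regions = {
            pheno: call_regions(
                r, max_gap=int(dmr_cfg.get("max_gap", 200)),
                min_sites=int(dmr_cfg.get("min_sites", 3)),
            )
            for pheno, r in results.items()
        }
        for pheno, regs in regions.items():
            write_results(regions_to_frame(regs), out / f"dmr_{pheno}.tsv")
        manifest["stages"]["dmr"] = {
            pheno: summarize_regions(regs, results[pheno]) | {"largest_region": None,
                                                              "size_counts": None}
            for pheno, regs in regions.items()
        }

        # ------------------------------------------------ meQTL + adjustment
        adjusted = None
        if geno is not None and geno.n_snps > 0:
            stage = "meqtl"
            mq = config.get("meqtl", {})
            clean = filter_snps(
                geno,
                maf_min=float(mq.get("maf_min", 0.05)),
                info_min=float(mq.get("info_min", 0.4)),
            )
            pairs = enumerate_cis_pairs(
                filtered, clean, window=int(mq.get("window", 250_000))
            )
            meqtl_table = scan_meqtl(
                pairs, filtered, clean, covariates,
                q_threshold=float(mq.get("q_threshold", 0.01)),
                q_method=mq.get("q_method", "storey"),
            )
            write_results(meqtl_table, out / "meqtl.tsv")
            manifest["stages"]["meqtl"] = {
                "n_snps_after_qc": clean.n_snps,
                "n_pairs": len(pairs),
                "n_meqtl": int(meqtl_table["is_meqtl"].sum()) if len(meqtl_table) else 0,
            }

            stage = "adjust"
            adj_cfg = config.get("adjust", {})
            adjusted = adjust_dmcs(
                filtered, site_results, meqtl_table, clean, covariates,
                phenotype=primary,
                folds=int(adj_cfg.get("folds", 5)),
                seed=seed,
                p_threshold=float(adj_cfg.get("p_threshold", 3e-5)),
            )
            write_results(adjusted, out / "adjusted.tsv")
            gdmrs = call_regions(adjusted) if len(adjusted) else []
            write_results(regions_to_frame(gdmrs), out / "gdmr.tsv")
            manifest["stages"]["adjust"] = {
                "n_dmc": len(adjusted),
                "n_gdmc": int(adjusted["gdmc"].sum()) if len(adjusted) else 0,
                "n_gdmr": len(gdmrs),
            }

        # ------------------------------------------------ permutation test
        stage = "permtest"
        pt = config.get("permtest", {})
        if len(results) >= 2:
            phenos = list(results)
            a_res, b_res = results[phenos[0]], results[phenos[1]]
            universe = list(zip(filtered.chrom.tolist(),
                                filtered.pos.astype(int).tolist()))
            a = set(zip(a_res.loc[a_res["dmc"], "chrom"],
                        a_res.loc[a_res["dmc"], "pos"].astype(int)))
            b = set(zip(b_res.loc[b_res["dmc"], "chrom"],
                        b_res.loc[b_res["dmc"], "pos"].astype(int)))
            if a and b:
                perm = permutation_test(
                    a, b, universe, statistic="num_overlaps",
                    n_perm=int(pt.get("n_perm", 10_000)), seed=seed,
                )
                manifest["stages"]["permtest"] = {
                    "observed_overlap": perm.observed,
                    "empirical_p": perm.p_value,
                    "n_perm": perm.n_perm,
                }

        # ------------------------------------------------ annotation
        stage = "annotate"
        ann = config.get("annotate", {})
        models = (
            read_gene_models(ann["gene_models"])
            if "gene_models" in ann
            else synthetic_gene_models(filtered)
        )
        features = build_gene_features(models)
        assignments = map_regions_to_genes(regions[primary], features)
        assignments.to_csv(out / "gene_assignments.tsv", sep="\t", index=False)
        manifest["stages"]["annotate"] = {
            "n_regions": len(regions[primary]),
            "n_genic": int((assignments["feature"] != "intergenic")
                           .groupby(assignments["region_idx"]).any().sum()),
            "n_genes": len(assigned_gene_set(assignments)),
        }

        # ------------------------------------------------ report
        stage = "report"
        rows = [
            model_summary_row(pheno, int(r["estimable"].sum()), r, regions[pheno])
            for pheno, r in results.items()
        ]
        (out / "summary.txt").write_text(render_summary(rows) + "\n")
    except Exception as err:  # partial outputs stay on disk for debugging
        manifest["failed_stage"] = stage
        manifest["error"] = str(err)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def make_report(run_dir: str | Path) -> str:
    """Assemble the per-model summary document for a completed run."""
    out = Path(run_dir)
    manifest_path = out / "manifest.json"
    summary_path = out / "summary.txt"
    missing = [p.name for p in (manifest_path, summary_path) if not p.exists()]
    if missing:
        raise FileNotFoundError(f"incomplete run: missing {missing}")
    manifest = json.loads(manifest_path.read_text())
    lines = [
        f"bsewas run (version {manifest['version']}, config {manifest['config_hash']}, "
        f"seed {manifest['seed']})",
        "",
        summary_path.read_text().rstrip(),
        "",
        "stage counts:",
        json.dumps(manifest["stages"], indent=2, default=str),
    ]
    return "\n".join(lines)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
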