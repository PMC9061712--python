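"""End-to-end orchestration: simulate/load -> QC -> QTL scans -> triplets ->
CIT -> Steiger -> colocalization -> report.

A single global seed fans out to per-stage seeds by fixed offsets so each
stage is individually reproducible; every output table carries commented
header metadata (package version, seed, config hash) and the JSON report's
headline counts are re-derived from the stage tables by an internal
consistency audit before it is written.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .cis_qtl import QtlConfig, compute_pcs, genomic_lambda, run_qtl_scan
from .cit_mediation import run_cit, summarize_labels
from .core_data import CovariateMatrix, filter_cpg_near_snp, qc_genotypes
from .multitrait_coloc import (LocusSkipped, MolocConfig, moloc_posterior,
                               moloc_table)
from .steiger_direction import run_steiger, triangulate
from .synthetic_data import (CohortConfig, LocusSpec, simulate_cohort,
                             simulate_gwas_locus, write_cohort)
from .triplet_integration import build_triplets, direction_concordance

logger = logging.getLogger(__name__)

# fixed per-stage seed offsets (single global seed fans out deterministically)
SEED_OFFSETS = {"cohort": 0, "cit": 211, "locus": 977}


@dataclass
class PipelineConfig:
    """Settings for one pipeline run."""

    outdir: str = "qtltriad_out"
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    qtl: QtlConfig = field(default_factory=QtlConfig)
    cit_n_perm: int = 1000
    cit_alpha: float = 0.05
    steiger_alpha: float = 0.05
    steiger_dependent: bool = True
    moloc: MolocConfig = field(default_factory=MolocConfig)
    locus_n_snps: int = 100
    locus_ld_rho: float = 0.5
    n_genotype_pcs: int = 2
    n_phenotype_pcs: int = 2
    write_inputs: bool = False


def validate_config(config: PipelineConfig) -> list[str]:
    """Return a list of problems; empty means runnable."""
    problems = []
    if not 0 < config.cit_alpha < 1:
        problems.append("cit_alpha: must lie in (0, 1)")
    if not 0 < config.steiger_alpha < 1:
        problems.append("steiger_alpha: must lie in (0, 1)")
    if config.cit_n_perm < 10:
        problems.append("cit_n_perm: need at least 10 permutations")
    if config.locus_n_snps < 1:
        problems.append("locus_n_snps: must be positive")
    if not 0 <= config.locus_ld_rho < 1:
        problems.append("locus_ld_rho: must lie in [0, 1)")
    if config.cohort.n_meth_samples < config.cohort.n_expr_samples:
        problems.append("cohort: expression subset larger than methylation cohort")
    if not config.outdir:
        problems.append("outdir: output directory required")
    return problems


def _config_hash(config: PipelineConfig) -> str:
    """Fingerprint of the analysis settings (output location excluded)."""
    fields = dataclasses.asdict(config)
    fields.pop("outdir", None)
    payload = json.dumps(fields, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _write_table(df: pd.DataFrame, path: str, meta: dict) -> None:
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def _locus_spec_from_truth(row, config: PipelineConfig) -> LocusSpec:
    """Dense summary-statistic locus matching one cohort locus's scenario.

    Non-null scenarios share one causal variant across all three traits at
    the index position; trait z-targets reflect the cohort effect sizes and
    sample-size asymmetry (large GWAS cohort, n~291 methylation, n~71
    expression).
    """
    cc = config.cohort
    null = row.scenario == "NULL"
    r2a = cc.var_explained_snp
    r2e = cc.var_explained_snp * cc.var_explained_link
    z_m = float(np.sqrt(r2a / (1 - r2a) * cc.n_meth_samples))
    z_e = float(np.sqrt(r2e / (1 - r2e) * cc.n_expr_samples))
    return LocusSpec(
        n_snps=config.locus_n_snps,
        ld_rho=config.locus_ld_rho,
        causal_index={} if null else {"G": 0, "E": 0, "M": 0},
        z_target={} if null else {"G": cc.gwas_z_target, "E": z_e, "M": z_m},
        n_per_trait={"G": cc.n_gwas, "E": cc.n_expr_samples * 20,
                     "M": cc.n_meth_samples * 10},
        chrom=str(row.chrom),
        seed=config.seed + SEED_OFFSETS["locus"]
        + zlib.crc32(str(row.locus_id).encode()) % 10_000,
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on a simulated cohort and write the report bundle.

    Returns the report dict; tables land in ``config.outdir`` as
    tab-delimited files with commented header metadata.
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    os.makedirs(config.outdir, exist_ok=True)
    meta = {"version": __version__, "seed": config.seed,
            "config_hash": _config_hash(config)}
    log_path = os.path.join(config.outdir, "run.log")
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("qtltriad")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    logger.info("pipeline start: %s", meta)

    try:
        cohort_cfg = dataclasses.replace(
            config.cohort, seed=config.seed + SEED_OFFSETS["cohort"])
        bundle = simulate_cohort(cohort_cfg)
        if config.write_inputs:
            write_cohort(bundle, os.path.join(config.outdir, "inputs"))

        genotypes = qc_genotypes(bundle.genotypes)
        methylation = filter_cpg_near_snp(bundle.methylation, genotypes)

        # covariates: measured covariates + genotype PCs (+ phenotype PCs)
        def covariates_for(pheno, n_pcs, prefix):
            idx = [bundle.covariates.sample_ids.index(s)
                   for s in pheno.sample_ids]
            base = bundle.covariates.table.iloc[idx].reset_index(drop=True)
            base = base.loc[:, base.std() > 0]   # subset may fix a covariate
            parts = [base]
            geno_sub = genotypes.subset_samples(pheno.sample_ids)
            k_g = min(config.n_genotype_pcs,
                      min(geno_sub.dosages.shape) - 1)
            if k_g > 0:
                parts.append(compute_pcs(np.nan_to_num(geno_sub.dosages),
                                         k_g, prefix="genoPC"))
            # phenotype PCs proxy hidden batch structure; with only a
            # handful of features they absorb the signals themselves
            k_p = min(config.n_phenotype_pcs, min(pheno.values.shape) - 1)
            if pheno.n_features < 30:
                k_p = 0
            if k_p > 0:
                parts.append(compute_pcs(pheno.values, k_p, prefix=prefix))
            return CovariateMatrix(pheno.sample_ids,
                                   pd.concat(parts, axis=1))

        cov_m = covariates_for(methylation, config.n_phenotype_pcs, "methPC")
        cov_e = covariates_for(bundle.expression, config.n_phenotype_pcs,
                               "exprPC")

        mqtl = run_qtl_scan(genotypes, methylation, cov_m, config.qtl,
                            kind="methylation")
        eqtl = run_qtl_scan(genotypes, bundle.expression, cov_e, config.qtl,
                            kind="expression")
        _write_table(mqtl, os.path.join(config.outdir, "mqtl.tsv"), meta)
        _write_table(eqtl, os.path.join(config.outdir, "eqtl.tsv"), meta)

        triplets = build_triplets(eqtl, mqtl, config.qtl.fdr_alpha)
        concordance = direction_concordance(triplets)
        _write_table(triplets, os.path.join(config.outdir, "triplets.tsv"),
                     meta)

        cit = run_cit(triplets, genotypes, methylation, bundle.expression,
                      bundle.covariates, n_perm=config.cit_n_perm,
                      seed=config.seed + SEED_OFFSETS["cit"],
                      alpha=config.cit_alpha)
        _write_table(cit, os.path.join(config.outdir, "cit.tsv"), meta)

        steiger, tiers = run_steiger(triplets, genotypes, methylation,
                                     bundle.expression,
                                     alpha=config.steiger_alpha,
                                     dependent=config.steiger_dependent)
        _write_table(steiger, os.path.join(config.outdir, "steiger.tsv"),
                     meta)
        triangulation = (triangulate(cit, steiger)
                         if not cit.empty and not steiger.empty
                         else pd.DataFrame())

        moloc_results, skipped = [], []
        for row in bundle.truth.itertuples(index=False):
            spec = _locus_spec_from_truth(row, config)
            gwas, tables, label = simulate_gwas_locus(spec)
            summaries = {"G": tables["G"], "E": tables["E"], "M": tables["M"]}
            try:
                res = moloc_posterior(summaries, config.moloc,
                                      locus_id=row.locus_id)
            except LocusSkipped as exc:
                skipped.append(str(exc))
                continue
            moloc_results.append(res)
        moloc_df = moloc_table(moloc_results)
        _write_table(moloc_df, os.path.join(config.outdir, "moloc.tsv"), meta)

        report = _build_report(config, meta, eqtl, mqtl, triplets,
                               concordance, cit, steiger, tiers,
                               triangulation, moloc_df, skipped)
        with open(os.path.join(config.outdir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        logger.info("pipeline complete: %s", config.outdir)
        return report
    finally:
        root.removeHandler(handler)
        handler.close()


def _build_report(config, meta, eqtl, mqtl, triplets, concordance, cit,
                  steiger, tiers, triangulation, moloc_df, skipped) -> dict:
    alpha = config.qtl.fdr_alpha
    thr = config.moloc.ppa_threshold
    n_coloc = 0
    if not moloc_df.empty and "PPA_GEM" in moloc_df:
        n_coloc = int((moloc_df["PPA_GEM"] >= thr).sum())
    report = {
        "meta": meta,
        "eqtl": {
            "n_tested": int(len(eqtl)),
            "n_significant": int((eqtl["q"] < alpha).sum()) if len(eqtl) else 0,
            "lambda": genomic_lambda(eqtl["p"].to_numpy()) if len(eqtl) else None,
        },
        "mqtl": {
            "n_tested": int(len(mqtl)),
            "n_significant": int((mqtl["q"] < alpha).sum()) if len(mqtl) else 0,
            "lambda": genomic_lambda(mqtl["p"].to_numpy()) if len(mqtl) else None,
        },
        "triplets": {
            "n_triplets": int(len(triplets)),
            "n_variants": int(triplets["variant_id"].nunique()) if len(triplets) else 0,
            "concordance": {k: (None if isinstance(v, float) and np.isnan(v)
                                else v)
                            for k, v in concordance.items()},
        },
        "cit": {"labels": summarize_labels(cit) if len(cit) else {}},
        "steiger": {"n_pairs": int(len(steiger)), "tiers": tiers},
        "triangulation": {
            "n_consistent": int(triangulation["consistent"].sum())
            if len(triangulation) else 0,
        },
        "coloc": {
            "n_loci": int(len(moloc_df)),
            "n_colocalized": n_coloc,
            "ppa_threshold": thr,
            "skipped": skipped,
        },
    }
    _audit_report(report, eqtl, mqtl, triplets, cit, moloc_df, alpha, thr)
    return report


def _audit_report(report, eqtl, mqtl, triplets, cit, moloc_df, alpha, thr):
    """Recompute headline counts from the stage tables; fail loudly on
    divergence (pure-function contract between tables and report)."""
    assert report["eqtl"]["n_significant"] == (
        0 if eqtl.empty else int((eqtl["q"] < alpha).sum()))
    assert report["mqtl"]["n_significant"] == (
        0 if mqtl.empty else int((mqtl["q"] < alpha).sum()))
    if len(triplets):
        per_snp = triplets.groupby("variant_id").size()
        assert int(per_snp.sum()) == report["triplets"]["n_triplets"]
    if len(cit):
        assert sum(report["cit"]["labels"].values()) <= len(cit)
    if len(moloc_df) and "PPA_GEM" in moloc_df:
        assert report["coloc"]["n_colocalized"] == int(
            (moloc_df["PPA_GEM"] >= thr).sum())
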