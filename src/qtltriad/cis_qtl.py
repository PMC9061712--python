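"""cis-eQTL / cis-mQTL mapping by additive-model linear regression.

For every (SNP, feature) pair within the cis window (default 1 Mb from the
gene TSS or CpG coordinate, boundary inclusive) the phenotype is regressed
on allele dosage plus covariates (sex, ancestry indicators, genotype PCs,
phenotype PCs, ...). Multiple testing is controlled per scan by
Benjamini-Hochberg FDR over all tested pairs of one kind, and test
calibration can be summarized with the genomic inflation factor lambda.

Incomplete sample rows are dropped pairwise per association; dosages enter
as-is (imputed-dosage convention, no rounding).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._regression import add_intercept, ols_fit
from .core_data import CovariateMatrix, GenotypeMatrix, PhenotypeMatrix

logger = logging.getLogger(__name__)

CHI2_1_NULL_MEDIAN = float(stats.chi2.isf(0.5, 1))

ASSOC_COLUMNS = [
    "variant_id", "feature_id", "kind", "beta", "se", "t_stat", "p", "q",
    "n_used", "distance_bp",
]


@dataclass(frozen=True)
class QtlConfig:
    """Scan settings; defaults follow common cis-QTL practice."""

    cis_window_bp: int = 1_000_000
    fdr_alpha: float = 0.05
    n_genotype_pcs: int = 10
    n_phenotype_pcs: int = 3
    methylation_scale: str = "beta"     # 'beta' or 'mvalue'

    def __post_init__(self) -> None:
        if self.cis_window_bp <= 0:
            raise ValueError("cis window must be positive")
        if not 0 < self.fdr_alpha < 1:
            raise ValueError("fdr_alpha must lie in (0, 1)")
        if self.methylation_scale not in ("beta", "mvalue"):
            raise ValueError("methylation_scale must be 'beta' or 'mvalue'")


def beta_to_mvalue(beta: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """log2(beta/(1-beta)) with clipping away from 0 and 1."""
    b = np.clip(beta, eps, 1 - eps)
    return np.log2(b / (1 - b))


def pair_cis(variants: pd.DataFrame, features: pd.DataFrame,
             window_bp: int = 1_000_000) -> pd.DataFrame:
    """Candidate (variant, feature) pairs on the same chromosome within the
    window (inclusive). Gene anchor is the strand-aware TSS; CpG anchor is
    its coordinate. Returns columns variant_id, feature_id, distance_bp
    where distance = SNP pos - anchor pos (signed)."""
    feats = features.copy()
    bad = feats["anchor_pos"].isna() | feats["chrom"].isna()
    if bad.any():
        warnings.warn(f"{int(bad.sum())} features lack annotation; excluded",
                      stacklevel=2)
        feats = feats.loc[~bad]
    out = []
    for chrom, vsub in variants.groupby("chrom"):
        fsub = feats[feats["chrom"].astype(str) == str(chrom)]
        if fsub.empty:
            continue
        vp = vsub["pos"].to_numpy(int)[:, None]
        fp = fsub["anchor_pos"].to_numpy(int)[None, :]
        dist = vp - fp
        i, j = np.nonzero(np.abs(dist) <= window_bp)
        out.append(pd.DataFrame({
            "variant_id": vsub["variant_id"].to_numpy()[i],
            "feature_id": fsub["feature_id"].to_numpy()[j],
            "distance_bp": dist[i, j],
        }))
    if not out:
        return pd.DataFrame(columns=["variant_id", "feature_id", "distance_bp"])
    return pd.concat(out, ignore_index=True)


def gene_tss(features: pd.DataFrame) -> pd.DataFrame:
    """Anchor expression features at the strand-aware TSS when both start
    and end columns are present (start for '+', end for '-')."""
    feats = features.copy()
    if {"start", "end"}.issubset(feats.columns):
        minus = feats["strand"] == "-"
        feats["anchor_pos"] = np.where(minus, feats["end"], feats["start"])
    return feats


def compute_pcs(matrix: np.ndarray, k: int, prefix: str = "PC") -> pd.DataFrame:
    """Top-k principal components of samples x features data.

    Columns are standardized (constant columns dropped), PCs are the top
    left singular vectors, and each PC's sign is fixed by making its
    largest-magnitude loading positive.
    """
    X = np.asarray(matrix, dtype=float)
    sd = X.std(axis=0)
    X = X[:, sd > 0]
    if k >= min(X.shape):
        raise ValueError("k must be smaller than both matrix dimensions")
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    pcs = U[:, :k] * s[:k]
    for j in range(k):
        i_max = np.argmax(np.abs(Vt[j]))
        if Vt[j, i_max] < 0:
            pcs[:, j] = -pcs[:, j]
    return pd.DataFrame(pcs, columns=[f"{prefix}{j + 1}" for j in range(k)])


def fit_qtl(g: np.ndarray, y: np.ndarray, C: np.ndarray | None = None) -> dict:
    """Single-pair additive-model fit: OLS of y on [1, g, covariates].

    Returns the dosage coefficient with its standard error, t statistic and
    two-sided p from the t distribution on the residual df. Incomplete rows
    are dropped; constant dosage or a rank-deficient design is flagged
    ``untestable`` rather than silently reported.
    """
    g = np.asarray(g, dtype=float)
    y = np.asarray(y, dtype=float)
    C_arr = None if C is None else np.asarray(C, dtype=float)
    if C_arr is not None and C_arr.ndim == 1:
        C_arr = C_arr[:, None]
    ok = ~(np.isnan(g) | np.isnan(y))
    if C_arr is not None:
        ok &= ~np.isnan(C_arr).any(axis=1)
    g, y = g[ok], y[ok]
    C_used = None if C_arr is None else C_arr[ok]
    n_cov = 0 if C_used is None else C_used.shape[1]
    n_used = int(ok.sum())
    out = {"beta": np.nan, "se": np.nan, "t_stat": np.nan, "p": np.nan,
           "n_used": n_used, "untestable": True}
    if n_used < n_cov + 3 or np.ptp(g) == 0:
        return out
    X = add_intercept(np.column_stack([g] + ([C_used] if C_used is not None else [])),
                      n_used)
    fit = ols_fit(y, X)
    if not fit.ok:
        return out
    out.update(beta=float(fit.beta[1]), se=float(fit.se[1]),
               t_stat=float(fit.t_stat[1]), p=float(fit.p[1]), untestable=False)
    return out


def bh_fdr(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def run_qtl_scan(genotypes: GenotypeMatrix, phenotypes: PhenotypeMatrix,
                 covariates: CovariateMatrix | None = None,
                 config: QtlConfig = QtlConfig(),
                 kind: str | None = None,
                 pairs: pd.DataFrame | None = None) -> pd.DataFrame:
    """Scan all cis pairs of one kind and BH-adjust jointly within the scan.

    ``kind`` restricts features to 'expression' (eQTL) or 'methylation'
    (mQTL); with None the feature table must already be homogeneous.
    ``pairs`` can restrict the scan to a pre-specified pair list (used by
    the replication mode).
    """
    feats = phenotypes.features
    if kind is not None:
        keep = (feats["kind"] == kind).to_numpy()
        phenotypes = phenotypes.subset_features(keep)
        feats = phenotypes.features
    kinds = set(feats["kind"])
    label = {"expression": "eQTL", "methylation": "mQTL"}.get(
        next(iter(kinds)) if len(kinds) == 1 else "", "QTL")

    shared = [s for s in phenotypes.sample_ids if s in set(genotypes.sample_ids)]
    if len(shared) < 10:
        raise ValueError("fewer than 10 samples shared between genotypes and phenotypes")
    geno = genotypes.subset_samples(shared)
    pheno = phenotypes.subset_samples(shared)
    C = None
    if covariates is not None:
        C = covariates.subset_samples(shared).as_array()

    values = pheno.values
    if pheno.beta_scale and label == "mQTL" and config.methylation_scale == "mvalue":
        values = beta_to_mvalue(values)

    if pairs is None:
        pairs = pair_cis(geno.variants, pheno.features, config.cis_window_bp)
    if pairs.empty:
        warnings.warn("no candidate cis pairs to test", stacklevel=2)
        return pd.DataFrame(columns=ASSOC_COLUMNS)

    v_idx = {v: j for j, v in enumerate(geno.variants["variant_id"])}
    f_idx = {f: j for j, f in enumerate(pheno.features["feature_id"])}
    rows = []
    for rec in pairs.itertuples(index=False):
        jv, jf = v_idx.get(rec.variant_id), f_idx.get(rec.feature_id)
        if jv is None or jf is None:
            continue
        res = fit_qtl(geno.dosages[:, jv], values[:, jf], C)
        if res.pop("untestable"):
            continue
        res.update(variant_id=rec.variant_id, feature_id=rec.feature_id,
                   kind=label,
                   distance_bp=int(getattr(rec, "distance_bp", 0)))
        rows.append(res)
    if not rows:
        warnings.warn("no testable cis pairs", stacklevel=2)
        return pd.DataFrame(columns=ASSOC_COLUMNS)
    table = pd.DataFrame(rows)
    table["q"] = bh_fdr(table["p"].to_numpy())
    table = table.sort_values(["q", "p"], kind="stable").reset_index(drop=True)
    logger.info("%s scan: %d pairs tested, %d significant at FDR %.3g",
                label, len(table), int((table["q"] < config.fdr_alpha).sum()),
                config.fdr_alpha)
    return table[ASSOC_COLUMNS]


def genomic_lambda(pvals: np.ndarray) -> float:
    """Genomic inflation factor: median 1-df chi-square implied by the
    p-values divided by the null median (~0.4549)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("genomic_lambda needs at least one p-value")
    chi2 = stats.chi2.isf(p, 1)
    return float(np.median(chi2) / CHI2_1_NULL_MEDIAN)
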