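"""Synthetic genotype/phenotype/summary-statistic generators.

The study design this package targets — a multi-ancestry placental cohort
with ~291 methylation samples, a ~71-sample expression subset, birthweight
GWAS summary statistics from a much larger cohort, and loci of tens to
hundreds of SNPs in LD around an index variant — relies on controlled-access
data. These generators emulate that statistical structure so every pipeline
stage can be exercised and calibrated end to end, with ground-truth causal
labels carried alongside the data.

Causal scenarios for a (SNP, methylation, expression) triplet:

``SME``          g -> m -> e      (methylation mediates)
``SEM``          g -> e -> m      (expression mediates)
``INDEPENDENT``  g -> m, g -> e   (independent pathways, no m-e link)
``NULL``         no genetic effect at all

Genotypes are standardized inside the generators so the effect sizes ``a``,
``b``, ``c`` are on an SD scale and comparable across allele frequencies.
All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import (
    CovariateMatrix,
    GenotypeMatrix,
    GwasSummary,
    PhenotypeMatrix,
    VARIANT_COLUMNS,
)

SCENARIOS = ("SME", "SEM", "INDEPENDENT", "NULL")


@dataclass(frozen=True)
class ScenarioSpec:
    """One causal-triplet simulation scenario."""

    scenario: str
    n_samples: int = 291
    maf: float = 0.3
    a: float = 0.8             # SNP -> first node, per SD of genotype
    b: float = 0.65            # first node -> second node, per SD
    c: float = 0.0             # SNP -> second node direct (INDEPENDENT only)
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if not 0 < self.maf < 0.5:
            raise ValueError("maf must lie in (0, 0.5)")
        if self.n_samples < 10:
            raise ValueError("need at least 10 samples")


@dataclass(frozen=True)
class LocusSpec:
    """A cis locus: correlated SNPs plus per-trait causal assignments.

    ``causal_index`` maps trait name to the index of its causal SNP (-1 for
    no causal variant); ``z_target`` maps trait name to the expected
    association z-score at the causal SNP; ``n_per_trait`` the per-trait
    sample size used to generate the summary statistics.
    """

    n_snps: int = 100
    ld_rho: float = 0.5
    maf_range: tuple[float, float] = (0.05, 0.5)
    causal_index: dict = field(default_factory=dict)
    z_target: dict = field(default_factory=dict)
    n_per_trait: dict = field(default_factory=dict)
    chrom: str = "1"
    start_pos: int = 1_000_000
    spacing_bp: int = 1_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if not 0 <= self.ld_rho < 1:
            raise ValueError("ld_rho must lie in [0, 1)")
        for t, j in self.causal_index.items():
            if j >= self.n_snps:
                raise ValueError(f"causal index {j} for {t} out of range")


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def simulate_genotypes(n: int, spec: LocusSpec,
                       rng: np.random.Generator | None = None,
                       sample_prefix: str = "S") -> GenotypeMatrix:
    """Draw an n x n_snps dosage matrix with AR(1)-decaying LD.

    Each haplotype is a latent AR(1) Gaussian vector across SNPs, thresholded
    at the per-SNP allele-frequency quantile. Marginally each genotype is
    Binomial(2, maf) — i.e. in Hardy-Weinberg equilibrium — while adjacent
    SNPs correlate through the latent process with decay rate ``ld_rho``.
    """
    rng = rng or np.random.default_rng(spec.seed)
    lo, hi = spec.maf_range
    mafs = rng.uniform(lo, hi, size=spec.n_snps)
    thresholds = stats.norm.ppf(mafs)

    def haplotypes() -> np.ndarray:
        z = np.empty((n, spec.n_snps))
        z[:, 0] = rng.standard_normal(n)
        if spec.n_snps > 1:
            innov = rng.standard_normal((n, spec.n_snps - 1))
            w = np.sqrt(1.0 - spec.ld_rho**2)
            for j in range(1, spec.n_snps):
                z[:, j] = spec.ld_rho * z[:, j - 1] + w * innov[:, j - 1]
        return (z < thresholds).astype(float)

    dosages = haplotypes() + haplotypes()
    positions = spec.start_pos + spec.spacing_bp * np.arange(spec.n_snps)
    variants = pd.DataFrame({
        "variant_id": [f"snp_{spec.chrom}_{p}" for p in positions],
        "chrom": spec.chrom,
        "pos": positions,
        "ref": "A",
        "alt": "G",
        "maf": np.nan,
    })[VARIANT_COLUMNS]
    sample_ids = [f"{sample_prefix}{i:04d}" for i in range(n)]
    return GenotypeMatrix(sample_ids, variants, dosages)


def simulate_triplet(spec: ScenarioSpec,
                     rng: np.random.Generator | None = None
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate (g, m, e) under one causal scenario.

    Returns raw 0/1/2 dosages g and phenotype vectors m (methylation) and e
    (expression); effects act on the standardized genotype.
    """
    rng = rng or np.random.default_rng(spec.seed)
    n = spec.n_samples
    g = rng.binomial(2, spec.maf, size=n).astype(float)
    gs = _standardize(g)
    e1 = rng.normal(0.0, spec.noise_sd, size=n)
    e2 = rng.normal(0.0, spec.noise_sd, size=n)
    if spec.scenario == "SME":
        m = spec.a * gs + e1
        e = spec.b * m + e2
    elif spec.scenario == "SEM":
        e = spec.a * gs + e1
        m = spec.b * e + e2
    elif spec.scenario == "INDEPENDENT":
        m = spec.a * gs + e1
        e = spec.c * gs + e2
    else:  # NULL
        m = e1
        e = e2
    return g, m, e


def _marginal_scan(y: np.ndarray, dosages: np.ndarray) -> pd.DataFrame:
    """Per-SNP simple regression summary statistics (vectorized OLS)."""
    n, p = dosages.shape
    gc = dosages - dosages.mean(axis=0)
    yc = y - y.mean()
    sxx = (gc**2).sum(axis=0)
    sxx = np.where(sxx == 0, np.nan, sxx)
    beta = gc.T @ yc / sxx
    rss = (yc**2).sum() - beta**2 * sxx
    sigma2 = rss / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    t = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(t), n - 2)
    return pd.DataFrame({"beta": beta, "se": se, "z": t, "p": pvals, "n": n})


def simulate_gwas_locus(spec: LocusSpec,
                        traits: tuple[str, ...] = ("G", "E", "M")
                        ) -> tuple[GwasSummary, dict[str, pd.DataFrame], str]:
    """Generate per-trait summary statistics for one locus.

    Each trait's statistics come from marginally regressing a freshly
    simulated phenotype on every SNP in an independent sample of the stated
    size. Returns the GWAS-style summary for trait "G", a per-trait summary
    table dict, and the generating configuration label (e.g. "GEM" for one
    shared causal variant, "G,EM" for a distinct GWAS variant, "null").
    """
    rng = np.random.default_rng(spec.seed)
    tables: dict[str, pd.DataFrame] = {}
    eaf_by_trait: dict[str, np.ndarray] = {}
    for trait in traits:
        n = int(spec.n_per_trait.get(trait, 50_000))
        g = simulate_genotypes(n, spec, rng=rng)
        j = spec.causal_index.get(trait, -1)
        z = spec.z_target.get(trait, 0.0)
        y = rng.standard_normal(n)
        if j >= 0 and z != 0.0:
            y = y + (z / np.sqrt(n)) * _standardize(g.dosages[:, j])
        tab = _marginal_scan(y, g.dosages)
        tab.insert(0, "variant_id", g.variants["variant_id"].to_numpy())
        tab["eaf"] = g.dosages.mean(axis=0) / 2.0
        tables[trait] = tab
        eaf_by_trait[trait] = tab["eaf"].to_numpy()

    base = tables[traits[0]]
    positions = spec.start_pos + spec.spacing_bp * np.arange(spec.n_snps)
    gwas = GwasSummary(pd.DataFrame({
        "variant_id": base["variant_id"],
        "chrom": spec.chrom,
        "pos": positions,
        "effect_allele": "G",
        "other_allele": "A",
        "eaf": base["eaf"],
        "beta": base["beta"],
        "se": base["se"],
        "p": base["p"].clip(lower=1e-320),
        "n": base["n"],
    }))
    label = _config_label(spec, traits)
    return gwas, tables, label


def _config_label(spec: LocusSpec, traits: tuple[str, ...]) -> str:
    active = {t: j for t, j in spec.causal_index.items()
              if t in traits and j >= 0 and spec.z_target.get(t, 0.0) != 0.0}
    if not active:
        return "null"
    groups: dict[int, list[str]] = {}
    for t in traits:
        if t in active:
            groups.setdefault(active[t], []).append(t)
    return ",".join("".join(members) for _, members in sorted(groups.items()))


# ---------------------------------------------------------------------------
# Cohort bundle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortConfig:
    """A miniature multi-locus cohort mirroring the methylation/expression
    sample-size asymmetry (n~291 with genotype+methylation, a ~71 subset with
    expression) and a large-cohort GWAS trait."""

    n_loci: int = 5
    scenario_mix: tuple[str, ...] = ("SME",)
    n_meth_samples: int = 291
    n_expr_samples: int = 71
    snps_per_locus: int = 5
    cpgs_per_locus: int = 3
    genes_per_locus: int = 1
    ld_rho: float = 0.6
    var_explained_snp: float = 0.4     # causal SNP -> first node r^2
    var_explained_link: float = 0.3    # first node -> second node r^2
    maf_range: tuple[float, float] = (0.1, 0.5)
    fst: float = 0.05                  # ancestry-group allele-frequency spread
    ancestry_fractions: tuple[float, ...] = (0.33, 0.26, 0.24, 0.17)
    n_gwas: int = 50_000
    gwas_z_target: float = 8.0
    seed: int = 0


@dataclass
class CohortBundle:
    genotypes: GenotypeMatrix
    methylation: PhenotypeMatrix
    expression: PhenotypeMatrix
    covariates: CovariateMatrix
    gwas: GwasSummary
    truth: pd.DataFrame               # one row per locus with scenario labels


def _effect_from_r2(r2: float) -> float:
    """Per-SD effect giving r^2 variance explained against unit noise."""
    if not 0 <= r2 < 1:
        raise ValueError("variance explained must lie in [0, 1)")
    return np.sqrt(r2 / (1.0 - r2))


def simulate_cohort(config: CohortConfig) -> CohortBundle:
    """Generate a deterministic multi-locus cohort with ground-truth labels.

    Each locus carries one index SNP (first SNP of an LD block) that, under
    its scenario, drives one causal CpG and one gene; remaining CpGs/genes at
    the locus are noise. Ancestry-group allele frequencies are differentiated
    (Balding-Nichols, Fst-like spread) and sex plus ancestry indicators are
    returned as covariates so confounding adjustment is exercised.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_meth_samples
    fracs = np.asarray(config.ancestry_fractions, dtype=float)
    fracs = fracs / fracs.sum()
    counts = np.floor(fracs * n).astype(int)
    counts[0] += n - counts.sum()
    ancestry = rng.permutation(np.repeat(np.arange(len(counts)), counts))
    sex = rng.integers(0, 2, size=n).astype(float)
    sample_ids = [f"P{i:04d}" for i in range(n)]

    a_eff = _effect_from_r2(config.var_explained_snp)
    b_eff = _effect_from_r2(config.var_explained_link)

    all_variants, all_dosages = [], []
    feat_rows_m, vals_m = [], []
    feat_rows_e, vals_e = [], []
    truth_rows = []
    gwas_rows = []

    for locus in range(config.n_loci):
        scenario = config.scenario_mix[locus % len(config.scenario_mix)]
        chrom = str(locus + 1)
        start = 10_000_000
        base_maf = rng.uniform(*config.maf_range, size=config.snps_per_locus)
        # Balding-Nichols differentiation of allele frequency per ancestry
        theta = config.fst
        if theta > 0:
            shape1 = base_maf * (1 - theta) / theta
            shape2 = (1 - base_maf) * (1 - theta) / theta
            group_maf = rng.beta(shape1, shape2,
                                 size=(len(counts), config.snps_per_locus))
            group_maf = np.clip(group_maf, 0.01, 0.99)
        else:
            group_maf = np.tile(base_maf, (len(counts), 1))

        # AR(1) latent haplotypes, threshold per individual's ancestry group
        thr = stats.norm.ppf(group_maf)[ancestry]  # n x snps

        def haplo() -> np.ndarray:
            z = np.empty((n, config.snps_per_locus))
            z[:, 0] = rng.standard_normal(n)
            w = np.sqrt(1 - config.ld_rho**2)
            for j in range(1, config.snps_per_locus):
                z[:, j] = config.ld_rho * z[:, j - 1] + w * rng.standard_normal(n)
            return (z < thr).astype(float)

        dos = haplo() + haplo()
        positions = start + 1_000 * np.arange(config.snps_per_locus)
        vids = [f"rs{locus}_{j}" for j in range(config.snps_per_locus)]
        all_variants.append(pd.DataFrame({
            "variant_id": vids, "chrom": chrom, "pos": positions,
            "ref": "A", "alt": "G", "maf": np.nan,
        }))
        all_dosages.append(dos)

        g_index = dos[:, 0]
        gs = _standardize(g_index)
        # mild ancestry shift on molecular traits so covariates matter
        anc_shift = 0.3 * (ancestry - ancestry.mean())

        for k in range(config.cpgs_per_locus):
            causal = k == 0 and scenario in ("SME", "INDEPENDENT")
            noise = rng.standard_normal(n)
            if scenario == "SME" and k == 0:
                m = a_eff * gs + noise
            elif scenario == "INDEPENDENT" and k == 0:
                m = a_eff * gs + noise
            elif scenario == "SEM" and k == 0:
                m = None  # filled after expression below
            else:
                m = noise
            feat_rows_m.append({
                "feature_id": f"cg{locus:02d}_{k}", "chrom": chrom,
                "anchor_pos": start + 200 + 37 * k, "strand": "+",
                "kind": "methylation",
            })
            vals_m.append((m, noise, causal))

        for k in range(config.genes_per_locus):
            noise = rng.standard_normal(n)
            if k == 0 and scenario == "SME":
                m0 = vals_m[-config.cpgs_per_locus][0]
                e = b_eff * _standardize(m0) + noise
            elif k == 0 and scenario == "SEM":
                e = a_eff * gs + noise
            elif k == 0 and scenario == "INDEPENDENT":
                e = a_eff * gs + noise
            else:
                e = noise
            feat_rows_e.append({
                "feature_id": f"gene{locus:02d}_{k}", "chrom": chrom,
                "anchor_pos": start + 500 + 911 * k, "strand": "+",
                "kind": "expression",
            })
            vals_e.append(e + anc_shift)

        # SEM: causal CpG responds to the causal gene's expression
        if scenario == "SEM":
            e0 = vals_e[-config.genes_per_locus]
            i0 = len(vals_m) - config.cpgs_per_locus
            noise = rng.standard_normal(n)
            vals_m[i0] = (b_eff * _standardize(e0 - anc_shift) + noise,
                          noise, True)

        truth_rows.append({
            "locus_id": f"locus{locus:02d}", "chrom": chrom,
            "scenario": scenario, "index_snp": vids[0],
            "causal_cpg": f"cg{locus:02d}_0", "causal_gene": f"gene{locus:02d}_0",
            "a_effect": 0.0 if scenario == "NULL" else a_eff,
            "b_effect": b_eff if scenario in ("SME", "SEM") else 0.0,
        })

        # GWAS trait: birthweight-like, causal at the index SNP except NULL
        n_g = config.n_gwas
        maf_g = float(np.clip(base_maf[0], 0.05, 0.95))
        g_gwas = rng.binomial(2, maf_g, size=n_g).astype(float)
        y_g = rng.standard_normal(n_g)
        if scenario != "NULL":
            y_g = y_g + (config.gwas_z_target / np.sqrt(n_g)) * _standardize(g_gwas)
        scan = _marginal_scan(y_g, g_gwas[:, None])
        gwas_rows.append({
            "variant_id": vids[0], "chrom": chrom, "pos": int(positions[0]),
            "effect_allele": "G", "other_allele": "A",
            "eaf": g_gwas.mean() / 2.0,
            "beta": float(scan["beta"][0]), "se": float(scan["se"][0]),
            "p": float(max(scan["p"][0], 1e-320)), "n": n_g,
        })

    meth_values = np.column_stack([
        (m if m is not None else noise) + 0.3 * (ancestry - ancestry.mean())
        for (m, noise, _) in vals_m
    ])
    expr_values = np.column_stack(vals_e)

    genotypes = GenotypeMatrix(
        sample_ids,
        pd.concat(all_variants, ignore_index=True),
        np.hstack(all_dosages),
    )
    methylation = PhenotypeMatrix(sample_ids, pd.DataFrame(feat_rows_m), meth_values)
    expression_full = PhenotypeMatrix(sample_ids, pd.DataFrame(feat_rows_e), expr_values)
    # expression measured on a subset of the methylation samples
    expr_ids = sample_ids[: config.n_expr_samples]
    expression = expression_full.subset_samples(expr_ids)

    anc_dummies = pd.get_dummies(pd.Series(ancestry, name="ancestry"),
                                 prefix="anc", drop_first=True).astype(float)
    cov = pd.concat([pd.Series(sex, name="sex"), anc_dummies], axis=1)
    covariates = CovariateMatrix(sample_ids, cov)

    gwas = GwasSummary(pd.DataFrame(gwas_rows))
    truth = pd.DataFrame(truth_rows)
    return CohortBundle(genotypes, methylation, expression, covariates, gwas, truth)


def write_cohort(bundle: CohortBundle, outdir: str) -> dict[str, str]:
    """Write the cohort bundle to tab-delimited files plus a truth manifest."""
    import os

    from . import core_data as cd

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "genotypes": os.path.join(outdir, "genotypes.vcf"),
        "methylation": os.path.join(outdir, "methylation.tsv"),
        "methylation_features": os.path.join(outdir, "methylation_features.tsv"),
        "expression": os.path.join(outdir, "expression.tsv"),
        "expression_features": os.path.join(outdir, "expression_features.tsv"),
        "covariates": os.path.join(outdir, "covariates.tsv"),
        "gwas": os.path.join(outdir, "gwas.tsv"),
        "truth": os.path.join(outdir, "truth.tsv"),
    }
    cd.write_genotypes(bundle.genotypes, paths["genotypes"])
    cd.write_phenotypes(bundle.methylation, paths["methylation"],
                        paths["methylation_features"])
    cd.write_phenotypes(bundle.expression, paths["expression"],
                        paths["expression_features"])
    cd.write_covariates(bundle.covariates, paths["covariates"])
    cd.write_gwas(bundle.gwas, paths["gwas"])
    bundle.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
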