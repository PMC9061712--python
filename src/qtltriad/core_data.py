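"""Core containers, file formats, and genotype/CpG quality-control filters.

The pipeline works on four in-memory objects:

``GenotypeMatrix``
    samples x variants allele-dosage matrix (values in [0, 2], NaN = missing)
    plus a variant table (chrom, 1-based pos, ref, alt, maf).
``PhenotypeMatrix``
    samples x features molecular phenotypes (expression or methylation) with a
    per-feature genomic anchor (gene TSS or CpG coordinate) for cis pairing.
``CovariateMatrix``
    samples x numeric covariates (categoricals pre-encoded as indicators).
``GwasSummary``
    per-variant GWAS summary statistics (beta, se, p, eaf, n).

Coordinates are 1-based inclusive throughout (VCF convention); chromosome
names are normalized by stripping a leading ``chr``. Distance filters are
inclusive at the boundary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

VARIANT_COLUMNS = ["variant_id", "chrom", "pos", "ref", "alt", "maf"]
FEATURE_COLUMNS = ["feature_id", "chrom", "anchor_pos", "strand", "kind"]
GWAS_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "p", "n",
]


def normalize_chrom(chrom) -> str:
    """Strip a leading 'chr' prefix so builds with either style interoperate."""
    s = str(chrom)
    return s[3:] if s.lower().startswith("chr") else s


def _compute_maf(dosages: np.ndarray) -> np.ndarray:
    """Minor allele frequency per variant column from non-missing dosages."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        alt_freq = np.nanmean(dosages, axis=0) / 2.0
    return np.fmin(alt_freq, 1.0 - alt_freq)


@dataclass
class GenotypeMatrix:
    """Allele dosages for samples x variants with per-variant metadata."""

    sample_ids: list[str]
    variants: pd.DataFrame          # columns VARIANT_COLUMNS
    dosages: np.ndarray             # float, NaN for missing

    def __post_init__(self) -> None:
        self.variants = self.variants.reset_index(drop=True)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        finite = self.dosages[~np.isnan(self.dosages)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValueError("dosages must lie in [0, 2] or be missing")
        if "maf" not in self.variants.columns or self.variants["maf"].isna().all():
            self.variants["maf"] = _compute_maf(self.dosages)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def subset_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            variants=self.variants.loc[mask].reset_index(drop=True),
            dosages=self.dosages[:, mask],
        )

    def subset_samples(self, sample_ids: list[str]) -> "GenotypeMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return GenotypeMatrix(
            sample_ids=list(sample_ids),
            variants=self.variants.copy(),
            dosages=self.dosages[idx, :],
        )

    def dosage_vector(self, variant_id: str) -> np.ndarray:
        j = self.variants.index[self.variants["variant_id"] == variant_id]
        if len(j) == 0:
            raise KeyError(f"variant {variant_id!r} not present")
        return self.dosages[:, j[0]]


@dataclass
class PhenotypeMatrix:
    """Molecular phenotype values for samples x features with genomic anchors.

    ``kind`` is 'expression' (anchor = strand-aware TSS) or 'methylation'
    (anchor = CpG coordinate). ``beta_scale`` declares methylation values as
    beta fractions in [0, 1]; M-value-like data leave it False.
    """

    sample_ids: list[str]
    features: pd.DataFrame          # columns FEATURE_COLUMNS
    values: np.ndarray
    beta_scale: bool = False

    def __post_init__(self) -> None:
        self.features = self.features.reset_index(drop=True)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.features)):
            raise ValueError("value shape does not match samples x features")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("phenotype values must be finite")
        if (self.features["anchor_pos"] <= 0).any():
            raise ValueError("anchor_pos must be positive (1-based)")
        if self.beta_scale:
            if self.values.min() < 0 or self.values.max() > 1:
                raise ValueError("beta-scale methylation must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.features)

    def subset_features(self, mask: np.ndarray) -> "PhenotypeMatrix":
        mask = np.asarray(mask)
        return PhenotypeMatrix(
            sample_ids=list(self.sample_ids),
            features=self.features.loc[mask].reset_index(drop=True),
            values=self.values[:, mask],
            beta_scale=self.beta_scale,
        )

    def subset_samples(self, sample_ids: list[str]) -> "PhenotypeMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return PhenotypeMatrix(
            sample_ids=list(sample_ids),
            features=self.features.copy(),
            values=self.values[idx, :],
            beta_scale=self.beta_scale,
        )

    def feature_vector(self, feature_id: str) -> np.ndarray:
        j = self.features.index[self.features["feature_id"] == feature_id]
        if len(j) == 0:
            raise KeyError(f"feature {feature_id!r} not present")
        return self.values[:, j[0]]


@dataclass
class CovariateMatrix:
    """Numeric covariates per sample; categoricals arrive pre-encoded."""

    sample_ids: list[str]
    table: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.table) != len(self.sample_ids):
            raise ValueError("covariate rows must match sample_ids")
        if self.table.isna().any().any():
            raise ValueError("covariates must not contain missing values")
        X = np.column_stack([np.ones(len(self.table)), self.table.to_numpy(float)])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("covariates rank-deficient after adding intercept")

    def as_array(self) -> np.ndarray:
        return self.table.to_numpy(dtype=float)

    def subset_samples(self, sample_ids: list[str]) -> "CovariateMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CovariateMatrix(list(sample_ids), self.table.iloc[idx].reset_index(drop=True))


@dataclass
class GwasSummary:
    """GWAS summary statistics, one row per variant."""

    table: pd.DataFrame             # columns GWAS_COLUMNS

    def __post_init__(self) -> None:
        missing = [c for c in GWAS_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"GWAS summary missing columns: {missing}")
        self.table = self.table.reset_index(drop=True)
        if (self.table["se"] <= 0).any():
            raise ValueError("all standard errors must be positive")
        self._check_p_consistency()

    def _check_p_consistency(self) -> None:
        # |z| implied by p should match beta/se within 10% relative tolerance
        t = self.table
        ok = (t["p"] > 1e-300) & (t["p"] < 1)
        if not ok.any():
            return
        z_from_p = stats.norm.isf(t.loc[ok, "p"] / 2.0)
        z = (t.loc[ok, "beta"] / t.loc[ok, "se"]).abs()
        testable = z_from_p > 0.5
        if testable.any():
            rel = np.abs(z[testable] - z_from_p[testable]) / z_from_p[testable]
            n_bad = int((rel > 0.10).sum())
            if n_bad:
                warnings.warn(
                    f"{n_bad} GWAS rows have |beta/se| inconsistent with p "
                    "beyond 10% relative tolerance",
                    stacklevel=3,
                )


# ---------------------------------------------------------------------------
# VCF input/output
# ---------------------------------------------------------------------------

def _parse_region(region: str) -> tuple[str, int, int]:
    chrom, _, span = region.partition(":")
    if span:
        start_s, _, end_s = span.partition("-")
        return normalize_chrom(chrom), int(start_s), int(end_s)
    return normalize_chrom(chrom), 1, 2**62


def read_genotypes(path: str, region: str | None = None) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Dosages come from the ``DS`` FORMAT field when present, else from hard
    ``GT`` calls coded 0/1/2. Multi-allelic records and indels are skipped
    with a logged warning; missing genotypes become NaN dosages.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    want = _parse_region(region) if region else None

    rows, columns = [], []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_skipped += 1
            continue
        chrom = normalize_chrom(rec.CHROM)
        if want is not None:
            wchrom, wstart, wend = want
            if chrom != wchrom or not (wstart <= rec.POS <= wend):
                continue
        gt_types = rec.gt_types  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        try:
            ds = rec.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            dos = np.asarray(ds, dtype=float).reshape(-1)
            dos = np.where((dos < 0) | (dos > 2), np.nan, dos)
        else:
            dos = np.choose(gt_types, [0.0, 1.0, np.nan, 2.0])
        dos = np.where(gt_types == 2, np.nan, dos)
        vid = rec.ID if rec.ID else f"{chrom}:{rec.POS}:{rec.REF}:{rec.ALT[0]}"
        rows.append((vid, chrom, rec.POS, rec.REF, rec.ALT[0]))
        columns.append(dos)
    if n_skipped:
        logger.warning("skipped %d multi-allelic/indel VCF records", n_skipped)

    if not columns:
        variants = pd.DataFrame(columns=VARIANT_COLUMNS)
        variants["pos"] = variants["pos"].astype(int)
        return GenotypeMatrix(sample_ids, variants,
                              np.empty((len(sample_ids), 0)))
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS[:-1])
    dosages = np.column_stack(columns)
    variants["maf"] = _compute_maf(dosages)
    gm = GenotypeMatrix(sample_ids, variants, dosages)
    order = variants.sort_values(["chrom", "pos"], kind="stable").index.to_numpy()
    if not np.array_equal(order, np.arange(len(variants))):
        gm = gm.subset_variants(order)
    return gm


def write_genotypes(g: GenotypeMatrix, path: str) -> None:
    """Write a minimal VCF 4.2 with GT (rounded) and full-precision DS."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        chroms = dict.fromkeys(g.variants["chrom"].astype(str))
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.sample_ids) + "\n")
        gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, row in g.variants.iterrows():
            cells = []
            for d in g.dosages[:, j]:
                if np.isnan(d):
                    cells.append("./.:.")
                else:
                    cells.append(f"{gt_codes[int(round(d))]}:{d:.17g}")
            fh.write(f"{row.chrom}\t{row.pos}\t{row.variant_id}\t{row.ref}\t"
                     f"{row.alt}\t.\tPASS\t.\tGT:DS\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Tab-delimited phenotype / covariate / GWAS IO
# ---------------------------------------------------------------------------

def write_phenotypes(p: PhenotypeMatrix, values_path: str, features_path: str) -> None:
    """Values: features in rows, first column feature_id, header = sample ids."""
    df = pd.DataFrame(p.values.T, index=p.features["feature_id"], columns=p.sample_ids)
    df.to_csv(values_path, sep="\t", index_label="feature_id", float_format="%.17g")
    p.features.to_csv(features_path, sep="\t", index=False)


def read_phenotypes(values_path: str, features_path: str,
                    beta_scale: bool = False) -> PhenotypeMatrix:
    df = pd.read_csv(values_path, sep="\t", index_col=0)
    feats = pd.read_csv(features_path, sep="\t", dtype={"chrom": str})
    feats["chrom"] = feats["chrom"].map(normalize_chrom)
    feats = feats.set_index("feature_id").loc[df.index].reset_index()
    missing = [c for c in FEATURE_COLUMNS if c not in feats.columns]
    if missing:
        raise ValueError(f"feature annotation missing columns: {missing}")
    return PhenotypeMatrix(
        sample_ids=[str(s) for s in df.columns],
        features=feats[FEATURE_COLUMNS],
        values=df.to_numpy(dtype=float).T,
        beta_scale=beta_scale,
    )


def write_covariates(c: CovariateMatrix, path: str) -> None:
    out = c.table.copy()
    out.insert(0, "sample_id", c.sample_ids)
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_covariates(path: str) -> CovariateMatrix:
    df = pd.read_csv(path, sep="\t")
    sample_ids = [str(s) for s in df["sample_id"]]
    return CovariateMatrix(sample_ids, df.drop(columns=["sample_id"]))


def write_gwas(g: GwasSummary, path: str) -> None:
    g.table.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_gwas(path: str) -> GwasSummary:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    df["chrom"] = df["chrom"].map(normalize_chrom)
    return GwasSummary(df)


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact two-sided Hardy-Weinberg test on genotype counts.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts no more probable than the observed one
    (Wigginton-style exact test). Computed in log space.
    """
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    # possible het counts share the parity of the rare-allele count
    hets = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    # log P(het = h | allele counts) up to a constant:
    #   n! / (hom_r! h! hom_c!) * 2^h with hom_r, hom_c from h
    from scipy.special import gammaln
    hom_rare = (n_rare - hets) // 2
    hom_common = n - hets - hom_rare
    logp = (hets * np.log(2.0)
            - gammaln(hom_rare + 1) - gammaln(hets + 1) - gammaln(hom_common + 1))
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    obs = prob[hets == n_het]
    if obs.size == 0:
        raise ValueError("observed heterozygote count inconsistent with allele counts")
    return float(min(1.0, prob[prob <= obs[0] * (1 + 1e-12)].sum()))


def qc_genotypes(g: GenotypeMatrix, max_missing: float = 0.05,
                 min_maf: float = 0.005, hwe_alpha: float = 1e-4) -> GenotypeMatrix:
    """Apply the standard variant filters: missingness, MAF, and exact HWE.

    Dosages are rounded to hard genotypes for the HWE count test. Filter
    thresholds follow common array-QC practice: drop variants with >5%
    missing calls, minor allele frequency <0.5%, or HWE exact p < 1e-4.
    """
    n = g.n_samples
    miss = np.isnan(g.dosages).sum(axis=0) / max(n, 1)
    maf = _compute_maf(g.dosages)
    maf = np.where(np.isnan(maf), 0.0, maf)

    hwe_p = np.ones(g.n_variants)
    for j in range(g.n_variants):
        d = g.dosages[:, j]
        d = d[~np.isnan(d)]
        if d.size == 0:
            continue
        hard = np.clip(np.round(d), 0, 2).astype(int)
        counts = np.bincount(hard, minlength=3)
        hwe_p[j] = hwe_exact_test(counts[0], counts[1], counts[2])

    keep = (miss <= max_missing) & (maf >= min_maf) & (hwe_p >= hwe_alpha)
    logger.info(
        "qc_genotypes: removed %d/%d variants (missingness %d, MAF %d, HWE %d)",
        int((~keep).sum()), g.n_variants,
        int((miss > max_missing).sum()), int((maf < min_maf).sum()),
        int((hwe_p < hwe_alpha).sum()),
    )
    if not keep.any():
        warnings.warn("qc_genotypes removed every variant", stacklevel=2)
    out = g.subset_variants(keep)
    out.variants["maf"] = _compute_maf(out.dosages)
    return out


def filter_cpg_near_snp(features: PhenotypeMatrix, variants: GenotypeMatrix,
                        min_dist_bp: int = 20) -> PhenotypeMatrix:
    """Drop methylation features whose CpG lies within ``min_dist_bp``
    (inclusive) of any variant position; expression features pass through."""
    if variants.n_variants == 0:
        return features
    keep = np.ones(features.n_features, dtype=bool)
    by_chrom = {
        chrom: np.sort(sub["pos"].to_numpy())
        for chrom, sub in variants.variants.groupby("chrom")
    }
    for j, row in features.features.iterrows():
        if row["kind"] != "methylation":
            continue
        pos = by_chrom.get(str(row["chrom"]))
        if pos is None:
            continue
        i = np.searchsorted(pos, row["anchor_pos"])
        nearest = min(
            (abs(int(pos[k]) - int(row["anchor_pos"]))
             for k in (i - 1, i) if 0 <= k < len(pos)),
            default=None,
        )
        if nearest is not None and nearest <= min_dist_bp:
            keep[j] = False
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("filter_cpg_near_snp: dropped %d CpG features", n_drop)
    return features.subset_features(keep)
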