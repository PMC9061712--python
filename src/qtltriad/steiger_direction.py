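"""MR Steiger directionality test between methylation and expression.

With a SNP instrumenting both molecular traits, the trait whose values share
more variance with the instrument is inferred to sit upstream: under a chain
g -> x -> y the path rule gives r2(g, y) = r2(g, x) * r2(x, y) < r2(g, x),
so comparing the two instrument r2 values orients the chain.

Because methylation and expression are measured on the same samples, the
default test is Steiger's (1980) Z for the difference of two dependent
correlations sharing one variable (here g), which accounts for cor(m, e);
an independent-samples approximation is available behind a flag. Direction
is ME (methylation -> expression) when the SNP explains more variance in
methylation, EM otherwise; exact ties are flagged, never silently broken.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cis_qtl import bh_fdr
from .core_data import GenotypeMatrix, PhenotypeMatrix

logger = logging.getLogger(__name__)

STEIGER_COLUMNS = [
    "variant_id", "cpg_id", "gene_id", "r2_methylation", "r2_expression",
    "direction", "z_stat", "p", "n",
]


@dataclass(frozen=True)
class SteigerResult:
    r2_exposure: float          # SNP-methylation variance explained
    r2_outcome: float           # SNP-expression variance explained
    direction: str              # 'ME', 'EM', or 'TIE'
    z_stat: float
    p: float
    n: int


def variance_explained(g: np.ndarray, x: np.ndarray) -> float:
    """Squared Pearson correlation of instrument and trait."""
    g = np.asarray(g, dtype=float)
    x = np.asarray(x, dtype=float)
    ok = ~(np.isnan(g) | np.isnan(x))
    g, x = g[ok], x[ok]
    if len(g) < 4:
        raise ValueError("variance_explained needs >= 4 complete cases")
    if np.ptp(g) == 0:
        raise ValueError("instrument is constant")
    if np.ptp(x) == 0:
        logger.warning("constant trait: variance explained reported as 0")
        return 0.0
    r = np.corrcoef(g, x)[0, 1]
    return float(r * r)


def r2_from_summary(t_stat: float, n: int) -> float:
    """Variance explained recovered from a t statistic: t^2/(t^2 + n - 2)."""
    if n <= 2:
        raise ValueError("need n > 2")
    return float(t_stat**2 / (t_stat**2 + n - 2))


def _steiger_dependent_z(r_gm: float, r_ge: float, r_me: float,
                         n: int) -> float:
    """Steiger's Z for H0: rho(g,m) = rho(g,e) with correlated m, e.

    Uses Fisher z-transformed correlations and the asymptotic covariance of
    two correlations sharing the variable g on one sample (Steiger 1980,
    Eq. 14 form with the mean correlation plugged in).
    """
    rb = 0.5 * (r_gm + r_ge)
    det_term = r_me * (1 - 2 * rb**2) - 0.5 * rb**2 * (1 - 2 * rb**2 - r_me**2)
    denom = (1 - rb**2) ** 2
    cov = det_term / denom
    z1 = math.atanh(max(min(r_gm, 1 - 1e-15), -1 + 1e-15))
    z2 = math.atanh(max(min(r_ge, 1 - 1e-15), -1 + 1e-15))
    var = 2.0 * (1.0 - cov)
    if var <= 0:
        return 0.0 if z1 == z2 else math.copysign(math.inf, z1 - z2)
    return (z1 - z2) * math.sqrt((n - 3) / var)


def steiger_test(g: np.ndarray, m: np.ndarray, e: np.ndarray,
                 dependent: bool = True) -> SteigerResult:
    """Directionality test between methylation m and expression e.

    Compares |cor(g, m)| and |cor(g, e)|; the Z statistic is positive when
    the instrument explains more variance in methylation. ``dependent=True``
    (default) uses the same-sample correlated-correlations variant;
    ``dependent=False`` uses the independent-samples approximation.
    """
    g = np.asarray(g, dtype=float)
    m = np.asarray(m, dtype=float)
    e = np.asarray(e, dtype=float)
    ok = ~(np.isnan(g) | np.isnan(m) | np.isnan(e))
    g, m, e = g[ok], m[ok], e[ok]
    n = len(g)
    if n <= 4:
        raise ValueError("steiger_test needs n > 4 complete cases")
    if np.ptp(g) == 0:
        raise ValueError("instrument is constant")
    r_gm = abs(np.corrcoef(g, m)[0, 1]) if np.ptp(m) > 0 else 0.0
    r_ge = abs(np.corrcoef(g, e)[0, 1]) if np.ptp(e) > 0 else 0.0
    r_me = np.corrcoef(m, e)[0, 1] if np.ptp(m) > 0 and np.ptp(e) > 0 else 0.0

    if dependent:
        z = _steiger_dependent_z(r_gm, r_ge, abs(r_me), n)
    else:
        z = ((math.atanh(min(r_gm, 1 - 1e-15))
              - math.atanh(min(r_ge, 1 - 1e-15)))
             / math.sqrt(2.0 / (n - 3)))
    p = 2.0 * stats.norm.sf(abs(z)) if math.isfinite(z) else 0.0
    if r_gm > r_ge:
        direction = "ME"
    elif r_ge > r_gm:
        direction = "EM"
    else:
        direction = "TIE"
    return SteigerResult(r_gm**2, r_ge**2, direction, float(z), float(p), n)


def run_steiger(triplets: pd.DataFrame, genotypes: GenotypeMatrix,
                methylation: PhenotypeMatrix, expression: PhenotypeMatrix,
                alpha: float = 0.05, dependent: bool = True
                ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Steiger test per unique DNAm-eGene pair, best instrument per pair.

    Triplets sharing a (CpG, gene) pair but instrumented by different SNPs
    are deduplicated to the instrument with the largest exposure r2 (larger
    of the two trait r2 values). Returns the per-pair table with BH q-values
    and the FDR tier counts at q < 0.05 / 0.1 / 0.25.
    """
    shared = [s for s in expression.sample_ids
              if s in set(genotypes.sample_ids)
              and s in set(methylation.sample_ids)]
    geno = genotypes.subset_samples(shared)
    meth = methylation.subset_samples(shared)
    expr = expression.subset_samples(shared)

    rows = []
    for trip in triplets.itertuples(index=False):
        try:
            g = geno.dosage_vector(trip.variant_id)
            m = meth.feature_vector(trip.cpg_id)
            e = expr.feature_vector(trip.gene_id)
            res = steiger_test(g, m, e, dependent=dependent)
        except (KeyError, ValueError) as exc:
            logger.warning("steiger untestable for %s/%s/%s: %s",
                           trip.variant_id, trip.cpg_id, trip.gene_id, exc)
            continue
        rows.append({
            "variant_id": trip.variant_id, "cpg_id": trip.cpg_id,
            "gene_id": trip.gene_id,
            "r2_methylation": res.r2_exposure,
            "r2_expression": res.r2_outcome,
            "direction": res.direction, "z_stat": res.z_stat,
            "p": res.p, "n": res.n,
        })
    table = pd.DataFrame(rows, columns=STEIGER_COLUMNS)
    if table.empty:
        return table, {"q<0.05": 0, "q<0.1": 0, "q<0.25": 0}

    # best instrument per unique DNAm-eGene pair
    table["r2_best"] = table[["r2_methylation", "r2_expression"]].max(axis=1)
    table = (table.sort_values("r2_best", ascending=False, kind="stable")
             .drop_duplicates(["cpg_id", "gene_id"], keep="first")
             .drop(columns="r2_best")
             .reset_index(drop=True))
    table["q"] = bh_fdr(table["p"].to_numpy())
    tiers = {f"q<{thr}": int((table["q"] < thr).sum())
             for thr in (0.05, 0.1, 0.25)}
    logger.info("steiger: %d pairs, tiers %s", len(table), tiers)
    return table, tiers


def triangulate(cit_table: pd.DataFrame, steiger_table: pd.DataFrame
                ) -> pd.DataFrame:
    """Mark triplets where the CIT label and Steiger direction agree.

    SME agrees with ME (methylation upstream), SEM with EM. The merged table
    carries a ``consistent`` boolean; triplets missing from either input are
    dropped.
    """
    merged = cit_table.merge(
        steiger_table[["variant_id", "cpg_id", "gene_id", "direction",
                       "p", "q"]].rename(columns={"p": "p_steiger"}),
        on=["variant_id", "cpg_id", "gene_id"],
    )
    agree = {("SME", "ME"), ("SEM", "EM")}
    merged["consistent"] = [
        (lab, d) in agree for lab, d in zip(merged["label"], merged["direction"])
    ]
    return merged
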