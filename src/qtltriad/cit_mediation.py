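"""Causal inference test (CIT): conditional-regression mediation analysis.

For a triplet (L = SNP dosage, G = putative mediator, T = outcome) the CIT
combines four component tests into an intersection-union omnibus whose p is
their maximum:

p1  L associates with T                    (F-test of L in T ~ L + C)
p2  L associates with G given T            (F-test of L in G ~ L + T + C)
p3  G associates with T given L            (F-test of G in T ~ G + L + C)
p4  L is independent of T given G          (permutation equivalence test)

p4 is the non-standard piece: the observed statistic is the F for L in
T ~ L + G + C; surrogate mediators G* are built by permuting the residuals
of G on [1, L, C] and adding back the fitted values, which preserves the
L-G association while breaking the G-T|L link. p4 is the smoothed fraction
of permutations whose F*(L in T ~ L + G* + C) is <= the observed F: a small
p4 means conditioning on the real G removes the L-T association far more
completely than chance mediators with the same L-association, i.e. evidence
of mediation.

Running the test in both orientations gives p_causal (SNP -> M -> E) and
p_reverse (SNP -> E -> M); triplets are labeled SME / SEM / INDEPENDENT /
UNCLASSIFIED by thresholding the two omnibus values at alpha.

Genotype enters every component as a numeric additive term (1-df tests),
matching the QTL model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._regression import add_intercept, ols_fit
from .core_data import CovariateMatrix, GenotypeMatrix, PhenotypeMatrix

logger = logging.getLogger(__name__)

LABELS = ("SME", "SEM", "INDEPENDENT", "UNCLASSIFIED")

CIT_COLUMNS = [
    "variant_id", "cpg_id", "gene_id",
    "p1_causal", "p2_causal", "p3_causal", "p4_causal", "p_causal",
    "p1_reverse", "p2_reverse", "p3_reverse", "p4_reverse", "p_reverse",
    "label", "n_used", "n_perm", "seed",
]


@dataclass(frozen=True)
class CitResult:
    """Component and omnibus p-values for both causal orientations."""

    p_components_causal: tuple[float, float, float, float]
    p_components_reverse: tuple[float, float, float, float]
    p_causal: float
    p_reverse: float
    label: str
    n_used: int
    n_perm: int
    seed: int


def _f_test_added(y: np.ndarray, X_base: np.ndarray, x_add: np.ndarray
                  ) -> tuple[float, float]:
    """F statistic and p for adding one column to an existing design."""
    X_full = np.column_stack([X_base, x_add])
    fit = ols_fit(y, X_full)
    if not fit.ok:
        return np.nan, np.nan
    t = fit.t_stat[-1]
    f = t * t
    p = 2.0 * stats.t.sf(abs(t), fit.df_resid)
    return float(f), float(p)


def cit_component_tests(L: np.ndarray, G: np.ndarray, T: np.ndarray,
                        C: np.ndarray | None = None,
                        n_perm: int = 1000, seed: int = 0
                        ) -> tuple[float, float, float, float]:
    """The four CIT component p-values for the direction L -> G -> T.

    Complete cases only; requires >= 20 of them and non-constant L.
    Raises ``ValueError`` on rank-deficient designs.
    """
    L = np.asarray(L, dtype=float)
    G = np.asarray(G, dtype=float)
    T = np.asarray(T, dtype=float)
    C_arr = None if C is None else np.asarray(C, dtype=float)
    if C_arr is not None and C_arr.ndim == 1:
        C_arr = C_arr[:, None]
    ok = ~(np.isnan(L) | np.isnan(G) | np.isnan(T))
    if C_arr is not None:
        ok &= ~np.isnan(C_arr).any(axis=1)
    L, G, T = L[ok], G[ok], T[ok]
    C_used = None if C_arr is None else C_arr[ok]
    n = int(ok.sum())
    if n < 20:
        raise ValueError(f"CIT needs >= 20 complete cases, got {n}")
    if np.ptp(L) == 0:
        raise ValueError("genotype is constant among complete cases")

    ones_C = add_intercept(C_used, n)            # [1, C]

    # p1: L in T ~ L + C
    _, p1 = _f_test_added(T, ones_C, L)
    # p2: L in G ~ L + T + C
    _, p2 = _f_test_added(G, np.column_stack([ones_C, T]), L)
    # p3: G in T ~ G + L + C
    _, p3 = _f_test_added(T, np.column_stack([ones_C, L]), G)
    if np.isnan(p1) or np.isnan(p2) or np.isnan(p3):
        raise ValueError("rank-deficient design in CIT component test")

    # p4: equivalence test of L independent of T given G
    f_obs, _ = _f_test_added(T, np.column_stack([ones_C, G]), L)
    fit_G = ols_fit(G, np.column_stack([ones_C, L]))
    resid_G, fitted_G = fit_G.resid, fit_G.fitted
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        G_star = fitted_G + rng.permutation(resid_G)
        f_star, _ = _f_test_added(T, np.column_stack([ones_C, G_star]), L)
        count += f_star <= f_obs
    p4 = (count + 1) / (n_perm + 1)
    return float(p1), float(p2), float(p3), float(p4)


def cit_omnibus(p1: float, p2: float, p3: float, p4: float) -> float:
    """Intersection-union omnibus: the maximum of the four component p."""
    comps = (p1, p2, p3, p4)
    if any(p is None or np.isnan(p) for p in comps):
        raise ValueError("omnibus undefined with a missing component p-value")
    return float(max(comps))


def cit_classify(p_causal: float, p_reverse: float,
                 alpha: float = 0.05) -> str:
    """Four-way triplet label from the two omnibus p-values."""
    causal = p_causal < alpha
    reverse = p_reverse < alpha
    if causal and not reverse:
        return "SME"
    if reverse and not causal:
        return "SEM"
    if not causal and not reverse:
        return "INDEPENDENT"
    return "UNCLASSIFIED"


def cit_test(L: np.ndarray, m: np.ndarray, e: np.ndarray,
             C: np.ndarray | None = None, n_perm: int = 1000,
             seed: int = 0, alpha: float = 0.05) -> CitResult:
    """Run the CIT in both orientations and classify.

    The causal direction treats methylation as the mediator
    (SNP -> M -> E); the reverse direction swaps the roles of m and e. The
    same seed drives both permutation nulls, so swapping the m and e inputs
    exactly swaps p_causal and p_reverse.
    """
    pc = cit_component_tests(L, m, e, C, n_perm=n_perm, seed=seed)
    pr = cit_component_tests(L, e, m, C, n_perm=n_perm, seed=seed)
    p_causal = cit_omnibus(*pc)
    p_reverse = cit_omnibus(*pr)
    ok = ~(np.isnan(np.asarray(L, float)) | np.isnan(np.asarray(m, float))
           | np.isnan(np.asarray(e, float)))
    return CitResult(pc, pr, p_causal, p_reverse,
                     cit_classify(p_causal, p_reverse, alpha),
                     int(ok.sum()), n_perm, seed)


def run_cit(triplets: pd.DataFrame, genotypes: GenotypeMatrix,
            methylation: PhenotypeMatrix, expression: PhenotypeMatrix,
            covariates: CovariateMatrix | None = None,
            n_perm: int = 1000, seed: int = 0,
            alpha: float = 0.05) -> pd.DataFrame:
    """Per-triplet CIT over a triplet table; returns one row per triplet.

    Samples are intersected across genotypes, methylation and expression
    (the expression subset governs). Triplets whose members are missing
    from the data are flagged ``untestable`` and excluded from summaries.
    """
    shared = [s for s in expression.sample_ids
              if s in set(genotypes.sample_ids)
              and s in set(methylation.sample_ids)]
    geno = genotypes.subset_samples(shared)
    meth = methylation.subset_samples(shared)
    expr = expression.subset_samples(shared)
    C = None
    if covariates is not None:
        idx = [covariates.sample_ids.index(s) for s in shared]
        tab = covariates.table.iloc[idx]
        tab = tab.loc[:, tab.std() > 0]    # subset may fix a covariate
        C = tab.to_numpy(dtype=float) if tab.shape[1] else None

    rows = []
    for i, trip in enumerate(triplets.itertuples(index=False)):
        row = {"variant_id": trip.variant_id, "cpg_id": trip.cpg_id,
               "gene_id": trip.gene_id}
        try:
            L = geno.dosage_vector(trip.variant_id)
            m = meth.feature_vector(trip.cpg_id)
            e = expr.feature_vector(trip.gene_id)
            res = cit_test(L, m, e, C, n_perm=n_perm,
                           seed=seed + i, alpha=alpha)
        except (KeyError, ValueError) as exc:
            logger.warning("triplet %s/%s/%s untestable: %s",
                           trip.variant_id, trip.cpg_id, trip.gene_id, exc)
            row.update(label="UNTESTABLE")
            rows.append(row)
            continue
        p1c, p2c, p3c, p4c = res.p_components_causal
        p1r, p2r, p3r, p4r = res.p_components_reverse
        row.update(
            p1_causal=p1c, p2_causal=p2c, p3_causal=p3c, p4_causal=p4c,
            p_causal=res.p_causal,
            p1_reverse=p1r, p2_reverse=p2r, p3_reverse=p3r, p4_reverse=p4r,
            p_reverse=res.p_reverse,
            label=res.label, n_used=res.n_used, n_perm=res.n_perm,
            seed=res.seed,
        )
        rows.append(row)
    out = pd.DataFrame(rows)
    if not out.empty:
        tested = out[out["label"] != "UNTESTABLE"]
        counts = tested["label"].value_counts().to_dict()
        logger.info("CIT labels: %s", counts)
    return out


def summarize_labels(cit_table: pd.DataFrame) -> dict[str, int]:
    """Label counts over testable triplets."""
    tested = cit_table[cit_table["label"].isin(LABELS)]
    return {lab: int((tested["label"] == lab).sum()) for lab in LABELS}
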