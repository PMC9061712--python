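"""Assembly of (SNP, CpG, gene) triplets from co-occurring eQTL and mQTL.

A variant is "co-occurring" when it has at least one FDR-significant eQTL
and one FDR-significant mQTL association at the same alpha. For each such
variant the full cross product of its significant eGenes and significant
CpGs forms the triplet list handed to the mediation, directionality and
colocalization stages. Direction concordance between the mQTL and eQTL
effects is summarized with a Spearman rank correlation and the fraction of
opposite-sign pairs (promoter-proximal methylation is classically expected
to oppose transcription, so an excess of opposite signs is the interesting
signature).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .enrichment_stats import spearman

TRIPLET_COLUMNS = [
    "variant_id", "cpg_id", "gene_id", "beta_m", "beta_e",
    "q_m", "q_e", "same_direction",
]


def find_cooccurring(eqtl_table: pd.DataFrame, mqtl_table: pd.DataFrame,
                     alpha: float = 0.05) -> set[str]:
    """Variants significant (q < alpha) in both the eQTL and mQTL scans."""
    e_sig = set(eqtl_table.loc[eqtl_table["q"] < alpha, "variant_id"])
    m_sig = set(mqtl_table.loc[mqtl_table["q"] < alpha, "variant_id"])
    return e_sig & m_sig


def build_triplets(eqtl_table: pd.DataFrame, mqtl_table: pd.DataFrame,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Cross product of significant eGenes x significant CpGs per variant."""
    shared = find_cooccurring(eqtl_table, mqtl_table, alpha)
    rows = []
    e_sig = eqtl_table[eqtl_table["q"] < alpha]
    m_sig = mqtl_table[mqtl_table["q"] < alpha]
    for vid in sorted(shared):
        genes = e_sig[e_sig["variant_id"] == vid]
        cpgs = m_sig[m_sig["variant_id"] == vid]
        for ge in genes.itertuples(index=False):
            for cg in cpgs.itertuples(index=False):
                rows.append({
                    "variant_id": vid,
                    "cpg_id": cg.feature_id,
                    "gene_id": ge.feature_id,
                    "beta_m": cg.beta,
                    "beta_e": ge.beta,
                    "q_m": cg.q,
                    "q_e": ge.q,
                    "same_direction": np.sign(cg.beta) == np.sign(ge.beta),
                })
    return pd.DataFrame(rows, columns=TRIPLET_COLUMNS)


def direction_concordance(triplets: pd.DataFrame) -> dict:
    """Spearman correlation of mQTL vs eQTL coefficients across triplets,
    plus the fraction with opposite effect signs."""
    n = len(triplets)
    out = {"n": n, "rho": np.nan, "p": np.nan, "frac_opposite": np.nan}
    if n == 0:
        return out
    out["frac_opposite"] = float(1.0 - triplets["same_direction"].mean())
    if n >= 3:
        rho, p = spearman(triplets["beta_m"].to_numpy(),
                          triplets["beta_e"].to_numpy())
        out.update(rho=rho, p=p)
    return out


def assess_replication(triplets: pd.DataFrame, replication_scan,
                       p_threshold: float = 0.05) -> pd.DataFrame:
    """Re-assess triplet pairs in a second dataset at nominal significance.

    ``replication_scan`` is a callable mapping a pair table (variant_id,
    feature_id) to an association table, typically ``run_qtl_scan`` bound to
    the replication cohort. Each unique (variant, feature) pair from the
    triplets is retested and flagged replicated when its nominal p falls
    below ``p_threshold``; no new statistics are introduced.
    """
    results = []
    for col, kind in (("cpg_id", "mQTL"), ("gene_id", "eQTL")):
        pairs = triplets[["variant_id", col]].drop_duplicates()
        pairs = pairs.rename(columns={col: "feature_id"})
        scan = replication_scan(pairs, kind)
        if scan.empty:
            continue
        scan = scan.assign(replicated=scan["p"] < p_threshold)
        results.append(scan)
    if not results:
        return pd.DataFrame()
    return pd.concat(results, ignore_index=True)
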