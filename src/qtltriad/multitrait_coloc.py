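"""Bayesian multi-trait colocalization from summary statistics.

Given per-SNP association summaries (beta, se) for up to three traits over
one locus — here a GWAS trait G, gene expression E, and DNA methylation M —
the engine evaluates every hypothesis about which traits are associated and
which associated traits share a causal variant. A hypothesis assigns each
trait either to "unassociated" or to a causal-variant group; groups
partition the associated traits, traits in one group share a single causal
SNP, and distinct groups must pick distinct SNPs. For k = 1/2/3 traits this
gives 1/4/14 non-null configurations, i.e. 2/5/15 hypotheses once the null
(no trait associated) is counted — the familiar 15-hypothesis layout for
three traits (H0 null .. H14 full sharing).

Per SNP and trait the evidence is a Wakefield approximate Bayes factor

    log ABF = 0.5 * log(V / (V + W)) + 0.5 * z^2 * W / (V + W),

with V = se^2, z = beta/se and prior effect variance W, averaged over a set
of W values (default {0.01, 0.1, 0.5}). Configuration marginal likelihoods
sum products of per-SNP ABFs over admissible SNP assignments (shared group:
same SNP; distinct groups: distinct SNPs, handled by inclusion-exclusion),
weighted by per-group priors p1/p2/p3 for group sizes 1/2/3. Posteriors are
normalized over all hypotheses including the null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

TRAITS_3 = ("G", "E", "M")


class LocusSkipped(ValueError):
    """Raised when a locus fails the minimum-SNP / MAF entry filter."""


@dataclass(frozen=True)
class MolocConfig:
    """Priors and entry filters for the colocalization engine."""

    prior_one: float = 1e-4      # SNP associated with exactly one trait
    prior_two: float = 1e-6      # SNP shared by two traits
    prior_three: float = 1e-7    # SNP shared by all three traits
    prior_var_set: tuple[float, ...] = (0.01, 0.1, 0.5)
    min_snps: int = 50
    min_maf: float = 0.05
    ppa_threshold: float = 0.8

    def __post_init__(self) -> None:
        if not self.prior_three < self.prior_two < self.prior_one < 1:
            raise ValueError("priors must satisfy p3 < p2 < p1 < 1")
        if any(w <= 0 for w in self.prior_var_set):
            raise ValueError("prior effect variances must be positive")

    def group_prior(self, size: int) -> float:
        return (self.prior_one, self.prior_two, self.prior_three)[size - 1]


@dataclass
class MolocResult:
    """Posterior over hypotheses for one locus."""

    locus_id: str
    posteriors: dict            # hypothesis label -> probability (incl 'null')
    aggregates: dict            # PPA_GEM, PPA_G_EM, PPA_GM_E, PPA_GE_M, ...
    best_snp: str | None        # top per-SNP posterior under the MAP config
    n_snps: int
    top_config: str = ""


def log_abf(beta, se, W) -> np.ndarray | float:
    """Wakefield log approximate Bayes factor, association vs null.

    ``W`` may be a scalar prior effect variance or an iterable of variances
    whose ABFs (not log-ABFs) are averaged arithmetically.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    Ws = np.atleast_1d(np.asarray(W, dtype=float))
    if np.any(Ws <= 0):
        raise ValueError("prior variance W must be positive")
    V = se**2
    z2 = (beta / se) ** 2
    per_w = np.stack([
        0.5 * np.log(V / (V + w)) + 0.5 * z2 * w / (V + w) for w in Ws
    ])
    out = logsumexp(per_w, axis=0) - np.log(len(Ws))
    return float(out) if out.ndim == 0 else out


def enumerate_configurations(k_traits: int,
                             trait_names: tuple[str, ...] | None = None,
                             include_null: bool = False) -> list[tuple]:
    """All association configurations for k traits.

    Each configuration is a tuple of groups (tuples of trait names); the
    traits present are the associated ones, each group sharing one causal
    variant and distinct groups having distinct variants. The null (empty
    tuple) is appended only when ``include_null`` is set. Counts: 1, 4, 14
    non-null for k = 1, 2, 3 (2, 5, 15 with the null).
    """
    if k_traits < 1:
        raise ValueError("k_traits must be >= 1")
    names = tuple(trait_names) if trait_names else TRAITS_3[:k_traits]
    if len(names) != k_traits:
        raise ValueError("trait_names length must equal k_traits")

    def partitions(items: tuple) -> list[tuple]:
        if not items:
            return [()]
        head, rest = items[0], items[1:]
        out = []
        for sub in partitions(rest):
            # head joins an existing group or starts its own
            for i in range(len(sub)):
                out.append(sub[:i] + ((head,) + sub[i],) + sub[i + 1:])
            out.append(((head,),) + sub)
        return out

    configs: list[tuple] = []
    for r in range(1, k_traits + 1):
        for subset in combinations(names, r):
            for part in partitions(subset):
                ordered = tuple(sorted(
                    (tuple(sorted(g, key=names.index)) for g in part),
                    key=lambda g: names.index(g[0]),
                ))
                configs.append(ordered)
    configs = sorted(set(configs), key=lambda c: (
        sum(len(g) for g in c), len(c), [names.index(g[0]) for g in c]))
    if include_null:
        configs = [()] + configs
    return configs


def config_label(config: tuple) -> str:
    """'GEM' for one shared group, 'G,EM' for distinct groups, 'null'."""
    if not config:
        return "null"
    return ",".join("".join(g) for g in config)


def _log_config_likelihood(config: tuple, labf: dict[str, np.ndarray],
                           cfg: MolocConfig) -> float:
    """Log of sum over admissible SNP assignments of ABF products x priors.

    Distinct groups must choose distinct SNPs; the sum over injective
    assignments is computed by inclusion-exclusion over partitions of the
    groups into coincident blocks (up to three groups arise for k <= 3).
    """
    group_vecs = [sum(labf[t] for t in g) for g in config]
    log_prior = float(sum(np.log(cfg.group_prior(len(g))) for g in config))
    r = len(group_vecs)
    if r == 1:
        return logsumexp(group_vecs[0]) + log_prior
    S = {}
    idx = tuple(range(r))
    for size in range(1, r + 1):
        for block in combinations(idx, size):
            S[block] = logsumexp(sum(group_vecs[i] for i in block))
    if r == 2:
        terms = [S[(0,)] + S[(1,)], S[(0, 1)]]
        signs = [1.0, -1.0]
    elif r == 3:
        terms = [
            S[(0,)] + S[(1,)] + S[(2,)],
            S[(0, 1)] + S[(2,)], S[(0, 2)] + S[(1,)], S[(1, 2)] + S[(0,)],
            S[(0, 1, 2)],
        ]
        signs = [1.0, -1.0, -1.0, -1.0, 2.0]
    else:  # pragma: no cover - k <= 3 in this pipeline
        raise NotImplementedError("more than three distinct groups")
    total, sign = logsumexp(terms, b=signs, return_sign=True)
    if sign <= 0 or not np.isfinite(total):
        # numerically zero admissible mass (cancellation): no support
        return -np.inf
    return float(total) + log_prior


def moloc_posterior(summaries: dict[str, pd.DataFrame],
                    config: MolocConfig = MolocConfig(),
                    locus_id: str = "locus",
                    trait_order: tuple[str, ...] | None = None) -> MolocResult:
    """Posterior probabilities over all association hypotheses for a locus.

    ``summaries`` maps trait name -> DataFrame with columns ``variant_id``,
    ``beta``, ``se`` and optionally ``eaf``. SNPs are intersected across
    traits; variants failing the MAF filter (when frequency is available)
    are dropped, and loci with fewer than ``min_snps`` remaining are skipped
    via :class:`LocusSkipped`.
    """
    traits = tuple(trait_order) if trait_order else tuple(summaries)
    tables = {}
    for t in traits:
        tab = summaries[t].copy()
        if "eaf" in tab.columns:
            maf = np.minimum(tab["eaf"], 1 - tab["eaf"])
            tab = tab[maf > config.min_maf]
        tables[t] = tab.set_index("variant_id")
    common = None
    for t in traits:
        ids = set(tables[t].index)
        common = ids if common is None else (common & ids)
    common = sorted(common)
    if len(common) < config.min_snps:
        raise LocusSkipped(
            f"{locus_id}: only {len(common)} SNPs shared after filters "
            f"(need >= {config.min_snps})")

    labf = {
        t: log_abf(tables[t].loc[common, "beta"].to_numpy(),
                   tables[t].loc[common, "se"].to_numpy(),
                   config.prior_var_set)
        for t in traits
    }
    configs = enumerate_configurations(len(traits), traits)
    logw = {"null": 0.0}
    for c in configs:
        logw[config_label(c)] = _log_config_likelihood(c, labf, config)
    labels = list(logw)
    vals = np.array([logw[l] for l in labels])
    post = np.exp(vals - logsumexp(vals))
    posteriors = dict(zip(labels, post))

    non_null = {l: p for l, p in posteriors.items() if l != "null"}
    top_label = max(non_null, key=non_null.get) if non_null else "null"
    best_snp = None
    if top_label != "null":
        top_cfg = configs[[config_label(c) for c in configs].index(top_label)]
        # per-SNP posterior within the group containing the first trait of
        # the top configuration (the shared group for full colocalization)
        lead = next((g for g in top_cfg if traits[0] in g), top_cfg[0])
        v = sum(labf[t] for t in lead)
        best_snp = common[int(np.argmax(v))]

    aggregates = {
        "PPA_" + lab.replace(",", "_"): posteriors.get(lab, 0.0)
        for lab in (config_label(c) for c in configs)
    }
    return MolocResult(locus_id, posteriors, aggregates, best_snp,
                       len(common), top_label)


def colocalize_pairwise(summaries: dict[str, pd.DataFrame],
                        config: MolocConfig = MolocConfig(),
                        locus_id: str = "locus") -> MolocResult:
    """Two-trait colocalization: the degenerate k=2 case (5 hypotheses)."""
    if len(summaries) != 2:
        raise ValueError("colocalize_pairwise needs exactly two traits")
    return moloc_posterior(summaries, config, locus_id)


def moloc_table(results: list[MolocResult]) -> pd.DataFrame:
    """Flatten locus results into a per-locus posterior table."""
    rows = []
    for r in results:
        row = {"locus_id": r.locus_id, "n_snps": r.n_snps,
               "top_config": r.top_config, "best_snp": r.best_snp}
        row.update({f"PPA_{lab.replace(',', '_')}": p
                    for lab, p in r.posteriors.items() if lab != "null"})
        row["PPA_null"] = r.posteriors.get("null", np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def harmonize_pair(left: pd.DataFrame, right: pd.DataFrame,
                   ambiguous_eaf_band: float = 0.08) -> pd.DataFrame:
    """Align two summary tables on (chrom, pos, alleles).

    Right-table betas are flipped when its effect allele matches the left
    table's other allele. Strand-ambiguous A/T and C/G SNPs are dropped when
    their frequency is uninformative (|eaf - 0.5| < band) in either table.
    """
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    key = ["chrom", "pos"]
    merged = left.merge(right, on=key, suffixes=("_l", "_r"))
    ea_l = merged["effect_allele_l"].str.upper()
    oa_l = merged["other_allele_l"].str.upper()
    ea_r = merged["effect_allele_r"].str.upper()
    oa_r = merged["other_allele_r"].str.upper()

    same = (ea_l == ea_r) & (oa_l == oa_r)
    flipped = (ea_l == oa_r) & (oa_l == ea_r)
    keep = same | flipped
    ambiguous = ea_l.map(comp) == oa_l
    if "eaf_l" in merged and "eaf_r" in merged:
        uninformative = ((merged["eaf_l"] - 0.5).abs() < ambiguous_eaf_band) | \
                        ((merged["eaf_r"] - 0.5).abs() < ambiguous_eaf_band)
        keep &= ~(ambiguous & uninformative)
    else:
        keep &= ~ambiguous
    merged = merged[keep].copy()
    flip = flipped[keep]
    merged.loc[flip, "beta_r"] = -merged.loc[flip, "beta_r"]
    if "eaf_r" in merged:
        merged.loc[flip, "eaf_r"] = 1 - merged.loc[flip, "eaf_r"]
    return merged
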