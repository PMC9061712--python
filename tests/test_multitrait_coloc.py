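"""Colocalization engine: ABF against a quadrature oracle, hypothesis
enumeration, posterior normalization and invariances, and recovery of
shared vs distinct causal variants."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from qtltriad.multitrait_coloc import (LocusSkipped, MolocConfig,
                                       colocalize_pairwise, config_label,
                                       enumerate_configurations,
                                       harmonize_pair, log_abf,
                                       moloc_posterior)
from qtltriad.synthetic_data import LocusSpec, simulate_gwas_locus


# ---------------------------------------------------------------------------
# approximate Bayes factor
# ---------------------------------------------------------------------------

def test_log_abf_closed_form_cases():
    # z = 0, W = V: log ABF = 0.5 log 0.5
    assert log_abf(0.0, 0.1, 0.01) == pytest.approx(0.5 * np.log(0.5),
                                                    rel=1e-12)
    # W -> 0: no prior mass on association, ABF -> 1
    assert abs(log_abf(0.5, 0.1, 1e-12)) < 1e-6


def test_log_abf_matches_quadrature_oracle():
    beta, se, W = 0.5, 0.1, 0.1

    def integrand(b):
        return stats.norm.pdf(beta, b, se) * stats.norm.pdf(b, 0, np.sqrt(W))

    marginal, _ = integrate.quad(integrand, -5, 5, epsabs=1e-14)
    bf_oracle = marginal / stats.norm.pdf(beta, 0, se)
    assert log_abf(beta, se, W) == pytest.approx(np.log(bf_oracle), rel=1e-6)


def test_log_abf_w_set_is_mean_of_abfs():
    Ws = (0.01, 0.1, 0.5)
    single = [np.exp(log_abf(0.3, 0.1, w)) for w in Ws]
    combined = np.exp(log_abf(0.3, 0.1, Ws))
    assert combined == pytest.approx(np.mean(single), rel=1e-12)
    with pytest.raises(ValueError):
        log_abf(0.1, 0.0, 0.1)


# ---------------------------------------------------------------------------
# hypothesis enumeration
# ---------------------------------------------------------------------------

def test_configuration_counts_and_labels():
    assert len(enumerate_configurations(1)) == 1
    k2 = enumerate_configurations(2, ("A", "B"))
    assert len(k2) == 4
    assert {config_label(c) for c in k2} == {"A", "B", "AB", "A,B"}
    k3 = enumerate_configurations(3)
    assert len(k3) == 14
    # with the null included the count is the printed 15-hypothesis layout
    assert len(enumerate_configurations(3, include_null=True)) == 15
    assert len(enumerate_configurations(2, include_null=True)) == 5
    labels = {config_label(c) for c in k3}
    assert {"GEM", "G,EM", "GE,M", "GM,E", "G,E,M"} <= labels


def test_configuration_count_recurrence():
    # counts including the null follow Bell(k+1): 2, 5, 15
    for k, bell in ((1, 2), (2, 5), (3, 15)):
        assert len(enumerate_configurations(k, include_null=True)) == bell


# ---------------------------------------------------------------------------
# posterior behavior
# ---------------------------------------------------------------------------

def shared_locus(seed, z=8.0, ld=0.5):
    spec = LocusSpec(n_snps=100, ld_rho=ld,
                     causal_index={"G": 30, "E": 30, "M": 30},
                     z_target={"G": z, "E": z, "M": z},
                     n_per_trait={"G": 4000, "E": 2000, "M": 2000},
                     seed=seed)
    _, tables, _ = simulate_gwas_locus(spec)
    return tables


def test_posteriors_normalize_and_scale_invariance():
    tables = shared_locus(1)
    res = moloc_posterior(tables, locus_id="L1")
    assert len(res.posteriors) == 15
    assert sum(res.posteriors.values()) == pytest.approx(1.0, abs=1e-9)
    assert all(0 <= p <= 1 for p in res.posteriors.values())

    # rescaling one trait's beta/se preserves z; with the prior effect
    # variance rescaled on the same squared factor the ABFs — and hence all
    # posteriors — are exactly unchanged
    scaled = {k: v.copy() for k, v in tables.items()}
    scaled["E"]["beta"] *= 7.3
    scaled["E"]["se"] *= 7.3
    np.testing.assert_allclose(scaled["E"]["beta"] / scaled["E"]["se"],
                               tables["E"]["beta"] / tables["E"]["se"])
    b1 = log_abf(tables["E"]["beta"].to_numpy(),
                 tables["E"]["se"].to_numpy(), 0.1)
    b2 = log_abf(scaled["E"]["beta"].to_numpy(),
                 scaled["E"]["se"].to_numpy(), 0.1 * 7.3**2)
    np.testing.assert_allclose(b1, b2, rtol=1e-12)
    # with W held fixed the dominant hypothesis is still insensitive to
    # moderate unit changes
    res2 = moloc_posterior(scaled, locus_id="L1")
    assert res2.aggregates["PPA_GEM"] == pytest.approx(
        res.aggregates["PPA_GEM"], abs=0.05)


def test_null_locus_posterior_mass_on_null():
    # exactly zero evidence: beta = 0 at every SNP of every trait
    flat = pd.DataFrame({
        "variant_id": [f"s{j}" for j in range(100)],
        "beta": 0.0, "se": 0.05,
    })
    res = moloc_posterior({t: flat.copy() for t in ("G", "E", "M")})
    assert res.posteriors["null"] > 0.99

    # a simulated no-signal locus: null is the clear MAP hypothesis
    spec = LocusSpec(n_snps=100, ld_rho=0.3,
                     n_per_trait={"G": 2000, "E": 1000, "M": 1000}, seed=9)
    _, tables, _ = simulate_gwas_locus(spec)
    res = moloc_posterior(tables)
    assert res.posteriors["null"] > 0.9
    assert res.posteriors["null"] == max(res.posteriors.values())


def test_shared_causal_recovery():
    n_hit = 0
    for seed in range(20):
        res = moloc_posterior(shared_locus(seed), locus_id=f"L{seed}")
        n_hit += res.aggregates["PPA_GEM"] >= 0.8
    assert n_hit >= 16      # >= 80% of replicates


def test_distinct_causals_rejected():
    n_ok = 0
    for seed in range(20):
        spec = LocusSpec(n_snps=100, ld_rho=0.0,
                         causal_index={"G": 10, "E": 50, "M": 90},
                         z_target={"G": 8, "E": 8, "M": 8},
                         n_per_trait={"G": 4000, "E": 2000, "M": 2000},
                         seed=100 + seed)
        _, tables, _ = simulate_gwas_locus(spec)
        res = moloc_posterior(tables)
        n_ok += res.aggregates["PPA_GEM"] <= 0.2
    assert n_ok >= 16


def test_best_snp_points_at_causal_variant():
    res = moloc_posterior(shared_locus(3), locus_id="L")
    causal_pos = 1_000_000 + 30 * 1_000
    best_pos = int(res.best_snp.split("_")[-1])
    assert abs(best_pos - causal_pos) <= 2_000      # causal or tight proxy


def test_min_snp_filter_skips_locus():
    tables = shared_locus(5)
    small = {k: v.iloc[:20] for k, v in tables.items()}
    with pytest.raises(LocusSkipped, match="20 SNPs"):
        moloc_posterior(small)


def test_pairwise_engine_consistent_with_flat_third_trait():
    tables = shared_locus(7)
    pair = {"G": tables["G"], "E": tables["E"]}
    res2 = colocalize_pairwise(pair, locus_id="L")
    assert len(res2.posteriors) == 5
    assert sum(res2.posteriors.values()) == pytest.approx(1.0, abs=1e-9)
    assert res2.posteriors["GE"] > 0.8

    flat = tables["M"].copy()
    flat["beta"] = 0.0
    res3 = moloc_posterior({"G": tables["G"], "E": tables["E"], "M": flat})
    # top structure among configurations ignoring M matches the 2-trait run
    assert res3.top_config in ("GE", "GE,M")
    assert res3.posteriors["GE"] == pytest.approx(res2.posteriors["GE"],
                                                  abs=0.1)


def test_monotone_in_shared_signal_strength():
    med = []
    for z in (4.0, 6.0, 8.0):
        ppa = [moloc_posterior(shared_locus(s, z=z)).aggregates["PPA_GEM"]
               for s in range(8)]
        med.append(np.median(ppa))
    assert med[0] <= med[1] + 0.05 and med[1] <= med[2] + 0.05


def test_harmonize_pair_flips_and_drops_ambiguous():
    left = pd.DataFrame({
        "chrom": ["1", "1", "1"], "pos": [100, 200, 300],
        "effect_allele": ["A", "A", "A"], "other_allele": ["G", "G", "T"],
        "beta": [0.5, 0.5, 0.5], "eaf": [0.3, 0.3, 0.5],
    })
    right = pd.DataFrame({
        "chrom": ["1", "1", "1"], "pos": [100, 200, 300],
        "effect_allele": ["A", "G", "A"], "other_allele": ["G", "A", "T"],
        "beta": [0.5, 0.5, 0.5], "eaf": [0.3, 0.7, 0.5],
    })
    out = harmonize_pair(left, right)
    assert list(out["pos"]) == [100, 200]      # ambiguous A/T at 0.5 dropped
    assert out.loc[out["pos"] == 200, "beta_r"].iloc[0] == pytest.approx(-0.5)
    assert out.loc[out["pos"] == 200, "eaf_r"].iloc[0] == pytest.approx(0.3)
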