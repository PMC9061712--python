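"""cis pairing, PCA covariates, the additive-model fit against a brute-force
OLS oracle, BH FDR, the scan, and the inflation factor."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from qtltriad import cis_qtl
from qtltriad.core_data import CovariateMatrix
from qtltriad.synthetic_data import CohortConfig, simulate_cohort

from conftest import make_genotypes, make_phenotypes


# ---------------------------------------------------------------------------
# cis-window pairing
# ---------------------------------------------------------------------------

def test_pair_cis_window_boundary_inclusive():
    variants = pd.DataFrame({"variant_id": ["v"], "chrom": ["1"],
                             "pos": [1_500_000]})
    feats = pd.DataFrame({
        "feature_id": ["at_1mb", "beyond", "other_chrom"],
        "chrom": ["1", "1", "2"],
        "anchor_pos": [2_500_000, 2_500_001, 1_500_000],
        "kind": "expression",
    })
    pairs = cis_qtl.pair_cis(variants, feats, window_bp=1_000_000)
    assert list(pairs["feature_id"]) == ["at_1mb"]
    assert pairs["distance_bp"].iloc[0] == -1_000_000


def test_gene_tss_strand_aware():
    feats = pd.DataFrame({
        "feature_id": ["plus", "minus"], "chrom": "1",
        "start": [100, 100], "end": [900, 900],
        "strand": ["+", "-"], "anchor_pos": [0, 0], "kind": "expression",
    })
    out = cis_qtl.gene_tss(feats)
    assert list(out["anchor_pos"]) == [100, 900]


# ---------------------------------------------------------------------------
# principal components
# ---------------------------------------------------------------------------

def test_compute_pcs_rank1_and_orthogonality(rng):
    u = rng.normal(size=10)
    v = rng.normal(size=6)
    rank1 = np.outer(u, v) + 0.0
    pcs = cis_qtl.compute_pcs(rank1, 2)
    var = pcs.var(axis=0, ddof=0)
    assert var.iloc[0] / var.sum() > 1 - 1e-9     # PC1 carries everything

    X = rng.normal(size=(30, 8))
    pcs = cis_qtl.compute_pcs(X, 4)
    gram = pcs.T.to_numpy() @ pcs.to_numpy()
    off = gram - np.diag(np.diag(gram))
    assert np.abs(off).max() < 1e-8


def test_compute_pcs_matches_eigendecomposition(rng):
    X = rng.normal(size=(5, 4))
    pcs = cis_qtl.compute_pcs(X, 2).to_numpy()
    Z = (X - X.mean(0)) / X.std(0)
    evals, evecs = np.linalg.eigh(Z.T @ Z)
    order = np.argsort(evals)[::-1]
    expected = Z @ evecs[:, order[:2]]
    for j in range(2):
        got, want = pcs[:, j], expected[:, j]
        if np.dot(got, want) < 0:
            want = -want
        np.testing.assert_allclose(got, want, atol=1e-8)


def test_compute_pcs_drops_constant_columns(rng):
    X = np.column_stack([np.ones(10), rng.normal(size=(10, 3))])
    pcs = cis_qtl.compute_pcs(X, 2)
    assert pcs.shape == (10, 2)


# ---------------------------------------------------------------------------
# single-pair fit vs brute-force oracle
# ---------------------------------------------------------------------------

def ols_oracle(y, X):
    """Normal equations + t CDF, written independently of the fit path."""
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    sigma2 = resid @ resid / df
    cov = sigma2 * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov))
    t = beta / se
    p = 2 * stats.t.sf(np.abs(t), df)
    return beta, se, t, p


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000),
       st.integers(min_value=12, max_value=30),
       st.integers(min_value=0, max_value=2))
def test_fit_qtl_matches_normal_equations_oracle(seed, n, n_cov):
    rng = np.random.default_rng(seed)
    g = rng.binomial(2, 0.4, size=n).astype(float)
    if np.ptp(g) == 0:
        g[0] = 1.0 if g[0] != 1.0 else 2.0
    C = rng.normal(size=(n, n_cov)) if n_cov else None
    y = 0.5 * g + rng.normal(size=n)
    res = cis_qtl.fit_qtl(g, y, C)
    X = np.column_stack([np.ones(n), g] + ([C] if C is not None else []))
    beta, se, t, p = ols_oracle(y, X)
    assert res["beta"] == pytest.approx(beta[1], rel=1e-9)
    assert res["se"] == pytest.approx(se[1], rel=1e-9)
    assert res["t_stat"] == pytest.approx(t[1], rel=1e-9)
    assert res["p"] == pytest.approx(p[1], rel=1e-9, abs=1e-300)


def test_fit_qtl_exact_fit_and_orthogonal_cases(rng):
    g = np.tile([0.0, 1.0, 2.0], 4)[:10]
    res = cis_qtl.fit_qtl(g, 2 * g)
    assert res["beta"] == pytest.approx(2.0)
    assert res["p"] < 1e-100

    gc = g - g.mean()
    y = rng.normal(size=10)
    y = y - y.mean()
    y = y - (y @ gc) / (gc @ gc) * gc             # orthogonal to g
    res = cis_qtl.fit_qtl(g, y)
    assert abs(res["beta"]) < 1e-12


def test_fit_qtl_orthogonal_covariate_leaves_beta(rng):
    n = 40
    g = rng.binomial(2, 0.4, size=n).astype(float)
    y = 0.3 * g + rng.normal(size=n)
    base = cis_qtl.fit_qtl(g, y)
    z = rng.normal(size=n)
    X = np.column_stack([np.ones(n), g, y])
    z = z - X @ np.linalg.lstsq(X, z, rcond=None)[0]   # orthogonalize
    with_cov = cis_qtl.fit_qtl(g, y, z)
    assert with_cov["beta"] == pytest.approx(base["beta"], abs=1e-9)


def test_fit_qtl_untestable_paths(rng):
    g = np.ones(30)
    assert cis_qtl.fit_qtl(g, rng.normal(size=30))["untestable"]
    g = rng.binomial(2, 0.4, size=30).astype(float)
    C = np.column_stack([g, g])                   # rank-deficient design
    assert cis_qtl.fit_qtl(g, rng.normal(size=30), C)["untestable"]


def test_fit_qtl_pairwise_deletion(rng):
    g = rng.binomial(2, 0.4, size=50).astype(float)
    y = 0.5 * g + rng.normal(size=50)
    g_miss = g.copy()
    g_miss[:5] = np.nan
    res = cis_qtl.fit_qtl(g_miss, y)
    ref = cis_qtl.fit_qtl(g[5:], y[5:])
    assert res["n_used"] == 45
    assert res["beta"] == pytest.approx(ref["beta"], rel=1e-12)


# ---------------------------------------------------------------------------
# BH FDR
# ---------------------------------------------------------------------------

def bh_oracle(p):
    """Literal step-up: q_i = min_{j >= i} min(1, m p_(j) / j)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.minimum.accumulate(
        (m * p[order] / (np.arange(m) + 1))[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def test_bh_fdr_worked_examples():
    np.testing.assert_allclose(cis_qtl.bh_fdr([0.03]), [0.03])
    np.testing.assert_allclose(cis_qtl.bh_fdr([0.01, 0.02, 0.03, 0.04]),
                               [0.04, 0.04, 0.04, 0.04])
    np.testing.assert_allclose(cis_qtl.bh_fdr([0.2, 0.2, 0.2]), [0.2] * 3)
    assert cis_qtl.bh_fdr(np.array([])).size == 0


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000),
       st.integers(min_value=1, max_value=1000))
def test_bh_fdr_matches_stepup_oracle(seed, m):
    p = np.random.default_rng(seed).uniform(1e-12, 1, size=m)
    got = cis_qtl.bh_fdr(p)
    np.testing.assert_allclose(got, bh_oracle(p), rtol=1e-12)
    assert (got >= p - 1e-15).all()               # q >= p always


# ---------------------------------------------------------------------------
# scan-level behavior
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def sme_cohort():
    return simulate_cohort(CohortConfig(n_loci=2, scenario_mix=("SME",),
                                        n_meth_samples=120, n_expr_samples=60,
                                        n_gwas=1000, seed=5))


def test_scan_invariant_to_sample_and_feature_order(sme_cohort, rng):
    b = sme_cohort
    base = cis_qtl.run_qtl_scan(b.genotypes, b.methylation, b.covariates,
                                kind="methylation")
    perm = rng.permutation(b.methylation.n_samples)
    meth_shuffled = b.methylation.subset_samples(
        [b.methylation.sample_ids[i] for i in perm])
    fperm = rng.permutation(b.methylation.n_features)
    meth_shuffled = meth_shuffled.subset_features(fperm)
    shuffled = cis_qtl.run_qtl_scan(b.genotypes, meth_shuffled, b.covariates,
                                    kind="methylation")
    key = ["variant_id", "feature_id"]
    a = base.set_index(key).sort_index()
    c = shuffled.set_index(key).sort_index()
    np.testing.assert_allclose(a["beta"], c["beta"], rtol=1e-9)
    np.testing.assert_allclose(a["q"], c["q"], rtol=1e-9)


def test_scan_permuting_labels_destroys_signal(sme_cohort, rng):
    b = sme_cohort
    base = cis_qtl.run_qtl_scan(b.genotypes, b.methylation, None,
                                kind="methylation")
    true_pairs = base[base["q"] < 0.05]
    assert len(true_pairs) > 0
    perm = rng.permutation(b.methylation.n_samples)
    shuffled_values = b.methylation.values[perm, :]
    meth_perm = make_phenotypes(shuffled_values)
    meth_perm.features = b.methylation.features
    meth_perm.sample_ids = b.methylation.sample_ids
    null = cis_qtl.run_qtl_scan(b.genotypes, meth_perm, None,
                                kind="methylation")
    merged = true_pairs.merge(null, on=["variant_id", "feature_id"],
                              suffixes=("", "_perm"))
    assert merged["q_perm"].median() > 0.5


def test_scan_empty_pairs_warns(sme_cohort):
    b = sme_cohort
    far = b.methylation.subset_features(np.arange(b.methylation.n_features))
    far.features["anchor_pos"] = 500_000_000
    with pytest.warns(UserWarning, match="no candidate"):
        out = cis_qtl.run_qtl_scan(b.genotypes, far, None, kind="methylation")
    assert out.empty


# ---------------------------------------------------------------------------
# genomic inflation factor
# ---------------------------------------------------------------------------

def test_genomic_lambda_definition_and_scaling(rng):
    assert cis_qtl.genomic_lambda(np.full(11, 0.5)) == 1.0

    p = rng.uniform(size=100_000)
    assert cis_qtl.genomic_lambda(p) == pytest.approx(1.0, abs=0.02)

    chi2 = stats.chi2.rvs(1, size=50_000, random_state=7)
    p_inflated = stats.chi2.sf(2 * chi2, 1)
    assert cis_qtl.genomic_lambda(p_inflated) == pytest.approx(2.0, abs=0.1)

    with pytest.raises(ValueError):
        cis_qtl.genomic_lambda([])
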