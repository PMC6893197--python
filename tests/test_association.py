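"""Variant filter, GRM, single-variant LMM and QQ diagnostics.

The LMM is checked against independent dense-matrix oracles: OLS when
K = I or lambda = 0, and brute-force GLS (X' V^-1 X)^-1 X' V^-1 y at a
pinned variance ratio.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from modscreen import association
from modscreen.association import (LMM, compute_grm, filter_variants,
                                   fit_lmm_variant, qq_diagnostics, run_gwas)
from modscreen.errors import DegenerateVariantError, ValidationError
from modscreen.types import RelatednessMatrix

from conftest import make_panel


# -- filtering --------------------------------------------------------------

def test_multiallelic_removed():
    panel = make_panel(np.zeros((4, 2)), alt_counts=[1, 2])
    panel.calls[:2, :] = 2.0
    kept, rep = filter_variants(panel)
    assert rep.n_non_biallelic == 1
    assert list(kept.variants["variant_id"]) == ["v0"]


def test_maf_boundary_inclusive_at_0_05():
    """200 lines: 9 minor-allele carriers (MAF 0.045) removed, 10 (0.05)
    retained — the filter keeps MAF >= 0.05."""
    calls = np.zeros((200, 2))
    calls[:9, 0] = 2.0
    calls[:10, 1] = 2.0
    kept, rep = filter_variants(make_panel(calls))
    assert list(kept.variants["variant_id"]) == ["v1"]
    assert rep.n_low_maf == 1


def test_missingness_threshold():
    calls = np.full((10, 2), 2.0)
    calls[:5, 0] = 0.0
    calls[:5, 1] = 0.0
    calls[:3, 0] = np.nan      # 30% missing -> dropped
    calls[:2, 1] = np.nan      # 20% missing -> kept (<= 0.20)
    kept, rep = filter_variants(make_panel(calls))
    assert list(kept.variants["variant_id"]) == ["v1"]
    assert rep.n_high_missing == 1


def test_filter_matches_brute_force_recount():
    rng = np.random.default_rng(41)
    n, m = 50, 1000
    calls = rng.choice([0.0, 2.0], size=(n, m),
                       p=[0.8, 0.2])
    calls[rng.random((n, m)) < 0.1] = np.nan
    alt_counts = rng.choice([1, 2], size=m, p=[0.9, 0.1])
    panel = make_panel(calls, alt_counts=list(alt_counts))
    kept, rep = filter_variants(panel)
    survivors = 0
    for j in range(m):
        if alt_counts[j] != 1:
            continue
        col = calls[:, j]
        if np.isnan(col).mean() > 0.20:
            continue
        f = np.nanmean(col) / 2
        if min(f, 1 - f) < 0.05:
            continue
        survivors += 1
    assert rep.n_retained == survivors == kept.n_variants


# -- GRM --------------------------------------------------------------------

def test_grm_hand_computed_3x2():
    # lines x variants: x1 = (0, 2, 2), x2 = (0, 0, 2)
    panel = make_panel([[0, 0], [2, 0], [2, 2]])
    K = compute_grm(panel).K
    Xc = np.array([[0 - 4 / 3, 0 - 2 / 3],
                   [2 - 4 / 3, 0 - 2 / 3],
                   [2 - 4 / 3, 2 - 2 / 3]])
    expected = Xc @ Xc.T / 2
    np.testing.assert_allclose(K, expected, atol=1e-12)


def test_grm_monomorphic_contributes_zero():
    base = make_panel([[0.0], [2.0], [2.0]])
    with_mono = make_panel([[0, 2], [2, 2], [2, 2]])
    K1 = compute_grm(base).K
    K2 = compute_grm(with_mono).K
    np.testing.assert_allclose(2 * K2, K1, atol=1e-12)


def test_grm_missing_imputed_to_variant_mean():
    panel = make_panel([[0.0], [np.nan], [2.0]])
    K = compute_grm(panel).K
    xc = np.array([-1.0, 0.0, 1.0])     # mean 1, missing -> centered 0
    np.testing.assert_allclose(K, np.outer(xc, xc), atol=1e-12)


def test_grm_symmetric_psd(small_screen):
    K = compute_grm(small_screen[0]).K
    np.testing.assert_allclose(K, K.T, atol=1e-10)
    assert np.linalg.eigvalsh(K).min() >= -1e-8 * np.trace(K)


def test_grm_all_monomorphic_rejected():
    with pytest.raises(ValidationError):
        compute_grm(make_panel(np.full((4, 3), 2.0)))


# -- LMM --------------------------------------------------------------------

def _ols(y, x):
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    sigma2 = resid @ resid / (len(y) - 2)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return coef[1], np.sqrt(cov[1, 1])


def test_identity_k_collapses_to_ols():
    rng = np.random.default_rng(42)
    n = 40
    x = rng.choice([0.0, 2.0], n)
    y = 5.0 + 0.8 * x + rng.normal(0, 1, n)
    K = RelatednessMatrix([f"L{i}" for i in range(n)], np.eye(n))
    fit = fit_lmm_variant(y, x, K)
    beta_ols, se_ols = _ols(y, x)
    assert fit["beta"] == pytest.approx(beta_ols, abs=1e-8)
    # chi2 Wald p vs the OLS t-test differ only through the reference
    # distribution; the statistics themselves agree
    assert fit["beta"] / fit["se"] == pytest.approx(beta_ols / se_ols,
                                                    rel=1e-6)


def test_lambda_zero_equals_ols_exactly():
    rng = np.random.default_rng(43)
    n = 25
    x = rng.choice([0.0, 2.0], n)
    y = rng.normal(0, 1, n)
    K = compute_grm(make_panel(rng.choice([0.0, 2.0], (n, 30))))
    fit = fit_lmm_variant(y, x, K, lambda_fixed=0.0)
    beta_ols, se_ols = _ols(y, x)
    assert fit["beta"] == pytest.approx(beta_ols, rel=1e-10)
    assert fit["se"] == pytest.approx(se_ols, rel=1e-10)


def test_fixed_lambda_matches_dense_gls_oracle():
    """n = 6 toy with lambda pinned at 2: beta equals brute-force
    (X'V^-1X)^-1 X'V^-1 y with V = 2K + I."""
    rng = np.random.default_rng(44)
    n = 6
    geno = rng.choice([0.0, 2.0], (n, 20))
    K = compute_grm(make_panel(geno))
    x = geno[:, 0]
    y = rng.normal(10, 2, n)
    fit = fit_lmm_variant(y, x, K, lambda_fixed=2.0)
    V = 2.0 * K.K + np.eye(n)
    Vi = np.linalg.inv(V)
    X = np.column_stack([np.ones(n), x])
    beta_gls = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    assert fit["beta"] == pytest.approx(beta_gls[1], abs=1e-8)
    assert fit["alpha"] == pytest.approx(beta_gls[0], abs=1e-8)


def test_coding_flip_negates_beta_keeps_p():
    rng = np.random.default_rng(45)
    n = 30
    geno = rng.choice([0.0, 2.0], (n, 50))
    K = compute_grm(make_panel(geno))
    x = geno[:, 3]
    y = rng.normal(100, 5, n) + 2 * x
    f1 = fit_lmm_variant(y, x, K)
    f2 = fit_lmm_variant(y, 2.0 - x, K)
    assert f2["beta"] == pytest.approx(-f1["beta"], rel=1e-6)
    assert f2["p_wald"] == pytest.approx(f1["p_wald"], rel=1e-6)


def test_constant_shift_changes_only_intercept():
    rng = np.random.default_rng(46)
    n = 30
    geno = rng.choice([0.0, 2.0], (n, 50))
    K = compute_grm(make_panel(geno))
    x = geno[:, 7]
    y = rng.normal(0, 1, n)
    f1 = fit_lmm_variant(y, x, K)
    f2 = fit_lmm_variant(y + 500.0, x, K)
    assert f2["beta"] == pytest.approx(f1["beta"], rel=1e-6, abs=1e-9)
    assert f2["se"] == pytest.approx(f1["se"], rel=1e-6)
    assert f2["alpha"] == pytest.approx(f1["alpha"] + 500.0, rel=1e-6)


def test_constant_genotype_rejected():
    K = RelatednessMatrix(["a", "b", "c"], np.eye(3))
    with pytest.raises(DegenerateVariantError):
        fit_lmm_variant(np.array([1.0, 2.0, 3.0]), np.full(3, 2.0), K)


def test_non_psd_k_rejected():
    bad = np.array([[1.0, 2.0], [2.0, 1.0]])   # eigenvalues 3, -1
    with pytest.raises(ValidationError):
        LMM(bad)


# -- run_gwas ---------------------------------------------------------------

def _strain_summary(line_ids, y):
    return pd.DataFrame({"line_id": line_ids, "n": 10, "mean_px": y,
                         "median_px": y, "sd_px": 1.0})


def test_gwas_recovers_strong_planted_signal():
    rng = np.random.default_rng(47)
    n, m = 60, 200
    geno = make_panel(rng.choice([0.0, 2.0], (n, m)))
    x = geno.calls[:, 17]
    y = 14000 + 800 * x + rng.normal(0, 100, n)
    assoc = run_gwas(_strain_summary(geno.line_ids, y), geno)
    assert assoc.loc[assoc["p_wald"].idxmin(), "variant_id"] == "v17"


def test_gwas_invariant_to_joint_line_relabeling():
    rng = np.random.default_rng(48)
    n, m = 40, 100
    geno = make_panel(rng.choice([0.0, 2.0], (n, m)))
    y = rng.normal(0, 1, n)
    K = compute_grm(geno)
    a1 = run_gwas(_strain_summary(geno.line_ids, y), geno, K, min_lines=10)
    perm = rng.permutation(n)
    geno2 = geno.subset_lines([geno.line_ids[i] for i in perm])
    a2 = run_gwas(_strain_summary(geno.line_ids, y), geno2, K, min_lines=10)
    # agreement limited by the lambda optimizer's 1e-6 tolerance under a
    # permuted eigendecomposition
    np.testing.assert_allclose(a1["beta"], a2["beta"], rtol=1e-6)
    np.testing.assert_allclose(a1["p_wald"], a2["p_wald"], rtol=1e-5)


def test_gwas_deterministic(small_screen):
    geno = small_screen[0]
    rng = np.random.default_rng(49)
    y = rng.normal(14000, 500, geno.n_lines)
    s = _strain_summary(geno.line_ids, y)
    a1 = run_gwas(s, geno)
    a2 = run_gwas(s, geno)
    pd.testing.assert_frame_equal(a1, a2)


def test_gwas_refuses_underpowered_join():
    rng = np.random.default_rng(50)
    geno = make_panel(rng.choice([0.0, 2.0], (10, 20)))
    with pytest.raises(ValidationError):
        run_gwas(_strain_summary(geno.line_ids, rng.normal(0, 1, 10)), geno)


# -- QQ / lambda_GC ---------------------------------------------------------

def test_lambda_gc_on_uniform_grid():
    m = 10_001
    p = (np.arange(1, m + 1)) / (m + 1)
    qq, lam = qq_diagnostics(p)
    assert lam == pytest.approx(1.0, abs=0.02)
    assert len(qq) == m


def test_lambda_gc_detects_inflation():
    """chi-square draws inflated x1.5 before p conversion show up as
    lambda_GC near 1.5."""
    rng = np.random.default_rng(51)
    chi2 = rng.chisquare(1, 200_000) * 1.5
    p = stats.chi2.sf(chi2, 1)
    _, lam = qq_diagnostics(p)
    assert lam == pytest.approx(1.5, abs=0.05)


def test_qq_rejects_tiny_input():
    with pytest.raises(ValidationError):
        qq_diagnostics(np.array([0.5]))
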