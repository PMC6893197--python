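"""Variant filtering, centered GRM, and linear-mixed-model association.

Model per variant, on the n strain means y:

    y = alpha + x * beta + u + eps
    u   ~ MVN_n(0, lambda * tau_inv * K)
    eps ~ MVN_n(0, tau_inv * I_n)

with K the centered marker-based relatedness matrix, ``lambda`` the ratio
of polygenic to residual variance and ``tau_inv`` the residual variance.
K is eigendecomposed once per scan; for each candidate ``lambda`` the
model rotates into the eigenbasis, weights observations by
``1 / (lambda * d_i + 1)`` and solves generalized least squares for
``(alpha, beta)``. ``lambda`` is maximized by
a 21-point grid on log10(lambda) in [-5, 5] followed by bounded Brent
refinement; the Wald p value compares ``(beta / se)^2`` to chi-square(1).
The genome scan estimates lambda under REML (the convention of the
standard mixed-model GWAS tools for Wald tests, and measurably better
calibrated here); plain ML is available behind the ``reml`` flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import DegenerateVariantError, ValidationError
from .types import ASSOC_COLUMNS, PanelGenotypes, RelatednessMatrix

log = logging.getLogger(__name__)

LOG10_LAMBDA_BOUNDS = (-5.0, 5.0)
GRID_POINTS = 21


@dataclass
class FilterReport:
    n_input: int
    n_non_biallelic: int
    n_high_missing: int
    n_low_maf: int
    n_retained: int


def filter_variants(geno: PanelGenotypes, maf_min: float = 0.05,
                    max_missing: float = 0.20
                    ) -> tuple[PanelGenotypes, FilterReport]:
    """Keep biallelic variants with missingness <= ``max_missing`` and
    sample MAF >= ``maf_min`` (computed over non-missing calls).

    Criteria are applied in order (biallelic, missingness, MAF); the
    report counts removals per criterion. An empty result is allowed.
    """
    bi = geno.is_biallelic()
    miss_ok = geno.missing_fraction() <= max_missing
    af = geno.allele_freq()
    with np.errstate(invalid="ignore"):
        maf = np.fmin(af, 1.0 - af)
    maf_ok = np.nan_to_num(maf, nan=0.0) >= maf_min

    n_non_bi = int((~bi).sum())
    n_miss = int((bi & ~miss_ok).sum())
    n_maf = int((bi & miss_ok & ~maf_ok).sum())
    keep = bi & miss_ok & maf_ok
    report = FilterReport(n_input=geno.n_variants, n_non_biallelic=n_non_bi,
                          n_high_missing=n_miss, n_low_maf=n_maf,
                          n_retained=int(keep.sum()))
    if report.n_retained == 0:
        log.warning("filter_variants: no variants survive filtering")
    return geno.subset_variants(keep), report


def compute_grm(geno: PanelGenotypes) -> RelatednessMatrix:
    """Centered genetic relatedness matrix.

    K = (1/p) * sum_k (x_k - xbar_k 1)(x_k - xbar_k 1)^T over the p
    variants, with missing calls imputed to the variant mean before
    centering, so a monomorphic variant contributes exactly zero.
    """
    if geno.n_variants < 1:
        raise ValidationError("need >= 1 variant for GRM")
    X = geno.calls
    col_mean = np.nanmean(np.where(np.isnan(X), np.nan, X), axis=0)
    Xc = np.where(np.isnan(X), 0.0, X - col_mean)
    if not np.any(Xc):
        raise ValidationError("all variants monomorphic; GRM undefined")
    K = (Xc @ Xc.T) / geno.n_variants
    K = (K + K.T) / 2.0
    return RelatednessMatrix(list(geno.line_ids), K)


class LMM:
    """Per-scan cache: eigendecomposition of K and rotated intercept."""

    def __init__(self, K: RelatednessMatrix | np.ndarray):
        Kmat = K.K if isinstance(K, RelatednessMatrix) else np.asarray(K)
        self.line_ids = K.line_ids if isinstance(K, RelatednessMatrix) else None
        if not np.allclose(Kmat, Kmat.T, atol=1e-8):
            raise ValidationError("K must be symmetric")
        d, U = np.linalg.eigh(Kmat)
        if d.min() < -1e-8 * max(np.trace(Kmat), 1.0):
            raise ValidationError("K must be positive semidefinite")
        self.d = np.clip(d, 0.0, None)
        self.U = U
        self.n = Kmat.shape[0]
        self.ones_rot = U.T @ np.ones(self.n)

    # -- likelihood machinery -------------------------------------------

    def _gls(self, yr: np.ndarray, Xr: np.ndarray, lam: float):
        """Weighted normal equations in the eigenbasis; returns
        (coef, rss, XtWX_inv)."""
        w = 1.0 / (lam * self.d + 1.0)
        XtW = Xr.T * w
        XtWX = XtW @ Xr
        XtWy = XtW @ yr
        XtWX_inv = np.linalg.inv(XtWX)
        coef = XtWX_inv @ XtWy
        resid = yr - Xr @ coef
        rss = float(np.sum(w * resid * resid))
        return coef, rss, XtWX_inv

    def _neg_loglik(self, log10_lam: float, yr, Xr, reml: bool) -> float:
        lam = 10.0 ** log10_lam
        n, c = self.n, Xr.shape[1]
        logdet = float(np.sum(np.log(lam * self.d + 1.0)))
        try:
            coef, rss, XtWX_inv = self._gls(yr, Xr, lam)
        except np.linalg.LinAlgError:
            return np.inf
        if rss <= 0:
            rss = 1e-300
        if reml:
            df = n - c
            _, ld_inv = np.linalg.slogdet(XtWX_inv)
            ll = -0.5 * (df * np.log(2 * np.pi * rss / df) + df
                         + logdet - ld_inv)
        else:
            ll = -0.5 * (n * np.log(2 * np.pi * rss / n) + n + logdet)
        return -ll

    def _optimize_lambda(self, yr, Xr, reml: bool) -> float:
        lo, hi = LOG10_LAMBDA_BOUNDS
        grid = np.linspace(lo, hi, GRID_POINTS)
        vals = [self._neg_loglik(g, yr, Xr, reml) for g in grid]
        i = int(np.argmin(vals))
        a = grid[max(i - 1, 0)]
        b = grid[min(i + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(
            self._neg_loglik, bounds=(a, b), args=(yr, Xr, reml),
            method="bounded", options={"xatol": 1e-6})
        best = res.x if res.fun <= vals[i] else grid[i]
        return float(best)

    # -- public fits -----------------------------------------------------

    def fit(self, y: np.ndarray, x: np.ndarray,
            lambda_fixed: float | None = None, reml: bool = False) -> dict:
        """Fit one variant; returns beta, se, lambda_hat, p_wald, alpha.

        ``lambda_fixed`` pins the variance ratio (0 gives exact OLS);
        otherwise lambda is optimized by grid + Brent under ML (or REML).
        """
        y = np.asarray(y, dtype=float)
        x = np.asarray(x, dtype=float)
        if y.shape != (self.n,) or x.shape != (self.n,):
            raise ValidationError("y, x must match K dimension")
        if np.ptp(x) == 0:
            raise DegenerateVariantError("constant genotype vector")
        yr = self.U.T @ y
        Xr = np.column_stack([self.ones_rot, self.U.T @ x])
        if lambda_fixed is not None:
            lam = float(lambda_fixed)
        else:
            lam = 10.0 ** self._optimize_lambda(yr, Xr, reml)
        coef, rss, XtWX_inv = self._gls(yr, Xr, lam)
        # unbiased residual-variance estimate (divisor n - c) for the se;
        # lambda itself is optimized under ML unless reml is set
        tau_inv_hat = rss / (self.n - 2)
        se = float(np.sqrt(tau_inv_hat * XtWX_inv[1, 1]))
        beta = float(coef[1])
        chi2 = (beta / se) ** 2 if se > 0 else np.inf
        p = float(stats.chi2.sf(chi2, df=1))
        return {"alpha": float(coef[0]), "beta": beta, "se": se,
                "lambda_hat": lam, "p_wald": max(p, 1e-300),
                "tau_inv_hat": tau_inv_hat}


def fit_lmm_variant(y: np.ndarray, x: np.ndarray,
                    K: RelatednessMatrix | np.ndarray,
                    lambda_fixed: float | None = None,
                    reml: bool = False) -> dict:
    """One-shot single-variant fit (eigendecomposes K; see :class:`LMM`)."""
    return LMM(K).fit(y, x, lambda_fixed=lambda_fixed, reml=reml)


def run_gwas(pheno_summary: pd.DataFrame, geno: PanelGenotypes,
             K: RelatednessMatrix | None = None, statistic: str = "mean",
             min_lines: int = 30, reml: bool = True) -> pd.DataFrame:
    """Scan every variant of the panel against the strain means.

    Lines are inner-joined across phenotype summary, genotypes and K;
    missing genotypes are mean-imputed so n stays constant across
    variants. Variants constant after the join get an NA row (they
    cannot be tested). Deterministic given inputs.
    """
    col = {"mean": "mean_px", "median": "median_px"}[statistic]
    pheno_lines = list(pheno_summary["line_id"])
    shared = [l for l in geno.line_ids if l in set(pheno_lines)]
    if K is not None:
        shared = [l for l in shared if l in set(K.line_ids)]
    if len(shared) < min_lines:
        raise ValidationError(
            f"only {len(shared)} lines shared across phenotype/genotype/K; "
            f"need >= {min_lines}")
    sub = geno.subset_lines(shared)
    if K is None:
        K = compute_grm(sub)
    else:
        K = K.subset(shared)
    y = (pheno_summary.set_index("line_id").loc[shared, col]
         .to_numpy(dtype=float))
    model = LMM(K)

    X = sub.calls
    col_mean = np.nanmean(X, axis=0)
    rows = []
    for k in range(sub.n_variants):
        x = X[:, k]
        n_obs = int(np.sum(~np.isnan(x)))
        af = float(np.nanmean(x) / 2.0) if n_obs else np.nan
        x = np.where(np.isnan(x), col_mean[k], x)
        meta = sub.variants.iloc[k]
        try:
            fit = model.fit(y, x, reml=reml)
            rows.append((meta["chrom"], meta["pos"], meta["variant_id"],
                         n_obs, af, fit["beta"], fit["se"],
                         fit["lambda_hat"], fit["p_wald"]))
        except DegenerateVariantError:
            rows.append((meta["chrom"], meta["pos"], meta["variant_id"],
                         n_obs, af, np.nan, np.nan, np.nan, np.nan))
    return pd.DataFrame(rows, columns=ASSOC_COLUMNS)


def qq_diagnostics(results: pd.DataFrame | np.ndarray
                   ) -> tuple[pd.DataFrame, float]:
    """QQ data and the genomic-inflation factor lambda_GC.

    Expected quantiles are ``-log10((i - 0.5) / m)`` for the m sorted p
    values; lambda_GC is the median chi-square(1) quantile of the observed
    p values divided by 0.4549 (the null median).
    """
    if isinstance(results, pd.DataFrame):
        p = results["p_wald"].to_numpy(dtype=float)
    else:
        p = np.asarray(results, dtype=float)
    p = p[~np.isnan(p)]
    m = len(p)
    if m < 10:
        raise ValidationError(f"need >= 10 p values for QQ, have {m}")
    obs = np.sort(p)
    expected = (np.arange(1, m + 1) - 0.5) / m
    qq = pd.DataFrame({
        "expected_neglog10p": -np.log10(expected),
        "observed_neglog10p": -np.log10(np.clip(obs, 1e-300, 1.0)),
    })
    lam_gc = float(np.median(stats.chi2.isf(p, df=1)) / 0.4549)
    return qq, lam_gc
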