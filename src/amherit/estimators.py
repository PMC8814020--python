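"""Marker-based heritability estimators: HE regression, single-component REML, LDSC.

The three estimator families the package studies are exposed as
scikit-learn-style estimator classes (``fit`` + trailing-underscore fitted
attributes + ``get_params``/``set_params``), with plain functions provided as
thin wrappers.  All operate on a genomic relatedness matrix (GRM)
``A = Z Z^T / m`` over standardized genotypes, or on the genotype matrix
itself for LD-score regression.

* ``HERegression`` - Haseman-Elston regression: the slope of the strictly
  sub-diagonal entries of the phenotypic outer product on the sub-diagonal
  GRM entries (optionally multiple component GRMs jointly).
* ``REML`` - residual maximum likelihood for a single genetic variance
  component, maximizing the profile likelihood on the covariate-orthogonal
  complement via one eigendecomposition.
* ``LDScoreRegression`` - regression of per-SNP association chi-square
  statistics on in-sample LD scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator

__all__ = [
    "GRM",
    "HeritabilityEstimate",
    "REMLFit",
    "HERegression",
    "REML",
    "LDScoreRegression",
    "compute_grm",
    "he_regression",
    "reml_single",
    "ldsc_regression",
    "marginal_chi2",
    "pc_covariates",
    "ld_scores",
    "partition_snps",
    "residualize",
]


@dataclass
class GRM:
    """Genomic relatedness matrix ``Z Z^T / m_used`` with bookkeeping."""

    n: int
    values: np.ndarray
    m_used: int
    ids: np.ndarray = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.n, self.n):
            raise ValueError("GRM values must be n x n")
        if self.ids is None:
            self.ids = np.arange(self.n)


@dataclass
class HeritabilityEstimate:
    method: str
    point: float
    se: float
    n: int
    components: dict = None
    converged: bool = True
    boundary: bool = False
    se_ols: float = None
    intercept: float = None
    n_pairs: int = None


@dataclass
class REMLFit:
    sigma_g_sq: float
    sigma_e_sq: float
    loglik: float
    h_sq: float
    n_eigen: int
    se: float = None
    boundary: bool = False
    identifiable: bool = True
    converged: bool = True


def compute_grm(genotypes: np.ndarray, drop_monomorphic: bool = True, ids=None):
    """Standardize allele counts and form the GRM.

    Columns are centered by twice the within-sample allele frequency and
    scaled by ``sqrt(2 f (1-f))``; monomorphic columns are dropped (and
    counted out of ``m_used``).  Returns ``(GRM, Z)`` where Z is the
    standardized matrix actually used.
    """
    G = np.asarray(genotypes, dtype=float)
    if G.ndim != 2 or G.shape[0] < 2:
        raise ValueError("genotype matrix must be 2-D with n >= 2 individuals")
    poly = G.var(axis=0) > 0
    if not poly.any():
        raise ValueError("all genotype columns are monomorphic")
    if drop_monomorphic:
        G = G[:, poly]
    f = G.mean(axis=0) / 2.0
    f = np.clip(f, 1e-12, 1 - 1e-12)
    m = G.shape[1]
    Z = (G - 2.0 * f) / np.sqrt(2.0 * f * (1.0 - f))
    A = (Z @ Z.T) / m
    return GRM(n=G.shape[0], values=A, m_used=m, ids=ids), Z


def _standardize(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    sd = y.std()
    if sd == 0:
        raise ValueError("phenotype has zero variance")
    return (y - y.mean()) / sd


def _as_matrix_list(grms):
    if isinstance(grms, (GRM, np.ndarray)):
        grms = [grms]
    return [np.asarray(getattr(g, "values", g), dtype=float) for g in grms]


def _row_xy(A, yt):
    """Per-individual contribution to sum_{i<j} x_ij * y_i y_j (x = A or ones)."""
    if A is None:
        return yt * (yt.sum() - yt)
    return yt * (A @ yt - np.diag(A) * yt)


def _row_xx(A, B, n):
    if A is None and B is None:
        return np.full(n, float(n - 1))
    if A is None:
        A, B = B, A
    if B is None:
        return A.sum(axis=1) - np.diag(A)
    return (A * B).sum(axis=1) - np.diag(A) * np.diag(B)


class HERegression(BaseEstimator):
    """Haseman-Elston regression over sub-diagonal GRM entries.

    Parameters
    ----------
    intercept : bool
        Include an intercept alongside the GRM regressor(s).  The default
        (False) regresses through the origin, appropriate for a standardized
        phenotype.
    standardize : bool
        Residualize on covariates (if given) and scale the phenotype to unit
        variance before forming pairwise products.
    se_method : {"jackknife", "ols"}
        Primary standard error.  The delete-one-individual jackknife is the
        default (grouped into ``n_blocks`` blocks above ``block_threshold``
        individuals); the naive OLS standard error is always reported
        alongside as ``se_ols_``.
    """

    def __init__(
        self,
        intercept: bool = False,
        standardize: bool = True,
        se_method: str = "jackknife",
        n_blocks: int = 100,
        block_threshold: int = 5000,
    ):
        self.intercept = intercept
        self.standardize = standardize
        self.se_method = se_method
        self.n_blocks = n_blocks
        self.block_threshold = block_threshold

    def fit(self, grms, y, covariates: np.ndarray = None):
        mats = _as_matrix_list(grms)
        n = mats[0].shape[0]
        if n < 2:
            raise ValueError("HE regression needs at least 2 individuals")
        yt = np.asarray(y, dtype=float)
        if self.standardize:
            if covariates is not None:
                yt, _ = residualize(yt, None, covariates)
            else:
                yt = _standardize(yt)

        regs = ([None] if self.intercept else []) + mats
        k = len(regs)
        rows_xy = np.stack([_row_xy(A, yt) for A in regs])  # (k, n)
        rows_xx = np.empty((k, k, n))
        for a in range(k):
            for b in range(a, k):
                rows_xx[a, b] = rows_xx[b, a] = _row_xx(regs[a], regs[b], n)
        XtY = 0.5 * rows_xy.sum(axis=1)
        XtX = 0.5 * rows_xx.sum(axis=2)
        cond = np.linalg.cond(XtX)
        if not np.isfinite(cond) or cond > 1e12:
            raise ValueError("collinear component regressors in HE regression")
        beta = np.linalg.solve(XtX, XtY)

        comp_slice = slice(1, None) if self.intercept else slice(None)
        point = float(beta[comp_slice].sum())

        # naive OLS standard error
        n_pairs = n * (n - 1) // 2
        yy2 = yt**2
        Syy = 0.5 * float((yy2 * (yy2.sum() - yy2)).sum())
        sse = Syy - 2.0 * beta @ XtY + beta @ XtX @ beta
        dof = max(n_pairs - k, 1)
        cov_ols = np.linalg.inv(XtX) * max(sse, 0.0) / dof
        w = np.zeros(k)
        w[comp_slice] = 1.0
        se_ols = float(np.sqrt(w @ cov_ols @ w))

        se_jack = self._jackknife_se(regs, yt, rows_xy, rows_xx, XtX, XtY, w)
        se = se_jack if self.se_method == "jackknife" else se_ols

        components = None
        if len(mats) > 1:
            components = {
                f"component_{c}": float(beta[comp_slice][c]) for c in range(len(mats))
            }

        self.h2_ = point
        self.se_ = se
        self.se_ols_ = se_ols
        self.coef_ = beta
        self.n_ = n
        self.estimate_ = HeritabilityEstimate(
            method="HE",
            point=point,
            se=se,
            n=n,
            components=components,
            se_ols=se_ols,
            intercept=float(beta[0]) if self.intercept else None,
            n_pairs=n_pairs,
        )
        return self

    def _jackknife_se(self, regs, yt, rows_xy, rows_xx, XtX, XtY, w):
        n = yt.size
        if n > self.block_threshold:
            blocks = np.array_split(np.arange(n), self.n_blocks)
        else:
            blocks = [np.array([i]) for i in range(n)]
        g = len(blocks)
        thetas = np.empty(g)
        for b, idx in enumerate(blocks):
            xy = XtY - rows_xy[:, idx].sum(axis=1)
            xx = XtX - rows_xx[:, :, idx].sum(axis=2)
            if idx.size > 1:
                # pairs with both ends inside the deleted block were
                # subtracted twice; add their contribution back once
                ys = yt[idx]
                for a, A in enumerate(regs):
                    sub = (
                        np.ones((idx.size, idx.size))
                        if A is None
                        else A[np.ix_(idx, idx)]
                    )
                    np.fill_diagonal(sub, 0.0)
                    xy[a] += 0.5 * float(ys @ sub @ ys)
                    for c, B in enumerate(regs):
                        subB = (
                            np.ones((idx.size, idx.size))
                            if B is None
                            else B[np.ix_(idx, idx)]
                        )
                        np.fill_diagonal(subB, 0.0)
                        xx[a, c] += 0.5 * float((sub * subB).sum())
            try:
                beta_b = np.linalg.solve(xx, xy)
            except np.linalg.LinAlgError:
                beta_b = np.full(len(regs), np.nan)
            thetas[b] = w @ beta_b
        thetas = thetas[np.isfinite(thetas)]
        g = thetas.size
        if g < 2:
            return np.nan
        return float(np.sqrt((g - 1) / g * ((thetas - thetas.mean()) ** 2).sum()))


class REML(BaseEstimator):
    """Single-component REML on the covariate-orthogonal complement.

    Projects out the covariates (an intercept is always included),
    eigendecomposes the projected GRM once, and maximizes the profile
    residual log-likelihood over ``h^2`` in ``bounds`` by bounded scalar
    optimization.  Estimates at an endpoint raise the ``boundary_`` flag; a
    GRM whose projected spectrum is (numerically) flat is unidentifiable and
    flagged as such.
    """

    def __init__(self, bounds=(0.0, 1.0 - 1e-6), tol: float = 1e-8):
        self.bounds = bounds
        self.tol = tol

    def fit(self, grm, y, covariates: np.ndarray = None):
        A = np.asarray(getattr(grm, "values", grm), dtype=float)
        y = np.asarray(y, dtype=float)
        n = y.size
        X = np.ones((n, 1))
        if covariates is not None:
            C = np.atleast_2d(np.asarray(covariates, dtype=float))
            if C.shape[0] != n:
                C = C.T
            X = np.column_stack([X, C])
            if np.linalg.matrix_rank(X) < X.shape[1]:
                raise ValueError("covariate matrix is rank deficient")
        c = X.shape[1]
        q = n - c
        # project onto the covariate-orthogonal complement and deflate col(X)
        # to eigenvalue -1 so its c eigenpairs separate exactly from the
        # (possibly rank-deficient) genuine spectrum
        Q, _ = np.linalg.qr(X)
        AQ = A @ Q
        QtAQ = Q.T @ AQ
        B = A - Q @ AQ.T - AQ @ Q.T + Q @ (QtAQ @ Q.T) - Q @ Q.T
        B = 0.5 * (B + B.T)
        lam_all, U = np.linalg.eigh(B)
        lam, U = lam_all[c:], U[:, c:]
        scale = max(1.0, float(lam.max(initial=1.0)))
        if lam.min() < -1e-6 * scale:
            raise ValueError(
                f"projected GRM is not positive semidefinite (min eig {lam.min():.3g})"
            )
        lam = np.clip(lam, 0.0, None)
        yt = U.T @ y  # U columns are orthogonal to col(X)
        yt2 = yt**2

        if lam.max() - lam.min() < 1e-8:
            # GRM ~ identity on the complement: likelihood depends only on
            # sigma_g^2 + sigma_e^2
            total = float(yt2.sum() / q)
            self.fit_ = REMLFit(
                sigma_g_sq=np.nan,
                sigma_e_sq=np.nan,
                loglik=np.nan,
                h_sq=np.nan,
                n_eigen=q,
                identifiable=False,
            )
            self.h2_ = np.nan
            self.total_variance_ = total
            return self

        def neg_profile(h):
            V = h * lam + (1.0 - h)
            return float(np.log(V).sum() + q * np.log((yt2 / V).sum()))

        lo, hi = self.bounds
        res = minimize_scalar(
            neg_profile, bounds=(lo, hi), method="bounded",
            options={"xatol": self.tol},
        )
        candidates = [(neg_profile(lo), lo), (neg_profile(hi), hi)]
        if res.success:
            candidates.append((res.fun, float(res.x)))
        fval, h = min(candidates)
        boundary = h <= lo + 10 * self.tol or h >= hi - 10 * self.tol

        V = h * lam + (1.0 - h)
        sigma_p = float((yt2 / V).sum() / q)
        sigma_g, sigma_e = h * sigma_p, (1.0 - h) * sigma_p
        loglik = -0.5 * (
            q * np.log(sigma_p) + np.log(V).sum() + q + q * np.log(2.0 * np.pi)
        )

        se = np.nan
        if not boundary:
            se = self._observed_info_se(lam, yt2, sigma_g, sigma_e)

        self.fit_ = REMLFit(
            sigma_g_sq=sigma_g,
            sigma_e_sq=sigma_e,
            loglik=float(loglik),
            h_sq=float(h),
            n_eigen=q,
            se=se,
            boundary=bool(boundary),
            converged=bool(res.success),
        )
        self.h2_ = float(h)
        self.se_ = se
        self.boundary_ = bool(boundary)
        return self

    @staticmethod
    def _observed_info_se(lam, yt2, sigma_g, sigma_e):
        V = sigma_g * lam + sigma_e
        c = np.stack([lam, np.ones_like(lam)])  # dV/d(sigma_g), dV/d(sigma_e)
        H = np.empty((2, 2))
        for a in range(2):
            for b in range(2):
                H[a, b] = -0.5 * (
                    -np.sum(c[a] * c[b] / V**2) + 2.0 * np.sum(yt2 * c[a] * c[b] / V**3)
                )
        info = -H
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            return np.nan
        tot = sigma_g + sigma_e
        grad = np.array([sigma_e, -sigma_g]) / tot**2
        var = float(grad @ cov @ grad)
        return float(np.sqrt(var)) if var > 0 else np.nan


def marginal_chi2(genotypes: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-SNP association chi-square, ``n * r_jy^2`` on standardized data."""
    Z = np.asarray(genotypes, dtype=float)
    n = Z.shape[0]
    sd = Z.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("monomorphic columns have no association statistic")
    Zs = (Z - Z.mean(axis=0)) / sd
    yt = _standardize(y)
    r = (Zs.T @ yt) / n
    return n * r**2


class LDScoreRegression(BaseEstimator):
    """LD score regression: chi-square statistics on in-sample LD scores.

    ``chi2_j = n * r_jy^2`` is regressed on the LD score ``l_j`` by weighted
    least squares (default weights ``1 / l_j``) with a free intercept;
    ``h2 = slope * M / n``.
    """

    def __init__(self, weights: str = "1/ld"):
        self.weights = weights

    def fit(self, genotypes, y, ld_scores, M: int = None):
        Z = np.asarray(genotypes, dtype=float)
        ell = np.asarray(ld_scores, dtype=float)
        n, p = Z.shape
        if ell.size != p:
            raise ValueError("one LD score per SNP required")
        if np.ptp(ell) < 1e-12:
            raise ValueError("degenerate (constant) LD scores")
        M = p if M is None else M
        chi2 = marginal_chi2(Z, y)
        w = 1.0 / ell if self.weights == "1/ld" else np.ones(p)
        design = sm.add_constant(ell)
        res = sm.WLS(chi2, design, weights=w).fit()
        slope = float(res.params[1])
        self.intercept_ = float(res.params[0])
        self.h2_ = slope * M / n
        self.se_ = float(res.bse[1]) * M / n
        self.n_ = n
        self.estimate_ = HeritabilityEstimate(
            method="LDSC",
            point=self.h2_,
            se=self.se_,
            n=n,
            intercept=self.intercept_,
        )
        return self


def he_regression(grms, y, covariates=None, **kwargs) -> HeritabilityEstimate:
    """Functional wrapper around :class:`HERegression`."""
    return HERegression(**kwargs).fit(grms, y, covariates=covariates).estimate_


def reml_single(grm, y, covariates=None, bounds=(0.0, 1.0 - 1e-6), tol=1e-8) -> REMLFit:
    """Functional wrapper around :class:`REML`."""
    return REML(bounds=bounds, tol=tol).fit(grm, y, covariates=covariates).fit_


def ldsc_regression(genotypes, y, ld_scores, n=None, M=None) -> HeritabilityEstimate:
    """Functional wrapper around :class:`LDScoreRegression`."""
    return LDScoreRegression().fit(genotypes, y, ld_scores, M=M).estimate_


def pc_covariates(grm, k: int) -> np.ndarray:
    """Top-k eigenvectors of the GRM, orthonormal, by descending eigenvalue."""
    A = np.asarray(getattr(grm, "values", grm), dtype=float)
    n = A.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than n={n}")
    lam, U = np.linalg.eigh(A)
    return U[:, ::-1][:, :k]


def ld_scores(
    genotypes: np.ndarray,
    map_cm: np.ndarray = None,
    chrom: np.ndarray = None,
    window_cm: float = 1.0,
    window_snps: int = None,
) -> np.ndarray:
    """Per-SNP LD scores: sum of sample r^2 within a sliding map window.

    The window spans ``window_cm`` centiMorgans on each side of the focal
    SNP (including the SNP itself, whose r^2 with itself is 1).  With no
    genetic map, a symmetric window of ``window_snps`` SNPs on each side is
    used instead.
    """
    Z = np.asarray(genotypes, dtype=float)
    n, p = Z.shape
    sd = Z.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("monomorphic columns cannot be scored")
    Zs = (Z - Z.mean(axis=0)) / sd
    if map_cm is None and window_snps is None:
        raise ValueError("need a genetic map or a SNP-count window")
    if map_cm is not None:
        map_cm = np.asarray(map_cm, dtype=float)
        if np.any(~np.isfinite(map_cm)):
            raise ValueError("unmapped SNPs (non-finite map positions)")
        if window_cm <= 0:
            raise ValueError("window_cm must be positive")
    chrom = np.zeros(p, dtype=int) if chrom is None else np.asarray(chrom)

    ell = np.empty(p)
    for c in np.unique(chrom):
        sel = np.flatnonzero(chrom == c)
        if map_cm is not None:
            order = sel[np.argsort(map_cm[sel], kind="stable")]
            cm = map_cm[order]
            lo = np.searchsorted(cm, cm - window_cm, side="left")
            hi = np.searchsorted(cm, cm + window_cm, side="right")
        else:
            order = sel
            idx = np.arange(order.size)
            lo = np.maximum(idx - window_snps, 0)
            hi = np.minimum(idx + window_snps + 1, order.size)
        Zc = Zs[:, order]
        for j in range(order.size):
            block = Zc[:, lo[j] : hi[j]]
            r = (Zc[:, j] @ block) / n
            ell[order[j]] = float((r**2).sum())
    return ell


def partition_snps(allele_freqs: np.ndarray, ld_scores: np.ndarray) -> list:
    """2x2 partition of SNPs by median MAF and median LD score.

    Ties go to the lower bin.  Returns four disjoint, exhaustive index sets
    ordered (low MAF, low LD), (low MAF, high LD), (high MAF, low LD),
    (high MAF, high LD).
    """
    f = np.asarray(allele_freqs, dtype=float)
    ell = np.asarray(ld_scores, dtype=float)
    if f.size != ell.size:
        raise ValueError("allele_freqs and ld_scores must have the same length")
    maf = np.minimum(f, 1.0 - f)
    low_maf = maf <= np.median(maf)
    low_ld = ell <= np.median(ell)
    sets = [
        np.flatnonzero(low_maf & low_ld),
        np.flatnonzero(low_maf & ~low_ld),
        np.flatnonzero(~low_maf & low_ld),
        np.flatnonzero(~low_maf & ~low_ld),
    ]
    if any(s.size == 0 for s in sets):
        warnings.warn(
            "degenerate median split: one or more annotation sets are empty",
            stacklevel=2,
        )
    return sets


def residualize(y: np.ndarray, genotypes: np.ndarray, covariates: np.ndarray):
    """Replace phenotype (and genotype columns) by standardized covariate residuals.

    Both outputs are re-standardized; adjusted genotypes become continuous
    dosages.  Heritability estimates downstream are invariant to any
    invertible affine transform of the covariate matrix.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(covariates, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    X = np.column_stack([np.ones(y.size), X]) if not _has_intercept(X) else X
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    Q, _ = np.linalg.qr(X)

    def _resid(v):
        return v - Q @ (Q.T @ v)

    y_adj = _standardize(_resid(y))
    G_adj = None
    if genotypes is not None:
        G = np.asarray(genotypes, dtype=float)
        G_adj = _resid(G)
        sd = G_adj.std(axis=0)
        sd[sd == 0] = 1.0
        G_adj = G_adj / sd
    return y_adj, G_adj


def _has_intercept(X: np.ndarray) -> bool:
    return any(np.ptp(X[:, j]) == 0 and X[0, j] != 0 for j in range(X.shape[1]))
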