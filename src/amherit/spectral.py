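"""Marchenko-Pastur reference law and GRM spectral diagnostics.

The eigenvalue distribution of a GRM built from n individuals and m
independent standardized variants converges, as n, m -> infinity with
n/m -> c, to the Marchenko-Pastur (MP) law with aspect ratio c: an
absolutely continuous bulk on [(1-sqrt(c))^2, (1+sqrt(c))^2] plus a point
mass 1 - 1/c at zero when c > 1.  Assortative mating perturbs the causal
covariance by a low-rank term, which can detach at most a bounded number of
eigenvalues from the bulk but leaves the limiting spectral distribution --
and hence the asymptotic behavior of REML -- unchanged.  This module
provides the law, empirical spectral distributions, and Kolmogorov-Smirnov
distances between them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MPLaw", "SpectralDistribution", "mp_density", "mp_cdf", "esd", "ks_distance"]


@dataclass(frozen=True)
class MPLaw:
    """Marchenko-Pastur law with aspect ratio c = n/m."""

    c: float

    def __post_init__(self):
        if self.c <= 0:
            raise ValueError(f"aspect ratio c must be positive, got {self.c}")

    @property
    def support(self) -> tuple:
        s = np.sqrt(self.c)
        return ((1.0 - s) ** 2, (1.0 + s) ** 2)

    @property
    def point_mass_at_zero(self) -> float:
        return max(0.0, 1.0 - 1.0 / self.c)

    def density(self, lam) -> np.ndarray:
        lam = np.asarray(lam, dtype=float)
        a, b = self.support
        out = np.zeros_like(lam)
        inside = (lam > a) & (lam < b) & (lam > 0)
        x = lam[inside]
        out[inside] = np.sqrt((b - x) * (x - a)) / (2.0 * np.pi * self.c * x)
        return out if out.ndim else float(out)

    def cdf(self, lam) -> np.ndarray:
        """CDF of the law (bulk integrated numerically, edges analytic)."""
        lam = np.atleast_1d(np.asarray(lam, dtype=float))
        a, b = self.support
        grid = np.linspace(a, b, 4001)
        dens = self.density(grid)
        bulk_mass = 1.0 - self.point_mass_at_zero
        cum = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) * 0.5 * np.diff(grid))])
        if cum[-1] > 0:
            cum = cum * ((bulk_mass) / cum[-1])  # normalize quadrature error
        out = np.interp(lam, grid, cum, left=0.0, right=bulk_mass)
        out = out + self.point_mass_at_zero * (lam >= 0)
        out[lam < a] = np.where(lam[lam < a] >= 0, self.point_mass_at_zero, 0.0)
        out[lam >= b] = 1.0
        return out if out.size > 1 else float(out[0])


def mp_density(lam, c: float):
    """Marchenko-Pastur density at ``lam`` for aspect ratio ``c``."""
    return MPLaw(c).density(lam)


def mp_cdf(lam, c: float):
    """Marchenko-Pastur CDF at ``lam`` for aspect ratio ``c``."""
    return MPLaw(c).cdf(lam)


@dataclass(frozen=True)
class SpectralDistribution:
    """Sorted eigenvalues of a GRM."""

    eigenvalues: np.ndarray
    n: int
    m_used: int = None


def esd(grm, symmetry_tol: float = 1e-8) -> SpectralDistribution:
    """Empirical spectral distribution (full sorted eigenvalue set) of a GRM."""
    A = np.asarray(getattr(grm, "values", grm), dtype=float)
    scale = max(1.0, float(np.abs(A).max()))
    if np.abs(A - A.T).max() > symmetry_tol * scale:
        raise ValueError("GRM is not symmetric within tolerance")
    lam = np.linalg.eigvalsh(0.5 * (A + A.T))
    if lam.min() < -1e-8 * scale:
        raise ValueError(f"GRM has a negative eigenvalue ({lam.min():.3g})")
    return SpectralDistribution(
        eigenvalues=np.sort(lam),
        n=A.shape[0],
        m_used=getattr(grm, "m_used", None),
    )


def _bulk(values: np.ndarray, exclude_top: bool) -> np.ndarray:
    return values[:-1] if (exclude_top and values.size > 1) else values


def ks_distance(dist_a, dist_b, exclude_top: bool = True) -> float:
    """Kolmogorov-Smirnov distance between spectral distributions.

    Accepts any mix of :class:`SpectralDistribution` and :class:`MPLaw`.
    By default the single largest eigenvalue of each empirical input is
    excluded: the low-rank equilibrium perturbation can detach one outlier
    without affecting the bulk the comparison targets.
    """
    emp_a = isinstance(dist_a, SpectralDistribution)
    emp_b = isinstance(dist_b, SpectralDistribution)
    if emp_a and emp_b:
        x = np.sort(_bulk(dist_a.eigenvalues, exclude_top))
        y = np.sort(_bulk(dist_b.eigenvalues, exclude_top))
        both = np.concatenate([x, y])
        cdf_x = np.searchsorted(x, both, side="right") / x.size
        cdf_y = np.searchsorted(y, both, side="right") / y.size
        return float(np.abs(cdf_x - cdf_y).max())
    if emp_a != emp_b:
        emp = dist_a if emp_a else dist_b
        law = dist_b if emp_a else dist_a
        lam = np.sort(_bulk(emp.eigenvalues, exclude_top))
        if lam.size == 0:
            raise ValueError("empty spectral distribution")
        F = np.atleast_1d(law.cdf(lam))
        n = lam.size
        upper = np.arange(1, n + 1) / n - F
        lower = F - np.arange(0, n) / n
        return float(max(upper.max(), lower.max()))
    raise ValueError("at least one input must be an empirical spectral distribution")
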