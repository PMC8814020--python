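"""Closed-form theory for heritability under primary phenotypic assortative mating.

Under Fisher's classical model of primary phenotypic assortment, mate choice
with phenotypic correlation ``r`` induces positive correlations between
trait-increasing allele counts at causal loci genome-wide.  Genetic variance
rises across generations from its panmictic value ``V_g0`` toward a stable
equilibrium ``V_g_inf = V_g0 / (1 - r * h_inf_sq)``, and the narrow-sense
heritability rises from ``h0_sq`` to ``h_inf_sq``.

This module provides:

* the equilibrium fixed point and the generation-by-generation variance
  recursion;
* the expected value of the Haseman-Elston (HE) regression estimator at
  equilibrium, both in its general quadratic-form expression and in the
  exchangeable-loci approximation ``h_inf_sq / (1 - r * h_inf_sq)``;
* corrected estimators of the equilibrium and panmictic heritabilities from
  an observed HE estimate and a known spousal correlation, together with
  disequilibrium bounds;
* construction and empirical estimation of the equilibrium causal-variant
  covariance matrix Upsilon_inf = D + 2 * phi phi^T.

All heritabilities are dimensionless proportions of phenotypic variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AMModelParams",
    "EquilibriumSolution",
    "VarianceTrajectory",
    "CausalCovariance",
    "CorrectedEstimates",
    "DisequilibriumBounds",
    "EquilibriumConvergenceError",
    "solve_equilibrium",
    "equilibrium_closed_form",
    "variance_trajectory",
    "expected_he_exchangeable",
    "expected_he_general",
    "corrected_h_inf",
    "corrected_h0",
    "corrected_estimates",
    "disequilibrium_bounds",
    "build_upsilon_equilibrium",
    "estimate_upsilon",
]


class EquilibriumConvergenceError(RuntimeError):
    """Fixed-point iteration failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_iterate: float):
        super().__init__(message)
        self.last_iterate = last_iterate


@dataclass(frozen=True)
class AMModelParams:
    """Parameters of the assortative-mating model.

    Parameters
    ----------
    h0_sq : float
        Panmictic (random-mating) narrow-sense heritability, in [0, 1].
    r : float
        Phenotypic correlation between mates, in [0, 1).
    V_g0 : float, optional
        Panmictic additive genetic variance.  Defaults to ``h0_sq`` so that
        the panmictic phenotypic variance is 1.
    V_e : float, optional
        Environmental variance.  Defaults to ``1 - h0_sq``.
    """

    h0_sq: float
    r: float
    V_g0: float = None  # type: ignore[assignment]
    V_e: float = None  # type: ignore[assignment]

    def __post_init__(self):
        if not 0.0 <= self.h0_sq <= 1.0:
            raise ValueError(f"h0_sq must lie in [0, 1], got {self.h0_sq}")
        if not 0.0 <= self.r < 1.0:
            raise ValueError(f"r must lie in [0, 1), got {self.r}")
        if self.V_g0 is None:
            object.__setattr__(self, "V_g0", float(self.h0_sq))
        if self.V_e is None:
            object.__setattr__(self, "V_e", float(1.0 - self.h0_sq))
        if self.V_g0 < 0 or self.V_e < 0:
            raise ValueError("variance components must be non-negative")
        total = self.V_g0 + self.V_e
        if total > 0 and abs(self.V_g0 / total - self.h0_sq) > 1e-8:
            raise ValueError(
                "inconsistent parameters: h0_sq must equal V_g0 / (V_g0 + V_e)"
            )


@dataclass(frozen=True)
class EquilibriumSolution:
    """Equilibrium heritability and genetic variance under sustained AM."""

    h_inf_sq: float
    V_g_inf: float
    n_iterations: int


@dataclass(frozen=True)
class VarianceTrajectory:
    """Per-generation genetic variance and heritability under the AM recursion."""

    generations: np.ndarray
    V_g: np.ndarray
    h_sq: np.ndarray


@dataclass(frozen=True)
class CausalCovariance:
    """The m x m covariance/correlation matrix among standardized causal variants.

    ``source`` tags provenance: "identity" (panmictic, independent loci),
    "rank_one_equilibrium" (constructed D + 2*phi*phi^T), or "empirical"
    (sample correlation matrix).
    """

    m: int
    matrix: np.ndarray
    source: str

    def __post_init__(self):
        mat = np.asarray(self.matrix, dtype=float)
        if mat.shape != (self.m, self.m):
            raise ValueError(f"matrix must be {self.m}x{self.m}, got {mat.shape}")
        if not np.allclose(mat, mat.T, atol=1e-10):
            raise ValueError("causal covariance matrix must be symmetric")
        if self.source != "empirical" and not np.allclose(np.diag(mat), 1.0, atol=1e-8):
            raise ValueError("causal covariance matrix must have unit diagonal")
        object.__setattr__(self, "matrix", mat)


@dataclass(frozen=True)
class CorrectedEstimates:
    """HE estimate with its equilibrium- and panmixis-corrected counterparts."""

    h_he_sq: float
    r: float
    h_inf_hat: float
    h0_hat: float
    inflation_ratio: float
    se_h_inf: float = None  # type: ignore[assignment]
    se_h0: float = None  # type: ignore[assignment]


@dataclass(frozen=True)
class DisequilibriumBounds:
    """Probabilistic intervals for the current-generation and panmictic h2."""

    current: tuple
    panmictic: tuple


def _check_heritability_input(value: float, name: str) -> float:
    value = float(value)
    if value < 0.0 or value > 1.0:
        warnings.warn(
            f"{name}={value} lies outside [0, 1]; passing through uncorrected "
            "(estimates are never clamped)",
            stacklevel=3,
        )
    return value


def equilibrium_closed_form(params: AMModelParams) -> float:
    """Closed-form equilibrium heritability.

    Eliminating V from ``h = V/(V+V_e)`` and ``V = V_g0/(1 - r h)`` gives the
    quadratic ``r V_e h^2 - (V_e + V_g0) h + V_g0 = 0``; the root in [0, 1]
    is the equilibrium heritability.  Serves as the cross-check for the
    fixed-point solver.
    """
    r, V_g0, V_e = params.r, params.V_g0, params.V_e
    if V_g0 + V_e == 0:
        return 0.0
    if r == 0 or V_e == 0:
        return params.h0_sq if V_e > 0 else 1.0
    b = V_e + V_g0
    disc = b * b - 4.0 * r * V_e * V_g0
    return (b - np.sqrt(disc)) / (2.0 * r * V_e)


def solve_equilibrium(
    params: AMModelParams,
    tol: float = 1e-10,
    max_iter: int = 10_000,
    damping: float = 0.5,
) -> EquilibriumSolution:
    """Solve for the AM equilibrium heritability by damped fixed-point iteration.

    Iterates ``h <- (1 - damping) * h + damping * f(h)`` with
    ``f(h) = V(h) / (V(h) + V_e)`` and ``V(h) = V_g0 / (1 - r h)`` until the
    update falls below ``tol``.

    Raises
    ------
    EquilibriumConvergenceError
        If ``max_iter`` iterations do not reach ``tol``; the exception carries
        the last iterate.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    r, V_g0, V_e = params.r, params.V_g0, params.V_e
    if V_g0 + V_e == 0:
        return EquilibriumSolution(0.0, 0.0, 0)
    h = params.h0_sq
    if r == 0:
        return EquilibriumSolution(h, V_g0, 0)
    # iterate to well below tol so the returned fixed point is accurate to
    # tol itself (the damped update understates the remaining error)
    inner_tol = 0.01 * tol
    for it in range(1, max_iter + 1):
        V = V_g0 / (1.0 - r * h)
        f = V / (V + V_e) if (V + V_e) > 0 else 1.0
        h_new = (1.0 - damping) * h + damping * f
        if abs(h_new - h) < inner_tol:
            h = h_new
            V = V_g0 / (1.0 - r * h)
            return EquilibriumSolution(float(h), float(V), it)
        h = h_new
    raise EquilibriumConvergenceError(
        f"equilibrium iteration did not converge in {max_iter} steps", h
    )


def variance_trajectory(params: AMModelParams, T: int) -> VarianceTrajectory:
    """Genetic variance across T generations of AM from the panmictic state.

    Applies the classical infinitesimal-model recursion

        V_{t+1} = (V_t / 2) * (1 + r * h_t^2) + V_g0 / 2,

    where ``h_t^2 = V_t / (V_t + V_e)``.  The first term is the variance of
    transmitted (parental-average) breeding values inflated by the mate
    correlation; the second is the segregation variance restored by free
    recombination each generation.  ``trajectory[0]`` is the panmictic state.
    """
    if T < 0:
        raise ValueError("T must be non-negative")
    r, V_g0, V_e = params.r, params.V_g0, params.V_e
    V = np.empty(T + 1)
    h = np.empty(T + 1)
    V[0] = V_g0
    for t in range(T + 1):
        h[t] = V[t] / (V[t] + V_e) if (V[t] + V_e) > 0 else 1.0
        if t < T:
            V[t + 1] = 0.5 * V[t] * (1.0 + r * h[t]) + 0.5 * V_g0
    return VarianceTrajectory(np.arange(T + 1), V, h)


def expected_he_exchangeable(h_inf_sq: float, r: float) -> float:
    """Expected HE regression estimate at equilibrium, exchangeable loci.

    ``E[h_HE^2] ~= h_inf_sq / (1 - r * h_inf_sq)``.  The bias factor
    ``1/(1 - r h_inf^2)`` exceeds 1 whenever AM is operating: the phenotypic
    outer product absorbs the AM-induced between-locus covariance while the
    GRM, an average of within-locus products, does not.
    """
    x = float(h_inf_sq) * float(r)
    if x >= 1.0:
        raise ValueError(f"r * h_inf_sq = {x} must be < 1")
    return float(h_inf_sq) / (1.0 - x)


def expected_he_general(
    u: np.ndarray, upsilon: CausalCovariance, V_e: float
) -> float:
    """Expected HE estimate for arbitrary causal covariance Upsilon.

    Evaluates ``(m u'YYu / (u'Yu * tr[YY])) * h_inf^2`` with
    ``h_inf^2 = u'Yu / (u'Yu + V_e)`` and Y the causal covariance matrix.
    For Y = I the bracket equals 1 and the plain heritability is returned.
    """
    u = np.asarray(u, dtype=float).ravel()
    if upsilon.m != u.size:
        raise ValueError(
            f"effect vector length {u.size} does not match upsilon.m={upsilon.m}"
        )
    Y = upsilon.matrix
    eigmin = float(np.linalg.eigvalsh(Y).min())
    if eigmin < -1e-8 * max(1.0, float(np.abs(Y).max())):
        raise ValueError(f"upsilon is not positive semidefinite (min eig {eigmin})")
    Yu = Y @ u
    uYu = float(u @ Yu)
    uYYu = float(Yu @ Yu)
    trYY = float(np.sum(Y * Y))
    h_inf_sq = uYu / (uYu + V_e)
    bracket = (upsilon.m * uYYu) / (uYu * trYY)
    return bracket * h_inf_sq


def corrected_h_inf(h_he_sq: float, r: float) -> float:
    """Equilibrium heritability implied by an HE estimate and mate correlation.

    Inverts the exchangeable-loci HE expectation:
    ``h_inf_hat = h_HE^2 / (1 + r * h_HE^2)``.
    """
    if not 0.0 <= r < 1.0:
        raise ValueError(f"r must lie in [0, 1), got {r}")
    x = _check_heritability_input(h_he_sq, "h_he_sq")
    return x / (1.0 + r * x)


def corrected_h0(h_he_sq: float, r: float) -> float:
    """Panmictic heritability implied by an HE estimate and mate correlation.

    ``h0_hat = h_HE^2 / (1 + 2 r h_HE^2 + r (r - 1) (h_HE^2)^2)``; the exact
    algebraic inverse of the composed map h0^2 -> h_inf^2 -> E[h_HE^2].
    """
    if not 0.0 <= r < 1.0:
        raise ValueError(f"r must lie in [0, 1), got {r}")
    x = _check_heritability_input(h_he_sq, "h_he_sq")
    return x / (1.0 + 2.0 * r * x + r * (r - 1.0) * x * x)


def corrected_estimates(
    h_he_sq: float, r: float, se: float = None
) -> CorrectedEstimates:
    """Bundle corrected equilibrium/panmictic estimates with delta-method s.e.

    Standard errors propagate only the sampling uncertainty of the HE
    estimate; ``r`` is treated as a known constant.
    """
    h_inf = corrected_h_inf(h_he_sq, r)
    h0 = corrected_h0(h_he_sq, r)
    x = float(h_he_sq)
    ratio = 1.0 + r * x  # == h_he_sq / h_inf_hat
    se_inf = se_0 = None
    if se is not None:
        se = float(se)
        # d h_inf / d x = 1 / (1 + r x)^2
        se_inf = se / (1.0 + r * x) ** 2
        g = 1.0 + 2.0 * r * x + r * (r - 1.0) * x * x
        gprime = 2.0 * r + 2.0 * r * (r - 1.0) * x
        se_0 = se * abs(g - x * gprime) / g**2
    return CorrectedEstimates(x, float(r), h_inf, h0, ratio, se_inf, se_0)


def disequilibrium_bounds(
    h_he_sq: float, h_reml_sq: float, r: float
) -> DisequilibriumBounds:
    """Probabilistic bounds when AM may not have reached equilibrium.

    The current-generation heritability is bounded in expectation by
    ``[corrected_h_inf(h_HE^2, r), h_HE^2]`` and the panmictic heritability
    by ``[corrected_h0(h_HE^2, r), h_REML^2]``.
    """
    lo_cur = corrected_h_inf(h_he_sq, r)
    lo_pan = corrected_h0(h_he_sq, r)
    if h_reml_sq < lo_pan:
        warnings.warn(
            f"REML estimate {h_reml_sq} falls below the panmictic lower bound "
            f"{lo_pan:.4f}: interval inversion suggests model misfit or "
            "sampling noise",
            stacklevel=2,
        )
    return DisequilibriumBounds(
        current=(lo_cur, float(h_he_sq)), panmictic=(lo_pan, float(h_reml_sq))
    )


def build_upsilon_equilibrium(
    u: np.ndarray, params: AMModelParams
) -> CausalCovariance:
    """Rank-one construction of the equilibrium causal covariance.

    Builds ``Upsilon_inf = D + 2 * phi phi^T`` with ``phi`` proportional to
    the effect vector and D diagonal, scaled so the equilibrium genetic
    variance satisfies ``u' Y u = u'u / (1 - r * h_inf^2)`` and the diagonal
    of Y is exactly 1.  This is an exchangeable-loci approximation: the exact
    phi is a more intricate function of the effects and mate correlation, but
    it shares the defining low-rank structure and calibrated variance.
    """
    u = np.asarray(u, dtype=float).ravel()
    uu = float(u @ u)
    if uu == 0:
        raise ValueError("effect vector must be non-zero")
    m = u.size
    eq = solve_equilibrium(params)
    if params.r == 0:
        return CausalCovariance(m, np.eye(m), "rank_one_equilibrium")
    target = uu / (1.0 - params.r * eq.h_inf_sq)  # equilibrium genetic variance
    u4 = float(np.sum(u**4))
    denom = 2.0 * (uu * uu - u4)
    if denom <= 0:
        raise ValueError("need at least two non-zero effects to build Upsilon_inf")
    alpha_sq = (target - uu) / denom
    phi = np.sqrt(alpha_sq) * u
    if np.any(2.0 * phi**2 >= 1.0):
        raise ValueError(
            "rank-one scaling infeasible: 2*phi_k^2 >= 1 for some locus; "
            "increase the number of causal loci m"
        )
    Y = 2.0 * np.outer(phi, phi)
    np.fill_diagonal(Y, 1.0)
    return CausalCovariance(m, Y, "rank_one_equilibrium")


def estimate_upsilon(causal_genotypes: np.ndarray) -> CausalCovariance:
    """Sample correlation matrix of (standardized) causal genotype columns."""
    Z = np.asarray(causal_genotypes, dtype=float)
    if Z.ndim != 2:
        raise ValueError("causal_genotypes must be a 2-D matrix")
    sd = Z.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"zero-variance causal column(s): {bad.tolist()}")
    Y = np.corrcoef(Z, rowvar=False)
    Y = np.atleast_2d(Y)
    return CausalCovariance(Z.shape[1], Y, "empirical")
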