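"""Stationary states, stability and bifurcation structure.

Setting the time derivatives to zero and fixing the force of infection
lambda = beta*I + epsilon reduces the three-compartment system to a scalar
problem: for a given lambda the stationary prevalence is the closed form

    i(lambda) = lambda*mu*(sigma*lambda + mu)
                / [ (lambda + mu) * ((mu + gamma)*(sigma*lambda + mu)
                                     - sigma*lambda*gamma) ],

and equilibria are the roots of the self-consistency condition

    g(lambda) = beta*N*i(lambda) + epsilon - lambda = 0

on [0, beta*N + epsilon]. With relapse amplification sigma > 1 the cubic g
can have up to three roots when epsilon = 0: the obesity-free state plus a
lower (unstable) and upper (stable) endemic branch — a backward bifurcation,
i.e. a stable endemic state below the R0 = 1 threshold. Intervention factors
alpha (primary) and kappa (secondary) enter through the correspondingly
modified closed form.

Stability is classified on the two-dimensional reduced system obtained by
eliminating R = N - S - I, which removes the spurious zero eigenvalue of the
conserved three-dimensional system.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .model import _rhs
from .params import InterventionFactors, ModelParams

__all__ = [
    "EquilibriumPoint",
    "BifurcationScan",
    "prevalence_given_lambda",
    "self_consistency",
    "solve_equilibria",
    "stability",
    "bifurcation_scan",
]

#: number of uniform pre-scan points used to isolate sign changes of g
DENSE_SCAN_POINTS = 10_000
#: relative tolerance of the bracketed root solve in lambda
ROOT_RTOL = 1e-12
#: |Re(eigenvalue)| below this is classified as marginal
MARGINAL_EIG = 1e-10
#: stationarity check threshold for user-supplied points, fraction of N
STATIONARITY_TOL = 1e-6


@dataclass(frozen=True)
class EquilibriumPoint:
    """A stationary state with its spectrum and stability class."""

    S_star: float
    I_star: float
    R_star: float
    lambda_star: float
    eigenvalues: tuple[complex, ...]
    classification: str  # "stable" | "unstable" | "marginal"

    @property
    def stable(self) -> bool:
        return self.classification == "stable"

    def prevalence(self, N: float) -> float:
        return self.I_star / N


@dataclass(frozen=True)
class BifurcationScan:
    """Equilibrium branches over a (beta, epsilon) grid, as tidy records."""

    beta_grid: np.ndarray
    epsilon_values: np.ndarray
    records: tuple[dict, ...]  # beta, epsilon, branch, prevalence, classification
    params: ModelParams

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame.from_records(list(self.records))


def prevalence_given_lambda(
    lam: float,
    params: ModelParams,
    factors: InterventionFactors | None = None,
) -> float:
    """Stationary prevalence I*/N consistent with a fixed force of infection.

    With intervention factors the closed form generalises to

        i(lam) = alpha*lam*mu*(kappa*sigma*lam + mu)
                 / [ (alpha*lam + mu) * ((mu + kappa*gamma)*(kappa*sigma*lam + mu)
                                         - kappa^2*sigma*lam*gamma) ]

    whose denominator is strictly positive for mu > 0.
    """
    if lam < 0:
        raise ValueError(f"lambda must be non-negative, got {lam}")
    if factors is None:
        factors = InterventionFactors()
    p, a, k = params, factors.alpha, factors.kappa
    num = a * lam * p.mu * (k * p.sigma * lam + p.mu)
    den = (a * lam + p.mu) * (
        (p.mu + k * p.gamma) * (k * p.sigma * lam + p.mu)
        - k * k * p.sigma * lam * p.gamma
    )
    return num / den


def self_consistency(
    lam: float | np.ndarray,
    params: ModelParams,
    factors: InterventionFactors | None = None,
) -> float | np.ndarray:
    """g(lambda) = beta*N*i(lambda) + epsilon - lambda; zero at equilibria.

    Vectorised over ``lam`` for dense scanning.
    """
    if factors is None:
        factors = InterventionFactors()
    p, a, k = params, factors.alpha, factors.kappa
    lam = np.asarray(lam, dtype=float)
    num = a * lam * p.mu * (k * p.sigma * lam + p.mu)
    den = (a * lam + p.mu) * (
        (p.mu + k * p.gamma) * (k * p.sigma * lam + p.mu)
        - k * k * p.sigma * lam * p.gamma
    )
    g = p.beta * p.N * num / den + p.epsilon - lam
    return float(g) if g.ndim == 0 else g


def _expand(lam: float, params: ModelParams, factors: InterventionFactors) -> EquilibriumPoint:
    """Build the full stationary state from a root lambda of g."""
    p, a, k = params, factors.alpha, factors.kappa
    i = prevalence_given_lambda(lam, params, factors)
    I = i * p.N
    S = p.mu * p.N / (a * lam + p.mu)
    R = p.N - S - I
    eigs, cls = _stability_raw(S, I, params, factors)
    return EquilibriumPoint(
        S_star=S,
        I_star=I,
        R_star=R,
        lambda_star=lam,
        eigenvalues=tuple(eigs),
        classification=cls,
    )


def solve_equilibria(
    params: ModelParams,
    factors: InterventionFactors | None = None,
    n_scan: int = DENSE_SCAN_POINTS,
) -> list[EquilibriumPoint]:
    """All stationary states, ordered by I*, each classified for stability.

    Roots of g(lambda) on [0, beta*N + epsilon] are isolated by a dense
    uniform pre-scan (``n_scan`` intervals) and polished by Brent's method
    to 1e-12 relative tolerance; lambda = 0 is an exact root precisely when
    epsilon = 0 (the obesity-free state). A continuous g with
    g(upper bound) <= 0 guarantees at least one root, so the list is never
    empty.
    """
    if factors is None:
        factors = InterventionFactors()
    p = params
    upper = p.beta * p.N + p.epsilon

    roots: list[float] = []
    if p.epsilon == 0.0:
        roots.append(0.0)  # obesity-free state, exact
    if upper == 0.0:
        # beta = epsilon = 0: no hazard at all, only the obesity-free state
        return [_expand(0.0, params, factors)]

    grid = np.linspace(0.0, upper, n_scan + 1)
    if p.epsilon == 0.0:
        # lambda=0 is an exact root already recorded; nudge the scan start
        # off zero so only interior roots produce sign changes
        grid[0] = upper * 1e-12
    g = np.asarray(self_consistency(grid, params, factors))
    for j in range(n_scan):
        a, b = grid[j], grid[j + 1]
        ga, gb = g[j], g[j + 1]
        if ga == 0.0:
            roots.append(float(a))
        elif ga * gb < 0.0:
            roots.append(float(brentq(
                lambda x: self_consistency(x, params, factors),
                a, b, xtol=1e-16, rtol=ROOT_RTOL,
            )))
    if g[-1] == 0.0:
        roots.append(float(grid[-1]))

    # dedupe (a root exactly on a grid node can be found twice)
    roots.sort()
    tol = 1e-9 * max(upper, 1e-30)
    unique: list[float] = []
    for r in roots:
        if not unique or r - unique[-1] > tol:
            unique.append(r)

    points = [_expand(lam, params, factors) for lam in unique]
    points.sort(key=lambda pt: pt.I_star)
    return points


def _stability_raw(
    S: float, I: float, params: ModelParams, factors: InterventionFactors
) -> tuple[np.ndarray, str]:
    """Eigenvalues of the analytic (S, I) Jacobian with R = N - S - I."""
    p, a, k = params, factors.alpha, factors.kappa
    lam = p.beta * I + p.epsilon
    R = p.N - S - I
    j11 = -a * lam - p.mu
    j12 = -a * p.beta * S
    j21 = a * lam - k * p.sigma * lam
    j22 = (
        a * p.beta * S
        + k * p.sigma * p.beta * R
        - k * p.sigma * lam
        - (p.mu + k * p.gamma)
    )
    eigs = np.linalg.eigvals(np.array([[j11, j12], [j21, j22]]))
    max_re = float(np.max(eigs.real))
    if max_re < -MARGINAL_EIG:
        cls = "stable"
    elif max_re > MARGINAL_EIG:
        cls = "unstable"
    else:
        cls = "marginal"
    return eigs, cls


def stability(
    point: EquilibriumPoint,
    params: ModelParams,
    factors: InterventionFactors | None = None,
) -> tuple[tuple[complex, ...], str]:
    """Spectrum and stability class of a stationary point.

    The point must actually be stationary: the right-hand side evaluated
    there must vanish to within 1e-6*N componentwise, otherwise a
    ``ValueError`` is raised.
    """
    if factors is None:
        factors = InterventionFactors()
    y = np.array([point.S_star, point.I_star, point.R_star])
    resid = np.abs(_rhs(y, params, factors.alpha, factors.kappa))
    if np.max(resid) > STATIONARITY_TOL * params.N:
        raise ValueError(
            f"point is not stationary: max |d/dt| = {np.max(resid):.3g} "
            f"(tolerance {STATIONARITY_TOL * params.N:.3g})"
        )
    eigs, cls = _stability_raw(point.S_star, point.I_star, params, factors)
    return tuple(eigs), cls


def bifurcation_scan(
    params: ModelParams,
    beta_grid: np.ndarray,
    epsilon_multipliers: tuple[float, ...] = (0.0, 0.1, 1.0, 10.0),
) -> BifurcationScan:
    """Equilibrium branches over a beta grid at several epsilon settings.

    For every (beta, epsilon*multiplier) pair all equilibria are solved and
    recorded with their stability class; this is the data behind the
    prevalence-versus-transmissibility curve family, including the
    backward-bifurcation window at epsilon = 0.
    """
    beta_grid = np.asarray(beta_grid, dtype=float)
    if beta_grid.size == 0 or len(epsilon_multipliers) == 0:
        raise ValueError("beta_grid and epsilon_multipliers must be non-empty")
    records: list[dict] = []
    eps_values = np.array([m * params.epsilon for m in epsilon_multipliers])
    for mult, eps in zip(epsilon_multipliers, eps_values):
        for b in beta_grid:
            pts = solve_equilibria(params.replace(beta=float(b), epsilon=float(eps)))
            for branch, pt in enumerate(pts):
                records.append(
                    {
                        "beta": float(b),
                        "epsilon_multiplier": float(mult),
                        "epsilon": float(eps),
                        "branch": branch,
                        "prevalence": pt.I_star / params.N,
                        "classification": pt.classification,
                    }
                )
    return BifurcationScan(
        beta_grid=beta_grid,
        epsilon_values=eps_values,
        records=tuple(records),
        params=params,
    )
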