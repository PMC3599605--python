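"""Age-specific and lifetime risk of obesity at an endemic equilibrium.

At a stationary state the force of infection lambda* is constant, so the
age profile of a birth cohort obeys the linear system

    dX/da = -(lambda* + mu) X
    dY/da =  lambda* X + sigma*lambda* Z - (mu + gamma) Y
    dZ/da =  gamma Y - (sigma*lambda* + mu) Z

with initial condition (Nc(0), 0, 0), Nc(0) = mu*N, since new-borns are
never obese. Exponential survival gives the cohort size
Nc(a) = Nc(0) exp(-mu a), the never-obese occupancy has the closed form
X(a) = Nc(0) exp(-(lambda*+mu) a), and the cumulative risk of having left
the never-obese state by age a is

    q(a) = lambda*/(lambda*+mu) * (1 - exp(-(lambda*+mu) a)),

whose a -> infinity limit lambda*/(lambda*+mu) is the lifetime risk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import minimize_scalar

from .model import IntegrationError
from .params import ModelParams

__all__ = [
    "AgeProfile",
    "age_system_matrix",
    "solve_age_profile",
    "cumulative_risk",
    "lifetime_risk",
    "peak_obesity_age",
]


@dataclass(frozen=True)
class AgeProfile:
    """Cohort occupancies (X, Y, Z) over an age grid at fixed lambda*."""

    ages: np.ndarray
    X: np.ndarray
    Y: np.ndarray
    Z: np.ndarray
    lambda_star: float
    Nc0: float  # birth cohort inflow mu*N (individuals/year)

    def risk(self, normalize: str = "birth") -> pd.DataFrame:
        """Per-compartment risk curves.

        ``normalize="birth"`` divides by the cohort inflow Nc(0) (the
        default; these proportions do not sum to one at positive ages
        because of mortality). ``normalize="age"`` divides by the surviving
        cohort Nc(a) instead, so the three curves sum to one at every age.
        """
        if normalize == "birth":
            denom = self.Nc0
        elif normalize == "age":
            denom = self.X + self.Y + self.Z
        else:
            raise ValueError(f"normalize must be 'birth' or 'age', got {normalize!r}")
        return pd.DataFrame(
            {
                "age": self.ages,
                "never_obese": self.X / denom,
                "obese": self.Y / denom,
                "ex_obese": self.Z / denom,
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"age": self.ages, "X": self.X, "Y": self.Y, "Z": self.Z}
        )


def age_system_matrix(lambda_star: float, params: ModelParams) -> np.ndarray:
    """Constant coefficient matrix A of the linear age system d(X,Y,Z)/da = A (X,Y,Z)."""
    p = params
    lam = lambda_star
    return np.array(
        [
            [-(lam + p.mu), 0.0, 0.0],
            [lam, -(p.mu + p.gamma), p.sigma * lam],
            [0.0, p.gamma, -(p.sigma * lam + p.mu)],
        ]
    )


def solve_age_profile(
    lambda_star: float,
    params: ModelParams,
    max_age: float = 110.0,
    step: float = 0.1,
) -> AgeProfile:
    """Integrate the stationary age system from (Nc(0), 0, 0).

    The system is linear with constant coefficients; it is integrated
    adaptively (rtol 1e-10) and sampled on a uniform age grid.
    """
    if lambda_star < 0:
        raise ValueError(f"lambda_star must be non-negative, got {lambda_star}")
    if max_age <= 0 or step <= 0:
        raise ValueError("max_age and step must be positive")
    Nc0 = params.mu * params.N
    A = age_system_matrix(lambda_star, params)
    ages = np.arange(0.0, max_age + 0.5 * step, step)
    ages[-1] = min(ages[-1], max_age)
    sol = solve_ivp(
        lambda a, y: A @ y,
        (0.0, max_age),
        [Nc0, 0.0, 0.0],
        method="LSODA",
        rtol=1e-10,
        atol=1e-12 * Nc0,
        t_eval=ages,
    )
    if not sol.success:
        raise IntegrationError(f"age-system solver failed: {sol.message}")
    return AgeProfile(
        ages=ages,
        X=sol.y[0],
        Y=sol.y[1],
        Z=sol.y[2],
        lambda_star=lambda_star,
        Nc0=Nc0,
    )


def cumulative_risk(a, lambda_star: float, mu: float):
    """Probability q(a) of having left the never-obese state by age a.

    Vectorised over ``a``; non-decreasing in a and bounded above by the
    lifetime risk lambda*/(lambda*+mu).
    """
    a = np.asarray(a, dtype=float)
    if np.any(a < 0):
        raise ValueError("age must be non-negative")
    if lambda_star < 0:
        raise ValueError(f"lambda_star must be non-negative, got {lambda_star}")
    rate = lambda_star + mu
    if rate <= 0:
        q = np.zeros_like(a)
    else:
        q = (lambda_star / rate) * (1.0 - np.exp(-rate * a))
    return float(q) if q.ndim == 0 else q


def lifetime_risk(lambda_star: float, mu: float) -> float:
    """Probability of ever becoming obese, lambda*/(lambda*+mu)."""
    if lambda_star < 0:
        raise ValueError(f"lambda_star must be non-negative, got {lambda_star}")
    if lambda_star == 0.0:
        return 0.0
    return lambda_star / (lambda_star + mu)


class _CohortObesityRisk:
    """Continuous evaluator of Y(a)/Nc(0) via eigen-decomposition of A."""

    def __init__(self, lambda_star: float, params: ModelParams):
        A = age_system_matrix(lambda_star, params)
        w, V = np.linalg.eig(A)
        c = np.linalg.solve(V, np.array([1.0, 0.0, 0.0]))  # x0 = e1 in units of Nc0
        self._w = w
        self._row = V[1] * c  # Y(a)/Nc0 = sum_k row_k exp(w_k a)

    def __call__(self, a: float) -> float:
        return float(np.real(np.sum(self._row * np.exp(self._w * a))))


def peak_obesity_age(
    lambda_star: float,
    params: ModelParams,
    max_age: float = 110.0,
    coarse_step: float = 0.5,
    xatol: float = 1e-3,
) -> float:
    """Age at which the birth-cohort obesity risk Y(a)/Nc(0) is maximal.

    A coarse grid brackets the maximum (first maximum wins on ties) and the
    bracket is refined by bounded scalar minimisation. Undefined at
    lambda* = 0, where Y is identically zero.
    """
    if lambda_star <= 0:
        raise ValueError(
            "peak age is undefined for lambda_star <= 0 (no obesity hazard)"
        )
    y = _CohortObesityRisk(lambda_star, params)
    grid = np.arange(0.0, max_age + 0.5 * coarse_step, coarse_step)
    vals = np.array([y(a) for a in grid])
    j = int(np.argmax(vals))
    lo = grid[max(j - 1, 0)]
    hi = grid[min(j + 1, len(grid) - 1)]
    if lo == hi:
        return float(lo)
    res = minimize_scalar(
        lambda a: -y(a), bounds=(lo, hi), method="bounded", options={"xatol": xatol}
    )
    return float(res.x)
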