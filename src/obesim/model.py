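"""Time-domain dynamics: the three-compartment ODE systems and integration.

The unintervened system is

    dS/dt = mu*N - (beta*I + epsilon)*S - mu*S
    dI/dt = (beta*I + epsilon)*S + sigma*(beta*I + epsilon)*R - (mu + gamma)*I
    dR/dt = gamma*I - sigma*(beta*I + epsilon)*R - mu*R

Primary prevention multiplies the hazard acting on S by ``alpha`` (the
relapse hazard on R is untouched); secondary prevention multiplies both the
recovery rate gamma and the relapse term sigma*(beta*I + epsilon)*R by
``kappa``. Both reduce to the baseline system at factor one, so a single
right-hand side parameterised by (alpha, kappa) covers all three variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .params import InterventionFactors, ModelParams

__all__ = [
    "State",
    "Trajectory",
    "IntegrationError",
    "NonConvergenceError",
    "force_of_infection",
    "hazard_components",
    "rhs_baseline",
    "rhs_primary",
    "rhs_secondary",
    "integrate",
    "time_to_equilibrium",
]

#: relative tolerance of the adaptive integrator
RTOL = 1e-8
#: absolute tolerance, as a fraction of N
ATOL_FRAC = 1e-10
#: conservation bound |S+I+R-N|/N enforced on every trajectory
CONSERVATION_TOL = 1e-6
#: non-negativity floor, as a fraction of N
NEGATIVITY_FLOOR = 1e-9


class IntegrationError(RuntimeError):
    """The ODE solver failed to meet its tolerances."""


class NonConvergenceError(RuntimeError):
    """A trajectory did not settle at the requested equilibrium."""


@dataclass(frozen=True)
class State:
    """Compartment occupancies at one time point."""

    S: float
    I: float
    R: float
    t: float = 0.0

    def __post_init__(self) -> None:
        if self.S < 0 or self.I < 0 or self.R < 0:
            raise ValueError(f"compartments must be non-negative: {self}")

    @property
    def N(self) -> float:
        return self.S + self.I + self.R

    def as_array(self) -> np.ndarray:
        return np.array([self.S, self.I, self.R], dtype=float)


@dataclass(frozen=True)
class Trajectory:
    """Compartment occupancies on a strictly increasing time grid."""

    times: np.ndarray
    S: np.ndarray
    I: np.ndarray
    R: np.ndarray
    params: ModelParams
    factors: InterventionFactors = field(default_factory=InterventionFactors)

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        n = len(self.times)
        if not (len(self.S) == len(self.I) == len(self.R) == n):
            raise ValueError("compartment arrays must align with times")

    def __len__(self) -> int:
        return len(self.times)

    def state_at(self, index: int) -> State:
        return State(
            S=float(self.S[index]),
            I=float(self.I[index]),
            R=float(self.R[index]),
            t=float(self.times[index]),
        )

    @property
    def terminal(self) -> State:
        return self.state_at(-1)

    @property
    def prevalence(self) -> np.ndarray:
        """I(t)/N on the grid."""
        return self.I / self.params.N

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.times, "S": self.S, "I": self.I, "R": self.R})


def force_of_infection(I: float, params: ModelParams) -> float:
    """Total hazard of obesity, lambda = beta*I + epsilon (per year).

    Affine and increasing in the number of obese individuals ``I`` with
    slope ``beta``; the intercept ``epsilon`` is the non-contagious hazard.
    """
    if I < 0:
        raise ValueError(f"obese count must be non-negative, got {I}")
    return params.beta * I + params.epsilon


def hazard_components(I: float, params: ModelParams) -> tuple[float, float]:
    """The additive decomposition (contagious beta*I, non-contagious epsilon)."""
    if I < 0:
        raise ValueError(f"obese count must be non-negative, got {I}")
    return params.beta * I, params.epsilon


def _rhs(y: np.ndarray, params: ModelParams, alpha: float, kappa: float) -> np.ndarray:
    S, I, R = y
    p = params
    lam = p.beta * I + p.epsilon
    dS = p.mu * p.N - alpha * lam * S - p.mu * S
    dI = alpha * lam * S + kappa * p.sigma * lam * R - (p.mu + kappa * p.gamma) * I
    dR = kappa * p.gamma * I - kappa * p.sigma * lam * R - p.mu * R
    return np.array([dS, dI, dR])


def rhs_baseline(state: State, params: ModelParams) -> tuple[float, float, float]:
    """(dS/dt, dI/dt, dR/dt) of the unintervened system (individuals/year)."""
    return tuple(_rhs(state.as_array(), params, 1.0, 1.0))


def rhs_primary(state: State, params: ModelParams, alpha: float) -> tuple[float, float, float]:
    """Derivatives under primary prevention: hazards on never-obese scaled by alpha."""
    if alpha < 0:
        raise ValueError(f"alpha must be non-negative, got {alpha}")
    return tuple(_rhs(state.as_array(), params, alpha, 1.0))


def rhs_secondary(state: State, params: ModelParams, kappa: float) -> tuple[float, float, float]:
    """Derivatives under secondary prevention: recovery and relapse scaled by kappa."""
    if kappa < 0:
        raise ValueError(f"kappa must be non-negative, got {kappa}")
    return tuple(_rhs(state.as_array(), params, 1.0, kappa))


def integrate(
    init: State,
    horizon: float,
    params: ModelParams,
    factors: InterventionFactors | None = None,
    step: float = 0.5,
) -> Trajectory:
    """Integrate the compartmental system over ``horizon`` years.

    Uses an adaptive-step solver (LSODA, rtol 1e-8, atol 1e-10*N) and
    samples the dense solution on a uniform output grid of spacing ``step``.
    Conservation of N and non-negativity are verified on the grid and a
    violation raises :class:`IntegrationError`; the solution is never
    renormalised.

    Parameters
    ----------
    init : State
        Initial compartments; (N, 0, 0) is the conventional starting point.
    horizon : float
        Integration horizon in years (> 0).
    params : ModelParams
    factors : InterventionFactors, optional
        alpha/kappa multipliers; omitted means the unintervened system.
    step : float
        Output grid spacing in years.
    """
    if horizon <= 0:
        raise ValueError(f"horizon must be positive, got {horizon}")
    if factors is None:
        factors = InterventionFactors()
    y0 = init.as_array()
    if abs(y0.sum() - params.N) > CONSERVATION_TOL * params.N:
        raise ValueError(
            f"initial compartments sum to {y0.sum():.6g}, expected N={params.N:.6g}"
        )

    sol = solve_ivp(
        lambda t, y: _rhs(y, params, factors.alpha, factors.kappa),
        (init.t, init.t + horizon),
        y0,
        method="LSODA",
        rtol=RTOL,
        atol=ATOL_FRAC * params.N,
        dense_output=True,
    )
    if not sol.success:
        raise IntegrationError(f"ODE solver failed: {sol.message}")

    times = np.arange(init.t, init.t + horizon + 0.5 * step, step)
    times[-1] = min(times[-1], init.t + horizon)
    ys = sol.sol(times)

    conservation = np.max(np.abs(ys.sum(axis=0) - params.N)) / params.N
    if conservation > CONSERVATION_TOL:
        raise IntegrationError(
            f"conservation violated: max |S+I+R-N|/N = {conservation:.3g}"
        )
    if ys.min() < -NEGATIVITY_FLOOR * params.N:
        raise IntegrationError(f"negative compartment: min = {ys.min():.3g}")

    return Trajectory(
        times=times, S=ys[0], I=ys[1], R=ys[2], params=params, factors=factors
    )


def time_to_equilibrium(traj: Trajectory, eq, rel_tol: float = 0.005) -> float:
    """First time after which the trajectory stays within ``rel_tol`` of ``eq``.

    Distance is the sup-norm over compartments relative to N. The returned
    time is the first grid point from which the band is never left again
    through the horizon, rounded to the nearest year. Raises
    :class:`NonConvergenceError` if the trajectory has not entered and
    stayed in the band by the end of the horizon.
    """
    if rel_tol <= 0:
        raise ValueError(f"rel_tol must be positive, got {rel_tol}")
    N = traj.params.N
    target = np.array([eq.S_star, eq.I_star, eq.R_star])
    dev = (
        np.max(
            np.abs(np.stack([traj.S, traj.I, traj.R]) - target[:, None]),
            axis=0,
        )
        / N
    )
    outside = np.nonzero(dev >= rel_tol)[0]
    if outside.size == 0:
        return 0.0
    last_out = outside[-1]
    if last_out == len(traj) - 1:
        raise NonConvergenceError(
            f"trajectory not within {rel_tol:g} of equilibrium by t={traj.times[-1]:g}"
        )
    return float(round(traj.times[last_out + 1]))
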