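"""Sensitivity sweeps, intervention comparison, late outcomes and CSV export.

The outcome measure throughout is the equilibrium prevalence I*/N on the
branch actually reached from the obesity-free start (N, 0, 0); in bistable
regions (backward bifurcation at epsilon = 0) all branches are retained in
the output with stability flags, and the headline value is the branch
selected by forward reachability. Sweeps express interventions as
multipliers on baseline values: a relative reduction r corresponds to the
multiplier 1 - r, and multipliers above 1 (worsening) are allowed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.stats import expon as _expon
from scipy.stats import gamma as _gamma_dist

from .age_risk import AgeProfile
from .equilibrium import EquilibriumPoint, solve_equilibria
from .households import HouseholdSample
from .model import State, Trajectory, integrate
from .params import InterventionFactors, ModelParams

__all__ = [
    "SweepCurve",
    "SweepResult",
    "LateOutcomeConfig",
    "headline_equilibrium",
    "univariate_sweep",
    "combined_sweep",
    "hazard_recovery_sweep",
    "late_outcome_risk",
    "export_csv",
    "generate_figure_tables",
]

UNIVARIATE_TARGETS = ("epsilon", "beta", "inverse_gamma", "sigma")

#: the low and high calibrated transmission coefficients bounding the
#: household-SAP estimate (per individual per year)
BETA_LOW = 1.99e-7
BETA_HIGH = 4.33e-7


def headline_equilibrium(
    params: ModelParams,
    factors: InterventionFactors | None = None,
) -> tuple[EquilibriumPoint, list[EquilibriumPoint]]:
    """The equilibrium reached from (N, 0, 0), plus all branches.

    With epsilon > 0 the equilibrium is unique in the relevant parameter
    range. At epsilon = 0 the obesity-free state is stationary: starting
    exactly at (N, 0, 0) the system stays there whenever that state is
    stable (including the bistable backward-bifurcation window); when it is
    unstable, any perturbation grows and the stable endemic branch is
    reached. Ambiguous cases fall back to forward integration.
    """
    if factors is None:
        factors = InterventionFactors()
    points = solve_equilibria(params, factors)
    stable = [pt for pt in points if pt.stable]
    if len(stable) == 1:
        return stable[0], points
    if len(stable) > 1:
        free = [pt for pt in stable if pt.I_star < 1e-9 * params.N]
        if free:
            return free[0], points
        # multiple stable endemic branches: settle by forward integration
        traj = integrate(State(S=params.N, I=0.0, R=0.0), 5000.0, params, factors)
        term = traj.terminal
        best = min(stable, key=lambda pt: abs(pt.I_star - term.I))
        return best, points
    # no strictly stable branch (e.g. marginal at a fold): report the
    # branch closest to marginal stability
    best = min(points, key=lambda pt: max(e.real for e in pt.eigenvalues))
    return best, points


@dataclass(frozen=True)
class SweepCurve:
    """One swept parameter/factor: grid, headline prevalence, all branches."""

    name: str
    grid: np.ndarray
    prevalence: np.ndarray
    branches: tuple[tuple[tuple[float, str], ...], ...]  # per point: (prev, class)


@dataclass(frozen=True)
class SweepResult:
    """A family of sweep curves with the baseline settings they share."""

    curves: tuple[SweepCurve, ...]
    params: ModelParams
    metadata: dict = field(default_factory=dict)

    def curve(self, name: str) -> SweepCurve:
        for c in self.curves:
            if c.name == name:
                return c
        raise KeyError(f"no curve named {name!r}")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.curves:
            for x, prev, br in zip(c.grid, c.prevalence, c.branches):
                rows.append(
                    {
                        "parameter": c.name,
                        "value": x,
                        "prevalence": prev,
                        "n_branches": len(br),
                        "branches": ";".join(
                            f"{p:.10g}:{cls}" for p, cls in br
                        ),
                    }
                )
        return pd.DataFrame(rows)


def _scaled_params(params: ModelParams, target: str, mult: float) -> ModelParams:
    if target == "epsilon":
        return params.replace(epsilon=params.epsilon * mult)
    if target == "beta":
        return params.replace(beta=params.beta * mult)
    if target == "inverse_gamma":
        # multiplier acts on the mean duration 1/gamma
        if mult == 0:
            raise ValueError("inverse_gamma multiplier 0 implies infinite recovery rate")
        return params.replace(gamma=params.gamma / mult)
    if target == "sigma":
        return params.replace(sigma=params.sigma * mult)
    raise ValueError(
        f"unknown sweep target {target!r}; expected one of {UNIVARIATE_TARGETS}"
    )


def _sweep_points(
    settings: Sequence[tuple[ModelParams, InterventionFactors]],
) -> tuple[np.ndarray, tuple]:
    prev = np.empty(len(settings))
    branches = []
    for j, (p, f) in enumerate(settings):
        head, pts = headline_equilibrium(p, f)
        prev[j] = head.I_star / p.N
        branches.append(tuple((pt.I_star / p.N, pt.classification) for pt in pts))
    return prev, tuple(branches)


def univariate_sweep(
    target: str,
    multipliers: Sequence[float],
    params: ModelParams,
) -> SweepResult:
    """Equilibrium prevalence as a single parameter is rescaled.

    ``target`` is one of epsilon, beta, inverse_gamma, sigma; each
    multiplier rescales that parameter's baseline value with everything
    else held fixed.
    """
    mult = np.asarray(multipliers, dtype=float)
    if np.any(mult < 0):
        raise ValueError("multipliers must be non-negative")
    settings = [(_scaled_params(params, target, m), InterventionFactors()) for m in mult]
    prev, branches = _sweep_points(settings)
    curve = SweepCurve(name=target, grid=mult, prevalence=prev, branches=branches)
    return SweepResult(curves=(curve,), params=params, metadata={"target": target})


def combined_sweep(
    alpha_grid: Sequence[float],
    kappa_grid: Sequence[float],
    params: ModelParams,
) -> SweepResult:
    """Primary (alpha) versus secondary (kappa) prevention curves.

    The alpha curve scales both hazards on never-obese individuals
    (kappa = 1); the kappa curve scales recovery and relapse together
    (alpha = 1). Both pass through the baseline prevalence at factor one.
    """
    alpha = np.asarray(alpha_grid, dtype=float)
    kappa = np.asarray(kappa_grid, dtype=float)
    if np.any(alpha < 0) or np.any(kappa < 0):
        raise ValueError("factor grids must be non-negative")
    a_prev, a_br = _sweep_points(
        [(params, InterventionFactors(alpha=a)) for a in alpha]
    )
    k_prev, k_br = _sweep_points(
        [(params, InterventionFactors(kappa=k)) for k in kappa]
    )
    return SweepResult(
        curves=(
            SweepCurve("alpha", alpha, a_prev, a_br),
            SweepCurve("kappa", kappa, k_prev, k_br),
        ),
        params=params,
    )


def hazard_recovery_sweep(
    params: ModelParams,
    beta_grid: Sequence[float],
    inverse_gamma_grid: Sequence[float],
    epsilon_multipliers: Sequence[float] = (0.0, 0.1, 1.0, 10.0),
    sigma_multipliers: Sequence[float] = (0.1, 1.0, 10.0),
) -> tuple[SweepResult, SweepResult]:
    """Prevalence versus transmissibility and versus obesity duration.

    Returns a pair of sweep families: prevalence as a function of beta at
    several non-contagious-hazard settings (showing the abrupt rise and the
    backward bifurcation at epsilon = 0), and prevalence as a function of
    the mean obesity duration 1/gamma at several relapse settings.
    """
    beta_grid = np.asarray(beta_grid, dtype=float)
    ig_grid = np.asarray(inverse_gamma_grid, dtype=float)
    if beta_grid.size == 0 or ig_grid.size == 0:
        raise ValueError("grids must be non-empty")

    a_curves = []
    for em in epsilon_multipliers:
        base = params.replace(epsilon=params.epsilon * em)
        prev, br = _sweep_points(
            [(base.replace(beta=float(b)), InterventionFactors()) for b in beta_grid]
        )
        a_curves.append(SweepCurve(f"epsilon_x{em:g}", beta_grid, prev, br))
    panel_a = SweepResult(
        curves=tuple(a_curves), params=params, metadata={"x": "beta"}
    )

    b_curves = []
    for sm in sigma_multipliers:
        base = params.replace(sigma=params.sigma * sm)
        prev, br = _sweep_points(
            [(base.replace(gamma=1.0 / float(d)), InterventionFactors()) for d in ig_grid]
        )
        b_curves.append(SweepCurve(f"sigma_x{sm:g}", ig_grid, prev, br))
    panel_b = SweepResult(
        curves=tuple(b_curves), params=params, metadata={"x": "inverse_gamma"}
    )
    return panel_a, panel_b


@dataclass(frozen=True)
class LateOutcomeConfig:
    """Scaling risk p and onset-to-outcome delay density for a late outcome.

    ``delay`` names the density family of the delay s from first obesity
    onset to the outcome (e.g. a heart attack): "point" (mass at
    ``location``), "exponential" (mean ``scale``) or "gamma"
    (``shape``/``scale``); alternatively ``pdf`` may be any callable density
    on [0, inf), which is checked for normalisation.
    """

    p: float
    delay: str = "gamma"
    shape: float = 2.0
    scale: float = 10.0
    location: float = 0.0
    pdf: Callable[[float], float] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p must be a probability, got {self.p}")
        if self.pdf is not None:
            mass, _ = quad(self.pdf, 0.0, np.inf, limit=200)
            if abs(mass - 1.0) > 1e-6:
                raise ValueError(
                    f"delay density integrates to {mass:.6g}, not 1, on [0, inf)"
                )
        elif self.delay not in ("point", "exponential", "gamma"):
            raise ValueError(
                f"unknown delay family {self.delay!r}; "
                "expected point, exponential or gamma"
            )

    def density(self) -> Callable[[float], float] | None:
        """The delay density, or None for a point mass."""
        if self.pdf is not None:
            return self.pdf
        if self.delay == "point":
            return None
        if self.delay == "exponential":
            return _expon(scale=self.scale).pdf
        return _gamma_dist(self.shape, scale=self.scale).pdf


def late_outcome_risk(
    a,
    config: LateOutcomeConfig,
    lambda_star: float,
    mu: float,
):
    """Age-specific risk of a delayed obesity sequel.

    Convolves the delay density f with the probability of having ever been
    obese by age u, 1 - x(u) = 1 - exp(-(lambda*+mu) u) (zero for u < 0),
    and scales by the overall outcome risk p:

        w(a) = p * integral_0^inf f(s) (1 - x(a - s)) ds.

    Non-decreasing in a and bounded above by p. Vectorised over ``a``;
    quadrature is adaptive with absolute tolerance 1e-8.
    """
    if lambda_star < 0:
        raise ValueError(f"lambda_star must be non-negative, got {lambda_star}")
    rate = lambda_star + mu

    def ever_obese(u):
        return np.where(u > 0, -np.expm1(-rate * np.maximum(u, 0.0)), 0.0)

    ages = np.atleast_1d(np.asarray(a, dtype=float))
    if np.any(ages < 0):
        raise ValueError("age must be non-negative")
    f = config.density()
    out = np.empty_like(ages)
    for j, age in enumerate(ages):
        if f is None:  # point mass at config.location
            out[j] = config.p * float(ever_obese(age - config.location))
        else:
            val, _ = quad(
                lambda s: f(s) * float(ever_obese(age - s)),
                0.0,
                age,
                epsabs=1e-8,
                limit=200,
            )
            out[j] = config.p * val
    return float(out[0]) if np.isscalar(a) or np.ndim(a) == 0 else out


def _metadata_lines(obj, params: ModelParams | None) -> list[str]:
    lines = [f"# obesim {type(obj).__name__}"]
    if params is not None:
        for key, val in params.to_dict().items():
            lines.append(f"# {key} = {val!r}")
    return lines


def export_csv(obj, path: str | Path) -> Path:
    """Write a result object to a headered CSV with '#' metadata lines.

    Supports Trajectory (columns t,S,I,R), AgeProfile (age,X,Y,Z),
    HouseholdSample (household_id,m,secondary_count), SweepResult and
    BifurcationScan-like objects exposing ``to_frame``. Output is
    bit-identical across runs for identical inputs (floats are written at
    full round-trip precision).
    """
    path = Path(path)
    if isinstance(obj, Trajectory):
        frame, params = obj.to_frame(), obj.params
    elif isinstance(obj, AgeProfile):
        frame, params = obj.to_frame(), None
    elif isinstance(obj, HouseholdSample):
        frame, params = obj.to_frame(), None
    elif isinstance(obj, SweepResult):
        frame, params = obj.to_frame(), obj.params
    elif hasattr(obj, "to_frame"):
        frame, params = obj.to_frame(), getattr(obj, "params", None)
    else:
        raise TypeError(f"don't know how to export {type(obj).__name__}")

    buf = io.StringIO()
    for line in _metadata_lines(obj, params):
        buf.write(line + "\n")
    frame.to_csv(buf, index=False)
    try:
        path.write_text(buf.getvalue())
    except OSError as exc:
        raise OSError(f"failed to write CSV to {path}: {exc}") from exc
    return path


def generate_figure_tables(
    params: ModelParams,
    out_dir: str | Path,
    horizon: float = 1000.0,
) -> dict[str, Path]:
    """Regenerate the full baseline / sensitivity / intervention table set.

    Produces, deterministically from the parameter set alone:

    - ``trajectory.csv`` — baseline time evolution from (N, 0, 0);
    - ``age_profile.csv`` — stationary age profile at the baseline
      equilibrium force of infection;
    - ``prevalence_vs_beta.csv`` — prevalence versus transmissibility at
      non-contagious-hazard multipliers {0, 0.1, 1, 10};
    - ``prevalence_vs_duration.csv`` — prevalence versus mean obesity
      duration at relapse multipliers {0.1, 1, 10};
    - ``univariate_low.csv`` / ``univariate_high.csv`` — single-parameter
      reduction sweeps at the low/high calibrated beta;
    - ``combined_low.csv`` / ``combined_high.csv`` — primary (alpha) versus
      secondary (kappa) prevention sweeps at the low/high calibrated beta.
    """
    from .age_risk import solve_age_profile  # local import to avoid cycle

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    traj = integrate(State(S=params.N, I=0.0, R=0.0), horizon, params)
    written["trajectory"] = export_csv(traj, out_dir / "trajectory.csv")

    head, _ = headline_equilibrium(params)
    profile = solve_age_profile(head.lambda_star, params)
    written["age_profile"] = export_csv(profile, out_dir / "age_profile.csv")

    beta_grid = np.linspace(0.0, 8.0e-7, 81)
    duration_grid = np.linspace(1.0, 70.0, 70)
    panel_a, panel_b = hazard_recovery_sweep(params, beta_grid, duration_grid)
    written["prevalence_vs_beta"] = export_csv(
        panel_a, out_dir / "prevalence_vs_beta.csv"
    )
    written["prevalence_vs_duration"] = export_csv(
        panel_b, out_dir / "prevalence_vs_duration.csv"
    )

    reduction = np.round(np.linspace(0.0, 1.0, 21), 10)
    for label, beta in (("low", BETA_LOW), ("high", BETA_HIGH)):
        p = params.replace(beta=beta)
        curves = []
        for target in UNIVARIATE_TARGETS:
            mult = reduction[::-1]
            if target == "inverse_gamma":
                mult = mult[mult > 0]  # duration multiplier 0 is ill-defined
            res = univariate_sweep(target, mult, p)
            curves.append(res.curves[0])
        uni = SweepResult(curves=tuple(curves), params=p)
        written[f"univariate_{label}"] = export_csv(
            uni, out_dir / f"univariate_{label}.csv"
        )
        comb = combined_sweep(reduction[::-1], reduction[::-1], p)
        written[f"combined_{label}"] = export_csv(
            comb, out_dir / f"combined_{label}.csv"
        )
    return written
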