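"""Parameter sets for the obesity social-contagion model.

The model tracks never-obese (S), obese (I) and ex-obese (R) individuals in a
closed, randomly mixing population of constant size N. Obesity is acquired
through two additive routes: a contagious hazard ``beta * I`` proportional to
current prevalence, and a constant non-contagious hazard ``epsilon``
(genetics, diet, lifestyle). Ex-obese individuals relapse at ``sigma`` times
the never-obese hazard; recovery occurs at rate ``gamma``; demographic
turnover (birth = death) occurs at rate ``mu``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

__all__ = ["ModelParams", "InterventionFactors", "load_config"]


@dataclass(frozen=True)
class ModelParams:
    """Epidemiological constants of the transmission system.

    Parameters
    ----------
    N : float
        Total population size (individuals, constant over time).
    mu : float
        Per-capita birth and death rate (1/year); 1/mu is the life
        expectancy at birth under exponential survival.
    beta : float
        Transmission coefficient (per individual per year); ``beta * I`` is
        the contagious hazard of obesity.
    epsilon : float
        Non-contagious hazard of obesity (1/year).
    sigma : float
        Relative hazard of (re-)acquiring obesity among ex-obese
        individuals (dimensionless); typically > 1.
    gamma : float
        Recovery rate from obesity (1/year); 1/gamma is the mean duration
        of an obese episode.
    """

    N: float = 100_000.0
    mu: float = 1.0 / 69.4
    beta: float = 2.96e-7
    epsilon: float = 0.012
    sigma: float = 8.0
    gamma: float = 1.0 / 35.8

    def __post_init__(self) -> None:
        if not self.N > 0:
            raise ValueError(f"N must be strictly positive, got {self.N}")
        if not self.mu > 0:
            # mu = 0 breaks the stationary age distribution and the
            # equilibrium reduction; demographic turnover is required.
            raise ValueError(f"mu must be strictly positive, got {self.mu}")
        if not self.gamma > 0:
            raise ValueError(f"gamma must be strictly positive, got {self.gamma}")
        if self.beta < 0:
            raise ValueError(f"beta must be non-negative, got {self.beta}")
        if self.epsilon < 0:
            raise ValueError(f"epsilon must be non-negative, got {self.epsilon}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be non-negative, got {self.sigma}")

    @property
    def life_expectancy(self) -> float:
        """Mean lifetime 1/mu in years."""
        return 1.0 / self.mu

    @property
    def obesity_duration(self) -> float:
        """Mean duration of an obese episode, 1/gamma, in years."""
        return 1.0 / self.gamma

    def replace(self, **changes: float) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class InterventionFactors:
    """Multiplicative intervention strengths.

    ``alpha`` rescales both hazards (contagious and non-contagious) acting on
    never-obese individuals — primary prevention. ``kappa`` rescales both the
    recovery rate and the ex-obese re-infection hazard — secondary
    prevention. ``alpha == kappa == 1`` reproduces the unintervened system
    exactly.
    """

    alpha: float = 1.0
    kappa: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError(f"alpha must be non-negative, got {self.alpha}")
        if self.kappa < 0:
            raise ValueError(f"kappa must be non-negative, got {self.kappa}")

    @property
    def is_baseline(self) -> bool:
        return self.alpha == 1.0 and self.kappa == 1.0


_CONFIG_KEYS = {"N", "mu", "beta", "epsilon", "sigma", "gamma"}


def load_config(path: str | Path) -> ModelParams:
    """Read model parameters from a flat key=value text file.

    Recognised keys are ``N, mu, beta, epsilon, sigma, gamma``; blank lines
    and lines starting with ``#`` are ignored. Keys not present keep their
    baseline values.
    """
    overrides: dict[str, float] = {}
    text = Path(path).read_text()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, value = line.partition("=")
        key = key.strip()
        if key not in _CONFIG_KEYS:
            raise ValueError(
                f"{path}:{lineno}: unknown parameter {key!r}; "
                f"expected one of {sorted(_CONFIG_KEYS)}"
            )
        overrides[key] = float(value.strip())
    return ModelParams(**overrides)
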