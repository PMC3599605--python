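"""Household secondary-attack-proportion calibration of transmissibility.

In a household with one index case and m susceptible-and-exposed members,
the secondary attack proportion relates to the basic reproduction number by

    SAP = R0 / (R0 + m),

so R0 = m*SAP/(1-SAP). In the special case without non-contagious hazard
(epsilon = 0 — a reasonable assumption over the short observation window of
household studies) the reproduction number of the transmission system is
R0 = beta*N/(gamma + mu), which converts R0 to the transmission
coefficient beta and back. Note that with epsilon > 0 or relapse (sigma > 1)
R0 = 1 is not a clean epidemic threshold for the population model; the
conversion is a calibration device, not a threshold statement.
"""

from __future__ import annotations

from dataclasses import dataclass

from .params import ModelParams

__all__ = [
    "CalibrationInput",
    "sap_to_R0",
    "R0_to_sap",
    "R0_to_beta",
    "beta_to_R0",
    "sap_to_beta",
]


@dataclass(frozen=True)
class CalibrationInput:
    """An observed household secondary attack proportion.

    sap : fraction of the m susceptible-and-exposed household members who
        acquired obesity from the single index case, in [0, 1).
    m : number of susceptible-and-exposed members per household (>= 1).
    """

    sap: float
    m: int

    def __post_init__(self) -> None:
        _check_sap(self.sap)
        _check_m(self.m)


def _check_sap(sap: float) -> None:
    if not 0.0 <= sap < 1.0:
        raise ValueError(f"SAP must be in [0, 1), got {sap} (SAP=1 has no finite R0)")


def _check_m(m: int) -> None:
    if int(m) != m or m < 1:
        raise ValueError(f"m must be an integer >= 1, got {m}")


def sap_to_R0(sap: float, m: int) -> float:
    """Basic reproduction number from a household SAP: R0 = m*sap/(1-sap)."""
    _check_sap(sap)
    _check_m(m)
    return m * sap / (1.0 - sap)


def R0_to_sap(R0: float, m: int) -> float:
    """Forward map SAP = R0/(R0+m); exact inverse of :func:`sap_to_R0`."""
    if R0 < 0:
        raise ValueError(f"R0 must be non-negative, got {R0}")
    _check_m(m)
    return R0 / (R0 + m)


def R0_to_beta(R0: float, params: ModelParams) -> float:
    """Transmission coefficient beta = R0*(gamma+mu)/N (per individual per year)."""
    if R0 < 0:
        raise ValueError(f"R0 must be non-negative, got {R0}")
    return R0 * (params.gamma + params.mu) / params.N

def beta_to_R0(beta: float, params: ModelParams) -> float:
    """Reproduction number R0 = beta*N/(gamma+mu) of the epsilon = 0 system."""
    if beta < 0:
        raise ValueError(f"beta must be non-negative, got {beta}")
    return beta * params.N / (params.gamma + params.mu)


def sap_to_beta(sap: float, m: int, params: ModelParams) -> float:
    """Full calibration chain SAP -> R0 -> beta."""
    return R0_to_beta(sap_to_R0(sap, m), params)
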