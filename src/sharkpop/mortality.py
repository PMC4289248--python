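"""Indirect natural-mortality estimators from life-history invariants.

Seven closed-form estimators relate annual instantaneous mortality to
longevity, growth, maturity and temperature: three Hoenig (1983) longevity
regressions (fish, cetacean, combined data sets), the Pauly (1980)
growth–temperature regression, and three Jensen (1996) life-history rules.
For an unfished population, total mortality Z and natural mortality M are
interchangeable, so the seven values bracket the plausible range of the
model's adult mortality probability μ and serve as an external check on the
band inferred by the pattern-oriented sweep.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

__all__ = [
    "LifeHistoryParams",
    "MortalityEstimate",
    "hoenig",
    "pauly",
    "jensen",
    "estimate_all",
    "HOENIG_COEFFS",
]

# ln(Z) = a - b * ln(t_max), per taxon group of the original regressions
HOENIG_COEFFS: Mapping[str, tuple[float, float]] = {
    "fish": (1.46, 1.01),
    "cetacean": (0.941, 0.873),
    "combined": (1.44, 0.982),
}

JENSEN_VARIANTS = ("age", "growth", "pauly_form")


@dataclass(frozen=True)
class LifeHistoryParams:
    """Lemon-shark life-history constants (defaults from the literature).

    K: von Bertalanffy growth coefficient (1/yr); L_inf: asymptotic length
    (cm); x_m: age at maturity (yr); t_max: maximum age (yr); T: mean water
    temperature (degrees C).
    """

    K: float = 0.057
    L_inf: float = 317.65
    x_m: float = 12.0
    t_max: float = 25.0
    T: float = 27.1

    def __post_init__(self) -> None:
        for name in ("K", "L_inf", "x_m", "t_max", "T"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.x_m > self.t_max:
            raise ValueError("x_m cannot exceed t_max")


@dataclass(frozen=True)
class MortalityEstimate:
    method: str
    value: float
    inputs_used: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("mortality estimate must be positive")

    @property
    def rounded(self) -> float:
        """Display convention: three decimals, half away from zero.

        A tiny epsilon guards exact .5 boundaries (e.g. 1.65/12 = 0.1375)
        against binary representation error.
        """
        return math.floor(self.value * 1000 + 0.5 + 1e-9) / 1000


def hoenig(t_max: float, variant: str) -> MortalityEstimate:
    """Longevity-based total mortality: Z = exp(a − b·ln(t_max))."""
    if variant not in HOENIG_COEFFS:
        raise ValueError(f"unknown Hoenig variant {variant!r}")
    if t_max <= 1:
        raise ValueError("t_max must exceed 1 year")
    a, b = HOENIG_COEFFS[variant]
    return MortalityEstimate(
        method=f"hoenig_{variant}",
        value=math.exp(a - b * math.log(t_max)),
        inputs_used={"t_max": t_max},
    )


def pauly(L_inf: float, K: float, T: float) -> MortalityEstimate:
    """Pauly's growth–temperature regression (base-10 logarithms).

    M = 10^(−0.0066 − 0.279·log10 L_inf + 0.6543·log10 K + 0.4634·log10 T).
    """
    if min(L_inf, K, T) <= 0:
        raise ValueError("L_inf, K and T must be strictly positive")
    log_m = (
        -0.0066
        - 0.279 * math.log10(L_inf)
        + 0.6543 * math.log10(K)
        + 0.4634 * math.log10(T)
    )
    return MortalityEstimate(
        method="pauly",
        value=10.0**log_m,
        inputs_used={"L_inf": L_inf, "K": K, "T": T},
    )


def jensen(params: LifeHistoryParams, variant: str) -> MortalityEstimate:
    """Jensen's life-history rules: M = 1.65/x_m, 1.5·K, or 1.6·K."""
    if variant == "age":
        value, inputs = 1.65 / params.x_m, {"x_m": params.x_m}
    elif variant == "growth":
        value, inputs = 1.5 * params.K, {"K": params.K}
    elif variant == "pauly_form":
        value, inputs = 1.6 * params.K, {"K": params.K}
    else:
        raise ValueError(f"unknown Jensen variant {variant!r}")
    return MortalityEstimate(method=f"jensen_{variant}", value=value, inputs_used=inputs)


def estimate_all(params: LifeHistoryParams = LifeHistoryParams()) -> list[MortalityEstimate]:
    """All seven estimators in canonical order.

    Hoenig fish, cetacean, combined; Pauly; Jensen age, growth, Pauly-form.
    """
    return [
        hoenig(params.t_max, "fish"),
        hoenig(params.t_max, "cetacean"),
        hoenig(params.t_max, "combined"),
        pauly(params.L_inf, params.K, params.T),
        jensen(params, "age"),
        jensen(params, "growth"),
        jensen(params, "pauly_form"),
    ]


def estimates_frame(params: LifeHistoryParams = LifeHistoryParams()) -> pd.DataFrame:
    ests = estimate_all(params)
    return pd.DataFrame(
        {
            "method": [e.method for e in ests],
            "mortality": [e.value for e in ests],
            "mortality_3dp": [e.rounded for e in ests],
        }
    )
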