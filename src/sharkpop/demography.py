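"""Single-step stochastic demographic kernel for the lemon shark nursery model.

The population is an integer vector of counts per age class ``0..t_max``
observed at a yearly census taken just after reproduction.  One census-to-
census step applies, in order:

1. survival — binomial deaths per class; the first (age-0) class dies with a
   density-dependent Hill probability of its own cohort size, every older
   class with the constant probability ``mu``; survivors age by one class and
   survivors of the oldest class are discarded;
2. reproduction — the breeding-female count is one quarter of the
   post-survival adult total (equal sex ratio, biennial breeding), and the
   newborn class is drawn either as a Poisson total or as a sum of empirical
   litter draws.

All randomness flows through a caller-supplied :class:`numpy.random.Generator`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

__all__ = [
    "LitterDistribution",
    "DemographicParams",
    "PopulationState",
    "StepRecord",
    "breeding_females",
    "draw_total_births",
    "first_class_mortality_prob",
    "draw_deaths",
    "advance",
    "juvenile_count",
]

#: Age classes counted as "juvenile": the animals caught in the nursery census.
JUVENILE_AGES = (0, 1, 2)


class ConfigError(ValueError):
    """Invalid model configuration (missing or inconsistent parameters)."""


@dataclass(frozen=True)
class LitterDistribution:
    """Probability of each litter size ``j`` in ``{0, ..., j_max}``.

    Probabilities must be non-negative and sum to one within ``1e-9`` after
    construction; :meth:`from_csv` renormalizes inputs whose sum is within
    ``1e-6`` of one and rejects anything farther off.
    """

    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 1 or p.size == 0:
            raise ConfigError("litter distribution needs a 1-d probability vector")
        if np.any(p < 0):
            raise ConfigError("litter probabilities must be non-negative")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ConfigError(
                f"litter probabilities sum to {p.sum():.12f}, not 1"
            )
        object.__setattr__(self, "probs", p)

    @property
    def j_max(self) -> int:
        return self.probs.size - 1

    @property
    def sizes(self) -> np.ndarray:
        return np.arange(self.probs.size)

    @property
    def mean(self) -> float:
        return float(self.sizes @ self.probs)

    @property
    def variance(self) -> float:
        return float((self.sizes**2) @ self.probs - self.mean**2)

    @classmethod
    def from_probs(cls, probs) -> "LitterDistribution":
        p = np.asarray(probs, dtype=float)
        s = p.sum()
        if abs(s - 1.0) > 1e-6:
            raise ConfigError(f"litter probabilities sum to {s:.8f}; refusing to renormalize")
        return cls(p / s)

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "LitterDistribution":
        """Read a ``litter_size,probability`` table (rows may arrive unsorted)."""
        df = pd.read_csv(path, comment="#")
        expected = {"litter_size", "probability"}
        if not expected.issubset(df.columns):
            raise ConfigError(f"litter CSV needs columns {sorted(expected)}")
        sizes = df["litter_size"].to_numpy()
        if not np.array_equal(sizes, sizes.astype(int)):
            raise ConfigError("litter sizes must be integers")
        sizes = sizes.astype(int)
        if sizes.min() < 0 or np.unique(sizes).size != sizes.size:
            raise ConfigError("litter sizes must be distinct and non-negative")
        p = np.zeros(int(sizes.max()) + 1)
        p[sizes] = df["probability"].to_numpy()
        return cls.from_probs(p)

    def to_csv(self, path: Union[str, Path]) -> None:
        pd.DataFrame({"litter_size": self.sizes, "probability": self.probs}).to_csv(
            path, index=False
        )


@dataclass(frozen=True)
class DemographicParams:
    """Model parameters (defaults are the nursery calibration).

    Parameters
    ----------
    lambda_mean:
        Mean litter size λ (pups per breeding female).
    fecundity_mode:
        ``"poisson"`` draws the newborn total as Poisson(λ·b); ``"empirical"``
        sums independent draws from ``litter_dist`` over the rounded number of
        breeding females.
    h, k:
        Hill exponent and half-saturation cohort size of the density-dependent
        first-year mortality; a cohort of exactly ``k`` newborns has mortality
        probability 0.5 regardless of ``h``.
    mu:
        Annual mortality probability for every age class ≥ 1.
    t_max:
        Maximum age; survivors of class ``t_max`` are removed.
    x_m:
        Age at maturity; classes ``x_m..t_max`` are adults.
    breeding_coeff:
        Fraction of adults breeding in a given year (1/4 = equal sex ratio ×
        biennial breeding with equal odd/even cohorts).
    """

    lambda_mean: float = 6.1
    fecundity_mode: str = "poisson"
    litter_dist: Optional[LitterDistribution] = None
    h: float = 1.0
    k: float = 100.0
    mu: float = 0.15
    t_max: int = 25
    x_m: int = 12
    breeding_coeff: float = 0.25

    def __post_init__(self) -> None:
        if self.fecundity_mode not in ("poisson", "empirical"):
            raise ConfigError(f"unknown fecundity_mode {self.fecundity_mode!r}")
        if self.fecundity_mode == "empirical" and self.litter_dist is None:
            raise ConfigError("empirical fecundity requires a litter distribution")
        if not 0.0 <= self.mu <= 1.0:
            raise ConfigError("mu must lie in [0, 1]")
        if self.k <= 0:
            raise ConfigError("k must be positive")
        if self.h < 1:
            raise ConfigError("Hill exponent h must be >= 1")
        if not 1 <= self.x_m <= self.t_max:
            raise ConfigError("need 1 <= x_m <= t_max")
        if not 0.0 < self.breeding_coeff <= 1.0:
            raise ConfigError("breeding_coeff must lie in (0, 1]")
        if self.lambda_mean < 0:
            raise ConfigError("lambda_mean must be non-negative")

    @property
    def n_classes(self) -> int:
        return self.t_max + 1

    def with_(self, **kw) -> "DemographicParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class PopulationState:
    """Integer shark counts per age class at census ``census_index``."""

    counts: np.ndarray
    census_index: int = 0

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if not np.issubdtype(c.dtype, np.integer):
            if not np.array_equal(c, np.floor(c)):
                raise ValueError("counts must be integers")
            c = c.astype(np.int64)
        else:
            c = c.astype(np.int64, copy=True)
        if c.ndim != 1 or np.any(c < 0):
            raise ValueError("counts must be a 1-d non-negative vector")
        if self.census_index < 0:
            raise ValueError("census_index must be >= 0")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def is_extinct(self) -> bool:
        return self.total == 0


@dataclass(frozen=True)
class StepRecord:
    """Bookkeeping for one census-to-census transition."""

    b: float                     # breeding-female count (may be fractional)
    births: int                  # newborn total entering class 0
    deaths: np.ndarray           # deaths per source age class
    age0_mortality_prob: float   # realized Hill probability for the 0->1 move


def breeding_females(state: PopulationState, params: DemographicParams) -> float:
    """Breeding-female count: ``breeding_coeff`` × the adult total.

    The 1/4 default folds together the equal sex ratio and biennial breeding;
    the count may be fractional and is used as-is by the Poisson fecundity.
    """
    return float(params.breeding_coeff * state.counts[params.x_m :].sum())


def draw_total_births(
    b: float, params: DemographicParams, rng: np.random.Generator
) -> int:
    """Total newborns produced by ``b`` breeding females.

    Poisson mode draws once with rate λ·b (fractional ``b`` enters the rate
    directly).  Empirical mode rounds ``b`` half-to-even to a female count and
    sums that many independent litter draws.
    """
    if b < 0:
        raise ValueError("breeding-female count must be non-negative")
    if params.fecundity_mode == "poisson":
        return int(rng.poisson(params.lambda_mean * b))
    dist = params.litter_dist
    if dist is None:
        raise ConfigError("empirical fecundity requires a litter distribution")
    n_females = int(np.rint(b))
    if n_females == 0:
        return 0
    litters = rng.multinomial(n_females, dist.probs)
    return int(litters @ dist.sizes)


def first_class_mortality_prob(x0: int, h: float, k: float) -> float:
    """Hill (generalized Michaelis–Menten) density-dependent mortality.

    ``p = x0**h / (k**h + x0**h)``: zero at zero density, exactly 0.5 at the
    half-saturation cohort size ``k``, saturating toward 1.  Larger ``k``
    means weaker competition among same-age nursery conspecifics.
    """
    if x0 < 0:
        raise ValueError("cohort size must be non-negative")
    if k <= 0 or h < 1:
        raise ValueError("need k > 0 and h >= 1")
    if x0 == 0:
        return 0.0
    # divide through by x0**h for numerical safety at large cohorts; clamp
    # below 1 so the strict upper bound survives floating-point rounding
    p = 1.0 / (1.0 + (k / x0) ** h)
    return min(p, np.nextafter(1.0, 0.0))


def draw_deaths(count: int, p: float, rng: np.random.Generator) -> int:
    """One binomial draw of deaths among ``count`` sharks at probability ``p``."""
    if count < 0:
        raise ValueError("count must be non-negative")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    return int(rng.binomial(count, p))


def _advance_counts(
    counts: np.ndarray, params: DemographicParams, rng: np.random.Generator
) -> tuple[np.ndarray, float, np.ndarray, float]:
    """Hot-loop core of :func:`advance` on raw count vectors.

    Returns ``(next_counts, b, deaths, p0)``.  RNG call order — age-0 binomial,
    one vectorized binomial for classes 1..t_max, then the fecundity draw — is
    part of the reproducibility contract.
    """
    t_max = params.t_max
    nxt = np.zeros_like(counts)
    p0 = first_class_mortality_prob(int(counts[0]), params.h, params.k)
    deaths = np.empty_like(counts)
    deaths[0] = rng.binomial(int(counts[0]), p0)
    deaths[1:] = rng.binomial(counts[1:], params.mu)
    # aging: survivors of class a move to a+1; class t_max survivors drop out
    nxt[1:] = counts[:t_max] - deaths[:t_max]
    # census happens just after reproduction: newborns are produced by the
    # post-survival adults and appear in class 0 of the new census
    b = float(params.breeding_coeff * nxt[params.x_m :].sum())
    nxt[0] = draw_total_births(b, params, rng)
    return nxt, b, deaths, p0


def advance(
    state: PopulationState, params: DemographicParams, rng: np.random.Generator
) -> tuple[PopulationState, StepRecord]:
    """Advance one census: survival and aging first, then reproduction.

    Deaths are binomial per class — density-dependent for the newborn cohort,
    constant ``mu`` above it.  The breeding-female count is taken from the
    post-survival adult classes of the new census, so newborns present at a
    census are the offspring of the adults alive at that same census.
    Extinction is absorbing: an all-zero state maps to an all-zero state.
    """
    if state.counts.size != params.n_classes:
        raise ValueError(
            f"state has {state.counts.size} classes, params expect {params.n_classes}"
        )
    nxt, b, deaths, p0 = _advance_counts(state.counts, params, rng)
    new_state = PopulationState(nxt, state.census_index + 1)
    return new_state, StepRecord(b=b, births=int(nxt[0]), deaths=deaths, age0_mortality_prob=p0)


def juvenile_count(state: PopulationState) -> int:
    """Sharks of ages 0–2: the animals actually caught in the nursery census."""
    return int(state.counts[: len(JUVENILE_AGES)].sum())
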