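"""Synthetic stand-ins for the unpublished field inputs.

The raw 17-year nursery census counts and the per-female litter-size
histogram were never deposited, so the pipeline ships generators that
emulate their published summary features: a juvenile census series with a
chosen sample mean and variance (optionally with one inflated and one
deflated year, mimicking the influential outlier censuses), and a litter-size
distribution on {0..18} with a chosen mean that can be over-dispersed
relative to Poisson.  Everything produced here is labeled synthetic; nothing
is a reconstruction of the actual Bimini counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .demography import LitterDistribution
from .inference import ObservedStats

__all__ = [
    "SyntheticCensus",
    "make_litter_distribution",
    "make_census_series",
    "observed_stats",
]


@dataclass(frozen=True)
class SyntheticCensus:
    """A generated census series plus the targets it was built to match."""

    years: np.ndarray
    juveniles: np.ndarray
    target_mean: float
    target_variance: float
    outlier_years: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if len(self.years) != len(self.juveniles):
            raise ValueError("years and juveniles must have equal length")
        if np.any(np.asarray(self.juveniles) < 0):
            raise ValueError("juvenile counts must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.years, "juvenile_count": self.juveniles})

    def to_csv(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            fh.write("# synthetic census series (not field data); ")
            fh.write(
                f"targets mean={self.target_mean} variance={self.target_variance}\n"
            )
            self.to_frame().to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "SyntheticCensus":
        df = pd.read_csv(path, comment="#")
        juv = df["juvenile_count"].to_numpy()
        return cls(
            years=df["year"].to_numpy(),
            juveniles=juv,
            target_mean=float(juv.mean()),
            target_variance=float(juv.var(ddof=1)),
        )


def _truncated_mean(pmf: np.ndarray) -> float:
    p = pmf / pmf.sum()
    return float(np.arange(p.size) @ p)


def make_litter_distribution(
    mean: float, dispersion: float = 1.0, j_max: int = 18
) -> LitterDistribution:
    """Litter-size distribution on {0..j_max} with the requested moments.

    ``dispersion`` is the variance-to-mean ratio of the underlying family:
    1 gives a truncated Poisson, > 1 a truncated negative binomial.  The
    underlying rate/mean is solved numerically so that the *truncated* mean
    matches ``mean`` (plain truncation would bias it low); the realized mean
    lands within 1% of target.
    """
    if mean <= 0:
        raise ValueError("mean must be positive")
    if dispersion < 1:
        raise ValueError("dispersion must be >= 1 (variance-to-mean ratio)")
    if j_max < mean + 0.5:
        raise ValueError(f"mean {mean} infeasible with support capped at {j_max}")
    sizes = np.arange(j_max + 1)

    def pmf_for(m0: float) -> np.ndarray:
        if dispersion == 1.0:
            return stats.poisson.pmf(sizes, m0)
        p = 1.0 / dispersion
        r = m0 * p / (1.0 - p)
        return stats.nbinom.pmf(sizes, r, p)

    def gap(m0: float) -> float:
        return _truncated_mean(pmf_for(m0)) - mean

    hi = 4.0 * j_max
    if gap(hi) < 0:
        raise ValueError(
            f"mean {mean} with dispersion {dispersion} is unreachable on 0..{j_max}"
        )
    m0 = optimize.brentq(gap, 1e-9, hi, xtol=1e-10)
    probs = pmf_for(m0)
    return LitterDistribution(probs / probs.sum())


def _sample_stats(x: np.ndarray) -> tuple[float, float]:
    return float(x.mean()), float(x.var(ddof=1))


def _integer_repair(
    x: np.ndarray, target_mean: float, target_var: float, rel_tol: float
) -> Optional[np.ndarray]:
    """Nudge an integer series onto its target mean/variance.

    First fixes the sum with single ±1 moves, then applies sum-preserving
    (+1, −1) pair moves that spread or shrink the series until the sample
    variance is within tolerance.  Returns None if it stalls.
    """
    x = x.copy()
    n = x.size
    target_sum = int(round(n * target_mean))
    while x.sum() != target_sum:
        if x.sum() < target_sum:
            x[int(np.argmin(x))] += 1
        else:
            i = int(np.argmax(x))
            x[i] -= 1
    mtol = max(rel_tol * abs(target_mean), 0.5)
    vtol = max(rel_tol * target_var, 0.5)
    for _ in range(2000):
        m, v = _sample_stats(x)
        if abs(m - target_mean) <= mtol and abs(v - target_var) <= vtol:
            return x
        if v < target_var:
            i, j = int(np.argmax(x)), int(np.argmin(x))
            if x[j] == 0:
                order = np.argsort(x)
                j = int(next(idx for idx in order if x[idx] > 0))
            x[i] += 1
            x[j] -= 1
        else:
            i, j = int(np.argmax(x)), int(np.argmin(x))
            if x[i] - x[j] <= 1:
                return None
            x[i] -= 1
            x[j] += 1
    return None


def make_census_series(
    n_years: int,
    target_mean: float,
    target_var: float,
    outliers: bool = False,
    rng: Optional[np.random.Generator] = None,
    *,
    start_year: int = 0,
    rel_tol: float = 0.02,
) -> SyntheticCensus:
    """Integer census series whose sample mean/variance hit the targets.

    Counts are drawn stochastically, affine-adjusted onto the exact targets,
    rounded, then repaired with ±1 moves until both statistics are within
    ``rel_tol`` (2%) of target.  With ``outliers=True`` the series contains
    one inflated and one deflated year carrying most of the variance: the
    remaining years are generated at a quarter of the target variance and the
    two flagged years absorb the rest, so dropping them collapses the sample
    variance while barely moving the mean.
    """
    if n_years < 2:
        raise ValueError("n_years must be >= 2")
    if target_var < 0 or target_mean < 0:
        raise ValueError("targets must be non-negative")
    rng = np.random.default_rng() if rng is None else rng

    for _attempt in range(40):
        if outliers:
            base = rng.normal(target_mean, np.sqrt(target_var / 4.0), n_years - 2)
            base = base - base.mean() + target_mean  # base mean pinned to target
            ss_base = float(((base - target_mean) ** 2).sum())
            excess = (n_years - 1) * target_var - ss_base
            if excess <= 0:
                continue
            u = float(np.sqrt(excess / 2.0))
            if target_mean - u < 0:
                raise ValueError(
                    "outlier construction needs target_mean - sqrt(excess/2) >= 0; "
                    "variance too large for a non-negative low year"
                )
            values = np.concatenate([base, [target_mean + u, target_mean - u]])
            perm = rng.permutation(n_years)
            values = values[perm]
            hi_year = int(np.where(perm == n_years - 2)[0][0])
            lo_year = int(np.where(perm == n_years - 1)[0][0])
            flagged: tuple[int, ...] = tuple(sorted((hi_year, lo_year)))
        else:
            values = rng.normal(target_mean, np.sqrt(max(target_var, 1e-12)), n_years)
            flagged = ()
        # affine map onto the exact float targets
        m, v = _sample_stats(values)
        if v > 0 and target_var > 0:
            values = target_mean + (values - m) * np.sqrt(target_var / v)
        else:
            values = np.full(n_years, target_mean)
        if values.min() < 0:
            continue  # resample rather than clip (clipping distorts both moments)
        x = np.rint(values).astype(np.int64)
        x[x < 0] = 0
        repaired = _integer_repair(x, target_mean, target_var, rel_tol)
        if repaired is None:
            continue
        return SyntheticCensus(
            years=np.arange(start_year, start_year + n_years),
            juveniles=repaired,
            target_mean=target_mean,
            target_variance=target_var,
            outlier_years=flagged,
        )
    raise ValueError(
        f"could not realize mean={target_mean}, variance={target_var} with "
        f"non-negative integers over {n_years} years"
    )


def observed_stats(series: Sequence[int]) -> ObservedStats:
    """Sample mean and (n−1)-denominator variance of a census series."""
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two census years")
    return ObservedStats(
        mean=float(x.mean()), variance=float(x.var(ddof=1)), n_years=int(x.size)
    )
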