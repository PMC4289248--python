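"""Inverse pattern-oriented inference over the demographic parameter grid.

A parameter combination is a "good" representation of the nursery when
(i) the observed mean juvenile census size falls within the middle 95% of
the Monte-Carlo sampling distribution of simulated window means, (ii) the
observed interannual variance falls within the middle 95% of the simulated
window variances, and (iii) none of the 100 replicate populations went
extinct within their run.  Sweeping the grid and keeping only good
combinations constrains parameters (notably adult mortality) that cannot be
measured directly in the field.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .demography import DemographicParams, LitterDistribution
from .engine import MonteCarloSettings, sampling_distribution

__all__ = [
    "ObservedStats",
    "GridSpec",
    "FitVerdict",
    "middle95_contains",
    "good_fit",
    "build_grid",
    "sweep",
    "region_bounds",
    "variance_explained",
]


@dataclass(frozen=True)
class ObservedStats:
    """Field summary statistics the simulations are tested against."""

    mean: float = 77.0
    variance: float = 498.0
    n_years: int = 17

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError("variance must be non-negative")
        if self.n_years < 2:
            raise ValueError("n_years must be >= 2")


def _arange_inclusive(lo: float, hi: float, step: float) -> tuple[float, ...]:
    n = int(round((hi - lo) / step)) + 1
    return tuple(round(lo + i * step, 10) for i in range(n))


@dataclass(frozen=True)
class GridSpec:
    """Cartesian parameter grid: λ outer, then k, then μ (h held fixed).

    Defaults reproduce the 15 × 20 × 30 = 9000-combination sweep: λ from 1 to
    15 by 1, k from 10 to 200 by 10 (larger k would make first-year mortality
    effectively linear and far weaker than observed), μ from 0.01 to 0.30 by
    0.01, with h = 1.  In empirical-fecundity mode the litter distribution is
    held fixed, so λ is its realized mean rather than a free axis.
    """

    lambda_values: tuple[float, ...] = tuple(float(v) for v in range(1, 16))
    k_values: tuple[float, ...] = tuple(float(v) for v in range(10, 201, 10))
    mu_values: tuple[float, ...] = _arange_inclusive(0.01, 0.30, 0.01)
    h: float = 1.0
    fecundity_mode: str = "poisson"
    litter_dist: Optional[LitterDistribution] = None

    def __post_init__(self) -> None:
        for name in ("lambda_values", "k_values", "mu_values"):
            vals = getattr(self, name)
            if len(vals) == 0:
                raise ValueError(f"{name} must be non-empty")
            if any(b <= a for a, b in zip(vals, vals[1:])):
                raise ValueError(f"{name} must be strictly increasing")
        if self.fecundity_mode == "empirical" and self.litter_dist is None:
            raise ValueError("empirical fecundity sweeps need a litter distribution")

    @property
    def size(self) -> int:
        n_lambda = 1 if self.fecundity_mode == "empirical" else len(self.lambda_values)
        return n_lambda * len(self.k_values) * len(self.mu_values)


@dataclass(frozen=True)
class FitVerdict:
    """Outcome of the three-criterion test at one parameter combination."""

    params: DemographicParams
    mean_ok: bool
    var_ok: bool
    persistence_ok: bool
    mean_of_means: float
    mean_of_variances: float
    n_extinct: int

    @property
    def good(self) -> bool:
        return self.mean_ok and self.var_ok and self.persistence_ok


def middle95_contains(
    values: Sequence[float],
    observed: float,
    alpha: float = 0.05,
    method: str = "interpolation",
) -> bool:
    """Two-tailed membership test against an empirical sampling distribution.

    True iff ``observed`` lies in the closed interval between the ``alpha/2``
    and ``1 - alpha/2`` empirical quantiles.  ``method="interpolation"`` uses
    linear-interpolation quantiles; ``method="trim"`` instead drops the
    ``floor(alpha/2 * n)`` smallest and largest order statistics and tests
    against the remaining range.  Boundary values count as inside.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values")
    if method == "interpolation":
        lo, hi = np.quantile(v, [alpha / 2.0, 1.0 - alpha / 2.0])
    elif method == "trim":
        s = np.sort(v)
        ndrop = int(np.floor(alpha / 2.0 * v.size))
        lo, hi = s[ndrop], s[v.size - 1 - ndrop]
    else:
        raise ValueError(f"unknown quantile method {method!r}")
    return bool(lo <= observed <= hi)


def good_fit(
    params: DemographicParams,
    obs: ObservedStats,
    settings: MonteCarloSettings,
    *,
    combo_index: int = 0,
    quantile_method: str = "interpolation",
) -> FitVerdict:
    """Run the Monte-Carlo protocol at one combination and apply criteria i–iii.

    Each combination draws its replicate streams from a seed derived from
    ``(master_seed, combo_index)``, so enlarging a grid never perturbs the
    verdicts of existing combinations.
    """
    seed = np.random.SeedSequence(settings.master_seed, spawn_key=(int(combo_index),))
    sd = sampling_distribution(params, obs.n_years, settings, seed=seed)
    mean_ok = middle95_contains(sd.means, obs.mean, settings.alpha, quantile_method)
    var_ok = middle95_contains(sd.variances, obs.variance, settings.alpha, quantile_method)
    return FitVerdict(
        params=params,
        mean_ok=mean_ok,
        var_ok=var_ok,
        persistence_ok=sd.n_extinct == 0,
        mean_of_means=float(np.mean(sd.means)),
        mean_of_variances=float(np.mean(sd.variances)),
        n_extinct=sd.n_extinct,
    )


def build_grid(spec: GridSpec) -> list[DemographicParams]:
    """Enumerate the grid in deterministic lexicographic order (λ, k, μ)."""
    if spec.fecundity_mode == "empirical":
        lambdas: Sequence[float] = (spec.litter_dist.mean,)
    else:
        lambdas = spec.lambda_values
    return [
        DemographicParams(
            lambda_mean=lam,
            fecundity_mode=spec.fecundity_mode,
            litter_dist=spec.litter_dist,
            h=spec.h,
            k=k,
            mu=mu,
        )
        for lam, k, mu in itertools.product(lambdas, spec.k_values, spec.mu_values)
    ]


def sweep(
    spec: GridSpec,
    obs: ObservedStats,
    settings: MonteCarloSettings,
    *,
    quantile_method: str = "interpolation",
    n_jobs: int = 1,
    progress: bool = False,
) -> pd.DataFrame:
    """Test every grid combination; one row per :class:`FitVerdict`.

    Deterministic for a given ``settings.master_seed`` and independent of
    ``n_jobs`` (worker scheduling cannot reorder the per-combination seeds).
    """
    combos = build_grid(spec)

    def _one(i: int, p: DemographicParams) -> FitVerdict:
        return good_fit(p, obs, settings, combo_index=i, quantile_method=quantile_method)

    if n_jobs == 1:
        iterator = enumerate(combos)
        if progress:
            from tqdm import tqdm  # optional nicety; never required

            iterator = tqdm(list(iterator), desc="sweep")
        verdicts = [_one(i, p) for i, p in iterator]
    else:
        from joblib import Parallel, delayed

        verdicts = Parallel(n_jobs=n_jobs)(
            delayed(_one)(i, p) for i, p in enumerate(combos)
        )
    rows = [
        {
            "lambda": v.params.lambda_mean,
            "k": v.params.k,
            "mu": v.params.mu,
            "h": v.params.h,
            "mean_of_means": v.mean_of_means,
            "mean_of_variances": v.mean_of_variances,
            "n_extinct": v.n_extinct,
            "mean_ok": v.mean_ok,
            "var_ok": v.var_ok,
            "persistence_ok": v.persistence_ok,
            "good": v.good,
        }
        for v in verdicts
    ]
    return pd.DataFrame(rows)


def region_bounds(verdicts: pd.DataFrame) -> Optional[dict[str, tuple[float, float]]]:
    """Per-parameter (min, max) over good-fit combinations.

    Returns ``None`` — an explicit "no region" — when nothing fit; callers
    must not mistake that for numeric bounds.
    """
    if len(verdicts) == 0:
        raise ValueError("verdict table is empty")
    good = verdicts[verdicts["good"]]
    if len(good) == 0:
        return None
    return {
        p: (float(good[p].min()), float(good[p].max())) for p in ("lambda", "k", "mu")
    }


def variance_explained(
    verdicts: pd.DataFrame, obs: ObservedStats
) -> tuple[pd.Series, Optional[tuple[float, float]]]:
    """Share of the observed interannual variance the model generates, in %.

    Per combination: ``100 * mean_of_variances / obs.variance``.  The second
    element is the (min, max) of that ratio over good fits, or ``None`` when
    the good-fit set is empty.
    """
    if obs.variance <= 0:
        raise ValueError("observed variance must be positive")
    ratio = 100.0 * verdicts["mean_of_variances"] / obs.variance
    ratio.name = "variance_explained_pct"
    good = ratio[verdicts["good"]]
    rng = (float(good.min()), float(good.max())) if len(good) else None
    return ratio, rng
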