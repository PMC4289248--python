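#!/usr/bin/env python
"""Generate the synthetic stand-ins for the unpublished field inputs.

Writes a 17-year synthetic juvenile census (sample mean ~77, sample variance
~498, with one inflated and one deflated year mimicking the influential
censuses) and an over-dispersed litter-size distribution on {0..18} with
mean 6.1, in the CSV formats the rest of the pipeline reads.
"""

import argparse
from pathlib import Path

import numpy as np

from sharkpop import make_census_series, make_litter_distribution, observed_stats

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out-dir", type=Path, default=Path("results"))
args = parser.parse_args()
args.out_dir.mkdir(parents=True, exist_ok=True)

rng = np.random.default_rng(args.seed)
census = make_census_series(17, 77.0, 498.0, outliers=True, rng=rng)
census.to_csv(args.out_dir / "synthetic_census.csv")
obs = observed_stats(census.juveniles)
keep = np.delete(census.juveniles, list(census.outlier_years))
reduced = observed_stats(keep)
print(f"census: mean={obs.mean:.2f} variance={obs.variance:.2f} (targets 77 / 498)")
print(
    f"dropping the {len(census.outlier_years)} flagged years: "
    f"mean={reduced.mean:.2f} variance={reduced.variance:.2f} "
    "(the two outlier years carry most of the variance)"
)

litter = make_litter_distribution(6.1, dispersion=1.5)
with open(args.out_dir / "synthetic_litter.csv", "w") as fh:
    fh.write("# synthetic litter-size distribution; mean=6.1 dispersion=1.5\n")
    litter.to_csv(fh)
print(
    f"litter distribution: mean={litter.mean:.3f} variance={litter.variance:.3f} "
    f"(Poisson at this mean would have variance {litter.mean:.3f})"
)
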