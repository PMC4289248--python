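#!/usr/bin/env python
"""Monte-Carlo sampling distributions at the default calibration.

Runs 100 replicates at lambda=6.1 (Poisson fecundity), mu=0.15, k=100, h=1,
takes one random 17-census window per replicate after the 100-step burn-in,
and summarizes the sampling distributions of the window mean and sample
variance of the juvenile count.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from sharkpop import DemographicParams, MonteCarloSettings, sampling_distribution

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out-dir", type=Path, default=Path("results"))
args = parser.parse_args()
args.out_dir.mkdir(parents=True, exist_ok=True)

params = DemographicParams()
settings = MonteCarloSettings(n_runs=100, master_seed=args.seed)
sd = sampling_distribution(params, 17, settings)
sd.to_frame().to_csv(args.out_dir / "default_calibration_windows.csv", index=False)
summary = sd.summary()
(args.out_dir / "default_calibration_summary.json").write_text(
    json.dumps(summary, indent=2) + "\n"
)

print(f"mean of {settings.n_runs} window means:     {sd.means.mean():8.2f} sharks")
print(f"mean of {settings.n_runs} window variances: {sd.variances.mean():8.2f} sharks^2")
print(f"extinctions within 300 censuses: {sd.n_extinct}")
lo, hi = np.percentile(sd.means, [2.5, 97.5])
print(f"middle 95% of window means: [{lo:.1f}, {hi:.1f}]")
lo, hi = np.percentile(sd.variances, [2.5, 97.5])
print(f"middle 95% of window variances: [{lo:.1f}, {hi:.1f}]")
print(
    "note: the variance matches the published sampling distribution closely, "
    "while the stationary juvenile mean at these defaults sits above the "
    "field mean of 77 (see docs/methods.md on calibration sensitivity)."
)
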