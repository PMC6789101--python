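#!/usr/bin/env python
"""Trend-test every driver-effect series and tabulate attribution.

For each model, quantity (WUE, CUE) and driver (climate, CO2
fertilization, N deposition, combined), runs the TFPW Mann-Kendall
test on the globally aggregated effect series and reports Sen's slope,
the percentage-change metric and the percent contribution.  Writes
results/summary_wue.csv and results/summary_cue.csv.
"""

import sys
from pathlib import Path

from ecoeff import RunConfig, load_ensemble
from ecoeff.attribution import ensemble_summary

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int = 1) -> None:
    cfg = RunConfig(seed=seed)
    ensembles = load_ensemble(ROOT / "scratch" / "archive", cfg)
    for quantity in ("wue", "cue"):
        tab = ensemble_summary(ensembles, quantity, cfg)
        path = ROOT / "results" / f"summary_{quantity}.csv"
        tab.to_csv(path, index=False)
        print(f"\n{quantity.upper()} attribution ({path}):")
        cols = ["model", "driver", "p", "sen_slope", "significant",
                "pct_change", "pct_contribution"]
        print(tab[cols].to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        sub = tab[tab.driver != "combined"]
        dominant = sub.loc[sub.groupby("model").pct_contribution.transform(
            lambda s: s.abs() == s.abs().max()).astype(bool), ["model", "driver"]]
        print("dominant driver per model:",
              dict(zip(dominant.model, dominant.driver)))


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
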