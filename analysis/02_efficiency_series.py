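#!/usr/bin/env python
"""Reduce every model's fluxes to global annual WUE and CUE series.

Writes one (year, value) CSV per model and quantity under
results/series/ plus a CUE quality-control report, and prints the
1901 and 2010 values so the magnitude of each model's drift is visible
at a glance.
"""

import json
import sys
from pathlib import Path

from ecoeff import RunConfig, load_ensemble
from ecoeff.attribution import quantity_field, scenario_series
from ecoeff.efficiency import cue_qc
from ecoeff.errors import VariableNotFoundError

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int = 1) -> None:
    cfg = RunConfig(seed=seed)
    arc = ROOT / "scratch" / "archive"
    out = ROOT / "results" / "series"
    out.mkdir(parents=True, exist_ok=True)
    qc = {}
    for ens in load_ensemble(arc, cfg):
        for quantity in ("wue", "cue"):
            try:
                s = scenario_series(ens, ens.max_scenario, quantity, "global", cfg)
            except VariableNotFoundError:
                print(f"  {ens.model_name}: {quantity} skipped (missing flux)")
                continue
            s.to_frame().to_csv(out / f"{ens.model_name}_{quantity}.csv", index=False)
            print(f"  {ens.model_name} {quantity}: 1901 = {s.values[0]:.4f}, "
                  f"2010 = {s.values[-1]:.4f} {s.units}")
        qc[ens.model_name] = cue_qc(quantity_field(ens, ens.max_scenario, "cue", cfg))
    qc_path = ROOT / "results" / "cue_qc.json"
    qc_path.write_text(json.dumps(qc, sort_keys=True, indent=1) + "\n")
    print(f"series under {out}; QC report {qc_path}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
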