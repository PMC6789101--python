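"""Per-model scenario ensembles and on-disk ensemble trees.

Disk layout consumed by :func:`load_ensemble`::

    root/
      <model>/
        model.json                    # name, has_nitrogen, lai_dynamic
        <scenario>/<variable>.nc      # one CF NetCDF per field

A model may lack a variable entirely (e.g. no evapotranspiration:
such a model enters the carbon-use-efficiency analysis only), never
partially in time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .errors import InconsistentGridError, ScenarioError, VariableNotFoundError
from .grids import GriddedField, read_field, write_field
from .scenarios import SCENARIOS, VARIABLES, max_scenario, scenarios_for


@dataclass
class ScenarioEnsemble:
    """One pseudo-model's fields keyed by (scenario, variable)."""

    model_name: str
    has_nitrogen: bool
    fields: dict[tuple[str, str], GriddedField] = field(default_factory=dict)
    lai_dynamic: bool = True

    def validate(self) -> None:
        ref = None
        for (scen, _var), fld in self.fields.items():
            if scen not in SCENARIOS:
                raise ScenarioError(f"unknown scenario code {scen!r}")
            if scen == "BG1" and not self.has_nitrogen:
                raise ScenarioError(
                    f"scenario inconsistent with model type: C-only model "
                    f"{self.model_name!r} has BG1"
                )
            if ref is None:
                ref = fld
            elif not fld.same_grid(ref):
                raise InconsistentGridError(
                    f"inconsistent grid in model {self.model_name!r}"
                )

    @property
    def max_scenario(self) -> str:
        return max_scenario(self.has_nitrogen)

    @property
    def scenarios(self) -> tuple[str, ...]:
        return tuple(s for s in SCENARIOS if any(k[0] == s for k in self.fields))

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(v for v in VARIABLES if any(k[1] == v for k in self.fields))

    def has_variable(self, variable: str) -> bool:
        return any(k[1] == variable for k in self.fields)

    def get(self, scenario: str, variable: str) -> GriddedField:
        try:
            return self.fields[(scenario, variable)]
        except KeyError:
            raise VariableNotFoundError(
                f"model {self.model_name!r} lacks ({scenario}, {variable})"
            ) from None

    def grid(self) -> GriddedField:
        """Any member field (all share one grid)."""
        return next(iter(self.fields.values()))


def write_ensemble(ens: ScenarioEnsemble, root) -> Path:
    """Write the <model>/<scenario>/<variable>.nc tree plus model.json."""
    ens.validate()
    mdir = Path(root) / ens.model_name
    mdir.mkdir(parents=True, exist_ok=True)
    meta = {
        "model_name": ens.model_name,
        "has_nitrogen": ens.has_nitrogen,
        "lai_dynamic": ens.lai_dynamic,
    }
    (mdir / "model.json").write_text(json.dumps(meta, sort_keys=True, indent=1) + "\n")
    for (scen, var), fld in sorted(ens.fields.items()):
        sdir = mdir / scen
        sdir.mkdir(exist_ok=True)
        write_field(fld, sdir / f"{var}.nc")
    return mdir


def load_ensemble(root, config=None) -> list[ScenarioEnsemble]:
    """Load every model tree under ``root``; never silently drops a field.

    Raises on grid mismatch within a model and on a C-only model
    carrying a BG1 scenario.
    """
    root = Path(root)
    ensembles: list[ScenarioEnsemble] = []
    for mdir in sorted(p for p in root.iterdir() if p.is_dir()):
        meta_path = mdir / "model.json"
        if meta_path.exists():
            meta = json.loads(meta_path.read_text())
            has_n = bool(meta["has_nitrogen"])
            lai_dynamic = bool(meta.get("lai_dynamic", True))
            name = str(meta.get("model_name", mdir.name))
        else:
            has_n = (mdir / "BG1").is_dir()
            lai_dynamic, name = True, mdir.name
        ens = ScenarioEnsemble(model_name=name, has_nitrogen=has_n, lai_dynamic=lai_dynamic)
        for sdir in sorted(p for p in mdir.iterdir() if p.is_dir()):
            scen = sdir.name
            if scen not in SCENARIOS:
                raise ScenarioError(f"unknown scenario directory {scen!r} in {name!r}")
            if scen == "BG1" and not has_n:
                raise ScenarioError(
                    f"scenario inconsistent with model type: C-only model {name!r} has BG1"
                )
            for nc in sorted(sdir.glob("*.nc")):
                var = nc.stem
                ens.fields[(scen, var)] = read_field(nc, var)
        ens.validate()
        _check_no_partial_variables(ens)
        ensembles.append(ens)
    return ensembles


def _check_no_partial_variables(ens: ScenarioEnsemble) -> None:
    # an annual variable must be present for every scenario the model ran,
    # or none; LAI is exempt (real archives supply it for a scenario subset)
    scens = ens.scenarios
    for var in ens.variables:
        if var == "lai":
            continue
        have = tuple(s for s in scens if (s, var) in ens.fields)
        if have != scens:
            missing = set(scens) - set(have)
            raise ScenarioError(
                f"model {ens.model_name!r}: variable {var!r} missing from "
                f"scenarios {sorted(missing)} but present elsewhere"
            )


__all__ = [
    "ScenarioEnsemble",
    "write_ensemble",
    "load_ensemble",
    "scenarios_for",
]
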