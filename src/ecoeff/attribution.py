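"""Driver attribution by factorial scenario differencing.

Single-driver impacts on any quantity come from differencing the
scenario pair that toggles exactly that driver: climate = SG1 - RG1,
CO2 fertilization = SG3 - SG2, N deposition = BG1 - SG3 (carbon-
nitrogen models only).  The combined impact is the all-drivers-on
scenario (BG1, or SG3 for carbon-only models) net of its 1901 value.

For ratio quantities (WUE, CUE) the efficiency is computed per scenario
FIRST and then differenced — the driver effect on the efficiency, not
the efficiency of the flux differences.

Percent contribution of a driver is the ratio of the mean effect series
to the mean combined-scenario series over the same years and scope,
times 100.  The dominant driver at a cell is the one with the largest
|percent contribution|; cells where every driver falls below a small
threshold are labeled "none", and ties break in the fixed order
climate > co2 > ndep.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import xarray as xr

from .config import RunConfig
from .efficiency import (
    EfficiencySeries,
    aggregate_ratio,
    area_weighted_mean,
    compute_cue,
    compute_wue,
)
from .ensemble import ScenarioEnsemble
from .errors import ScenarioError, VariableNotFoundError
from .grids import GriddedField
from .scenarios import DRIVER_PAIRS
from .trends import percentage_change, tfpw_mk_test

#: integer codes for the categorical dominant-driver grid
DRIVER_CODES = {"none": 0, "climate": 1, "co2": 2, "ndep": 3}
_CODE_NAMES = {v: k for k, v in DRIVER_CODES.items()}
_TIE_ORDER = ("climate", "co2", "ndep")

_RATIO_PARTS = {"wue": ("gpp", "et"), "cue": ("npp", "gpp")}


@dataclass
class DriverEffect:
    """Per-year impact series of one driver on one quantity."""

    driver: str
    quantity: str
    scope: object
    years: np.ndarray
    values: np.ndarray
    units: str = ""
    percent_contribution: float | None = None

    def as_series(self) -> EfficiencySeries:
        return EfficiencySeries(self.quantity, self.scope, self.years, self.values,
                                self.units)


@dataclass
class DominantDriverMap:
    """Per-cell categorical dominant-driver labels plus audit magnitudes."""

    quantity: str
    period: tuple[int, int]
    labels: np.ndarray  # (lat, lon) int codes, -1 over ocean
    lat: np.ndarray
    lon: np.ndarray
    land_mask: np.ndarray
    contributions: dict = dc_field(default_factory=dict)  # driver -> (lat, lon) %

    def label_name(self, i: int, j: int) -> str:
        code = int(self.labels[i, j])
        return "ocean" if code < 0 else _CODE_NAMES[code]

    def to_xarray(self) -> xr.Dataset:
        ds = xr.Dataset(
            {
                "dominant_driver": (
                    ("lat", "lon"), self.labels.astype(np.int32),
                    {"flag_values": "0 1 2 3",
                     "flag_meanings": "none climate co2 ndep",
                     "missing_value": np.int32(-1),
                     "long_name": f"dominant driver of {self.quantity}, "
                                  f"{self.period[0]}-{self.period[1]}"},
                ),
            },
            coords={
                "lat": ("lat", self.lat, {"units": "degrees_north"}),
                "lon": ("lon", self.lon, {"units": "degrees_east"}),
            },
        )
        for d, c in sorted(self.contributions.items()):
            ds[f"pct_contribution_{d}"] = (("lat", "lon"), c, {"units": "percent"})
        return ds

    def to_netcdf(self, path) -> None:
        self.to_xarray().to_netcdf(path, engine="scipy", format="NETCDF3_CLASSIC")


def _applicable_drivers(ens: ScenarioEnsemble) -> tuple[str, ...]:
    return ("climate", "co2", "ndep") if ens.has_nitrogen else ("climate", "co2")


def quantity_field(ens: ScenarioEnsemble, scenario: str, quantity: str,
                   config: RunConfig | None = None) -> GriddedField:
    """Per-cell field of a quantity for one scenario (ratios formed here)."""
    cfg = config or RunConfig()
    if quantity == "wue":
        return compute_wue(ens.get(scenario, "gpp"), ens.get(scenario, "et"),
                           et_floor=cfg.et_floor)
    if quantity == "cue":
        return compute_cue(ens.get(scenario, "npp"), ens.get(scenario, "gpp"),
                           gpp_floor=cfg.gpp_floor)
    return ens.get(scenario, quantity)


def scenario_series(ens: ScenarioEnsemble, scenario: str, quantity: str,
                    scope="global", config: RunConfig | None = None) -> EfficiencySeries:
    """Aggregate one scenario's quantity to a scalar series.

    Ratio quantities aggregate-then-divide by default (ratio of
    area-weighted flux means); set ``config.aggregation`` to
    ``"mean_of_ratios"`` for the other order.
    """
    cfg = config or RunConfig()
    if quantity in _RATIO_PARTS and cfg.aggregation == "ratio_of_means":
        num, den = _RATIO_PARTS[quantity]
        floor = cfg.et_floor if quantity == "wue" else cfg.gpp_floor
        return aggregate_ratio(ens.get(scenario, num), ens.get(scenario, den),
                               scope=scope, den_floor=floor, quantity=quantity)
    return area_weighted_mean(quantity_field(ens, scenario, quantity, cfg), scope)


def _require(ens: ScenarioEnsemble, quantity: str) -> None:
    needed = _RATIO_PARTS.get(quantity, (quantity,))
    for v in needed:
        if not ens.has_variable(v):
            raise VariableNotFoundError(
                f"quantity unavailable: model {ens.model_name!r} lacks {v!r}"
            )


def driver_effect(ens: ScenarioEnsemble, driver: str, quantity: str,
                  scope="global", config: RunConfig | None = None) -> DriverEffect:
    """Single-driver impact series from the factorial scenario pair."""
    if driver == "combined":
        return net_change(ens, quantity, scope, config)
    if driver not in DRIVER_PAIRS:
        raise ValueError(f"unknown driver {driver!r}")
    if driver == "ndep" and not ens.has_nitrogen:
        raise ScenarioError(
            f"driver unavailable for model type: {ens.model_name!r} is carbon-only"
        )
    _require(ens, quantity)
    hi, lo = DRIVER_PAIRS[driver]
    a = scenario_series(ens, hi, quantity, scope, config)
    b = scenario_series(ens, lo, quantity, scope, config)
    return DriverEffect(driver, quantity, scope, a.years, a.values - b.values, a.units)


def net_change(ens: ScenarioEnsemble, quantity: str, scope="global",
               config: RunConfig | None = None) -> DriverEffect:
    """Combined-impact series: all-drivers scenario minus its 1901 value."""
    _require(ens, quantity)
    s = scenario_series(ens, ens.max_scenario, quantity, scope, config)
    years = np.floor(s.years).astype(int)
    if 1901 not in years:
        raise ValueError("1901 absent from time axis; net change undefined")
    base = s.values[years == 1901][0]
    return DriverEffect("combined", quantity, scope, s.years, s.values - base, s.units)


def percent_contribution(effect: DriverEffect, ens: ScenarioEnsemble,
                         years: tuple[int, int] = (1901, 2010),
                         config: RunConfig | None = None) -> float:
    """100 * mean(effect series) / mean(combined-scenario series).

    The denominator is the BG1 series for carbon-nitrogen models and
    the SG3 series for carbon-only models, over the same years/scope.
    """
    y0, y1 = years
    denom_series = scenario_series(ens, ens.max_scenario, effect.quantity,
                                   effect.scope, config).window(y0, y1)
    eff = effect.as_series().window(y0, y1)
    denom = float(np.nanmean(denom_series.values))
    if denom == 0.0 or not np.isfinite(denom):
        raise ZeroDivisionError("undefined contribution: zero denominator mean")
    pct = 100.0 * float(np.nanmean(eff.values)) / denom
    effect.percent_contribution = pct
    return pct


def percent_increase(series: EfficiencySeries, y0: int = 1901, y1: int = 2010) -> float:
    """100 * (x[y1] - x[y0]) / x[y0]."""
    a, b = series.at_year(y0), series.at_year(y1)
    if a == 0.0:
        raise ZeroDivisionError(f"undefined percent increase: value at {y0} is zero")
    return 100.0 * (b - a) / a


# ---------------------------------------------------------------------------
# per-cell dominance

def _cell_contribution_maps(ens: ScenarioEnsemble, quantity: str,
                            period: tuple[int, int],
                            config: RunConfig | None = None) -> tuple[dict, GriddedField]:
    """Per-cell mean driver-effect maps and the per-cell denominator mean."""
    cfg = config or RunConfig()
    y0, y1 = period
    denom_field = quantity_field(ens, ens.max_scenario, quantity, cfg).select_years(y0, y1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN ocean cells
        denom_mean = np.nanmean(denom_field.values, axis=2)
        maps = {}
        for d in _applicable_drivers(ens):
            hi, lo = DRIVER_PAIRS[d]
            fa = quantity_field(ens, hi, quantity, cfg).select_years(y0, y1)
            fb = quantity_field(ens, lo, quantity, cfg).select_years(y0, y1)
            maps[d] = np.nanmean(fa.values - fb.values, axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = {d: 100.0 * m / denom_mean for d, m in maps.items()}
    return pct, denom_field


def _classify(pct: dict, land_mask: np.ndarray, threshold: float) -> np.ndarray:
    shape = land_mask.shape
    labels = np.full(shape, -1, dtype=int)
    drivers = [d for d in _TIE_ORDER if d in pct]
    mags = np.stack([np.abs(pct[d]) for d in drivers])  # tie order = stack order
    mags = np.where(np.isfinite(mags), mags, -np.inf)
    best = np.argmax(mags, axis=0)  # argmax takes first max -> fixed tie order
    best_mag = np.take_along_axis(mags, best[None], axis=0)[0]
    code = np.array([DRIVER_CODES[d] for d in drivers])[best]
    code = np.where(best_mag >= threshold, code, DRIVER_CODES["none"])
    labels[land_mask] = code[land_mask]
    return labels


def dominant_driver_map(ens: ScenarioEnsemble, quantity: str,
                        period: tuple[int, int] = (1982, 2008),
                        threshold: float = 0.1,
                        config: RunConfig | None = None) -> DominantDriverMap:
    """Per-cell dominant driver of a quantity over a period for one model."""
    _require(ens, quantity)
    pct, denom_field = _cell_contribution_maps(ens, quantity, period, config)
    labels = _classify(pct, denom_field.land_mask, threshold)
    return DominantDriverMap(
        quantity=quantity, period=period, labels=labels,
        lat=denom_field.lat, lon=denom_field.lon, land_mask=denom_field.land_mask,
        contributions=pct,
    )


def dominant_driver_map_ensemble(ensembles: list[ScenarioEnsemble], quantity: str,
                                 period: tuple[int, int] = (1982, 2008),
                                 threshold: float = 0.1,
                                 config: RunConfig | None = None) -> DominantDriverMap:
    """Dominance computed on the multi-model mean.

    Per-cell effect and denominator maps are averaged over the models
    that provide the quantity (each model contributing its own maximal
    scenario) before classification.
    """
    usable = []
    for ens in ensembles:
        try:
            _require(ens, quantity)
        except VariableNotFoundError:
            continue
        usable.append(ens)
    if not usable:
        raise VariableNotFoundError(f"no model provides {quantity!r}")
    acc_pct: dict[str, list] = {}
    ref = None
    for ens in usable:
        pct, denom_field = _cell_contribution_maps(ens, quantity, period, config)
        ref = denom_field
        for d, m in pct.items():
            acc_pct.setdefault(d, []).append(m)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # ocean cells all-NaN
        mean_pct = {d: np.nanmean(np.stack(ms), axis=0) for d, ms in acc_pct.items()}
    labels = _classify(mean_pct, ref.land_mask, threshold)
    return DominantDriverMap(
        quantity=quantity, period=period, labels=labels,
        lat=ref.lat, lon=ref.lon, land_mask=ref.land_mask, contributions=mean_pct,
    )


def ensemble_summary(ensembles: list[ScenarioEnsemble], quantity: str,
                     config: RunConfig | None = None) -> pd.DataFrame:
    """Per (model, driver) trend test, percentage change and contribution.

    Rows: TFPW-MK result on the driver-effect series plus the
    percentage-change metric and percent contribution.  Models lacking
    a needed variable (e.g. no evapotranspiration for WUE) are skipped
    for that quantity.
    """
    cfg = config or RunConfig()
    rows = []
    for ens in ensembles:
        try:
            _require(ens, quantity)
        except VariableNotFoundError:
            continue
        drivers = list(_applicable_drivers(ens)) + ["combined"]
        for d in drivers:
            eff = driver_effect(ens, d, quantity, "global", cfg)
            res = tfpw_mk_test(eff.values, alpha=cfg.alpha)
            denom = scenario_series(ens, ens.max_scenario, quantity, "global", cfg)
            mean_q = float(np.nanmean(denom.values))
            pct_chg = percentage_change(res.sen_slope, eff.years.size, mean_q) \
                if mean_q != 0.0 else np.nan
            pct_con = (percent_contribution(eff, ens, config=cfg)
                       if d != "combined" else np.nan)
            rows.append({
                "model": ens.model_name, "quantity": quantity, "driver": d,
                "n": res.n, "S": res.S, "z": res.z, "p": res.p, "tau": res.tau,
                "sen_slope": res.sen_slope, "significant": res.significant,
                "pct_change": pct_chg, "pct_contribution": pct_con,
            })
    return pd.DataFrame(rows)
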