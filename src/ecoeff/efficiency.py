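"""Water- and carbon-use efficiency fields and their spatial aggregates.

WUE = GPP/ET (gC per kgH2O) and CUE = NPP/GPP (dimensionless) are
formed per grid cell with floor thresholds on the denominators; cells
below the floor become missing, never zero or infinite.  Aggregation to
global or latitude-band series weights land cells by cos(latitude);
missing cells leave both the numerator and the denominator.

For ratio quantities two aggregation orders exist and differ on
heterogeneous grids: aggregate-then-divide (the ratio of area-weighted
flux totals — the pipeline default, robust to near-zero-ET cells) and
divide-then-aggregate (the area-weighted mean of cell ratios).  Both
are exposed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyDomainError, InconsistentGridError
from .grids import CANONICAL_UNITS, GriddedField


@dataclass
class EfficiencySeries:
    """A scalar annual (or monthly) series reduced from a gridded field."""

    quantity: str
    scope: object  # "global" | ("band", lo, hi) | ("cell", i, j)
    years: np.ndarray  # time axis (float years)
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.years.size != self.values.size:
            raise ValueError("years and values must have equal length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.years, "value": self.values})

    def window(self, y0: int, y1: int) -> "EfficiencySeries":
        keep = (np.floor(self.years) >= y0) & (np.floor(self.years) <= y1)
        return EfficiencySeries(self.quantity, self.scope,
                                self.years[keep], self.values[keep], self.units)

    def at_year(self, year: int) -> float:
        idx = np.nonzero(np.floor(self.years).astype(int) == year)[0]
        if idx.size == 0:
            raise KeyError(f"year {year} not in series")
        return float(np.nanmean(self.values[idx]))


def _check_same_grid(a: GriddedField, b: GriddedField) -> None:
    if not a.same_grid(b) or a.time.shape != b.time.shape or \
            not np.array_equal(a.time, b.time):
        raise InconsistentGridError("fields do not share a grid/time axis")


def compute_wue(gpp: GriddedField, et: GriddedField, et_floor: float = 10.0) -> GriddedField:
    """Per-cell WUE = GPP/ET; cells with ET below the floor become missing."""
    _check_same_grid(gpp, et)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(et.values >= et_floor, gpp.values / et.values, np.nan)
    return GriddedField(
        name="wue", values=vals, lat=gpp.lat, lon=gpp.lon, time=gpp.time,
        units=CANONICAL_UNITS["wue"], land_mask=gpp.land_mask, freq=gpp.freq,
    )


def compute_cue(npp: GriddedField, gpp: GriddedField, gpp_floor: float = 1.0) -> GriddedField:
    """Per-cell CUE = NPP/GPP; GPP below the floor becomes missing.

    Values outside [0, 1] are retained, not clipped (clipping would bias
    trend statistics); :func:`cue_qc` counts them.
    """
    _check_same_grid(npp, gpp)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(gpp.values >= gpp_floor, npp.values / gpp.values, np.nan)
    return GriddedField(
        name="cue", values=vals, lat=npp.lat, lon=npp.lon, time=npp.time,
        units=CANONICAL_UNITS["cue"], land_mask=npp.land_mask, freq=npp.freq,
    )


def cue_qc(cue: GriddedField) -> dict:
    """QC tally of CUE values outside the physical [0, 1] range."""
    finite = np.isfinite(cue.values)
    out = finite & ((cue.values < 0.0) | (cue.values > 1.0))
    return {
        "n_finite": int(finite.sum()),
        "n_outside_unit_interval": int(out.sum()),
        "fraction_outside": float(out.sum() / max(finite.sum(), 1)),
        "min": float(np.nanmin(cue.values)) if finite.any() else None,
        "max": float(np.nanmax(cue.values)) if finite.any() else None,
    }


def _scope_selector(field: GriddedField, scope):
    """Boolean (lat, lon) selector for a scope, restricted to land."""
    sel = field.land_mask.copy()
    if scope == "global":
        pass
    elif isinstance(scope, tuple) and scope[0] == "band":
        _, lo, hi = scope
        inband = (field.lat > lo) & (field.lat <= hi)
        sel &= inband[:, None]
    elif isinstance(scope, tuple) and scope[0] == "cell":
        _, i, j = scope
        cell = np.zeros_like(sel)
        cell[i, j] = True
        sel &= cell
    else:
        raise ValueError(f"unknown scope {scope!r}")
    if not sel.any():
        raise EmptyDomainError(f"empty aggregation domain for scope {scope!r}")
    return sel


def area_weighted_mean(field: GriddedField, scope="global") -> EfficiencySeries:
    """cos(latitude)-weighted mean over unmasked, non-missing land cells.

    Missing cells are excluded from both numerator and denominator at
    each time step independently.
    """
    sel = _scope_selector(field, scope)
    w = np.cos(np.deg2rad(field.lat))[:, None] * np.ones((1, field.lon.size))
    w = np.where(sel, w, 0.0)[:, :, None]
    finite = np.isfinite(field.values)
    num = np.nansum(np.where(finite, field.values, 0.0) * w, axis=(0, 1))
    den = np.sum(np.where(finite, w, 0.0), axis=(0, 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(den > 0.0, num / den, np.nan)
    return EfficiencySeries(field.name, scope, field.time, vals, field.units)


def aggregate_ratio(num_field: GriddedField, den_field: GriddedField,
                    scope="global", den_floor: float = 0.0,
                    quantity: str | None = None) -> EfficiencySeries:
    """Aggregate-then-divide: ratio of area-weighted flux means.

    Cells where either flux is missing (or the denominator is below the
    floor) leave both sums, so numerator and denominator always cover
    the same cells.
    """
    _check_same_grid(num_field, den_field)
    sel = _scope_selector(num_field, scope)
    w = np.cos(np.deg2rad(num_field.lat))[:, None] * np.ones((1, num_field.lon.size))
    w = np.where(sel, w, 0.0)[:, :, None]
    ok = (np.isfinite(num_field.values) & np.isfinite(den_field.values)
          & (den_field.values >= den_floor))
    num = np.nansum(np.where(ok, num_field.values, 0.0) * w, axis=(0, 1))
    den = np.nansum(np.where(ok, den_field.values, 0.0) * w, axis=(0, 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(den != 0.0, num / den, np.nan)
    q = quantity or f"{num_field.name}/{den_field.name}"
    units = _ratio_units(num_field, den_field)
    return EfficiencySeries(q, scope, num_field.time, vals, units)


def ratio_of_means_vs_mean_of_ratios(
    num_field: GriddedField, den_field: GriddedField, scope="global",
    den_floor: float = 0.0, quantity: str | None = None,
) -> tuple[EfficiencySeries, EfficiencySeries]:
    """Both aggregation orders for a ratio quantity.

    Returns ``(aggregate_then_divide, divide_then_aggregate)``; the two
    coincide for spatially uniform fields and diverge otherwise.
    """
    rom = aggregate_ratio(num_field, den_field, scope, den_floor, quantity)
    with np.errstate(invalid="ignore", divide="ignore"):
        cell_ratio = np.where(den_field.values >= max(den_floor, 1e-300),
                              num_field.values / den_field.values, np.nan)
    ratio_field = GriddedField(
        name=quantity or rom.quantity, values=cell_ratio, lat=num_field.lat,
        lon=num_field.lon, time=num_field.time, units=rom.units,
        land_mask=num_field.land_mask, freq=num_field.freq,
    )
    mor = area_weighted_mean(ratio_field, scope)
    return rom, mor


def _ratio_units(num_field: GriddedField, den_field: GriddedField) -> str:
    pair = (num_field.name, den_field.name)
    if pair == ("gpp", "et"):
        return CANONICAL_UNITS["wue"]
    if pair == ("npp", "gpp"):
        return CANONICAL_UNITS["cue"]
    return f"({num_field.units})/({den_field.units})"
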