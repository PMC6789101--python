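"""Gridded fields and CF-style NetCDF I/O.

A :class:`GriddedField` is the atom of the pipeline: one variable on a
(lat, lon, time) grid with a land mask, a units label from a closed
canonical set, and NaN as the single missing-value sentinel.  Any
computation touching a missing value yields missing, never zero, so
ocean and undefined cells cannot bias aggregates.

Time is stored as a float axis: annual fields carry integer-valued
calendar years; monthly fields carry ``year + (month - 0.5) / 12`` and
are tagged ``freq="monthly"`` (months recoverable exactly by rounding).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import xarray as xr

from .errors import MalformedGridError, UnknownUnitsError, VariableNotFoundError

#: canonical units per variable after normalization
CANONICAL_UNITS = {
    "gpp": "gC m-2 yr-1",
    "npp": "gC m-2 yr-1",
    "ra": "gC m-2 yr-1",
    "et": "kgH2O m-2 yr-1",
    "lai": "m2 m-2",
    "soil_moisture": "kg m-2",
    "soil_temperature": "K",
    "wue": "gC kgH2O-1",
    "cue": "1",
}

_SECONDS_PER_YEAR = 365.0 * 86400.0  # 365-day convention, no leap handling

#: alias -> (scale, offset, canonical label)
_UNIT_TABLE = {
    "gC m-2 yr-1": (1.0, 0.0, "gC m-2 yr-1"),
    "g C m-2 yr-1": (1.0, 0.0, "gC m-2 yr-1"),
    "gC/m2/yr": (1.0, 0.0, "gC m-2 yr-1"),
    "gC m-2 day-1": (365.0, 0.0, "gC m-2 yr-1"),
    "gC m-2 s-1": (_SECONDS_PER_YEAR, 0.0, "gC m-2 yr-1"),
    "kgC m-2 s-1": (1000.0 * _SECONDS_PER_YEAR, 0.0, "gC m-2 yr-1"),
    "kgC m-2 yr-1": (1000.0, 0.0, "gC m-2 yr-1"),
    "kgH2O m-2 yr-1": (1.0, 0.0, "kgH2O m-2 yr-1"),
    "kg m-2 yr-1": (1.0, 0.0, "kgH2O m-2 yr-1"),
    "mm yr-1": (1.0, 0.0, "kgH2O m-2 yr-1"),
    "mm/yr": (1.0, 0.0, "kgH2O m-2 yr-1"),
    "kg m-2 s-1": (_SECONDS_PER_YEAR, 0.0, "kgH2O m-2 yr-1"),
    "kgH2O m-2 s-1": (_SECONDS_PER_YEAR, 0.0, "kgH2O m-2 yr-1"),
    "m2 m-2": (1.0, 0.0, "m2 m-2"),
    "m2/m2": (1.0, 0.0, "m2 m-2"),
    "1": (1.0, 0.0, "1"),
    "kg m-2": (1.0, 0.0, "kg m-2"),
    "mm": (1.0, 0.0, "kg m-2"),
    "K": (1.0, 0.0, "K"),
    "degC": (1.0, 273.15, "K"),
    "gC kgH2O-1": (1.0, 0.0, "gC kgH2O-1"),
    "gC/kgH2O": (1.0, 0.0, "gC kgH2O-1"),
}

_FILL_VALUE = 1.0e20


def normalize_units(values: np.ndarray, units: str) -> tuple[np.ndarray, str]:
    """Convert ``values`` with a recognized units label to canonical units.

    Idempotent: canonical labels map to the identity transform.
    Raises :class:`UnknownUnitsError` for labels outside the table.
    """
    try:
        scale, offset, canonical = _UNIT_TABLE[units.strip()]
    except KeyError:
        raise UnknownUnitsError(f"unknown units: {units!r}") from None
    if scale == 1.0 and offset == 0.0:
        return np.asarray(values, dtype=float), canonical
    return np.asarray(values, dtype=float) * scale + offset, canonical


def monthly_time_axis(years: np.ndarray) -> np.ndarray:
    """Fractional-year axis for all 12 months of each year."""
    years = np.asarray(years, dtype=float)
    months = np.arange(1, 13)
    return (years[:, None] + (months[None, :] - 0.5) / 12.0).ravel()


def months_of(time: np.ndarray) -> np.ndarray:
    """Recover month indices 1..12 from a monthly fractional-year axis."""
    frac = np.asarray(time, dtype=float) % 1.0
    return np.rint(frac * 12.0 + 0.5).astype(int)


def years_of(time: np.ndarray) -> np.ndarray:
    """Recover integer calendar years from an annual or monthly axis."""
    return np.floor(np.asarray(time, dtype=float)).astype(int)


@dataclass
class GriddedField:
    """One variable on a (lat, lon, time) grid with land mask and units.

    ``values`` has shape ``(len(lat), len(lon), len(time))`` with NaN as
    the missing sentinel; every ocean cell (mask False) is missing at
    all times.
    """

    name: str
    values: np.ndarray
    lat: np.ndarray
    lon: np.ndarray
    time: np.ndarray
    units: str
    land_mask: np.ndarray
    freq: str = "annual"
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        self.land_mask = np.asarray(self.land_mask, dtype=bool)
        self.validate()

    def validate(self) -> None:
        expected = (self.lat.size, self.lon.size, self.time.size)
        if self.values.shape != expected:
            raise MalformedGridError(
                f"values shape {self.values.shape} != (lat, lon, time) {expected}"
            )
        for axis_name, axis in (("lat", self.lat), ("lon", self.lon), ("time", self.time)):
            d = np.diff(axis)
            if axis.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
                raise MalformedGridError(f"malformed grid: {axis_name} not strictly monotonic")
        if self.land_mask.shape != (self.lat.size, self.lon.size):
            raise MalformedGridError("land mask shape does not match grid")
        # enforce the ocean-is-missing invariant
        self.values[~self.land_mask, :] = np.nan
        if self.freq not in ("annual", "monthly"):
            raise ValueError(f"unknown frequency {self.freq!r}")

    @property
    def years(self) -> np.ndarray:
        return years_of(self.time)

    def same_grid(self, other: "GriddedField") -> bool:
        return (
            self.lat.shape == other.lat.shape
            and self.lon.shape == other.lon.shape
            and np.array_equal(self.lat, other.lat)
            and np.array_equal(self.lon, other.lon)
            and np.array_equal(self.land_mask, other.land_mask)
        )

    def copy(self) -> "GriddedField":
        return replace(
            self,
            values=self.values.copy(),
            lat=self.lat.copy(),
            lon=self.lon.copy(),
            time=self.time.copy(),
            land_mask=self.land_mask.copy(),
            attrs=dict(self.attrs),
        )

    def select_years(self, y0: int, y1: int) -> "GriddedField":
        """Restrict the time axis to calendar years y0..y1 inclusive."""
        keep = (self.years >= y0) & (self.years <= y1)
        return replace(self, values=self.values[:, :, keep], time=self.time[keep])

    def to_xarray(self) -> xr.Dataset:
        data = np.where(np.isfinite(self.values), self.values, _FILL_VALUE)
        ds = xr.Dataset(
            {
                self.name: (
                    ("lat", "lon", "time"),
                    data,
                    {"units": self.units, "missing_value": _FILL_VALUE,
                     "_FillValue": _FILL_VALUE},
                ),
                "land_mask": (("lat", "lon"), self.land_mask.astype(np.int8),
                              {"flag_values": "0 1", "flag_meanings": "ocean land"}),
            },
            coords={
                "lat": ("lat", self.lat, {"units": "degrees_north"}),
                "lon": ("lon", self.lon, {"units": "degrees_east"}),
                "time": ("time", self.time, {"units": "year", "frequency": self.freq}),
            },
            attrs={"Conventions": "CF-1.8", **self.attrs},
        )
        return ds


def write_field(fld: GriddedField, path) -> None:
    """Write a field as CF-style classic NetCDF; deterministic for fixed input."""
    ds = fld.to_xarray()
    ds.to_netcdf(path, engine="scipy", format="NETCDF3_CLASSIC")


def read_field(path, variable: str) -> GriddedField:
    """Read one variable from a CF-style NetCDF file into a GriddedField.

    Units are normalized to the canonical set; the land mask comes from
    an explicit ``land_mask`` variable if present, else is inferred as
    "finite at any time".
    """
    with xr.open_dataset(path, engine="scipy", mask_and_scale=False, decode_times=False) as ds:
        if variable not in ds:
            raise VariableNotFoundError(f"variable not found: {variable!r}")
        da = ds[variable]
        lat = _coord(ds, ("lat", "latitude"))
        lon = _coord(ds, ("lon", "longitude"))
        time = _coord(ds, ("time", "year"))
        values = np.asarray(da.transpose("lat", "lon", "time").values, dtype=float)
        fill = da.attrs.get("_FillValue", da.attrs.get("missing_value"))
        if fill is not None:
            values = np.where(np.isclose(values, float(fill)), np.nan, values)
        units = da.attrs.get("units")
        if units is None:
            raise UnknownUnitsError(f"unknown units: variable {variable!r} has no units attribute")
        values, units = normalize_units(values, str(units))
        if "land_mask" in ds:
            mask = np.asarray(ds["land_mask"].values).astype(bool)
        else:
            mask = np.isfinite(values).any(axis=2)
        freq = str(ds["time"].attrs.get("frequency", "annual")) if "time" in ds else "annual"
        return GriddedField(
            name=variable, values=values, lat=lat, lon=lon, time=time,
            units=units, land_mask=mask, freq=freq,
        )


def _coord(ds: xr.Dataset, names: tuple[str, ...]) -> np.ndarray:
    for n in names:
        if n in ds.coords or n in ds:
            return np.asarray(ds[n].values, dtype=float)
    raise MalformedGridError(f"malformed grid: none of {names} present")
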