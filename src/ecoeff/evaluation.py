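"""Model-vs-reference comparison and the N-deposition LAI procedure.

Modeled water-use efficiency from the climate-only (SG1) scenario is
compared to a reference WUE series over a fixed window (default
1982-2008, 27 annual values): mean absolute error, mean bias, and a
TFPW Mann-Kendall trend test on each series.

The leaf-area-index N-deposition analysis is restricted to land north
of 25 degrees latitude (the nitrogen-limited zone) and the April-
October months: for each year, the area-weighted monthly means of the
seven growing-season months are averaged with equal month weights,
yielding one annual series for 1901-2010.  The N-deposition impact is
the BG1 minus SG3 difference of that series.  Models whose LAI is
prescribed rather than dynamically estimated are excluded via the
``lai_dynamic`` capability flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import RunConfig
from .efficiency import EfficiencySeries, area_weighted_mean
from .ensemble import ScenarioEnsemble
from .errors import EcoeffError, EmptyDomainError
from .grids import months_of, years_of
from .trends import TrendResult, tfpw_mk_test


@dataclass
class ComparisonReport:
    """Model-vs-reference agreement over one window."""

    model_name: str
    window: tuple[int, int]
    mae: float
    bias: float  # mean(model - reference)
    model_trend: TrendResult
    reference_trend: TrendResult

    def to_dict(self) -> dict:
        return {
            "model_name": self.model_name,
            "window": list(self.window),
            "mae": self.mae,
            "bias": self.bias,
            "model_trend": self.model_trend.to_dict(),
            "reference_trend": self.reference_trend.to_dict(),
        }


def compare_to_reference(model_wue: EfficiencySeries, reference_wue: EfficiencySeries,
                         window: tuple[int, int] = (1982, 2008),
                         alpha: float = 0.05,
                         model_name: str = "model") -> ComparisonReport:
    """MAE, bias and per-series TFPW-MK trends over the window years."""
    y0, y1 = window
    m = model_wue.window(y0, y1)
    r = reference_wue.window(y0, y1)
    wanted = np.arange(y0, y1 + 1)
    for s, label in ((m, "model"), (r, "reference")):
        have = np.floor(s.years).astype(int)
        if not np.isin(wanted, have).all():
            raise EcoeffError(f"{label} series does not cover the window {y0}-{y1}")
    diff = m.values - r.values
    return ComparisonReport(
        model_name=model_name,
        window=window,
        mae=float(np.mean(np.abs(diff))),
        bias=float(np.mean(diff)),
        model_trend=tfpw_mk_test(m.values, alpha=alpha),
        reference_trend=tfpw_mk_test(r.values, alpha=alpha),
    )


def lai_ndep_series(ens: ScenarioEnsemble, months: tuple[int, int] = (4, 10),
                    lat_min: float = 25.0,
                    config: RunConfig | None = None
                    ) -> tuple[EfficiencySeries, EfficiencySeries]:
    """Growing-season LAI series north of ``lat_min`` and its N-dep impact.

    Returns ``(bg1_series, bg1_minus_sg3_series)`` of annual values,
    each year the equal-weight average of the area-weighted means of
    months ``months[0]..months[1]`` over land cells with center
    latitude strictly north of ``lat_min``.
    """
    if not ens.has_nitrogen:
        raise EcoeffError(f"not applicable: {ens.model_name!r} is carbon-only")
    if not ens.lai_dynamic:
        raise EcoeffError(
            f"not applicable: {ens.model_name!r} LAI is prescribed, not dynamic"
        )
    scope = ("band", lat_min, 90.0)
    out = {}
    for scen in ("BG1", "SG3"):
        fld = ens.get(scen, "lai")
        if fld.freq != "monthly":
            raise EcoeffError("monthly LAI required")
        monthly = area_weighted_mean(fld, scope)  # may raise EmptyDomainError
        mon = months_of(monthly.years)
        yrs = years_of(monthly.years)
        keep = (mon >= months[0]) & (mon <= months[1])
        years = np.unique(yrs)
        vals = np.array([
            np.mean(monthly.values[keep & (yrs == y)]) for y in years
        ])
        out[scen] = EfficiencySeries("lai", scope, years.astype(float), vals,
                                     fld.units)
    diff = EfficiencySeries("lai", scope, out["BG1"].years,
                            out["BG1"].values - out["SG3"].values, out["BG1"].units)
    return out["BG1"], diff


__all__ = ["ComparisonReport", "compare_to_reference", "lai_ndep_series",
           "EmptyDomainError"]
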