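"""Run configuration: grid size, years, thresholds, seed, paths."""

from __future__ import annotations

from dataclasses import dataclass, asdict, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Parameters shared across the pipeline.

    ``et_floor`` (kgH2O m-2 yr-1) and ``gpp_floor`` (gC m-2 yr-1) guard
    the WUE and CUE ratios against division blow-ups in desert/ice
    cells; ``alpha`` is the two-sided significance level for all trend
    tests; ``window`` is the model-vs-reference comparison period.
    """

    nlat: int = 10
    nlon: int = 20
    land_fraction: float = 0.55
    year_start: int = 1901
    year_end: int = 2010
    alpha: float = 0.05
    et_floor: float = 10.0
    gpp_floor: float = 1.0
    window: tuple[int, int] = (1982, 2008)
    seed: int = 0
    outdir: str = "results"
    aggregation: str = "ratio_of_means"  # or "mean_of_ratios"
    dominance_threshold: float = 0.1  # percent points below which a cell is "none"
    noise_sd: float = 0.02
    noise_rho: float = 0.35
    independent_noise: bool = False  # stress test: break noise sharing across scenarios
    models: list = field(default_factory=list)  # optional explicit ModelSpec dicts

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        self.window = (int(self.window[0]), int(self.window[1]))
        if not (self.year_start <= self.window[0] <= self.window[1] <= self.year_end):
            raise ValueError("comparison window must lie within the simulation years")

    @property
    def years(self):
        import numpy as np

        return np.arange(self.year_start, self.year_end + 1)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "window" in raw:
            raw["window"] = tuple(raw["window"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["window"] = list(d["window"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))
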