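"""Factorial scenario semantics.

The five simulation protocols form a nested ladder of active
environmental drivers; each rung switches on exactly one more driver,
so pairwise differences isolate single-driver impacts:

    climate = SG1 - RG1,  co2 = SG3 - SG2,  ndep = BG1 - SG3.

Carbon-only models have no nitrogen cycle, hence no BG1; their maximal
scenario is SG3.
"""

SCENARIOS = ("RG1", "SG1", "SG2", "SG3", "BG1")

#: scenario code -> set of active drivers (the nesting RG1 ⊂ SG1 ⊂ ... ⊂ BG1)
DRIVER_SETS = {
    "RG1": frozenset(),
    "SG1": frozenset({"climate"}),
    "SG2": frozenset({"climate", "landuse"}),
    "SG3": frozenset({"climate", "landuse", "co2"}),
    "BG1": frozenset({"climate", "landuse", "co2", "ndep"}),
}

#: attributable driver -> (varying scenario, fixed scenario)
DRIVER_PAIRS = {
    "climate": ("SG1", "RG1"),
    "co2": ("SG3", "SG2"),
    "ndep": ("BG1", "SG3"),
}

DRIVERS = ("climate", "co2", "ndep")

VARIABLES = ("gpp", "npp", "ra", "et", "lai", "soil_moisture", "soil_temperature")


def max_scenario(has_nitrogen: bool) -> str:
    """The all-drivers-on scenario: BG1 for C-N models, SG3 for C-only."""
    return "BG1" if has_nitrogen else "SG3"


def scenarios_for(has_nitrogen: bool) -> tuple[str, ...]:
    return SCENARIOS if has_nitrogen else SCENARIOS[:-1]
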