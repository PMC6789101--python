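"""Scenario differencing, contributions and dominant-driver recovery."""

import numpy as np
import pytest

from ecoeff import RunConfig
from ecoeff.attribution import (
    DRIVER_CODES,
    dominant_driver_map,
    dominant_driver_map_ensemble,
    driver_effect,
    ensemble_summary,
    net_change,
    percent_contribution,
    percent_increase,
    scenario_series,
)
from ecoeff.efficiency import EfficiencySeries
from ecoeff.errors import ScenarioError, VariableNotFoundError
from ecoeff.synthetic import ModelSpec, generate_ensemble

YEARS = np.arange(1901, 2011)
CFG = RunConfig(seed=0)


class TestDriverEffect:
    def test_null_ensemble_all_drivers_zero(self, null_ensemble):
        for driver in ("climate", "co2", "ndep"):
            for quantity in ("wue", "cue", "gpp"):
                eff = driver_effect(null_ensemble, driver, quantity, config=CFG)
                np.testing.assert_array_equal(eff.values, 0.0)

    def test_co2_wue_effect_closed_form(self, co2_only_ensemble):
        # injected co2 gpp +0.20, et untouched:
        # WUE effect(t) = WUE0 * 0.20 * f(t), exactly at sd=0
        ens = co2_only_ensemble
        eff = driver_effect(ens, "co2", "wue", config=CFG)
        wue0 = scenario_series(ens, "RG1", "wue", config=CFG).values[0]
        f = (YEARS - 1901) / 109.0
        np.testing.assert_allclose(eff.values, wue0 * 0.20 * f, rtol=1e-10, atol=1e-14)

    def test_identical_scenarios_give_zero_series(self, co2_only_ensemble):
        # climate has no injected effect, so SG1 == RG1 exactly
        eff = driver_effect(co2_only_ensemble, "climate", "gpp", config=CFG)
        np.testing.assert_array_equal(eff.values, 0.0)

    def test_exchanging_pair_negates_effect(self, co2_only_ensemble):
        ens = co2_only_ensemble
        swapped = type(ens)(model_name=ens.model_name, has_nitrogen=ens.has_nitrogen)
        swapped.fields = dict(ens.fields)
        for var in ("gpp", "npp", "et"):
            swapped.fields[("SG3", var)] = ens.fields[("SG2", var)]
            swapped.fields[("SG2", var)] = ens.fields[("SG3", var)]
        a = driver_effect(ens, "co2", "wue", config=CFG)
        b = driver_effect(swapped, "co2", "wue", config=CFG)
        np.testing.assert_allclose(a.values, -b.values, rtol=1e-12)

    def test_ndep_for_carbon_only_rejected(self, small_grid):
        spec = ModelSpec(name="C", has_nitrogen=False, seed=2, noise_sd=0.0)
        ens = generate_ensemble(spec, grid=small_grid, years=YEARS)
        with pytest.raises(ScenarioError, match="driver unavailable"):
            driver_effect(ens, "ndep", "gpp", config=CFG)

    def test_missing_variable_rejected(self, co2_only_ensemble):
        ens = co2_only_ensemble
        stripped = type(ens)(model_name="X", has_nitrogen=True)
        stripped.fields = {k: v for k, v in ens.fields.items() if k[1] != "et"}
        with pytest.raises(VariableNotFoundError, match="quantity unavailable"):
            driver_effect(stripped, "co2", "wue", config=CFG)


class TestNetChange:
    def test_zero_at_1901_and_constant_series(self, null_ensemble, ensembles):
        for ens in [null_ensemble, *ensembles]:
            for quantity in ("wue", "cue"):
                nc = net_change(ens, quantity, config=CFG)
                assert nc.values[0] == 0.0
        nc_null = net_change(null_ensemble, "wue", config=CFG)
        np.testing.assert_array_equal(nc_null.values, 0.0)

    def test_combined_effect_closed_form(self, co2_only_ensemble):
        # only co2 injected: net change at 2010 = 0.20 * WUE(1901)
        nc = net_change(co2_only_ensemble, "wue", config=CFG)
        wue0 = scenario_series(co2_only_ensemble, "BG1", "wue", config=CFG).values[0]
        assert nc.values[-1] == pytest.approx(0.20 * wue0, rel=1e-10)


class TestPercentContribution:
    def test_zero_effect(self, null_ensemble):
        eff = driver_effect(null_ensemble, "co2", "wue", config=CFG)
        assert percent_contribution(eff, null_ensemble, config=CFG) == 0.0

    def test_arithmetic(self, null_ensemble):
        # effect constantly 0.1 against denominator constantly 2.0 -> 5 %
        denom = scenario_series(null_ensemble, "BG1", "wue", config=CFG)
        scale = 2.0 / denom.values[0]
        for key in list(null_ensemble.fields):
            if key[1] == "gpp":
                null_ensemble.fields[key].values *= scale
        try:
            eff = driver_effect(null_ensemble, "co2", "wue", config=CFG)
            eff.values = np.full_like(eff.values, 0.1)
            assert percent_contribution(eff, null_ensemble, config=CFG) == \
                pytest.approx(5.0, rel=1e-12)
        finally:
            for key in list(null_ensemble.fields):
                if key[1] == "gpp":
                    null_ensemble.fields[key].values /= scale

    def test_closed_form_single_driver(self, co2_only_ensemble):
        # mean effect / mean combined = 0.2*mean(f) / (1 + 0.2*mean(f))
        eff = driver_effect(co2_only_ensemble, "co2", "wue", config=CFG)
        pct = percent_contribution(eff, co2_only_ensemble, config=CFG)
        fbar = np.mean((YEARS - 1901) / 109.0)
        expected = 100.0 * 0.2 * fbar / (1.0 + 0.2 * fbar)
        assert pct == pytest.approx(expected, rel=1e-9)

    def test_invariant_under_common_rescaling(self, co2_only_ensemble):
        ens = co2_only_ensemble
        eff = driver_effect(ens, "co2", "gpp", config=CFG)
        base = percent_contribution(eff, ens, config=CFG)
        scaled = type(ens)(model_name="S", has_nitrogen=True)
        scaled.fields = {}
        for k, v in ens.fields.items():
            f = v.copy()
            f.values = f.values * 4.2
            scaled.fields[k] = f
        eff2 = driver_effect(scaled, "co2", "gpp", config=CFG)
        assert percent_contribution(eff2, scaled, config=CFG) == \
            pytest.approx(base, rel=1e-12)


class TestPercentIncrease:
    def test_arithmetic(self):
        s = EfficiencySeries("gpp", "global", np.array([1901.0, 2010.0]),
                             np.array([100.0, 104.0]))
        assert percent_increase(s) == pytest.approx(4.0, rel=1e-14)

    def test_constant_series(self):
        s = EfficiencySeries("gpp", "global", np.array([1901.0, 2010.0]),
                             np.array([5.0, 5.0]))
        assert percent_increase(s) == 0.0

    def test_generator_injected_effect(self, co2_only_ensemble):
        s = scenario_series(co2_only_ensemble, "SG3", "gpp", config=CFG)
        assert percent_increase(s) == pytest.approx(20.0, abs=0.01)


class TestDominantDriverMap:
    def test_single_injected_driver_labels_every_cell(self, co2_only_ensemble):
        dmap = dominant_driver_map(co2_only_ensemble, "wue", config=CFG)
        land = dmap.land_mask
        assert (dmap.labels[land] == DRIVER_CODES["co2"]).all()
        assert (dmap.labels[~land] == -1).all()

    def test_null_ensemble_all_none(self, null_ensemble):
        dmap = dominant_driver_map(null_ensemble, "wue", config=CFG)
        assert (dmap.labels[dmap.land_mask] == DRIVER_CODES["none"]).all()

    def test_spatial_split_recovery(self, small_grid):
        # climate effect north of 45N only, co2 south only, strong SNR
        spec = ModelSpec(
            name="SPLIT", has_nitrogen=True, seed=31, noise_sd=0.02, rho=0.3,
            effects={"climate": {"gpp": -0.3}, "co2": {"gpp": 0.3}},
            effect_region={"climate": (45.0, 90.0), "co2": (-90.0, 45.0)},
        )
        ens = generate_ensemble(spec, grid=small_grid, years=YEARS)
        dmap = dominant_driver_map(ens, "gpp", config=CFG)
        lat, _, mask = small_grid
        want = np.where(lat[:, None] > 45.0, DRIVER_CODES["climate"],
                        DRIVER_CODES["co2"])
        agree = (dmap.labels == want)[mask]
        assert agree.mean() >= 0.90

    def test_ensemble_mean_map(self, ensembles, config):
        dmap = dominant_driver_map_ensemble(ensembles, "wue",
                                            period=config.window, config=config)
        # the default archive is CO2-dominated in the multi-model mean
        land = dmap.land_mask
        labels = dmap.labels[land]
        assert (labels == DRIVER_CODES["co2"]).mean() > 0.5


class TestEnsembleSummary:
    def test_null_rows_not_significant(self, null_ensemble):
        tab = ensemble_summary([null_ensemble], "wue", CFG)
        assert not tab["significant"].any()
        np.testing.assert_allclose(tab["pct_change"].to_numpy(), 0.0, atol=1e-12)

    def test_dominant_column_matches_ground_truth(self, ensembles, config):
        tab = ensemble_summary(ensembles, "wue", config)
        expected = {"CN-CO2DOM": "co2", "CN-NDEPDOM": "ndep", "C-CLIMDOM": "climate"}
        for model, want in expected.items():
            sub = tab[(tab.model == model) & (tab.driver != "combined")]
            got = sub.loc[sub.pct_contribution.abs().idxmax(), "driver"]
            assert got == want

    def test_model_without_et_skipped_for_wue_only(self, ensembles, config):
        stripped = []
        for ens in ensembles:
            s = type(ens)(model_name=ens.model_name, has_nitrogen=ens.has_nitrogen)
            s.fields = {k: v for k, v in ens.fields.items()
                        if not (ens.model_name == "CN-CO2DOM" and k[1] == "et")}
            stripped.append(s)
        wue_tab = ensemble_summary(stripped, "wue", config)
        cue_tab = ensemble_summary(stripped, "cue", config)
        assert "CN-CO2DOM" not in set(wue_tab.model)
        assert "CN-CO2DOM" in set(cue_tab.model)
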