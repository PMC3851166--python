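"""Lability rules, river loaders, deposition and synthetic scenarios."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from coastbgc import (ParameterSet, LabilityRules, apply_lability,
                      load_river_series, atmospheric_deposition_flux,
                      synthetic_forcing, light_extinction)
from coastbgc.forcing import (deposition_to_concentration, TABLE_RIVERS,
                              CARONTE_DISCHARGE)
from coastbgc.fixtures import FixtureSpec, make_river_fixture

RAW = {"DOC": 100.0, "DON": 10.0, "DOP": 10.0,
       "POC": 50.0, "PON": 5.0, "POP": 2.0,
       "NO3": 80.0, "NH4": 2.0, "PO4": 1.0}


class TestLability:
    def test_published_fractions(self):
        lab = apply_lability(dict(RAW))
        assert lab["LDOC"] == pytest.approx(20.0)    # 20% of DOC
        assert lab["DPOC"] == pytest.approx(9.0)     # 18% of POC
        assert lab["LDOP"] == pytest.approx(8.8)     # 88% of DOP
        assert lab["LDON"] == pytest.approx(2.0)     # 20% of DON
        assert lab["DPOP"] == pytest.approx(1.76)    # 88% of POP

    def test_nutrients_pass_through(self):
        lab = apply_lability(dict(RAW))
        assert lab["NO3"] == RAW["NO3"]

    def test_pon_basis_readings(self):
        default = apply_lability(dict(RAW))
        assert default["DPON"] == pytest.approx(0.20 * RAW["PON"])
        alt = apply_lability(dict(RAW), LabilityRules(pon_basis="poc"))
        assert alt["DPON"] == pytest.approx(0.20 * RAW["POC"])

    def test_reapplication_rejected(self):
        lab = apply_lability(dict(RAW))
        with pytest.raises(ValueError, match="re-apply"):
            apply_lability({**RAW, **lab})

    @given(lam=st.floats(0.0, 1e3))
    def test_linearity(self, lam):
        base = apply_lability(dict(RAW))
        scaled = apply_lability({k: lam * v for k, v in RAW.items()})
        for k in ("LDOC", "DPOC", "LDOP"):
            assert scaled[k] == pytest.approx(lam * base[k], rel=1e-12)


@pytest.fixture(scope="module")
def river_files(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("rivers")
    return make_river_fixture(FixtureSpec(seed=7, n_days=60), outdir)


class TestRiverLoaders:
    def test_grand_rhone_discharge_factor(self, river_files):
        raw = pd.read_csv(river_files["rhone"], parse_dates=["date"])
        out = load_river_series(river_files["rhone"], "rhone")
        assert np.allclose(out["discharge"].values,
                           0.90 * raw["discharge"].values)

    def test_rhone_lability_applied(self, river_files):
        raw = pd.read_csv(river_files["rhone"], parse_dates=["date"])
        out = load_river_series(river_files["rhone"], "rhone")
        assert np.allclose(out["LDOC"].values, 0.20 * raw["DOC"].values)
        assert np.allclose(out["DPOC"].values, 0.18 * raw["POC"].values)

    def test_caronte_constant_source(self, river_files):
        out = load_river_series(river_files["caronte"], "caronte")
        row = TABLE_RIVERS["caronte"]
        assert (out["discharge"] == CARONTE_DISCHARGE).all()
        for var in ("NO3", "NH4", "PO4", "LDOC", "LDON", "LDOP",
                    "DPOC", "DPON", "DPOP"):
            assert (out[var] == row[var]).all()

    def test_wwtp_fixed_phosphate(self, river_files):
        out = load_river_series(river_files["wwtp"], "wwtp")
        assert (out["PO4"] == 13.4).all()
        assert (out["LDOC"] == 135.0).all()

    def test_urban_river_borrows_rhone_nutrients(self, river_files,
                                                 tmp_path):
        rhone = load_river_series(river_files["rhone"], "rhone")
        dates = rhone.index[:20]
        urban = pd.DataFrame({"date": dates, "discharge": 0.5})
        p = tmp_path / "huveaune.csv"
        urban.to_csv(p, index=False)
        out = load_river_series(p, "huveaune", rhone=rhone)
        assert np.allclose(out["NO3"].values,
                           rhone["NO3"].reindex(dates).values)
        assert (out["LDOC"] == TABLE_RIVERS["huveaune"]["LDOC"]).all()

    def test_plankton_absent_from_inputs(self, river_files):
        out = load_river_series(river_files["rhone"], "rhone")
        for var in ("Cb", "Chla", "Cba"):
            assert (out[var] == 0.0).all()

    def test_unknown_river_rejected(self, river_files):
        with pytest.raises(KeyError):
            load_river_series(river_files["rhone"], "seine")


class TestAtmosphericDeposition:
    def _dry(self):
        return pd.DataFrame({
            "start": ["2008-01-01", "2008-01-08"],
            "end": ["2008-01-08", "2008-01-15"],
            "NO3": [7.0, 14.0],
        })

    def _wet(self, conc=2.0):
        return pd.DataFrame({
            "start": ["2008-01-01"], "end": ["2008-01-15"],
            "NO3": [conc],
        })

    def test_dry_mean_flux(self):
        rain = pd.Series(0.0, index=pd.date_range("2008-01-01",
                                                  periods=14, freq="D"))
        flux = atmospheric_deposition_flux(
            self._dry(), self._wet(0.0), rain,
            dry_units="umol m-2", wet_units="umol L-1")
        first_week = flux.loc["2008-01-01":"2008-01-07", "NO3"]
        assert np.allclose(first_week, 1.0)   # 7 umol over 7 days

    def test_no_rain_no_wet_flux(self):
        rain = pd.Series(0.0, index=pd.date_range("2008-01-01",
                                                  periods=14, freq="D"))
        dry0 = self._dry()
        dry0[["NO3"]] = 0.0
        flux = atmospheric_deposition_flux(
            dry0, self._wet(2.0), rain,
            dry_units="umol m-2", wet_units="umol L-1")
        assert (flux["NO3"] == 0.0).all()

    def test_mass_conservation(self):
        """Integrated dry flux reproduces the sampled totals exactly."""
        rain = pd.Series(0.0, index=pd.date_range("2008-01-01",
                                                  periods=14, freq="D"))
        flux = atmospheric_deposition_flux(
            self._dry(), self._wet(0.0), rain,
            dry_units="umol m-2", wet_units="umol L-1")
        total = flux.loc["2008-01-01":"2008-01-14", "NO3"].sum()
        assert total == pytest.approx(21.0, abs=1e-12)

    def test_wet_dilution_arithmetic(self):
        """2 umol/L in 10 mm of rain over a 10 m mixed layer raises the
        surface concentration by 0.002 umol/L."""
        days = pd.date_range("2008-01-01", periods=3, freq="D")
        rain = pd.Series([0.0, 10.0, 0.0], index=days)
        dry0 = pd.DataFrame({"start": ["2008-01-01"],
                             "end": ["2008-01-03"], "NO3": [0.0]})
        flux = atmospheric_deposition_flux(
            dry0, self._wet(2.0), rain,
            dry_units="umol m-2", wet_units="umol L-1")
        conc = deposition_to_concentration(flux, mixed_layer_depth=10.0)
        assert conc.loc["2008-01-02", "NO3"] == pytest.approx(0.002)

    def test_units_must_be_declared(self):
        rain = pd.Series(0.0, index=pd.date_range("2008-01-01",
                                                  periods=3, freq="D"))
        with pytest.raises(ValueError, match="umol m-2"):
            atmospheric_deposition_flux(self._dry(), self._wet(), rain,
                                        dry_units="mg", wet_units="umol L-1")

    def test_overlapping_samples_rejected(self):
        rain = pd.Series(0.0, index=pd.date_range("2008-01-01",
                                                  periods=14, freq="D"))
        bad = pd.DataFrame({
            "start": ["2008-01-01", "2008-01-05"],
            "end": ["2008-01-08", "2008-01-12"],
            "NO3": [1.0, 1.0]})
        with pytest.raises(ValueError, match="overlap"):
            atmospheric_deposition_flux(bad, self._wet(0.0), rain,
                                        dry_units="umol m-2",
                                        wet_units="umol L-1")


class TestSyntheticForcing:
    def test_seed_reproducibility(self):
        a = synthetic_forcing(seed=5, duration=200, scenario="seasonal")
        b = synthetic_forcing(seed=5, duration=200, scenario="seasonal")
        assert np.array_equal(a.T, b.T) and np.array_equal(a.E0, b.E0)

    def test_upwelling_colder_than_baseline(self):
        """During each upwelling episode the temperature is below the
        baseline seasonal scenario at the same times (same seed, same
        weather noise)."""
        base = synthetic_forcing(seed=5, duration=365, scenario="seasonal")
        up = synthetic_forcing(seed=5, duration=365,
                               scenario="upwelling_pulse")
        assert len(up.events) > 0
        for e in up.events:
            mask = (up.time >= e["start"]) & (up.time < e["end"])
            assert (up.T[mask] < base.T[mask]).all()

    def test_intrusion_ratio_in_band(self):
        f = synthetic_forcing(seed=6, duration=365,
                              scenario="rhone_intrusion")
        assert len(f.events) > 0
        for e in f.events:
            assert 65.0 <= e["no3_po4_ratio"] <= 80.0
        mask = f.boundary["NO3"] > 0
        ratio = f.boundary["NO3"][mask] / f.boundary["PO4"][mask]
        assert ((ratio >= 65.0 - 1e-9) & (ratio <= 80.0 + 1e-9)).all()

    def test_unknown_scenario_rejected(self):
        with pytest.raises(KeyError):
            synthetic_forcing(seed=0, duration=10, scenario="tsunami")


class TestLightExtinction:
    def test_pure_water_decay(self):
        params = ParameterSet()
        k, e = light_extinction([0.0, 0.0], [5.0, 5.0], params, E0=1.0)
        kw = params.optics.k_w
        assert np.allclose(k, kw)
        assert e[0] == pytest.approx(np.exp(-kw * 2.5))
        assert e[1] == pytest.approx(np.exp(-kw * 7.5))

    def test_self_shading_reduces_light(self):
        params = ParameterSet()
        _, dim = light_extinction([2.0, 2.0], [5.0, 5.0], params)
        _, dimmer = light_extinction([4.0, 4.0], [5.0, 5.0], params)
        assert (dimmer < dim).all()

    def test_closed_form_optical_depth(self):
        """k_w=0.04 + k_chl=0.03 * Chla=2 = 0.1 /m; at 10 m depth
        E/E0 = exp(-1) = 0.368."""
        params = ParameterSet()
        params.optics.k_w, params.optics.k_chl = 0.04, 0.03
        _, e = light_extinction([2.0], [20.0], params, E0=1.0)
        assert e[0] == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_bad_thickness_rejected(self):
        with pytest.raises(ValueError):
            light_extinction([1.0], [0.0], ParameterSet())
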