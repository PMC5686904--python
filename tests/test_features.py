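"""Feature engineering: humidity derivation, window aggregation, vegetation
summaries, land cover handling, mast lookups and table assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import tickdyn as td
from tickdyn.features import (MissingDataError, WEATHER_FEATURES, WINDOWS,
                              aggregate_weather, assemble_features,
                              derive_humidity_vars, feature_names,
                              majority_resample, mast_features,
                              reclassify_landcover,
                              saturation_vapour_pressure,
                              vegetation_features, weather_feature_table)
from tickdyn.io import NODATA


class TestHumidity:
    @pytest.mark.parametrize("tmin, tmax, rh, exp_vp, exp_sd", [
        (20.0, 20.0, 100.0, 23.33, 0.0),       # saturation: zero deficit
        (20.0, 20.0, 50.0, 11.67, 11.67),
        (-5.0, 5.0, 80.0, 4.890, 1.222),       # T = 0 reduces to 6.112 hPa
    ])
    def test_magnus_worked_examples(self, tmin, tmax, rh, exp_vp, exp_sd):
        sd, vp = derive_humidity_vars(tmin, tmax, rh)
        assert vp == pytest.approx(exp_vp, abs=0.01)
        assert sd == pytest.approx(exp_sd, abs=0.01)

    @given(st.floats(-30, 35), st.floats(0, 15), st.floats(0.1, 100))
    def test_conservation_identity(self, tmin, drange, rh):
        """sd + vp always reconstructs the saturation pressure exactly."""
        tmax = tmin + drange
        sd, vp = derive_humidity_vars(tmin, tmax, rh)
        es = saturation_vapour_pressure((tmin + tmax) / 2)
        assert sd + vp == pytest.approx(es, rel=1e-12)
        assert sd >= 0 and vp > 0

    @pytest.mark.parametrize("rh", [0.0, -10.0, 101.0])
    def test_humidity_domain_errors(self, rh):
        with pytest.raises(ValueError):
            derive_humidity_vars(10.0, 20.0, rh)

    def test_inverted_temperatures_rejected(self):
        with pytest.raises(ValueError):
            derive_humidity_vars(15.0, 10.0, 50.0)


def _daily(values, start="2010-01-01", var="ev"):
    idx = pd.date_range(start, periods=len(values), freq="D")
    return pd.DataFrame({var: values}, index=idx)


class TestAggregateWeather:
    def test_window_one_is_previous_day(self):
        series = _daily([1.0, 2.0, 3.0, 4.0])
        assert aggregate_weather(series, "2010-01-04", 1, "ev") == 3.0

    def test_constant_series(self):
        series = _daily([7.5] * 40)
        for w in (1, 7, 30):
            assert aggregate_weather(series, "2010-02-05", w, "ev") == 7.5

    def test_arithmetic_sequence(self):
        series = _daily([1, 2, 3, 4, 5, 6, 7, 99.0])
        assert aggregate_weather(series, "2010-01-08", 7, "ev") == 4.0

    def test_insufficient_coverage_raises(self):
        series = _daily([1.0] * 10)
        with pytest.raises(MissingDataError):
            aggregate_weather(series, "2010-01-05", 7, "ev")

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            aggregate_weather(_daily([1.0] * 40), "2010-02-01", 13, "ev")

    def test_matches_bruteforce_day_enumeration(self):
        """Oracle: mean of the w individually looked-up calendar days."""
        rng = np.random.default_rng(5)
        idx = pd.date_range("2009-01-01", periods=500, freq="D")
        series = pd.DataFrame(
            {v: rng.normal(size=500) for v in ("tmin", "ev", "rh")}, index=idx)
        for date in pd.to_datetime(["2010-01-10", "2010-03-05", "2010-04-30"]):
            for w in WINDOWS:
                for var in ("tmin", "ev", "rh"):
                    days = [date - pd.Timedelta(days=k)
                            for k in range(1, w + 1)]
                    oracle = np.mean([series.loc[d, var] for d in days])
                    got = aggregate_weather(series, date, w, var)
                    assert got == pytest.approx(oracle, rel=1e-12)

    def test_rolling_table_matches_pointwise(self, small_world):
        wx = small_world.weather["s01"]
        dates = pd.to_datetime(["2008-03-15", "2010-11-02"])
        table = weather_feature_table(wx, dates)
        assert list(table.columns) == list(WEATHER_FEATURES)
        from tickdyn.features import add_derived_weather
        full = add_derived_weather(wx)
        for date in dates:
            for w in (1, 14, 365):
                for var in ("tmax", "sd", "vp"):
                    assert table.loc[date, f"{var}-{w}"] == pytest.approx(
                        aggregate_weather(full, date, w, var), rel=1e-10)


class TestVegetation:
    @staticmethod
    def _composites(values_fn, n_years=4):
        idx = pd.date_range("2008-01-01", periods=46 * n_years, freq="8D")
        month = idx.month.to_numpy()
        return pd.DataFrame({"ndvi": values_fn(month)}, index=idx)

    def test_pure_sinusoid_min_and_range(self):
        comp = self._composites(
            lambda m: 0.5 + 0.3 * np.sin(2 * np.pi * m / 12))
        out = vegetation_features(comp)
        assert out["min_ndvi"] == pytest.approx(0.2, abs=0.05)
        assert out["range_ndvi"] == pytest.approx(0.6, abs=0.05)

    def test_constant_series_has_no_seasonality(self):
        comp = self._composites(lambda m: np.full(m.shape, 0.4))
        out = vegetation_features(comp)
        assert out["range_ndvi"] == pytest.approx(0.0, abs=1e-9)
        assert out["min_ndvi"] == pytest.approx(0.4, abs=1e-9)

    def test_six_outputs_for_three_indices(self, small_world):
        out = vegetation_features(small_world.vegetation_series(0, 0))
        assert len(out) == 6
        assert set(out) == {"min_ndvi", "range_ndvi", "min_evi", "range_evi",
                            "min_ndwi", "range_ndwi"}

    def test_short_series_rejected(self):
        idx = pd.date_range("2008-01-01", periods=40, freq="8D")
        comp = pd.DataFrame({"ndvi": np.linspace(0, 1, 40)}, index=idx)
        with pytest.raises(ValueError):
            vegetation_features(comp)


class TestLandcover:
    def test_identity_map(self):
        raster = np.array([[1, 2], [3, 4]])
        out = reclassify_landcover(raster, {i: i for i in range(1, 13)})
        assert np.array_equal(out, raster)

    def test_crop_codes_collapse_to_agriculture(self):
        raster = np.array([[1, 2], [3, 4]])
        out = reclassify_landcover(raster, {1: 7, 2: 7, 3: 7, 4: 7})
        assert np.array_equal(out, np.full((2, 2), 7))

    def test_unmapped_code_reported(self):
        with pytest.raises(ValueError, match="42"):
            reclassify_landcover(np.array([[1, 42]]), {1: 1})

    def test_world_raster_has_at_most_12_classes(self, small_world):
        codes = np.unique(small_world.landcover_native12)
        assert len(codes[codes != NODATA]) <= 12

    def test_majority_uniform_block(self):
        assert majority_resample(np.full((4, 4), 9), 2).tolist() == [[9, 9],
                                                                     [9, 9]]

    def test_majority_mode_and_ties(self):
        assert majority_resample(np.array([[1, 1], [2, 3]]), 2)[0, 0] == 1
        assert majority_resample(np.array([[1, 1], [2, 2]]), 2)[0, 0] == 1

    def test_majority_ignores_nodata(self):
        block = np.array([[NODATA, NODATA], [NODATA, 5]])
        assert majority_resample(block, 2)[0, 0] == 5
        assert majority_resample(np.full((2, 2), NODATA), 2)[0, 0] == NODATA

    def test_majority_pads_indivisible_rasters(self):
        out = majority_resample(np.ones((3, 3), dtype=int), 2)
        assert out.shape == (2, 2)
        assert out[0, 0] == 1

    def test_invalid_factor(self):
        with pytest.raises(ValueError):
            majority_resample(np.ones((2, 2)), 0)

    @given(st.integers(0, 2 ** 31 - 1))
    def test_majority_matches_block_vote_oracle(self, seed):
        rng = np.random.default_rng(seed)
        factor = int(rng.integers(1, 5))
        shape = (factor * int(rng.integers(1, 5)),
                 factor * int(rng.integers(1, 5)))
        raster = rng.integers(1, 6, size=shape)
        raster[rng.random(shape) < 0.2] = NODATA
        got = majority_resample(raster, factor)
        for bi in range(shape[0] // factor):
            for bj in range(shape[1] // factor):
                block = raster[bi * factor:(bi + 1) * factor,
                               bj * factor:(bj + 1) * factor].ravel()
                votes = block[block != NODATA]
                if votes.size == 0:
                    assert got[bi, bj] == NODATA
                    continue
                best = max(sorted(set(votes.tolist())),
                           key=lambda v: (votes == v).sum())
                counts = {v: (votes == v).sum() for v in set(votes.tolist())}
                top = max(counts.values())
                expected = min(v for v, n in counts.items() if n == top)
                assert got[bi, bj] == expected, (block, best)


class TestMast:
    @staticmethod
    def _mast(scores):
        rows = []
        for sp in ("oak", "aoak", "beech"):
            for year in (2008, 2009, 2010):
                rows.append({"species": sp, "year": year,
                             "score": scores.get((sp, year), 0)})
        return pd.DataFrame(rows)

    def test_all_zero(self):
        out = mast_features(self._mast({}), 2010)
        assert len(out) == 9
        assert all(v == 0 for v in out.values())

    def test_positional_lookup(self):
        mast = self._mast({("oak", 2010): 5, ("oak", 2009): 0,
                           ("oak", 2008): 2})
        out = mast_features(mast, 2010)
        assert (out["oak-0"], out["oak-1"], out["oak-2"]) == (5, 0, 2)
        assert out["beech-1"] == 0

    def test_missing_year_raises(self):
        with pytest.raises(MissingDataError, match="2007"):
            mast_features(self._mast({}), 2009)


class TestAssembly:
    def test_full_mode_column_accounting(self, small_features):
        names = feature_names()
        assert len(names) == 101
        assert [c for c in small_features.columns if c in names] == names
        weather = [n for n in names if n in WEATHER_FEATURES]
        assert len(weather) == 77

    def test_country_mode_drops_habitat_and_mast(self, small_world,
                                                 small_variants):
        table = assemble_features(small_variants["kept_raw"].frame.head(30),
                                  small_world, country_level=True)
        names = feature_names(country_level=True)
        assert len(names) == 86
        assert [c for c in table.columns if c in names] == names
        assert "litter" not in table.columns and "oak-0" not in table.columns

    def test_block_size_identity(self):
        # 6 habitat + 9 mast + 77 weather + 6 vegetation + 3 land cover
        assert 6 + 9 + 77 + 6 + 3 == len(feature_names()) == 101
        assert 101 - 6 - 9 == len(feature_names(country_level=True)) == 86

    def test_no_missing_values_and_keys_carried(self, small_features,
                                                small_variants):
        names = feature_names()
        assert not small_features[names].isna().any().any()
        assert {"site", "transect", "date", "target"}.issubset(
            small_features.columns)
        assert len(small_features) == len(small_variants["kept_smooth"].frame)

    def test_uncovered_observation_rejected(self, small_world):
        obs = pd.DataFrame({"site": ["s01"], "transect": ["a"],
                            "date": [pd.Timestamp("2005-06-15")],
                            "aqt_count": [1]})
        with pytest.raises(MissingDataError):
            assemble_features(obs, small_world)
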