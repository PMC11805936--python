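"""Climate I/O, Thornthwaite PET, water balance and the SPEI machinery."""

import math

import numpy as np
import pandas as pd
import pytest

from dioica.climate import (
    ClimateTable,
    aggregate_scale,
    build_spei_cube,
    fit_loglogistic_pwm,
    loglogistic_cdf,
    loglogistic_ppf,
    read_climate,
    spei_transform,
    thornthwaite_pet,
    water_balance,
    write_climate,
)
from dioica.errors import CoverageError, FitError, ValidationError
from conftest import make_climate_frame


class TestClimateTable:
    def test_single_year_file(self, tmp_path):
        df = make_climate_frame(range(2000, 2001))
        p = tmp_path / "c.csv"
        write_climate(ClimateTable(df), p)
        table = read_climate(p)
        assert len(table.data) == 12
        assert table.gaps() == []

    def test_missing_month_reported_as_gap(self):
        df = make_climate_frame(range(2000, 2001))
        table = ClimateTable(df[~((df.year == 2000) & (df.month == 6))])
        assert table.gaps() == [(2000, 6)]

    def test_duplicate_month_rejected(self):
        df = make_climate_frame(range(2000, 2001))
        with pytest.raises(ValidationError, match="duplicate"):
            ClimateTable(pd.concat([df, df.iloc[[0]]]))

    def test_cloud_cover_bounds_enforced(self):
        df = make_climate_frame(range(2000, 2001))
        df.loc[0, "cld"] = 101.0
        with pytest.raises(ValidationError, match="cloud"):
            ClimateTable(df)

    def test_round_trip(self, tmp_path):
        df = make_climate_frame(range(1990, 1995))
        p = write_climate(ClimateTable(df), tmp_path / "c.csv")
        back = read_climate(p)
        pd.testing.assert_frame_equal(
            back.data, ClimateTable(df).data, check_exact=False, rtol=1e-5
        )


class TestThornthwaite:
    def test_all_freezing_months_give_zero_pet(self):
        idx = pd.MultiIndex.from_product([[2000], range(1, 13)], names=["year", "month"])
        t = pd.Series(-5.0, index=idx)
        assert (thornthwaite_pet(t, 45.0) == 0).all()

    def test_independent_hand_coded_oracle(self):
        """Cross-check one configuration against a from-scratch evaluation."""
        temps = [2.0, 3.0, 6.0, 9.0, 13.0, 17.0, 20.0, 19.0, 15.0, 10.0, 6.0, 3.0]
        idx = pd.MultiIndex.from_product([[2000], range(1, 13)], names=["year", "month"])
        pet = thornthwaite_pet(pd.Series(temps, index=idx), 42.8)

        heat = sum((max(t, 0.0) / 5.0) ** 1.514 for t in temps)
        a = 6.75e-7 * heat**3 - 7.71e-5 * heat**2 + 1.792e-2 * heat + 0.49239
        mid_doy = [15, 45, 74, 105, 135, 166, 196, 227, 258, 288, 319, 349]
        days = [31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31]
        phi = math.radians(42.8)
        for m, (t, j, d) in enumerate(zip(temps, mid_doy, days), start=1):
            decl = 0.4093 * math.sin(2 * math.pi * (284 + j) / 365)
            ws = math.acos(max(-1, min(1, -math.tan(phi) * math.tan(decl))))
            n_hours = 24 / math.pi * ws
            expected = 16 * (10 * t / heat) ** a * (n_hours / 12) * (d / 30)
            assert pet[(2000, m)] == pytest.approx(expected, rel=1e-12)

    def test_summer_exceeds_winter(self):
        idx = pd.MultiIndex.from_product([[2000], range(1, 13)], names=["year", "month"])
        temps = pd.Series([1, 2, 5, 8, 12, 16, 19, 18, 14, 9, 4, 2.0], index=idx)
        pet = thornthwaite_pet(temps, 42.8)
        assert pet[(2000, 7)] > pet[(2000, 1)]


class TestWaterBalance:
    def test_elementwise_subtraction(self):
        df = make_climate_frame(range(2000, 2002))
        d = water_balance(ClimateTable(df))
        np.testing.assert_allclose(
            d.to_numpy(),
            ClimateTable(df).data["prec"].to_numpy() - ClimateTable(df).data["pet"].to_numpy(),
        )

    def test_prec_equal_pet_gives_zero(self):
        df = make_climate_frame(range(2000, 2001))
        df["pet"] = df["prec"]
        assert (water_balance(ClimateTable(df)) == 0).all()


class TestAggregateScale:
    def test_k1_identity(self, rng):
        x = rng.normal(0, 1, 50)
        np.testing.assert_allclose(aggregate_scale(x, 1), x)

    def test_constant_series(self):
        out = aggregate_scale(np.full(30, 2.0), 6)
        np.testing.assert_allclose(out[5:], 12.0)
        assert np.isnan(out[:5]).all()

    def test_brute_force_window_sums(self, rng):
        x = rng.normal(0, 10, 40)
        out = aggregate_scale(x, 7)
        for m in range(6, 40):
            assert out[m] == pytest.approx(x[m - 6 : m + 1].sum())

    def test_telescoping(self, rng):
        x = rng.normal(0, 5, 60)
        k = 9
        diff = aggregate_scale(x, k) - aggregate_scale(x, k - 1)
        for m in range(k - 1, 60):
            assert diff[m] == pytest.approx(x[m - k + 1])

    def test_scale_exceeding_length_raises(self):
        with pytest.raises(CoverageError):
            aggregate_scale(np.ones(5), 6)


class TestLogLogisticPWM:
    def test_parameter_recovery_from_known_distribution(self, rng):
        alpha, beta, gamma = 30.0, 4.0, 0.0
        u = rng.uniform(1e-6, 1 - 1e-6, 10_000)
        sample = loglogistic_ppf(u, alpha, beta, gamma)
        a_hat, b_hat, g_hat = fit_loglogistic_pwm(sample)
        assert a_hat == pytest.approx(alpha, rel=0.05)
        assert b_hat == pytest.approx(beta, rel=0.05)
        assert abs(g_hat) < 0.05 * alpha

    def test_location_equivariance(self, rng):
        u = rng.uniform(0.01, 0.99, 500)
        sample = loglogistic_ppf(u, 25.0, 3.0, 5.0)
        a1, b1, g1 = fit_loglogistic_pwm(sample)
        a2, b2, g2 = fit_loglogistic_pwm(sample + 100.0)
        assert g2 - g1 == pytest.approx(100.0, abs=1e-6)
        assert a2 == pytest.approx(a1, rel=1e-9)
        assert b2 == pytest.approx(b1, rel=1e-9)

    def test_constant_sample_raises(self):
        with pytest.raises(FitError):
            fit_loglogistic_pwm(np.full(20, 3.0))

    def test_small_sample_raises(self):
        with pytest.raises(FitError):
            fit_loglogistic_pwm(np.arange(5.0))


class TestSpeiTransform:
    def test_median_maps_to_zero(self):
        params = (30.0, 4.0, -10.0)
        median = loglogistic_ppf(0.5, *params)
        assert spei_transform(median, params) == pytest.approx(0.0, abs=1e-9)

    def test_monotone_in_x(self, rng):
        params = (30.0, 4.0, 0.0)
        xs = np.sort(rng.uniform(1, 100, 50))
        out = spei_transform(xs, params)
        assert (np.diff(out) >= 0).all()

    def test_calibration_standardisation(self, table):
        """SPEI of each cell's calibration sample has mean ~0 and sd ~1."""
        cube = build_spei_cube(table, scales=[1, 6, 12])
        for ki in range(3):
            for m in range(12):
                col = cube.values[ki, :, m]
                col = col[np.isfinite(col)]
                if len(col) < 45:
                    continue
                assert abs(col.mean()) <= 0.05
                assert abs(col.std(ddof=0) - 1.0) <= 0.1

    def test_clamping_bounds(self):
        from scipy.stats import norm

        params = (30.0, 4.0, 0.0)
        bound = norm.ppf(1 - 1e-6)
        assert spei_transform(1e12, params) <= bound + 1e-9
        assert spei_transform(-1e12, params) >= -bound - 1e-9


@pytest.fixture(scope="module")
def table():
    """50 years of realistic (right-skewed precipitation) monthly climate."""
    from dioica.synth import ScenarioConfig, generate_climate

    return generate_climate(ScenarioConfig(years=(1950, 1999), seed=11))


class TestSpeiCube:
    def test_k1_matches_direct_per_month_fit(self, table):
        cube = build_spei_cube(table, scales=[1])
        d = water_balance(table).to_numpy().reshape(-1, 12)
        for m in range(12):
            try:
                params = fit_loglogistic_pwm(d[:, m])
            except FitError:
                assert np.isnan(cube.values[0, :, m]).all()
                continue
            expected = spei_transform(d[:, m], params)
            np.testing.assert_allclose(cube.values[0, :, m], expected, atol=1e-10)

    def test_defined_cells_within_clamp_bounds(self, table):
        from scipy.stats import norm

        cube = build_spei_cube(table, scales=[1, 6, 12])
        finite = cube.values[np.isfinite(cube.values)]
        assert (np.abs(finite) <= norm.ppf(1 - 1e-6) + 1e-9).all()

    def test_row_order_invariance(self, table):
        shuffled = ClimateTable(
            table.data.sample(frac=1.0, random_state=3).reset_index(drop=True)
        )
        c1 = build_spei_cube(table, scales=[3])
        c2 = build_spei_cube(shuffled, scales=[3])
        np.testing.assert_allclose(c1.values, c2.values, equal_nan=True)

    def test_first_window_undefined(self, table):
        cube = build_spei_cube(table, scales=[12])
        assert np.isnan(cube.values[0, 0, :11]).all()
        if not any(k == 12 and m == 12 for k, m, _ in cube.fit_failures):
            assert np.isfinite(cube.values[0, 0, 11])

    def test_monotone_in_aggregated_balance(self, table):
        """SPEI at a fixed (k, month) preserves the ordering of X^k."""
        cube = build_spei_cube(table, scales=[6])
        d = water_balance(table).to_numpy()
        agg = aggregate_scale(d, 6).reshape(-1, 12)
        for m in (5, 11):
            x = agg[:, m]
            z = cube.values[0, :, m]
            ok = np.isfinite(x) & np.isfinite(z)
            order = np.argsort(x[ok])
            assert (np.diff(z[ok][order]) >= -1e-12).all()
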