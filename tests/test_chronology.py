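"""Chronology building, detrending, and common-signal statistics."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr
from hypothesis import given, settings
from hypothesis import strategies as st

from qwa.chronology import (
    ar1,
    biweight_mean,
    chronology_frame,
    chronology_stats,
    eps,
    first_difference,
    power_transform,
    rbar,
    sector_chronology,
    snr,
    spline_detrend,
    split_group_test,
    ztransform,
)
from qwa.io_formats import ValidationError
from qwa.tracheidogram import sector_labels


class TestZTransform:
    def test_closed_form(self):
        z = ztransform(pd.Series([1.0, 2.0, 3.0]))
        assert np.allclose(z, [-1.0, 0.0, 1.0])

    def test_mean_zero_sd_one(self, rng):
        s = pd.Series(rng.normal(5, 3, 80), index=np.arange(1940, 2020))
        z = ztransform(s)
        assert abs(z.mean()) < 1e-12
        assert abs(z.std(ddof=1) - 1) < 1e-12

    def test_constant_series_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            ztransform(pd.Series([2.0, 2.0, 2.0]))

    def test_out_of_period_values_use_period_scaling(self):
        s = pd.Series([1.0, 2.0, 3.0, 10.0], index=[2000, 2001, 2002, 2003])
        z = ztransform(s, period=(2000, 2002))
        assert np.allclose(z.loc[2000:2002], [-1, 0, 1])
        assert np.isclose(z.loc[2003], (10 - 2.0) / 1.0)


class TestFirstDifference:
    def test_values_and_year_labels(self):
        d = first_difference(pd.Series([1.0, 3.0, 2.0], index=[2000, 2001, 2002]))
        assert np.allclose(d, [2.0, -1.0])
        assert list(d.index) == [2001, 2002]

    def test_constant_series_gives_zeros(self):
        d = first_difference(pd.Series([4.0] * 5))
        assert np.allclose(d, 0.0)

    def test_reduces_persistence_of_ar1_process(self, rng):
        phi = 0.7
        eps_ = rng.normal(size=500)
        x = np.empty(500)
        x[0] = eps_[0]
        for i in range(1, 500):
            x[i] = phi * x[i - 1] + eps_[i]
        s = pd.Series(x)
        assert ar1(first_difference(s)) < ar1(s)

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            first_difference(pd.Series([1.0]))


def _biweight_oracle(x, c=9.0, tol=1e-9):
    """Independent fixed-point iteration, written from the weight definition."""
    x = np.asarray(x, dtype=float)
    t = np.median(x)
    mad = np.median(np.abs(x - t))
    if mad == 0:
        return t
    for _ in range(500):
        u = (x - t) / (c * mad)
        w = np.clip(1 - u**2, 0, None) ** 2
        t_new = (w * x).sum() / w.sum()
        if abs(t_new - t) < tol:
            break
        t = t_new
    return t_new


class TestBiweightMean:
    def test_degenerate_and_symmetric(self):
        assert biweight_mean([5.0, 5.0, 5.0]) == 5.0
        assert np.isclose(biweight_mean([1.0, 2.0, 3.0]), 2.0)

    def test_matches_independent_fixed_point(self):
        x = [1.0, 1.0, 1.0, 1.0, 100.0]
        assert abs(biweight_mean(x) - _biweight_oracle(x)) < 1e-6
        assert abs(biweight_mean(x) - 1.0) < 1e-3

    @settings(max_examples=50, derandomize=True)
    @given(seed=st.integers(0, 9999), n=st.integers(5, 60))
    def test_agrees_with_oracle_on_random_samples(self, seed, n):
        x = np.random.default_rng(seed).normal(10, 2, n)
        assert abs(biweight_mean(x) - _biweight_oracle(x)) < 1e-5

    def test_near_mean_on_clean_symmetric_data(self, rng):
        x = rng.normal(0, 1, 2000)
        assert abs(biweight_mean(x) - x.mean()) < 0.02


class TestPowerTransform:
    def _spread_slope(self, x):
        x = np.asarray(x, dtype=float)
        spread = np.abs(np.diff(x))
        level = (x[1:] + x[:-1]) / 2
        ok = spread > 0
        return np.polyfit(np.log(level[ok]), np.log(spread[ok]), 1)[0]

    def test_level_independent_spread_keeps_series(self, rng):
        # level varies 1→40 but absolute spread is constant ⇒ p ≈ 1
        x = np.linspace(1, 40, 300) + rng.normal(0, 0.3, 300)
        res = power_transform(pd.Series(np.abs(x) + 0.1))
        assert abs(res.power - 1.0) < 0.15

    def test_proportional_spread_maps_to_log(self):
        # relative fluctuations of fixed size at every level ⇒ spread scales
        # with level (slope 1) ⇒ p ≈ 0 and the log branch fires
        t = np.arange(300)
        x = np.exp(t / 100.0) * (1.0 + 0.2 * (-1.0) ** t)
        res = power_transform(pd.Series(x))
        assert res.power == 0.0  # log branch
        assert np.allclose(res.values, np.log(x))

    def test_homogenizes_spread_level_dependence(self, rng):
        x = np.exp(np.linspace(0, 3, 300)) * np.exp(rng.normal(0, 0.2, 300))
        res = power_transform(pd.Series(x))
        out = res.values.to_numpy()
        out = out - out.min() + 1.0  # positive shift for the slope diagnostic
        assert abs(self._spread_slope(out)) < abs(self._spread_slope(x))

    def test_short_series_rejected(self):
        with pytest.raises(ValidationError):
            power_transform(pd.Series([1.0, 2.0, 3.0]))


class TestSplineDetrend:
    def test_linear_trend_reproduced(self):
        s = pd.Series(1.0 + 0.01 * np.arange(100))
        res = spline_detrend(s)
        assert np.max(np.abs(res.index.values - 1.0)) < 0.01

    def _fit_amplitude(self, fit, t, wl, interior=True):
        if interior:
            sl = slice(len(t) // 4, 3 * len(t) // 4)
            t, fit = t[sl], fit[sl]
        X = np.column_stack(
            [np.ones_like(t), t, np.sin(2 * np.pi * t / wl), np.cos(2 * np.pi * t / wl)]
        )
        beta, *_ = np.linalg.lstsq(X, fit, rcond=None)
        return np.hypot(beta[2], beta[3])

    def test_half_amplitude_at_cutoff_wavelength(self):
        # away from the series ends the spline passes ~50% of a sinusoid at
        # the 0.66·n cutoff wavelength
        n, amp = 200, 0.2
        t = np.arange(n, dtype=float)
        wl = 0.66 * n
        s = pd.Series(2.0 + 0.005 * t + amp * np.sin(2 * np.pi * t / wl))
        res = spline_detrend(s)
        ratio = self._fit_amplitude(res.fit.to_numpy(), t, wl) / amp
        assert abs(ratio - 0.5) < 0.05  # ±10% relative

    def test_high_frequency_survives_in_index(self):
        n, amp = 200, 0.1
        t = np.arange(n, dtype=float)
        wl = n / 10
        s = pd.Series(2.0 + 0.005 * t + amp * np.sin(2 * np.pi * t / wl))
        res = spline_detrend(s)
        passed = self._fit_amplitude(
            s.to_numpy() - res.fit.to_numpy(), t, wl, interior=False
        )
        assert passed / amp > 0.9

    def test_index_mean_near_one_on_multiplicative_noise(self, rng):
        ages = np.arange(60, 160)
        w = (2.5 * np.exp(-ages / 80) + 0.4) * np.exp(rng.normal(0, 0.2, 100))
        res = spline_detrend(pd.Series(w))
        assert abs(res.index.mean() - 1.0) < 0.05


class TestRbar:
    def test_identical_and_negated(self, rng):
        x = pd.Series(rng.normal(size=40))
        assert np.isclose(rbar(pd.DataFrame({"a": x, "b": x})), 1.0)
        assert np.isclose(rbar(pd.DataFrame({"a": x, "b": -x})), -1.0)

    def test_mean_of_pairwise_oracle(self, rng):
        df = pd.DataFrame(rng.normal(size=(60, 3)), columns=list("abc"))
        oracle = np.mean(
            [
                np.corrcoef(df["a"], df["b"])[0, 1],
                np.corrcoef(df["a"], df["c"])[0, 1],
                np.corrcoef(df["b"], df["c"])[0, 1],
            ]
        )
        assert np.isclose(rbar(df), oracle)

    def test_short_overlap_pair_excluded_with_warning(self, rng):
        idx = np.arange(2000, 2040)
        a = pd.Series(rng.normal(size=40), index=idx)
        b = pd.Series(rng.normal(size=40), index=idx)
        c = pd.Series(np.nan, index=idx)
        c.iloc[:5] = rng.normal(size=5)
        df = pd.DataFrame({"a": a, "b": b, "c": c})
        with pytest.warns(UserWarning, match="overlapping years"):
            value = rbar(df)
        assert np.isclose(value, np.corrcoef(a, b)[0, 1])


class TestEpsSnr:
    @pytest.mark.parametrize(
        "rb,expected",
        [(0.283, 0.703), (0.241, 0.656), (0.305, 0.725), (0.389, 0.793)],
    )
    def test_six_tree_reference_values(self, rb, expected):
        assert abs(eps(rb, 6) - expected) <= 0.001

    def test_perfect_common_signal(self):
        for n in (2, 6, 50):
            assert eps(1.0, n) == 1.0

    def test_snr_closed_forms(self):
        assert np.isclose(snr(0.5, 6), 6.0)
        assert snr(0.0, 6) == 0.0

    @settings(max_examples=200, derandomize=True)
    @given(
        rb=st.floats(0.0, 0.999),
        n=st.integers(2, 60),
    )
    def test_eps_snr_identity_and_monotonicity(self, rb, n):
        s = snr(rb, n)
        assert abs(eps(rb, n) - s / (1 + s)) < 1e-12
        assert eps(rb + 1e-4, n) >= eps(rb, n)
        assert eps(rb, n + 1) >= eps(rb, n) or rb <= 0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            eps(0.3, 1)
        with pytest.raises(ValidationError):
            snr(1.0, 6)
        with pytest.raises(ValidationError):
            eps(-0.99, 6)


class TestAr1:
    def test_alternating_series(self):
        s = pd.Series([1.0, -1.0] * 25)
        assert ar1(s) < -0.99

    def test_white_noise_near_zero(self, rng):
        assert abs(ar1(pd.Series(rng.normal(size=2000)))) < 0.05

    def test_ar1_simulation_recovers_phi(self, rng):
        phi = 0.6
        x = np.empty(2000)
        x[0] = rng.normal()
        for i in range(1, 2000):
            x[i] = phi * x[i - 1] + rng.normal()
        assert 0.55 <= ar1(pd.Series(x)) <= 0.65

    def test_constant_rejected(self):
        with pytest.raises(ValidationError):
            ar1(pd.Series(np.ones(20)))


def _matrix_from_values(values: np.ndarray) -> xr.Dataset:
    """tree × year × sector dataset from a raw value array."""
    t, y, s = values.shape
    return xr.Dataset(
        {
            "ld": (("tree", "year", "sector"), values),
            "cwt": (("tree", "year", "sector"), values),
            "depth": (("tree", "year"), np.full((t, y), 10)),
        },
        coords={
            "tree": [f"T{i}" for i in range(t)],
            "year": np.arange(2000, 2000 + y),
            "sector": np.arange(1, s + 1),
        },
        attrs={"sector_labels": sector_labels(s)},
    )


class TestSectorChronology:
    def test_identical_trees_give_their_zscores(self, rng):
        base = rng.uniform(10, 20, size=(1, 30, 2))
        vals = np.repeat(base, 2, axis=0)
        chrons = sector_chronology(_matrix_from_values(vals))
        z = ztransform(pd.Series(vals[0, :, 0]))
        assert np.allclose(chrons["I"].index, z)

    def test_opposite_zscore_trees_cancel(self):
        years = 30
        a = np.linspace(10, 20, years)
        vals = np.stack([a, a[::-1]])[:, :, None]
        chrons = sector_chronology(_matrix_from_values(vals))
        assert np.allclose(chrons["I"].index, 0.0, atol=1e-12)

    def test_equals_column_means_of_z_matrix(self, rng):
        vals = rng.uniform(5, 25, size=(6, 40, 3))
        m = _matrix_from_values(vals)
        chrons = sector_chronology(m)
        for j, lab in enumerate(sector_labels(3)):
            z = np.column_stack(
                [ztransform(pd.Series(vals[t, :, j])) for t in range(6)]
            )
            assert np.allclose(chrons[lab].index, z.mean(axis=1), atol=1e-12)

    def test_biweight_matches_arithmetic_on_symmetric_data(self, rng):
        # a two-tree sample is symmetric about its mean by construction, so
        # the biweight location coincides with the arithmetic mean
        vals = rng.uniform(5, 25, size=(2, 40, 1))
        m = _matrix_from_values(vals)
        a = sector_chronology(m, method="arithmetic")["I"].index
        b = sector_chronology(m, method="biweight")["I"].index
        assert np.allclose(a, b, atol=1e-6)


class TestChronologyStats:
    def test_mean_row_is_mean_of_sectors(self, small_matrix):
        stats = chronology_stats(small_matrix, "ld", period=(1985, 2019))
        sectors = stats.drop(index="Mean")
        assert np.allclose(stats.loc["Mean"], sectors.mean(axis=0), atol=1e-12)

    def test_independent_trees_have_weak_eps(self, rng):
        vals = rng.normal(15, 2, size=(2, 60, 1))
        stats = chronology_stats(_matrix_from_values(vals), "ld")
        assert stats.loc["I", "eps"] < 0.5

    def test_rbar_matches_generator_common_share(self):
        # trend/step-free generator: the common log-signal share is
        # (βp² + βt²) / (βp² + βt² + noise²); cell-level noise is negligible
        # after averaging ~10 files × ~4 cells per sector
        import qwa

        params = qwa.SyntheticParams(seed=5, tmax_trend=0.0, ld_break_step_sd=0.0)
        clim = qwa.gen_climate(params)
        m = qwa.build_sector_matrix(qwa.gen_anatomy(clim, params))
        stats = chronology_stats(m, "ld", period=(1963, 2019))
        b2 = params.beta_precip_may**2 + params.beta_tmax_summer**2
        share = b2 / (b2 + params.noise_sd**2)
        assert abs(stats.loc["Mean", "rbar"] - share) < 0.1


class TestSplitGroupTest:
    def test_hand_computed_anova(self):
        s = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                      index=[1989, 1990, 1991, 1992, 1993, 1994])
        res = split_group_test(s, 1992)
        assert np.isclose(res.f_stat, 13.5)
        assert np.isclose(res.p_value, 0.0213, atol=5e-4)
        assert res.mean_before == 2.0 and res.mean_after == 5.0

    def test_identical_groups_give_f_zero(self):
        s = pd.Series([1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
                      index=[1989, 1990, 1991, 1992, 1993, 1994])
        res = split_group_test(s, 1992)
        assert np.isclose(res.f_stat, 0.0)
        assert np.isclose(res.p_value, 1.0)

    def test_small_group_rejected(self):
        s = pd.Series([1.0, 2.0, 3.0, 4.0], index=[1990, 1991, 1992, 1993])
        with pytest.raises(ValidationError):
            split_group_test(s, 1992)


class TestChronologyFrame:
    def test_frame_matches_chronologies(self, small_matrix):
        chrons = sector_chronology(small_matrix, "ld", period=(1985, 2019))
        frame = chronology_frame(chrons)
        assert list(frame.columns) == list(chrons.keys())
        assert np.allclose(frame["I"].dropna(), chrons["I"].index)
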