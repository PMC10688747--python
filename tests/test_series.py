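"""Preprocessing: smoothing, resampling, log rates, warfare encoding."""

import numpy as np
import pytest

from andesdyn.series import (
    Period,
    ProxyTimeSeries,
    WarfarePeriodCoding,
    aligned_table,
    apply_floor,
    clip_range,
    encode_warfare,
    growth_rates,
    read_period_table,
    read_proxy_csv,
    resample,
    smooth_spline,
    write_proxy_csv,
    _spar_to_lam,
)


def green_silverman_smooth(x, y, lam):
    """Independent penalized-least-squares solve (natural cubic spline,
    banded roughness matrix); the oracle for the smoother."""
    n = len(x)
    h = np.diff(x).astype(float)
    Q = np.zeros((n, n - 2))
    R = np.zeros((n - 2, n - 2))
    for j in range(n - 2):
        Q[j, j] = 1 / h[j]
        Q[j + 1, j] = -1 / h[j] - 1 / h[j + 1]
        Q[j + 2, j] = 1 / h[j + 1]
        R[j, j] = (h[j] + h[j + 1]) / 3
        if j + 1 < n - 2:
            R[j, j + 1] = R[j + 1, j] = h[j + 1] / 6
    K = Q @ np.linalg.solve(R, Q.T)
    return np.linalg.solve(np.eye(n) + lam * K, y)


class TestProxyTimeSeries:
    def test_validation(self):
        with pytest.raises(ValueError, match="increasing"):
            ProxyTimeSeries([1, 1, 2], [0.0, 1.0, 2.0])
        with pytest.raises(ValueError, match="mismatch"):
            ProxyTimeSeries([1, 2], [0.0])

    def test_step_detection(self):
        assert ProxyTimeSeries([50, 75, 100], [1.0, 2.0, 3.0]).step == 25
        assert ProxyTimeSeries([50, 75, 110], [1.0, 2.0, 3.0]).step is None


class TestSmoothSpline:
    @pytest.mark.parametrize("spar", [0.0, 0.4, 0.65, 0.9, 1.0])
    def test_constant_series_unchanged(self, spar):
        s = ProxyTimeSeries(np.arange(20), np.full(20, 3.7))
        out = smooth_spline(s, spar)
        np.testing.assert_allclose(out.values, 3.7, rtol=1e-9)

    @pytest.mark.parametrize("spar", [0.0, 0.65, 0.9, 1.0])
    def test_linear_series_unchanged(self, spar):
        t = np.arange(30)
        s = ProxyTimeSeries(t, 2.5 * t - 4.0)
        out = smooth_spline(s, spar)
        np.testing.assert_allclose(out.values, s.values, rtol=1e-8, atol=1e-8)

    def test_rss_monotone_and_matches_direct_solve(self, noisy_sinusoid):
        """RSS against the raw data is non-decreasing in spar, and the
        fitted values agree with an independent penalized solve."""
        y = noisy_sinusoid.values
        t = noisy_sinusoid.times
        x01 = (t - t[0]) / (t[-1] - t[0])
        prev = -np.inf
        for spar in np.arange(0.1, 0.95, 0.1):
            fitted = smooth_spline(noisy_sinusoid, spar).values
            oracle = green_silverman_smooth(x01.astype(float), y, _spar_to_lam(spar))
            np.testing.assert_allclose(fitted, oracle, atol=1e-5)
            rss = float(np.sum((y - fitted) ** 2))
            assert rss >= prev - 1e-9
            prev = rss

    def test_four_points_supported_three_rejected(self):
        s4 = ProxyTimeSeries([0, 1, 2, 3], [1.0, 2.0, 1.5, 3.0])
        out = smooth_spline(s4, 0.5)
        assert len(out) == 4 and np.all(np.isfinite(out.values))
        with pytest.raises(ValueError, match="at least 4"):
            smooth_spline(ProxyTimeSeries([0, 1, 2], [1.0, 2.0, 1.5]), 0.5)

    def test_spar_domain(self, noisy_sinusoid):
        for bad in (-0.1, 1.5):
            with pytest.raises(ValueError, match="spar"):
                smooth_spline(noisy_sinusoid, bad)

    def test_smooth_then_resample_constant(self):
        s = ProxyTimeSeries(np.arange(50, 1501), np.full(1451, 0.42))
        out = resample(smooth_spline(s, 0.9), 25, 50, 1500)
        np.testing.assert_allclose(out.values, 0.42, rtol=1e-9)


class TestResample:
    def test_output_length_and_grid(self):
        s = ProxyTimeSeries(np.arange(50, 1501), np.linspace(0, 1, 1451))
        out = resample(s, 25, 50, 1500)
        assert len(out) == 59
        assert out.step == 25

    def test_northern_window_36_points(self):
        s = ProxyTimeSeries(np.arange(0, 1001), np.linspace(1, 2, 1001))
        assert len(resample(s, 25, 50, 925)) == 36

    def test_passthrough_and_idempotence(self):
        grid = np.arange(50, 550, 25)
        s = ProxyTimeSeries(grid, np.sin(grid / 100.0))
        once = resample(s, 25, 50, 525)
        np.testing.assert_array_equal(once.values, s.values)
        twice = resample(once, 25, 50, 525)
        np.testing.assert_array_equal(twice.values, once.values)

    def test_linear_interpolation_between_points(self):
        s = ProxyTimeSeries([0, 10], [0.0, 1.0])
        out = resample(s, 5, 0, 10)
        np.testing.assert_allclose(out.values, [0.0, 0.5, 1.0])

    def test_window_outside_span(self):
        s = ProxyTimeSeries(np.arange(100, 201), np.ones(101))
        with pytest.raises(ValueError, match="outside"):
            resample(s, 25, 50, 200)


class TestGrowthRates:
    def test_exact_log_differences(self):
        s = ProxyTimeSeries([0, 1, 2], [1.0, np.e, np.e**2])
        r = growth_rates(s)
        np.testing.assert_allclose(r.values, [1.0, 1.0], rtol=1e-14)
        np.testing.assert_array_equal(r.times, [1, 2])  # stamped at step end

    def test_constant_gives_zero(self):
        r = growth_rates(ProxyTimeSeries(np.arange(5), np.full(5, 2.3)))
        np.testing.assert_allclose(r.values, 0.0, atol=1e-15)

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(7)
        v = rng.uniform(0.1, 5.0, 20)
        r = growth_rates(ProxyTimeSeries(np.arange(20), v))
        expected = [np.log(v[i + 1]) - np.log(v[i]) for i in range(19)]
        np.testing.assert_allclose(r.values, expected, rtol=1e-14)

    def test_exponential_series_constant_rate(self):
        t = np.arange(0, 250, 25)
        s = ProxyTimeSeries(t, np.exp(0.3 + 0.02 * t))
        np.testing.assert_allclose(growth_rates(s).values, 0.02 * 25, rtol=1e-10)

    def test_nonpositive_value_names_year(self):
        with pytest.raises(ValueError, match="875"):
            growth_rates(ProxyTimeSeries([850, 875, 900], [1.0, 0.0, 1.0]))


class TestWarfareCoding:
    def test_single_period_constant(self):
        coding = WarfarePeriodCoding((Period("only", 0, 101, 2),))
        out = encode_warfare(coding, (0, 100))
        np.testing.assert_array_equal(out.values, 2.0)

    def test_boundary_half_open(self):
        coding = WarfarePeriodCoding((
            Period("early", 0, 500, 1), Period("late", 500, 1000, 3),
        ))
        out = encode_warfare(coding, (498, 502))
        np.testing.assert_array_equal(out.values, [1, 1, 3, 3, 3])

    def test_range_endpoints_attainable(self):
        # three evidence categories coded 0/1/2 each, summed
        assert WarfarePeriodCoding.component_codes_valid([0, 0, 0])
        assert WarfarePeriodCoding.component_codes_valid([2, 2, 2])
        assert not WarfarePeriodCoding.component_codes_valid([3])
        assert sum([0, 0, 0]) == 0 and sum([2, 2, 2]) == 6
        coding = WarfarePeriodCoding((Period("a", 0, 50, 0), Period("b", 50, 100, 6)))
        out = encode_warfare(coding, (0, 99))
        assert out.values.min() == 0 and out.values.max() == 6

    def test_uncovered_year_rejected(self):
        coding = WarfarePeriodCoding((Period("a", 100, 200, 1),))
        with pytest.raises(ValueError, match="covered"):
            encode_warfare(coding, (50, 150))

    def test_gap_and_bad_code_rejected(self):
        with pytest.raises(ValueError, match="contiguous"):
            WarfarePeriodCoding((Period("a", 0, 100, 1), Period("b", 150, 200, 2)))
        with pytest.raises(ValueError, match="outside"):
            Period("bad", 0, 10, 7)

    def test_smoothing_overshoot_clipped(self):
        coding = WarfarePeriodCoding((
            Period("a", 0, 200, 0), Period("b", 200, 400, 6), Period("c", 400, 600, 0),
        ))
        annual = encode_warfare(coding, (0, 599))
        smoothed = smooth_spline(annual, 0.3)
        clipped = clip_range(smoothed)
        assert smoothed.values.max() > 6 or smoothed.values.min() < 0
        assert clipped.values.min() >= 0 and clipped.values.max() <= 6

    def test_floor_applied_before_log(self):
        w = ProxyTimeSeries([0, 25], [0.0, 2.0])
        floored = apply_floor(w, 0.1)
        np.testing.assert_allclose(floored.values, [0.1, 2.1])
        growth_rates(floored)  # no longer raises


class TestIO:
    def test_proxy_csv_roundtrip(self, tmp_path):
        s = ProxyTimeSeries(np.arange(50, 150, 25), [1.0, 2.5, 3.0, 0.5])
        p = tmp_path / "proxy.csv"
        write_proxy_csv(s, p)
        back = read_proxy_csv(p, label="x")
        np.testing.assert_array_equal(back.times, s.times)
        np.testing.assert_allclose(back.values, s.values)

    def test_period_table_csv_and_yaml(self, tmp_path):
        csv = tmp_path / "periods.csv"
        csv.write_text("name,start,end,code\nEIP,0,600,1\nMH,600,1000,3\n")
        yml = tmp_path / "periods.yml"
        yml.write_text(
            "- {name: EIP, start: 0, end: 600, code: 1}\n"
            "- {name: MH, start: 600, end: 1000, code: 3}\n"
        )
        for path in (csv, yml):
            coding = read_period_table(path)
            assert coding.span == (0, 1000)
            assert [p.code for p in coding.periods] == [1, 3]

    def test_aligned_table_columns_and_rates(self):
        grid = np.arange(50, 950, 25)
        n = len(grid)
        rng = np.random.default_rng(0)
        spd = ProxyTimeSeries(grid, rng.uniform(0.5, 1.5, n))
        spd_nn = ProxyTimeSeries(grid, 120 * spd.values)
        lith = ProxyTimeSeries(grid, np.full(n, 35.0))
        war = ProxyTimeSeries(grid, rng.uniform(0.5, 5.5, n))
        table = aligned_table(spd, spd_nn, lith, war)
        assert list(table.columns) == [
            "calBP", "yearAD", "SPDn", "SPDnn", "Rn", "Rnn", "LithPct", "War", "Rwar",
        ]
        np.testing.assert_array_equal(table["calBP"], 1950 - grid)
        np.testing.assert_allclose(
            table["Rn"].to_numpy()[1:], growth_rates(spd).values, rtol=1e-12
        )
        assert np.isnan(table["Rn"].iloc[0])
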