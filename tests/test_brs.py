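"""BRS regression, the windowed dBRS metric, polynomial fits, onset logic."""

import numpy as np
import pytest

from vvrkit import (
    BeatSeries,
    DeltaBRSSeries,
    InsufficientBeatsError,
    brs_regression,
    delta_brs,
    delta_brs_max,
    detect_tvvr_crossing,
    fit_polynomial,
    onset_lead_time,
    poly_derivative,
)


def beats_from_pairs(sbp, isi):
    sbp = np.asarray(sbp, dtype=float)
    isi = np.asarray(isi, dtype=float)
    times = np.concatenate([[0.0], np.cumsum(isi)])
    # one more systole than intervals
    return BeatSeries(peak_times=times, sbp=sbp, dbp=sbp - 40.0)


def random_beats(rng, n):
    isi = rng.uniform(0.12, 0.3, n - 1)
    times = np.concatenate([[0.0], np.cumsum(isi)])
    sbp = 120 + rng.normal(0, 5, n)
    return BeatSeries(peak_times=times, sbp=sbp, dbp=sbp - 40.0)


class TestBrsRegression:
    def test_exact_linear_relation(self):
        rng = np.random.default_rng(0)
        sbp = 120 + rng.normal(0, 5, 50)
        isi = 0.005 * sbp[:-1] + 0.2  # interval follows the systole opening it
        b = beats_from_pairs(sbp, isi)
        res = brs_regression(b)
        assert res.slope == pytest.approx(0.005, rel=1e-9)
        assert res.r == pytest.approx(1.0)
        assert not res.degenerate

    def test_constant_pressure_degenerate(self):
        b = beats_from_pairs(np.full(20, 120.0), np.full(19, 0.2))
        res = brs_regression(b)
        assert res.degenerate
        assert res.slope == 0.0 and res.r == 0.0

    def test_null_simulation_slope_within_two_se(self):
        """Independent pressure and interval: slope statistically zero."""
        from scipy.stats import linregress

        rng = np.random.default_rng(42)
        n = 2000
        sbp = 120 + rng.normal(0, 5, n)
        isi = np.abs(0.2 + rng.normal(0, 0.01, n - 1))
        b = beats_from_pairs(sbp, isi)
        res = brs_regression(b)
        se = linregress(sbp[:-1], isi).stderr
        assert abs(res.slope) < 2 * se

    def test_too_few_beats(self):
        b = beats_from_pairs([120.0, 121.0], [0.2])
        with pytest.raises(InsufficientBeatsError):
            brs_regression(b)

    def test_slope_invariant_under_pressure_offset(self):
        rng = np.random.default_rng(3)
        b = random_beats(rng, 100)
        res0 = brs_regression(b)
        shifted = BeatSeries(
            peak_times=b.peak_times, sbp=b.sbp + 37.0, dbp=b.dbp + 37.0
        )
        res1 = brs_regression(shifted)
        assert res1.slope == pytest.approx(res0.slope, rel=1e-9)
        assert res1.intercept != pytest.approx(res0.intercept)


def brute_force_delta_brs(beats, W, eps):
    """Loop oracle: consecutive-beat ratios, eps exclusion, window means."""
    isi = list(beats.isi)
    sbp = list(beats.sbp)
    retained, times, values, n_excl = [], [], [], 0
    for i in range(1, len(isi)):
        dsbp = sbp[i] - sbp[i - 1]
        if abs(dsbp) < eps:
            n_excl += 1
            continue
        retained.append((isi[i] - isi[i - 1]) / dsbp)
        window = retained[-W:]
        values.append(sum(window) / len(window))
        times.append(beats.peak_times[i])
    return times, values, n_excl


class TestDeltaBrs:
    def test_hand_computed_example(self):
        # every consecutive ratio equals -0.01, so any window mean is -0.01
        b = beats_from_pairs(
            [120.0, 118.0, 121.0, 117.0, 119.0, 120.0],
            [0.50, 0.52, 0.49, 0.53, 0.51],
        )
        s = delta_brs(b, window_beats=4, eps=0.5)
        assert s.values[-1] == pytest.approx(-0.01, rel=1e-9)

    def test_window_one_gives_raw_ratios(self):
        rng = np.random.default_rng(5)
        b = random_beats(rng, 40)
        s1 = delta_brs(b, window_beats=1, eps=0.5)
        isi, sbp = b.isi, b.sbp
        raw = [
            (isi[i] - isi[i - 1]) / (sbp[i] - sbp[i - 1])
            for i in range(1, len(isi))
            if abs(sbp[i] - sbp[i - 1]) >= 0.5
        ]
        np.testing.assert_array_equal(s1.values, raw)

    def test_small_increment_excluded_and_counted(self):
        b = beats_from_pairs(
            [120.0, 122.0, 125.0, 120.0], [0.2, 0.21, 0.22]
        )
        s = delta_brs(b, window_beats=2, eps=1e-6)
        assert s.n_excluded == 0
        b2 = beats_from_pairs([120.0, 125.0, 125.0, 120.0], [0.2, 0.21, 0.22])
        s2 = delta_brs(b2, window_beats=2, eps=0.5)
        assert s2.n_excluded == 1

    def test_all_excluded_raises(self):
        b = beats_from_pairs(np.full(10, 120.0), np.full(9, 0.2))
        with pytest.raises(InsufficientBeatsError):
            delta_brs(b, window_beats=3, eps=0.5)

    @pytest.mark.parametrize("seed", range(25))
    def test_equals_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 80))
        W = int(rng.integers(1, 8))
        eps = float(rng.uniform(0.1, 5.0))
        b = random_beats(rng, n)
        try:
            s = delta_brs(b, window_beats=W, eps=eps)
        except InsufficientBeatsError:
            assert not brute_force_delta_brs(b, W, eps)[1]
            return
        times, values, n_excl = brute_force_delta_brs(b, W, eps)
        np.testing.assert_array_equal(s.times, times)
        np.testing.assert_array_equal(s.values, values)
        assert s.n_excluded == n_excl


class TestDeltaBrsMax:
    def test_signed_maximum_magnitude(self):
        s = DeltaBRSSeries(
            times=np.array([1.0, 2.0, 3.0]),
            values=np.array([0.1, -0.5, 0.2]),
            window_beats=1,
            eps=0.5,
            n_excluded=0,
        )
        mx = delta_brs_max(s, (0.0, 5.0))
        assert mx.magnitude == 0.5 and mx.signed == -0.5 and mx.time == 2.0

    def test_all_zero(self):
        s = DeltaBRSSeries(np.arange(3.0), np.zeros(3), 1, 0.5, 0)
        assert delta_brs_max(s, (0.0, 5.0)).magnitude == 0.0

    def test_empty_overlap_raises(self):
        s = DeltaBRSSeries(np.arange(3.0), np.zeros(3), 1, 0.5, 0)
        with pytest.raises(ValueError):
            delta_brs_max(s, (10.0, 20.0))


def series_from_function(f, t0=0.0, t1=10.0, n=60):
    t = np.linspace(t0, t1, n)
    return DeltaBRSSeries(t, f(t), window_beats=1, eps=0.5, n_excluded=0)


class TestPolynomialMachinery:
    def test_exact_quadratic_recovered(self):
        s = series_from_function(lambda t: 2.0 - 0.3 * t + 0.05 * t**2)
        fit = fit_polynomial(s, degree=2)
        assert fit.rms_residual < 1e-10
        np.testing.assert_allclose(fit(s.times), s.values, atol=1e-10)

    def test_exact_quintic_recovered(self):
        coeffs = [1.0, -0.5, 0.2, -0.03, 0.002, -5e-5]
        s = series_from_function(lambda t: sum(c * t**i for i, c in enumerate(coeffs)))
        fit = fit_polynomial(s, degree=5)
        np.testing.assert_allclose(fit(s.times), s.values, atol=1e-8)

    def test_degree_zero_rejected(self):
        s = series_from_function(lambda t: t)
        with pytest.raises(ValueError):
            fit_polynomial(s, degree=0)

    def test_too_few_points_rejected(self):
        s = series_from_function(lambda t: t, n=4)
        with pytest.raises(ValueError):
            fit_polynomial(s, degree=5)

    def test_derivative_of_constant_is_zero(self):
        s = series_from_function(lambda t: np.full_like(t, 3.0))
        d = poly_derivative(fit_polynomial(s, degree=1))
        np.testing.assert_allclose(d(s.times), 0.0, atol=1e-10)

    def test_derivative_of_square_is_2t(self):
        s = series_from_function(lambda t: t**2, t0=0.0, t1=10.0)
        d = poly_derivative(fit_polynomial(s, degree=2))
        np.testing.assert_allclose(d(s.times), 2 * s.times, atol=1e-8)

    def test_second_derivative_of_cubic(self):
        a3, a2 = 0.02, -0.4
        s = series_from_function(lambda t: a3 * t**3 + a2 * t**2 + t - 5)
        dd = poly_derivative(poly_derivative(fit_polynomial(s, degree=3)))
        np.testing.assert_allclose(dd(s.times), 6 * a3 * s.times + 2 * a2, atol=1e-8)


class TestTvvrCrossing:
    def test_never_crossing_returns_none(self):
        s = series_from_function(lambda t: np.zeros_like(t))
        d = poly_derivative(fit_polynomial(s, degree=1))
        assert detect_tvvr_crossing(d, -0.02, "below") is None

    def test_linear_downward_crossing_location(self):
        # dBRS = 0.05 - 0.005 t^2/2 -> derivative -0.005 t crosses -0.02 at t=4
        s = series_from_function(lambda t: 0.05 - 0.0025 * t**2)
        d = poly_derivative(fit_polynomial(s, degree=2))
        c = detect_tvvr_crossing(d, -0.02, "below", n_grid=4000)
        grid_step = 10.0 / 3999
        assert c == pytest.approx(4.0, abs=2 * grid_step)

    def test_earliest_of_multiple_crossings(self):
        # derivative of sin wiggles below the threshold repeatedly
        s = series_from_function(lambda t: np.sin(t), n=200)
        d = poly_derivative(fit_polynomial(s, degree=12))
        c = detect_tvvr_crossing(d, -0.5, "below")
        # cos(t) <= -0.5 first at t = 2pi/3
        assert c == pytest.approx(2 * np.pi / 3, abs=0.05)

    def test_magnitude_direction(self):
        s = series_from_function(lambda t: 0.05 - 0.0025 * t**2)
        d = poly_derivative(fit_polynomial(s, degree=2))
        c = detect_tvvr_crossing(d, 0.02, "magnitude")
        assert c == pytest.approx(4.0, abs=0.05)


class TestOnset:
    def _dropping_beats(self):
        sbp = np.concatenate([np.full(50, 120.0), np.linspace(120, 80, 30)])
        isi = np.full(79, 0.2)
        return beats_from_pairs(sbp, isi)

    def test_lead_time_arithmetic(self):
        b = self._dropping_beats()
        res = onset_lead_time(8.0, b, baseline_window=(0.0, 9.9), tvvr=-0.02)
        assert res.bp_drop_onset_time is not None
        assert res.lead_time == pytest.approx(res.bp_drop_onset_time - 8.0)
        assert res.lead_time > 0

    def test_no_crossing_propagates_none(self):
        b = self._dropping_beats()
        res = onset_lead_time(None, b, baseline_window=(0.0, 9.9))
        assert res.crossing_time is None and res.lead_time is None

    def test_no_drop_gives_no_onset(self):
        sbp = np.full(60, 120.0)
        b = beats_from_pairs(sbp, np.full(59, 0.2))
        res = onset_lead_time(5.0, b, baseline_window=(0.0, 6.0))
        assert res.bp_drop_onset_time is None and res.lead_time is None

    def test_half_drop_onset_position(self):
        """Onset = first beat below baseline minus half the full excursion."""
        b = self._dropping_beats()
        from vvrkit.brs import bp_drop_onset

        onset = bp_drop_onset(b, (0.0, 9.9), drop_fraction=0.5)
        # baseline 120, min 80 -> threshold 100; the ramp starts at beat 50
        idx = np.flatnonzero(b.sbp < 100.0)
        assert onset == pytest.approx(b.peak_times[idx[0]])
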