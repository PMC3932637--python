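"""Kinetic reductions against brute-force and closed-form oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

import praakit as pk
from praakit.curves import is_nd


def brute_force_vmax(t, y, k):
    """Independent oracle: enumerate every k-point window with polyfit."""
    best, best_t = None, None
    for i in range(len(t) - k + 1):
        s = np.polyfit(t[i : i + k], y[i : i + k], 1)[0]
        if best is None or abs(s) > abs(best):
            best, best_t = s, t[i]
    return best * 1000.0, best_t


def random_curve(rng, n=71):
    """Noisy mixture of ramp, sigmoid and wiggle on a 1-min grid."""
    t = np.arange(float(n))
    y = (
        0.06
        + rng.uniform(0, 0.01) * t
        + rng.uniform(0, 0.5) / (1 + np.exp(-(t - rng.uniform(10, 60)) / rng.uniform(1, 8)))
        + rng.normal(0, 0.005, n)
    )
    return pk.KineticCurve("A1", t, y)


class TestVmaxRate:
    @pytest.mark.parametrize("k", [2, 5, 10])
    def test_exact_on_linear_curve(self, k):
        t = np.arange(0.0, 30.0)
        curve = pk.KineticCurve("A1", t, 0.06 + 0.001 * t)
        rate, _ = pk.vmax_rate(curve, pk.ReductionSettings(t_max=30, vmax_points=k))
        assert rate == pytest.approx(1.0, rel=1e-9)

    def test_control_fixture_rate(self, linear_curve, settings):
        rate, t0 = pk.vmax_rate(linear_curve, settings)
        assert rate == pytest.approx(0.54 / 70.0 * 1000.0, rel=1e-9)  # ~7.71 mOD/min

    @pytest.mark.parametrize("k", list(range(2, 11)))
    def test_matches_brute_force_enumeration(self, k):
        rng = np.random.default_rng(2024)
        for _ in range(5):
            c = random_curve(rng)
            s = pk.ReductionSettings(vmax_points=k)
            got_rate, got_t = pk.vmax_rate(c, s)
            exp_rate, exp_t = brute_force_vmax(c.times, c.od, k)
            assert got_rate == pytest.approx(exp_rate, rel=1e-9, abs=1e-9)
            assert got_t == exp_t

    def test_steepest_negative_slope_reported_signed(self):
        t = np.arange(0.0, 20.0)
        curve = pk.KineticCurve("A1", t, 1.0 - 0.01 * t)
        rate, _ = pk.vmax_rate(curve, pk.ReductionSettings(t_max=20, vmax_points=4))
        assert rate == pytest.approx(-10.0, rel=1e-9)

    def test_tie_broken_by_earliest_window(self):
        # two identical steep segments; the first must win
        t = np.arange(0.0, 12.0)
        y = np.concatenate([[0, 1, 2], [2, 2, 2], [2, 3, 4], [4, 4, 4]])
        rate, t0 = pk.vmax_rate(
            pk.KineticCurve("A1", t, y), pk.ReductionSettings(t_max=12, vmax_points=3)
        )
        assert t0 == 0.0

    def test_too_few_points_names_counts(self, linear_curve):
        s = pk.ReductionSettings(t_min=0, t_max=2, vmax_points=5)
        with pytest.raises(ValueError, match="3 readings.*needs >= 5"):
            pk.vmax_rate(linear_curve, s)


class TestSlope:
    def test_linear(self, linear_curve, settings):
        assert pk.slope(linear_curve, settings) == pytest.approx(
            0.54 / 70 * 1000, rel=1e-9
        )

    def test_equals_vmax_at_full_window(self):
        rng = np.random.default_rng(5)
        c = random_curve(rng)
        s = pk.ReductionSettings(vmax_points=len(c.times))
        assert pk.slope(c) == pytest.approx(pk.vmax_rate(c, s)[0], rel=1e-9)

    def test_matches_closed_form_least_squares(self):
        rng = np.random.default_rng(6)
        c = random_curve(rng)
        t, y = c.times, c.od
        beta = ((t - t.mean()) @ (y - y.mean())) / ((t - t.mean()) @ (t - t.mean()))
        assert pk.slope(c) == pytest.approx(beta * 1000.0, rel=1e-9)


class TestAuc:
    def test_constant(self, settings):
        t = np.arange(0.0, 71.0)
        c = pk.KineticCurve("A1", t, np.full(71, 0.1))
        assert pk.auc(c, settings) == pytest.approx(7.0, rel=1e-12)

    def test_additive_over_split_window(self):
        rng = np.random.default_rng(7)
        c = random_curve(rng)
        a = pk.auc(c, pk.ReductionSettings(t_min=0, t_max=35))
        b = pk.auc(c, pk.ReductionSettings(t_min=35, t_max=70))
        whole = pk.auc(c, pk.ReductionSettings(t_min=0, t_max=70))
        assert a + b == pytest.approx(whole, rel=1e-12)

    def test_quadratic_within_trapezoid_error_bound(self, settings):
        t = np.arange(0.0, 71.0)
        c = pk.KineticCurve("A1", t, 0.06 + 1e-4 * t**2)
        exact = 0.06 * 70 + 1e-4 * 70**3 / 3
        bound = (70.0 * 1.0**2 / 12.0) * 2e-4  # (b-a) h^2 |f''| / 12
        assert abs(pk.auc(c, settings) - exact) <= bound * (1 + 1e-12)

    @hyp_settings(derandomize=True, max_examples=25, deadline=None)
    @given(scale=st.floats(-5, 5, allow_nan=False))
    def test_linearity_in_the_curve(self, scale):
        t = np.arange(0.0, 20.0)
        y = 0.06 + 0.004 * t
        base = pk.auc(pk.KineticCurve("A1", t, y), pk.ReductionSettings(t_max=20))
        scaled = pk.auc(pk.KineticCurve("A1", t, scale * y), pk.ReductionSettings(t_max=20))
        assert scaled == pytest.approx(scale * base, rel=1e-9, abs=1e-9)


class TestPeakMean:
    def test_constant_curve(self, settings):
        t = np.arange(0.0, 71.0)
        c = pk.KineticCurve("A1", t, np.full(71, 0.2))
        assert pk.peak(c, settings) == 0.2
        assert pk.mean_od(c, settings) == pytest.approx(0.2)

    def test_monotone_curve_peaks_at_window_end(self, linear_curve, settings):
        assert pk.peak(linear_curve, settings) == pytest.approx(0.60, rel=1e-12)
        assert pk.mean_od(linear_curve, settings) == pytest.approx(0.33, rel=1e-12)

    def test_exhaustive_scan_oracle(self, settings):
        rng = np.random.default_rng(8)
        c = random_curve(rng)
        assert pk.peak(c, settings) == max(c.od)
        assert pk.mean_od(c, settings) == pytest.approx(sum(c.od) / len(c.od), rel=1e-12)


class TestTimeToHalfMax:
    def test_linear_interpolated_crossing(self, linear_curve, settings):
        # peak 0.60, target 0.30, crossing of 0.06 + (0.54/70) t
        expected = (0.30 - 0.06) / (0.54 / 70.0)
        assert pk.time_to_half_max(linear_curve, settings) == pytest.approx(
            expected, rel=1e-9
        )

    def test_constant_curve_is_nd(self, settings):
        t = np.arange(0.0, 71.0)
        c = pk.KineticCurve("A1", t, np.full(71, 0.2))
        assert is_nd(pk.time_to_half_max(c, settings))

    def test_step_midpoint(self):
        t = np.arange(0.0, 21.0)
        y = np.where(t <= 10, 0.0, 1.0)
        s = pk.ReductionSettings(t_max=21)
        assert pk.time_to_half_max(pk.KineticCurve("A1", t, y), s) == pytest.approx(10.5)

    def test_within_limits_on_nondecreasing_curves(self, control_curve, settings):
        th = pk.time_to_half_max(control_curve, settings)
        assert settings.t_min <= th <= settings.t_max


class TestLagTime:
    def test_no_induction_phase_on_control(self, control_curve, settings):
        assert pk.lag_time(control_curve, settings) == pytest.approx(0.0, abs=0.5)

    def test_exactly_linear_curve_has_zero_lag(self, linear_curve, settings):
        assert pk.lag_time(linear_curve, settings) == 0.0

    def test_flat_curve_is_nd(self, settings):
        t = np.arange(0.0, 71.0)
        c = pk.KineticCurve("A1", t, np.full(71, 0.06))
        assert is_nd(pk.lag_time(c, settings))

    def test_matches_analytic_induction_time(self, strong_scavenger_params):
        p = strong_scavenger_params
        ah = 1e-5
        expected = p.n_stoich * ah / pk.radical_flux(p, 0.0)
        est = pk.lag_time(pk.simulate_well(p, ah))
        assert est == pytest.approx(expected, rel=0.10)


class TestWindowing:
    def test_reductions_ignore_out_of_window_points(self, settings):
        rng = np.random.default_rng(9)
        c = random_curve(rng)
        t_ext2 = np.concatenate([c.times, [80.0, 90.0]])
        y_ext2 = np.concatenate([c.od, [9.9, 9.9]])
        ext2 = pk.KineticCurve("A1", t_ext2, y_ext2)
        a, b = pk.reduce_curve(c, settings), pk.reduce_curve(ext2, settings)
        for f in ("vmax_mOD_per_min", "slope_mOD_per_min", "auc_OD_min",
                  "peak_OD", "mean_OD"):
            assert getattr(a, f) == pytest.approx(getattr(b, f), rel=1e-12)

    def test_vmax_dominates_full_slope_on_smooth_curves(
        self, strong_scavenger_params, settings
    ):
        for ah in (0.0, 1e-6, 1e-5):
            c = pk.simulate_well(strong_scavenger_params, ah)
            r = pk.reduce_curve(c, settings)
            assert abs(r.vmax_mOD_per_min) >= abs(r.slope_mOD_per_min) - 1e-9


class TestReducePlate:
    def _plate(self, seed=3):
        layout = pk.example_layout(
            compounds=("trolox_like", "nicotinate_like"), n_controls=2, n_blanks=2
        )
        p = pk.SimulationParams(seed=seed)
        curves = pk.simulate_plate(p, layout)
        return pk.blank_correct(curves, layout), layout

    def test_one_result_per_non_blank_well(self):
        curves, layout = self._plate()
        results = pk.reduce_plate(curves, layout)
        assert set(results) == set(layout.wells("control")) | set(layout.wells("sample"))

    def test_matches_single_well_calls(self, settings):
        curves, layout = self._plate()
        results = pk.reduce_plate(curves, layout, settings)
        w = layout.wells("sample")[0]
        solo = pk.reduce_curve(curves[w], settings)
        assert results[w] == solo

    def test_per_well_failure_names_the_well(self, settings):
        t = np.arange(0.0, 3.0)
        curves = {"A1": pk.KineticCurve("A1", t, np.full(3, 0.1))}
        layout = pk.PlateLayout([pk.LayoutEntry("A1", "x", 1e-6, "sample")])
        with pytest.raises(ValueError, match="A1"):
            pk.reduce_plate(curves, layout, settings)


class TestReductionCsv:
    def test_round_trip_with_nd(self, tmp_path, settings):
        t = np.arange(0.0, 71.0)
        flat = pk.KineticCurve("B1", t, np.full(71, 0.2))
        rising = pk.KineticCurve("B2", t, 0.06 + 0.005 * t)
        results = {
            "B1": pk.reduce_curve(flat, settings),
            "B2": pk.reduce_curve(rising, settings),
        }
        path = tmp_path / "red.csv"
        from praakit.reductions import read_reductions, write_reductions

        write_reductions(results, path)
        back = read_reductions(path)
        assert is_nd(back["B1"].t_half_max_min) and is_nd(back["B1"].lag_min)
        assert back["B2"].vmax_mOD_per_min == pytest.approx(
            results["B2"].vmax_mOD_per_min, rel=1e-9
        )
        assert back["B2"].t_half_max_min == pytest.approx(
            results["B2"].t_half_max_min, rel=1e-9
        )
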