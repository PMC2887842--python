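import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iesim.analytic import AnalyticScenario, analytic_af_along_fiber
from iesim.metrics import (
    AFStats,
    MetricsError,
    activating_function,
    relative_threshold,
    selectivity,
)
from iesim.nerves import PotentialProfile


def profile_from(v: np.ndarray, truncated=True, name="p") -> PotentialProfile:
    s = 0.1 * np.arange(v.size)
    return PotentialProfile(name, s, np.asarray(v, float), truncated)


def quadratic_profile(a_v_per_m2: float, n=201):
    s_m = 1e-4 * np.arange(n)  # 0.1 mm steps in metres
    return profile_from(a_v_per_m2 * s_m**2)


class TestActivatingFunction:
    def test_quadratic_field_gives_exact_second_derivative(self):
        """V = a s^2 has AF = 2a at every interior node, exactly."""
        af = activating_function(quadratic_profile(1.0), 0)
        assert np.allclose(af.interior_af, 2.0, rtol=1e-9)

    def test_linear_field_zero_interior_terminal_slope(self):
        b = 3.0  # V/m
        prof = profile_from(b * 1e-4 * np.arange(101))
        af = activating_function(prof, 0)
        assert np.allclose(af.interior_af, 0.0, atol=1e-9)
        assert af.terminal_af == pytest.approx(b, rel=1e-9)
        # sealed-end folding puts the terminal drive into the node max
        assert af.max_af == pytest.approx(b / 5e-4, rel=1e-9)

    def test_offsets_shift_the_node_grid(self):
        prof = quadratic_profile(1.0)
        for off in range(5):
            af = activating_function(prof, off)
            assert af.node_s_mm[0] == pytest.approx(0.1 * off)
            assert np.all(np.diff(af.node_s_mm) == pytest.approx(0.5))

    @pytest.mark.parametrize("d, bound", [(3.0, 0.022), (4.5, 0.01)])
    def test_point_source_matches_analytic_second_derivative(self, d, bound):
        """Discrete AF of a 1 mA point source agrees with the closed-form
        second derivative to the Taylor bound of the central difference,
        3 l^2 / (4 d^2) at the peak: 2.1% at d = 3 mm, under 1% by 4.5 mm."""
        sc = AnalyticScenario("point-source", sigma=0.05)
        x = np.arange(-15.0, 15.0 + 1e-9, 0.1)
        v = -1e-3 / (4 * np.pi * 0.05 * 1e-3 * np.sqrt(d**2 + x**2))
        prof = profile_from(v)
        af = activating_function(prof, 0, terminal_mode="exclude")
        nodes_x = x[0] + af.node_s_mm[1:-1]
        exact = analytic_af_along_fiber(sc, d, nodes_x)
        assert np.max(np.abs(af.interior_af - exact) / exact.max()) < bound

    def test_error_decreases_as_internodal_length_shrinks(self):
        """The second difference converges to the analytic second
        derivative as l decreases (checked at l = 2, 1, 0.5 mm)."""
        sc = AnalyticScenario("point-source", sigma=0.05)
        d = 3.0
        x = np.arange(-15.0, 15.0 + 1e-9, 0.1)
        v = -1e-3 / (4 * np.pi * 0.05 * 1e-3 * np.sqrt(d**2 + x**2))
        prof = profile_from(v)
        errs = []
        for l in (2.0, 1.0, 0.5):
            af = activating_function(prof, 0, terminal_mode="exclude", l_mm=l)
            nodes_x = x[0] + af.node_s_mm[1:-1]
            exact = analytic_af_along_fiber(sc, d, nodes_x)
            errs.append(np.max(np.abs(af.interior_af - exact)) / exact.max())
        assert errs[0] > errs[1] > errs[2]

    def test_profile_too_short_rejected(self):
        with pytest.raises(MetricsError):
            activating_function(profile_from(np.zeros(8)), 0)

    @given(st.integers(0, 4), st.lists(st.floats(-1, 1), min_size=40, max_size=120))
    @settings(max_examples=50, deadline=None)
    def test_interior_sum_telescopes(self, off, vals):
        """Sum of interior second differences times l^2 telescopes to the
        difference of the one-sided first differences at the two ends."""
        prof = profile_from(np.asarray(vals))
        try:
            af = activating_function(prof, off)
        except MetricsError:
            return
        idx = np.arange(off, len(vals), 5)
        vn = np.asarray(vals)[idx]
        expect = (vn[-1] - vn[-2]) - (vn[1] - vn[0])
        assert np.sum(af.interior_af) * (5e-4) ** 2 == pytest.approx(expect, abs=1e-9)

    @given(st.floats(0.1, 10), st.integers(0, 4))
    @settings(max_examples=30, deadline=None)
    def test_af_is_linear_in_the_field(self, alpha, off):
        rng = np.random.default_rng(0)
        v = rng.normal(size=60)
        a1 = activating_function(profile_from(v), off)
        a2 = activating_function(profile_from(alpha * v), off)
        assert np.allclose(a2.interior_af, alpha * a1.interior_af, rtol=1e-9)
        assert a2.max_af == pytest.approx(alpha * a1.max_af, rel=1e-9)


class TestStats:
    def test_selectivity_arithmetic(self):
        res = selectivity(AFStats("a", 2.0, 0.5, 10, ()), AFStats("b", 1.0, 0.2, 10, ()))
        assert res.selectivity == pytest.approx(1.25)
        assert res.af_ratio == pytest.approx(2.0)
        assert res.selective

    def test_identical_stats_not_selective(self):
        a = AFStats("a", 1.0, 0.0, 10, ())
        res = selectivity(a, a)
        assert res.selectivity == 1.0 and res.af_ratio == 1.0
        assert not res.selective  # strict inequalities

    def test_boundary_just_above_thresholds(self):
        res = selectivity(AFStats("a", 1.6, 0.0, 5, ()), AFStats("b", 1.0, 0.0, 5, ()))
        assert res.selective

    def test_zero_denominator_flagged_undefined(self):
        res = selectivity(AFStats("a", 1.0, 0.1, 5, ()), AFStats("b", 0.0, 0.0, 5, ()))
        assert not res.defined and not res.selective

    def test_undepolarized_off_target_is_infinitely_selective(self):
        res = selectivity(AFStats("a", 1.0, 0.1, 5, ()), AFStats("b", -2.0, 0.5, 5, ()))
        assert res.selective and np.isinf(res.selectivity)

    def test_afstats_from_values(self):
        st_ = AFStats.from_values("x", [1.0, 2.0, 3.0])
        assert st_.mean == pytest.approx(2.0)
        assert st_.sd == pytest.approx(1.0)
        assert st_.n == 3

    def test_relative_threshold_inverts_and_normalizes(self):
        out = relative_threshold({"a": 2.0, "b": 1.0})
        assert out == {"a": 1.0, "b": 2.0}
        out = relative_threshold({"a": 3.0, "b": 3.0, "c": 3.0})
        assert all(v == 1.0 for v in out.values())
        with pytest.raises(MetricsError):
            relative_threshold({"a": 0.0})
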