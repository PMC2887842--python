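import numpy as np
import pytest
from scipy import stats

import iesim
from iesim.nerves import NerveError, NerveParams, NervePath, build_branch_set


@pytest.fixture(scope="module")
def paths():
    return iesim.build_trunk_paths()


def min_distance_to_axis(path: NervePath, x_lo: float, x_hi: float) -> float:
    """Closest approach of the path to lumen-axis points with x in [lo, hi]."""
    axis_x = np.linspace(x_lo, x_hi, 40)
    pts = path.points
    d = np.sqrt(
        (pts[:, 0, None] - axis_x[None, :]) ** 2
        + pts[:, 1, None] ** 2
        + pts[:, 2, None] ** 2
    )
    return float(d.min())


class TestTrunks:
    def test_dnp_nearer_penile_than_membranous_urethra(self, paths):
        p = paths["DNP-right"]
        assert min_distance_to_axis(p, 10, 40) < min_distance_to_axis(p, 50, 70)

    def test_csn_nearer_membranous_than_penile_urethra(self, paths):
        p = paths["CSN-right"]
        assert min_distance_to_axis(p, 50, 70) < min_distance_to_axis(p, 10, 40)

    def test_bilateral_pairs_are_exact_mirrors(self, paths):
        for nerve in ("DNP", "CSN"):
            left, right = paths[f"{nerve}-left"].points, paths[f"{nerve}-right"].points
            assert np.max(np.abs(left - right * [1, -1, 1])) < 1e-9

    def test_paths_stay_inside_the_model_volume(self, paths):
        hull = iesim.AnatomyParams().build_grid()
        for p in paths.values():
            assert hull.contains(p.points).all()

    def test_arclength_strictly_increasing(self, paths):
        for p in paths.values():
            assert np.all(np.diff(p._cum) > 0)


class TestBranches:
    def test_seed_reproducibility(self):
        a, b = build_branch_set(1), build_branch_set(1)
        assert np.array_equal(a.realized_x_mm, b.realized_x_mm)
        assert all(
            np.array_equal(p.points, q.points) for p, q in zip(a.paths, b.paths)
        )
        assert not np.array_equal(a.realized_x_mm, build_branch_set(2).realized_x_mm)

    def test_zero_jitter_recovers_base_positions(self):
        bs = build_branch_set(7, jitter_mm=0.0)
        assert bs.realized_x_mm == pytest.approx([14.0, 17.0, 20.0, 23.0, 26.0])
        assert np.diff(bs.realized_x_mm) == pytest.approx([3.0] * 4)

    def test_jitter_is_uniform_over_plus_minus_one_cm(self):
        """Across many seeds the middle branch's offset passes a KS test
        against U(-10, 10) (the middle branch never hits the clamp)."""
        offsets = np.array(
            [build_branch_set(s).realized_x_mm[2] - 20.0 for s in range(120)]
        )
        assert abs(offsets).max() <= 10.0
        p = stats.kstest(offsets, stats.uniform(loc=-10, scale=20).cdf).pvalue
        assert p > 0.01

    def test_branches_dive_toward_the_urethra(self):
        n = NerveParams()
        for path in build_branch_set(3).paths:
            r = np.hypot(path.points[:, 1], path.points[:, 2])
            assert r[0] == pytest.approx(n.branch_terminal_radius_mm, abs=0.2)
            assert r[-1] > r[0] + 1.0  # root on the trunk, farther out
            assert path.points[0, 2] < 0  # terminal is ventral of the equator

    def test_clamping_keeps_branches_in_the_penile_segment(self):
        lo, hi = NerveParams().branch_clamp_x_mm
        for s in range(40):
            x = build_branch_set(s).realized_x_mm
            assert np.all((x >= lo) & (x <= hi))


class TestSampling:
    def test_constant_field_samples_constant(self):
        from tests_helpers import uniform_field

        f = uniform_field(np.full((40, 20, 20), -2.5))
        path = NervePath("p", np.array([[2.0, 2.0, 2.0], [12.0, 2.0, 2.0]]))
        prof = iesim.sample_potential(f, path)
        assert np.allclose(prof.v, -2.5, atol=1e-12)

    @pytest.mark.parametrize("method, atol", [("linear", 1e-12), ("cubic", 1e-7)])
    def test_linear_field_sampled_exactly(self, method, atol):
        """Trilinear interpolation reproduces an affine field to machine
        precision anywhere; the tricubic spline does so in the interior
        (its mirror-boundary influence decays geometrically and is below
        1e-7 a few cells in)."""
        from tests_helpers import uniform_field

        f = uniform_field(np.zeros((60, 30, 30)))
        X, Y, Z = f.grid.centers()
        f.values[:] = 0.3 * X - 0.1 * Y + 0.05 * Z
        path = NervePath("p", np.array([[6.0, 7.0, 8.0], [24.0, 8.0, 7.0]]))
        prof = iesim.sample_potential(f, path, method=method)
        pts = path.at_arclength(prof.s_mm)
        expect = 0.3 * pts[:, 0] - 0.1 * pts[:, 1] + 0.05 * pts[:, 2]
        assert np.allclose(prof.v, expect, atol=atol)

    def test_one_cm_path_yields_101_samples(self):
        from tests_helpers import uniform_field

        f = uniform_field(np.zeros((40, 20, 20)))
        path = NervePath("p", np.array([[2.0, 2.0, 2.0], [12.0, 2.0, 2.0]]))
        prof = iesim.sample_potential(f, path)
        assert prof.v.size == 101
        assert prof.s_mm[-1] == pytest.approx(10.0)

    def test_point_outside_grid_rejected(self):
        from tests_helpers import uniform_field

        f = uniform_field(np.zeros((10, 10, 10)))
        path = NervePath("p", np.array([[1.0, 1.0, 1.0], [100.0, 1.0, 1.0]]))
        with pytest.raises(NerveError):
            iesim.sample_potential(f, path)

    def test_bilateral_profiles_agree_for_ring_field(self, ring_field, trunk_paths):
        left = iesim.sample_potential(ring_field, trunk_paths["DNP-left"])
        right = iesim.sample_potential(ring_field, trunk_paths["DNP-right"])
        assert np.allclose(left.v, right.v, rtol=0, atol=1e-3 * abs(right.v).max())
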