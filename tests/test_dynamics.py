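"""Field time-stepping, equilibria and isogloss measurement."""

import numpy as np
import pytest

import isogloss as ig
from isogloss.dynamics import masked_laplacian


def make_uniform(n=32, boundary="periodic", cell=1.0):
    return ig.PopulationRaster(np.ones((n, n)), cell_size=cell,
                               boundary_mode=boundary)


class TestSteppers:
    def test_uniform_states_are_fixed_points(self):
        raster = make_uniform()
        params = ig.ModelParams(sigma=2.0, beta=1.4)
        op = ig.build_interaction_operator(raster, None, params)
        for m0 in (0.5, 1.0, 0.0):
            st = ig.FieldState(np.full(raster.shape, m0))
            out_nl = ig.step_nonlocal(st, op, params, 0.1)
            out_lo = ig.step_local(st, raster, params, 0.1)
            assert np.abs(out_nl.m - m0).max() == 0.0
            assert np.abs(out_lo.m - m0).max() < 1e-14

    def test_uniform_fixed_point_on_nonuniform_density(self, rng):
        """The normalization counterterm keeps m ≡ const stationary even
        where ∇²ρ ≠ 0."""
        vals = rng.uniform(0.5, 3.0, (24, 24))
        raster = ig.PopulationRaster(vals, boundary_mode="closed")
        params = ig.ModelParams(sigma=1.5, beta=1.2)
        st = ig.FieldState(np.full(raster.shape, 1.0))
        out = ig.step_local(st, raster, params, 0.1)
        assert np.abs(out.m - 1.0).max() < 1e-12

    def test_relabel_symmetry(self, rng):
        """At α=1, evolving 1−m mirrors evolving m, to machine precision."""
        raster = make_uniform()
        params = ig.ModelParams(sigma=2.5, beta=1.3, alpha=1.0)
        op = ig.build_interaction_operator(raster, None, params)
        m0 = rng.random(raster.shape)
        a = ig.FieldState(m0.copy())
        b = ig.FieldState(1.0 - m0)
        for _ in range(20):
            a = ig.step_nonlocal(a, op, params, 0.1)
            b = ig.step_nonlocal(b, op, params, 0.1)
        assert np.abs(a.m - (1.0 - b.m)).max() < 1e-13

    def test_translation_invariance(self, rng):
        raster = make_uniform()
        params = ig.ModelParams(sigma=2.0, beta=1.2)
        op = ig.build_interaction_operator(raster, None, params)
        m0 = rng.random(raster.shape)
        a = ig.FieldState(m0)
        b = ig.FieldState(np.roll(m0, (5, -3), axis=(0, 1)))
        for _ in range(15):
            a = ig.step_nonlocal(a, op, params, 0.1)
            b = ig.step_nonlocal(b, op, params, 0.1)
        assert np.abs(np.roll(a.m, (5, -3), axis=(0, 1)) - b.m).max() < 1e-10

    @pytest.mark.parametrize("dt", [0.05, 0.5, 1.0])
    def test_boundedness(self, dt, rng):
        raster = make_uniform(24)
        params = ig.ModelParams(sigma=2.0, beta=2.0, alpha=1.3)
        op = ig.build_interaction_operator(raster, None, params)
        st = ig.FieldState(rng.random(raster.shape))
        for _ in range(10):
            st = ig.step_nonlocal(st, op, params, dt)
            assert st.m.min() >= 0.0 and st.m.max() <= 1.0

    def test_nan_detection(self):
        raster = make_uniform(8)
        params = ig.ModelParams(sigma=2.0)
        op = ig.build_interaction_operator(raster, None, params)
        bad = np.full(raster.shape, 0.5)
        bad[3, 4] = np.nan
        with pytest.raises(FloatingPointError, match=r"\(3, 4\)"):
            ig.step_nonlocal(ig.FieldState(bad), op, params, 0.1)

    def test_local_stability_guard(self):
        raster = make_uniform(16, cell=0.5)
        params = ig.ModelParams(sigma=4.0)
        with pytest.raises(ValueError, match="unstable"):
            ig.step_local(ig.FieldState(np.full(raster.shape, 0.5)),
                          raster, params, 0.1)

    def test_zero_density_error(self):
        raster = ig.PopulationRaster(np.zeros((8, 8)))
        params = ig.ModelParams(sigma=1.0)
        with pytest.raises(ZeroDivisionError):
            ig.step_local(ig.FieldState(np.full((8, 8), 0.5)), raster, params, 0.01)

    def test_local_matches_nonlocal_to_fourth_order(self):
        """One local step differs from one nonlocal step by O(σ⁴); halving σ
        shrinks the difference by ≈ 16 (sine-mode oracle)."""
        n, cell, lam = 128, 0.5, 32.0
        x = cell * np.arange(n)
        X, _ = np.meshgrid(x, x, indexing="ij")
        m0 = 0.5 + 0.2 * np.sin(2 * np.pi * X / lam)
        diffs = {}
        for sig in (4.0, 2.0):
            raster = make_uniform(n, cell=cell)
            params = ig.ModelParams(sigma=sig, beta=1.0 + 1e-12)
            op = ig.build_interaction_operator(raster, None, params)
            dt = 0.005
            nl = ig.step_nonlocal(ig.FieldState(m0.copy()), op, params, dt)
            lo = ig.step_local(ig.FieldState(m0.copy()), raster, params, dt)
            diffs[sig] = np.abs(nl.m - lo.m).max()
        assert 12.0 < diffs[4.0] / diffs[2.0] < 20.0


class TestEquilibriumDriver:
    def test_converges_and_flags(self):
        raster = make_uniform(16)
        params = ig.ModelParams(sigma=2.0, beta=1.5)
        op = ig.build_interaction_operator(raster, None, params)
        st = ig.FieldState(np.full(raster.shape, 0.9))
        res = ig.run_to_equilibrium(st, dynamics="nonlocal", params=params, op=op,
                                    config=ig.SolverConfig(max_time=100.0))
        assert res.converged and res.residual < 1e-6
        assert np.abs(res.state.m - 1.0).max() < 1e-4
        res2 = ig.run_to_equilibrium(
            ig.FieldState(np.full(raster.shape, 0.9)), dynamics="nonlocal",
            params=params, op=op, config=ig.SolverConfig(max_time=0.5))
        assert not res2.converged

    def test_snapshots(self):
        raster = make_uniform(12)
        params = ig.ModelParams(sigma=2.0)
        op = ig.build_interaction_operator(raster, None, params)
        st = ig.FieldState(np.full(raster.shape, 0.8))
        res = ig.run_to_equilibrium(st, dynamics="nonlocal", params=params, op=op,
                                    config=ig.SolverConfig(max_time=5.0),
                                    snapshot_times=[1.0, 2.0])
        assert [round(s.t, 5) for s in res.snapshots] == [1.0, 2.0]


class TestRandomInit:
    def test_statistics_and_reproducibility(self):
        raster = ig.PopulationRaster(np.ones((100, 100)))
        a = ig.random_init(raster, 7)
        b = ig.random_init(raster, 7)
        c = ig.random_init(raster, 8)
        assert abs(a.m.mean() - 0.5) < 0.015  # 3 sigma CLT bound at n = 1e4
        assert np.array_equal(a.m, b.m)
        assert (a.m != c.m).mean() > 0.99

    def test_zero_off_land(self):
        mask = np.zeros((10, 10), bool)
        mask[:5] = True
        raster = ig.PopulationRaster(np.ones((10, 10)), land_mask=mask)
        st = ig.random_init(raster, 0)
        assert st.m[~mask].sum() == 0.0


class TestIsoglosses:
    def test_uniform_field_has_no_contours(self):
        raster = make_uniform(16)
        params = ig.ModelParams(beta=1.0 + 1e-12)
        st = ig.FieldState(np.full(raster.shape, 0.8))
        assert ig.extract_isoglosses(st, params, raster) == []

    def test_planted_circle(self):
        raster = ig.PopulationRaster(np.ones((51, 51)), boundary_mode="closed")
        params = ig.ModelParams(beta=1.0 + 1e-12)
        X, Y = raster.coords()
        prof = 1 / (1 + np.exp((np.hypot(X - 25, Y - 25) - 20.0) / 1.5))
        cs = ig.extract_isoglosses(ig.FieldState(prof), params, raster)
        assert len(cs) == 1 and cs[0].closed
        mean, sd = ig.measure_radius(cs[0], (25.0, 25.0))
        assert mean == pytest.approx(20.0, abs=0.5)
        assert cs[0].curvature.mean() == pytest.approx(1 / 20.0, rel=0.1)
        # outward normal points down-gradient (away from the A disc)
        pts = cs[0].vertices[:-1]
        rad = pts - 25.0
        rad /= np.hypot(rad[:, 0], rad[:, 1])[:, None]
        assert (cs[0].normal[:-1] * rad).sum(axis=1).mean() > 0.95

    def test_planted_vertical_front(self):
        raster = ig.PopulationRaster(np.ones((20, 12)), boundary_mode="closed")
        params = ig.ModelParams(beta=1.0 + 1e-12)
        X, _ = raster.coords()
        x0 = 7.25  # between grid columns
        m = np.clip(0.5 - 0.1 * (X - x0), 0, 1)
        cs = ig.extract_isoglosses(ig.FieldState(m), params, raster)
        assert len(cs) == 1 and not cs[0].closed
        assert np.abs(cs[0].vertices[:, 0] - x0).max() < 0.5

    def test_radius_requires_closed_contour(self):
        c = ig.IsoglossContour(np.array([[0.0, 0.0], [1.0, 0.0]]), False,
                               np.zeros(2), np.zeros((2, 2)))
        with pytest.raises(ValueError):
            ig.measure_radius(c, (0.0, 0.0))

    def test_ellipse_radius_bounds(self):
        raster = ig.PopulationRaster(np.ones((81, 81)), boundary_mode="closed")
        params = ig.ModelParams(beta=1.0 + 1e-12)
        X, Y = raster.coords()
        r_ell = np.hypot((X - 40) / 20.0, (Y - 40) / 10.0)
        m = np.clip(1.0 - 0.5 * r_ell, 0, 1)  # crosses 1/2 on the ellipse
        cs = [c for c in ig.extract_isoglosses(ig.FieldState(m), params, raster)
              if c.closed]
        mean, _ = ig.measure_radius(cs[0], (40.0, 40.0))
        assert 10.0 < mean < 20.0


class TestFrontSpeed:
    def test_stationary_front_at_no_bias(self):
        nx, ny, sig = 200, 4, 4.0
        raster = ig.PopulationRaster(np.ones((nx, ny)), boundary_mode="closed")
        params = ig.ModelParams(sigma=sig, beta=1.2, alpha=1.0)
        op = ig.build_interaction_operator(raster, None, params)
        X, _ = raster.coords()
        st = ig.FieldState((X < nx / 2).astype(float))
        snaps = []
        for k in range(600):
            st = ig.step_nonlocal(st, op, params, 0.1)
            if k >= 200 and k % 50 == 0:
                snaps.append(st)
        v = ig.measure_front_speed(snaps, params, raster, axis=0)
        assert abs(v) < 1e-3 * sig

    def test_multiple_fronts_detected(self):
        raster = make_uniform(32)
        params = ig.ModelParams(sigma=2.0, beta=1.2)
        X, _ = raster.coords()
        st = ig.FieldState(((X >= 8) & (X < 24)).astype(float))  # a band
        with pytest.raises(ValueError, match="multiple"):
            ig.measure_front_speed([st, ig.FieldState(st.m, 1.0)], params, raster)


def test_coarsening_shortens_isoglosses():
    """Total isogloss length decreases over time after the transient."""
    params = ig.ModelParams(sigma=3.0, beta=1.3)
    for seed in (0, 1, 2):
        raster = make_uniform(48)
        op = ig.build_interaction_operator(raster, None, params)
        st = ig.random_init(raster, seed)
        lengths = []
        for k in range(400):
            st = ig.step_nonlocal(st, op, params, 0.1)
            if (k + 1) % 100 == 0:
                lengths.append(ig.total_isogloss_length(st, params, raster))
        assert all(b <= a * 1.02 for a, b in zip(lengths, lengths[1:]))


def test_masked_laplacian_zero_flux():
    """Constant fields have zero Laplacian under mask closure, and the
    stencil drops off-land neighbours."""
    mask = np.zeros((6, 6), bool)
    mask[2:5, 2:5] = True
    F = np.where(mask, 3.0, 99.0)
    lap = masked_laplacian(F, mask, 1.0, periodic=False)
    assert np.abs(lap[mask]).max() == 0.0
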