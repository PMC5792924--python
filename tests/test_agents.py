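"""Stochastic speaker lattice: occupancy, network, mixing, immigration."""

import numpy as np
import pytest

import isogloss as ig
from isogloss.agents import NETWORK_CUTOFF_SIGMAS
from isogloss.fixtures import FixtureSpec


def uniform_lattice(n=40, p=0.5, seed=0, m0=1.0):
    raster = ig.PopulationRaster(np.full((n, n), p), boundary_mode="periodic")
    return ig.sample_lattice(raster, seed, initial_memory=m0)


class TestSampling:
    def test_full_occupancy(self):
        lat = uniform_lattice(p=1.0)
        assert lat.n == 1600

    def test_binomial_count(self):
        raster = ig.PopulationRaster(np.full((200, 200), 0.1),
                                     boundary_mode="periodic")
        lat = ig.sample_lattice(raster, 3)
        mean, sd = 4000, np.sqrt(4000 * 0.9)
        assert abs(lat.n - mean) < 3 * sd

    def test_reproducible_and_probability_validated(self):
        raster = ig.PopulationRaster(np.full((30, 30), 0.4),
                                     boundary_mode="periodic")
        a = ig.sample_lattice(raster, 9)
        b = ig.sample_lattice(raster, 9)
        assert np.array_equal(a.occupied, b.occupied)
        with pytest.raises(ValueError):
            ig.sample_lattice(
                ig.PopulationRaster(np.full((5, 5), 1.2)), 0)

    def test_city_discs_denser_than_background(self):
        b = ig.make_fixture(FixtureSpec("stripe_two_city", {
            "size": 100, "radius_1": 25.0, "radius_2": 25.0,
            "center_1": (50.0, 25.0), "center_2": (50.0, 75.0)}))
        lat = ig.sample_lattice(b.raster, 1, initial_memory=b.initial_state.m)
        X, Y = b.raster.coords()
        d1 = (X - 50) ** 2 + (Y - 25) ** 2
        d2 = (X - 50) ** 2 + (Y - 75) ** 2
        in_city = (d1 <= 25.0**2) | (d2 <= 25.0**2)
        far = (d1 > 40.0**2) & (d2 > 40.0**2)
        assert lat.occupied[in_city].mean() > 3 * lat.occupied[far].mean()


class TestEmbeddedNetwork:
    def test_adjacency_symmetric_no_self_links(self):
        lat = uniform_lattice(30, 0.5, seed=2)
        ig.build_embedded_network(lat, 2.0, 2)
        A = lat.adjacency
        assert (A != A.T).nnz == 0
        assert A.diagonal().sum() == 0

    def test_neighbour_link_probability(self):
        """Adjacent sites link with probability e^(−1/18) ≈ 0.946 at σ=3."""
        lat = uniform_lattice(60, 1.0, seed=4)
        ig.build_embedded_network(lat, 3.0, 4)
        idx = -np.ones((60, 60), np.int64)
        idx[lat.occupied] = np.arange(lat.n)
        A = lat.adjacency.tolil()
        hits = sum(
            A[idx[i, j], idx[(i + 1) % 60, j]] != 0
            for i in range(60) for j in range(0, 60, 3)
        )
        n_pairs = 60 * 20
        p_hat = hits / n_pairs
        p = np.exp(-1 / 18)
        assert abs(p_hat - p) < 3 * np.sqrt(p * (1 - p) / n_pairs) + 1e-9

    def test_expected_degree_matches_gaussian_sum(self):
        """Mean degree ≈ occupancy × Σ_{Δ≠0} e^(−|Δ|²/2σ²) (≈ 2πσ²p for
        σ ≫ 1), checked over several seeds."""
        sigma, occ = 3.0, 0.1
        cut = NETWORK_CUTOFF_SIGMAS * sigma
        k = int(cut)
        dx = np.arange(-k, k + 1)
        D2 = dx[:, None] ** 2 + dx[None, :] ** 2
        gauss_sum = np.exp(-D2[D2 > 0] / (2 * sigma**2))[
            D2[D2 > 0] <= cut * cut
        ].sum()
        expect = occ * gauss_sum
        degs = []
        for seed in range(5):
            lat = uniform_lattice(60, occ, seed=seed)
            ig.build_embedded_network(lat, sigma, seed)
            degs.append(lat.adjacency.sum() / lat.n)
        assert np.mean(degs) == pytest.approx(expect, rel=0.05)


class TestAgentStep:
    def test_consensus_fixed_points(self):
        params = ig.ModelParams(sigma=2.0, beta=1.3)
        for m0 in (1.0, 0.5):
            lat = uniform_lattice(20, 0.6, seed=1, m0=m0)
            ig.build_embedded_network(lat, 2.0, 1)
            ig.step_agents(lat, params, 0.1)
            assert np.abs(lat.memory - m0).max() < 1e-14

    def test_relabel_symmetry(self):
        params = ig.ModelParams(sigma=2.0, beta=1.4, alpha=1.0)
        rng = np.random.default_rng(11)
        lat_a = uniform_lattice(20, 0.6, seed=5)
        ig.build_embedded_network(lat_a, 2.0, 5)
        m0 = rng.random(lat_a.n)
        lat_a.memory = m0.copy()
        lat_b = uniform_lattice(20, 0.6, seed=5)
        ig.build_embedded_network(lat_b, 2.0, 5)
        lat_b.memory = 1.0 - m0
        for _ in range(10):
            ig.step_agents(lat_a, params, 0.1)
            ig.step_agents(lat_b, params, 0.1)
        assert np.abs(lat_a.memory - (1.0 - lat_b.memory)).max() < 1e-13

    def test_isolated_speaker_relaxes_to_own_fixed_point(self):
        occ = np.zeros((9, 9), bool)
        occ[4, 4] = True
        lat = ig.AgentLattice(occ, np.array([0.7]))
        ig.build_embedded_network(lat, 1.0, 0)
        params = ig.ModelParams(sigma=1.0, beta=2.0)
        for _ in range(300):
            ig.step_agents(lat, params, 0.1)
        assert lat.memory[0] == pytest.approx(1.0, abs=1e-3)  # p(m)>m above 1/2


class TestMixing:
    def test_multiset_conserved_exactly(self):
        lat = uniform_lattice(25, 0.7, seed=6)
        ig.build_embedded_network(lat, 2.0, 6)
        rng = np.random.default_rng(13)
        lat.memory = rng.random(lat.n)
        before = np.sort(lat.memory.copy())
        for t in range(20):
            ig.apply_mixing(lat, ig.MixingSchedule(0.8), 0.5, rng, t)
        assert np.array_equal(np.sort(lat.memory), before)

    def test_zero_rate_identity(self):
        lat = uniform_lattice(10, 0.5, seed=0)
        before = lat.memory.copy()
        ig.apply_mixing(lat, ig.MixingSchedule(0.0), 0.1,
                        np.random.default_rng(0))
        assert np.array_equal(lat.memory, before)

    def test_needs_two_sites(self):
        occ = np.zeros((4, 4), bool)
        occ[0, 0] = True
        lat = ig.AgentLattice(occ, np.array([0.5]))
        with pytest.raises(ValueError):
            ig.apply_mixing(lat, ig.MixingSchedule(0.5), 0.1,
                            np.random.default_rng(0))

    def test_time_ramp(self):
        sched = ig.MixingSchedule(lambda t: 5e-4 * t)
        assert sched.rate(100.0) == pytest.approx(0.05)


class TestImmigration:
    def test_zero_rate_identity(self):
        lat = uniform_lattice(10, 0.5)
        before = lat.memory.copy()
        ig.apply_immigration(lat, ig.ImmigrationConfig(0.0), 0.1,
                             np.random.default_rng(0))
        assert np.array_equal(lat.memory, before)

    def test_replacement_fraction(self):
        lat = uniform_lattice(60, 1.0)
        nu, dt = 0.2, 0.5
        ig.apply_immigration(lat, ig.ImmigrationConfig(nu), dt,
                             np.random.default_rng(3))
        frac = (lat.memory == 0.0).mean()
        p = nu * dt
        assert abs(frac - p) < 4 * np.sqrt(p * (1 - p) / lat.n)

    def test_extinction_above_threshold_survival_below(self):
        """Well-connected lattice: the resident variant survives at ν < ν_c
        and is wiped out at ν > ν_c (3 seeds each)."""
        beta = 1.5
        nu_c = ig.critical_immigration_rate(beta).nu_c
        params = ig.ModelParams(sigma=50.0, beta=beta)
        for nu, survives in ((0.6 * nu_c, True), (1.6 * nu_c, False)):
            for seed in range(3):
                lat = uniform_lattice(30, 0.8, seed=seed)
                ig.build_embedded_network(lat, 50.0, seed)
                rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
                cfg = ig.ImmigrationConfig(nu)
                for _ in range(600):
                    ig.step_agents(lat, params, 0.1)
                    ig.apply_immigration(lat, cfg, 0.1, rng)
                mean = lat.memory.mean()
                if survives:
                    assert mean > 0.5
                else:
                    assert mean < 0.2


class TestMeanField:
    @pytest.mark.parametrize(
        "m, beta, nu, expected",
        [
            (0.0, 1.5, 0.3, 0.0),
            (0.5, 1.5, 0.0, 0.0),
            (0.75, 1.5, 0.1,
             0.75**1.5 / (0.75**1.5 + 0.25**1.5) - 1.1 * 0.75),
        ],
    )
    def test_rhs_values(self, m, beta, nu, expected):
        assert ig.mean_field_rhs(m, beta, nu) == pytest.approx(expected, abs=1e-12)

    def test_critical_rate_values(self):
        res = ig.critical_immigration_rate(1.5)
        assert res.nu_c == pytest.approx(0.118, abs=5e-4)
        assert 0.5 < res.m_tan < 1.0
        assert ig.critical_immigration_rate(2.0).nu_c > res.nu_c
        assert ig.critical_immigration_rate(1.001).nu_c < 2e-3
        low = ig.critical_immigration_rate(1.0)
        assert low.nu_c == 0.0 and "no bistability" in low.note

    def test_fixed_point_structure(self):
        below = ig.solve_mean_field(1.5, 0.05, T=30.0)
        assert below.m_star is not None and below.m_star > 0.5
        assert below.m[-1] == pytest.approx(below.m_star, abs=1e-3)
        for m, _ in below.fixed_points:
            assert abs(ig.mean_field_rhs(m, 1.5, 0.05)) < 1e-10
        above = ig.solve_mean_field(1.5, 0.15, T=60.0)
        assert above.m_star is None
        assert above.m[-1] < 0.05

    def test_interleaved_updates_stay_bounded(self):
        params = ig.ModelParams(sigma=2.0, beta=1.6, alpha=1.1)
        lat = uniform_lattice(20, 0.6, seed=8)
        ig.build_embedded_network(lat, 2.0, 8)
        rng = np.random.default_rng(21)
        for t in range(50):
            ig.step_agents(lat, params, 0.5)
            ig.apply_mixing(lat, ig.MixingSchedule(0.3), 0.5, rng, t)
            ig.apply_immigration(lat, ig.ImmigrationConfig(0.2), 0.5, rng)
            assert lat.memory.min() >= 0.0 and lat.memory.max() <= 1.0


class TestExperiments:
    def test_shrinking_minority_domain(self):
        """Unequal cities at high conformity under constant mixing: the
        small-city domain shrinks monotonically (smoothed) to zero
        (reduced-size analogue of the two-city shrinkage experiment)."""
        b = ig.make_fixture(FixtureSpec("shrink_two_city", {
            "size": 120, "radius_1": 30.0, "radius_2": 15.0,
            "center_1": (60.0, 30.0), "center_2": (60.0, 90.0)}))
        for seed in (5, 6):
            lat = ig.sample_lattice(b.raster, seed,
                                    initial_memory=b.initial_state.m)
            ig.build_embedded_network(lat, b.params.sigma, seed)
            res = ig.run_shrink_experiment(lat, b.params, epsilon=0.1,
                                           T=80.0, seed=seed)
            mf = res["minority_fraction"]
            smooth = np.convolve(mf, np.ones(5) / 5, mode="valid")
            assert np.all(np.diff(smooth) < 0.02)  # non-increasing after noise
            assert mf[-1] == 0.0

    def test_mixing_ramp_destroys_minority(self):
        """Slowly ramping the mixing rate destroys the minority variant from
        within (reduced-size analogue of the stripe experiment)."""
        b = ig.make_fixture(FixtureSpec("stripe_two_city", {
            "size": 200, "radius_1": 50.0, "radius_2": 50.0,
            "center_1": (100.0, 50.0), "center_2": (100.0, 150.0)}))
        lat = ig.sample_lattice(b.raster, 7, initial_memory=b.initial_state.m)
        ig.build_embedded_network(lat, b.params.sigma, 7)
        res = ig.run_mixing_ramp(lat, b.params, ramp_rate=5e-4,
                                 eps_max=0.16, seed=7)
        eps = res["epsilon_at_destruction"]
        assert eps is not None and 0.0 < eps <= 0.15
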