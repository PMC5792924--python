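"""Gravity-model reduction: coupled ODEs for per-city memories.

When interactions between metropolitan cores dominate, the field model
reduces to N coupled ODEs ṁ_i = f̄_i − m_i with

    f̄_i = (P_i·f_i + Σ_{j≠i} P_j f_j / (1 + r_ij²/γ²)) / N_i,
    N_i  = P_i + Σ_{j≠i} P_j / (1 + r_ij²/γ²),

the long-range Lorentzian weights realizing the classical gravity law of
hierarchical diffusion (influence ∝ populations over squared distance).
The reduction becomes exact as σ → 0 and γ → ∞.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad

from .core import ModelParams, conformity_map

__all__ = [
    "CityNetwork",
    "CityTrajectory",
    "network_weights",
    "simulate_city_odes",
    "core_interaction_fraction",
    "core_population",
]


@dataclass
class CityNetwork:
    """Point cities with core populations, pairwise distances and parameters.

    positions: (N, 2) city-centre coordinates.
    populations: core populations P_i > 0.
    params: model parameters (γ, β, α used here).
    core_factor: core-radius multiple c (core radius = c·R_i).
    core_radii: optional per-city core radii (needed for the
        own-city interaction quadrature).
    """

    positions: np.ndarray
    populations: np.ndarray
    params: ModelParams
    core_factor: float = 1.0
    core_radii: np.ndarray | None = None
    distances: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.populations = np.atleast_1d(np.asarray(self.populations, dtype=float))
        if len(self.positions) != len(self.populations):
            raise ValueError("positions and populations length mismatch")
        if np.any(self.populations <= 0):
            raise ValueError("populations must be > 0")
        d = self.positions[:, None, :] - self.positions[None, :, :]
        self.distances = np.hypot(d[..., 0], d[..., 1])
        n = len(self.populations)
        off = ~np.eye(n, dtype=bool)
        if np.any(self.distances[off] == 0):
            raise ValueError("coincident cities (zero pairwise distance)")

    def __len__(self) -> int:
        return len(self.populations)

    @property
    def normalizers(self) -> np.ndarray:
        """N_i = P_i + Σ_{j≠i} P_j/(1 + r_ij²/γ²)."""
        g2 = self.params.gamma**2
        lor = 1.0 / (1.0 + self.distances**2 / g2)
        np.fill_diagonal(lor, 1.0)
        return (lor * self.populations[None, :]).sum(axis=1)


def network_weights(net: CityNetwork) -> np.ndarray:
    """Row-stochastic gravity weight matrix.

    W_ii = P_i/N_i and W_ij = (P_j/(1 + r_ij²/γ²))/N_i; each row sums to 1.
    """
    g2 = net.params.gamma**2
    lor = 1.0 / (1.0 + net.distances**2 / g2)
    np.fill_diagonal(lor, 1.0)
    W = lor * net.populations[None, :]
    return W / W.sum(axis=1, keepdims=True)


@dataclass
class CityTrajectory:
    times: np.ndarray
    m: np.ndarray  # (n_times, n_cities)
    f: np.ndarray

    def crossing_time(self, i: int, level: float = 0.5) -> float | None:
        """First time city i's frequency crosses ``level`` upward, or None."""
        above = self.f[:, i] >= level
        if not above.any() or above[0]:
            return float(self.times[0]) if above.any() else None
        k = int(np.argmax(above))
        f0, f1 = self.f[k - 1, i], self.f[k, i]
        t0, t1 = self.times[k - 1], self.times[k]
        return float(t0 + (level - f0) / (f1 - f0) * (t1 - t0))


def simulate_city_odes(
    net: CityNetwork,
    m0: np.ndarray,
    T: float,
    dt: float = 0.01,
    store_every: int = 10,
) -> CityTrajectory:
    """Integrate ṁ_i = Σ_j W_ij p(m_j) − m_i with classical RK4.

    Because W is row stochastic and p maps [0, 1] to itself, m stays in
    [0, 1].  ``store_every`` thins the stored trajectory.
    """
    if dt > 1:
        raise ValueError("dt must be <= 1")
    m = np.asarray(m0, dtype=float).copy()
    if m.shape != (len(net),) or np.any(m < 0) or np.any(m > 1):
        raise ValueError("m0 must be per-city memories in [0, 1]")
    W = network_weights(net)
    p = net.params

    def rhs(mm: np.ndarray) -> np.ndarray:
        return W @ conformity_map(np.clip(mm, 0, 1), p) - mm

    nsteps = int(round(T / dt))
    times = [0.0]
    traj = [m.copy()]
    for k in range(1, nsteps + 1):
        k1 = rhs(m)
        k2 = rhs(m + 0.5 * dt * k1)
        k3 = rhs(m + 0.5 * dt * k2)
        k4 = rhs(m + dt * k3)
        m = np.clip(m + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4), 0.0, 1.0)
        if k % store_every == 0 or k == nsteps:
            times.append(k * dt)
            traj.append(m.copy())
    marr = np.array(traj)
    return CityTrajectory(np.array(times), marr, conformity_map(marr, p))


def core_population(omega: float, radius: float, core_factor: float = 1.0) -> float:
    """Population of a Gaussian city's metropolitan core disc.

    ∫₀^{cR} ω e^(−r²/R²) 2πr dr = πωR²(1 − e^(−c²)).
    """
    return float(np.pi * omega * radius**2 * (1.0 - np.exp(-(core_factor**2))))


def core_interaction_fraction(
    i: int,
    net: CityNetwork,
    sigma: float,
    density_profile=None,
) -> float:
    """Fraction of a central speaker's interactions with their own city.

    Numeric quadrature of the two-regime integral: Lorentzian (scale γ)
    weighting inside the metropolitan core disc of radius c·R_i, Gaussian
    (scale σ) weighting outside, both against the city's radial density
    profile, normalized by N_i.  When σ ≪ cR_i ≪ γ this tends to P_i/N_i,
    and to 1 for an isolated city.

    density_profile: callable r ↦ ρ_i(r); defaults to the Gaussian profile
    with peak density P_i/(π R_i²(1−e^(−c²))) matching the stored core
    population.
    """
    if net.core_radii is None:
        raise ValueError("network lacks core_radii")
    cR = net.core_factor * net.core_radii[i]
    if sigma >= cR:
        import warnings

        warnings.warn(
            "sigma >= core radius: outside the approximation regime sigma < cR",
            stacklevel=2,
        )
    if density_profile is None:
        R = net.core_radii[i]
        peak = net.populations[i] / (
            np.pi * R**2 * (1.0 - np.exp(-(net.core_factor**2)))
        )
        density_profile = lambda r: peak * np.exp(-(r**2) / R**2)
    g2 = net.params.gamma**2
    inner, _ = quad(lambda r: r * density_profile(r) / (1 + r**2 / g2), 0, cR)
    outer, _ = quad(
        lambda r: r * np.exp(-(r**2) / (2 * sigma**2)) * density_profile(r),
        cR,
        cR + 12 * sigma,
    )
    own = 2 * np.pi * (inner + outer)
    others = (
        net.populations / (1.0 + net.distances[i] ** 2 / g2)
    ).sum() - net.populations[i]
    return float(own / (own + others))
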