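"""Stochastic per-speaker model on a lattice with mixing and immigration.

Speakers occupy lattice sites independently with probability ρ_xy (the
capped city density), interact over an embedded random network whose link
probability decays as a Gaussian of separation (scale σ, periodic
boundaries), and relax their memories toward the mean spoken frequency of
their network neighbours.  Two stochastic perturbations model population
mobility:

* mixing — at rate ϵ a speaker swaps memories with a partner chosen
  uniformly at random among occupied sites (a symmetric exchange, so the
  multiset of memory values is conserved);
* immigration — at rate ν a speaker is replaced by an outsider with a
  fixed incoming memory (0 = a pure B speaker).

The mean-field approximation of the immigration dynamics is the scalar
ODE ṁ = m^β/(m^β + (1−m)^β) − (1+ν)m, which loses its nonzero stable
fixed point m* > 1/2 at a critical rate ν_c(β) — above it the resident
variant goes extinct.  ν_c(1.5) ≈ 0.118.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import scipy.sparse as sp
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, minimize_scalar

from .core import ModelParams, PopulationRaster, conformity_map

__all__ = [
    "AgentLattice",
    "MixingSchedule",
    "ImmigrationConfig",
    "MeanFieldResult",
    "CriticalRate",
    "sample_lattice",
    "build_embedded_network",
    "step_agents",
    "apply_mixing",
    "apply_immigration",
    "mean_field_rhs",
    "critical_immigration_rate",
    "solve_mean_field",
    "run_mixing_ramp",
    "run_shrink_experiment",
]

NETWORK_CUTOFF_SIGMAS = 6.0  # link prob beyond 6 sigma < 2e-8


@dataclass
class AgentLattice:
    """Occupied sites with per-speaker memories and a contact network.

    ``occupied`` is a boolean grid; ``sites`` the (n, 2) integer coordinates
    of occupied sites in row-major order; ``memory`` the per-speaker memory
    values aligned with ``sites``; ``adjacency`` a symmetric boolean CSR
    matrix with zero diagonal (set by :func:`build_embedded_network`).
    Boundaries are periodic.
    """

    occupied: np.ndarray
    memory: np.ndarray
    sites: np.ndarray = field(init=False)
    adjacency: sp.csr_matrix | None = None

    def __post_init__(self) -> None:
        self.occupied = np.asarray(self.occupied, dtype=bool)
        self.sites = np.argwhere(self.occupied)
        self.memory = np.asarray(self.memory, dtype=float)
        if self.memory.shape != (len(self.sites),):
            raise ValueError("memory must have one value per occupied site")

    @property
    def n(self) -> int:
        return len(self.sites)

    def memory_grid(self) -> np.ndarray:
        g = np.full(self.occupied.shape, np.nan)
        g[self.occupied] = self.memory
        return g

    def preference_grid(self, params: ModelParams) -> np.ndarray:
        """Boolean grid: True where the occupant prefers variant A
        (p(m) ≥ 1/2); False elsewhere (including empty sites)."""
        g = np.zeros(self.occupied.shape, dtype=bool)
        g[self.occupied] = conformity_map(np.clip(self.memory, 0, 1), params) >= 0.5
        return g


@dataclass(frozen=True)
class MixingSchedule:
    """Mixing rate ϵ, constant or a time ramp ϵ(t)."""

    epsilon: float | Callable[[float], float] = 0.0

    def rate(self, t: float) -> float:
        e = self.epsilon(t) if callable(self.epsilon) else self.epsilon
        if e < 0:
            raise ValueError("mixing rate must be >= 0")
        return float(e)


@dataclass(frozen=True)
class ImmigrationConfig:
    nu: float = 0.0
    incoming_memory: float = 0.0

    def __post_init__(self) -> None:
        if self.nu < 0:
            raise ValueError("nu must be >= 0")
        if not 0 <= self.incoming_memory <= 1:
            raise ValueError("incoming memory must lie in [0, 1]")


def sample_lattice(
    raster: PopulationRaster, seed: int, initial_memory: float | np.ndarray = 1.0
) -> AgentLattice:
    """Occupy each site independently with probability ρ_xy.

    ρ must lie in [0, 1] (use the capped city-density mode).  Reproducible
    per seed.  ``initial_memory`` may be a scalar or a grid to sample at
    occupied sites.
    """
    rho = raster.values
    if np.any(rho > 1):
        raise ValueError("occupation probabilities must be <= 1 (use capped density)")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x0CC]))
    occ = rng.random(rho.shape) < rho
    if np.isscalar(initial_memory):
        mem = np.full(int(occ.sum()), float(initial_memory))
    else:
        mem = np.asarray(initial_memory, dtype=float)[occ]
    return AgentLattice(occ, mem)


def build_embedded_network(lattice: AgentLattice, sigma: float, seed: int) -> None:
    """Link each occupied pair with probability exp(−Δ²/2σ²), periodic.

    Pairs farther than 6σ (periodic displacement) are skipped.  The
    adjacency is stored on the lattice as a symmetric CSR matrix.  The
    construction sweeps half the displacement stencil and draws one
    Bernoulli per candidate pair, vectorized over the grid.
    """
    occ = lattice.occupied
    nx, ny = occ.shape
    idx = np.full(occ.shape, -1, dtype=np.int64)
    idx[occ] = np.arange(lattice.n)
    cut = NETWORK_CUTOFF_SIGMAS * sigma
    # each unordered pair once: the stencil may not exceed half the
    # periodic domain, beyond which displacements alias to earlier ones
    kmax = min(int(np.floor(cut)), (min(nx, ny) - 1) // 2)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x4E7]))
    rows, cols = [], []
    for dx in range(0, kmax + 1):
        for dy in range(-kmax, kmax + 1):
            if dx == 0 and dy <= 0:
                continue  # half stencil: each unordered pair once
            d2 = dx * dx + dy * dy
            if d2 > cut * cut:
                continue
            p = np.exp(-d2 / (2.0 * sigma**2))
            nbr = np.roll(np.roll(occ, -dx, axis=0), -dy, axis=1)
            both = occ & nbr
            if not both.any():
                continue
            cand = np.argwhere(both)
            keep = rng.random(len(cand)) < p
            cand = cand[keep]
            if len(cand) == 0:
                continue
            a = idx[cand[:, 0], cand[:, 1]]
            b = idx[(cand[:, 0] + dx) % nx, (cand[:, 1] + dy) % ny]
            rows.append(a)
            cols.append(b)
    if rows:
        r = np.concatenate(rows)
        c = np.concatenate(cols)
    else:
        r = c = np.empty(0, dtype=np.int64)
    n = lattice.n
    A = sp.coo_matrix(
        (np.ones(2 * len(r), dtype=np.int8), (np.r_[r, c], np.r_[c, r])),
        shape=(n, n),
    ).tocsr()
    lattice.adjacency = A


def step_agents(lattice: AgentLattice, params: ModelParams, dt: float = 0.1) -> None:
    """Deterministic memory relaxation toward the neighbour-mean frequency.

    m_xy ← m_xy + dt·(mean of p(m) over network neighbours − m_xy).
    Isolated speakers (no neighbours) relax toward their own p(m) — the
    self-consistent fixed point of a speaker who hears only themselves.
    Updates in place.
    """
    if dt > 1:
        raise ValueError("dt must be <= 1")
    if lattice.adjacency is None:
        raise ValueError("lattice has no contact network; call build_embedded_network")
    f = conformity_map(np.clip(lattice.memory, 0, 1), params)
    deg = np.asarray(lattice.adjacency.sum(axis=1)).ravel()
    target = np.where(deg > 0, lattice.adjacency @ f / np.maximum(deg, 1), f)
    lattice.memory = np.clip(
        lattice.memory + dt * (target - lattice.memory), 0.0, 1.0
    )


def apply_mixing(
    lattice: AgentLattice,
    schedule: MixingSchedule,
    dt: float,
    rng: np.random.Generator,
    t: float = 0.0,
) -> None:
    """Memory exchanges: each speaker is selected w.p. ϵ(t)·dt and swaps
    memories with a partner drawn uniformly from the other occupied sites.

    Swaps are applied sequentially as symmetric exchanges, so the multiset
    of memory values is exactly conserved.
    """
    eps = schedule.rate(t)
    if eps == 0.0:
        return
    if eps * dt > 1:
        raise ValueError("epsilon*dt must be <= 1")
    n = lattice.n
    if n < 2:
        raise ValueError("mixing needs at least two occupied sites")
    sel = np.nonzero(rng.random(n) < eps * dt)[0]
    if len(sel) == 0:
        return
    partners = rng.integers(0, n - 1, size=len(sel))
    partners[partners >= sel] += 1  # uniform over sites excluding self
    mem = lattice.memory
    for s, q in zip(sel, partners):
        mem[s], mem[q] = mem[q], mem[s]


def apply_immigration(
    lattice: AgentLattice,
    config: ImmigrationConfig,
    dt: float,
    rng: np.random.Generator,
) -> None:
    """Each speaker is replaced w.p. ν·dt by an immigrant with the
    configured incoming memory."""
    if config.nu == 0.0:
        return
    if config.nu * dt > 1:
        raise ValueError("nu*dt must be <= 1")
    hit = rng.random(lattice.n) < config.nu * dt
    lattice.memory[hit] = config.incoming_memory


def mean_field_rhs(m, beta: float, nu: float):
    """ṁ = m^β/(m^β + (1−m)^β) − (1 + ν)m, the mean-field immigration ODE."""
    m = np.asarray(m, dtype=float)
    if np.any(m < 0) or np.any(m > 1):
        raise ValueError("m must lie in [0, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        mb = m**beta
        g = np.where(m > 0, mb / np.where(m > 0, mb + (1 - m) ** beta, 1.0), 0.0)
    out = g - (1.0 + nu) * m
    return float(out) if np.ndim(m) == 0 else out


@dataclass
class CriticalRate:
    nu_c: float
    m_tan: float
    note: str = ""


def critical_immigration_rate(beta: float, tol: float = 1e-9) -> CriticalRate:
    """Largest ν for which the mean-field ODE keeps a root in (0, 1).

    At the threshold the nonzero root is repeated (tangency), so
    ν_c = max_{m∈(0,1)} g(m)/m − 1 with g the conformity sigmoid at α = 1.
    β ≤ 1 has no bistability: returns 0 with a note.
    """
    if beta <= 1:
        return CriticalRate(0.0, 0.0, "beta <= 1: no bistability, nu_c = 0")

    def neg(m: float) -> float:
        g = m**beta / (m**beta + (1 - m) ** beta)
        return -(g / m - 1.0)

    res = minimize_scalar(
        neg, bounds=(1e-9, 1 - 1e-9), method="bounded", options={"xatol": tol}
    )
    return CriticalRate(float(-res.fun), float(res.x))


@dataclass
class MeanFieldResult:
    times: np.ndarray
    m: np.ndarray
    fixed_points: list[tuple[float, bool]]  # (m*, stable)
    m_star: float | None
    nu_c: float


def solve_mean_field(
    beta: float, nu: float, m0: float = 1.0, T: float = 50.0
) -> MeanFieldResult:
    """Solve the mean-field ODE and classify its fixed points."""
    sol = solve_ivp(
        lambda t, y: [mean_field_rhs(min(max(y[0], 0.0), 1.0), beta, nu)],
        (0.0, T),
        [m0],
        dense_output=False,
        max_step=0.1,
        rtol=1e-8,
        atol=1e-10,
    )
    # locate fixed points by sign scanning
    grid = np.linspace(0.0, 1.0, 2001)
    vals = mean_field_rhs(grid, beta, nu)
    fps: list[tuple[float, bool]] = []
    if abs(vals[0]) < 1e-12:
        fps.append((0.0, vals[1] < 0))
    for i in range(1, len(grid) - 1):
        if vals[i] == 0.0 or vals[i] * vals[i + 1] < 0:
            root = brentq(lambda m: mean_field_rhs(m, beta, nu), grid[i], grid[i + 1])
            h = 1e-7
            lo = max(root - h, 0.0)
            hi = min(root + h, 1.0)
            stable = mean_field_rhs(lo, beta, nu) > 0 > mean_field_rhs(hi, beta, nu)
            fps.append((float(root), bool(stable)))
    stars = [m for m, ok in fps if ok and m > 0.5]
    return MeanFieldResult(
        sol.t,
        sol.y[0],
        fps,
        max(stars) if stars else None,
        critical_immigration_rate(beta).nu_c,
    )


def _minority_fraction(lattice: AgentLattice, params: ModelParams) -> float:
    pref = conformity_map(np.clip(lattice.memory, 0, 1), params) >= 0.5
    return float(min(pref.mean(), 1.0 - pref.mean()))


def run_mixing_ramp(
    lattice: AgentLattice,
    params: ModelParams,
    *,
    ramp_rate: float = 5e-4,
    dt: float = 0.1,
    eps_max: float = 0.15,
    seed: int = 0,
    record_every: int = 10,
) -> dict:
    """Spontaneous internal destruction: ramp ϵ(t) = ramp_rate·t and track
    the minority variant.  Returns the time series and the ϵ at which the
    minority share first drops below 1%, or None if it survives."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x3A]))
    sched = MixingSchedule(lambda t: ramp_rate * t)
    t = 0.0
    times, eps_list, minority = [], [], []
    eps_destroyed = None
    k = 0
    while ramp_rate * t <= eps_max:
        step_agents(lattice, params, dt)
        apply_mixing(lattice, sched, dt, rng, t)
        t += dt
        k += 1
        if k % record_every == 0:
            frac = _minority_fraction(lattice, params)
            times.append(t)
            eps_list.append(sched.rate(t))
            minority.append(frac)
            if eps_destroyed is None and frac < 0.01:
                eps_destroyed = sched.rate(t)
                break
    return {
        "t": np.array(times),
        "epsilon": np.array(eps_list),
        "minority_fraction": np.array(minority),
        "epsilon_at_destruction": eps_destroyed,
    }


def run_shrink_experiment(
    lattice: AgentLattice,
    params: ModelParams,
    *,
    epsilon: float = 0.1,
    dt: float = 0.1,
    T: float = 60.0,
    seed: int = 0,
    record_every: int = 10,
) -> dict:
    """Destruction by isogloss migration: constant mixing at rate ϵ;
    records the minority-domain fraction over time."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5B]))
    sched = MixingSchedule(epsilon)
    times, minority = [], []
    nsteps = int(round(T / dt))
    for k in range(1, nsteps + 1):
        step_agents(lattice, params, dt)
        apply_mixing(lattice, sched, dt, rng)
        if k % record_every == 0:
            times.append(k * dt)
            minority.append(_minority_fraction(lattice, params))
    return {"t": np.array(times), "minority_fraction": np.array(minority)}
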