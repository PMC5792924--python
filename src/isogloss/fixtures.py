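"""Seeded synthetic geographies for the standard model experiments.

Each fixture bundles a complete, reproducible configuration — population
raster, model parameters, metropolitan field or city network, initial
memory field, and any stochastic-experiment settings — for the canonical
scenarios studied with this model:

* ``four_city``        — hierarchical diffusion: a large source city, two
                         nearby small satellites and a distant large city
                         on a 200×200 landscape.
* ``line20``           — a line of 20 equally spaced cities (gravity ODE).
* ``two_lobes``        — a two-lobed land mass with one city per lobe
                         (isogloss pinned at the boundary indentations).
* ``stripe_two_city``  — the 400×400 periodic two-city lattice in a stripe
                         state (mixing-ramp internal destruction).
* ``shrink_two_city``  — unequal cities, high conformity (domain shrinkage
                         under constant mixing).
* ``island_sectors``   — a disc island split into two angular domains with
                         the sector-bound parameters attached.
* ``archipelago``      — a randomized multi-island landscape for
                         regionalization tests.

All geometry choices not fixed by the scenario definitions (e.g. the four
city positions) are recorded in the bundle's serialized ``config``.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield
from typing import Any

import numpy as np

from .cities import CityNetwork, core_population
from .core import (
    CitySpec,
    MetropolitanField,
    ModelParams,
    PopulationRaster,
    build_city_density,
    metropolitan_field,
)
from .dynamics import FieldState
from .theory import SectorBound

__all__ = ["FixtureSpec", "FixtureBundle", "make_fixture", "available_fixtures"]

SQRT2 = float(np.sqrt(2.0))


@dataclass(frozen=True)
class FixtureSpec:
    name: str
    overrides: dict[str, Any] = dfield(default_factory=dict)
    seed: int = 0


@dataclass
class FixtureBundle:
    name: str
    params: ModelParams
    raster: PopulationRaster | None = None
    metropolitan: MetropolitanField | None = None
    network: CityNetwork | None = None
    initial_state: FieldState | None = None
    initial_city_memory: np.ndarray | None = None
    cities: list[CitySpec] = dfield(default_factory=list)
    sector: SectorBound | None = None
    agent: dict[str, Any] = dfield(default_factory=dict)
    config: dict[str, Any] = dfield(default_factory=dict)


def _merge(defaults: dict[str, Any], overrides: dict[str, Any]) -> dict[str, Any]:
    unknown = set(overrides) - set(defaults)
    if unknown:
        raise ValueError(f"unknown override keys {sorted(unknown)}")
    out = dict(defaults)
    out.update(overrides)
    return out


def _four_city(spec: FixtureSpec) -> FixtureBundle:
    cfg = _merge(
        {
            "size": 200,
            "cell_size": 1.0,
            "omega_large": 10.0,
            "radius_large": 10.0,
            "omega_small": 5.0,
            "radius_small": 5.0,
            "hinterland_factor": 5.0,  # background radius is 5x the city radius
            "sigma": 2 * SQRT2,
            "gamma": 25.0,
            "beta": 1.1,
            "alpha": 1.0,
            "source": (32.0, 32.0),
            "satellites": ((62.0, 47.0), (45.0, 64.0)),
            "distant": (172.0, 172.0),
            "core_factor": 1.0,
            "initial_radius": 28.0,
        },
        spec.overrides,
    )
    params = ModelParams(
        sigma=cfg["sigma"], gamma=cfg["gamma"], beta=cfg["beta"], alpha=cfg["alpha"]
    )
    h = cfg["hinterland_factor"]
    cities = [
        CitySpec(cfg["source"], cfg["omega_large"], cfg["radius_large"],
                 h * cfg["radius_large"]),
        CitySpec(cfg["satellites"][0], cfg["omega_small"], cfg["radius_small"],
                 h * cfg["radius_small"]),
        CitySpec(cfg["satellites"][1], cfg["omega_small"], cfg["radius_small"],
                 h * cfg["radius_small"]),
        CitySpec(cfg["distant"], cfg["omega_large"], cfg["radius_large"],
                 h * cfg["radius_large"]),
    ]
    n = int(cfg["size"] / cfg["cell_size"]) + 1
    raster = build_city_density(
        cities, shape=(n, n), cell_size=cfg["cell_size"], mode="with_hinterland",
        boundary_mode="closed",
    )
    M = metropolitan_field(raster, cities, cfg["core_factor"])
    X, Y = raster.coords()
    sx, sy = cfg["source"]
    m0 = ((X - sx) ** 2 + (Y - sy) ** 2 <= cfg["initial_radius"] ** 2).astype(float)
    pops = np.array(
        [core_population(c.omega, c.radius, cfg["core_factor"]) for c in cities]
    )
    net = CityNetwork(
        positions=np.array([c.center for c in cities]),
        populations=pops,
        params=params,
        core_factor=cfg["core_factor"],
        core_radii=np.array([c.radius for c in cities]),
    )
    m0_net = np.zeros(4)
    m0_net[0] = 1.0
    return FixtureBundle(
        "four_city", params, raster=raster, metropolitan=M, network=net,
        initial_state=FieldState(m0), initial_city_memory=m0_net,
        cities=cities, config=cfg,
    )


def _line20(spec: FixtureSpec) -> FixtureBundle:
    cfg = _merge(
        {
            "n_cities": 20,
            "spacing": 50.0,
            "gamma": 25.0,
            "beta": 1.1,
            "alpha": 1.0,
            "P1": 30.0,
            "P_rest": 5.0,
        },
        spec.overrides,
    )
    params = ModelParams(sigma=1.0, gamma=cfg["gamma"], beta=cfg["beta"],
                         alpha=cfg["alpha"])
    n = int(cfg["n_cities"])
    pos = np.column_stack([cfg["spacing"] * np.arange(n), np.zeros(n)])
    pops = np.full(n, cfg["P_rest"])
    pops[0] = cfg["P1"]
    net = CityNetwork(positions=pos, populations=pops, params=params)
    m0 = np.zeros(n)
    m0[0] = 1.0
    return FixtureBundle("line20", params, network=net,
                         initial_city_memory=m0, config=cfg)


def _two_lobes(spec: FixtureSpec) -> FixtureBundle:
    cfg = _merge(
        {
            "lobe_diameter": 80.0,
            "lobe_gap": 76.0,  # centre separation < diameter: overlapping lobes
            "omega": 10.0,
            "radius": 10.0,
            "background": 1.0,
            "sigma": 4.0,
            "beta": 1.1,
            "alpha": 1.0,
            "cell_size": 2.0,  # sigma/2: resolves the front, stable at dt=0.1
        },
        spec.overrides,
    )
    params = ModelParams(sigma=cfg["sigma"], gamma=25.0, beta=cfg["beta"],
                         alpha=cfg["alpha"])
    rad = cfg["lobe_diameter"] / 2.0
    sep = cfg["lobe_gap"]
    pad = 4.0
    Lx = sep + 2 * rad + 2 * pad
    Ly = 2 * rad + 2 * pad
    cell = cfg["cell_size"]
    nx, ny = int(Lx / cell) + 1, int(Ly / cell) + 1
    x = cell * np.arange(nx)
    y = cell * np.arange(ny)
    X, Y = np.meshgrid(x, y, indexing="ij")
    c1 = (pad + rad, pad + rad)
    c2 = (pad + rad + sep, pad + rad)
    mask = ((X - c1[0]) ** 2 + (Y - c1[1]) ** 2 <= rad**2) | (
        (X - c2[0]) ** 2 + (Y - c2[1]) ** 2 <= rad**2
    )
    cities = [
        CitySpec(c1, cfg["omega"], cfg["radius"]),
        CitySpec(c2, cfg["omega"], cfg["radius"]),
    ]
    raster = build_city_density(
        cities, shape=(nx, ny), cell_size=cell, mode="bare_gaussian",
        background=cfg["background"], land_mask=mask, boundary_mode="closed",
    )
    mid = (c1[0] + c2[0]) / 2.0
    m0 = np.where(X < mid, 1.0, 0.0)
    return FixtureBundle(
        "two_lobes", params, raster=raster, cities=cities,
        initial_state=FieldState(np.where(mask, m0, 0.0)), config=cfg,
    )


def _stripe_two_city(spec: FixtureSpec) -> FixtureBundle:
    cfg = _merge(
        {
            "size": 400,
            "radius_1": 100.0,
            "radius_2": 100.0,
            "center_1": (200.0, 100.0),
            "center_2": (200.0, 300.0),
            "rho0": 0.1,
            "sigma": 3.0,
            "beta": 1.1,
            "alpha": 1.0,
            "ramp_rate": 5e-4,
        },
        spec.overrides,
    )
    params = ModelParams(sigma=cfg["sigma"], gamma=25.0, beta=cfg["beta"],
                         alpha=cfg["alpha"])
    n = int(cfg["size"])
    cities = [
        CitySpec(cfg["center_1"], 1.0, cfg["radius_1"]),
        CitySpec(cfg["center_2"], 1.0, cfg["radius_2"]),
    ]
    raster = build_city_density(
        cities, shape=(n, n), cell_size=1.0, mode="capped",
        background=cfg["rho0"], boundary_mode="periodic",
    )
    # two equal stripes, each city centred in its own stripe
    X, Y = raster.coords()
    m0 = np.where(Y < cfg["size"] / 2.0, 1.0, 0.0)
    return FixtureBundle(
        "stripe_two_city", params, raster=raster, cities=cities,
        initial_state=FieldState(m0),
        agent={"ramp_rate": cfg["ramp_rate"], "seed": spec.seed},
        config=cfg,
    )


def _shrink_two_city(spec: FixtureSpec) -> FixtureBundle:
    over = dict(spec.overrides)
    over.setdefault("radius_2", 50.0)
    over.setdefault("beta", 2.0)
    inner = FixtureSpec("stripe_two_city", over, spec.seed)
    b = _stripe_two_city(inner)
    b.name = "shrink_two_city"
    b.agent = {"epsilon": 0.1, "seed": spec.seed}
    b.config = dict(b.config)
    b.config["epsilon"] = 0.1
    return b


def _island_sectors(spec: FixtureSpec) -> FixtureBundle:
    cfg = _merge(
        {
            "island_radius": 50.0,
            "theta_A": float(np.pi / 2),
            "r": 30.0,
            "theta_B": float(np.pi),
            "R": 30.0,
            "gamma": 10.0,
            "beta": 1.1,
            "cell_size": 1.0,
        },
        spec.overrides,
    )
    params = ModelParams(sigma=3.0, gamma=cfg["gamma"], beta=cfg["beta"])
    rad = cfg["island_radius"]
    cell = cfg["cell_size"]
    n = int(2 * (rad + 3) / cell) + 1
    x = cell * np.arange(n) - (rad + 3)
    X, Y = np.meshgrid(x, x, indexing="ij")
    mask = X**2 + Y**2 <= rad**2
    raster = PopulationRaster(
        np.where(mask, 1.0, 0.0), cell_size=cell, land_mask=mask,
        boundary_mode="closed", origin=(-(rad + 3), -(rad + 3)),
    )
    # domain A: angular wedge of size theta_A
    theta = np.arctan2(Y, X)
    m0 = np.where(np.abs(theta) <= cfg["theta_A"] / 2.0, 1.0, 0.0)
    sector = SectorBound(cfg["theta_A"], cfg["r"], cfg["theta_B"], cfg["R"],
                         cfg["gamma"])
    return FixtureBundle(
        "island_sectors", params, raster=raster, sector=sector,
        initial_state=FieldState(np.where(mask, m0, 0.0)), config=cfg,
    )


def _archipelago(spec: FixtureSpec) -> FixtureBundle:
    cfg = _merge(
        {
            "size": 96,
            "n_islands": 3,
            "island_radius": (14.0, 22.0),
            "background": 1.0,
            "n_cities": 2,
            "omega": 5.0,
            "city_radius": 6.0,
            "sigma": 4.0,
            "beta": 1.1,
            "cell_size": 2.0,
        },
        spec.overrides,
    )
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xA2C]))
    params = ModelParams(sigma=cfg["sigma"], gamma=25.0, beta=cfg["beta"])
    n = int(cfg["size"])
    x = cfg["cell_size"] * np.arange(n)
    X, Y = np.meshgrid(x, x, indexing="ij")
    mask = np.zeros((n, n), dtype=bool)
    lo, hi = cfg["island_radius"]
    for _ in range(cfg["n_islands"]):
        cx, cy = rng.uniform(0.2 * n, 0.8 * n, size=2)
        r = rng.uniform(lo, hi)
        mask |= (X - cx) ** 2 + (Y - cy) ** 2 <= r**2
    land = np.argwhere(mask)
    cities = []
    for _ in range(cfg["n_cities"]):
        i, j = land[rng.integers(len(land))]
        cities.append(CitySpec((x[i], x[j]), cfg["omega"], cfg["city_radius"]))
    raster = build_city_density(
        cities, shape=(n, n), cell_size=cfg["cell_size"], mode="bare_gaussian",
        background=cfg["background"], land_mask=mask, boundary_mode="closed",
    )
    return FixtureBundle("archipelago", params, raster=raster, cities=cities,
                         config=cfg)


_REGISTRY = {
    "four_city": _four_city,
    "line20": _line20,
    "two_lobes": _two_lobes,
    "stripe_two_city": _stripe_two_city,
    "shrink_two_city": _shrink_two_city,
    "island_sectors": _island_sectors,
    "archipelago": _archipelago,
}


def available_fixtures() -> list[str]:
    return sorted(_REGISTRY)


def make_fixture(spec: FixtureSpec | str, **overrides) -> FixtureBundle:
    """Build a named fixture bundle; unknown names list the alternatives."""
    if isinstance(spec, str):
        spec = FixtureSpec(spec, overrides)
    elif overrides:
        raise TypeError("pass overrides via FixtureSpec when giving a spec object")
    if spec.name not in _REGISTRY:
        raise ValueError(
            f"unknown fixture {spec.name!r}; available: {available_fixtures()}"
        )
    return _REGISTRY[spec.name](spec)
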