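"""Core landscape and parameter types for the surface-tension dialect model.

The model lives on a gridded population landscape.  Speakers at position
``r`` carry a *memory* ``m(r, t)`` of the frequency with which they have
heard linguistic variant A, and speak it with frequency ``f = p(m)``, where
``p`` is a sigmoidal conformity map.  This module provides:

* :class:`ModelParams` — the interaction scales (σ, γ), conformity β,
  inherent bias α and the memory timescale τ;
* :class:`CitySpec` and :func:`build_city_density` — Gaussian city
  population profiles (with hinterlands, bare, or capped for lattice
  occupation probabilities);
* :class:`PopulationRaster` and :class:`MetropolitanField` — the gridded
  density and the local fraction of metropolitan (long-range interacting)
  speakers;
* :func:`conformity_map` — the memory-to-usage map
  ``p(m) = m^(αβ) / (m^(αβ) + (1 − m^α)^β)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "ModelParams",
    "CitySpec",
    "PopulationRaster",
    "MetropolitanField",
    "conformity_map",
    "build_city_density",
    "metropolitan_field",
]

BoundaryMode = Literal["periodic", "closed"]


@dataclass(frozen=True)
class ModelParams:
    """Model parameters.

    Parameters
    ----------
    sigma
        Length scale of short-range (Gaussian) interactions, σ > 0.
    gamma
        Length scale of long-range metropolitan (Lorentzian) interactions,
        γ > 0.
    beta
        Conformity number β ≥ 1: the strength of the tendency to copy the
        locally most common variant.  β > 1 generates surface tension at
        isoglosses.
    alpha
        Inherent bias α > 0.  α = 1 means no bias; α > 1 biases *against*
        variant A (speakers must remember hearing A more than half the time
        before using it half the time).
    tau
        Memory timescale τ > 0.  Time is measured in units of τ throughout,
        so solvers use τ = 1.
    """

    sigma: float = 5.0
    gamma: float = 25.0
    beta: float = 1.1
    alpha: float = 1.0
    tau: float = 1.0

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if not self.gamma > 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if not self.beta >= 1:
            raise ValueError(f"beta must be >= 1, got {self.beta}")
        if not self.alpha > 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if not self.tau > 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")


@dataclass(frozen=True)
class CitySpec:
    """A Gaussian city: peak density ω over radius R, optional hinterland B.

    The density contribution is ``ω·exp(−|r−r_i|²/R²) + exp(−|r−r_i|²/B²)``
    in hinterland mode; the hinterland term represents outlying towns and
    villages and requires 0 < R < B.
    """

    center: tuple[float, float]
    omega: float
    radius: float
    background_radius: float | None = None

    def __post_init__(self) -> None:
        if not self.omega > 0:
            raise ValueError(f"omega must be > 0, got {self.omega}")
        if not self.radius > 0:
            raise ValueError(f"radius must be > 0, got {self.radius}")
        if self.background_radius is not None and not (
            self.radius < self.background_radius
        ):
            raise ValueError(
                "background_radius must exceed radius "
                f"(got R={self.radius}, B={self.background_radius})"
            )


@dataclass
class PopulationRaster:
    """Gridded population density ρ(r) ≥ 0 with land mask and cell size.

    ``values[i, j]`` is the density of cell (i, j); the first index is x,
    the second y.  Densities are zero off land.  ``boundary_mode`` selects
    periodic wrapping or closed (coastline) boundaries; closed boundaries
    are realized by zero density off-land plus per-row renormalization of
    interaction weights over land, which is what makes stable isoglosses
    meet coastlines perpendicularly.
    """

    values: np.ndarray
    cell_size: float = 1.0
    land_mask: np.ndarray | None = None
    boundary_mode: BoundaryMode = "closed"
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D grid")
        if self.land_mask is None:
            self.land_mask = np.ones(self.values.shape, dtype=bool)
        self.land_mask = np.asarray(self.land_mask, dtype=bool)
        if self.land_mask.shape != self.values.shape:
            raise ValueError(
                f"land_mask shape {self.land_mask.shape} does not match "
                f"values shape {self.values.shape}"
            )
        if not self.cell_size > 0:
            raise ValueError("cell_size must be > 0")
        if self.boundary_mode not in ("periodic", "closed"):
            raise ValueError(f"unknown boundary_mode {self.boundary_mode!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("densities must be finite")
        if np.any(self.values < 0):
            raise ValueError("densities must be >= 0")
        # densities are zero off-land by definition
        self.values = np.where(self.land_mask, self.values, 0.0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def cell_area(self) -> float:
        return self.cell_size**2

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Cell-centre coordinate grids (X, Y) in length units."""
        nx, ny = self.shape
        x = self.origin[0] + self.cell_size * np.arange(nx)
        y = self.origin[1] + self.cell_size * np.arange(ny)
        return np.meshgrid(x, y, indexing="ij")

    def total_population(self) -> float:
        return float(self.values.sum() * self.cell_area)

    def same_geometry(self, other: "PopulationRaster | MetropolitanField") -> bool:
        return self.shape == getattr(other, "shape", None)


@dataclass
class MetropolitanField:
    """Fraction M(r) ∈ [0, 1] of locally metropolitan speakers."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("M field must be a 2-D grid")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("M must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def conformity_map(m, params: ModelParams | None = None, *,
                   alpha: float | None = None, beta: float | None = None):
    """The sigmoidal memory-to-usage map p(m) = m^(αβ)/(m^(αβ)+(1−m^α)^β).

    Maps a memory (remembered frequency of variant A) in [0, 1] to the
    frequency with which A is currently used.  β ≥ 1 is conformity to the
    local majority, α the inherent bias (α = β = 1 is the identity map).
    The endpoint corners 0^0 are resolved by continuity: p(0) = 0, p(1) = 1.

    Parameters may be given either as a :class:`ModelParams` or as keyword
    ``alpha``/``beta`` scalars.  Accepts scalars or arrays; raises
    ``ValueError`` if any input lies outside [0, 1].
    """
    if params is not None:
        a, b = params.alpha, params.beta
    else:
        a = 1.0 if alpha is None else float(alpha)
        b = 1.0 if beta is None else float(beta)
    m_arr = np.asarray(m, dtype=float)
    if np.any(m_arr < 0) or np.any(m_arr > 1) or not np.all(np.isfinite(m_arr)):
        raise ValueError("memory values must lie in [0, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        ma = m_arr**a
        num = m_arr ** (a * b)
        den = num + (1.0 - ma) ** b
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    # continuity at the endpoints
    out = np.where(m_arr <= 0.0, 0.0, out)
    out = np.where(m_arr >= 1.0, 1.0, out)
    if np.isscalar(m) or np.ndim(m) == 0:
        return float(out)
    return out


DensityMode = Literal["with_hinterland", "bare_gaussian", "capped"]


def build_city_density(
    cities: Sequence[CitySpec],
    *,
    shape: tuple[int, int],
    cell_size: float = 1.0,
    background: float | None = None,
    mode: DensityMode = "with_hinterland",
    land_mask: np.ndarray | None = None,
    boundary_mode: BoundaryMode = "closed",
    origin: tuple[float, float] = (0.0, 0.0),
) -> PopulationRaster:
    """Build a gridded density from Gaussian city profiles.

    Modes
    -----
    ``with_hinterland``
        ρ = Σ_i [ω_i e^(−Δ_i²/R_i²) + e^(−Δ_i²/B_i²)] (+ background if given).
        Each city needs a ``background_radius``.
    ``bare_gaussian``
        ρ = Σ_i ω_i e^(−Δ_i²/R_i²) (+ constant background if given).  With a
        single city and ``background`` this is the radially symmetric profile
        used for stable-radius analysis.
    ``capped``
        ρ = min{(1 − ρ₀)·Σ_i e^(−Δ_i²/R_i²) + ρ₀, 1} with ρ₀ = ``background``
        ∈ [0, 1]; suitable as a site-occupation probability for the
        stochastic lattice.

    Distances honour ``boundary_mode``: with periodic boundaries the
    displacement to each city wraps around the domain.
    """
    if not cities:
        raise ValueError("at least one city is required")
    nx, ny = shape
    x = origin[0] + cell_size * np.arange(nx)
    y = origin[1] + cell_size * np.arange(ny)
    X, Y = np.meshgrid(x, y, indexing="ij")
    Lx, Ly = nx * cell_size, ny * cell_size

    def sq_dist(cx: float, cy: float) -> np.ndarray:
        dx = X - cx
        dy = Y - cy
        if boundary_mode == "periodic":
            dx = (dx + Lx / 2) % Lx - Lx / 2
            dy = (dy + Ly / 2) % Ly - Ly / 2
        return dx**2 + dy**2

    rho = np.zeros(shape, dtype=float)
    if mode == "with_hinterland":
        for c in cities:
            if c.background_radius is None:
                raise ValueError(
                    f"city at {c.center} lacks background_radius "
                    "(required in with_hinterland mode)"
                )
            d2 = sq_dist(*c.center)
            rho += c.omega * np.exp(-d2 / c.radius**2)
            rho += np.exp(-d2 / c.background_radius**2)
        if background is not None:
            rho += background
    elif mode == "bare_gaussian":
        for c in cities:
            rho += c.omega * np.exp(-sq_dist(*c.center) / c.radius**2)
        if background is not None:
            rho += background
    elif mode == "capped":
        rho0 = 0.0 if background is None else float(background)
        if not 0.0 <= rho0 <= 1.0:
            raise ValueError(f"capped mode needs rho0 in [0, 1], got {rho0}")
        for c in cities:
            rho += np.exp(-sq_dist(*c.center) / c.radius**2)
        rho = np.minimum((1.0 - rho0) * rho + rho0, 1.0)
    else:
        raise ValueError(f"unknown density mode {mode!r}")

    return PopulationRaster(
        rho,
        cell_size=cell_size,
        land_mask=land_mask,
        boundary_mode=boundary_mode,
        origin=origin,
    )


def metropolitan_field(
    raster: PopulationRaster,
    cities: Sequence[CitySpec],
    core_factor: float = 1.0,
) -> MetropolitanField:
    """Indicator M field: 1 within distance c·R_i of any city centre.

    All speakers within the metropolitan core of a city behave as
    metropolitans; everyone else is purely local.  ``core_factor`` is the
    core-radius multiple c (default 1).
    """
    X, Y = raster.coords()
    nx, ny = raster.shape
    Lx, Ly = nx * raster.cell_size, ny * raster.cell_size
    M = np.zeros(raster.shape, dtype=float)
    for c in cities:
        dx = X - c.center[0]
        dy = Y - c.center[1]
        if raster.boundary_mode == "periodic":
            dx = (dx + Lx / 2) % Lx - Lx / 2
            dy = (dy + Ly / 2) % Ly - Ly / 2
        M[dx**2 + dy**2 <= (core_factor * c.radius) ** 2] = 1.0
    return MetropolitanField(M)
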