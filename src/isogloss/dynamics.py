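"""Time integration of the memory-field equation and isogloss measurement.

Two dynamics are provided, both explicit forward-Euler relaxations of the
memory field m(r, t) toward a local average of the spoken frequency
f = p(m):

* ``step_nonlocal`` — the full nonlocal equation ṁ = f̄ − m, where f̄ is
  the interaction-operator average of f.  The update is a convex
  combination for dt ≤ 1, so m stays in [0, 1] unconditionally.
* ``step_local`` — the short-range (saddle-point) reduction valid when the
  population density varies slowly on the scale σ:

      ṁ = f − m + (σ²/2)·[∇²(ρ f) − f ∇²ρ]/ρ.

  The −f∇²ρ counterterm comes from expanding the *normalized* spatial
  average to O(σ²); it vanishes wherever ∇²ρ = 0 and keeps the uniform
  states m ≡ const exact fixed points on any landscape.  The widely quoted
  form without the counterterm is available via ``form="unnormalized"``.

Isoglosses are the f = 1/2 level set, extracted by marching squares with
linear interpolation, with per-vertex signed curvature (positive when the
contour bows toward the interior of the A domain) and outward normals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
from skimage import measure as _skmeasure

from .core import ModelParams, PopulationRaster, conformity_map
from .operator import InteractionOperator

__all__ = [
    "FieldState",
    "SolverConfig",
    "IsoglossContour",
    "EquilibriumResult",
    "step_nonlocal",
    "step_local",
    "run_to_equilibrium",
    "random_init",
    "extract_isoglosses",
    "measure_radius",
    "measure_front_speed",
    "total_isogloss_length",
    "modal_map",
]


@dataclass
class FieldState:
    """Memory field m ∈ [0, 1] on land cells, at elapsed time t (units of τ)."""

    m: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=float)
        if self.t < 0:
            raise ValueError("t must be >= 0")

    def frequency(self, params: ModelParams) -> np.ndarray:
        """The spoken-frequency view f = p(m)."""
        return conformity_map(self.m, params)


@dataclass(frozen=True)
class SolverConfig:
    dt: float = 0.1
    tol: float = 1e-6
    max_time: float = 5000.0
    seed: int = 0
    consecutive: int = 10  # steps below tol required to declare equilibrium

    def __post_init__(self) -> None:
        if not 0 < self.dt <= 1:
            raise ValueError("dt must lie in (0, 1]")
        if not self.tol > 0:
            raise ValueError("tol must be > 0")


@dataclass
class EquilibriumResult:
    state: FieldState
    steps: int
    residual: float
    converged: bool
    snapshots: list[FieldState] = field(default_factory=list)


def _check_nan(m: np.ndarray, mask: np.ndarray) -> None:
    bad = mask & ~np.isfinite(m)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise FloatingPointError(f"non-finite memory at cell ({i}, {j})")


def step_nonlocal(
    state: FieldState,
    op: InteractionOperator,
    params: ModelParams,
    dt: float = 0.1,
) -> FieldState:
    """One forward-Euler step of ṁ = f̄ − m with f̄ = ⟨p(m)⟩."""
    if dt > 1:
        raise ValueError("dt must be <= 1")
    mask = op.raster.land_mask
    _check_nan(state.m, mask)
    f = conformity_map(np.where(mask, state.m, 0.0), params)
    fbar = op.apply(f)
    m = np.where(mask, state.m + dt * (fbar - state.m), state.m)
    return FieldState(np.clip(m, 0.0, 1.0), state.t + dt)


def masked_laplacian(
    F: np.ndarray, mask: np.ndarray, cell: float, periodic: bool
) -> np.ndarray:
    """5-point Laplacian with zero-flux (mirror) closure at mask boundaries.

    Off-land/off-grid neighbours contribute the centre value (ghost-cell
    mirroring), i.e. they are simply dropped from the stencil sum.
    """
    out = np.zeros_like(F)
    for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        if periodic:
            nbr = np.roll(F, shift, axis=axis)
            nmask = np.roll(mask, shift, axis=axis)
        else:
            nbr = np.empty_like(F)
            nmask = np.zeros_like(mask)
            src = [slice(None)] * 2
            dst = [slice(None)] * 2
            if shift == 1:
                dst[axis], src[axis] = slice(1, None), slice(None, -1)
            else:
                dst[axis], src[axis] = slice(None, -1), slice(1, None)
            nbr[tuple(dst)] = F[tuple(src)]
            nmask[tuple(dst)] = mask[tuple(src)]
        valid = mask & nmask
        out += np.where(valid, nbr - F, 0.0)
    return out / cell**2


def step_local(
    state: FieldState,
    raster: PopulationRaster,
    params: ModelParams,
    dt: float = 0.1,
    form: Literal["normalized", "unnormalized"] = "normalized",
) -> FieldState:
    """One forward-Euler step of the local (short-range) reduction.

    Requires ρ > 0 on every land cell.  The diffusion-like term can
    overshoot slightly at sharp initial conditions; the update is clipped
    to [0, 1] (the invariant the continuum equation preserves).
    """
    if dt > 1:
        raise ValueError("dt must be <= 1")
    # FTCS diffusion stability: D·dt/h² ≤ 1/4 with D = σ²/2
    dt_max = raster.cell_size**2 / (2.0 * params.sigma**2)
    if dt > dt_max * (1 + 1e-12):
        raise ValueError(
            f"dt={dt} unstable for the explicit local stepper: "
            f"need dt <= cell²/(2σ²) = {dt_max:.4g}"
        )
    mask = raster.land_mask
    _check_nan(state.m, mask)
    rho = raster.values
    if np.any(mask & (rho <= 0)):
        i, j = np.argwhere(mask & (rho <= 0))[0]
        raise ZeroDivisionError(f"zero density on land cell ({i}, {j})")
    periodic = raster.boundary_mode == "periodic"
    f = conformity_map(np.where(mask, state.m, 0.0), params)
    lap_rf = masked_laplacian(
        np.where(mask, rho * f, 0.0), mask, raster.cell_size, periodic
    )
    if form == "normalized":
        lap_r = masked_laplacian(rho, mask, raster.cell_size, periodic)
        diff = lap_rf - f * lap_r
    else:
        diff = lap_rf
    dm = f - state.m + (params.sigma**2 / 2.0) * np.where(
        mask, diff / np.where(mask, rho, 1.0), 0.0
    )
    m = np.where(mask, state.m + dt * dm, state.m)
    return FieldState(np.clip(m, 0.0, 1.0), state.t + dt)


def run_to_equilibrium(
    state: FieldState,
    *,
    dynamics: Literal["nonlocal", "local"],
    params: ModelParams,
    raster: PopulationRaster | None = None,
    op: InteractionOperator | None = None,
    config: SolverConfig = SolverConfig(),
    snapshot_times: Sequence[float] = (),
) -> EquilibriumResult:
    """Iterate until max|ṁ| < tol for `consecutive` steps or max_time.

    Non-convergence at max_time is flagged in the result, not raised.
    """
    if dynamics == "nonlocal":
        if op is None:
            raise ValueError("nonlocal dynamics needs an interaction operator")
        stepper = lambda s: step_nonlocal(s, op, params, config.dt)
        mask = op.raster.land_mask
    elif dynamics == "local":
        if raster is None:
            raise ValueError("local dynamics needs a population raster")
        stepper = lambda s: step_local(s, raster, params, config.dt)
        mask = raster.land_mask
    else:
        raise ValueError(f"unknown dynamics {dynamics!r}")

    snaps_due = sorted(snapshot_times)
    snapshots: list[FieldState] = []
    below = 0
    steps = 0
    residual = np.inf
    while state.t < config.max_time:
        new = stepper(state)
        residual = float(np.abs(new.m[mask] - state.m[mask]).max() / config.dt)
        state = new
        steps += 1
        while snaps_due and state.t >= snaps_due[0] - 1e-9:
            snapshots.append(replace(state))
            snaps_due.pop(0)
        below = below + 1 if residual < config.tol else 0
        if below >= config.consecutive:
            return EquilibriumResult(state, steps, residual, True, snapshots)
    return EquilibriumResult(state, steps, residual, False, snapshots)


def random_init(raster: PopulationRaster, seed: int) -> FieldState:
    """Memory i.i.d. uniform on [0, 1] on each land cell (0 off-land)."""
    rng = np.random.default_rng(seed)
    m = rng.uniform(0.0, 1.0, size=raster.shape)
    return FieldState(np.where(raster.land_mask, m, 0.0), 0.0)


@dataclass
class IsoglossContour:
    """A polyline along the f = 1/2 level set, in length units.

    ``vertices`` has shape (n, 2) (x, y); ``closed`` contours repeat the
    first vertex at the end.  ``curvature`` is the signed curvature κ at
    each vertex, positive where the contour bows toward the A-domain
    interior (so a circular isogloss enclosing an A island has κ = +1/a);
    ``normal`` is the outward unit normal ĝ (pointing away from A, i.e.
    down the gradient of f).
    """

    vertices: np.ndarray
    closed: bool
    curvature: np.ndarray
    normal: np.ndarray

    def length(self) -> float:
        d = np.diff(self.vertices, axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())


def _contour_geometry(
    verts: np.ndarray, closed: bool, f: np.ndarray, raster: PopulationRaster
) -> tuple[np.ndarray, np.ndarray]:
    """Signed curvature and outward normal along a polyline."""
    pts = verts[:-1] if closed and len(verts) > 3 else verts
    n = len(pts)
    if closed and n > 2:
        prev = np.roll(pts, 1, axis=0)
        nxt = np.roll(pts, -1, axis=0)
    else:
        prev = np.vstack([pts[0], pts[:-1]])
        nxt = np.vstack([pts[1:], pts[-1]])
    t = nxt - prev
    tn = np.hypot(t[:, 0], t[:, 1])
    tn[tn == 0] = 1.0
    t /= tn[:, None]
    # Menger curvature: 4·signed-area / product of the triangle sides —
    # exact for circular arcs regardless of vertex spacing
    u = pts - prev
    w = nxt - pts
    cross = u[:, 0] * w[:, 1] - u[:, 1] * w[:, 0]
    la = np.hypot(u[:, 0], u[:, 1])
    lb = np.hypot(w[:, 0], w[:, 1])
    lc = np.hypot(*(nxt - prev).T)
    denom = la * lb * lc
    denom[denom == 0] = 1.0
    kappa_left = 2.0 * cross / denom  # positive: bends toward the left normal
    left = np.column_stack([-t[:, 1], t[:, 0]])
    # outward normal: direction of decreasing f, from the bilinear gradient
    gx, gy = np.gradient(f, raster.cell_size)
    ij = (pts - np.asarray(raster.origin)) / raster.cell_size
    i = np.clip(ij[:, 0], 0, f.shape[0] - 1).astype(int)
    j = np.clip(ij[:, 1], 0, f.shape[1] - 1).astype(int)
    grad = np.column_stack([gx[i, j], gy[i, j]])
    gn = np.hypot(grad[:, 0], grad[:, 1])
    gn[gn == 0] = 1.0
    outward = -grad / gn[:, None]
    # bowing toward A-interior == bending away from the outward normal
    side = np.sign((left * outward).sum(axis=1))
    side[side == 0] = 1.0
    kappa = -kappa_left * side
    if closed and len(verts) > 3:
        kappa = np.append(kappa, kappa[0])
        outward = np.vstack([outward, outward[0]])
    return kappa, outward


def extract_isoglosses(
    state: FieldState, params: ModelParams, raster: PopulationRaster
) -> list[IsoglossContour]:
    """Marching-squares level set of f = p(m) at 1/2.

    Contours are classified closed when they return to their start; open
    contours end on the land boundary.  A field uniformly on one side of
    1/2 yields an empty list.
    """
    f = conformity_map(np.clip(state.m, 0, 1), params)
    fm = np.where(raster.land_mask, f, np.nan)
    out = []
    for c in _skmeasure.find_contours(fm, 0.5):
        verts = np.asarray(raster.origin) + c * raster.cell_size
        closed = bool(np.allclose(verts[0], verts[-1])) and len(verts) > 3
        kappa, normal = _contour_geometry(verts, closed, f, raster)
        out.append(IsoglossContour(verts, closed, kappa, normal))
    return out


def measure_radius(
    contour: IsoglossContour, center: tuple[float, float]
) -> tuple[float, float]:
    """Mean and s.d. of vertex distances to ``center`` (closed contours)."""
    if not contour.closed:
        raise ValueError("radius is defined only for closed contours")
    pts = contour.vertices[:-1]
    d = np.hypot(pts[:, 0] - center[0], pts[:, 1] - center[1])
    return float(d.mean()), float(d.std())


def measure_front_speed(
    states: Iterable[FieldState],
    params: ModelParams,
    raster: PopulationRaster,
    axis: int = 0,
    burn_in: float = 0.0,
) -> float:
    """Front speed from a least-squares fit of front position vs. time.

    Assumes a quasi-1-D geometry with a single f = 1/2 crossing of the
    transverse-averaged profile along ``axis``; raises if several fronts
    are present.  Snapshots with t < burn_in are discarded.
    """
    ts, xs = [], []
    coord = np.asarray(raster.origin)[axis] + raster.cell_size * np.arange(
        raster.shape[axis]
    )
    for s in states:
        if s.t < burn_in:
            continue
        f = conformity_map(np.clip(s.m, 0, 1), params)
        prof = np.where(raster.land_mask, f, np.nan)
        prof = np.nanmean(prof, axis=1 - axis)
        sgn = np.sign(prof - 0.5)
        crossings = np.nonzero(np.diff(sgn) != 0)[0]
        crossings = crossings[np.abs(np.diff(sgn))[crossings] > 0]
        if len(crossings) == 0:
            raise ValueError(f"no front at t={s.t}")
        if len(crossings) > 1:
            raise ValueError(f"multiple fronts at t={s.t}")
        i = crossings[0]
        th = (0.5 - prof[i]) / (prof[i + 1] - prof[i])
        ts.append(s.t)
        xs.append(coord[i] + th * raster.cell_size)
    if len(ts) < 2:
        raise ValueError("need at least two snapshots after burn-in")
    slope = np.polyfit(ts, xs, 1)[0]
    return float(slope)


def total_isogloss_length(
    state: FieldState, params: ModelParams, raster: PopulationRaster
) -> float:
    """Total length of the f = 1/2 level set (coarsening diagnostic)."""
    return sum(c.length() for c in extract_isoglosses(state, params, raster))


def modal_map(state: FieldState, params: ModelParams) -> np.ndarray:
    """Boolean modal-variant map: True where f ≥ 1/2 (ties break toward A)."""
    return conformity_map(np.clip(state.m, 0, 1), params) >= 0.5
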