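"""Regionalization: ensembles of stable isoglosses clustered into dialect areas.

The pipeline mirrors how stable dialect regions are predicted on a real
landscape: smooth the raw population raster (mass-conserving, with
off-land mass re-apportioned onto land), evolve the local dynamics from
many randomized initial memory fields to a fixed horizon, record each
run's modal-variant map, describe every scored location by its binary
vector of modal variants across runs, group locations by Ward-linkage
hierarchical clustering, and score agreement between two label maps by
the area (OL) or population-weighted (WOL) fraction of matching labels
after optimal label alignment (Hungarian assignment).  A Voronoi
tessellation with seeds uniform on land serves as the geometry-free null
model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.signal import fftconvolve
from scipy.spatial import cKDTree

from .core import ModelParams, PopulationRaster
from .dynamics import FieldState, SolverConfig, modal_map, random_init, run_to_equilibrium

__all__ = [
    "ClusteringConfig",
    "EnsembleResult",
    "DialectMap",
    "OverlapReport",
    "smooth_population",
    "run_ensemble",
    "cluster_dialects",
    "align_and_overlap",
    "voronoi_null",
]


@dataclass(frozen=True)
class ClusteringConfig:
    """Knobs of the regionalization pipeline.

    sigma_s: smoothing length σ_s (same units as the raster); should be
        comparable to, but somewhat smaller than, the interaction range σ.
    n_runs: ensemble size (number of randomized initial conditions).
    n_c: number of dialect areas to cut the cluster tree into.
    sample_points: number of scored locations (None = all land cells).
    t_end: evolution time per run, units of τ.
    seed: master seed; run r uses seed·10⁴ + r.
    """

    sigma_s: float = 0.0
    n_runs: int = 50
    n_c: int = 2
    sample_points: int | None = None
    t_end: float = 200.0
    seed: int = 0
    dt: float = 0.1

    def __post_init__(self) -> None:
        if self.sigma_s < 0:
            raise ValueError("sigma_s must be >= 0")
        if self.n_runs < 2:
            raise ValueError("n_runs must be >= 2")
        if self.n_c < 2:
            raise ValueError("n_c must be >= 2")


@dataclass
class EnsembleResult:
    """Per-run modal-variant maps on a shared geometry."""

    modal_maps: np.ndarray  # (n_runs, nx, ny) boolean
    raster: PopulationRaster
    converged: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))


@dataclass
class DialectMap:
    """Cluster label (1..n_c) per scored land cell.

    ``labels`` is a flat array aligned with ``cells`` (indices into the
    raster grid).  ``label_grid()`` scatters labels onto the grid with 0
    for unscored cells.
    """

    labels: np.ndarray
    cells: np.ndarray  # (n, 2) integer grid indices
    shape: tuple[int, int]

    def label_grid(self) -> np.ndarray:
        g = np.zeros(self.shape, dtype=int)
        g[self.cells[:, 0], self.cells[:, 1]] = self.labels
        return g

    @property
    def n_labels(self) -> int:
        return int(len(np.unique(self.labels)))


@dataclass
class OverlapReport:
    OL: float
    WOL: float | None
    label_mapping: dict[int, int]


def smooth_population(raw: PopulationRaster, sigma_s: float) -> PopulationRaster:
    """Gaussian population smoothing, conserving total population on land.

    Each source cell's population is spread with a Gaussian of s.d. σ_s;
    the share that would land off-land is re-apportioned onto land by
    per-source renormalization (the boundary-aware "skew").  σ_s = 0 is the
    identity.
    """
    if sigma_s == 0.0:
        return raw
    cell = raw.cell_size
    k = int(np.ceil(5 * sigma_s / cell))
    off = cell * np.arange(-k, k + 1)
    G = np.exp(-(off[:, None] ** 2 + off[None, :] ** 2) / (2 * sigma_s**2))
    G /= G.sum()
    mask = raw.land_mask.astype(float)
    if raw.boundary_mode == "periodic":
        def conv(F):
            pad = ((k, k), (k, k))
            Fp = np.pad(F, pad, mode="wrap")
            return fftconvolve(Fp, G, mode="same")[k:-k, k:-k]
    else:
        def conv(F):
            return fftconvolve(F, G, mode="same")
    reach = conv(mask)  # fraction of each source's mass that lands on land
    src = np.where(raw.land_mask, raw.values / np.maximum(reach, 1e-300), 0.0)
    sm = mask * conv(src)
    sm = np.where(raw.land_mask, np.maximum(sm, 0.0), 0.0)  # FFT roundoff
    return PopulationRaster(
        sm,
        cell_size=cell,
        land_mask=raw.land_mask,
        boundary_mode=raw.boundary_mode,
        origin=raw.origin,
    )


def run_ensemble(
    raster: PopulationRaster,
    params: ModelParams,
    config: ClusteringConfig,
) -> EnsembleResult:
    """Evolve n_runs randomized initial conditions to t_end (local dynamics)
    and record each equilibrium modal-variant map.

    Runs that have not reached the equilibrium tolerance by t_end are
    retained and flagged.  Fully reproducible from the master seed.
    """
    smoothed = smooth_population(raster, config.sigma_s)
    maps = np.empty((config.n_runs, *raster.shape), dtype=bool)
    conv = np.empty(config.n_runs, dtype=bool)
    for r in range(config.n_runs):
        state = random_init(smoothed, config.seed * 10_000 + r)
        res = run_to_equilibrium(
            state,
            dynamics="local",
            params=params,
            raster=smoothed,
            config=SolverConfig(dt=config.dt, max_time=config.t_end),
        )
        maps[r] = modal_map(res.state, params) & raster.land_mask
        conv[r] = res.converged
    return EnsembleResult(maps, smoothed, conv)


def cluster_dialects(ensemble: EnsembleResult, config: ClusteringConfig) -> DialectMap:
    """Ward clustering of scored locations by their modal-variant vectors.

    Each scored land cell gets the binary vector of its modal variant
    across runs; Ward linkage on Euclidean distances; the tree is cut into
    n_c clusters.  Raises when n_c exceeds the number of distinct vectors.
    """
    if ensemble.modal_maps.size == 0:
        raise ValueError("empty ensemble")
    land = np.argwhere(ensemble.raster.land_mask)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xD1A]))
    if config.sample_points is not None and config.sample_points < len(land):
        pick = rng.choice(len(land), size=config.sample_points, replace=False)
        cells = land[np.sort(pick)]
    else:
        cells = land
    X = ensemble.modal_maps[:, cells[:, 0], cells[:, 1]].T.astype(float)
    n_distinct = len(np.unique(X, axis=0))
    if config.n_c > n_distinct:
        raise ValueError(
            f"n_c={config.n_c} exceeds the {n_distinct} distinct modal vectors"
        )
    Z = linkage(X, method="ward")
    labels = fcluster(Z, t=config.n_c, criterion="maxclust")
    return DialectMap(labels, cells, ensemble.raster.shape)


def _common_cells(map_a: DialectMap, map_b: DialectMap) -> np.ndarray:
    if map_a.shape != map_b.shape:
        raise ValueError("maps have different geometry")
    ga = map_a.label_grid()
    gb = map_b.label_grid()
    common = (ga > 0) & (gb > 0)
    if not common.any():
        raise ValueError("maps have no scored cells in common (disjoint masks)")
    return common


def align_and_overlap(
    map_a: DialectMap,
    map_b: DialectMap,
    population: PopulationRaster | None = None,
) -> OverlapReport:
    """Agreement between two label maps after optimal label alignment.

    Builds the label-confusion matrix over commonly scored cells, solves
    the assignment maximizing agreement (Hungarian algorithm), and reports
    OL (area fraction) and, when a population raster is given, WOL (the
    population-weighted fraction).  Label counts may differ; OL and WOL
    are invariant to relabelling either map.
    """
    common = _common_cells(map_a, map_b)
    ga = map_a.label_grid()[common]
    gb = map_b.label_grid()[common]
    la = np.unique(ga)
    lb = np.unique(gb)
    ia = np.searchsorted(la, ga)
    ib = np.searchsorted(lb, gb)
    area = np.ones(common.sum())
    C_area = np.zeros((len(la), len(lb)))
    np.add.at(C_area, (ia, ib), area)
    rows, cols = linear_sum_assignment(C_area, maximize=True)
    mapping = {int(la[r]): int(lb[c]) for r, c in zip(rows, cols)}
    OL = float(C_area[rows, cols].sum() / area.sum())
    WOL = None
    if population is not None:
        w = population.values[common]
        C_w = np.zeros_like(C_area)
        np.add.at(C_w, (ia, ib), w)
        rw, cw = linear_sum_assignment(C_w, maximize=True)
        WOL = float(C_w[rw, cw].sum() / max(w.sum(), 1e-300))
    return OverlapReport(OL, WOL, mapping)


def voronoi_null(raster: PopulationRaster, n_c: int, seed: int) -> DialectMap:
    """Null dialect map: Voronoi cells of n_c seeds uniform on land."""
    land = np.argwhere(raster.land_mask)
    if n_c > len(land):
        raise ValueError("n_c exceeds the number of land cells")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7080]))
    pick = rng.choice(len(land), size=n_c, replace=False)
    seeds = land[pick].astype(float)
    tree = cKDTree(seeds)
    _, nearest = tree.query(land.astype(float))
    return DialectMap(nearest + 1, land, raster.shape)
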