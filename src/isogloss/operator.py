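"""The nonlocal interaction operator: spatial averaging of fields.

The expected fraction of interactions that speakers at r₁ have with
speakers near r₂ is the interaction density

    ψ(r₁, r₂) ∝ [(1 − M₁M₂)·exp(−d²/2σ²) + M₁M₂/(1 + d²/γ²)]·ρ(r₂),

a mixture of a short-range Gaussian kernel (scale σ) between ordinary
speakers and a long-range Lorentzian kernel (scale γ) between metropolitan
speakers, weighted by the local population density and normalized so that
each row integrates to one over land.  Integrated over two distant compact
metropolitan centres the Lorentzian part reproduces the gravity law
P₁P₂/r².

Applying the operator to a frequency field gives the spatially averaged
frequency f̄ that a speaker samples.  Application is done with FFT
convolutions (the kernels are translation invariant; the M-weights
factorize as M₁·M₂), with an explicit dense-matrix path retained for small
grids as an independent check.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import fftconvolve

from .core import MetropolitanField, ModelParams, PopulationRaster

__all__ = ["InteractionOperator", "build_interaction_operator", "spatial_average"]

GAUSSIAN_TRUNCATION = 5.0  # kernel support in units of sigma; tail error < 4e-6


def _gaussian_kernel(sigma: float, cell: float) -> np.ndarray:
    k = int(np.ceil(GAUSSIAN_TRUNCATION * sigma / cell))
    off = cell * np.arange(-k, k + 1)
    dx2 = off[:, None] ** 2 + off[None, :] ** 2
    K = np.exp(-dx2 / (2.0 * sigma**2))
    K[dx2 > (GAUSSIAN_TRUNCATION * sigma) ** 2] = 0.0
    return K


def _lorentzian_kernel(gamma: float, cell: float, shape: tuple[int, int]) -> np.ndarray:
    # untruncated: spans every possible displacement on the grid
    nx, ny = shape
    ox = cell * np.arange(-(nx - 1), nx)
    oy = cell * np.arange(-(ny - 1), ny)
    d2 = ox[:, None] ** 2 + oy[None, :] ** 2
    return 1.0 / (1.0 + d2 / gamma**2)


def _wrapped_kernel_grid(kernel_func, cell, shape, *args):
    """Kernel evaluated on wrapped (periodic) displacements, FFT layout."""
    nx, ny = shape
    ix = np.arange(nx)
    iy = np.arange(ny)
    dx = cell * np.minimum(ix, nx - ix)
    dy = cell * np.minimum(iy, ny - iy)
    d2 = dx[:, None] ** 2 + dy[None, :] ** 2
    return kernel_func(d2, *args)


class InteractionOperator:
    """Row-normalized spatial-averaging operator on a population raster.

    Constructed by :func:`build_interaction_operator`.  ``apply(f)`` returns
    the spatial average f̄ on land cells (zero elsewhere).  The operator is
    linear, row-stochastic over land (rows sum to one by construction, so a
    constant field is mapped to itself), and positivity preserving, hence
    ``min f ≤ f̄ ≤ max f``.
    """

    def __init__(
        self,
        raster: PopulationRaster,
        M: MetropolitanField,
        params: ModelParams,
    ):
        if raster.shape != M.shape:
            raise ValueError("raster and metropolitan field geometry differ")
        if not raster.land_mask.any():
            raise ValueError("empty land mask: no land cells to average over")
        self.raster = raster
        self.M = M
        self.params = params
        self._mask = raster.land_mask
        self._rho = raster.values
        self._Mv = np.where(self._mask, M.values, 0.0)
        self._metropolitan = bool(np.any(self._Mv > 0))
        cell = raster.cell_size
        if raster.boundary_mode == "periodic":
            self._gk = _wrapped_kernel_grid(
                lambda d2, s: np.where(
                    d2 <= (GAUSSIAN_TRUNCATION * s) ** 2,
                    np.exp(-d2 / (2 * s**2)),
                    0.0,
                ),
                cell,
                raster.shape,
                params.sigma,
            )
            if self._metropolitan:
                self._lk = _wrapped_kernel_grid(
                    lambda d2, g: 1.0 / (1.0 + d2 / g**2),
                    cell,
                    raster.shape,
                    params.gamma,
                )
        else:
            self._gk = _gaussian_kernel(params.sigma, cell)
            if self._metropolitan:
                self._lk = _lorentzian_kernel(params.gamma, cell, raster.shape)
        self._norm = self._numerator(np.ones(raster.shape))
        # FFT roundoff can leave ~1e-16 residue where the true weight is zero
        bad = self._mask & (self._norm <= 1e-12 * max(self._norm.max(), 1e-300))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"land cell ({i}, {j}) has no reachable population: "
                "interaction weights cannot be normalized"
            )

    def _conv(self, field: np.ndarray, kernel: np.ndarray) -> np.ndarray:
        if self.raster.boundary_mode == "periodic":
            return np.real(
                np.fft.irfft2(
                    np.fft.rfft2(field) * np.fft.rfft2(kernel), s=field.shape
                )
            )
        return fftconvolve(field, kernel, mode="same")

    def _numerator(self, f: np.ndarray) -> np.ndarray:
        src = np.where(self._mask, self._rho * f, 0.0)
        out = self._conv(src, self._gk)
        if self._metropolitan:
            msrc = self._Mv * src
            out = out + self._Mv * (
                self._conv(msrc, self._lk) - self._conv(msrc, self._gk)
            )
        return out

    def apply(self, f: np.ndarray) -> np.ndarray:
        """Spatial average f̄(r) = ∫ψ(r, r′)f(r′)dr′ over land cells."""
        f = np.asarray(f, dtype=float)
        if f.shape != self.raster.shape:
            raise ValueError(
                f"field shape {f.shape} does not match raster {self.raster.shape}"
            )
        if not np.all(np.isfinite(f[self._mask])):
            raise ValueError("field must be finite on land cells")
        out = np.zeros_like(f)
        m = self._mask
        out[m] = self._numerator(f)[m] / self._norm[m]
        return out

    def dense_matrix(self, max_cells: int = 4096) -> np.ndarray:
        """Explicit row-stochastic matrix over land cells (small grids only).

        Brute-force construction from pairwise distances; used as the
        independent oracle for the convolution path.  Rows are normalized to
        one; raises if a row has no weight.
        """
        idx = np.argwhere(self._mask)
        n = len(idx)
        if n > max_cells:
            raise ValueError(f"dense path limited to {max_cells} land cells, got {n}")
        cell = self.raster.cell_size
        pos = idx * cell
        diff = pos[:, None, :] - pos[None, :, :]
        if self.raster.boundary_mode == "periodic":
            L = np.array(self.raster.shape) * cell
            diff = (diff + L / 2) % L - L / 2
        d2 = (diff**2).sum(axis=-1)
        p = self.params
        G = np.where(
            d2 <= (GAUSSIAN_TRUNCATION * p.sigma) ** 2,
            np.exp(-d2 / (2 * p.sigma**2)),
            0.0,
        )
        Lor = 1.0 / (1.0 + d2 / p.gamma**2)
        Mi = self._Mv[self._mask]
        M12 = Mi[:, None] * Mi[None, :]
        W = ((1.0 - M12) * G + M12 * Lor) * self._rho[self._mask][None, :]
        rowsum = W.sum(axis=1)
        if np.any(rowsum <= 0):
            i, j = idx[int(np.argmax(rowsum <= 0))]
            raise ValueError(
                f"land cell ({i}, {j}) has no reachable population: "
                "interaction weights cannot be normalized"
            )
        return W / rowsum[:, None]


def build_interaction_operator(
    raster: PopulationRaster,
    M: MetropolitanField | None,
    params: ModelParams,
) -> InteractionOperator:
    """Construct the interaction operator for a landscape.

    ``M=None`` means no metropolitan speakers anywhere (pure Gaussian
    smoothing weighted by population).
    """
    if M is None:
        M = MetropolitanField(np.zeros(raster.shape))
    return InteractionOperator(raster, M, params)


def spatial_average(f: np.ndarray, op: InteractionOperator) -> np.ndarray:
    """f̄ = ∫ψ(r, r′) f(r′) dr′; a convex combination of land values of f."""
    return op.apply(f)
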