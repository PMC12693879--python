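"""2D noise power spectrum with polynomial detrending, radial profile and
summary scalars.

Normalisation: ``NPS2D(fx, fy) = (dx*dy / (Nx*Ny)) * <|DFT2(residual)|^2>``
averaged over ROIs, where ``Nx, Ny`` are the ROI pixel dimensions and
``residual`` is the ROI minus its least-squares bivariate polynomial fit of
total degree <= 2. With this choice the NPS carries units HU^2 mm^2 and its
Riemann integral over the Nyquist square equals the mean residual pixel
variance exactly (Parseval), so ``noise_magnitude = sqrt(integral)`` is the
stationary noise standard deviation.

No window is applied before the DFT; detrending is the sole leakage
control. The DC bin is excluded from the radial profile and both frequency
summaries (detrending forces it to ~0; residual numerical DC would bias the
average frequency).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import ImageStack, PhantomGeometry, RoiSpec

__all__ = [
    "NoiseRoiSet",
    "NpsResult",
    "detrend_roi",
    "nps_2d",
    "radial_average",
    "nps_summary",
    "extract_noise_rois",
    "measure_nps",
]


@dataclass
class NoiseRoiSet:
    """Square pixel blocks treated as independent noise realisations."""

    blocks: list[np.ndarray]
    pixel_spacing: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("at least one ROI block is required")
        shape0 = self.blocks[0].shape
        for b in self.blocks:
            if b.ndim != 2 or b.shape != shape0:
                raise ValueError("all ROI blocks must share the same 2D shape")

    @property
    def n_rois(self) -> int:
        return len(self.blocks)

    @property
    def block_shape(self) -> tuple[int, int]:
        return self.blocks[0].shape


@dataclass
class NpsResult:
    """2D + radial NPS with frequency axes and summary scalars.

    ``nps2d`` is fftshifted (DC at the centre); ``fx`` / ``fy`` are the
    matching axes in mm^-1. ``f_peak`` / ``f_average`` are NaN when the
    spectrum is identically zero.
    """

    nps2d: np.ndarray
    fx: np.ndarray
    fy: np.ndarray
    f1d: np.ndarray = field(default_factory=lambda: np.array([]))
    nps1d: np.ndarray = field(default_factory=lambda: np.array([]))
    partial_annulus: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))
    f_peak: float = float("nan")
    f_average: float = float("nan")
    noise_magnitude: float = float("nan")


def _design_matrix(ny: int, nx: int) -> np.ndarray:
    y, x = np.mgrid[0:ny, 0:nx]
    x = x.ravel().astype(float)
    y = y.ravel().astype(float)
    return np.column_stack([np.ones_like(x), x, y, x * x, x * y, y * y])


def detrend_roi(block: np.ndarray) -> np.ndarray:
    """Residual of a least-squares bivariate polynomial (degree <= 2) fit.

    The fitted model spans the six monomials ``1, x, y, x^2, xy, y^2``; any
    block exactly in that class detrends to zeros at machine precision.
    """
    block = np.asarray(block, dtype=float)
    if block.ndim != 2 or min(block.shape) < 6:
        raise ValueError("ROI block must be 2D with both sides >= 6 pixels")
    ny, nx = block.shape
    A = _design_matrix(ny, nx)
    coef, *_ = np.linalg.lstsq(A, block.ravel(), rcond=None)
    return block - (A @ coef).reshape(ny, nx)


def nps_2d(rois: NoiseRoiSet) -> NpsResult:
    """Ensemble-averaged, detrended 2D noise power spectrum.

    Returns an :class:`NpsResult` with the fftshifted spectrum and
    frequency axes; radial profile and summaries are left unset (see
    :func:`radial_average` / :func:`nps_summary`).
    """
    ny, nx = rois.block_shape
    dx, dy = rois.pixel_spacing
    acc = np.zeros((ny, nx))
    for b in rois.blocks:
        res = detrend_roi(b)
        acc += np.abs(np.fft.fft2(res)) ** 2
    nps = dx * dy / (nx * ny) * acc / rois.n_rois
    nps = np.fft.fftshift(nps)
    fx = np.fft.fftshift(np.fft.fftfreq(nx, dx))
    fy = np.fft.fftshift(np.fft.fftfreq(ny, dy))
    return NpsResult(nps2d=nps, fx=fx, fy=fy)


def radial_average(result: NpsResult) -> NpsResult:
    """Average the 2D NPS into annular bins of the axial bin spacing.

    Bin width is the fx DFT spacing; the DC cell is excluded. Bins whose
    annulus extends beyond the inscribed Nyquist circle are flagged
    ``partial`` (they average only the cells present on the square grid).
    """
    nps = result.nps2d
    FX, FY = np.meshgrid(result.fx, result.fy)
    rho = np.hypot(FX, FY)
    df = float(result.fx[1] - result.fx[0])
    nyq = min(np.abs(result.fx).max(), np.abs(result.fy).max())
    n_bins = int(math.ceil(rho.max() / df))
    idx = np.minimum((rho / df).astype(int), n_bins - 1)
    dc = (FX == 0) & (FY == 0)
    valid = ~dc
    sums = np.bincount(idx[valid], weights=nps[valid], minlength=n_bins)
    counts = np.bincount(idx[valid], minlength=n_bins)
    with np.errstate(invalid="ignore"):
        prof = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = (np.arange(n_bins) + 0.5) * df
    keep = counts > 0
    result.f1d = centers[keep]
    result.nps1d = prof[keep]
    result.partial_annulus = (centers[keep] + df / 2) > nyq
    return result


def nps_summary(result: NpsResult) -> NpsResult:
    """Fill ``f_peak``, ``f_average`` and ``noise_magnitude`` in place.

    * ``f_peak``: argmax of the radial profile, ties broken toward the
      lowest frequency.
    * ``f_average``: NPS-weighted mean frequency of the radial profile.
    * ``noise_magnitude``: sqrt of the Riemann integral of the full 2D
      spectrum over the Nyquist square (not just the inscribed circle).

    Partial annuli (beyond the inscribed Nyquist circle) are excluded from
    both frequency summaries: their sparse corner cells would bias the
    weighted mean upward. The magnitude integral keeps the full square.
    """
    if result.f1d.size == 0:
        radial_average(result)
    dfx = float(result.fx[1] - result.fx[0])
    dfy = float(result.fy[1] - result.fy[0])
    result.noise_magnitude = float(math.sqrt(max(result.nps2d.sum() * dfx * dfy, 0.0)))
    full = ~result.partial_annulus
    f1d, nps1d = result.f1d[full], result.nps1d[full]
    total = nps1d.sum()
    if total <= 0 or f1d.size == 0:
        result.f_peak = float("nan")
        result.f_average = float("nan")
    else:
        result.f_peak = float(f1d[int(np.argmax(nps1d))])
        result.f_average = float((f1d * nps1d).sum() / total)
    return result


def extract_noise_rois(stack: ImageStack, geometry: PhantomGeometry,
                       module: str = "uniformity", roi_size_mm: float = 25.0,
                       n_per_slice: int = 8, ring_radius_mm: float = 45.0,
                       ) -> NoiseRoiSet:
    """Cut the default layout of square noise ROIs from every slice.

    ``n_per_slice`` square ROIs of ``roi_size_mm`` are placed on a ring of
    ``ring_radius_mm`` around the module centre, replicated over all
    slices; each (ROI, slice) pair counts as one realisation.
    """
    cx, cy = geometry.center_of(module)
    dx, _ = stack.pixel_spacing
    n_px = max(int(round(roi_size_mm / dx)), 6)
    blocks: list[np.ndarray] = []
    for s in range(stack.n_slices):
        for k in range(n_per_slice):
            ang = 2 * math.pi * k / n_per_slice
            ox = cx + ring_radius_mm * math.cos(ang)
            oy = cy + ring_radius_mm * math.sin(ang)
            i0 = int(round(oy / stack.pixel_spacing[1])) - n_px // 2
            j0 = int(round(ox / dx)) - n_px // 2
            if i0 < 0 or j0 < 0 or i0 + n_px > stack.shape[1] or j0 + n_px > stack.shape[2]:
                raise ValueError("noise ROI extends outside the image")
            blocks.append(stack.voxels[s, i0:i0 + n_px, j0:j0 + n_px].copy())
    return NoiseRoiSet(blocks=blocks, pixel_spacing=stack.pixel_spacing)


def measure_nps(stack: ImageStack, geometry: PhantomGeometry,
                module: str = "uniformity", **roi_kwargs) -> NpsResult:
    """End-to-end NPS measurement: ROI layout -> NPS2D -> radial -> summary."""
    rois = extract_noise_rois(stack, geometry, module, **roi_kwargs)
    return nps_summary(radial_average(nps_2d(rois)))
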