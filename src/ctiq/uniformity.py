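"""Uniformity, histogram, insert CT-number, contrast and CNR/SNR metrics.

Formula conventions (asserted literally, no invented invariances):

* ``UI = 100 * (mean_periphery - mean_center) / (mean_center + 1000)``;
  positive UI -> cupping, negative -> capping.
* ``IN = (max - min) / (max + min + 2000)`` over five ROI means.
* Michelson contrast ``c = (insert - bkg) / (insert + bkg)``;
  ``CNR = c / sd_bkg``; ``SNR = insert_mean / sd_bkg``.

The single periphery mean of the uniformity index is taken as the average
of the four periphery ROI means (each itself averaged over the slice
layout) — an interpretation, since pooling is not otherwise specified.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .core import ImageStack, InsertSpec, PhantomGeometry, RoiSpec, RoiStats, extract_roi, roi_pixels

__all__ = [
    "UniformityResult",
    "HistogramStats",
    "ContrastResult",
    "uniformity_index",
    "integral_nonuniformity",
    "measure_uniformity",
    "histogram_stats",
    "insert_hu",
    "michelson_contrast",
    "cnr_snr",
]


@dataclass(frozen=True)
class UniformityResult:
    ui: float
    integral_nonuniformity: float
    center_mean: float
    periphery_means: tuple[float, ...]
    classification: Literal["cupping", "capping", "neutral"]


@dataclass(frozen=True)
class HistogramStats:
    """Median/IQR plus population moment shape statistics.

    Skewness and kurtosis (excess, Fisher convention) are NaN-flagged for
    constant input, where the moment ratios are undefined.
    """

    median: float
    iqr: float
    kurtosis: float
    skewness: float
    bin_width: float = 1.0


@dataclass(frozen=True)
class ContrastResult:
    contrast: float
    noise_sd: float
    cnr: float
    snr: float


def uniformity_index(center: RoiStats, periphery: Sequence[RoiStats]) -> float:
    """Uniformity index from a centre ROI and >=1 periphery ROIs.

    ``100 * (mean(periphery means) - center mean) / (center mean + 1000)``.
    """
    if not periphery:
        raise ValueError("at least one periphery ROI is required")
    if center.mean == -1000.0:
        raise ValueError("uniformity index undefined: center mean is -1000 HU")
    p = float(np.mean([r.mean for r in periphery]))
    return 100.0 * (p - center.mean) / (center.mean + 1000.0)


def integral_nonuniformity(roi_means: Sequence[float]) -> float:
    """``(max - min) / (max + min + 2000)`` over the ROI means."""
    if len(roi_means) < 2:
        raise ValueError("at least two ROI means are required")
    hi, lo = max(roi_means), min(roi_means)
    denom = hi + lo + 2000.0
    if denom == 0:
        raise ValueError("integral non-uniformity undefined: max + min = -2000")
    return (hi - lo) / denom


def _classify(ui: float, tol: float = 0.0) -> Literal["cupping", "capping", "neutral"]:
    if ui > tol:
        return "cupping"
    if ui < -tol:
        return "capping"
    return "neutral"


def measure_uniformity(stack: ImageStack, geometry: PhantomGeometry,
                       module: str = "uniformity") -> UniformityResult:
    """Run the full centre + 4-periphery, multi-slice uniformity protocol.

    ROI means are first averaged over the layout's slice count (centred on
    the stack), then combined into UI and IN.
    """
    layout = geometry.uniformity_layout
    cx, cy = geometry.center_of(module)
    n = min(layout.n_slices, stack.n_slices)
    first = (stack.n_slices - n) // 2
    offsets = [(0.0, 0.0),
               (0.0, -layout.periphery_radius), (layout.periphery_radius, 0.0),
               (0.0, layout.periphery_radius), (-layout.periphery_radius, 0.0)]
    means = []
    for ox, oy in offsets:
        per_slice = [
            extract_roi(stack, RoiSpec(center=(cx + ox, cy + oy),
                                       size=layout.roi_diameter,
                                       slice_index=first + k)).mean
            for k in range(n)
        ]
        means.append(float(np.mean(per_slice)))
    center_mean, periphery = means[0], means[1:]
    ui = uniformity_index(
        RoiStats(center_mean, 0.0, 1),
        [RoiStats(m, 0.0, 1) for m in periphery],
    )
    inu = integral_nonuniformity(means)
    return UniformityResult(ui=ui, integral_nonuniformity=inu,
                            center_mean=center_mean,
                            periphery_means=tuple(periphery),
                            classification=_classify(ui))


def histogram_stats(pixels: np.ndarray, bin_width: float = 1.0) -> HistogramStats:
    """Median, IQR (linear-interpolation quantiles) and shape moments.

    Quantiles use linear interpolation between order statistics; skewness
    and excess kurtosis use population moment formulas. Constant input
    yields NaN moments (flagged undefined) with median/IQR still returned.
    """
    pixels = np.asarray(pixels, dtype=float).ravel()
    if pixels.size < 4:
        raise ValueError("need at least 4 pixels for histogram statistics")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    q25, med, q75 = np.percentile(pixels, [25, 50, 75])
    if np.ptp(pixels) == 0:
        skew = kurt = float("nan")
    else:
        skew = float(stats.skew(pixels, bias=True))
        kurt = float(stats.kurtosis(pixels, fisher=True, bias=True))
    return HistogramStats(median=float(med), iqr=float(q75 - q25),
                          kurtosis=kurt, skewness=skew, bin_width=bin_width)


def central_histogram_roi(stack: ImageStack, geometry: PhantomGeometry,
                          module: str = "uniformity", size_px: int = 128) -> np.ndarray:
    """Pixels of the square ``size_px`` ROI centred in the module's slice."""
    cx, cy = geometry.center_of(module)
    roi = RoiSpec(center=(cx, cy), size=size_px, shape="square", unit="px",
                  slice_index=stack.n_slices // 2)
    return roi_pixels(stack, roi)


def insert_hu(stack: ImageStack, insert: InsertSpec,
              phantom_center: tuple[float, float],
              slice_index: int | None = None,
              roi_diameter_px: float = 8.0) -> RoiStats:
    """CT number of an insert over a circular ROI of ``roi_diameter_px``.

    The ROI diameter is in pixels (used verbatim, not converted through a
    mm size). A warning is attached to the module logger if the ROI would
    overlap the insert edge.
    """
    dx, _ = stack.pixel_spacing
    if roi_diameter_px * dx > insert.diameter:
        import warnings

        warnings.warn(
            f"ROI ({roi_diameter_px} px = {roi_diameter_px * dx:.1f} mm) wider "
            f"than insert {insert.material!r} ({insert.diameter} mm)",
            stacklevel=2,
        )
    idx = stack.n_slices // 2 if slice_index is None else slice_index
    center = (phantom_center[0] + insert.center[0], phantom_center[1] + insert.center[1])
    return extract_roi(stack, RoiSpec(center=center, size=roi_diameter_px,
                                      unit="px", slice_index=idx))


def michelson_contrast(insert: RoiStats, bkg: RoiStats) -> float:
    """Michelson contrast ``(insert - bkg) / (insert + bkg)`` of ROI means."""
    denom = insert.mean + bkg.mean
    if denom == 0:
        raise ValueError(
            "Michelson contrast undefined: insert and background means sum to zero"
        )
    return (insert.mean - bkg.mean) / denom


def cnr_snr(insert: RoiStats, bkg: RoiStats) -> ContrastResult:
    """Contrast, CNR (= contrast / background sd) and SNR (= mean / sd)."""
    if bkg.sd <= 0:
        raise ValueError("background sd must be positive for CNR/SNR")
    c = michelson_contrast(insert, bkg)
    return ContrastResult(contrast=c, noise_sd=bkg.sd,
                          cnr=c / bkg.sd, snr=insert.mean / bkg.sd)
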