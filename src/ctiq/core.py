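"""Domain types and ROI extraction shared by all metric stages.

Conventions
-----------
* Pixel indices are 0-based, ``voxels[slice, row, col]``.
* Physical in-plane coordinates ``(x, y)`` are measured in mm from the
  centre of the top-left pixel; ``x`` runs along columns, ``y`` along rows.
* Standard deviations are population standard deviations (divide by N)
  throughout the package, so CNR/SNR and NPS normalisations stay mutually
  consistent.
* ROI membership is decided by the pixel *centre* lying inside the shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

__all__ = [
    "ProtocolMeta",
    "ImageStack",
    "InsertSpec",
    "RampSpec",
    "PhantomGeometry",
    "UniformityLayout",
    "RoiSpec",
    "RoiStats",
    "extract_roi",
    "roi_pixels",
    "locate_center",
]


@dataclass(frozen=True)
class ProtocolMeta:
    """Descriptive acquisition metadata.

    Purely informational: no metric computation reads ``kv``, ``mas`` or
    ``ctdi_vol``.
    """

    protocol_id: str = ""
    kv: float | None = None
    mas: float | None = None
    collimation: str = ""
    recon_kernel: str = ""
    ctdi_vol: float | None = None


@dataclass
class ImageStack:
    """A calibrated axial CT stack.

    Parameters
    ----------
    voxels
        3D array ``(n_slices, n_rows, n_cols)`` of CT numbers in HU.
        Rescale slope/intercept must already have been applied.
    pixel_spacing
        In-plane spacing ``(dx, dy)`` in mm (column spacing, row spacing).
    z_positions
        Per-slice axial position in mm, strictly monotonic.
    slice_thickness_nominal
        Nominal reconstructed slice thickness in mm.
    meta
        Descriptive protocol metadata.
    """

    voxels: np.ndarray
    pixel_spacing: tuple[float, float]
    z_positions: np.ndarray
    slice_thickness_nominal: float = 1.0
    meta: ProtocolMeta = field(default_factory=ProtocolMeta)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array (slice, row, col)")
        dx, dy = self.pixel_spacing
        if dx <= 0 or dy <= 0:
            raise ValueError("pixel spacing must be positive")
        self.z_positions = np.asarray(self.z_positions, dtype=float)
        if self.z_positions.shape != (self.voxels.shape[0],):
            raise ValueError("z_positions must have one entry per slice")
        dz = np.diff(self.z_positions)
        if dz.size and not (np.all(dz > 0) or np.all(dz < 0)):
            raise ValueError("z_positions must be strictly monotonic")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def slice_nearest(self, z: float) -> int:
        """Index of the slice closest to axial position ``z`` (mm)."""
        return int(np.argmin(np.abs(self.z_positions - z)))

    def xy_grid(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical pixel-centre coordinate grids ``(x, y)`` in mm."""
        dx, dy = self.pixel_spacing
        _, nrow, ncol = self.voxels.shape
        x = np.arange(ncol) * dx
        y = np.arange(nrow) * dy
        return np.meshgrid(x, y)


@dataclass(frozen=True)
class InsertSpec:
    """A circular material insert, positioned relative to the phantom centre."""

    material: str
    center: tuple[float, float]  # (x, y) mm offset from phantom centre
    diameter: float  # mm
    nominal_hu: float

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("insert diameter must be positive")


@dataclass(frozen=True)
class RampSpec:
    """A tilted wire ramp for slice-thickness measurement.

    ``direction`` is the in-plane unit vector along which the ramp runs;
    ``tilt_deg`` is the angle between the wire and the axial plane.
    """

    center: tuple[float, float]  # (x, y) mm offset from phantom centre
    direction: tuple[float, float] = (1.0, 0.0)
    tilt_deg: float = 23.0

    def __post_init__(self) -> None:
        if not (0.0 < self.tilt_deg < 90.0):
            raise ValueError("tilt angle must be in (0, 90) degrees")
        n = float(np.hypot(*self.direction))
        if n == 0:
            raise ValueError("direction must be a nonzero vector")
        object.__setattr__(self, "direction", (self.direction[0] / n, self.direction[1] / n))


@dataclass(frozen=True)
class UniformityLayout:
    """Centre + periphery ROI layout for the uniformity module.

    Four periphery ROIs (top, right, bottom, left) at ``periphery_radius``
    from the phantom centre, each of ``roi_diameter``, evaluated over
    ``n_slices`` slices.
    """

    periphery_radius: float = 55.0  # mm
    roi_diameter: float = 20.0  # mm
    n_slices: int = 13


@dataclass
class PhantomGeometry:
    """Module / insert / ramp layout of a QA phantom, in mm.

    ``phantom_center`` maps module id to the in-plane phantom centre;
    ``module_z`` maps module id to its axial (z_min, z_max) range.
    """

    phantom_center: Mapping[str, tuple[float, float]]
    module_z: Mapping[str, tuple[float, float]]
    phantom_radius: float = 75.0
    inserts: Sequence[InsertSpec] = ()
    ramps: Sequence[RampSpec] = ()
    uniformity_layout: UniformityLayout = field(default_factory=UniformityLayout)

    def __post_init__(self) -> None:
        for ins in self.inserts:
            r = np.hypot(*ins.center) + ins.diameter / 2
            if r > self.phantom_radius:
                raise ValueError(f"insert {ins.material!r} lies outside the phantom radius")

    def center_of(self, module: str) -> tuple[float, float]:
        return tuple(self.phantom_center[module])

    def insert(self, material: str) -> InsertSpec:
        for ins in self.inserts:
            if ins.material == material:
                return ins
        raise KeyError(f"no insert named {material!r}")


@dataclass(frozen=True)
class RoiSpec:
    """A circular or square region of interest on one slice.

    ``size`` is the diameter (circle) or side length (square); ``unit``
    states whether ``size`` is in mm or pixels. Pixel-unit sizes are used
    verbatim; mm sizes are converted with the slice's own spacing.
    """

    center: tuple[float, float]  # (x, y) in mm
    size: float
    shape: Literal["circle", "square"] = "circle"
    unit: Literal["mm", "px"] = "mm"
    slice_index: int = 0

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError("ROI size must be positive")


@dataclass(frozen=True)
class RoiStats:
    """Mean / population-sd summary of an ROI."""

    mean: float
    sd: float
    n_pixels: int

    def __post_init__(self) -> None:
        if self.n_pixels < 1:
            raise ValueError("ROI must contain at least one pixel")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


def _roi_mask(stack: ImageStack, roi: RoiSpec) -> np.ndarray:
    dx, dy = stack.pixel_spacing
    cx, cy = roi.center
    if roi.unit == "px":
        # pixel-unit sizes apply in pixel space; use column spacing for x,
        # row spacing for y so a "d px" disc is d pixels across either axis
        half_x = roi.size / 2 * dx
        half_y = roi.size / 2 * dy
    else:
        half_x = half_y = roi.size / 2
    x, y = stack.xy_grid()
    if roi.shape == "circle":
        mask = ((x - cx) / half_x) ** 2 + ((y - cy) / half_y) ** 2 <= 1.0
    elif roi.shape == "square":
        mask = (np.abs(x - cx) <= half_x) & (np.abs(y - cy) <= half_y)
    else:  # pragma: no cover - dataclass Literal guards this
        raise ValueError(f"unknown ROI shape {roi.shape!r}")
    return mask


def roi_pixels(stack: ImageStack, roi: RoiSpec) -> np.ndarray:
    """Return the 1D array of HU values whose pixel centres fall in ``roi``.

    Raises
    ------
    ValueError
        If the ROI extends beyond the image bounds or selects no pixels.
    """
    nslices, nrow, ncol = stack.shape
    if not (0 <= roi.slice_index < nslices):
        raise ValueError(f"slice index {roi.slice_index} out of range")
    dx, dy = stack.pixel_spacing
    cx, cy = roi.center
    half = roi.size / 2 * (dx if roi.unit == "px" else 1.0)
    half_y = roi.size / 2 * (dy if roi.unit == "px" else 1.0)
    if (cx - half < -dx / 2 or cx + half > (ncol - 0.5) * dx
            or cy - half_y < -dy / 2 or cy + half_y > (nrow - 0.5) * dy):
        raise ValueError("ROI extends outside image bounds")
    mask = _roi_mask(stack, roi)
    vals = stack.voxels[roi.slice_index][mask]
    if vals.size == 0:
        raise ValueError("ROI selected zero pixels")
    return vals


def extract_roi(stack: ImageStack, roi: RoiSpec) -> RoiStats:
    """Mean and population standard deviation over an ROI.

    The mean and sd are computed over pixels whose centres fall inside the
    ROI shape; the sd divides by N (population convention).
    """
    vals = roi_pixels(stack, roi)
    return RoiStats(mean=float(vals.mean()), sd=float(vals.std(ddof=0)), n_pixels=int(vals.size))


def locate_center(stack: ImageStack, slice_index: int = 0,
                  threshold_hu: float = -500.0) -> tuple[float, float]:
    """Centroid (x, y) in mm of the thresholded phantom foreground.

    An optional alignment refinement: geometry is normally supplied by
    config, and this is used only when the config does not pin the centre.

    Raises
    ------
    ValueError
        If no pixel exceeds ``threshold_hu`` (empty foreground).
    """
    img = stack.voxels[slice_index]
    mask = img > threshold_hu
    if not mask.any():
        raise ValueError("empty foreground: no pixels above threshold")
    x, y = stack.xy_grid()
    return float(x[mask].mean()), float(y[mask].mean())
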