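"""Non-prewhitening detectability index, protocol comparisons, and
HU-vs-attenuation linearity.

The detectability index follows the NPW matched-filter form

    d'^2 = [ II W^2 TTF^2 du dv ]^2  /  [ II W^2 TTF^2 NPS du dv ]

with all integrals taken as Riemann sums on the common NPS frequency grid.
``W`` is the analytic Fourier transform of a uniform disc (first-order
Bessel form) — not a rasterised DFT, which exists only as a test oracle.
TTF values beyond the last computed frequency are extrapolated as zero
(conservative) and flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import special, stats

from .nps import NpsResult
from .resolution import TtfResult

__all__ = [
    "TaskFunction",
    "DetectabilityResult",
    "ComparisonResult",
    "LinearityResult",
    "task_function",
    "detectability_index",
    "compare_dprime",
    "hu_linearity",
]


@dataclass
class TaskFunction:
    """Frequency-domain template of a uniform circular detection task."""

    diameter_mm: float
    contrast_hu: float
    w: np.ndarray  # values on the (v, u) grid, HU mm^2
    u: np.ndarray  # frequency axis mm^-1
    v: np.ndarray


@dataclass(frozen=True)
class DetectabilityResult:
    dprime: float
    numerator: float  # II W^2 TTF^2
    denominator: float  # II W^2 TTF^2 NPS
    infinite: bool = False  # zero-noise sentinel
    ttf_truncated: bool = False  # TTF extrapolated as 0 beyond its range


@dataclass(frozen=True)
class ComparisonResult:
    """Difference of two labelled d' values, reference first."""

    label_a: str
    label_b: str
    dprime_a: float
    dprime_b: float

    @property
    def difference(self) -> float:
        return self.dprime_a - self.dprime_b

    @property
    def percent(self) -> float:
        if self.dprime_a == 0:
            raise ZeroDivisionError("percent difference undefined: reference d' is zero")
        return 100.0 * (self.dprime_a - self.dprime_b) / self.dprime_a


@dataclass(frozen=True)
class LinearityResult:
    slope: float  # HU per cm^-1
    intercept: float  # HU
    r_squared: float
    pairs: tuple[tuple[float, float], ...]


def disc_transform(rho: np.ndarray, diameter_mm: float, contrast_hu: float) -> np.ndarray:
    """Analytic FT of a uniform disc: ``C pi r^2 * 2 J1(x)/x``, x = 2 pi r rho."""
    r = diameter_mm / 2.0
    x = 2.0 * math.pi * r * np.asarray(rho, dtype=float)
    out = np.full(x.shape, contrast_hu * math.pi * r * r)
    nz = x != 0
    out[nz] *= 2.0 * special.j1(x[nz]) / x[nz]
    return out


def task_function(diameter_mm: float, contrast_hu: float,
                  u: np.ndarray, v: np.ndarray) -> TaskFunction:
    """Circular task function evaluated on a 2D frequency grid.

    ``W(0,0) = C * pi * (d/2)^2`` and ``W`` depends only on the radial
    frequency. A warning is raised when the grid Nyquist lies below the
    first zero of the disc transform (severe truncation).
    """
    if diameter_mm <= 0:
        raise ValueError("task diameter must be positive")
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    U, V = np.meshgrid(u, v)
    w = disc_transform(np.hypot(U, V), diameter_mm, contrast_hu)
    first_zero = 1.2196698912665045 / (diameter_mm / 2.0) / 2.0  # j1 root / (2 pi r) * 2pi
    nyq = min(np.abs(u).max(), np.abs(v).max())
    if nyq < first_zero:
        import warnings

        warnings.warn("frequency grid Nyquist below the first task-function zero; "
                      "integrals will be strongly truncated", stacklevel=2)
    return TaskFunction(diameter_mm=diameter_mm, contrast_hu=contrast_hu,
                        w=w, u=u, v=v)


def _ttf_on_grid(ttf: TtfResult | None, u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, bool]:
    U, V = np.meshgrid(u, v)
    rho = np.hypot(U, V)
    if ttf is None:
        return np.ones_like(rho), False
    truncated = bool(rho.max() > ttf.frequency.max())
    vals = np.interp(rho.ravel(), ttf.frequency, ttf.ttf, right=0.0).reshape(rho.shape)
    return vals, truncated


def detectability_index(ttf: TtfResult | None, nps: NpsResult,
                        task: TaskFunction) -> DetectabilityResult:
    """NPW d' from a TTF curve, a 2D NPS and a task function.

    The TTF is interpolated radially onto the NPS grid (``ttf=None`` means
    an ideal system, TTF ≡ 1). A zero denominator (no noise anywhere the
    task has support) is flagged as an infinite-d' sentinel rather than a
    number.
    """
    if not np.array_equal(task.u, nps.fx) or not np.array_equal(task.v, nps.fy):
        raise ValueError("task function grid does not match the NPS grid")
    du = float(nps.fx[1] - nps.fx[0])
    dv = float(nps.fy[1] - nps.fy[0])
    t2, truncated = _ttf_on_grid(ttf, nps.fx, nps.fy)
    w2t2 = task.w**2 * t2**2
    num = float(w2t2.sum() * du * dv)
    den = float((w2t2 * nps.nps2d).sum() * du * dv)
    if den == 0:
        if num == 0:  # zero-contrast task: d' = 0 by convention
            return DetectabilityResult(0.0, 0.0, 0.0, infinite=False,
                                       ttf_truncated=truncated)
        return DetectabilityResult(float("inf"), num, 0.0, infinite=True,
                                   ttf_truncated=truncated)
    return DetectabilityResult(dprime=math.sqrt(num * num / den),
                               numerator=num, denominator=den,
                               ttf_truncated=truncated)


def compare_dprime(label_a: str, dprime_a: float,
                   label_b: str, dprime_b: float) -> ComparisonResult:
    """Labelled d' comparison; the first (reference) value is the
    denominator of the percent relative difference."""
    for name, val in ((label_a, dprime_a), (label_b, dprime_b)):
        if not math.isfinite(val):
            raise ValueError(f"d' for {name!r} is not finite")
    return ComparisonResult(label_a=label_a, label_b=label_b,
                            dprime_a=float(dprime_a), dprime_b=float(dprime_b))


def hu_linearity(pairs: Sequence[tuple[float, float]]) -> LinearityResult:
    """OLS regression of measured HU on linear attenuation coefficient.

    ``pairs`` are ``(HU, mu)`` with mu in cm^-1, supplied by the caller
    (spectrum modelling is out of scope). Returns slope, intercept and R^2.
    """
    if len(pairs) < 3:
        raise ValueError("need at least three (HU, mu) pairs")
    hu = np.array([p[0] for p in pairs], dtype=float)
    mu = np.array([p[1] for p in pairs], dtype=float)
    if np.ptp(mu) == 0:
        raise ValueError("degenerate design: all attenuation coefficients identical")
    res = stats.linregress(mu, hu)
    return LinearityResult(slope=float(res.slope), intercept=float(res.intercept),
                           r_squared=float(res.rvalue**2),
                           pairs=tuple((float(a), float(b)) for a, b in pairs))
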