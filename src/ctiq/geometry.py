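"""Default Catphan-style geometry and YAML geometry configuration.

The layout mirrors the three modules the analysis uses: a sensitometry
module with seven material inserts and four tilted wire ramps
(``sensitometry``), a homogeneous uniformity module (``uniformity``), and a
low-contrast module (``low_contrast``). All positions are in mm; insert and
ramp centres are offsets from the phantom centre of their module.

Geometry is supplied explicitly (phantom alignment is assumed done, as with
laser-aligned acquisitions); :func:`ctiq.core.locate_center` exists only as
an optional refinement.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Mapping

import yaml

from .core import InsertSpec, PhantomGeometry, RampSpec, UniformityLayout

__all__ = [
    "SENSITOMETRY",
    "UNIFORMITY",
    "LOW_CONTRAST",
    "default_geometry",
    "load_geometry",
]

SENSITOMETRY = "sensitometry"
UNIFORMITY = "uniformity"
LOW_CONTRAST = "low_contrast"

#: Nominal insert HU of the sensitometry module materials.
DEFAULT_INSERT_HU: Mapping[str, float] = {
    "air": -1000.0,
    "pmp": -200.0,
    "ldpe": -100.0,
    "polystyrene": -35.0,
    "acrylic": 120.0,
    "delrin": 340.0,
    "teflon": 990.0,
}

_INSERT_RADIUS_MM = 58.4  # ring radius of the sensitometry inserts
_INSERT_DIAMETER_MM = 12.2


def default_geometry(fov_mm: float = 160.0) -> PhantomGeometry:
    """Catphan-style geometry centred in a square field of view.

    Parameters
    ----------
    fov_mm
        Reconstructed field-of-view side length; the phantom centre is at
        ``(fov/2, fov/2)`` for all modules.
    """
    c = (fov_mm / 2.0, fov_mm / 2.0)
    inserts = []
    materials = list(DEFAULT_INSERT_HU)
    for k, mat in enumerate(materials):
        ang = 2.0 * math.pi * k / 8.0  # 8 slots, one left vacant
        inserts.append(InsertSpec(
            material=mat,
            center=(_INSERT_RADIUS_MM * math.cos(ang), _INSERT_RADIUS_MM * math.sin(ang)),
            diameter=_INSERT_DIAMETER_MM,
            nominal_hu=DEFAULT_INSERT_HU[mat],
        ))
    ramps = [
        RampSpec(center=(0.0, -25.0), direction=(1.0, 0.0)),
        RampSpec(center=(0.0, 25.0), direction=(1.0, 0.0)),
        RampSpec(center=(-25.0, 0.0), direction=(0.0, 1.0)),
        RampSpec(center=(25.0, 0.0), direction=(0.0, 1.0)),
    ]
    return PhantomGeometry(
        phantom_center={SENSITOMETRY: c, UNIFORMITY: c, LOW_CONTRAST: c},
        module_z={SENSITOMETRY: (-10.0, 10.0), UNIFORMITY: (30.0, 70.0),
                  LOW_CONTRAST: (90.0, 130.0)},
        phantom_radius=75.0,
        inserts=inserts,
        ramps=ramps,
        uniformity_layout=UniformityLayout(),
    )


def load_geometry(path: str | Path) -> PhantomGeometry:
    """Load a phantom geometry from a YAML config file.

    Expected keys: ``phantom_center`` (module -> [x, y]), ``module_z``
    (module -> [zmin, zmax]), ``phantom_radius``, ``inserts`` (list of
    {material, center, diameter, nominal_hu}), ``ramps`` (list of {center,
    direction, tilt_deg}), ``uniformity_layout`` ({periphery_radius,
    roi_diameter, n_slices}).
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    inserts = [
        InsertSpec(material=d["material"], center=tuple(d["center"]),
                   diameter=float(d["diameter"]), nominal_hu=float(d["nominal_hu"]))
        for d in cfg.get("inserts", [])
    ]
    ramps = [
        RampSpec(center=tuple(d["center"]),
                 direction=tuple(d.get("direction", (1.0, 0.0))),
                 tilt_deg=float(d.get("tilt_deg", 23.0)))
        for d in cfg.get("ramps", [])
    ]
    ul = cfg.get("uniformity_layout", {})
    layout = UniformityLayout(
        periphery_radius=float(ul.get("periphery_radius", 55.0)),
        roi_diameter=float(ul.get("roi_diameter", 20.0)),
        n_slices=int(ul.get("n_slices", 13)),
    )
    return PhantomGeometry(
        phantom_center={k: tuple(v) for k, v in cfg["phantom_center"].items()},
        module_z={k: tuple(v) for k, v in cfg["module_z"].items()},
        phantom_radius=float(cfg.get("phantom_radius", 75.0)),
        inserts=inserts,
        ramps=ramps,
        uniformity_layout=layout,
    )
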