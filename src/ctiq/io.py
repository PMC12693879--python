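"""Reading and writing axial image series.

Two on-disk forms are supported:

* **Flat text series** — one JSON header per slice plus a whitespace text
  matrix of stored pixel values. This is the format the simulator writes
  and the test harness reads; it round-trips integer-storable HU exactly.
* **DICOM** — read via :mod:`pydicom` when it is installed (optional
  dependency); pixel data, ``PixelSpacing``, ``RescaleSlope``/``Intercept``
  and ``ImagePositionPatient``/``SliceLocation`` are honoured.

In both cases :func:`load_series` returns voxels already rescaled to HU and
slices sorted ascending in z.
"""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .core import ImageStack, ProtocolMeta

__all__ = ["load_series", "write_series"]

_SPACING_TOL = 1e-6


def _load_flat_slice(path: Path) -> dict:
    with open(path) as fh:
        header = json.load(fh)
    required = ("pixel_spacing", "rescale_slope", "rescale_intercept", "slice_location")
    for key in required:
        if key not in header:
            raise ValueError(f"{path.name}: missing required tag {key!r}")
    pix_file = path.parent / header["pixels"]
    stored = np.loadtxt(pix_file, ndmin=2)
    header["_stored"] = stored
    return header


def _load_dicom_slice(path: Path) -> dict:
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ImportError(
            f"{path} is not a flat-text slice header and pydicom is not "
            "installed; install the 'dicom' extra to read DICOM series"
        ) from exc
    ds = pydicom.dcmread(str(path))
    if not hasattr(ds, "PixelSpacing"):
        raise ValueError(f"{path.name}: missing PixelSpacing tag")
    z = None
    if getattr(ds, "ImagePositionPatient", None) is not None:
        z = float(ds.ImagePositionPatient[2])
    elif getattr(ds, "SliceLocation", None) is not None:
        z = float(ds.SliceLocation)
    else:
        raise ValueError(f"{path.name}: missing slice z position tag")
    return {
        # DICOM PixelSpacing is (row, col); our convention is (dx, dy)
        "pixel_spacing": [float(ds.PixelSpacing[1]), float(ds.PixelSpacing[0])],
        "rescale_slope": float(getattr(ds, "RescaleSlope", 1.0)),
        "rescale_intercept": float(getattr(ds, "RescaleIntercept", 0.0)),
        "slice_location": z,
        "slice_thickness": float(getattr(ds, "SliceThickness", 1.0)),
        "_stored": ds.pixel_array.astype(float),
    }


def load_series(paths: Iterable[str | os.PathLike]) -> ImageStack:
    """Load one axial series from per-slice files.

    Parameters
    ----------
    paths
        Slice files forming one series: flat-text JSON headers, or DICOM
        files when pydicom is available. A directory may also be given, in
        which case every ``*.json`` file inside is used.

    Returns
    -------
    ImageStack
        Voxels in HU (rescale applied), slices sorted ascending in z.

    Raises
    ------
    ValueError
        On inconsistent pixel spacing or missing mandatory tags.
    """
    paths = [Path(p) for p in paths]
    if len(paths) == 1 and paths[0].is_dir():
        candidates = sorted(paths[0].glob("*.json"))
        paths = []
        for p in candidates:  # skip sidecars (e.g. ground-truth files)
            try:
                with open(p) as fh:
                    if "pixels" in json.load(fh):
                        paths.append(p)
            except (json.JSONDecodeError, OSError):
                continue
    if not paths:
        raise ValueError("no slice files given")

    headers = []
    for p in paths:
        p = Path(p)
        if p.suffix.lower() == ".json":
            headers.append(_load_flat_slice(p))
        else:
            headers.append(_load_dicom_slice(p))

    spacing0 = np.asarray(headers[0]["pixel_spacing"], dtype=float)
    for h in headers[1:]:
        if not np.allclose(h["pixel_spacing"], spacing0, atol=_SPACING_TOL):
            raise ValueError("inconsistent spacing across series slices")

    headers.sort(key=lambda h: h["slice_location"])
    hu = np.stack([
        h["_stored"] * h["rescale_slope"] + h["rescale_intercept"] for h in headers
    ])
    z = np.array([h["slice_location"] for h in headers], dtype=float)
    meta_raw = headers[0].get("meta", {}) or {}
    meta = ProtocolMeta(
        protocol_id=meta_raw.get("protocol_id", ""),
        kv=meta_raw.get("kv"),
        mas=meta_raw.get("mas"),
        collimation=meta_raw.get("collimation", ""),
        recon_kernel=meta_raw.get("recon_kernel", ""),
        ctdi_vol=meta_raw.get("ctdi_vol"),
    )
    return ImageStack(
        voxels=hu,
        pixel_spacing=(float(spacing0[0]), float(spacing0[1])),
        z_positions=z,
        slice_thickness_nominal=float(headers[0].get("slice_thickness", 1.0)),
        meta=meta,
    )


def write_series(stack: ImageStack, out_dir: str | os.PathLike, *,
                 rescale_slope: float = 1.0, rescale_intercept: float = -1024.0,
                 prefix: str = "slice") -> list[Path]:
    """Write a stack as a flat-text series (one JSON header + txt per slice).

    Stored values are ``(HU - intercept) / slope``; integer-storable values
    survive a round trip through :func:`load_series` bit-exactly.

    Returns the list of written header paths.
    """
    if rescale_slope == 0:
        raise ValueError("rescale slope must be nonzero")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = stack.meta
    written = []
    for i in range(stack.n_slices):
        stored = (stack.voxels[i] - rescale_intercept) / rescale_slope
        pix_name = f"{prefix}_{i:04d}.txt"
        if np.allclose(stored, np.round(stored), atol=1e-9):
            np.savetxt(out / pix_name, np.round(stored).astype(np.int64), fmt="%d")
        else:
            np.savetxt(out / pix_name, stored, fmt="%.10g")
        header = {
            "pixel_spacing": list(stack.pixel_spacing),
            "rescale_slope": rescale_slope,
            "rescale_intercept": rescale_intercept,
            "slice_location": float(stack.z_positions[i]),
            "slice_thickness": stack.slice_thickness_nominal,
            "pixels": pix_name,
            "meta": {
                "protocol_id": meta.protocol_id,
                "kv": meta.kv,
                "mas": meta.mas,
                "collimation": meta.collimation,
                "recon_kernel": meta.recon_kernel,
                "ctdi_vol": meta.ctdi_vol,
            },
        }
        hdr_path = out / f"{prefix}_{i:04d}.json"
        with open(hdr_path, "w") as fh:
            json.dump(header, fh, indent=1)
        written.append(hdr_path)
    return written
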