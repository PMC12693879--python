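"""Reference detectability values used as inputs to the protocol-comparison
workflow.

These are externally published per-protocol d' values for the sensitometry
inserts of a Catphan600 measured on a clinical photon-counting CT scanner;
they serve as worked-example inputs for :func:`ctiq.detectability.compare_dprime`
(the comparison arithmetic itself is what this package computes). Bracketed
nominal contrasts (HU vs background) accompany each material.
"""

from __future__ import annotations

__all__ = ["DPRIME_TABLE", "MATERIAL_CONTRAST_HU"]

#: Nominal insert contrast against the phantom background, HU.
MATERIAL_CONTRAST_HU: dict[str, float] = {
    "acrylic": 30.0,
    "polystyrene": -120.0,
    "air": -1065.0,
    "ldpe": -160.0,
    "pmp": -250.0,
    "teflon": 800.0,
    "delrin": 240.0,
}

#: Published d' per (protocol label -> material -> value).
DPRIME_TABLE: dict[str, dict[str, float]] = {
    "Hr60 (44.32 mGy), 1 mm": {
        "acrylic": 11.38, "polystyrene": 56.25, "air": 467.54,
        "ldpe": 80.92, "pmp": 121.37, "teflon": 372.59, "delrin": 106.23,
    },
    "UHR Hr72 (5.12 mGy)": {
        "acrylic": 3.38, "polystyrene": 15.21, "air": 144.45,
        "ldpe": 22.41, "pmp": 32.16, "teflon": 108.24, "delrin": 29.74,
    },
    "UHR Hr72 (13.5 mGy)": {
        "acrylic": 6.13, "polystyrene": 35.36, "air": 318.26,
        "ldpe": 51.16, "pmp": 76.17, "teflon": 230.28, "delrin": 66.19,
    },
    "Hr72 (5.04 mGy), 0.4 mm": {
        "acrylic": 3.93, "polystyrene": 29.07, "air": 265.10,
        "ldpe": 42.45, "pmp": 62.62, "teflon": 200.78, "delrin": 53.22,
    },
    "Hr72 (13.3 mGy), 0.4 mm": {
        "acrylic": 10.59, "polystyrene": 44.06, "air": 412.75,
        "ldpe": 65.58, "pmp": 100.39, "teflon": 294.66, "delrin": 88.62,
    },
    "Br40 (2.36 mGy), 1 mm": {
        "acrylic": 4.74, "polystyrene": 35.29, "air": 258.53,
        "ldpe": 51.39, "pmp": 72.00, "teflon": 205.56, "delrin": 65.80,
    },
    "Br40 (3.44 mGy) Flash, 1 mm": {
        "acrylic": 5.06, "polystyrene": 41.12, "air": 322.64,
        "ldpe": 60.77, "pmp": 88.84, "teflon": 261.07, "delrin": 73.76,
    },
    "Br40 (2.36 mGy) Flash, 1 mm": {
        "acrylic": 4.25, "polystyrene": 28.24, "air": 220.34,
        "ldpe": 41.14, "pmp": 59.75, "teflon": 163.62, "delrin": 52.30,
    },
    "UHR Br40 (11.6 mGy)": {
        "acrylic": 6.66, "polystyrene": 39.90, "air": 318.37,
        "ldpe": 57.59, "pmp": 84.57, "teflon": 248.73, "delrin": 76.52,
    },
    "Br40 (11.6 mGy), 0.4 mm": {
        "acrylic": 10.62, "polystyrene": 59.29, "air": 457.19,
        "ldpe": 83.97, "pmp": 124.45, "teflon": 360.21, "delrin": 108.81,
    },
}
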