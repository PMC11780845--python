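"""Stain vocabulary and per-stain rendering/analysis defaults.

Four stains are supported for residual-nucleus detection in decellularized
extracellular matrix (dECM) sections:

* HE (hematoxylin-eosin): nuclei blue-purple, ECM red/pink; dust blue-black.
* Feulgen reaction: DNA-specific, nuclei red/purplish-red; dust black-gray.
* Acetocarmine: nuclei red, ECM lightly stained; dust black-gray.
* DAPI: fluorescence, nuclei bright blue on a dark field; dust invisible
  (no DNA, hence no probe binding above the background glow).
"""

from __future__ import annotations

from enum import Enum

# ITU-R 601 luminance weights, the fixed "luminance" channel convention.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


class StainMethod(str, Enum):
    """The four staining methods used for residual-nucleus QC."""

    HE = "he"
    FEULGEN = "feulgen"
    ACETOCARMINE = "acetocarmine"
    DAPI = "dapi"

    @property
    def is_fluorescent(self) -> bool:
        return self is StainMethod.DAPI

    @classmethod
    def parse(cls, value: "StainMethod | str") -> "StainMethod":
        if isinstance(value, cls):
            return value
        return cls(str(value).strip().lower())


#: Brightfield stains (objects darker than the matrix); DAPI is the lone
#: dark-field stain (objects brighter than background).
BRIGHTFIELD_STAINS = (StainMethod.HE, StainMethod.FEULGEN, StainMethod.ACETOCARMINE)


def luminance(rgb):
    """Luminance of an (..., 3) RGB array with the fixed 0.299/0.587/0.114 weights."""
    r, g, b = LUMA_WEIGHTS
    return r * rgb[..., 0] + g * rgb[..., 1] + b * rgb[..., 2]


# Unit hue directions (normalized so luminance(dir) == 1); multiplying by a
# target gray level yields an RGB triple whose luminance equals that level.
def _hue(r: float, g: float, b: float) -> tuple[float, float, float]:
    lum = LUMA_WEIGHTS[0] * r + LUMA_WEIGHTS[1] * g + LUMA_WEIGHTS[2] * b
    return (r / lum, g / lum, b / lum)


#: Per-stain qualitative color model: hue directions for the nucleus, dust and
#: ECM compartments plus background / ECM luminance targets (0-255 scale).
#: DAPI is single-channel; hues are unused there.
STAIN_PALETTES: dict[StainMethod, dict] = {
    StainMethod.HE: {
        "nucleus_hue": _hue(0.50, 0.40, 0.90),   # blue-purple hematoxylin
        "dust_hue": _hue(0.85, 0.90, 1.00),      # blue-black particulate
        "ecm_hue": _hue(1.00, 0.75, 0.78),       # eosin pink-red
        "background_luminance": 238.0,
        "ecm_luminance": 205.0,
    },
    StainMethod.FEULGEN: {
        "nucleus_hue": _hue(0.90, 0.35, 0.55),   # purplish-red Schiff product
        "dust_hue": _hue(1.00, 1.00, 1.00),      # neutral black-gray
        "ecm_hue": _hue(1.00, 0.82, 0.84),       # faint pink matrix
        "background_luminance": 240.0,
        "ecm_luminance": 210.0,
    },
    StainMethod.ACETOCARMINE: {
        "nucleus_hue": _hue(0.95, 0.40, 0.45),   # carmine red
        "dust_hue": _hue(1.00, 1.00, 1.00),
        "ecm_hue": _hue(1.00, 0.90, 0.90),       # lightly stained matrix
        "background_luminance": 240.0,
        "ecm_luminance": 218.0,
    },
    StainMethod.DAPI: {
        "nucleus_hue": _hue(0.30, 0.40, 1.80),   # only used if rendered as RGB
        "dust_hue": _hue(1.00, 1.00, 1.00),
        "ecm_hue": _hue(0.60, 0.70, 1.30),
        "background_luminance": 22.0,            # residual probe glow
        "ecm_luminance": 30.0,
    },
}
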