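"""Masked-region colorimetry for body-colour quantification.

Converts 8-bit sRGB pixels through XYZ into CIELAB (D65 reference white),
averages L*, a*, b* over a binary region mask, and derives the cylindrical
attributes hue angle h (degrees) and chroma C from the region-mean opponent
values.  This is the measurement stage of the pipeline: one photograph plus
one mask yields one :class:`ColourAttributes` record.

Conventions
-----------
* sRGB per IEC 61966-2-1: two-piece transfer function (threshold 0.04045,
  exponent 2.4) and the 4-digit D65 / 2 degree observer primaries matrix.
  The reference white is taken from the matrix row sums so that the pixel
  (255, 255, 255) maps to exactly L* = 100, a* = b* = 0.
* CIELAB per CIE 1976: two-branch cube-root function with delta = 6/29 and
  the 4/29 offset.
* Averaging happens in Lab space, pixel by pixel, after conversion; hue and
  chroma are computed from the averaged a*, b*, not averaged per pixel.
* Mask inclusion rule: grey value strictly greater than 127 on a 0-255 scale.
* Hue is reported in degrees in [0, 360); a neutral region (C = 0) reports
  h = 0 by convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

__all__ = [
    "SRGB_TO_XYZ",
    "XYZ_TO_SRGB",
    "D65_WHITE",
    "RGBImage",
    "RegionMask",
    "XYZColour",
    "LabColour",
    "ColourAttributes",
    "load_mask",
    "srgb_to_xyz",
    "xyz_to_lab",
    "lab_to_xyz",
    "mean_region_colour",
    "hue_chroma",
    "attributes_for_image",
]

# IEC 61966-2-1 linear-RGB -> XYZ matrix, D65 / 2 degree observer.
SRGB_TO_XYZ = np.array(
    [
        [0.4124, 0.3576, 0.1805],
        [0.2126, 0.7152, 0.0722],
        [0.0193, 0.1192, 0.9505],
    ]
)
XYZ_TO_SRGB = np.linalg.inv(SRGB_TO_XYZ)

# White point = image of linear RGB (1, 1, 1); Y sums to exactly 1.
D65_WHITE = SRGB_TO_XYZ.sum(axis=1)

_DELTA = 6.0 / 29.0
_DELTA3 = _DELTA**3
_NEG_XYZ_TOL = -1e-9
_MASK_THRESHOLD = 127  # strictly greater than -> included


class XYZColour(NamedTuple):
    """CIE tristimulus values with Y normalised to 1 at the reference white."""

    X: float
    Y: float
    Z: float


class LabColour(NamedTuple):
    """CIE 1976 L*a*b* coordinates."""

    L: float
    a: float
    b: float


@dataclass(frozen=True)
class RGBImage:
    """An 8-bit sRGB image, height x width x 3, channel values 0-255."""

    pixels: np.ndarray
    colour_space_tag: str = "sRGB-8bit"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected a height x width x 3 array, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must have at least one pixel")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("channel values must lie in [0, 255]")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class RegionMask:
    """Boolean pixel-inclusion map paired with an image of the same shape."""

    include: np.ndarray
    n_pixels: int = field(init=False)

    def __post_init__(self) -> None:
        inc = np.asarray(self.include, dtype=bool)
        object.__setattr__(self, "include", inc)
        object.__setattr__(self, "n_pixels", int(inc.sum()))

    @property
    def shape(self) -> tuple[int, int]:
        return self.include.shape


@dataclass(frozen=True)
class ColourAttributes:
    """Mean region colour of one fish at one time point.

    ``L``, ``a``, ``b`` are the region means; ``h`` (degrees, [0, 360)) and
    ``C`` (>= 0) are derived from the mean ``a``, ``b``.
    """

    L: float
    a: float
    b: float
    h: float
    C: float


def _pixels(image: RGBImage | np.ndarray) -> np.ndarray:
    if isinstance(image, RGBImage):
        return image.pixels
    return RGBImage(np.asarray(image)).pixels


# ---------------------------------------------------------------------------
# sRGB <-> linear <-> XYZ <-> Lab, vectorised over trailing channel axis
# ---------------------------------------------------------------------------


def decode_srgb(encoded: np.ndarray) -> np.ndarray:
    """Invert the sRGB transfer function; input and output in [0, 1]."""
    c = np.asarray(encoded, dtype=float)
    return np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)


def encode_srgb(linear: np.ndarray) -> np.ndarray:
    """Apply the sRGB transfer function; input clipped to [0, 1]."""
    c = np.clip(np.asarray(linear, dtype=float), 0.0, 1.0)
    return np.where(c <= 0.0031308, 12.92 * c, 1.055 * c ** (1.0 / 2.4) - 0.055)


def _srgb8_to_xyz_array(rgb8: np.ndarray) -> np.ndarray:
    """(..., 3) array of 8-bit sRGB values -> (..., 3) XYZ."""
    linear = decode_srgb(np.asarray(rgb8, dtype=float) / 255.0)
    return linear @ SRGB_TO_XYZ.T


def _lab_f(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    return np.where(t > _DELTA3, np.cbrt(t), t / (3.0 * _DELTA**2) + 4.0 / 29.0)


def _lab_f_inv(u: np.ndarray) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    return np.where(u > _DELTA, u**3, 3.0 * _DELTA**2 * (u - 4.0 / 29.0))


def _xyz_to_lab_array(xyz: np.ndarray, white: np.ndarray = D65_WHITE) -> np.ndarray:
    xyz = np.asarray(xyz, dtype=float)
    if xyz.min() < _NEG_XYZ_TOL:
        raise ValueError(f"negative tristimulus value beyond tolerance: min={xyz.min()}")
    ratios = np.clip(xyz, 0.0, None) / np.asarray(white, dtype=float)
    f = _lab_f(ratios)
    fx, fy, fz = f[..., 0], f[..., 1], f[..., 2]
    L = 116.0 * fy - 16.0
    a = 500.0 * (fx - fy)
    b = 200.0 * (fy - fz)
    return np.stack([L, a, b], axis=-1)


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def load_mask(mask_image: np.ndarray, image: RGBImage | np.ndarray | None = None) -> RegionMask:
    """Build a :class:`RegionMask` from a single-channel 8-bit mask image.

    A pixel is included iff its grey value is strictly greater than 127
    (i.e. >= 128 on the 0-255 scale).  If ``image`` is given, the mask and
    image dimensions must match exactly; no resizing is performed.
    """
    grey = np.asarray(mask_image)
    if grey.ndim != 2:
        raise ValueError(f"mask must be single-channel (2-D), got shape {grey.shape}")
    if grey.min() < 0 or grey.max() > 255:
        raise ValueError("mask grey values must lie in [0, 255]")
    if image is not None:
        img_shape = _pixels(image).shape[:2]
        if grey.shape != img_shape:
            raise ValueError(
                f"mask shape {grey.shape} does not match image shape {img_shape}"
            )
    return RegionMask(include=grey > _MASK_THRESHOLD)


def srgb_to_xyz(rgb: tuple[float, float, float] | np.ndarray) -> XYZColour:
    """Convert one 8-bit sRGB triple (channels 0-255) to XYZ."""
    rgb = np.asarray(rgb, dtype=float)
    if rgb.shape != (3,):
        raise ValueError(f"expected 3 channel values, got shape {rgb.shape}")
    if rgb.min() < 0 or rgb.max() > 255:
        raise ValueError(f"channel values must lie in [0, 255], got {rgb.tolist()}")
    return XYZColour(*_srgb8_to_xyz_array(rgb))


def xyz_to_lab(xyz: XYZColour | np.ndarray, white: XYZColour | np.ndarray = None) -> LabColour:
    """Convert one XYZ triple to CIE 1976 L*a*b* against ``white`` (default D65)."""
    w = D65_WHITE if white is None else np.asarray(white, dtype=float)
    if w[1] <= 0:
        raise ValueError("reference white must have Y > 0")
    return LabColour(*_xyz_to_lab_array(np.asarray(xyz, dtype=float), w))


def lab_to_xyz(lab: LabColour | np.ndarray, white: XYZColour | np.ndarray = None) -> XYZColour:
    """Inverse Lab -> XYZ transform (used for rendering and round-trip checks)."""
    w = D65_WHITE if white is None else np.asarray(white, dtype=float)
    L, a, b = np.asarray(lab, dtype=float)
    fy = (L + 16.0) / 116.0
    fx = fy + a / 500.0
    fz = fy - b / 200.0
    return XYZColour(*(_lab_f_inv(np.array([fx, fy, fz])) * w))


def lab_to_srgb8(lab: np.ndarray) -> np.ndarray:
    """(..., 3) Lab -> 8-bit sRGB with gamut clipping (rendering helper)."""
    lab = np.asarray(lab, dtype=float)
    fy = (lab[..., 0] + 16.0) / 116.0
    fx = fy + lab[..., 1] / 500.0
    fz = fy - lab[..., 2] / 200.0
    xyz = _lab_f_inv(np.stack([fx, fy, fz], axis=-1)) * D65_WHITE
    linear = xyz @ XYZ_TO_SRGB.T
    return np.clip(np.rint(encode_srgb(linear) * 255.0), 0, 255).astype(np.uint8)


def mean_region_colour(
    image: RGBImage | np.ndarray, mask: RegionMask
) -> tuple[float, float, float]:
    """Unweighted arithmetic mean of per-pixel L*, a*, b* over the mask region.

    Every included pixel is converted sRGB -> XYZ -> Lab individually; the
    mean is taken in Lab space (not in RGB).
    """
    px = _pixels(image)
    if mask.shape != px.shape[:2]:
        raise ValueError(f"mask shape {mask.shape} does not match image shape {px.shape[:2]}")
    if mask.n_pixels == 0:
        raise ValueError("empty region: mask includes no pixels")
    selected = px[mask.include]
    lab = _xyz_to_lab_array(_srgb8_to_xyz_array(selected))
    mean = lab.mean(axis=0)
    return float(mean[0]), float(mean[1]), float(mean[2])


def hue_chroma(a: float, b: float) -> tuple[float, float]:
    """Hue angle (degrees in [0, 360)) and chroma from opponent values.

    C = sqrt(a^2 + b^2); h = atan2(b, a) wrapped into [0, 360).  A neutral
    colour (C = 0) reports h = 0 by convention.
    """
    C = float(np.hypot(a, b))
    if C == 0.0:
        return 0.0, 0.0
    h = float(np.degrees(np.arctan2(b, a)) % 360.0)
    if h == 360.0:  # guard against rounding at the wrap point
        h = 0.0
    return h, C


def attributes_for_image(image: RGBImage | np.ndarray, mask: RegionMask) -> ColourAttributes:
    """Full measurement for one photograph: region-mean Lab plus hue/chroma."""
    L, a, b = mean_region_colour(image, mask)
    h, C = hue_chroma(a, b)
    return ColourAttributes(L=L, a=a, b=b, h=h, C=C)
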