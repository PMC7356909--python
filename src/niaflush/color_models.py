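"""Pixel-level color-space transforms and the chrominance skin filter.

Flushed skin is detected through its color coordinates rather than raw RGB:
the red chrominance Cr of the YCbCr space tracks erythema directly, while
hue/saturation separate chromatic change from brightness.  This module
implements the three conversions used throughout the pipeline and the
Cr/Cb window test that decides whether a pixel is plausibly skin.

All conversions are vectorised: they accept an array of shape ``(..., 3)``
holding 8-bit RGB values and return an array of the same shape.  Scalars
are handled by passing a length-3 sequence.

Conventions
-----------
* HSV is computed with the arccos ("polar") hue formula on channels
  normalised to [0, 1]; H is in degrees on [0, 360), S and V on [0, 1].
  Achromatic pixels (R = G = B) return H = 0, S = 0 by convention.
* YUV and YCbCr use the ITU-R BT.601 studio-range matrix with offset
  (16, 128, 128); chrominance rows sum to zero, so neutral grays map to
  Cb = Cr = U = V = 128 exactly.  Outputs are clipped to [0, 255] and kept
  in floating point; rounding to integers happens only where a downstream
  statistic requires it (the mode).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = [
    "RGB_TO_YCBCR_MATRIX",
    "YCBCR_OFFSET",
    "SkinThresholds",
    "rgb_to_hsv",
    "rgb_to_yuv",
    "rgb_to_ycbcr",
    "skin_plausible",
]

#: BT.601 studio-range conversion matrix; rows give Y, Cb (=U), Cr (=V).
RGB_TO_YCBCR_MATRIX = np.array(
    [
        [0.257, 0.504, 0.098],
        [-0.148, -0.291, 0.439],
        [0.439, -0.368, -0.071],
    ]
)

#: Additive offset for the studio-range transform.
YCBCR_OFFSET = np.array([16.0, 128.0, 128.0])


def _as_rgb_array(rgb: np.ndarray | list | tuple) -> np.ndarray:
    arr = np.asarray(rgb, dtype=float)
    if arr.shape[-1] != 3:
        raise ValidationError(f"expected RGB data with last axis 3, got shape {arr.shape}")
    if arr.min() < 0 or arr.max() > 255:
        raise ValidationError("RGB channel values must lie in [0, 255]")
    return arr


def rgb_to_hsv(rgb: np.ndarray | list | tuple) -> np.ndarray:
    """Convert 8-bit RGB values to HSV via the arccos hue formula.

    Parameters
    ----------
    rgb
        Array-like of shape ``(..., 3)`` with channels in [0, 255].

    Returns
    -------
    numpy.ndarray
        Same leading shape, last axis = (H in degrees [0, 360),
        S in [0, 1], V in [0, 1]).

    Notes
    -----
    The hue angle is ``theta = arccos(((R-G) + (R-B)) / 2 /
    sqrt((R-G)^2 + (R-B)(G-B)))`` with ``H = theta`` when ``B <= G`` and
    ``360 - theta`` otherwise.  This polar hue agrees with the familiar
    hexcone (max/min) hue to within about 1.2 degrees everywhere and
    exactly at multiples of 60 degrees.
    """
    arr = _as_rgb_array(rgb) / 255.0
    r, g, b = arr[..., 0], arr[..., 1], arr[..., 2]

    num = 0.5 * ((r - g) + (r - b))
    # den^2 == ((R-G)^2 + (R-B)^2 + (G-B)^2) / 2, zero iff achromatic
    den_sq = (r - g) ** 2 + (r - b) * (g - b)
    achromatic = den_sq <= 0.0
    den = np.sqrt(np.where(achromatic, 1.0, den_sq))
    cos_theta = np.clip(np.where(achromatic, 1.0, num / den), -1.0, 1.0)
    theta = np.degrees(np.arccos(cos_theta))
    h = np.where(b <= g, theta, 360.0 - theta) % 360.0
    h = np.where(achromatic, 0.0, h)

    total = r + g + b
    safe_total = np.where(total == 0.0, 1.0, total)
    s = 1.0 - 3.0 * np.minimum(np.minimum(r, g), b) / safe_total
    s = np.where(achromatic | (total == 0.0), 0.0, s)
    v = np.maximum(np.maximum(r, g), b)
    return np.stack([h, s, v], axis=-1)


def rgb_to_yuv(rgb: np.ndarray | list | tuple) -> np.ndarray:
    """Convert 8-bit RGB to studio-range YUV (BT.601), clipped to [0, 255].

    Returns an array with last axis (Y, U, V).  U and V are numerically
    identical to Cb and Cr of :func:`rgb_to_ycbcr`.
    """
    arr = _as_rgb_array(rgb)
    r, g, b = arr[..., 0], arr[..., 1], arr[..., 2]
    y = 0.257 * r + 0.504 * g + 0.098 * b + 16.0
    # chrominance rows written in channel-difference form: algebraically
    # identical (rows sum to zero) and exactly neutral for R = G = B
    cb = -0.148 * (r - b) - 0.291 * (g - b) + 128.0
    cr = 0.439 * (r - g) - 0.071 * (b - g) + 128.0
    out = np.stack([y, cb, cr], axis=-1)
    return np.clip(out, 0.0, 255.0)


def rgb_to_ycbcr(rgb: np.ndarray | list | tuple) -> np.ndarray:
    """Convert 8-bit RGB to studio-range YCbCr, clipped to [0, 255].

    Returns an array with last axis (Y, Cb, Cr):

    * ``Y  =  0.257 R + 0.504 G + 0.098 B + 16``
    * ``Cb = -0.148 R - 0.291 G + 0.439 B + 128``
    * ``Cr =  0.439 R - 0.368 G - 0.071 B + 128``
    """
    return rgb_to_yuv(rgb)


@dataclass(frozen=True)
class SkinThresholds:
    """Chrominance window deciding whether a pixel is plausibly skin.

    A pixel passes when ``cr_min <= Cr <= cr_max`` and
    ``cb_min <= Cb <= cb_max``; when ``hue_band`` is set, additionally when
    ``H/360`` lies inside the band (disabled by default).

    The stock window (``Cr in [140, 165]``, ``Cb in [140, 195]``) matches
    the camera and lighting conditions the method was developed under.  The
    Cb interval in particular is tied to those conditions — typical skin
    tones under neutral illumination sit well below Cb = 140 — so the
    bounds are plain configuration values, not physical constants; use
    :meth:`permissive` to disable filtering altogether.
    """

    cr_min: float = 140.0
    cr_max: float = 165.0
    cb_min: float = 140.0
    cb_max: float = 195.0
    hue_band: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.cr_min > self.cr_max:
            raise ValidationError("cr_min must not exceed cr_max")
        if self.cb_min > self.cb_max:
            raise ValidationError("cb_min must not exceed cb_max")
        if self.hue_band is not None and self.hue_band[0] > self.hue_band[1]:
            raise ValidationError("hue band lower bound must not exceed upper bound")

    @classmethod
    def defaults(cls) -> "SkinThresholds":
        """The stock Cr [140, 165] / Cb [140, 195] window."""
        return cls()

    @classmethod
    def permissive(cls) -> "SkinThresholds":
        """A window accepting every pixel (filtering disabled)."""
        return cls(cr_min=0.0, cr_max=255.0, cb_min=0.0, cb_max=255.0)


def skin_plausible(
    rgb: np.ndarray | list | tuple, thresholds: SkinThresholds | None = None
) -> np.ndarray:
    """Test pixels against the chrominance skin-plausibility window.

    Returns a boolean array of the input's leading shape (a 0-d array for a
    single pixel): ``True`` where Cr and Cb fall inside the configured
    intervals (inclusive) and, if a hue band is enabled, where H/360 lies
    inside it.
    """
    if thresholds is None:
        thresholds = SkinThresholds.defaults()
    ycbcr = rgb_to_ycbcr(rgb)
    cb, cr = ycbcr[..., 1], ycbcr[..., 2]
    ok = (
        (cr >= thresholds.cr_min)
        & (cr <= thresholds.cr_max)
        & (cb >= thresholds.cb_min)
        & (cb <= thresholds.cb_max)
    )
    if thresholds.hue_band is not None:
        h_unit = rgb_to_hsv(rgb)[..., 0] / 360.0
        ok &= (h_unit >= thresholds.hue_band[0]) & (h_unit <= thresholds.hue_band[1])
    return ok
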