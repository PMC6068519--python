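"""HSI colour-model vegetation segmentation.

Green vegetation is extracted from an RGB streetscape picture by converting to
the hue/saturation/intensity (HSI) colour model and keeping pixels whose hue
falls strictly inside a green band, 75° < H < 170° by default.  The band was
originally calibrated by maximizing the linear agreement between automatic and
manual segmentation fractions over a 60–180° search window; the same grid
search is provided here as :func:`calibrate_hue_thresholds`.

The HSI transform follows the Gonzalez & Woods definition::

    I = (R + G + B) / 3
    S = 1 - 3 min(R, G, B) / (R + G + B)
    H = theta            if B <= G
      = 360 - theta      otherwise,

    theta = arccos( ((R-G) + (R-B)) / 2
                    / sqrt((R-G)^2 + (R-B)(G-B)) )   in degrees.

Hue is undefined for achromatic pixels (R = G = B, i.e. S = 0); such pixels
are never classified as vegetation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "HSIImage",
    "GreenMask",
    "SegmentationParams",
    "rgb_to_hsi",
    "hsi_to_rgb",
    "hue_mask",
    "green_fraction",
    "extract_vegetation",
    "calibrate_hue_thresholds",
]

#: default green hue band, degrees (strict inequalities)
DEFAULT_HUE_LO = 75.0
DEFAULT_HUE_HI = 170.0
#: calibration search window, degrees
CALIBRATION_WINDOW = (60.0, 180.0)


@dataclass(frozen=True)
class SegmentationParams:
    """Hue-band thresholds for the vegetation test.

    A pixel is vegetation iff its hue is defined and
    ``hue_lo < hue < hue_hi`` (strict) and ``saturation >= min_saturation``.
    ``min_saturation`` defaults to 0 (no saturation gate) but is exposed
    because the hue of near-achromatic pixels is numerically unstable.
    """

    hue_lo: float = DEFAULT_HUE_LO
    hue_hi: float = DEFAULT_HUE_HI
    min_saturation: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.hue_lo < self.hue_hi < 360.0):
            raise ValueError(
                f"require 0 <= hue_lo < hue_hi < 360, got ({self.hue_lo}, {self.hue_hi})"
            )
        if not (0.0 <= self.min_saturation <= 1.0):
            raise ValueError("min_saturation must be in [0, 1]")


@dataclass
class HSIImage:
    """Hue/saturation/intensity decomposition of an RGB picture.

    ``hue`` is in degrees on [0, 360) and is NaN where undefined (achromatic
    pixels, exactly where ``saturation == 0``); ``saturation`` and
    ``intensity`` are unitless in [0, 1].
    """

    hue: np.ndarray
    saturation: np.ndarray
    intensity: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.hue.shape


@dataclass
class GreenMask:
    """Boolean per-pixel vegetation mask with its pixel counts."""

    mask: np.ndarray
    green_count: int = field(init=False)
    total_count: int = field(init=False)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.green_count = int(self.mask.sum())
        self.total_count = int(self.mask.size)

    @property
    def fraction(self) -> float:
        return self.green_count / self.total_count


def _validate_rgb(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 RGB array, got shape {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1 or arr.size == 0:
        raise ValueError("empty image")
    if arr.dtype.kind not in "ui":
        raise ValueError("RGB channels must be integer valued in [0, 255]")
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("RGB channel values must lie in [0, 255]")
    return arr


def rgb_to_hsi(img: np.ndarray) -> HSIImage:
    """Convert an 8-bit RGB image to the HSI colour model.

    Parameters
    ----------
    img : ndarray, shape (H, W, 3)
        Integer RGB channels in [0, 255].

    Returns
    -------
    HSIImage
        Hue in degrees on [0, 360) (NaN for achromatic pixels), saturation
        and intensity in [0, 1].
    """
    arr = _validate_rgb(img).astype(np.float64)
    r, g, b = arr[..., 0], arr[..., 1], arr[..., 2]

    total = r + g + b
    intensity = total / (3.0 * 255.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        saturation = np.where(total > 0, 1.0 - 3.0 * np.minimum(np.minimum(r, g), b) / total, 0.0)

    achromatic = (r == g) & (g == b)
    num = 0.5 * ((r - g) + (r - b))
    den = np.sqrt((r - g) ** 2 + (r - b) * (g - b))
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_theta = np.clip(np.where(den > 0, num / np.where(den > 0, den, 1.0), 1.0), -1.0, 1.0)
    theta = np.degrees(np.arccos(cos_theta))
    hue = np.where(b <= g, theta, 360.0 - theta)
    hue = np.where(hue >= 360.0, hue - 360.0, hue)
    hue = np.where(achromatic, np.nan, hue)
    saturation = np.where(achromatic, 0.0, saturation)

    return HSIImage(hue=hue, saturation=saturation, intensity=intensity)


def hsi_to_rgb(hue: np.ndarray, saturation: np.ndarray, intensity: np.ndarray) -> np.ndarray:
    """Inverse HSI transform producing an 8-bit RGB image.

    Standard sector-based inversion: the 120° sector containing the hue
    determines which channel is reconstructed from ``I (1 + S cos H / cos(60 - H))``.
    NaN hue (achromatic) maps to gray at the given intensity.
    """
    h = np.asarray(hue, dtype=np.float64)
    s = np.asarray(saturation, dtype=np.float64)
    i = np.asarray(intensity, dtype=np.float64)
    h, s, i = np.broadcast_arrays(h, s, i)

    achromatic = ~np.isfinite(h) | (s <= 0)
    h = np.where(achromatic, 0.0, np.mod(h, 360.0))

    r = np.empty_like(i)
    g = np.empty_like(i)
    b = np.empty_like(i)

    def sector(mask: np.ndarray, h0: float, c1: np.ndarray, c2: np.ndarray, c3: np.ndarray) -> None:
        # c1 = I(1 - S); c2 = I(1 + S cosH'/cos(60 - H')); c3 = 3I - (c1 + c2)
        hh = np.radians(h[mask] - h0)
        x = i[mask] * (1.0 - s[mask])
        y = i[mask] * (1.0 + s[mask] * np.cos(hh) / np.cos(np.radians(60.0) - hh))
        z = 3.0 * i[mask] - (x + y)
        c1[mask], c2[mask], c3[mask] = x, y, z

    m0 = h < 120.0
    m1 = (h >= 120.0) & (h < 240.0)
    m2 = h >= 240.0
    sector(m0, 0.0, b, r, g)
    sector(m1, 120.0, r, g, b)
    sector(m2, 240.0, g, b, r)

    rgb = np.stack([r, g, b], axis=-1)
    rgb[achromatic] = i[achromatic][..., None]
    return np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)


def hue_mask(hsi: HSIImage, params: SegmentationParams | None = None) -> GreenMask:
    """Mark vegetation pixels by the strict hue-band test.

    A pixel is marked iff its hue is defined, ``hue_lo < hue < hue_hi``
    (strict inequalities, as in the segmentation rule), and its saturation is
    at least ``min_saturation``.
    """
    params = params or SegmentationParams()
    with np.errstate(invalid="ignore"):
        mask = (
            np.isfinite(hsi.hue)
            & (hsi.hue > params.hue_lo)
            & (hsi.hue < params.hue_hi)
            & (hsi.saturation >= params.min_saturation)
        )
    return GreenMask(mask=mask)


def green_fraction(img: np.ndarray, params: SegmentationParams | None = None) -> float:
    """Vegetation pixel fraction of a single RGB picture."""
    return hue_mask(rgb_to_hsi(img), params).fraction


def extract_vegetation(img: np.ndarray, mask: GreenMask) -> np.ndarray:
    """Blank out non-vegetation pixels, preserving vegetation pixels bit-exactly."""
    arr = _validate_rgb(img)
    if mask.mask.shape != arr.shape[:2]:
        raise ValueError(
            f"mask shape {mask.mask.shape} does not match image shape {arr.shape[:2]}"
        )
    out = np.zeros_like(arr)
    out[mask.mask] = arr[mask.mask]
    return out


def calibrate_hue_thresholds(
    pictures: Sequence[np.ndarray],
    reference_fractions: Sequence[float],
    window: tuple[float, float] = CALIBRATION_WINDOW,
    step: float = 5.0,
) -> SegmentationParams:
    """Grid-search the hue band maximizing R² against reference fractions.

    For every candidate band ``(lo, hi)`` on the grid inside ``window`` the
    segmentation fraction of each picture is computed and the squared Pearson
    correlation with ``reference_fractions`` is evaluated; the band with the
    highest R² wins, ties broken by the widest band.  Mirrors the original
    calibration that narrowed an initial 60–180° window.

    Raises
    ------
    ValueError
        Fewer than 3 pairs, zero-variance references, or no picture has any
        pixel with hue inside the window (the band is then non-identifiable).
    """
    if len(pictures) != len(reference_fractions):
        raise ValueError("pictures and reference_fractions must have equal length")
    if len(pictures) < 3:
        raise ValueError("need at least 3 picture/reference pairs")
    refs = np.asarray(reference_fractions, dtype=np.float64)
    if np.ptp(refs) == 0:
        raise ValueError("reference fractions have zero variance; R-squared undefined")

    lo0, hi0 = window
    # sorted in-window hues per picture -> strict-band counts via searchsorted
    hue_sorted: list[np.ndarray] = []
    sizes = np.empty(len(pictures))
    for k, img in enumerate(pictures):
        hsi = rgb_to_hsi(img)
        h = hsi.hue[np.isfinite(hsi.hue)]
        hue_sorted.append(np.sort(h[(h > lo0) & (h < hi0)]))
        sizes[k] = hsi.hue.size
    if all(h.size == 0 for h in hue_sorted):
        raise ValueError(
            f"no pixels with hue inside the search window {window}; band non-identifiable"
        )

    grid = np.arange(lo0, hi0 + 0.5 * step, step)
    best: tuple[float, float, SegmentationParams] | None = None  # (r2, width, params)
    for i, lo in enumerate(grid[:-1]):
        for hi in grid[i + 1 :]:
            fracs = np.array(
                [
                    (np.searchsorted(h, hi, "left") - np.searchsorted(h, lo, "right")) / n
                    for h, n in zip(hue_sorted, sizes)
                ]
            )
            if np.ptp(fracs) == 0:
                continue
            r = np.corrcoef(fracs, refs)[0, 1]
            r2 = r * r
            width = hi - lo
            if best is None or (r2, width) > (best[0], best[1]):
                best = (r2, width, SegmentationParams(hue_lo=float(lo), hue_hi=float(hi)))
    if best is None:
        raise ValueError("segmentation fraction constant for every candidate band")
    return best[2]
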