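"""Green View Index computation from directional street-view picture sets.

The GVI at a sampling site is the pooled ratio of vegetation pixels to total
pixels over the site's pictures:

    GVI    = sum_i Area_g_i / sum_i Area_t_i                 (m horizontal pictures)
    GVI_g  = sum_j sum_i Area_g_ij / sum_j sum_i Area_t_ij   (m headings x n pitches)
    PGVI   = Area_g / Area_t                                 (single panorama)

With n = 1 and heading offset 0 the general form reduces exactly to the
horizontal form.  Values are stored as fractions in [0, 1]; the conventional
x100% is presentation only.

Five named configurations are provided: GVI4 (4 headings at 90°), GVI6
(6 headings at 60° — the reference method), GVI8 (8 headings at 45°), GVI18
(6 headings x 3 pitches) and PGVI (one stitched cylindrical panorama).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from greenview.segmentation import SegmentationParams, hue_mask, rgb_to_hsi

__all__ = [
    "GVIConfig",
    "SVPSet",
    "GVIResult",
    "MethodComparison",
    "gvi_horizontal",
    "gvi_general",
    "pgvi",
    "stitch_panorama",
    "compare_methods",
]

#: nominal panoramic-camera height above ground, metres
CAMERA_HEIGHT = 2.5


@dataclass(frozen=True)
class GVIConfig:
    """A named picture configuration: which (heading, pitch) pairs a site needs."""

    name: str
    headings: tuple[float, ...]
    pitches: tuple[float, ...] = (0.0,)

    @property
    def m(self) -> int:
        return len(self.headings)

    @property
    def n(self) -> int:
        return len(self.pitches)

    @property
    def keys(self) -> list[tuple[float, float]]:
        return [(h, p) for p in self.pitches for h in self.headings]

    @classmethod
    def named(cls, name: str, heading_offset: float = 0.0, gvi18_pitch: float = 30.0) -> "GVIConfig":
        """Build one of the standard configurations.

        ``gvi18_pitch`` selects the vertical aperture of GVI18: 30° for the
        nominal three-pitch grid, 20° for services whose pitch range is
        limited to [-20°, 90°].
        """
        name = name.upper()
        if name == "GVI4":
            return cls("GVI4", tuple((heading_offset + 90.0 * i) % 360 for i in range(4)))
        if name in ("GVI6", "GVI"):
            return cls("GVI6", tuple((heading_offset + 60.0 * i) % 360 for i in range(6)))
        if name == "GVI8":
            return cls("GVI8", tuple((heading_offset + 45.0 * i) % 360 for i in range(8)))
        if name == "GVI18":
            return cls(
                "GVI18",
                tuple((heading_offset + 60.0 * i) % 360 for i in range(6)),
                (gvi18_pitch, 0.0, -gvi18_pitch),
            )
        if name == "PGVI":
            return cls("PGVI", (0.0,))
        raise ValueError(f"unknown configuration {name!r}")


@dataclass
class SVPSet:
    """The street-view pictures at one sampling site, indexed by (heading, pitch).

    All pictures must share one resolution; ``camera_height`` is metadata
    recording the panoramic camera's height above ground (metres).
    """

    site_id: str | int
    pictures: Mapping[tuple[float, float], np.ndarray]
    camera_height: float = CAMERA_HEIGHT

    def __post_init__(self) -> None:
        shapes = {np.asarray(img).shape for img in self.pictures.values()}
        if len(shapes) > 1:
            raise ValueError(f"pictures at site {self.site_id} have mixed shapes: {shapes}")

    def picture(self, heading: float, pitch: float = 0.0) -> np.ndarray:
        return self.pictures[(heading, pitch)]


@dataclass(frozen=True)
class GVIResult:
    site_id: str | int
    config_name: str
    green_pixels: int
    total_pixels: int

    @property
    def gvi(self) -> float:
        """Pooled green-pixel fraction in [0, 1]."""
        return self.green_pixels / self.total_pixels


@dataclass(frozen=True)
class MethodComparison:
    """Summary of per-site differences d_k = GVI_ref(k) - GVI_other(k)."""

    label: str
    mean_difference: float
    rmse: float
    n_positive: int
    n_negative: int
    n_sites: int


def _pooled(svp: SVPSet, keys: Sequence[tuple[float, float]], params: SegmentationParams | None,
            site_config: str) -> GVIResult:
    missing = [k for k in keys if k not in svp.pictures]
    if missing:
        raise ValueError(
            f"site {svp.site_id}: missing pictures for (heading, pitch) = {sorted(missing)}"
        )
    green = total = 0
    for key in keys:
        gm = hue_mask(rgb_to_hsi(svp.pictures[key]), params)
        green += gm.green_count
        total += gm.total_count
    return GVIResult(svp.site_id, site_config, green, total)


def gvi_horizontal(svp: SVPSet, params: SegmentationParams | None = None,
                   m: int = 6, heading_offset: float = 0.0) -> GVIResult:
    """GVI from m horizontal pictures at equal heading intervals (default m = 6)."""
    headings = [(heading_offset + 360.0 * i / m) % 360 for i in range(m)]
    return _pooled(svp, [(h, 0.0) for h in headings], params, f"GVI{m}")


def gvi_general(svp: SVPSet, config: GVIConfig, params: SegmentationParams | None = None) -> GVIResult:
    """General GVI: pooled pixel ratio over the m x n (heading, pitch) grid."""
    return _pooled(svp, config.keys, params, config.name)


def pgvi(panorama: np.ndarray, params: SegmentationParams | None = None,
         site_id: str | int = "") -> GVIResult:
    """Panoramic GVI: green fraction of a single stitched panorama."""
    gm = hue_mask(rgb_to_hsi(panorama), params)
    return GVIResult(site_id, "PGVI", gm.green_count, gm.total_count)


def stitch_panorama(svp: SVPSet, fov: float = 90.0, m: int = 6,
                    heading_offset: float = 0.0) -> np.ndarray:
    """Stitch m horizontal pictures into a cylindrical 360° panorama.

    Each picture spans ``fov`` degrees of azimuth centred on its heading.
    Output columns are mapped to azimuth at the pictures' native angular
    resolution (width / fov columns per degree); where ``fov > 360/m``
    adjacent pictures overlap and the overlapping columns are averaged —
    this duplicated-then-merged content is what makes PGVI differ from the
    discrete-picture GVI.  At ``fov = 360/m`` the panorama degenerates to the
    exact side-by-side concatenation of the pictures.

    Raises
    ------
    ValueError
        If ``fov < 360/m`` (angular gaps between pictures).
    """
    seg = 360.0 / m
    if fov < seg - 1e-9:
        raise ValueError(f"fov {fov}° leaves angular gaps: need fov >= 360/m = {seg}°")
    headings = [heading_offset + seg * i for i in range(m)]
    pics = [np.asarray(svp.picture(h % 360, 0.0)) for h in headings]
    height, width = pics[0].shape[:2]

    cols_per_deg = width / fov
    out_w = int(round(360.0 * cols_per_deg))
    acc = np.zeros((height, out_w, 3), dtype=np.float64)
    cnt = np.zeros(out_w, dtype=np.int64)

    # azimuth of output column j, measured from the left edge of picture 0
    alpha = (np.arange(out_w) + 0.5) / cols_per_deg + (headings[0] - fov / 2.0)
    for h, pic in zip(headings, pics):
        rel = np.mod(alpha - (h - fov / 2.0), 360.0)
        inside = rel < fov
        x = np.floor(rel[inside] * cols_per_deg).astype(np.int64)
        np.clip(x, 0, width - 1, out=x)
        acc[:, inside] += pic[:, x]
        cnt[inside] += 1
    if (cnt == 0).any():
        raise ValueError("angular coverage gap during stitching")
    out = acc / cnt[None, :, None]
    return np.round(out).astype(np.uint8)


def compare_methods(
    sites: Sequence[SVPSet],
    configs: tuple[GVIConfig, GVIConfig],
    params: SegmentationParams | None = None,
    gvi_values: tuple[Sequence[float], Sequence[float]] | None = None,
) -> MethodComparison:
    """Compare two picture configurations over a set of sites.

    The first config of the pair is the reference; per-site differences
    ``d_k = GVI_ref(k) - GVI_other(k)`` are summarized by their mean, RMSE,
    and the counts of sites with d > 0 and d < 0 (ties count in neither).

    ``gvi_values`` allows supplying precomputed per-site GVI pairs (then
    ``sites`` may be empty of pictures and only its length is used).
    """
    ref_cfg, other_cfg = configs
    if gvi_values is not None:
        ref_vals = np.asarray(gvi_values[0], dtype=np.float64)
        other_vals = np.asarray(gvi_values[1], dtype=np.float64)
        if ref_vals.size != other_vals.size or ref_vals.size == 0:
            raise ValueError("gvi_values must be two equal-length non-empty sequences")
    else:
        if len(sites) == 0:
            raise ValueError("no sites to compare")
        ref_vals = np.array([gvi_general(s, ref_cfg, params).gvi for s in sites])
        other_vals = np.array([gvi_general(s, other_cfg, params).gvi for s in sites])
    d = ref_vals - other_vals
    return MethodComparison(
        label=f"{ref_cfg.name} vs {other_cfg.name}",
        mean_difference=float(d.mean()),
        rmse=float(np.sqrt(np.mean(d**2))),
        n_positive=int((d > 0).sum()),
        n_negative=int((d < 0).sum()),
        n_sites=int(d.size),
    )
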