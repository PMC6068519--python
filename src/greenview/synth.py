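"""Synthetic streetscapes, road networks and GVI surfaces with exact ground truth.

Everything the pipeline consumes can be generated here with its true answer
known by construction: flat-colour streetscape compositions whose
vegetation-labelled pixel fraction is exact to one pixel, ring-and-radial
road networks echoing the lattice layout of a large city, and spatially
autocorrelated site-GVI surfaces drawn from a Gaussian random field.

Scenes are deliberately geometric rather than photorealistic: hue bands for
vegetation (default 90–150°), sky, built surfaces and pavement are disjoint
from each other and from the 75–170° segmentation band except where a
distractor is requested, so segmentation recall and precision are exactly
1.0 on distractor-free scenes.  In-band distractors (green-painted objects)
occupying fraction q shift the measured GVI by exactly +q, reproducing the
known misrecognition failure mode of hue-threshold segmentation in a
controlled way.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from greenview.gvi import SVPSet
from greenview.roadnet import ROAD_TYPES, RoadPolyline
from greenview.segmentation import hsi_to_rgb

__all__ = [
    "SceneSpec",
    "NetworkSpec",
    "render_streetscape",
    "render_svp_set",
    "generate_network",
    "generate_gvi_surface",
]

#: hue (degrees), saturation, intensity used for non-vegetation scene elements
SKY = (220.0, 0.55, 0.62)
BUILDING = (30.0, 0.45, 0.40)
ROAD_SURFACE = (float("nan"), 0.0, 0.35)  # achromatic pavement
VEGETATION_SI = (0.75, 0.35)  # saturation, intensity of vegetation pixels


@dataclass
class SceneSpec:
    """Recipe for one labelled streetscape picture."""

    target_green_fraction: float
    vegetation_hue_range: tuple[float, float] = (90.0, 150.0)
    distractor_in_band_fraction: float = 0.0  # green-painted objects inside 75-170
    distractor_out_band_fraction: float = 0.0  # yellowish objects outside the band
    resolution: tuple[int, int] = (600, 600)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.target_green_fraction <= 1.0):
            raise ValueError("target_green_fraction must be in [0, 1]")
        total = (
            self.target_green_fraction
            + self.distractor_in_band_fraction
            + self.distractor_out_band_fraction
        )
        if total > 1.0 + 1e-12:
            raise ValueError("vegetation + distractor fractions exceed 1")


@dataclass
class NetworkSpec:
    """Recipe for a ring + radial synthetic road network."""

    n_rings: int = 2
    n_radials: int = 4
    extent: float = 2000.0  # outermost ring radius, metres
    center: tuple[float, float] = (100_000.0, 100_000.0)
    ring_vertices: int = 72
    jitter: float = 0.0  # relative seeded perturbation of radii/angles
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rings < 0 or self.n_radials < 2:
            raise ValueError("need n_rings >= 0 and n_radials >= 2")


#: width (metres) by road type, loosely realistic for each class
TYPE_WIDTHS = {"T1": 30.0, "T2": 20.0, "T3": 25.0, "T4": 15.0, "T5": 8.0, "T6": 12.0, "T7": 6.0}


def render_streetscape(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render one labelled scene; returns (RGB image, boolean vegetation label mask).

    The realized vegetation fraction is ``round(target * H*W) / (H*W)`` — within
    half a pixel of the target.  Vegetation hues are drawn uniformly inside
    ``vegetation_hue_range``; in-band distractor pixels get the same hues but a
    False label; out-of-band distractors sit at 60–70° (outside the default
    75–170 band, inside the 60–180 calibration window).
    """
    h_px, w_px = spec.resolution
    n = h_px * w_px
    rng = np.random.default_rng(spec.seed)

    n_veg = int(round(spec.target_green_fraction * n))
    n_din = int(round(spec.distractor_in_band_fraction * n))
    n_dout = int(round(spec.distractor_out_band_fraction * n))
    n_rest = n - n_veg - n_din - n_dout
    if n_rest < 0:
        raise ValueError("fractions leave no room for background")
    n_sky = n_rest // 2
    n_bld = (n_rest - n_sky) // 2
    n_road = n_rest - n_sky - n_bld

    lo, hi = spec.vegetation_hue_range
    hue = np.empty(n)
    sat = np.empty(n)
    inten = np.empty(n)
    label = np.zeros(n, dtype=bool)

    # contiguous bands, top to bottom: sky | vegetation | in-band distractor
    # | out-of-band distractor | building | pavement
    pos = 0
    for count, hsi_triplet, lab in (
        (n_sky, SKY, False),
        (n_veg, None, True),
        (n_din, None, False),
        (n_dout, (65.0, 0.7, 0.45), False),
        (n_bld, BUILDING, False),
        (n_road, ROAD_SURFACE, False),
    ):
        sl = slice(pos, pos + count)
        if hsi_triplet is None:  # vegetation-hued pixels (true vegetation or distractor)
            hue[sl] = rng.uniform(lo, hi, count)
            sat[sl] = VEGETATION_SI[0]
            inten[sl] = VEGETATION_SI[1]
        else:
            hue[sl], sat[sl], inten[sl] = hsi_triplet
        label[sl] = lab
        pos += count

    img = hsi_to_rgb(hue, sat, inten).reshape(h_px, w_px, 3)
    return img, label.reshape(h_px, w_px)


def _column_colours(height: int, green_rows: int, veg_rgb: np.ndarray, sky_rgb: np.ndarray) -> np.ndarray:
    col = np.empty((height, 3), dtype=np.uint8)
    col[: height - green_rows] = sky_rgb
    if green_rows:
        col[height - green_rows:] = veg_rgb
    return col


def render_svp_set(
    site_id: str | int,
    fractions: list[float] | np.ndarray,
    fov: float = 90.0,
    resolution: tuple[int, int] = (600, 600),
    heading_offset: float = 0.0,
    camera_height: float = 2.5,
    smooth: bool = False,
    pitches: tuple[float, ...] = (0.0,),
) -> SVPSet:
    """Render the m horizontal pictures of one sampling site.

    The site's surroundings are modelled as a 360° cylindrical world split
    into m equal sectors; sector i carries vegetation filling fraction
    ``fractions[i]`` of each of its columns (vegetation at the bottom, sky
    above, so every column at world azimuth a shows ``round(f(a) * H)`` green
    rows).  Each picture spans ``fov`` degrees centred on its heading, so at
    ``fov = 360/m`` picture i realizes exactly ``round(fractions[i]*H)/H``,
    and at wider fov adjacent pictures share consistent overlapping content
    for stitching tests.

    With ``smooth`` the vegetation profile varies continuously with azimuth:
    linear interpolation between the sector centres plus a heading-locked
    ripple that concentrates vegetation between headings (roadside trees seen
    obliquely, the road corridor itself ahead).  Greenness then differs
    between picture-overlap zones and picture centres, which is what makes a
    stitched panorama (overlap regions merged once) disagree with the
    discrete-picture GVI (overlap regions counted by every covering picture).

    Non-zero ``pitches`` add tilted views of the same world: an upward view
    trades vegetation for sky, a downward one for pavement, so the vegetation
    fraction at pitch p scales by ``1 - |p|/90 * (0.8 if p > 0 else 0.4)`` —
    a deliberately simple tilt model sufficient for multi-pitch
    configuration comparisons.
    """
    fr = np.asarray(fractions, dtype=np.float64)
    m = fr.size
    if m < 1 or np.any(fr < 0) or np.any(fr > 1):
        raise ValueError("fractions must be non-empty with values in [0, 1]")
    h_px, w_px = resolution
    seg = 360.0 / m
    veg_rgb = hsi_to_rgb(np.array(120.0), np.array(VEGETATION_SI[0]), np.array(VEGETATION_SI[1]))
    sky_rgb = hsi_to_rgb(np.array(SKY[0]), np.array(SKY[1]), np.array(SKY[2]))

    ripple = 0.25 * (fr.mean() if fr.mean() > 0 else 0.1)

    def world_fraction(alpha: float) -> float:
        rel = (alpha - heading_offset) % 360.0
        if smooth:
            # linear interpolation between sector-centre nodes, wrapped,
            # plus a ripple peaking midway between headings
            xp = np.arange(m + 1) * seg
            fp = np.append(fr, fr[0])
            base = float(np.interp(rel, xp, fp))
            return float(np.clip(base - ripple * math.cos(math.radians(m * rel)), 0.0, 1.0))
        sector = int(math.floor(((rel + seg / 2.0) % 360.0) / seg))
        return float(fr[sector % m])

    pictures = {}
    for pitch in pitches:
        scale = 1.0 - abs(pitch) / 90.0 * (0.8 if pitch > 0 else 0.4)
        for i in range(m):
            heading = (heading_offset + seg * i) % 360.0
            img = np.empty((h_px, w_px, 3), dtype=np.uint8)
            for c in range(w_px):
                alpha = heading - fov / 2.0 + (c + 0.5) * fov / w_px
                g = int(round(world_fraction(alpha) * scale * h_px))
                img[:, c] = _column_colours(h_px, g, veg_rgb, sky_rgb)
            pictures[(heading, float(pitch))] = img
    return SVPSet(site_id=site_id, pictures=pictures, camera_height=camera_height)


def generate_network(spec: NetworkSpec) -> list[RoadPolyline]:
    """Generate concentric ring roads plus radial spokes.

    Rings are closed ``ring_vertices``-gons at radii ``extent * k / n_rings``
    typed as urban expressways (T3); spokes run from the centre to the outer
    extent and cycle through the remaining road types.  ``jitter`` adds a
    seeded relative perturbation to ring radii and spoke angles so repeated
    seeds give distinct but structurally identical networks.
    """
    rng = np.random.default_rng(spec.seed)
    cx, cy = spec.center
    roads: list[RoadPolyline] = []

    for k in range(1, spec.n_rings + 1):
        r = spec.extent * k / spec.n_rings
        if spec.jitter:
            r *= 1.0 + spec.jitter * rng.uniform(-1, 1)
        theta = np.linspace(0.0, 2.0 * np.pi, spec.ring_vertices + 1)
        coords = np.stack([cx + r * np.cos(theta), cy + r * np.sin(theta)], axis=1)
        coords[-1] = coords[0]  # exact closure
        roads.append(
            RoadPolyline(
                road_id=f"ring{k}", coordinates=coords, width=TYPE_WIDTHS["T3"], road_type="T3"
            )
        )

    spoke_types = [t for t in ROAD_TYPES if t != "T3"]
    for j in range(spec.n_radials):
        ang = 2.0 * np.pi * j / spec.n_radials
        if spec.jitter:
            ang += spec.jitter * rng.uniform(-1, 1) * (np.pi / spec.n_radials)
        rtype = spoke_types[j % len(spoke_types)]
        end = (cx + spec.extent * np.cos(ang), cy + spec.extent * np.sin(ang))
        roads.append(
            RoadPolyline(
                road_id=f"radial{j}",
                coordinates=np.array([[cx, cy], end]),
                width=TYPE_WIDTHS[rtype],
                road_type=rtype,
            )
        )
    return roads


def generate_gvi_surface(
    coordinates: np.ndarray,
    spatial_range: float,
    sill: float = 0.015,
    mean: float = 0.17,
    seed: int | None = None,
) -> np.ndarray:
    """Draw site-GVI values from a clipped Gaussian random field.

    Covariance between sites i and j is ``sill * exp(-d_ij / spatial_range)``
    (exponential model); ``spatial_range = 0`` degenerates to i.i.d. noise of
    variance ``sill``.  Values are shifted to ``mean`` and clipped to [0, 1].
    The defaults echo a low-greenery urban corpus (site mean ≈ 0.17,
    variance ≈ 0.016).
    """
    pts = np.asarray(coordinates, dtype=np.float64)
    n = pts.shape[0]
    if n < 10:
        raise ValueError("need at least 10 sites")
    rng = np.random.default_rng(seed)
    normal = rng.standard_normal(n)
    if spatial_range <= 0:
        values = mean + math.sqrt(sill) * normal
    else:
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        cov = sill * np.exp(-d / spatial_range)
        cov[np.diag_indices(n)] += 1e-10 * sill
        chol = np.linalg.cholesky(cov)
        values = mean + chol @ normal
    return np.clip(values, 0.0, 1.0)
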