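"""Independent scalar reference implementations used only by the tests.

Everything here is deliberately naive — per-pixel loops, O(n^2) scans,
exhaustive enumeration — and shares no code with the package, so agreement
is evidence of correctness rather than of shared bugs.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def hsi_pixel(r: int, g: int, b: int) -> tuple[float, float, float]:
    """Gonzalez–Woods HSI of one 8-bit RGB pixel; hue NaN when achromatic."""
    rf, gf, bf = float(r), float(g), float(b)
    total = rf + gf + bf
    intensity = total / (3.0 * 255.0)
    if r == g == b:
        return float("nan"), 0.0, intensity
    saturation = 1.0 - 3.0 * min(rf, gf, bf) / total
    num = 0.5 * ((rf - gf) + (rf - bf))
    den = math.sqrt((rf - gf) ** 2 + (rf - bf) * (gf - bf))
    theta = math.degrees(math.acos(max(-1.0, min(1.0, num / den)))) if den > 0 else 0.0
    hue = theta if bf <= gf else 360.0 - theta
    return hue % 360.0, saturation, intensity


def mask_loop(img: np.ndarray, lo: float, hi: float, min_sat: float = 0.0) -> np.ndarray:
    """Per-pixel double-loop vegetation mask (strict hue band)."""
    h_px, w_px = img.shape[:2]
    out = np.zeros((h_px, w_px), dtype=bool)
    for i in range(h_px):
        for j in range(w_px):
            hue, sat, _ = hsi_pixel(*img[i, j])
            out[i, j] = (not math.isnan(hue)) and lo < hue < hi and sat >= min_sat
    return out


def moran_double_sum(values: np.ndarray, wmat: np.ndarray) -> float:
    """Global Moran's I by explicit double summation."""
    x = np.asarray(values, float)
    n = x.size
    z = x - x.mean()
    s0 = num = 0.0
    for i in range(n):
        for j in range(n):
            s0 += wmat[i, j]
            num += wmat[i, j] * z[i] * z[j]
    return (n / s0) * num / float(z @ z)


def gistar_scalar(values: np.ndarray, neighbours: list[np.ndarray]) -> np.ndarray:
    """Getis-Ord Gi* z-scores, scalar global-moments form (self-inclusive)."""
    x = np.asarray(values, float)
    n = x.size
    xbar = sum(x) / n
    s = math.sqrt(sum(v * v for v in x) / n - xbar * xbar)
    out = np.empty(n)
    for i in range(n):
        wi = len(neighbours[i])
        num = sum(x[j] for j in neighbours[i]) - xbar * wi
        den = s * math.sqrt((n * wi - wi * wi) / (n - 1))
        out[i] = num / den if den > 0 else 0.0
    return out


def jenks_bruteforce(values, k: int):
    """Exhaustive minimizer of within-class SSD over sorted contiguous partitions."""
    v = sorted(values)
    n = len(v)

    def ssd(chunk) -> float:
        mu = sum(chunk) / len(chunk)
        return sum((x - mu) ** 2 for x in chunk)

    best_cost, best_bounds = float("inf"), None
    for cuts in itertools.combinations(range(1, n), k - 1):
        bounds = (0,) + cuts + (n,)
        cost = sum(ssd(v[a:b]) for a, b in zip(bounds, bounds[1:]))
        if cost < best_cost - 1e-12:
            best_cost, best_bounds = cost, bounds
    edges = [v[0]] + [v[b - 1] for b in best_bounds[1:]]
    return best_cost, edges


def arc_point(coords: np.ndarray, chainage: float) -> tuple[float, float]:
    """Point at a given arc length along a polyline, by segment walking."""
    remaining = chainage
    for (x1, y1), (x2, y2) in zip(coords, coords[1:]):
        seg = math.hypot(x2 - x1, y2 - y1)
        if remaining <= seg or seg == 0:
            t = 0.0 if seg == 0 else remaining / seg
            return x1 + t * (x2 - x1), y1 + t * (y2 - y1)
        remaining -= seg
    return tuple(coords[-1])
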