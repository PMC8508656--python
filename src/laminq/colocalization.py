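"""Pearson colocalization with Costes automatic thresholding.

The degree of overlap between the lamin A/C and lamin B1 networks is scored
by the Pearson product-moment correlation of the two channels' pixel
intensities (+1 perfect co-variation, -1 perfect anti-correlation).  To make
the score background-independent, channel thresholds are chosen by the
Costes procedure: fit an orthogonal (total least squares) regression
``ch2 = a * ch1 + b`` through the 2D intensity scatter, then walk the
candidate threshold ``T1`` down the sorted unique intensities of channel 1
(with ``T2 = a * T1 + b`` locked to the regression line) until the pixels
below both thresholds are uncorrelated (Pearson <= 0).  Pixels above
threshold in either channel then carry the colocalization signal.

Top-of-nucleus planes, where the lamina meshwork fills the field, are the
intended input; a mid-plane rim can be analyzed but mixes in large empty
regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from scipy import ndimage

from .simulate import ImageStack


class CostesError(ValueError):
    """Costes thresholds are undefined for this channel pair."""


@dataclass
class CostesResult:
    """Thresholds, regression, and Pearson coefficients for one image pair."""

    slope: float
    intercept: float
    threshold_ch1: float
    threshold_ch2: float
    pearson_global: float
    pearson_coloc: float
    pearson_below: Optional[float]
    n_pixels_used: int


@dataclass
class DualProfile:
    """Two-channel intensity trace along a straight line, each normalized to 1."""

    distance: np.ndarray  # nm
    intensity_ch1: np.ndarray
    intensity_ch2: np.ndarray

    def __post_init__(self) -> None:
        for trace in (self.intensity_ch1, self.intensity_ch2):
            if not np.isclose(trace.max(), 1.0):
                raise ValueError("normalized trace must have maximum 1")


def pearson(ch1: np.ndarray, ch2: np.ndarray, mask: Optional[np.ndarray] = None) -> float:
    """Product-moment correlation of two planes over an optional mask."""
    a = np.asarray(ch1, dtype=float)
    b = np.asarray(ch2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("channel shapes differ")
    if mask is not None:
        a, b = a[mask], b[mask]
    else:
        a, b = a.ravel(), b.ravel()
    if a.size < 2:
        raise ValueError("need at least 2 pixels")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("undefined correlation: constant channel on mask")
    return float(np.corrcoef(a, b)[0, 1])


def _tls_regression(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Orthogonal (total least squares) regression y = a*x + b via the
    principal axis of the centred scatter."""
    sxx = np.var(x)
    syy = np.var(y)
    sxy = np.mean((x - x.mean()) * (y - y.mean()))
    if sxy == 0:
        raise CostesError("channels are uncorrelated: TLS slope undefined")
    a = (syy - sxx + np.sqrt((syy - sxx) ** 2 + 4.0 * sxy**2)) / (2.0 * sxy)
    b = float(y.mean() - a * x.mean())
    return float(a), b


def costes_thresholds(
    ch1: np.ndarray,
    ch2: np.ndarray,
    below: Literal["both", "either"] = "both",
) -> tuple[float, float, float, float]:
    """Automatic (T1, T2, a, b): walk T1 down until the below-set decorrelates.

    ``T2 = a * T1 + b`` stays on the orthogonal regression line.  Scanning the
    sorted unique intensities of ch1 from the top, the first T1 whose
    below-threshold pixel set (below both thresholds by default) has Pearson
    <= 0 is returned; the scan also stops when fewer than 2 below-set pixels
    remain or their correlation becomes undefined.  Anti-correlated channels
    (slope <= 0) have no valid thresholds and raise :class:`CostesError`.
    """
    x = np.asarray(ch1, dtype=float).ravel()
    y = np.asarray(ch2, dtype=float).ravel()
    if x.std() == 0 or y.std() == 0:
        raise CostesError("constant channel")
    a, b = _tls_regression(x, y)
    if a <= 0:
        raise CostesError(
            "anti-correlated channels (TLS slope <= 0): Costes thresholds undefined; "
            "report the global Pearson coefficient instead"
        )

    # pixel i is in the below-set exactly when T1 > ch1_i and T1 > (ch2_i - b)/a,
    # so membership is a simple threshold on t_i = max(ch1_i, (ch2_i - b)/a)
    t = np.maximum(x, (y - b) / a)
    order = np.argsort(t, kind="stable")
    xs, ys, ts = x[order], y[order], t[order]
    c_n = np.arange(1, xs.size + 1, dtype=float)
    c_x, c_y = np.cumsum(xs), np.cumsum(ys)
    c_xx, c_yy, c_xy = np.cumsum(xs * xs), np.cumsum(ys * ys), np.cumsum(xs * ys)

    def below_pearson(count: int) -> Optional[float]:
        n = float(count)
        k = count - 1
        vx = c_xx[k] - c_x[k] ** 2 / n
        vy = c_yy[k] - c_y[k] ** 2 / n
        cov = c_xy[k] - c_x[k] * c_y[k] / n
        if vx <= 0 or vy <= 0:
            return None
        return float(cov / np.sqrt(vx * vy))

    candidates = np.unique(x)[::-1]  # exact intensity grid, descending
    if below == "both":
        counts = np.searchsorted(ts, candidates, side="left")
    elif below == "either":
        # below-set: ch1 < T1 OR ch2 < T2  ->  min(ch1, (ch2-b)/a) < T1
        t_either = np.minimum(x, (y - b) / a)
        order_e = np.argsort(t_either, kind="stable")
        xs, ys = x[order_e], y[order_e]
        ts = t_either[order_e]
        c_x, c_y = np.cumsum(xs), np.cumsum(ys)
        c_xx, c_yy, c_xy = np.cumsum(xs * xs), np.cumsum(ys * ys), np.cumsum(xs * ys)
        counts = np.searchsorted(ts, candidates, side="left")
    else:
        raise ValueError("below must be 'both' or 'either'")

    t1 = float(candidates[0])
    for t1_candidate, count in zip(candidates, counts):
        t1 = float(t1_candidate)
        if count < 2:
            break
        r = below_pearson(int(count))
        if r is None or r <= 0:
            break
    t2 = a * t1 + b
    return t1, float(t2), a, b


def coloc_report(
    ch1: np.ndarray,
    ch2: np.ndarray,
    below: Literal["both", "either"] = "both",
) -> CostesResult:
    """Full Costes-thresholded Pearson report for one channel pair.

    ``pearson_global`` uses every pixel; ``pearson_coloc`` the pixels above
    threshold in either channel (the colocalization score reported in group
    comparisons); ``pearson_below`` re-evaluates the excluded set at the
    returned thresholds (None when that set is degenerate).
    """
    a1 = np.asarray(ch1, dtype=float)
    a2 = np.asarray(ch2, dtype=float)
    t1, t2, slope, intercept = costes_thresholds(a1, a2, below=below)
    above = (a1 >= t1) | (a2 >= t2)
    below_mask = ~above
    r_global = pearson(a1, a2)
    r_coloc = pearson(a1, a2, mask=above)
    try:
        r_below = pearson(a1, a2, mask=below_mask)
    except ValueError:
        r_below = None
    return CostesResult(
        slope=slope,
        intercept=intercept,
        threshold_ch1=t1,
        threshold_ch2=t2,
        pearson_global=r_global,
        pearson_coloc=r_coloc,
        pearson_below=r_below,
        n_pixels_used=int(above.sum()),
    )


def dual_profile(
    stack: ImageStack,
    start: tuple[float, float],
    end: tuple[float, float],
    channels: tuple[int | str, int | str] = (0, 1),
    z: Optional[int] = None,
) -> DualProfile:
    """Two-channel intensity trace along a straight line (pixel coordinates).

    Bilinear sampling at spacing pixel_size/3; each channel is normalized to
    its own maximum, matching the convention of published dual-channel rim
    intensity plots.
    """
    p0 = np.asarray(start, dtype=float)
    p1 = np.asarray(end, dtype=float)
    plane1 = stack.plane(channels[0], z=z)
    plane2 = stack.plane(channels[1], z=z)
    for p in (p0, p1):
        if np.any(p < 0) or p[0] > plane1.shape[0] - 1 or p[1] > plane1.shape[1] - 1:
            raise ValueError("line endpoint outside image bounds")
    length_px = float(np.linalg.norm(p1 - p0))
    if length_px == 0:
        raise ValueError("degenerate line")
    n = max(int(np.ceil(length_px * 3.0)) + 1, 15)
    frac = np.linspace(0.0, 1.0, n)
    coords = p0[:, None] + (p1 - p0)[:, None] * frac[None, :]
    traces = []
    for plane in (plane1, plane2):
        v = ndimage.map_coordinates(plane, coords, order=1)
        if v.max() <= 0:
            raise ValueError("channel has zero maximum along the line")
        traces.append(v / v.max())
    return DualProfile(
        distance=frac * length_px * stack.pixel_size,
        intensity_ch1=traces[0],
        intensity_ch2=traces[1],
    )
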