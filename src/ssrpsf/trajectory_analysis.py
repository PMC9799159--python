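"""Hotspot trajectory and rate-of-rotation (ROR) analysis.

As the emitter defocuses, the bright lobe of the rotating PSF moves along
a circle about the Gaussian image point.  This module extracts hotspot
centres from camera images, fits the trajectory circle (algebraic Kasa fit
refined by geometric least squares), and fits angle-vs-depth by ordinary
least squares to estimate the ROR.

Angle convention: hotspot positions are (x, y) with x along image columns
and y along image rows (row index increasing downward, the display
orientation).  With ``sense="cw"`` (default) angles increase for rotation
that appears clockwise on screen, which makes the canonical slope
positive; ``sense="ccw"`` gives the mathematical counter-clockwise
convention for y-up axes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .psf_sim import CameraImage

__all__ = [
    "HotspotTrack",
    "CircleFit",
    "RORFit",
    "hotspot_center",
    "extract_hotspot_track",
    "fit_circle",
    "angle_series",
    "fit_ror",
]


@dataclass(frozen=True)
class HotspotTrack:
    """Hotspot positions (um) versus strictly increasing defocus (um)."""

    dz: np.ndarray
    xy: np.ndarray  # (n, 2): x along columns, y along rows
    method: str = "max_pixel"

    def __post_init__(self) -> None:
        dz = np.asarray(self.dz, dtype=float)
        xy = np.asarray(self.xy, dtype=float)
        if xy.shape != (dz.size, 2):
            raise ValueError("xy must be an (n, 2) array matching dz")
        if dz.size > 1 and not np.all(np.diff(dz) > 0):
            raise ValueError("dz must be strictly increasing")
        object.__setattr__(self, "dz", dz)
        object.__setattr__(self, "xy", xy)


@dataclass(frozen=True)
class CircleFit:
    center: tuple[float, float]
    radius: float
    rms_residual: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("fitted radius must be positive")


@dataclass(frozen=True)
class RORFit:
    slope: float  # rad / um
    intercept: float  # rad
    r_squared: float

    def __post_init__(self) -> None:
        if not -1e-9 <= self.r_squared <= 1 + 1e-9:
            raise ValueError("R^2 must lie in [0, 1]")


def hotspot_center(
    image: CameraImage | np.ndarray, method: str = "max_pixel", threshold: float = 0.9
) -> tuple[float, float]:
    """Hotspot position (x, y) in pixels within the image.

    ``max_pixel``: coordinates of the global intensity maximum (first in
    row-major order on ties).  ``com_threshold``: intensity-weighted
    centroid of all pixels at or above ``threshold`` times the maximum —
    the robust choice for noisy data.
    """
    v = image.values if isinstance(image, CameraImage) else np.asarray(image, dtype=float)
    if not np.any(v > 0):
        raise ValueError("image has no positive intensity")
    if method == "max_pixel":
        r, c = np.unravel_index(int(np.argmax(v)), v.shape)
        return float(c), float(r)
    if method == "com_threshold":
        sel = v >= threshold * v.max()
        rr, cc = np.nonzero(sel)
        w = v[rr, cc]
        return float((cc * w).sum() / w.sum()), float((rr * w).sum() / w.sum())
    raise ValueError(f"unknown hotspot method {method!r}")


def extract_hotspot_track(stack, method: str = "max_pixel", threshold: float = 0.9,
                          dz_range: tuple[float, float] | None = (-2.0, None)) -> HotspotTrack:
    """Hotspot centres of every plane of a defocus stack, in sample-plane
    micrometres relative to the image centre.

    ``dz_range`` restricts the planes used; the default drops planes below
    -2 um, where the single spot splits into two angularly separated lobes
    and its centre is ill-defined.  Pass ``None`` to keep all planes.
    """
    labels = stack.labels
    keep = np.ones(labels.size, dtype=bool)
    if dz_range is not None:
        lo, hi = dz_range
        if lo is not None:
            keep &= labels >= lo - 1e-9
        if hi is not None:
            keep &= labels <= hi + 1e-9
    h, w = stack.planes.shape[1:]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    pts = []
    for i in np.nonzero(keep)[0]:
        x, y = hotspot_center(stack.planes[i], method, threshold)
        pts.append(((x - cx) * stack.pixel_sample, (y - cy) * stack.pixel_sample))
    return HotspotTrack(labels[keep], np.asarray(pts), method)


def fit_circle(points: np.ndarray) -> CircleFit:
    """Least-squares circle through 2D points.

    Algebraic (Kasa) solution of ``x^2 + y^2 = 2*a*x + 2*b*y + c`` followed
    by geometric refinement minimizing radial residuals.  Requires at least
    three non-collinear points.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need an (n>=3, 2) array of points")
    x, y = pts[:, 0], pts[:, 1]
    centered = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[1] <= 1e-9 * max(sv[0], 1e-300):
        raise ValueError("points are collinear; no circle fit")
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    sol, *_ = np.linalg.lstsq(A, x * x + y * y, rcond=None)
    a, b, c = sol
    r2 = c + a * a + b * b
    if not np.isfinite(r2) or r2 <= 0:
        raise ValueError("points are collinear or degenerate; no circle fit")
    # geometric refinement
    def resid(p):
        return np.hypot(x - p[0], y - p[1]) - p[2]

    fit = least_squares(resid, x0=[a, b, np.sqrt(r2)], method="lm")
    cx, cy, r = fit.x
    if r <= 0:
        raise ValueError("degenerate circle fit")
    res = resid(fit.x)
    return CircleFit((float(cx), float(cy)), float(r), float(np.sqrt(np.mean(res**2))))


def angle_series(
    track: HotspotTrack | np.ndarray,
    center: tuple[float, float],
    sense: str = "cw",
) -> np.ndarray:
    """Unwrapped hotspot angles (rad) about ``center``, first point at 0.

    Adjacent angular steps are assumed smaller than pi.  ``sense="cw"``
    counts screen-clockwise rotation positive for row-down image
    coordinates; ``sense="ccw"`` is the standard y-up mathematical
    convention.
    """
    xy = track.xy if isinstance(track, HotspotTrack) else np.asarray(track, dtype=float)
    dx = xy[:, 0] - center[0]
    dy = xy[:, 1] - center[1]
    if np.any(np.hypot(dx, dy) == 0):
        raise ValueError("a point coincides with the circle center")
    raw = np.arctan2(dy, dx)
    if sense == "ccw":
        raw = -raw  # row-down axes: screen-CCW is negative atan2 direction
    elif sense != "cw":
        raise ValueError("sense must be 'cw' or 'ccw'")
    ang = np.unwrap(raw)
    return ang - ang[0]


def fit_ror(angles: np.ndarray, dz_values: np.ndarray) -> RORFit:
    """Ordinary least-squares line ``angle = slope * dz + intercept``."""
    ang = np.asarray(angles, dtype=float)
    dz = np.asarray(dz_values, dtype=float)
    if ang.size != dz.size or ang.size < 2:
        raise ValueError("need at least two (dz, angle) pairs")
    slope, intercept = np.polyfit(dz, ang, 1)
    pred = slope * dz + intercept
    ss_res = np.sum((ang - pred) ** 2)
    ss_tot = np.sum((ang - ang.mean()) ** 2)
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return RORFit(float(slope), float(intercept), float(min(max(r2, 0.0), 1.0)))
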