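"""Two-stage template-matching 3D localization.

Stage one matches a target image against a depth-labelled template library
by normalized (Pearson) cross-correlation over integer displacements; the
best template fixes the integer z-plane and the correlation argmax fixes
the integer (x, y).  Stage two refines: a general paraboloid (elliptic or
hyperbolic) least-squares fit to the 3x3 correlation neighbourhood gives
sub-pixel (x, y), and the analytic vertex of a parabola through the three
per-plane peak scores around the best plane gives sub-plane z.  Sub-pixel
fractions whose magnitude reaches one pixel (or whose fit is not a
maximum) are clamped to zero: the refinement stage is never allowed to
move the estimate by a whole pixel or plane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.feature import match_template

from .psf_sim import ImageStack

__all__ = [
    "TemplateLibrary",
    "CorrelationSurface",
    "LocalizationResult",
    "PrecisionReport",
    "build_template_library",
    "ncc_match",
    "best_template",
    "subpixel_xy",
    "subpixel_z",
    "localize",
    "evaluate_precision",
]


@dataclass(frozen=True)
class TemplateLibrary:
    """Depth-labelled square reference images of a single centred emitter.

    The canonical library holds 61 templates of 51x51 pixels labelled
    -3…+3 um in 100-nm steps.
    """

    templates: np.ndarray  # (n, s, s)
    dz_labels: np.ndarray  # (n,), um, strictly increasing, uniform step
    pixel_sample: float  # um / pixel in the sample plane

    def __post_init__(self) -> None:
        t = np.asarray(self.templates, dtype=float)
        labels = np.asarray(self.dz_labels, dtype=float)
        if t.ndim != 3 or t.shape[1] != t.shape[2]:
            raise ValueError("templates must be a stack of square images")
        if t.shape[1] % 2 == 0:
            raise ValueError("template side length must be odd")
        if labels.shape != (t.shape[0],):
            raise ValueError("one dz label per template required")
        steps = np.diff(labels)
        if labels.size > 1 and (np.any(steps <= 0) or not np.allclose(steps, steps[0])):
            raise ValueError("dz_labels must increase in uniform steps")
        object.__setattr__(self, "templates", t)
        object.__setattr__(self, "dz_labels", labels)

    def __len__(self) -> int:
        return self.templates.shape[0]

    @property
    def z_step(self) -> float:
        return float(self.dz_labels[1] - self.dz_labels[0]) if len(self) > 1 else 0.0

    @property
    def size(self) -> int:
        return self.templates.shape[1]


@dataclass(frozen=True)
class CorrelationSurface:
    """Pearson-normalized cross-correlation over integer displacements.

    ``values[j, i]`` is the correlation with the template's *centre* placed
    at displacement ``(dy, dx) = (j, i) - center_index`` from the target
    centre; only full-overlap placements are evaluated.
    """

    values: np.ndarray
    center_index: tuple[int, int]

    @property
    def peak_index(self) -> tuple[int, int]:
        j, i = np.unravel_index(int(np.argmax(self.values)), self.values.shape)
        return int(j), int(i)

    @property
    def peak_displacement(self) -> tuple[int, int]:
        """(dy, dx) of the maximum, pixels, relative to centred placement."""
        j, i = self.peak_index
        return j - self.center_index[0], i - self.center_index[1]

    @property
    def peak_value(self) -> float:
        j, i = self.peak_index
        return float(self.values[j, i])


def build_template_library(
    stack: ImageStack, center_xy: tuple[int, int], size: int = 51
) -> TemplateLibrary:
    """Crop one ``size`` x ``size`` template around pixel ``center_xy``
    (row, col) from every plane of a defocus stack."""
    if size % 2 == 0 or size < 3:
        raise ValueError("template size must be odd and >= 3")
    r0, c0 = center_xy
    half = size // 2
    n, h, w = stack.planes.shape
    if r0 - half < 0 or c0 - half < 0 or r0 + half >= h or c0 + half >= w:
        raise ValueError("template crop falls outside the stack planes")
    crops = stack.planes[:, r0 - half : r0 + half + 1, c0 - half : c0 + half + 1]
    return TemplateLibrary(crops.copy(), stack.labels, stack.pixel_sample)


def ncc_match(target: np.ndarray, template: np.ndarray) -> CorrelationSurface:
    """Normalized cross-correlation of a template against a target image
    at every full-overlap integer displacement.

    Each overlap window is compared after removing the mean and scaling to
    unit variance (Pearson), so the score is invariant to affine intensity
    changes of either image.  Ties in the argmax resolve to the first
    occurrence in row-major order.
    """
    target = np.asarray(target, dtype=float)
    template = np.asarray(template, dtype=float)
    if template.shape[0] > target.shape[0] or template.shape[1] > target.shape[1]:
        raise ValueError("template must not be larger than the target")
    if np.ptp(template) == 0:
        raise ValueError("template has zero variance")
    values = match_template(target, template, pad_input=False)
    center = ((target.shape[0] - template.shape[0]) // 2, (target.shape[1] - template.shape[1]) // 2)
    return CorrelationSurface(values, center)


def best_template(
    target: np.ndarray, library: TemplateLibrary
) -> tuple[int, np.ndarray, list[CorrelationSurface]]:
    """Index of the library template with the highest peak correlation.

    Returns ``(index, peak_scores, surfaces)`` with the full score-vs-plane
    curve retained for the sub-plane z refinement.  Ties resolve to the
    lower plane index.
    """
    if len(library) == 0:
        raise ValueError("template library is empty")
    surfaces = [ncc_match(target, library.templates[i]) for i in range(len(library))]
    scores = np.array([s.peak_value for s in surfaces])
    return int(np.argmax(scores)), scores, surfaces


def subpixel_xy(surface: CorrelationSurface) -> tuple[float, float]:
    """Sub-pixel (dx, dy) refinement of the correlation maximum.

    Least-squares fit of ``q(x, y) = a + bx + cy + dx^2 + exy + fy^2`` to
    the 3x3 neighbourhood of the peak; returns the stationary point if it
    is a true maximum with both offsets under one pixel, else (0, 0).
    """
    j, i = surface.peak_index
    v = surface.values
    if j == 0 or i == 0 or j == v.shape[0] - 1 or i == v.shape[1] - 1:
        warnings.warn("correlation maximum on the surface border; no sub-pixel fit")
        return 0.0, 0.0
    patch = v[j - 1 : j + 2, i - 1 : i + 2]
    yy, xx = np.mgrid[-1:2, -1:2].astype(float)
    x, y, q = xx.ravel(), yy.ravel(), patch.ravel()
    A = np.column_stack([np.ones(9), x, y, x * x, x * y, y * y])
    a, b, c, d, e, f = np.linalg.lstsq(A, q, rcond=None)[0]
    det = 4 * d * f - e * e
    if not (d < 0 and det > 0):  # stationary point is not a maximum
        return 0.0, 0.0
    dx = (c * e - 2 * b * f) / det
    dy = (b * e - 2 * c * d) / det
    if abs(dx) >= 1.0 or abs(dy) >= 1.0:
        return 0.0, 0.0
    return float(dx), float(dy)


def subpixel_z(scores: Sequence[float]) -> float:
    """Fractional plane offset from a parabola through three peak scores
    ``(s[p-1], s[p], s[p+1])``: vertex at
    ``(s[p-1] - s[p+1]) / (2 * (s[p-1] - 2*s[p] + s[p+1]))``.

    Returns 0 when the parabola is not concave (curvature >= 0) or the
    vertex lies a full plane or more away.
    """
    sm, s0, sp = (float(s) for s in scores)
    curv = sm - 2.0 * s0 + sp
    if curv >= 0:
        if curv == 0:
            warnings.warn("degenerate (flat) score triplet; sub-plane offset set to 0")
        return 0.0
    delta = (sm - sp) / (2.0 * curv)
    if abs(delta) >= 1.0:
        return 0.0
    return float(delta)


@dataclass(frozen=True)
class LocalizationResult:
    """Sub-pixel 3D localization of one target image.

    ``(x_px, y_px)`` is the emitter position relative to the target-image
    centre (pixels; x along columns, y along rows); ``(x_um, y_um)`` the
    same in sample-plane micrometres; ``z_um`` the depth from the template
    labels plus the sub-plane offset.
    """

    x_px: float
    y_px: float
    x_um: float
    y_um: float
    z_um: float
    best_plane: int
    peak_score: float
    edge_plane: bool = False

    def __post_init__(self) -> None:
        if abs(self.x_px - round(self.x_px)) >= 1 or abs(self.y_px - round(self.y_px)) >= 1:
            raise ValueError("sub-pixel fraction must have magnitude < 1")


def localize(target: np.ndarray, library: TemplateLibrary) -> LocalizationResult:
    """Full two-stage localization of a single emitter in ``target``."""
    p, scores, surfaces = best_template(target, library)
    surface = surfaces[p]
    dy, dx = surface.peak_displacement
    fx, fy = subpixel_xy(surface)
    edge = p == 0 or p == len(library) - 1
    if edge:
        dz_frac = 0.0
    else:
        dz_frac = subpixel_z(scores[p - 1 : p + 2])
    x_px, y_px = dx + fx, dy + fy
    z_um = float(library.dz_labels[p] + dz_frac * library.z_step)
    return LocalizationResult(
        x_px=x_px,
        y_px=y_px,
        x_um=x_px * library.pixel_sample,
        y_um=y_px * library.pixel_sample,
        z_um=z_um,
        best_plane=p,
        peak_score=surface.peak_value,
        edge_plane=edge,
    )


@dataclass(frozen=True)
class PrecisionReport:
    """Precision metrics against ground truth.

    Metric 1 (frame-to-frame agreement): measured per-step position changes
    ``dx_px, dy_px`` (pixels; truth 0) and ``dz_planes`` (planes; truth 1
    for a stack stepped one plane per frame).
    Metric 2 (per-plane precision): SD of the localization error at each
    ground-truth plane, in nm.
    """

    planes: np.ndarray
    sigma_x_nm: np.ndarray
    sigma_y_nm: np.ndarray
    sigma_z_nm: np.ndarray
    dx_px: np.ndarray
    dy_px: np.ndarray
    dz_planes: np.ndarray

    def mean_sigmas_nm(self) -> tuple[float, float, float]:
        """Mean per-plane precision (sigma_x, sigma_y, sigma_z), nm."""
        return (
            float(np.nanmean(self.sigma_x_nm)),
            float(np.nanmean(self.sigma_y_nm)),
            float(np.nanmean(self.sigma_z_nm)),
        )

    def step_histogram(self, axis: str, bin_width: float = 0.25):
        """Percentage histogram of per-step differences for ``axis`` in
        {'x', 'y', 'z'}; frequencies sum to 100."""
        data = {"x": self.dx_px, "y": self.dy_px, "z": self.dz_planes}[axis]
        lo = np.floor(data.min() / bin_width) * bin_width
        hi = np.ceil(data.max() / bin_width) * bin_width + bin_width / 2
        edges = np.arange(lo - bin_width / 2, hi + bin_width, bin_width)
        counts, edges = np.histogram(data, bins=edges)
        return edges, 100.0 * counts / counts.sum()


def evaluate_precision(
    results: Sequence[LocalizationResult],
    truth_xyz_um: np.ndarray,
    pixel_sample: float,
    z_step: float,
) -> PrecisionReport:
    """Compare localizations with ground truth positions (um).

    ``results`` and ``truth_xyz_um`` must be aligned frame-by-frame and
    ordered in acquisition order (step differences are taken between
    consecutive entries).  Per-plane SDs group frames by their true z.
    """
    truth = np.asarray(truth_xyz_um, dtype=float)
    if truth.shape != (len(results), 3):
        raise ValueError("truth must be an (n, 3) array aligned with results")
    meas = np.array([[r.x_um, r.y_um, r.z_um] for r in results])
    err_nm = (meas - truth) * 1e3
    planes = np.unique(truth[:, 2])
    sig = np.full((planes.size, 3), np.nan)
    for k, z in enumerate(planes):
        sel = truth[:, 2] == z
        if sel.sum() >= 2:
            sig[k] = err_nm[sel].std(axis=0)
        else:
            sig[k] = np.abs(err_nm[sel]).ravel()
    steps = np.diff(meas, axis=0)
    return PrecisionReport(
        planes=planes,
        sigma_x_nm=sig[:, 0],
        sigma_y_nm=sig[:, 1],
        sigma_z_nm=sig[:, 2],
        dx_px=steps[:, 0] / pixel_sample,
        dy_px=steps[:, 1] / pixel_sample,
        dz_planes=steps[:, 2] / z_step,
    )
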