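"""Scalar high-NA simulation of the single-spot rotating PSF.

The camera-plane field of a point emitter is modelled as the Fourier
transform of a pupil function

    P(u, phi) = A(u) * exp(i * [psi_spp + psi_defocus + psi_tilt]),

with ``u`` the normalized pupil radius, ``psi_spp`` the spiral-phase-plate
phase, the high-NA defocus term

    psi_defocus = s * (2*pi/lambda0) * n0 * dz * (1 - sqrt(1 - (NA*u/n0)^2)),

and a lateral tilt ``(2*pi/lambda0) * NA * u * (x*cos(phi) + y*sin(phi))``
encoding the emitter's in-plane position.  The apodization ``A(u)`` is
uniform over the pupil by default (an optional ``(1-(NA*u/n0)^2)^(-1/4)``
radiometric factor is available).  Intensity is the squared magnitude of
the transform, integrated onto the camera pixel grid.

Sampling is chosen from the camera geometry: the transform grid is sized so
its pitch equals ``sample_pixel / oversample``, which fixes the pupil
diameter in samples at ``2 * n_fft * dx * NA / lambda0``.  Images are
indexed ``[row, col]`` with the row index increasing downward (display
orientation); the defocus sign below makes the hotspot rotate clockwise in
that orientation as the emitter moves to larger ``dz``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spp_design import OpticalSystem, PhaseMask, SPPDesign, TWO_PI, _defocus_fraction

__all__ = [
    "EmitterPose",
    "SimulationGrid",
    "PupilField",
    "CameraImage",
    "ImageStack",
    "SamplingError",
    "RpsfSimulator",
    "defocus_phase",
    "pupil_field",
    "image_of_point",
    "simulate_stack",
]

#: Global defocus sign convention (see module docstring).
DEFOCUS_SIGN = -1.0


class SamplingError(ValueError):
    """Raised when the requested grid cannot resolve the pupil or pixels."""


@dataclass(frozen=True)
class EmitterPose:
    """Point-emitter position: lateral (x, y) and signed defocus dz, in
    sample-plane micrometres; dz = 0 is the Gaussian focal plane."""

    x: float = 0.0
    y: float = 0.0
    dz: float = 0.0
    photons: float = 1.0

    def __post_init__(self) -> None:
        if self.photons < 0:
            raise ValueError("photons must be nonnegative")


@dataclass(frozen=True)
class SimulationGrid:
    """Transform sampling: ``n_fft`` grid points per axis and ``oversample``
    sub-samples per camera pixel (odd, >= 3 so pixel centres align)."""

    n_fft: int = 1024
    oversample: int = 3
    apodization: str = "uniform"  # or "radiometric"

    def __post_init__(self) -> None:
        if self.oversample < 2:
            raise SamplingError("need >= 2 transform samples per camera pixel")
        if self.oversample % 2 == 0:
            raise SamplingError("oversample must be odd for centred pixel binning")
        if self.apodization not in ("uniform", "radiometric"):
            raise ValueError(f"unknown apodization {self.apodization!r}")


@dataclass(frozen=True)
class PupilField:
    """Complex pupil samples embedded in the transform grid."""

    values: np.ndarray  # (n_fft, n_fft) complex
    dx: float  # sample-plane pitch of the transform output (um)
    oversample: int
    pupil_radius_samples: float


@dataclass(frozen=True)
class CameraImage:
    """Nonnegative intensity on the camera pixel grid.

    ``pixel_camera`` is the physical pitch (um); ``pixel_sample`` the same
    pitch projected to the sample plane.  Pixel (r, c) of an odd-sized image
    is centred at ``((c - (w-1)/2), (r - (h-1)/2)) * pixel_sample``.
    """

    values: np.ndarray
    pixel_camera: float
    pixel_sample: float

    def __post_init__(self) -> None:
        if np.any(self.values < 0):
            raise ValueError("intensities must be nonnegative")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("intensities must be finite")

    def peak_normalized(self) -> "CameraImage":
        """Scale so the maximum intensity is 1."""
        peak = float(self.values.max())
        if peak == 0:
            return self
        return CameraImage(self.values / peak, self.pixel_camera, self.pixel_sample)


@dataclass(frozen=True)
class ImageStack:
    """Ordered planes with strictly monotone labels (defocus for z-stacks,
    time for movies) and shared pixel geometry."""

    planes: np.ndarray  # (n, h, w)
    labels: np.ndarray  # (n,)
    pixel_camera: float
    pixel_sample: float
    kind: str = "z"  # "z" or "t"

    def __post_init__(self) -> None:
        planes = np.asarray(self.planes)
        labels = np.asarray(self.labels, dtype=float)
        if planes.ndim != 3:
            raise ValueError("planes must be a (n, h, w) array")
        if labels.shape != (planes.shape[0],):
            raise ValueError("one label per plane required")
        if labels.size > 1 and not np.all(np.diff(labels) > 0):
            raise ValueError("labels must be strictly increasing")
        if self.kind not in ("z", "t"):
            raise ValueError("kind must be 'z' or 't'")
        object.__setattr__(self, "planes", planes)
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return self.planes.shape[0]

    def plane(self, i: int) -> CameraImage:
        return CameraImage(self.planes[i], self.pixel_camera, self.pixel_sample)


def defocus_phase(u, dz: float, system: OpticalSystem, sign: float = DEFOCUS_SIGN):
    """High-NA defocus phase (rad) at normalized pupil radius ``u`` for an
    emitter displaced ``dz`` um from the Gaussian focal plane."""
    u = np.asarray(u, dtype=float)
    if np.any(u < 0) or np.any(u > 1):
        raise ValueError("normalized radius must lie in [0, 1]")
    return sign * (TWO_PI / system.lambda0) * system.n0 * dz * _defocus_fraction(
        u, system.na, system.n0
    )


class RpsfSimulator:
    """Cached-grid simulator for repeated PSF evaluations.

    Precomputes the pupil support, spiral phase and defocus profile on the
    transform grid once, so per-pose work is one complex exponential and one
    FFT.  ``mask`` may be an :class:`SPPDesign` (phase evaluated analytically
    at every grid sample), a :class:`PhaseMask` (nearest-neighbour lookup),
    or ``None`` for the plain diffraction-limited pupil.
    """

    def __init__(
        self,
        system: OpticalSystem,
        mask: SPPDesign | PhaseMask | None,
        grid: SimulationGrid = SimulationGrid(),
    ) -> None:
        self.system = system
        self.grid = grid
        n = grid.n_fft
        self.dx = system.sample_pixel / grid.oversample
        # spatial frequency pitch and pupil radius in grid samples
        self.pupil_radius_samples = n * self.dx * system.na / system.lambda0
        if self.pupil_radius_samples < 12:
            raise SamplingError(
                f"pupil spans only {self.pupil_radius_samples:.1f} samples; "
                "increase n_fft or oversample"
            )
        if 2 * self.pupil_radius_samples > n:
            raise SamplingError("pupil does not fit in the transform grid")
        c = np.arange(n) - n // 2
        fx, fy = np.meshgrid(c, c)  # [row, col] = [y, x]
        with np.errstate(invalid="ignore"):
            u = np.hypot(fx, fy) / self.pupil_radius_samples
        self.support = u <= 1.0
        self._u = np.where(self.support, u, 0.0)
        phi = np.arctan2(fy, fx)
        if mask is None:
            spp = np.zeros_like(self._u)
        elif isinstance(mask, SPPDesign):
            spp = np.zeros_like(self._u)
            spp[self.support] = mask.zone_of(self._u[self.support]) * (
                phi[self.support] - mask.alignment_angle
            )
        elif isinstance(mask, PhaseMask):
            m = mask.n_samples
            ix = np.clip(np.round(fx / self.pupil_radius_samples * (m // 2)) + m // 2, 0, m - 1)
            iy = np.clip(np.round(fy / self.pupil_radius_samples * (m // 2)) + m // 2, 0, m - 1)
            spp = mask.values[iy.astype(int), ix.astype(int)]
        else:
            raise TypeError("mask must be SPPDesign, PhaseMask or None")
        self._spp_phase = np.where(self.support, spp, 0.0)
        self._w = _defocus_fraction(self._u, system.na, system.n0)
        # tilt direction cosines per grid sample
        self._tx = self._u * np.cos(phi)
        self._ty = self._u * np.sin(phi)
        if grid.apodization == "radiometric":
            apod = (1.0 - (system.na * self._u / system.n0) ** 2) ** -0.25
        else:
            apod = np.ones_like(self._u)
        self._apod = np.where(self.support, apod, 0.0)

    def pupil(self, pose: EmitterPose) -> PupilField:
        k = TWO_PI / self.system.lambda0
        phase = (
            self._spp_phase
            + DEFOCUS_SIGN * k * self.system.n0 * pose.dz * self._w
            + k * self.system.na * (pose.x * self._tx + pose.y * self._ty)
        )
        values = self._apod * np.exp(1j * phase)
        values[~self.support] = 0.0
        return PupilField(values, self.dx, self.grid.oversample, self.pupil_radius_samples)

    def intensity_fine(self, pose: EmitterPose) -> np.ndarray:
        """Squared-magnitude transform on the oversampled grid, scaled so
        the full-grid total equals ``pose.photons``."""
        p = self.pupil(pose)
        field = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(p.values)))
        inten = np.abs(field) ** 2
        total = inten.sum()
        if total > 0:
            inten *= pose.photons / total
        return inten

    def image(self, pose: EmitterPose, out_pixels: int = 51) -> CameraImage:
        """Camera image of the emitter, ``out_pixels`` square (odd), centred
        on the optical axis; pixel values integrate the oversampled
        intensity so they sum to the photon count captured by the window."""
        return _bin_to_camera(self.intensity_fine(pose), self, out_pixels)


def _bin_to_camera(fine: np.ndarray, sim: RpsfSimulator, out_pixels: int) -> CameraImage:
    if out_pixels % 2 == 0 or out_pixels < 1:
        raise ValueError("out_pixels must be odd and positive")
    os_ = sim.grid.oversample
    span = out_pixels * os_
    n = fine.shape[0]
    if span > n:
        raise SamplingError("output window exceeds the transform grid")
    start = n // 2 - span // 2
    window = fine[start : start + span, start : start + span]
    binned = window.reshape(out_pixels, os_, out_pixels, os_).sum(axis=(1, 3))
    return CameraImage(binned, sim.system.camera_pixel, sim.system.sample_pixel)


# ---------------------------------------------------------------------------
# functional surface


def pupil_field(
    pose: EmitterPose,
    system: OpticalSystem,
    mask: SPPDesign | PhaseMask | None,
    grid: SimulationGrid = SimulationGrid(),
) -> PupilField:
    """Pupil function of a point emitter (see module docstring)."""
    return RpsfSimulator(system, mask, grid).pupil(pose)


def image_of_point(
    pose: EmitterPose,
    system: OpticalSystem,
    mask: SPPDesign | PhaseMask | None,
    grid: SimulationGrid = SimulationGrid(),
    out_pixels: int = 51,
    peak_norm: bool = False,
) -> CameraImage:
    """Camera-plane intensity image of a single point emitter."""
    img = RpsfSimulator(system, mask, grid).image(pose, out_pixels)
    return img.peak_normalized() if peak_norm else img


def simulate_stack(
    pose_xy: tuple[float, float],
    z_labels,
    system: OpticalSystem,
    mask: SPPDesign | PhaseMask | None,
    photons: float = 1.0,
    grid: SimulationGrid = SimulationGrid(),
    out_pixels: int = 51,
    binned: bool = True,
) -> ImageStack:
    """Noiseless defocus stack of one emitter at fixed lateral position.

    One image per entry of ``z_labels`` (strictly increasing);
    deterministic given the configuration.  With ``binned=True`` (default)
    planes are integrated onto the camera pixel grid; with
    ``binned=False`` they stay at the transform's native sampling
    (``sample_pixel / oversample``) over the same field of view, which
    avoids camera-pixel quantization when analysing the simulated hotspot
    trajectory.
    """
    z_labels = np.asarray(z_labels, dtype=float)
    if z_labels.size > 1 and not np.all(np.diff(z_labels) > 0):
        raise ValueError("z_labels must be strictly increasing")
    sim = RpsfSimulator(system, mask, grid)
    x, y = pose_xy
    if binned:
        side, px_sample, px_cam = out_pixels, system.sample_pixel, system.camera_pixel
    else:
        side = out_pixels * grid.oversample
        px_sample = sim.dx
        px_cam = px_sample * system.magnification
    planes = np.empty((z_labels.size, side, side))
    for i, dz in enumerate(z_labels):
        pose = EmitterPose(x, y, dz, photons)
        if binned:
            planes[i] = sim.image(pose, out_pixels).values
        else:
            fine = sim.intensity_fine(pose)
            n = fine.shape[0]
            start = n // 2 - side // 2
            planes[i] = fine[start : start + side, start : start + side]
    return ImageStack(planes, z_labels, px_cam, px_sample, kind="z")
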