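"""Multi-zone spiral phase plate (SPP) design for a single-spot rotating PSF.

The plate divides the objective pupil into ``L`` concentric annular zones;
zone ``l`` (1-based) carries an azimuthal vortex phase ``l * phi``, wrapped
modulo 2*pi into ``l`` sub-ramps per turn ("spiral staircase").  Zone radii
are chosen so that the high-NA defocus function

    W(u) = 1 - sqrt(1 - (NA*u/n0)**2)

advances by an equal increment across every zone.  With that choice the
superposed vortex (Bessel-like) beams interfere constructively in a single
off-axis hotspot that rotates uniformly with emitter defocus, at the
analytic rate of rotation

    d(theta)/dz = 2*pi*n0 / (lambda0 * L) * (1 - sqrt(1 - NA**2/n0**2)).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "OpticalSystem",
    "SPPDesign",
    "PhaseMask",
    "CANONICAL_SYSTEM",
    "zone_boundaries",
    "spiral_phase_at",
    "render_phase_mask",
    "height_map",
    "analytic_ror",
    "full_rotation_range",
]

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class OpticalSystem:
    """Geometry and wavelengths of the imaging system.

    Parameters
    ----------
    na : float
        Numerical aperture of the objective.
    lambda0 : float
        Emission vacuum wavelength in micrometres.
    n0 : float
        Refractive index of the immersion medium.
    magnification : float
        Lateral magnification onto the camera.
    camera_pixel : float
        Camera pixel pitch in micrometres.
    z_step, z_min, z_max : float
        Axial sampling of the canonical defocus stack, micrometres.
    """

    na: float = 1.3
    lambda0: float = 0.525
    n0: float = 1.406
    magnification: float = 60.0
    camera_pixel: float = 6.48
    z_step: float = 0.1
    z_min: float = -3.0
    z_max: float = 3.0

    def __post_init__(self) -> None:
        if not 0.0 < self.na < self.n0:
            raise ValueError(f"require 0 < na < n0, got na={self.na}, n0={self.n0}")
        if self.lambda0 <= 0:
            raise ValueError("lambda0 must be positive")
        if self.magnification <= 0 or self.camera_pixel <= 0:
            raise ValueError("magnification and camera_pixel must be positive")
        if not (self.z_min < self.z_max and self.z_step > 0):
            raise ValueError("require z_min < z_max and z_step > 0")

    @property
    def sample_pixel(self) -> float:
        """Camera pixel pitch projected into the sample plane (um)."""
        return self.camera_pixel / self.magnification

    def z_labels(self) -> np.ndarray:
        """Defocus labels of the canonical stack (inclusive of both ends)."""
        n = int(round((self.z_max - self.z_min) / self.z_step)) + 1
        return self.z_min + self.z_step * np.arange(n)


#: Acquisition geometry used throughout: NA 1.3 silicone-oil objective
#: (n0 = 1.406), 525-nm emission, 60x magnification, 108-nm sample pixel,
#: 61 defocus planes from -3 to +3 um in 100-nm steps.
CANONICAL_SYSTEM = OpticalSystem()


def _defocus_fraction(u, na: float, n0: float):
    """High-NA defocus function W(u) = 1 - sqrt(1 - (na*u/n0)^2)."""
    a = np.asarray(u, dtype=float) * (na / n0)
    return 1.0 - np.sqrt(1.0 - a * a)


def zone_boundaries(L: int, na: float, n0: float) -> np.ndarray:
    """Normalized pupil radii ``u_0 .. u_L`` of the L annular zones.

    Boundary ``u_l`` solves ``W(u_l) = (l/L) * W(1)`` with
    ``W(u) = 1 - sqrt(1 - (na*u/n0)^2)``: equal increments of the high-NA
    defocus function per zone, which yields the uniform rotation rate.
    In the paraxial limit this reduces to ``u_l = sqrt(l/L)``.

    Returns an array of length ``L + 1`` with ``u_0 = 0`` and ``u_L = 1``.
    """
    if not (isinstance(L, (int, np.integer)) and L >= 1):
        raise ValueError(f"L must be a positive integer, got {L!r}")
    if not 0.0 < na < n0:
        raise ValueError(f"require 0 < na < n0, got na={na}, n0={n0}")
    w_full = _defocus_fraction(1.0, na, n0)
    frac = np.arange(L + 1) / L
    # invert W: (na*u/n0)^2 = 1 - (1 - f*W(1))^2
    u = (n0 / na) * np.sqrt(1.0 - (1.0 - frac * w_full) ** 2)
    u[0] = 0.0
    u[-1] = 1.0
    return u


@dataclass(frozen=True)
class SPPDesign:
    """An L-zone phase-wrapped spiral phase plate.

    Zone ``l`` (1-based) spans normalized radii
    ``[zone_boundaries[l-1], zone_boundaries[l])`` (the last zone is closed)
    and carries integer vortex charge ``l``.  All zones share one phase
    discontinuity azimuth, ``alignment_angle``.
    """

    num_zones: int = 7
    na: float = 1.3
    n0: float = 1.406
    alignment_angle: float = 0.0
    design_wavelength: float = 0.525
    substrate_index: float = 1.46
    boundaries: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.boundaries is None:
            object.__setattr__(
                self, "boundaries", zone_boundaries(self.num_zones, self.na, self.n0)
            )
        b = np.asarray(self.boundaries, dtype=float)
        if b.shape != (self.num_zones + 1,):
            raise ValueError("boundaries must have length num_zones + 1")
        if not (b[0] == 0.0 and b[-1] == 1.0 and np.all(np.diff(b) > 0)):
            raise ValueError("boundaries must increase strictly from 0 to 1")
        object.__setattr__(self, "boundaries", b)

    @property
    def charges(self) -> np.ndarray:
        """Per-zone vortex charge: zone l carries charge l."""
        return np.arange(1, self.num_zones + 1)

    def zone_of(self, u) -> np.ndarray:
        """1-based zone index containing radius ``u`` (half-open bins,
        final zone closed at u = 1)."""
        u = np.asarray(u, dtype=float)
        if np.any(u < 0) or np.any(u > 1):
            raise ValueError("normalized radius must lie in [0, 1]")
        idx = np.searchsorted(self.boundaries, u, side="right")
        return np.clip(idx, 1, self.num_zones)

    def with_effective_zones(self, L_effective: int) -> "SPPDesign":
        """Same optics but with an effective zone count, modelling the
        demagnified appearance of the plate at the objective exit pupil."""
        return replace(self, num_zones=L_effective, boundaries=None)


@dataclass(frozen=True)
class PhaseMask:
    """Wrapped optical phase sampled on a square grid over the pupil.

    ``values[j, i]`` is the phase (rad, in [0, 2*pi)) at normalized pupil
    coordinates ``(ux[i], uy[j])``; ``support`` flags samples with
    ``|u| <= 1``.  Values outside the support are unused.
    """

    values: np.ndarray
    support: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != self.support.shape or self.values.ndim != 2:
            raise ValueError("values and support must be equal-shape 2D grids")
        inside = self.values[self.support]
        if inside.size and (inside.min() < 0 or inside.max() >= TWO_PI):
            raise ValueError("in-support phases must lie in [0, 2*pi)")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


def spiral_phase_at(u, phi, design: SPPDesign):
    """Wrapped SPP phase at normalized radius ``u`` and azimuth ``phi``.

    Returns ``(l * (phi - alignment_angle)) mod 2*pi`` where ``l`` is the
    charge of the zone containing ``u``.
    """
    l = design.zone_of(u)
    return np.mod(l * (np.asarray(phi, dtype=float) - design.alignment_angle), TWO_PI)


def render_phase_mask(design: SPPDesign, n_samples: int = 512) -> PhaseMask:
    """Sample the wrapped spiral phase on an ``n_samples``-square grid over
    pupil coordinates; the grid is FFT-aligned (sample ``n_samples // 2``
    sits exactly at u = 0)."""
    if n_samples < 64:
        raise ValueError("n_samples must be at least 64")
    c = (np.arange(n_samples) - n_samples // 2) / (n_samples // 2)
    ux, uy = np.meshgrid(c, c)
    u = np.hypot(ux, uy)
    phi = np.arctan2(uy, ux)
    support = u <= 1.0
    values = np.zeros_like(u)
    values[support] = spiral_phase_at(u[support], phi[support], design)
    return PhaseMask(values=values, support=support)


def height_map(mask: PhaseMask, design: SPPDesign) -> np.ndarray:
    """Etch depth (um) realizing the mask in a transmissive substrate:
    ``h = phase * lambda_design / (2*pi * (n_substrate - 1))``."""
    if design.substrate_index <= 1.0:
        raise ValueError("substrate_index must exceed 1")
    scale = design.design_wavelength / (TWO_PI * (design.substrate_index - 1.0))
    return mask.values * scale


def analytic_ror(system: OpticalSystem, L: int) -> float:
    """Analytic hotspot rotation rate d(theta)/dz in rad/um.

    ``2*pi*n0 / (lambda0*L) * (1 - sqrt(1 - NA^2/n0^2))`` — for the
    canonical NA 1.3 / 525 nm / n0 1.406 / L = 7 system this is 1.49 rad/um.
    """
    if not (isinstance(L, (int, np.integer)) and L >= 1):
        raise ValueError(f"L must be a positive integer, got {L!r}")
    w = _defocus_fraction(1.0, system.na, system.n0)
    return TWO_PI * system.n0 / (system.lambda0 * L) * w


def full_rotation_range(system: OpticalSystem, L: int) -> float:
    """Axial range (um) over which the hotspot completes one full turn:
    ``2*pi / analytic_ror`` (4.2 um for the canonical system)."""
    return TWO_PI / analytic_ror(system, L)
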