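"""Synthetic acquisitions: noisy bead stacks, bead fields and Brownian movies.

Emulates the bead/cell experiments the pipeline is designed for: 61-plane
defocus stacks (−3…+3 um, 100-nm steps), fields of 4–20 beads at least 40
camera pixels apart, ten-replicate averaging, and 200-frame/0.3-s Brownian
movies of a diffusing emitter.  All generators are pure functions of
(configuration, seed).

Noise model: each noiseless frame is scaled to an expected photon budget,
a constant background is added, the sum is Poisson-sampled per pixel and
Gaussian read noise is added.  The signal-to-noise ratio is defined, as in
the bead experiments, as (hotspot peak − background mean) / background SD.
The default budget of 11 800 photons/frame is calibrated so the focal-plane
SNR is ~100 for the canonical system (peak pixel captures ~3.2% of the
photons; background 10 counts/px and 2-count read noise give a background
SD of sqrt(14)).  SNR then falls with defocus as the pattern spreads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .psf_sim import CameraImage, EmitterPose, ImageStack, RpsfSimulator, SimulationGrid
from .spp_design import OpticalSystem, PhaseMask, SPPDesign

__all__ = [
    "NoiseModel",
    "BeadField",
    "Track",
    "add_noise",
    "measure_snr",
    "make_bead_field",
    "brownian_track",
    "render_movie",
    "average_replicates",
]


@dataclass(frozen=True)
class NoiseModel:
    """Camera noise: Poisson shot noise on signal + background, plus
    Gaussian read noise.  Counts are arbitrary units calibrated only
    through the SNR definition above."""

    photon_budget: float = 11800.0
    background_level: float = 10.0
    read_noise_sd: float = 2.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.photon_budget, self.background_level, self.read_noise_sd) < 0:
            raise ValueError("noise parameters must be nonnegative")


@dataclass(frozen=True)
class BeadField:
    """Lateral bead positions (um, sample plane) with a minimum pairwise
    separation in camera pixels."""

    poses: tuple[EmitterPose, ...]
    min_separation_px: float


@dataclass(frozen=True)
class Track:
    """Time-stamped 3D positions (um); timestamps in seconds, strictly
    increasing."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    ground_truth: bool = True

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        arrs = {}
        for name in ("x", "y", "z"):
            a = np.asarray(getattr(self, name), dtype=float)
            if a.shape != t.shape:
                raise ValueError("t, x, y, z must have equal lengths")
            arrs[name] = a
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        object.__setattr__(self, "t", t)
        for name, a in arrs.items():
            object.__setattr__(self, name, a)

    def __len__(self) -> int:
        return self.t.size

    def positions(self) -> np.ndarray:
        """(n, 3) position array."""
        return np.column_stack([self.x, self.y, self.z])


def add_noise(image: CameraImage, model: NoiseModel, rng: np.random.Generator | None = None) -> CameraImage:
    """Noisy realization of a noiseless frame.

    The input is interpreted as a unit-budget rendering (expected photons
    per pixel for a total budget of 1, as produced by
    :class:`~ssrpsf.psf_sim.RpsfSimulator` with ``photons=1``); it is
    scaled by ``model.photon_budget`` before sampling, so one noiseless
    frame is reusable across photon budgets.
    """
    if rng is None:
        rng = np.random.default_rng(model.rng_seed)
    expected = image.values * model.photon_budget + model.background_level
    counts = rng.poisson(expected).astype(float)
    if model.read_noise_sd > 0:
        counts += rng.normal(0.0, model.read_noise_sd, size=counts.shape)
    return CameraImage(np.maximum(counts, 0.0), image.pixel_camera, image.pixel_sample)


def measure_snr(noisy: CameraImage, background_mask: np.ndarray | None = None) -> float:
    """SNR = (peak − background mean) / background SD.

    ``background_mask`` selects background-only pixels; by default the
    frame's 2-pixel border is used as "nearby background".
    """
    v = noisy.values
    if background_mask is None:
        background_mask = np.zeros(v.shape, dtype=bool)
        background_mask[:2, :] = background_mask[-2:, :] = True
        background_mask[:, :2] = background_mask[:, -2:] = True
    bg = v[background_mask]
    sd = bg.std()
    if sd == 0:
        raise ValueError("background has zero variance; cannot form an SNR")
    return float((v.max() - bg.mean()) / sd)


def make_bead_field(
    n_beads: int,
    field_shape: tuple[int, int],
    min_separation: float = 40.0,
    rng_seed: int = 0,
    margin: float = 26.0,
    max_tries: int = 10000,
    sample_pixel: float = OpticalSystem().sample_pixel,
) -> BeadField:
    """Rejection-sample ``n_beads`` lateral positions on a ``field_shape``
    (rows, cols) pixel field with all pairwise distances >= ``min_separation``
    pixels and at least ``margin`` pixels from the edges.

    Raises ``RuntimeError`` if the packing cannot be achieved within
    ``max_tries`` draws.
    """
    if n_beads < 1:
        raise ValueError("n_beads must be positive")
    rng = np.random.default_rng(rng_seed)
    h, w = field_shape
    if h - 2 * margin <= 0 or w - 2 * margin <= 0:
        raise ValueError("field too small for the requested margin")
    placed: list[np.ndarray] = []
    tries = 0
    while len(placed) < n_beads:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {n_beads} beads at separation "
                f"{min_separation} px in a {h}x{w} field"
            )
        tries += 1
        cand = rng.uniform([margin, margin], [h - margin, w - margin])
        if all(np.hypot(*(cand - p)) >= min_separation for p in placed):
            placed.append(cand)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    poses = tuple(
        EmitterPose(x=(p[1] - cx) * sample_pixel, y=(p[0] - cy) * sample_pixel)
        for p in placed
    )
    return BeadField(poses=poses, min_separation_px=min_separation)


def brownian_track(
    D: float,
    n_frames: int = 200,
    dt: float = 0.3,
    start_xyz: tuple[float, float, float] = (0.0, 0.0, 0.0),
    rng_seed: int = 0,
) -> Track:
    """Free 3D Brownian motion: independent Gaussian increments per axis
    with variance ``2*D*dt``.

    ``D`` is in nm^2/s; positions are returned in micrometres.  The
    defaults (200 frames, 0.3-s interval) mirror a 60-s single-particle
    tracking acquisition.
    """
    if D < 0:
        raise ValueError("D must be nonnegative")
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    rng = np.random.default_rng(rng_seed)
    sigma_um = np.sqrt(2.0 * D * dt) * 1e-3
    steps = rng.normal(0.0, sigma_um, size=(n_frames - 1, 3)) if sigma_um > 0 else np.zeros((n_frames - 1, 3))
    pos = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)]) + np.asarray(start_xyz, dtype=float)
    t = dt * np.arange(n_frames)
    return Track(t=t, x=pos[:, 0], y=pos[:, 1], z=pos[:, 2])


def render_movie(
    track: Track,
    system: OpticalSystem,
    mask: SPPDesign | PhaseMask | None,
    model: NoiseModel,
    grid: SimulationGrid = SimulationGrid(),
    out_pixels: int = 51,
) -> ImageStack:
    """One noisy camera frame per track point, with the emitter at
    ``(x_t, y_t)`` and defocus ``z_t`` (position sampled at frame start;
    motion blur within the exposure is not modelled)."""
    sim = RpsfSimulator(system, mask, grid)
    rng = np.random.default_rng(model.rng_seed)
    half_fov = (out_pixels // 2) * system.sample_pixel
    frames = np.empty((len(track), out_pixels, out_pixels))
    for i in range(len(track)):
        if abs(track.x[i]) > half_fov or abs(track.y[i]) > half_fov:
            raise ValueError(f"track leaves the field of view at frame {i}")
        clean = sim.image(
            EmitterPose(track.x[i], track.y[i], track.z[i], photons=1.0), out_pixels
        )
        frames[i] = add_noise(clean, model, rng).values
    return ImageStack(frames, track.t, system.camera_pixel, system.sample_pixel, kind="t")


def average_replicates(stacks: list[ImageStack]) -> ImageStack:
    """Per-pixel mean of replicate stacks of the same field of view.

    Averaging N replicates reduces the background noise SD by ~sqrt(N).
    """
    if not stacks:
        raise ValueError("need at least one stack")
    first = stacks[0]
    for s in stacks[1:]:
        if s.planes.shape != first.planes.shape or not np.array_equal(s.labels, first.labels):
            raise ValueError("replicate stacks must share shape and labels")
    mean = np.mean([s.planes for s in stacks], axis=0)
    return ImageStack(mean, first.labels, first.pixel_camera, first.pixel_sample, first.kind)
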