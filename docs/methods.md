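# Methods

`ssrpsf` implements end-to-end 3D single-particle localization with a
single-spot rotating point spread function (SS-RPSF): a multi-zone spiral
phase plate (SPP) in the pupil of a high-NA fluorescence microscope encodes
the emitter's defocus in the azimuth of a single bright lobe, and a
two-stage template-matching pipeline decodes sub-pixel (x, y, z) from 2D
camera frames.

## Plate design

The pupil is divided into `L` concentric annular zones (default `L = 7`);
zone `l` carries the vortex phase `l * (phi - phi_0)`, wrapped modulo 2π
into `l` sub-ramps per turn so the physical etch depth never exceeds one
design wavelength. All zones share one phase-discontinuity azimuth
`phi_0` (default 0). Zone radii solve

    W(u_l) = (l / L) * W(1),    W(u) = 1 - sqrt(1 - (NA * u / n0)^2)

— equal increments of the high-NA defocus function per zone. This is the
construction for which the lobe of the superposed vortex (Bessel-like)
beams rotates uniformly with defocus at the closed-form rate

    dθ/dz = (2π n0) / (λ0 L) * (1 - sqrt(1 - NA²/n0²)),

1.488 rad/μm for the canonical system (NA 1.3, λ0 525 nm, n0 1.406,
L 7), i.e. one full turn per 4.22 μm of depth. In the paraxial limit the
radii degenerate to `u_l = sqrt(l/L)` (equal-area Fresnel zones) and the
rate to `π NA² / (n0 λ0 L)`; both limits are covered by tests.

Zone membership at a boundary uses half-open intervals `[u_{l-1}, u_l)`
with the outermost zone closed — an arbitrary but fixed convention. The
etch-depth map assumes a fused-silica substrate (`n = 1.46` near 525 nm,
configurable); a full 2π phase step is then a 1.14-μm etch. An
`L_effective` knob (`SPPDesign.with_effective_zones`) models the apparent
demagnification of a plate mounted downstream of the objective exit
pupil, which raises the effective zone count and lowers the observed
rotation rate.

## PSF model

The camera field is the scalar Fourier transform of

    P(u, φ) = A(u) · exp(i [ψ_spp + ψ_defocus + ψ_tilt]),

with the high-NA defocus term `s · (2π/λ0) n0 dz W(u)` and the lateral
tilt `(2π/λ0) NA u (x cosφ + y sinφ)`. The apodization is uniform by
default; a `(1 - (NA u/n0)²)^(-1/4)` radiometric factor is available
(switching it moves none of the rotation observables measurably).
Polarization/dipole (vectorial) imaging is deliberately out of scope; the
scalar model reproduces the rotation-rate, linearity and helicity
observables this package targets (see "Known limitations" for the one
observable it does not pin down).

Images are indexed `[row, col]` with rows increasing downward (display
orientation). The defocus sign `s = -1` is fixed once so that the hotspot
rotates clockwise on screen as `dz` increases, which makes the fitted
rotation slope positive under the package's clockwise-positive angle
convention.

Sampling is derived from the camera geometry rather than a fixed pad
factor: the transform grid pitch is `sample_pixel / oversample`
(`oversample` odd, default 3, so camera pixels bin symmetrically), and the
pupil then spans `2 · n_fft · dx · NA/λ0` grid samples (~182 across at the
default `n_fft = 1024`), comfortably resolving the ±3-μm defocus phase
(≤ 0.6 rad per radial sample). Configurations that leave fewer than 2
samples per camera pixel or a pupil under 24 samples across raise a
`SamplingError`. Camera pixels integrate (sum) the oversampled intensity,
and frames are normalized so the full-grid energy equals the photon count,
making relative peak decay with defocus physical. Energy is conserved
through the transform (Parseval) to better than 1e-6 relative.

## Synthetic data

The generator emulates the bead and live-cell acquisitions the method was
designed for, with no external data:

- **Defocus stacks** — 61 planes, dz = -3…+3 μm in 100-nm steps, 51×51-px
  templates, 108-nm sample pixel (54 μm / 500 px at 60×; camera pitch
  6.48 μm).
- **Noise** — Poisson shot noise on signal + constant background plus
  Gaussian read noise. SNR is defined as (hotspot peak − background mean)
  / background SD, measured against the frame border. The default budget
  of 11 800 photons/frame is calibrated so the focal-plane SNR is ≈ 100
  (background 10 counts/px, read noise 2 counts); counts are arbitrary
  units since camera gain is not modelled. With a depth-independent
  budget the SNR falls with defocus as the pattern spreads — to ≈ 15 at
  ±3 μm under the scalar model, whose defocused peak decays faster than
  real acquisitions of this system (measured ≈ 28 there); tests therefore
  assert the focal calibration and the monotone decay, not a specific
  deep-defocus value.
- **Bead fields** — rejection-sampled positions with all pairwise
  separations ≥ 40 camera pixels (4.32 μm), 4–20 beads per 500×500-px
  field.
- **Brownian movies** — 200 frames at 0.3 s (a 60-s acquisition),
  per-axis Gaussian increments of variance `2 D dt`; positions are
  sampled at frame start (motion blur within the exposure is ignored).
  `D` defaults to the few-hundred-nm²/s regime typical of interphase
  chromatin loci.
- **Replicate averaging** — per-pixel mean of N seeded replicates of one
  field, reducing background SD by ≈ √N (ten replicates in the emulated
  protocol).

Every generator is a pure function of (configuration, seed). What passing
tests on these data do *not* show: robustness to spherical aberration and
depth-dependent "wobble", photobleaching, structured cellular background,
or camera-specific noise maps — none of which are modelled.

## Localization

Stage one: Pearson-normalized cross-correlation (`skimage.feature.
match_template`) of the target against each depth-labelled template at
every full-overlap integer displacement; the best template fixes the
plane and the argmax the integer shift (ties: first in row-major order).
Stage two: a general paraboloid (elliptic or hyperbolic) least-squares
fit to the 3×3 correlation neighbourhood gives sub-pixel x/y from its
stationary point, and the analytic vertex of the parabola through the
three per-plane peak scores gives sub-plane z:

    δ = (s_{p-1} - s_{p+1}) / (2 (s_{p-1} - 2 s_p + s_{p+1})).

Clamping: any refinement whose magnitude reaches one pixel/plane, or
whose fitted surface is not a maximum (hyperbolic fit, non-concave
triplet, border argmax), contributes 0 — refinement is never allowed to
move the estimate by a whole pixel. The one-pixel clamp is stated for z
in the original procedure and applied symmetrically to x/y here for
robustness. Edge planes (best template first or last) get δ = 0 and are
flagged. On noiseless synthetic stacks the closed loop recovers z within
half a 100-nm step at every interior plane; note that plane
discrimination degrades for emitters at half-pixel lateral offsets, where
the sub-pixel pattern shift competes with the per-plane rotation
(≈ 0.6 px of arc per 100-nm step).

Precision reporting follows the two experimental metrics: per-step
position differences (truth: 0 px laterally, 1 plane axially for a
stepped stack) and the per-plane SD of the localization error.

## Trajectory and diffusion analysis

Hotspot centres come from either the global maximum pixel (clean
simulated images) or the intensity-weighted centroid of pixels ≥ 0.9 of
the maximum (noisy data). The trajectory circle is fitted algebraically
(Kåsa linearization) and refined by geometric least squares; angles about
the fitted centre are unwrapped assuming sub-π steps and fitted against
depth by ordinary least squares. The -3…-2 μm region, where the single
spot splits into two angularly separated lobes, is excluded from
trajectory fits by default. Trajectory radii are reported in camera-plane
micrometres (sample coordinates × magnification). For trajectory
analysis of simulated stacks the hotspot is extracted at the transform's
native sampling (`binned=False`, 36-nm pitch) rather than the 108-nm
camera grid: the orbit radius is only ~4 camera pixels, and max-pixel
quantization at camera pitch would dominate the angular residuals.

Time-averaged MSD uses all overlapping pairs at each lag; the diffusion
coefficient is the ordinary least-squares slope over the first 25% of
lags (configurable — large-lag points average few pairs and are noisy)
divided by `2 n` (`n` the dimensionality), with a free intercept that
absorbs the localization-noise offset.

## Numerical choices and degenerate inputs

- Zone boundaries come from the closed-form inversion of the defining
  equation (no iteration); a bisection solve serves as the test oracle.
- FFT conventions (`fftshift`/`ifftshift` pairing) place an on-axis
  emitter's pattern at the grid centre sample; the rendered-mask lookup
  is nearest-neighbour (phase wraps make interpolation meaningless).
- Collinear points are rejected in the circle fit via the singular values
  of the centred point cloud; all-zero images, zero-variance templates,
  non-monotone labels and non-uniform time stamps raise `ValueError`.
- Simulation problem sizes in tests: 512-point transforms for unit tests
  and the closed-loop library, 1024 for the canonical 51-plane rotation
  analysis — sizes at which all reported observables are converged to
  well within their stated tolerances.

## Known limitations

- The scalar (and an exploratory vectorial) model places the hotspot
  orbit at ≈ 26 μm camera-plane radius for the documented 7-zone design,
  while the fabricated system shows ≈ 40 μm; the radius — unlike the
  rotation rate — is sensitive to the exact fabricated zone radii and
  charge layout, which are not public. The rotation rate, linearity
  (R² > 0.999), helicity reversal and angular excess are reproduced.
- Single-emitter analysis only: no overlap resolution, no PSF-model
  (MLE) fitting, no deconvolution or learned localizers.
- No aberration, index-mismatch or wobble modelling; the template library
  and targets share the same ideal optics.
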