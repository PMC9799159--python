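"""Time-averaged mean-squared displacement and diffusion estimation.

For a uniformly sampled track r(t), the time-averaged MSD at lag tau = k*dt
averages the squared displacement over every overlapping pair of time
points.  Free diffusion in n dimensions obeys MSD(tau) = 2*n*D*tau, so D
is the fitted MSD slope divided by 2n (6 in 3D).  The fit intercept is
left free: it absorbs the constant offset produced by localization noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic_data import Track

__all__ = ["MSDCurve", "DiffusionEstimate", "msd", "fit_diffusion"]


@dataclass(frozen=True)
class MSDCurve:
    """Lag-averaged displacement statistics of one track.

    ``values`` is the 3D MSD in um^2 at each lag (s); per-axis components
    satisfy ``values = msd_x + msd_y + msd_z`` exactly; ``n_pairs`` counts
    the displacement pairs averaged at each lag.
    """

    lags: np.ndarray
    values: np.ndarray
    msd_x: np.ndarray
    msd_y: np.ndarray
    msd_z: np.ndarray
    n_pairs: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.values < 0):
            raise ValueError("MSD values must be nonnegative")


@dataclass(frozen=True)
class DiffusionEstimate:
    """Diffusion coefficient from a linear MSD fit."""

    D: float  # nm^2 / s
    n_dims: int
    fit_lags: np.ndarray  # s
    slope: float  # um^2 / s
    intercept: float  # um^2
    slope_stderr: float  # um^2 / s

    def __post_init__(self) -> None:
        if self.n_dims not in (1, 2, 3):
            raise ValueError("n_dims must be 1, 2 or 3")


def msd(track: Track, max_lag_fraction: float = 0.25) -> MSDCurve:
    """Time-averaged MSD of a uniformly sampled track.

    Lags run from dt to ``max_lag_fraction`` of the track duration
    (default the first quarter — larger lags average too few pairs to be
    useful).  Raises on non-uniform sampling.
    """
    if len(track) < 2:
        raise ValueError("need at least two track points")
    dts = np.diff(track.t)
    if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-12):
        raise ValueError("track must be uniformly sampled in time")
    dt = float(dts[0])
    n = len(track)
    max_lag = max(1, int(np.floor(max_lag_fraction * (n - 1))))
    pos = track.positions()  # (n, 3) um
    lags = dt * np.arange(1, max_lag + 1)
    per_axis = np.empty((max_lag, 3))
    n_pairs = np.empty(max_lag, dtype=int)
    for k in range(1, max_lag + 1):
        d = pos[k:] - pos[:-k]
        per_axis[k - 1] = np.mean(d * d, axis=0)
        n_pairs[k - 1] = d.shape[0]
    return MSDCurve(
        lags=lags,
        values=per_axis.sum(axis=1),
        msd_x=per_axis[:, 0],
        msd_y=per_axis[:, 1],
        msd_z=per_axis[:, 2],
        n_pairs=n_pairs,
    )


def fit_diffusion(
    curve: MSDCurve, n_dims: int = 3, fit_lags: np.ndarray | None = None, component: str = "3d"
) -> DiffusionEstimate:
    """Diffusion coefficient from an ordinary least-squares line through
    the MSD curve: ``D = slope / (2 * n_dims)``, reported in nm^2/s.

    ``component`` selects the curve fitted: '3d' (default) or a single
    axis 'x' / 'y' / 'z' (use ``n_dims=1`` with an axis component).
    """
    y = {"3d": curve.values, "x": curve.msd_x, "y": curve.msd_y, "z": curve.msd_z}[component]
    lags = curve.lags if fit_lags is None else np.asarray(fit_lags, dtype=float)
    sel = np.isin(curve.lags, lags)
    if sel.sum() < 2:
        raise ValueError("need at least two lags to fit")
    t, m = curve.lags[sel], y[sel]
    if t.size > 2:
        (slope, intercept), cov = np.polyfit(t, m, 1, cov=True)
        stderr = float(np.sqrt(cov[0, 0]))
    else:
        slope, intercept = np.polyfit(t, m, 1)
        stderr = float("nan")
    D_um2 = slope / (2.0 * n_dims)
    return DiffusionEstimate(
        D=float(D_um2 * 1e6),
        n_dims=n_dims,
        fit_lags=t,
        slope=float(slope),
        intercept=float(intercept),
        slope_stderr=stderr,
    )
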