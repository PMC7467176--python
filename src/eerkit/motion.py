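"""Trajectory interpolation, shift-compensated application, exposure weighting.

Beam-induced motion is measured from a modest number of exposure fractions
(motion *estimation* is out of scope here — existing aligners do that), and
the measured knots are then interpolated to the camera frame rate before
being applied at the event level:

* ``spline`` mode fits an interpolating cubic B-spline through the knots
  and evaluates it at every frame time, continuing linearly beyond the
  terminal knots.  An optional smoothing parameter switches to a penalized
  smoothing spline.
* ``piecewise_constant`` mode assigns each frame its fraction's knot value
  unchanged — the behaviour of conventional fraction-level processing, kept
  as the control.

Knot times default to fraction centres ((start + end - 1)/2 in frame units):
a shift measured from a fraction is an average over that fraction's frames,
so anchoring it mid-fraction minimises systematic lag.

Exposure weighting down-weights spatial frequency k in later frames as
``w(k, N) = exp(-N / (2 Nc(k)))`` where N is the cumulative exposure
(e-/A^2) and ``Nc(k) = a k**-b + c`` is the resolution-dependent critical
exposure.  The default constants (a = 0.245, b = 1.665, c = 2.81) are the
published critical-exposure measurements commonly used by movie-processing
pipelines; they are configuration, not constants of this package.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.interpolate import make_interp_spline, make_smoothing_spline

from .errors import ValidationError
from .events import EventMovie, GainReference
from .render import RasterReport, RenderSpec, rasterize

__all__ = [
    "Trajectory",
    "ExposureWeightParams",
    "fraction_centers",
    "interpolate_trajectory",
    "apply_trajectory",
    "residual_blur",
    "critical_exposure",
    "exposure_weights",
    "exposure_weighted_average",
    "read_trajectory",
    "write_trajectory",
]


@dataclass
class Trajectory:
    """Measured motion knots: times (frame units) and (dx, dy) shifts (pixels)."""

    knot_times: np.ndarray
    knot_shifts: np.ndarray  # (n_knots, 2), physical-pixel units
    mode: Literal["spline", "piecewise_constant"] = "spline"
    smoothing: float | None = None  # lambda of a penalized smoothing spline

    def __post_init__(self) -> None:
        self.knot_times = np.asarray(self.knot_times, dtype=np.float64)
        self.knot_shifts = np.asarray(self.knot_shifts, dtype=np.float64)
        if self.knot_shifts.ndim != 2 or self.knot_shifts.shape[1] != 2:
            raise ValidationError("knot_shifts must be an (n_knots, 2) array")
        if self.knot_times.shape[0] != self.knot_shifts.shape[0]:
            raise ValidationError("knot_times and knot_shifts disagree in length")
        if np.any(np.diff(self.knot_times) <= 0):
            raise ValidationError("knot_times must be strictly ascending")
        if self.mode == "spline" and self.knot_times.shape[0] < 2:
            raise ValidationError("spline mode needs at least 2 knots")


def fraction_centers(n_frames: int, frames_per_fraction: int) -> np.ndarray:
    """Centre time (frame units) of each complete fraction."""
    if frames_per_fraction < 1:
        raise ValidationError("frames_per_fraction must be >= 1")
    n_fractions = n_frames // frames_per_fraction
    starts = np.arange(n_fractions) * frames_per_fraction
    return starts + (frames_per_fraction - 1) / 2.0


def _spline_axis(t: np.ndarray, y: np.ndarray, times: np.ndarray,
                 smoothing: float | None) -> np.ndarray:
    k = min(3, t.shape[0] - 1)
    if smoothing is not None and t.shape[0] > 3:
        sp = make_smoothing_spline(t, y, lam=smoothing)
    else:
        sp = make_interp_spline(t, y, k=k)
    out = sp(times)
    # Linear continuation beyond terminal knots with the terminal slope.
    der = sp.derivative() if k >= 1 else None
    lo, hi = t[0], t[-1]
    before, after = times < lo, times > hi
    if der is not None:
        out[before] = sp(lo) + der(lo) * (times[before] - lo)
        out[after] = sp(hi) + der(hi) * (times[after] - hi)
    else:
        out[before] = y[0]
        out[after] = y[-1]
    return out


def interpolate_trajectory(
    traj: Trajectory,
    n_frames: int,
    frames_per_fraction: int | None = None,
) -> np.ndarray:
    """Per-frame (dx, dy) shifts, shape (n_frames, 2).

    Spline mode evaluates the (optionally smoothed) cubic spline at every
    frame time with linear extrapolation outside the knot span.  Piecewise
    mode replicates each fraction's knot value over that fraction's frames
    and needs ``frames_per_fraction`` to delimit fractions.
    """
    if n_frames < 1:
        raise ValidationError("n_frames must be >= 1")
    times = np.arange(n_frames, dtype=np.float64)
    if traj.mode == "spline":
        out = np.empty((n_frames, 2))
        for ax in range(2):
            out[:, ax] = _spline_axis(
                traj.knot_times, traj.knot_shifts[:, ax], times, traj.smoothing
            )
        return out
    # piecewise_constant
    if frames_per_fraction is None:
        frames_per_fraction = max(1, n_frames // traj.knot_times.shape[0])
    if np.any(traj.knot_times < 0) or np.any(traj.knot_times >= n_frames):
        raise ValidationError("piecewise mode needs knots inside [0, n_frames)")
    idx = np.minimum(times.astype(np.int64) // frames_per_fraction,
                     traj.knot_shifts.shape[0] - 1)
    return traj.knot_shifts[idx]


def apply_trajectory(
    movie: EventMovie,
    shifts: np.ndarray,
    spec: RenderSpec = RenderSpec(),
    gain: GainReference | None = None,
) -> tuple[np.ndarray, RasterReport]:
    """Motion-corrected supersampled image via shift-compensated placement.

    Each electron is deposited at its trajectory-compensated position
    (see :func:`eerkit.render.rasterize`); no image interpolation occurs.
    """
    return rasterize(movie, spec, gain, shifts=shifts)


def residual_blur(true_shifts: np.ndarray, applied_shifts: np.ndarray) -> float:
    """RMS deviation (pixels) between applied and true per-frame positions.

    The deposited position of an electron in frame f is off by
    ``applied[f] - true[f]``; with electrons spread uniformly over frames
    the RMS over frames measures the residual blur of the corrected image.
    """
    true_shifts = np.asarray(true_shifts, dtype=np.float64)
    applied_shifts = np.asarray(applied_shifts, dtype=np.float64)
    if true_shifts.shape != applied_shifts.shape:
        raise ValidationError("shift tables must have the same shape")
    d = applied_shifts - true_shifts
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


# ---------------------------------------------------------------------------
# exposure weighting
# ---------------------------------------------------------------------------


@dataclass
class ExposureWeightParams:
    """Critical-exposure curve Nc(k) = a * k**-b + c (k in 1/A, Nc in e-/A^2)."""

    a: float = 0.245
    b: float = 1.665
    c: float = 2.81

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0 or self.c <= 0:
            raise ValidationError("critical-exposure constants must be positive")


def critical_exposure(k: np.ndarray, params: ExposureWeightParams) -> np.ndarray:
    """Nc(k); diverges at k = 0 (no damage limit at zero frequency)."""
    k = np.asarray(k, dtype=np.float64)
    with np.errstate(divide="ignore"):
        return params.a * np.power(k, -params.b, where=k > 0,
                                   out=np.full_like(k, np.inf)) + params.c


def exposure_weights(
    spatial_freq: np.ndarray,
    cumulative_exposure: float,
    params: ExposureWeightParams = ExposureWeightParams(),
) -> np.ndarray:
    """w(k, N) = exp(-N / (2 Nc(k))) for cumulative exposure N (e-/A^2)."""
    if cumulative_exposure < 0:
        raise ValidationError("cumulative exposure must be non-negative")
    nc = critical_exposure(spatial_freq, params)
    return np.exp(-cumulative_exposure / (2.0 * nc))


def _freq_grid(shape: tuple[int, int], pixel_size: float) -> np.ndarray:
    ky = np.fft.fftfreq(shape[0], d=pixel_size)
    kx = np.fft.fftfreq(shape[1], d=pixel_size)
    return np.sqrt(ky[:, None] ** 2 + kx[None, :] ** 2)


def exposure_weighted_average(
    fractions: np.ndarray,
    cumulative_exposures: np.ndarray,
    params: ExposureWeightParams = ExposureWeightParams(),
    pixel_size: float = 1.0,
    normalize: Literal["none", "sum_sq"] = "none",
) -> np.ndarray:
    """Frequency-weighted sum of fraction images.

    ``cumulative_exposures[f]`` is the exposure (e-/A^2) accumulated on the
    specimen by the (centre of) fraction f.  With ``normalize="sum_sq"``
    the summed weights are scaled so the per-frequency sum of squared
    weights is 1, keeping the noise power spectrum flat — the convention of
    several movie-processing tools; ``"none"`` leaves the plain weighted sum.
    """
    fractions = np.asarray(fractions, dtype=np.float64)
    if fractions.ndim != 3:
        raise ValidationError("fractions must be a (n, h, w) stack")
    cumulative_exposures = np.asarray(cumulative_exposures, dtype=np.float64)
    if cumulative_exposures.shape[0] != fractions.shape[0]:
        raise ValidationError("one cumulative exposure per fraction is required")
    if np.any(np.diff(cumulative_exposures) < 0):
        raise ValidationError("cumulative exposures must be ascending")

    kgrid = _freq_grid(fractions.shape[1:], pixel_size)
    acc = np.zeros(fractions.shape[1:], dtype=np.complex128)
    wsq = np.zeros(fractions.shape[1:], dtype=np.float64)
    for img, n in zip(fractions, cumulative_exposures):
        w = exposure_weights(kgrid, float(n), params)
        acc += w * np.fft.fft2(img)
        wsq += w * w
    if normalize == "sum_sq":
        acc /= np.sqrt(np.maximum(wsq, np.finfo(np.float64).tiny))
    return np.fft.ifft2(acc).real


# ---------------------------------------------------------------------------
# plain-text trajectory tables
# ---------------------------------------------------------------------------

def write_trajectory(path, times: np.ndarray, shifts: np.ndarray) -> None:
    """Write a (time, dx, dy) table; shifts in physical pixels."""
    table = np.column_stack([times, np.asarray(shifts)])
    np.savetxt(path, table, header="time_frames dx_px dy_px")


def read_trajectory(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a (time, dx, dy) table written by :func:`write_trajectory`."""
    table = np.atleast_2d(np.loadtxt(path))
    if table.shape[1] != 3:
        raise ValidationError("trajectory table must have 3 columns: t, dx, dy")
    return table[:, 0], table[:, 1:3]
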