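"""Synthetic event-movie generator with ground truth.

Emulates what a counting detector sees: electrons arrive as a Poisson
process over a (possibly drifting) specimen intensity pattern defined on
the u-times supersampled lattice, and the hardware records at most one
electron per physical pixel per frame.

Two arrival models are offered:

* ``coincidence=True`` (default): independent Poisson arrivals per
  supersampled cell; all arrivals within one physical pixel in one frame
  collapse to a single recorded event at one arrival's subpixel cell, so
  coincidence loss emerges mechanistically and can be compared with the
  closed form ``1 - (1 - exp(-lam))/lam``.
* ``coincidence=False``: at most one electron is drawn per physical pixel
  (Bernoulli with probability equal to the pixel's summed cell intensity,
  subpixel chosen proportionally to the within-pixel intensity).  Expected
  counts equal rate x duration x N_pixels exactly, and the stream satisfies
  the one-event-per-pixel movie invariant by construction — which the RLE
  gap encoding requires.  This mode needs the per-pixel rate <= 1.

At low rates the two models agree to first order and both induce the
Bernoulli hit probability p = exposure_rate / frame_rate of the size model.

Everything is deterministic under the config seed: same seed, same movie,
bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np

from .errors import ValidationError
from .events import (
    AcquisitionMetadata,
    DetectorGeometry,
    EventMovie,
    GainReference,
)

__all__ = [
    "UniformSpecimen",
    "GratingSpecimen",
    "ImageSpecimen",
    "LinearDrift",
    "DecayingDrift",
    "TableDrift",
    "SimulationConfig",
    "SimulationResult",
    "simulate_movie",
    "make_grating",
    "make_gain_map",
    "trajectory_shifts",
]


# ---------------------------------------------------------------------------
# specimen patterns (intensity relative to the mean, on the u-grid)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class UniformSpecimen:
    """Featureless specimen: intensity 1 everywhere."""


@dataclass(frozen=True)
class GratingSpecimen:
    """Sinusoidal grating: 1 + contrast*cos(2 pi f (x cos t + y sin t)).

    ``freq`` is in cycles per *physical* pixel and may exceed the physical
    Nyquist of 0.5 — recovering such gratings is the point of the
    super-resolution tests.
    """

    freq: float
    orientation_deg: float = 0.0
    contrast: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.contrast <= 1:
            raise ValidationError("contrast must lie in (0, 1] "
                                  "(larger would go negative)")
        if self.freq < 0:
            raise ValidationError("freq must be non-negative")


@dataclass(frozen=True)
class ImageSpecimen:
    """Caller-supplied non-negative intensity image on the u-grid (mean ~1)."""

    intensity: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensity, dtype=np.float64)
        if np.any(arr < 0):
            raise ValidationError("specimen intensity must be non-negative")
        object.__setattr__(self, "intensity", arr)


Specimen = Union[UniformSpecimen, GratingSpecimen, ImageSpecimen]


# ---------------------------------------------------------------------------
# ground-truth drift trajectories (physical-pixel units)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LinearDrift:
    """Constant velocity (pixels per frame)."""

    vx: float
    vy: float


@dataclass(frozen=True)
class DecayingDrift:
    """Exponentially decaying velocity: d(t) = v0*tau*(1 - exp(-t/tau)).

    Mimics the fast early beam-induced motion that slows as the exposure
    proceeds; ``tau`` is in frames.
    """

    v0x: float
    v0y: float
    tau: float

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValidationError("tau must be positive")


@dataclass(frozen=True)
class TableDrift:
    """Explicit per-frame shifts, shape (n_frames, 2)."""

    shifts: np.ndarray


Drift = Union[LinearDrift, DecayingDrift, TableDrift, None]


def trajectory_shifts(trajectory: Drift, n_frames: int) -> np.ndarray:
    """Evaluate a drift model at every frame time; shape (n_frames, 2)."""
    t = np.arange(n_frames, dtype=np.float64)
    if trajectory is None:
        return np.zeros((n_frames, 2))
    if isinstance(trajectory, LinearDrift):
        return np.column_stack([trajectory.vx * t, trajectory.vy * t])
    if isinstance(trajectory, DecayingDrift):
        fac = trajectory.tau * (1.0 - np.exp(-t / trajectory.tau))
        return np.column_stack([trajectory.v0x * fac, trajectory.v0y * fac])
    shifts = np.asarray(trajectory.shifts, dtype=np.float64)
    if shifts.shape != (n_frames, 2):
        raise ValidationError("drift table shape must be (n_frames, 2)")
    return shifts


# ---------------------------------------------------------------------------
# configuration / result
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic movie.

    Defaults follow the published worked example for a counting camera:
    a sensor read at 240 frames/s with an exposure rate of 3 e-/pixel/s,
    i.e. p = 0.0125 per pixel per frame, with 4x4 subpixels.
    """

    geometry: DetectorGeometry
    exposure_rate: float = 3.0      # e-/pixel/s
    duration: float = 1.0           # s; n_frames = round(duration*frame_rate)
    pixel_size: float = 1.0         # A per physical pixel
    specimen: Specimen = field(default_factory=UniformSpecimen)
    trajectory: Drift = None
    coincidence: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.exposure_rate < 0:
            raise ValidationError("exposure_rate must be non-negative")
        if self.duration < 0:
            raise ValidationError("duration must be non-negative")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.geometry.frame_rate))


@dataclass
class SimulationResult:
    """Simulated movie plus the ground truth that produced it."""

    movie: EventMovie
    true_shifts: np.ndarray     # (n_frames, 2), physical pixels
    n_arrivals: int             # electrons before coincidence collapse
    n_events: int               # electrons recorded

    @property
    def loss_fraction(self) -> float:
        """Realized coincidence loss."""
        if self.n_arrivals == 0:
            return 0.0
        return 1.0 - self.n_events / self.n_arrivals


# ---------------------------------------------------------------------------
# pattern evaluation
# ---------------------------------------------------------------------------


def make_grating(
    geometry: DetectorGeometry,
    freq: float,
    orientation_deg: float = 0.0,
    contrast: float = 0.5,
    shift: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Evaluate a grating on the supersampled lattice (mean 1).

    ``shift`` displaces the pattern by (dx, dy) physical pixels, exactly —
    used by the simulator to drift the specimen under the detector.
    """
    GratingSpecimen(freq, orientation_deg, contrast)  # validate
    u = geometry.u
    x = (np.arange(geometry.width * u) + 0.5) / u - shift[0]
    y = (np.arange(geometry.height * u) + 0.5) / u - shift[1]
    th = np.deg2rad(orientation_deg)
    phase = 2 * np.pi * freq * (x[None, :] * np.cos(th) + y[:, None] * np.sin(th))
    return 1.0 + contrast * np.cos(phase)


def _intensity(specimen: Specimen, geometry: DetectorGeometry,
               shift: np.ndarray) -> np.ndarray | None:
    """Pattern on the u-grid at the given drift; None means uniform."""
    if isinstance(specimen, UniformSpecimen):
        return None
    if isinstance(specimen, GratingSpecimen):
        return make_grating(geometry, specimen.freq, specimen.orientation_deg,
                            specimen.contrast, shift=(shift[0], shift[1]))
    arr = specimen.intensity
    if arr.shape != geometry.super_shape:
        raise ValidationError("specimen image must match the supersampled grid")
    u = geometry.u
    return np.roll(
        np.roll(arr, int(round(shift[1] * u)), axis=0),
        int(round(shift[0] * u)), axis=1,
    )


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------


def _collapse_uniform(rng, geometry, lam_pixel):
    """Uniform specimen, coincidence on: sample arrivals directly."""
    g = geometry
    n_cells = g.n_pixels * g.u * g.u
    n_arr = int(rng.poisson(lam_pixel * g.n_pixels))
    cells = rng.integers(0, n_cells, size=n_arr)
    uw = g.u * g.width
    gy, gx = cells // uw, cells % uw
    pix = (gy // g.u) * g.width + (gx // g.u)
    # keep the first arrival in each hit pixel
    _, first = np.unique(pix, return_index=True)
    return gx[first], gy[first], n_arr


def _collapse_grid(rng, geometry, lam_grid):
    """Arbitrary pattern, coincidence on: Poisson per supersampled cell."""
    g = geometry
    u = g.u
    counts = rng.poisson(lam_grid)
    n_arr = int(counts.sum())
    cc = counts.reshape(g.height, u, g.width, u)
    per_pixel = cc.sum(axis=(1, 3))
    hit = per_pixel > 0
    py, px = np.nonzero(hit)
    cells = cc.transpose(0, 2, 1, 3).reshape(g.height, g.width, u * u)[hit]
    r = rng.random(py.shape[0]) * per_pixel[hit]
    pick = (np.cumsum(cells, axis=1) > r[:, None]).argmax(axis=1)
    sy, sx = pick // u, pick % u
    return px * u + sx, py * u + sy, n_arr


def _bernoulli(rng, geometry, lam_pixel, lam_grid):
    """Coincidence off: at most one electron per physical pixel."""
    g = geometry
    u = g.u
    if lam_grid is None:
        p_pix = np.full((g.height, g.width), lam_pixel)
    else:
        p_pix = lam_grid.reshape(g.height, u, g.width, u).sum(axis=(1, 3))
    if p_pix.max() > 1:
        raise ValidationError(
            "per-pixel rate exceeds 1 electron/frame; coincidence-free "
            "counting cannot represent that"
        )
    hit = rng.random((g.height, g.width)) < p_pix
    py, px = np.nonzero(hit)
    n = py.shape[0]
    if lam_grid is None:
        sx = rng.integers(0, u, size=n)
        sy = rng.integers(0, u, size=n)
    else:
        cells = lam_grid.reshape(g.height, u, g.width, u)
        cells = cells.transpose(0, 2, 1, 3).reshape(g.height, g.width, u * u)[hit]
        r = rng.random(n) * cells.sum(axis=1)
        pick = (np.cumsum(cells, axis=1) > r[:, None]).argmax(axis=1)
        sy, sx = pick // u, pick % u
    return px * u + sx, py * u + sy, n


def simulate_movie(config: SimulationConfig) -> SimulationResult:
    """Generate a movie under the configured conditions, with ground truth."""
    g = config.geometry
    u = g.u
    n_frames = config.n_frames
    rng = np.random.default_rng(config.seed)
    shifts = trajectory_shifts(config.trajectory, n_frames)
    lam_pixel = config.exposure_rate / g.frame_rate  # mean e-/pixel/frame

    frames, pxs, pys, sxs, sys_ = [], [], [], [], []
    n_arrivals = 0
    for f in range(n_frames):
        pattern = _intensity(config.specimen, g, shifts[f])
        lam_grid = None if pattern is None else lam_pixel / (u * u) * pattern
        if config.coincidence:
            if lam_grid is None:
                gx, gy, n_arr = _collapse_uniform(rng, g, lam_pixel)
            else:
                gx, gy, n_arr = _collapse_grid(rng, g, lam_grid)
        else:
            gx, gy, n_arr = _bernoulli(rng, g, lam_pixel, lam_grid)
        n_arrivals += n_arr
        order = np.lexsort((gx // u, gy // u))
        gx, gy = gx[order], gy[order]
        frames.append(np.full(gx.shape[0], f, dtype=np.int64))
        pxs.append(gx // u)
        pys.append(gy // u)
        sxs.append(gx % u)
        sys_.append(gy % u)

    def cat(parts):
        return (np.concatenate(parts) if parts
                else np.zeros(0, dtype=np.int64))

    metadata = AcquisitionMetadata(
        exposure_rate=max(config.exposure_rate, np.finfo(float).tiny),
        pixel_size=config.pixel_size,
        total_exposure=(config.exposure_rate * config.duration
                        / config.pixel_size**2),
    )
    movie = EventMovie(
        g, n_frames, cat(frames), cat(pxs), cat(pys), cat(sxs), cat(sys_),
        metadata,
    )
    return SimulationResult(
        movie=movie,
        true_shifts=shifts,
        n_arrivals=n_arrivals,
        n_events=movie.n_events,
    )


def make_gain_map(
    geometry: DetectorGeometry,
    spread: float = 0.05,
    defect_fraction: float = 0.001,
    seed: int = 0,
) -> GainReference:
    """Random flat-field gain map with a fixed number of zeroed defects.

    Gains are drawn near 1 with the given relative spread (clipped away from
    zero so only true defects carry gain 0); exactly
    ``round(defect_fraction * N_pixels)`` pixels are zeroed, sampled without
    replacement.
    """
    if not 0 <= defect_fraction < 1:
        raise ValidationError("defect_fraction must lie in [0, 1)")
    if spread < 0:
        raise ValidationError("spread must be non-negative")
    rng = np.random.default_rng(seed)
    gain = rng.normal(1.0, spread, size=(geometry.height, geometry.width))
    gain = np.clip(gain, 0.05, None)
    n_def = int(round(defect_fraction * geometry.n_pixels))
    if n_def:
        flat = rng.choice(geometry.n_pixels, size=n_def, replace=False)
        gain.flat[flat] = 0.0
    return GainReference(gain)
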