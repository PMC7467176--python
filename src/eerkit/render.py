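"""Event-level image formation: rasterization, Fourier cropping, fractions.

Decoded electrons are reconstructed on the full ``u_grid x u_grid``
supersampled lattice (4x4 by default) and subsequently Fourier-cropped to
the desired output sampling.  Working on the supersampled grid first keeps
all subpixel information; Fourier cropping then resamples without real-space
interpolation, retaining the anti-aliasing benefit of super-resolution.

Placement conventions (fixed here, used symmetrically by motion/simulate):

* Electrons are delta deposits at the nearest lattice cell — no bilinear
  spreading, so no interpolation artefacts.
* A specimen trajectory d(t) displaces the recorded electron by +d;
  compensation therefore deposits it at (supersampled position - d*u_grid),
  rounded to the nearest cell.  Electrons pushed off the detector are
  dropped (wrapping would alias specimen content) and counted in the report.
* The gain coefficient is looked up at the electron's ORIGINAL physical
  pixel and applied as a weight at the shifted position; gain 0 (defect)
  suppresses the electron's contribution without deleting it from the
  stream.
* Fourier cropping preserves the image sum (total counts / DC term); the
  per-pixel mean is not preserved because pixel area changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .events import EventMovie, GainReference

__all__ = [
    "RenderSpec",
    "RasterReport",
    "rasterize",
    "fourier_crop",
    "render_fractions",
    "randomize_subpixels",
]


@dataclass(frozen=True)
class RenderSpec:
    """Rendering parameters.

    u_grid is the rasterization supersampling (events are placed on a
    u_grid-per-physical-pixel lattice); target_supersample is the output
    sampling after the Fourier crop (1 = physical pixels, 2 = 2x2
    super-resolution).  preserve_counts keeps the image sum equal to the
    electron count through cropping (the default); when False the crop is
    rescaled to preserve the per-pixel mean instead.
    """

    u_grid: int = 4
    target_supersample: int = 1
    preserve_counts: bool = True

    def __post_init__(self) -> None:
        if self.u_grid < 1 or self.target_supersample < 1:
            raise ValidationError("u_grid and target_supersample must be >= 1")
        if self.target_supersample > self.u_grid:
            raise ValidationError("target_supersample cannot exceed u_grid")


@dataclass
class RasterReport:
    """Bookkeeping from one rasterization pass."""

    n_events: int
    n_out_of_bounds: int
    n_defect_suppressed: int


def rasterize(
    movie: EventMovie,
    spec: RenderSpec = RenderSpec(),
    gain: GainReference | None = None,
    shifts: np.ndarray | None = None,
) -> tuple[np.ndarray, RasterReport]:
    """Deposit electrons on the supersampled lattice.

    Returns the (u_grid*height, u_grid*width) float image and a report of
    dropped/suppressed electrons.  ``shifts`` is an (n_frames, 2) array of
    per-frame (dx, dy) trajectory values in physical-pixel units; every
    event's frame index must be covered.
    """
    g = movie.geometry
    ug = spec.u_grid
    h, w = ug * g.height, ug * g.width
    img = np.zeros((h, w), dtype=np.float64)
    n = movie.n_events
    if n == 0:
        return img, RasterReport(0, 0, 0)

    # Continuous supersampled coordinates; exact integers when u_grid == u.
    xs = (movie.px + (movie.sx + 0.5) / g.u) * ug - 0.5
    ys = (movie.py + (movie.sy + 0.5) / g.u) * ug - 0.5
    if shifts is not None:
        shifts = np.asarray(shifts, dtype=np.float64)
        if shifts.ndim != 2 or shifts.shape[1] != 2:
            raise ValidationError("shifts must be an (n_frames, 2) array")
        if movie.frame.max() >= shifts.shape[0]:
            raise ValidationError(
                f"shifts cover {shifts.shape[0]} frames but events reach "
                f"frame {int(movie.frame.max())}"
            )
        xs = xs - shifts[movie.frame, 0] * ug
        ys = ys - shifts[movie.frame, 1] * ug

    xi = np.floor(xs + 0.5).astype(np.int64)
    yi = np.floor(ys + 0.5).astype(np.int64)
    inb = (xi >= 0) & (xi < w) & (yi >= 0) & (yi < h)

    if gain is not None:
        if gain.gain.shape != (g.height, g.width):
            raise ValidationError("gain map shape does not match the geometry")
        weights = gain.gain[movie.py, movie.px]
    else:
        weights = np.ones(n, dtype=np.float64)

    np.add.at(img, (yi[inb], xi[inb]), weights[inb])
    n_defect = int(np.count_nonzero(weights[inb] == 0))
    return img, RasterReport(n, int(np.count_nonzero(~inb)), n_defect)


def fourier_crop(image: np.ndarray, target_shape: tuple[int, int],
                 preserve_counts: bool = True) -> np.ndarray:
    """Resample by retaining the central region of the Fourier transform.

    Both the input and target shapes must be even (avoids half-pixel centre
    ambiguity).  With preserve_counts (default) the output sum equals the
    input sum to within floating-point error — the DC term is carried over
    unchanged; otherwise the result is scaled to preserve the mean.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValidationError("fourier_crop expects a 2-D image")
    th, tw = target_shape
    sh, sw = image.shape
    if any(s % 2 for s in (th, tw, sh, sw)):
        raise ValidationError("fourier_crop requires even dimensions")
    if th > sh or tw > sw:
        raise ValidationError("target shape must not exceed the image shape")

    spec = np.fft.fftshift(np.fft.fft2(image))
    r0, c0 = sh // 2 - th // 2, sw // 2 - tw // 2
    cropped = spec[r0:r0 + th, c0:c0 + tw]
    out = np.fft.ifft2(np.fft.ifftshift(cropped)).real
    if not preserve_counts:
        out = out * ((th * tw) / (sh * sw))
    return out


def render_fractions(
    movie: EventMovie,
    fractionation: list[int],
    spec: RenderSpec = RenderSpec(),
    gain: GainReference | None = None,
    shifts: np.ndarray | None = None,
) -> tuple[np.ndarray, list[RasterReport]]:
    """Rasterize and crop each exposure fraction.

    ``fractionation`` lists frames per fraction; the movie must be
    normalized.  Output stack shape is
    (n_fractions, ts*height, ts*width) with ts = spec.target_supersample.
    """
    g = movie.geometry
    if sum(fractionation) > movie.n_frames:
        raise ValidationError("fractionation covers more frames than the movie")
    if any(f < 1 for f in fractionation):
        raise ValidationError("zero-length fraction")
    ts = spec.target_supersample
    out_shape = (ts * g.height, ts * g.width)
    bounds = movie.frame_slices()
    stack = np.empty((len(fractionation),) + out_shape, dtype=np.float64)
    reports: list[RasterReport] = []
    start = 0
    for i, nf in enumerate(fractionation):
        lo, hi = int(bounds[start]), int(bounds[start + nf])
        sub = movie.replace(
            frame=movie.frame[lo:hi], px=movie.px[lo:hi], py=movie.py[lo:hi],
            sx=movie.sx[lo:hi], sy=movie.sy[lo:hi],
        )
        img, rep = rasterize(sub, spec, gain, shifts)
        stack[i] = (img if img.shape == out_shape
                    else fourier_crop(img, out_shape, spec.preserve_counts))
        reports.append(rep)
        start += nf
    return stack, reports


def randomize_subpixels(movie: EventMovie, seed: int) -> EventMovie:
    """Replace subpixel offsets by i.i.d. uniform draws on [0, u).

    The control experiment for super-resolution: physical-pixel positions
    and frame indices are untouched, so physical-resolution renders are
    identical while genuine sub-pixel information is destroyed.
    """
    u = movie.geometry.u
    if u == 1 or movie.n_events == 0:
        return movie.replace()
    rng = np.random.default_rng(seed)
    return movie.replace(
        sx=rng.integers(0, u, size=movie.n_events),
        sy=rng.integers(0, u, size=movie.n_events),
    )
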