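"""Core domain model for counted-electron event movies.

In the electron-event representation (EER) a cryoEM movie is not a stack of
pixel-intensity images but a stream of electron-detection events, each
recorded as (frame, physical pixel, subpixel offset).  Camera frames in
counting mode are sparse — roughly one electron per 40–100 pixels — and each
physical pixel is subdivided into ``u × u`` subpixels (``u = 4`` for current
detectors) so that super-resolution information survives storage.

This module defines the in-memory contract used by every other module:

* :class:`DetectorGeometry` — sensor dimensions, subpixel factor, frame rate.
* :class:`ElectronEvent` — a single detection.
* :class:`EventMovie` — an ordered event stream with its geometry/metadata.
* :class:`GainReference` — per-pixel gain map; a value of 0 marks a defect.

Conventions fixed here and relied on everywhere else:

* Coordinates are 0-based and half-open: ``0 <= px < width``.
* Scanline order is row-major, ``index = py * width + px``, rows
  top-to-bottom; the RLE codec encodes gaps in exactly this order.
* The supersampled position of an event is ``(px*u + sx, py*u + sy)``;
  subpixel offset ``k`` addresses subpixel cell ``k`` and renders at that
  cell's centre.
* Within one camera frame a physical pixel holds at most one event (the
  Bernoulli counting-mode assumption; coincident arrivals are collapsed by
  the counting hardware, emulated by :mod:`eerkit.simulate`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "DetectorGeometry",
    "ElectronEvent",
    "AcquisitionMetadata",
    "GainReference",
    "EventMovie",
    "validate_movie",
    "sparsity_report",
]


@dataclass(frozen=True)
class DetectorGeometry:
    """Sensor geometry and timing.

    Parameters
    ----------
    width, height : int
        Sensor size in physical pixels.
    u : int
        Subpixel subdivision factor per axis (1 = no super-resolution).
    frame_rate : float
        Camera frames per second (Hz).
    """

    width: int
    height: int
    u: int = 4
    frame_rate: float = 240.0

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValidationError("sensor dimensions must be at least 1 pixel")
        if self.u < 1:
            raise ValidationError("subpixel factor u must be at least 1")
        if not self.frame_rate > 0:
            raise ValidationError("frame rate must be positive")

    @property
    def n_pixels(self) -> int:
        """Number of physical pixels."""
        return self.width * self.height

    @property
    def super_shape(self) -> tuple[int, int]:
        """(rows, cols) of the u-times supersampled grid."""
        return (self.u * self.height, self.u * self.width)


class ElectronEvent(NamedTuple):
    """One electron detection: camera frame, physical pixel, subpixel cell."""

    frame: int
    px: int
    py: int
    sx: int = 0
    sy: int = 0

    def super_position(self, u: int) -> tuple[int, int]:
        """Supersampled (x, y) lattice cell of this event."""
        return (self.px * u + self.sx, self.py * u + self.sy)


@dataclass
class AcquisitionMetadata:
    """Acquisition conditions attached to a movie.

    exposure_rate is in e-/physical pixel/s, pixel_size in Angstrom per
    physical pixel.  total_exposure (e-/A^2 on the specimen) is optional and
    derivable from the other two plus the movie duration.
    """

    exposure_rate: float
    pixel_size: float
    total_exposure: float | None = None

    def __post_init__(self) -> None:
        if not self.exposure_rate > 0:
            raise ValidationError("exposure_rate must be positive")
        if not self.pixel_size > 0:
            raise ValidationError("pixel_size must be positive")


@dataclass
class GainReference:
    """Per-physical-pixel multiplicative gain; 0 marks a defective pixel."""

    gain: np.ndarray  # shape (height, width), float

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=np.float64)
        if self.gain.ndim != 2:
            raise ValidationError("gain map must be 2-D (height, width)")
        if np.any(self.gain < 0):
            raise ValidationError("gain values must be >= 0 (0 marks a defect)")

    @property
    def defect_mask(self) -> np.ndarray:
        """Boolean mask of defective pixels (gain exactly 0)."""
        return self.gain == 0

    @property
    def n_defects(self) -> int:
        return int(self.defect_mask.sum())


_COORD_FIELDS = ("frame", "px", "py", "sx", "sy")


@dataclass
class EventMovie:
    """An event stream plus the geometry and metadata needed to interpret it.

    Events are stored as parallel integer arrays (``frame``, ``px``, ``py``,
    ``sx``, ``sy``) for vectorised processing; :meth:`events` materialises
    :class:`ElectronEvent` tuples when per-event access is convenient.

    A *normalized* movie is sorted by (frame, py, px) — frame order, then
    scanline order within a frame — which is the order the codec requires.
    """

    geometry: DetectorGeometry
    n_frames: int
    frame: np.ndarray
    px: np.ndarray
    py: np.ndarray
    sx: np.ndarray
    sy: np.ndarray
    metadata: AcquisitionMetadata | None = None

    def __post_init__(self) -> None:
        for name in _COORD_FIELDS:
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.int64))
        lengths = {getattr(self, name).shape for name in _COORD_FIELDS}
        if len(lengths) != 1:
            raise ValidationError("event coordinate arrays must have equal length")
        if self.n_frames < 0:
            raise ValidationError("n_frames must be non-negative")

    # -- constructors ---------------------------------------------------

    @classmethod
    def empty(
        cls,
        geometry: DetectorGeometry,
        n_frames: int,
        metadata: AcquisitionMetadata | None = None,
    ) -> "EventMovie":
        z = np.zeros(0, dtype=np.int64)
        return cls(geometry, n_frames, z, z, z, z, z, metadata)

    @classmethod
    def from_events(
        cls,
        geometry: DetectorGeometry,
        n_frames: int,
        events: Iterable[ElectronEvent] | Sequence[tuple],
        metadata: AcquisitionMetadata | None = None,
    ) -> "EventMovie":
        arr = np.asarray([tuple(e) for e in events], dtype=np.int64)
        if arr.size == 0:
            return cls.empty(geometry, n_frames, metadata)
        return cls(geometry, n_frames, *(arr[:, i] for i in range(5)), metadata)

    # -- basic accessors ------------------------------------------------

    @property
    def n_events(self) -> int:
        return int(self.frame.shape[0])

    def events(self) -> list[ElectronEvent]:
        """Materialise the stream as ElectronEvent tuples."""
        return [
            ElectronEvent(*map(int, row))
            for row in zip(self.frame, self.px, self.py, self.sx, self.sy)
        ]

    def frame_counts(self) -> np.ndarray:
        """Event count per camera frame, length n_frames."""
        if self.n_frames == 0:
            return np.zeros(0, dtype=np.int64)
        return np.bincount(self.frame, minlength=self.n_frames)

    def frame_slices(self) -> np.ndarray:
        """Start offsets of each frame in a normalized movie (length n_frames+1)."""
        return np.searchsorted(self.frame, np.arange(self.n_frames + 1))

    # -- normalization --------------------------------------------------

    def is_normalized(self) -> bool:
        key = self._sort_key()
        return bool(np.all(np.diff(key) > 0)) if key.size else True

    def _sort_key(self) -> np.ndarray:
        g = self.geometry
        return (self.frame * g.n_pixels) + self.py * g.width + self.px

    def normalized(self) -> "EventMovie":
        """Return a copy sorted by (frame, py, px).  Idempotent."""
        order = np.argsort(self._sort_key(), kind="stable")
        return dataclasses.replace(
            self,
            **{name: getattr(self, name)[order] for name in _COORD_FIELDS},
        )

    def replace(self, **kwargs) -> "EventMovie":
        return dataclasses.replace(self, **kwargs)


def validate_movie(movie: EventMovie) -> list[str]:
    """Check every type invariant; return human-readable violations.

    An empty list means the movie is valid.  Each violation names the rule
    and the offending event index (index into the movie's event arrays).
    """
    g = movie.geometry
    out: list[str] = []
    if movie.n_events == 0:
        return out

    def report(mask: np.ndarray, rule: str) -> None:
        for i in np.nonzero(mask)[0][:20]:
            out.append(f"event {int(i)}: {rule}")
        extra = int(mask.sum()) - min(int(mask.sum()), 20)
        if extra > 0:
            out.append(f"... and {extra} more violations of: {rule}")

    report((movie.frame < 0) | (movie.frame >= movie.n_frames),
           f"frame index out of range [0, {movie.n_frames})")
    report((movie.px < 0) | (movie.px >= g.width),
           f"px out of range [0, {g.width})")
    report((movie.py < 0) | (movie.py >= g.height),
           f"py out of range [0, {g.height})")
    report((movie.sx < 0) | (movie.sx >= g.u),
           f"sx out of range [0, {g.u})")
    report((movie.sy < 0) | (movie.sy >= g.u),
           f"sy out of range [0, {g.u})")

    # Ordering and duplicate pixels only make sense for in-bounds events.
    key = movie._sort_key()
    d = np.diff(key)
    unsorted = np.zeros(movie.n_events, dtype=bool)
    unsorted[1:] = d < 0
    report(unsorted, "not in (frame, scanline) order")
    dup = np.zeros(movie.n_events, dtype=bool)
    dup[1:] = d == 0
    report(dup, "duplicate event at the same (frame, px, py) "
                "(one electron per pixel per frame)")
    return out


def sparsity_report(
    movie: EventMovie, pixels_per_electron_threshold: float = 40.0
) -> pd.DataFrame:
    """Per-frame electron counts and sparsity ratio.

    Counting-mode frames should carry about one electron per 40–100 pixels;
    frames denser than the threshold (fewer pixels per electron) are flagged
    as too dense for reliable counting.

    Returns a DataFrame with columns ``frame``, ``n_events``,
    ``pixels_per_electron`` (inf for empty frames) and ``flagged``.
    """
    counts = movie.frame_counts()
    with np.errstate(divide="ignore"):
        ratio = np.where(counts > 0, movie.geometry.n_pixels / np.maximum(counts, 1),
                         np.inf)
    return pd.DataFrame(
        {
            "frame": np.arange(movie.n_frames),
            "n_events": counts,
            "pixels_per_electron": ratio,
            "flagged": ratio < pixels_per_electron_threshold,
        }
    )
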