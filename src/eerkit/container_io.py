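"""EER container (BigTIFF dialect) and MRC I/O.

The event-movie container is a BigTIFF file with one image directory per
camera frame.  Each directory's pixel data is the frame's raw RLE payload
stored as a (1, n_bytes) uint8 strip, and the first directory's
ImageDescription tag carries a JSON header with the geometry, codec
parameters and acquisition metadata.  BigTIFF (64-bit offsets) is used
unconditionally: 4k sensors at thousands of frames exceed 32-bit-offset
territory.  This is a documented dialect faithful to the published encoding;
vendor (Falcon) tag layouts are unpublished and not claimed.

Gain references travel separately as 2-D MRC images (mode 2); a gain value
of 0 marks a defective pixel.  Decoded movies export as MRC2014 mode-2
exposure-fraction stacks whose voxel size records the output sampling.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import tifffile

from . import _mrc
from .errors import CodecError, EerFormatError, ValidationError
from .events import (
    AcquisitionMetadata,
    DetectorGeometry,
    EventMovie,
    GainReference,
)
from .render import RenderSpec, render_fractions
from .rle_codec import RleParams, decode_movie, encode_movie

logger = logging.getLogger(__name__)

__all__ = [
    "EerFileHeader",
    "write_eer",
    "read_eer",
    "read_gain",
    "write_gain",
    "plan_fractionation",
    "export_fraction_stack",
]

_DIALECT = "eerkit-eer"
_DIALECT_VERSION = 1

_KNOWN_KEYS = {
    "dialect", "version", "width", "height", "u", "frame_rate", "n_frames",
    "b_rle", "exposure_rate", "pixel_size", "total_exposure",
}


@dataclass
class EerFileHeader:
    """Decoded container header."""

    geometry: DetectorGeometry
    n_frames: int
    rle_params: RleParams
    acquisition: AcquisitionMetadata | None = None


def _header_json(movie: EventMovie, params: RleParams) -> str:
    g = movie.geometry
    doc = {
        "dialect": _DIALECT,
        "version": _DIALECT_VERSION,
        "width": g.width,
        "height": g.height,
        "u": g.u,
        "frame_rate": g.frame_rate,
        "n_frames": movie.n_frames,
        "b_rle": params.b_rle,
    }
    if movie.metadata is not None:
        doc["exposure_rate"] = movie.metadata.exposure_rate
        doc["pixel_size"] = movie.metadata.pixel_size
        if movie.metadata.total_exposure is not None:
            doc["total_exposure"] = movie.metadata.total_exposure
    return json.dumps(doc)


def write_eer(path, movie: EventMovie, params: RleParams | None = None) -> None:
    """Encode and write a movie as a one-directory-per-frame BigTIFF."""
    params = params or RleParams(u=movie.geometry.u)
    if params.u != movie.geometry.u:
        raise ValidationError("codec u must match the movie geometry")
    movie = movie.normalized()
    frames, _ = encode_movie(movie, params)
    header = _header_json(movie, params)
    with tifffile.TiffWriter(path, bigtiff=True) as tw:
        for i, ef in enumerate(frames):
            arr = np.frombuffer(ef.payload, dtype=np.uint8).reshape(1, -1)
            tw.write(
                arr,
                photometric="minisblack",
                description=header if i == 0 else None,
                metadata=None,
            )


def read_header(path) -> EerFileHeader:
    """Read and validate the container header without decoding frames."""
    try:
        with tifffile.TiffFile(path) as tf:
            return _parse_header(tf)
    except EerFormatError:
        raise
    except Exception as e:  # malformed TIFF structure
        raise EerFormatError(f"not a readable EER container: {e}") from e


def _parse_header(tf: tifffile.TiffFile) -> EerFileHeader:
    pages = tf.pages
    if len(pages) == 0:
        raise EerFormatError("container holds no frame directories")
    desc = pages[0].description
    if not desc:
        raise EerFormatError("first directory carries no dialect header")
    try:
        doc = json.loads(desc)
    except json.JSONDecodeError as e:
        raise EerFormatError(f"header is not valid JSON: {e}") from e
    if doc.get("dialect") != _DIALECT:
        raise EerFormatError("unrecognized container dialect")
    unknown = set(doc) - _KNOWN_KEYS
    if unknown:
        logger.warning("ignoring unknown header keys: %s", sorted(unknown))
    try:
        geometry = DetectorGeometry(
            width=int(doc["width"]), height=int(doc["height"]),
            u=int(doc["u"]), frame_rate=float(doc["frame_rate"]),
        )
        n_frames = int(doc["n_frames"])
        params = RleParams(b_rle=int(doc["b_rle"]), u=geometry.u)
    except KeyError as e:
        raise EerFormatError(f"header is missing required key {e}") from e
    acquisition = None
    if "exposure_rate" in doc and "pixel_size" in doc:
        acquisition = AcquisitionMetadata(
            exposure_rate=float(doc["exposure_rate"]),
            pixel_size=float(doc["pixel_size"]),
            total_exposure=doc.get("total_exposure"),
        )
    return EerFileHeader(geometry, n_frames, params, acquisition)


def read_eer(path) -> EventMovie:
    """Read and fully decode a container into a normalized EventMovie."""
    try:
        with tifffile.TiffFile(path) as tf:
            header = _parse_header(tf)
            if len(tf.pages) != header.n_frames:
                raise EerFormatError(
                    f"header declares {header.n_frames} frames but the file "
                    f"holds {len(tf.pages)} directories"
                )
            payloads = []
            for f, page in enumerate(tf.pages):
                try:
                    payloads.append(page.asarray().tobytes())
                except Exception as e:
                    raise EerFormatError(f"frame {f}: unreadable strip: {e}") from e
    except (EerFormatError, CodecError):
        raise
    except Exception as e:
        raise EerFormatError(f"not a readable EER container: {e}") from e
    movie = decode_movie(payloads, header.geometry, header.rle_params,
                         metadata=header.acquisition)
    return movie.normalized()


# ---------------------------------------------------------------------------
# gain references
# ---------------------------------------------------------------------------


def write_gain(path, gain: GainReference) -> None:
    """Write a gain map as a 2-D mode-2 MRC image (defects stay exact zeros)."""
    _mrc.write_mrc(path, gain.gain.astype(np.float32), voxel_size=1.0)


def read_gain(path, geometry: DetectorGeometry | None = None) -> GainReference:
    """Read a gain map; optionally check it against a detector geometry."""
    data, _ = _mrc.read_mrc(path)
    if data.shape[0] != 1:
        raise EerFormatError("gain reference must be a single 2-D image")
    img = np.asarray(data[0], dtype=np.float64)
    if np.any(img < 0):
        raise ValidationError("gain reference contains negative values")
    if geometry is not None and img.shape != (geometry.height, geometry.width):
        raise ValidationError(
            f"gain shape {img.shape} does not match geometry "
            f"({geometry.height}, {geometry.width})"
        )
    return GainReference(img)


# ---------------------------------------------------------------------------
# exposure-fraction export
# ---------------------------------------------------------------------------


def plan_fractionation(
    n_frames: int,
    fractionation: int | list[int],
    short_tail: bool = False,
) -> tuple[list[int], int]:
    """Turn a fraction request into a frames-per-fraction table.

    An integer asks for that many equal fractions; frames that do not divide
    evenly are dropped from the tail (2312 frames at 30 fractions gives
    30 x 77 with 2 dropped) unless ``short_tail`` keeps them as one short
    final fraction.  Returns (table, n_dropped_frames).
    """
    if isinstance(fractionation, int):
        if fractionation < 1:
            raise ValidationError("fraction count must be >= 1")
        per = n_frames // fractionation
        if per < 1:
            raise ValidationError("more fractions than frames")
        table = [per] * fractionation
        dropped = n_frames - per * fractionation
        if short_tail and dropped:
            table.append(dropped)
            dropped = 0
        return table, dropped
    table = [int(x) for x in fractionation]
    if any(x < 1 for x in table):
        raise ValidationError("zero-length fraction")
    if sum(table) > n_frames:
        raise ValidationError("fractionation exceeds the movie's frame count")
    return table, n_frames - sum(table)


def export_fraction_stack(
    movie: EventMovie,
    fractionation: int | list[int],
    path,
    u_out: int = 1,
    gain: GainReference | None = None,
    shifts: np.ndarray | None = None,
    short_tail: bool = False,
) -> tuple[list[int], int]:
    """Render and write an exposure-fraction stack as MRC2014 mode 2.

    Each section is the Fourier-cropped sum of its fraction's frames at
    ``u_out``-times supersampling; the voxel size in the header is
    pixel_size / u_out.  Returns the fraction table used and the number of
    tail frames dropped.
    """
    table, dropped = plan_fractionation(movie.n_frames, fractionation, short_tail)
    movie = movie.normalized()
    spec = RenderSpec(u_grid=movie.geometry.u, target_supersample=u_out)
    stack, _ = render_fractions(movie, table, spec, gain=gain, shifts=shifts)
    pixel_size = movie.metadata.pixel_size if movie.metadata else 1.0
    _mrc.write_mrc(path, stack.astype(np.float32),
                   voxel_size=pixel_size / u_out)
    return table, dropped
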