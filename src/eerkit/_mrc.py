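"""Minimal MRC2014 image/stack reader and writer.

Covers exactly what the toolkit needs: 2-D images and 3-D stacks in mode 2
(32-bit float) or mode 6 (16-bit unsigned), little-endian, with a cubic
voxel size recorded in the cell dimensions.  Header layout follows the
MRC2014 convention (NX/NY/NZ, MODE, MX/MY/MZ, CELLA, MAPC/MAPR/MAPS,
DMIN/DMAX/DMEAN, ISPG = 0 for image stacks, 'MAP ' magic and the
little-endian machine stamp).  Reading tolerates files written by other
conforming tools as long as the mode is one we support and the axis order
is the default (1, 2, 3).
"""

from __future__ import annotations

import struct

import numpy as np

from .errors import EerFormatError

HEADER_BYTES = 1024
_MODE_DTYPES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}
_DTYPE_MODES = {np.dtype(np.float32): 2, np.dtype(np.uint16): 6,
                np.dtype(np.int16): 1, np.dtype(np.int8): 0}


def write_mrc(path, data: np.ndarray, voxel_size: float = 1.0,
              dtype=np.float32) -> None:
    """Write a 2-D image or 3-D stack as a little-endian MRC2014 file."""
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None, :, :]
    if data.ndim != 3:
        raise EerFormatError("MRC writer expects a 2-D image or 3-D stack")
    dtype = np.dtype(dtype)
    if dtype not in _DTYPE_MODES:
        raise EerFormatError(f"unsupported MRC dtype {dtype}")
    data = np.ascontiguousarray(data.astype(dtype, copy=False))
    nz, ny, nx = data.shape
    mode = _DTYPE_MODES[dtype]

    stats = data.astype(np.float64)
    header = bytearray(HEADER_BYTES)
    struct.pack_into("<10i", header, 0,
                     nx, ny, nz, mode,      # NX NY NZ MODE
                     0, 0, 0,               # NXSTART NYSTART NZSTART
                     nx, ny, nz)            # MX MY MZ
    struct.pack_into("<6f", header, 40,
                     nx * voxel_size, ny * voxel_size, nz * voxel_size,
                     90.0, 90.0, 90.0)      # CELLA, CELLB
    struct.pack_into("<3i", header, 64, 1, 2, 3)  # MAPC MAPR MAPS
    struct.pack_into("<3f", header, 76,
                     float(stats.min()), float(stats.max()),
                     float(stats.mean()))   # DMIN DMAX DMEAN
    struct.pack_into("<2i", header, 88, 0, 0)     # ISPG (0: image stack), NSYMBT
    header[208:212] = b"MAP "
    header[212:216] = bytes([0x44, 0x44, 0x00, 0x00])  # little-endian stamp
    struct.pack_into("<f", header, 216, float(stats.std()))  # RMS
    struct.pack_into("<i", header, 220, 1)        # NLABL
    label = b"eerkit MRC2014 writer"
    header[224:224 + len(label)] = label

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(data.tobytes())


def read_mrc(path) -> tuple[np.ndarray, float]:
    """Read an MRC file; return (data as (nz, ny, nx) array, voxel size)."""
    with open(path, "rb") as fh:
        header = fh.read(HEADER_BYTES)
        if len(header) < HEADER_BYTES:
            raise EerFormatError("file too short to hold an MRC header")
        if header[208:212] not in (b"MAP ", b"MAP\x00"):
            raise EerFormatError("missing MRC 'MAP ' magic")
        nx, ny, nz, mode = struct.unpack_from("<4i", header, 0)
        mapc, mapr, maps = struct.unpack_from("<3i", header, 64)
        if (mapc, mapr, maps) != (1, 2, 3):
            raise EerFormatError("only default MRC axis order (1,2,3) is supported")
        if mode not in _MODE_DTYPES:
            raise EerFormatError(f"unsupported MRC mode {mode}")
        (nsymbt,) = struct.unpack_from("<i", header, 92)
        cella_x, = struct.unpack_from("<f", header, 40)
        (mx,) = struct.unpack_from("<i", header, 28)
        voxel = cella_x / mx if mx else 1.0
        fh.seek(HEADER_BYTES + nsymbt)
        dtype = np.dtype(_MODE_DTYPES[mode]).newbyteorder("<")
        count = nx * ny * nz
        data = np.fromfile(fh, dtype=dtype, count=count)
        if data.size != count:
            raise EerFormatError("MRC data section truncated")
    return data.reshape(nz, ny, nx), float(voxel)
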