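"""Minimal MRC (mode 2, float32) image I/O.

Only the fields needed for single 2D images are handled: dimensions, mode,
cell size (encodes the pixel size) and basic statistics. Data are written
little-endian with the standard 1024-byte header and 'MAP ' stamp.
"""

from __future__ import annotations

import struct
from pathlib import Path
from typing import Tuple, Union

import numpy as np

_HEADER_SIZE = 1024


def write_mrc(path: Union[str, Path], data: np.ndarray, pixel_size: float) -> Path:
    """Write a 2D float image as an MRC mode-2 file."""
    data = np.asarray(data, dtype="<f4")
    if data.ndim != 2:
        raise ValueError("only 2D images are supported")
    ny, nx = data.shape
    header = bytearray(_HEADER_SIZE)
    struct.pack_into("<3i", header, 0, nx, ny, 1)          # NX NY NZ
    struct.pack_into("<i", header, 12, 2)                  # MODE 2 = float32
    struct.pack_into("<3i", header, 28, nx, ny, 1)         # MX MY MZ
    struct.pack_into(
        "<3f", header, 40, nx * pixel_size, ny * pixel_size, pixel_size
    )                                                      # CELLA
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)  # CELLB
    struct.pack_into("<3i", header, 64, 1, 2, 3)           # MAPC MAPR MAPS
    struct.pack_into(
        "<3f", header, 76, float(data.min()), float(data.max()), float(data.mean())
    )
    struct.pack_into("<i", header, 88, 0)                  # ISPG
    struct.pack_into("<i", header, 92, 0)                  # NSYMBT
    header[208:212] = b"MAP "
    header[212:216] = bytes([0x44, 0x44, 0x00, 0x00])      # little-endian stamp
    struct.pack_into("<f", header, 216, float(data.std()))
    path = Path(path)
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(data.tobytes())
    return path


def read_mrc(path: Union[str, Path]) -> Tuple[np.ndarray, float]:
    """Read a 2D MRC mode-2 file; returns (image, pixel_size in A/px)."""
    with open(path, "rb") as fh:
        header = fh.read(_HEADER_SIZE)
        nx, ny, nz = struct.unpack_from("<3i", header, 0)
        (mode,) = struct.unpack_from("<i", header, 12)
        if mode != 2:
            raise ValueError(f"unsupported MRC mode {mode}; expected 2 (float32)")
        if nz != 1:
            raise ValueError("only single-section 2D MRC files are supported")
        xlen, _, _ = struct.unpack_from("<3f", header, 40)
        pixel_size = xlen / nx if nx else 1.0
        data = np.frombuffer(fh.read(nx * ny * 4), dtype="<f4").reshape(ny, nx)
    return data.astype(np.float64), float(pixel_size)
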