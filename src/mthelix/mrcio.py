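"""Minimal MRC2014 reader/writer (mode 2, float32).

Covers exactly what the pipeline needs: 3D maps and 2D image stacks with a
physical voxel/pixel size, written as little-endian mode-2 MRC2014 files with
a standards-compliant 1024-byte header. Extended headers are skipped on read.
"""

from __future__ import annotations

import struct

import numpy as np

_HEADER_SIZE = 1024
# little-endian machine stamp per MRC2014
_MACHINE_STAMP = b"\x44\x44\x00\x00"


def write_mrc(path, data: np.ndarray, voxel_size_A: float, is_stack: bool = False) -> None:
    """Write a 2D image, 3D volume, or image stack as mode-2 MRC.

    ``data`` axis order is (nz, ny, nx) for volumes/stacks and (ny, nx) for a
    single image. ``is_stack`` sets MZ=1 so readers treat sections as images.
    """
    data = np.asarray(data, dtype="<f4")
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"expected 2D or 3D array, got {data.ndim}D")
    nz, ny, nx = data.shape
    mz = 1 if is_stack else nz
    cella = (nx * voxel_size_A, ny * voxel_size_A, mz * voxel_size_A)

    header = bytearray(_HEADER_SIZE)
    struct.pack_into("<10i", header, 0, nx, ny, nz, 2, 0, 0, 0, nx, ny, mz)
    struct.pack_into("<6f", header, 40, *cella, 90.0, 90.0, 90.0)
    struct.pack_into("<3i", header, 64, 1, 2, 3)
    struct.pack_into("<3f", header, 76, float(data.min()), float(data.max()),
                     float(data.mean()))
    struct.pack_into("<2i", header, 88, 1, 0)  # ispg=1 (volume), nsymbt=0
    if is_stack:
        struct.pack_into("<i", header, 88, 0)  # ispg=0 for image stacks
    header[208:212] = b"MAP "
    header[212:216] = _MACHINE_STAMP
    struct.pack_into("<f", header, 216, float(data.std()))
    struct.pack_into("<i", header, 220, 0)  # nlabl

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(data.tobytes())


def read_mrc(path):
    """Read an MRC file; returns (data, voxel_size_A).

    Data comes back as float64 with shape (nz, ny, nx); single-section files
    are returned as 2D arrays.
    """
    with open(path, "rb") as fh:
        header = fh.read(_HEADER_SIZE)
        if len(header) < _HEADER_SIZE:
            raise ValueError(f"{path}: truncated MRC header")
        nx, ny, nz, mode = struct.unpack_from("<4i", header, 0)
        mx, my, mz = struct.unpack_from("<3i", header, 28)
        cella = struct.unpack_from("<3f", header, 40)
        nsymbt = struct.unpack_from("<i", header, 92)[0]
        if header[208:212] not in (b"MAP ", b"MAP\x00"):
            raise ValueError(f"{path}: missing MAP identifier, not MRC2014")
        dtype = {0: "<i1", 1: "<i2", 2: "<f4", 6: "<u2", 12: "<f2"}.get(mode)
        if dtype is None:
            raise ValueError(f"{path}: unsupported MRC mode {mode}")
        fh.seek(_HEADER_SIZE + nsymbt)
        raw = fh.read(nx * ny * nz * np.dtype(dtype).itemsize)
    data = np.frombuffer(raw, dtype=dtype).reshape(nz, ny, nx).astype(np.float64)
    voxel = cella[0] / mx if mx else 1.0
    if nz == 1:
        data = data[0]
    return data, float(voxel)
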