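"""Minimal MRC2014 volume I/O.

Supports the subset of the MRC2014 format produced by tomographic
reconstruction pipelines: modes 0 (int8), 1 (int16), 2 (float32) and
6 (uint16), single-volume files, no extended header interpretation
beyond skipping it. Voxel size is derived from the ``cella`` cell
dimensions divided by the grid size (``mx, my, mz``), in Angstrom per
the standard, converted to nm here.
"""

from __future__ import annotations

import struct

import numpy as np

_MODE_TO_DTYPE = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}
_DTYPE_TO_MODE = {
    np.dtype(np.int8): 0,
    np.dtype(np.int16): 1,
    np.dtype(np.float32): 2,
    np.dtype(np.uint16): 6,
}

_HEADER_SIZE = 1024
_MAP_ID_OFFSET = 208


def read_mrc(path) -> tuple[np.ndarray, tuple[float, float, float] | None]:
    """Read an MRC2014 file.

    Returns
    -------
    data : ndarray, shape (nz, ny, nx)
    voxel_size : (z, y, x) in nm, or None when the header carries no
        (nonzero) cell dimensions.
    """
    with open(path, "rb") as fh:
        header = fh.read(_HEADER_SIZE)
        if len(header) < _HEADER_SIZE:
            raise ValueError(f"{path}: truncated MRC header")
        # machine-stamp endianness: 0x44 0x44 little, 0x11 0x11 big
        stamp = header[212:214]
        endian = "<" if stamp != b"\x11\x11" else ">"
        nx, ny, nz, mode = struct.unpack(endian + "4i", header[:16])
        mx, my, mz = struct.unpack(endian + "3i", header[28:40])
        cella = struct.unpack(endian + "3f", header[40:52])
        nsymbt = struct.unpack(endian + "i", header[92:96])[0]
        if mode not in _MODE_TO_DTYPE:
            raise ValueError(f"{path}: unsupported MRC mode {mode}")
        dtype = np.dtype(_MODE_TO_DTYPE[mode]).newbyteorder(endian)
        fh.seek(_HEADER_SIZE + nsymbt)
        count = nx * ny * nz
        data = np.fromfile(fh, dtype=dtype, count=count)
        if data.size != count:
            raise ValueError(f"{path}: data block shorter than header promises")
    data = data.reshape(nz, ny, nx)
    voxel = None
    if all(c > 0 for c in cella) and mx > 0 and my > 0 and mz > 0:
        # Angstrom -> nm
        voxel = (cella[2] / mz / 10.0, cella[1] / my / 10.0, cella[0] / mx / 10.0)
    return np.ascontiguousarray(data.astype(data.dtype.newbyteorder("="))), voxel


def write_mrc(path, data: np.ndarray, voxel_size_nm: tuple[float, float, float]) -> None:
    """Write ``data`` (z, y, x) as MRC2014 with the given voxel size in nm."""
    data = np.asarray(data)
    if data.ndim != 3:
        raise ValueError("MRC writer expects a 3D array")
    dt = data.dtype
    if dt not in _DTYPE_TO_MODE:
        data = data.astype(np.float32)
        dt = data.dtype
    mode = _DTYPE_TO_MODE[dt]
    nz, ny, nx = data.shape
    vz, vy, vx = voxel_size_nm
    header = bytearray(_HEADER_SIZE)
    struct.pack_into("<4i", header, 0, nx, ny, nz, mode)
    struct.pack_into("<3i", header, 28, nx, ny, nz)  # mx, my, mz
    # cella in Angstrom
    struct.pack_into("<3f", header, 40, nx * vx * 10.0, ny * vy * 10.0, nz * vz * 10.0)
    struct.pack_into("<3i", header, 52, 90, 90, 90)  # cellb placeholder (ints ok: read as floats unused)
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)
    struct.pack_into("<3i", header, 64, 1, 2, 3)  # mapc, mapr, maps
    dmin, dmax = float(data.min()), float(data.max())
    struct.pack_into("<3f", header, 76, dmin, dmax, float(data.mean()))
    header[_MAP_ID_OFFSET:_MAP_ID_OFFSET + 4] = b"MAP "
    header[212:216] = b"\x44\x44\x00\x00"
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        data.astype(dt.newbyteorder("<")).tofile(fh)
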