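"""3D density volumes and MRC2014 (mode 2) input/output.

The :class:`DensityVolume` is the common currency of the whole pipeline:
simulator output, tomographic reconstructions, subvolume boxes, averages
and filtered maps are all plain float32 scalar grids in (z, y, x) axis
order with an isotropic physical voxel size in Å.

Coordinate convention: 0-based voxel indices, voxel centers at integer
coordinates; the physical position of voxel (0, 0, 0) is ``origin`` (Å).
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import affine_transform

__all__ = [
    "DensityVolume",
    "MRCFormatError",
    "read_mrc",
    "write_mrc",
    "mrc_roundtrip",
    "rotate_volume",
]

# axis permutation between (x, y, z) vectors and (z, y, x) array order
_J = np.array([[0.0, 0.0, 1.0], [0.0, 1.0, 0.0], [1.0, 0.0, 0.0]])


class MRCFormatError(ValueError):
    """Raised when an MRC file cannot be interpreted; names the bad field."""


@dataclass
class DensityVolume:
    grid: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float32)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.voxel_size <= 0:
            raise ValueError(f"voxel_size must be > 0, got {self.voxel_size}")
        if self.grid.ndim != 3:
            raise ValueError(f"grid must be 3D, got ndim={self.grid.ndim}")
        if min(self.grid.shape) < 2:
            raise ValueError(f"grid dimensions must be >= 2, got {self.grid.shape}")
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("grid contains non-finite values")
        if self.origin.shape != (3,):
            raise ValueError("origin must be a 3-vector (z, y, x) in Å")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    def copy(self) -> "DensityVolume":
        return DensityVolume(self.grid.copy(), self.voxel_size, self.origin.copy())

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical coordinates (Å) of voxel centers along one axis (0=z)."""
        n = self.grid.shape[axis]
        return self.origin[axis] + self.voxel_size * np.arange(n)

    def is_cubic(self) -> bool:
        nz, ny, nx = self.grid.shape
        return nz == ny == nx


# ---------------------------------------------------------------------------
# MRC2014 I/O (mode 2 / float32 only)
# ---------------------------------------------------------------------------

_HEADER_SIZE = 1024


def write_mrc(volume: DensityVolume, path) -> None:
    grid = np.ascontiguousarray(volume.grid, dtype="<f4")
    nz, ny, nx = grid.shape
    vs = float(volume.voxel_size)
    header = bytearray(_HEADER_SIZE)
    struct.pack_into("<3i", header, 0, nx, ny, nz)            # NX NY NZ
    struct.pack_into("<i", header, 12, 2)                      # MODE 2 = float32
    struct.pack_into("<3i", header, 16, 0, 0, 0)               # NXSTART..
    struct.pack_into("<3i", header, 28, nx, ny, nz)            # MX MY MZ
    struct.pack_into("<3f", header, 40, nx * vs, ny * vs, nz * vs)  # CELLA
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)      # CELLB
    struct.pack_into("<3i", header, 64, 1, 2, 3)               # MAPC MAPR MAPS
    struct.pack_into(
        "<3f", header, 76, float(grid.min()), float(grid.max()), float(grid.mean())
    )                                                          # DMIN DMAX DMEAN
    struct.pack_into("<i", header, 88, 1)                      # ISPG (volume)
    struct.pack_into("<i", header, 92, 0)                      # NSYMBT
    oz, oy, ox = volume.origin
    struct.pack_into("<3f", header, 196, float(ox), float(oy), float(oz))  # ORIGIN
    header[208:212] = b"MAP "
    header[212:216] = bytes([0x44, 0x44, 0x00, 0x00])          # MACHST little-endian
    struct.pack_into("<f", header, 216, float(grid.std()))     # RMS
    struct.pack_into("<i", header, 220, 0)                     # NLABL
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(grid.tobytes())


def read_mrc(path) -> DensityVolume:
    with open(path, "rb") as fh:
        header = fh.read(_HEADER_SIZE)
        if len(header) < _HEADER_SIZE:
            raise MRCFormatError("truncated file: header shorter than 1024 bytes")
        if header[208:212] not in (b"MAP ", b"MAP\x00"):
            raise MRCFormatError("bad MAP magic word at header bytes 208-211")
        nx, ny, nz = struct.unpack_from("<3i", header, 0)
        if min(nx, ny, nz) < 1:
            raise MRCFormatError(f"bad NX/NY/NZ dimensions ({nx}, {ny}, {nz})")
        (mode,) = struct.unpack_from("<i", header, 12)
        if mode != 2:
            raise MRCFormatError(f"unsupported MODE {mode}; only mode 2 (float32)")
        mx, my, mzv = struct.unpack_from("<3i", header, 28)
        ca, cb, cc = struct.unpack_from("<3f", header, 40)
        if mx <= 0 or ca <= 0:
            raise MRCFormatError("bad CELLA/MX grid sampling fields")
        voxel = ca / mx
        ox, oy, oz = struct.unpack_from("<3f", header, 196)
        (nsymbt,) = struct.unpack_from("<i", header, 92)
        fh.seek(_HEADER_SIZE + nsymbt)
        data = np.frombuffer(fh.read(4 * nx * ny * nz), dtype="<f4")
        if data.size != nx * ny * nz:
            raise MRCFormatError(
                f"truncated data section: expected {nx * ny * nz} voxels, got {data.size}"
            )
    grid = data.reshape(nz, ny, nx)
    return DensityVolume(grid, voxel, origin=np.array([oz, oy, ox], dtype=float))


def mrc_roundtrip(volume: DensityVolume, path) -> DensityVolume:
    """Write *volume* to *path* and read it back (bit-stable for float32)."""
    write_mrc(volume, path)
    return read_mrc(path)


def write_mrc_stack(images: np.ndarray, pixel_size: float, path) -> None:
    """Write a stack of 2D images (n, ny, nx) as an MRC volume file."""
    write_mrc(DensityVolume(np.asarray(images, dtype=np.float32), pixel_size), path)


# ---------------------------------------------------------------------------
# Rotation / resampling
# ---------------------------------------------------------------------------

def rotate_volume(volume: DensityVolume, transform, order: int = 1) -> DensityVolume:
    """Apply a rigid transform to a cubic volume about its center.

    The transform maps the reference frame into the particle frame: density
    at reference point u appears at R u + shift in the output.  Trilinear
    interpolation; values sampled outside the source are 0.
    """
    if not volume.is_cubic():
        raise ValueError(
            f"rotate_volume requires a cubic volume, got shape {volume.shape}"
        )
    grid = rotate_grid(volume.grid, transform, order=order)
    return DensityVolume(grid, volume.voxel_size, volume.origin.copy())


def rotate_grid(grid: np.ndarray, transform, order: int = 1) -> np.ndarray:
    """Grid-level version of :func:`rotate_volume` (shift in voxels, zyx)."""
    r_zyx = _J @ transform.matrix @ _J
    shift = np.asarray(transform.shift, dtype=float)
    center = (np.array(grid.shape, dtype=float) - 1.0) / 2.0
    a = r_zyx.T  # input coords = R^-1 (output - center - shift) + center
    offset = center - a @ (center + shift)
    out = affine_transform(
        grid.astype(np.float32, copy=False),
        a,
        offset=offset,
        order=order,
        mode="constant",
        cval=0.0,
        prefilter=(order > 1),
    )
    return out.astype(np.float32, copy=False)


def flip_x180(grid: np.ndarray) -> np.ndarray:
    """Exact 180° rotation about the x axis through the box center.

    Maps (z, y, x) -> (-z, -y, x); an index flip, no interpolation.
    """
    return np.ascontiguousarray(grid[::-1, ::-1, :])
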