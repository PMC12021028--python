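"""3-D scalar volumes and MRC2014 input/output.

Volumes are stored as ``(z, y, x)`` numpy arrays, 0-based and voxel-centered.
The physical scale is carried by a single isotropic ``voxel_size`` in
angstroms plus an ``origin`` giving the position (in Å, x/y/z order as in the
MRC header) of voxel ``(0, 0, 0)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .errors import FormatError, ValidationError

__all__ = ["Volume3D", "read_volume", "write_volume"]


@dataclass
class Volume3D:
    """A 3-D scalar grid with physical voxel size.

    Parameters
    ----------
    data:
        3-D array indexed ``(z, y, x)``; stored as float32.
    voxel_size:
        Isotropic voxel edge length in Å; must be positive.
    origin:
        Position of voxel (0,0,0) in Å, given in MRC header order (x, y, z).
    """

    data: np.ndarray
    voxel_size: float
    origin: tuple[float, float, float] = field(default=(0.0, 0.0, 0.0))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValidationError(
                f"data must be 3-D (z,y,x); got ndim={self.data.ndim}"
            )
        if not (self.voxel_size > 0) or not math.isfinite(self.voxel_size):
            raise ValidationError(f"voxel_size must be > 0, got {self.voxel_size}")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("data contains non-finite values")
        self.origin = tuple(float(v) for v in self.origin)
        if len(self.origin) != 3:
            raise ValidationError("origin must have three components (x, y, z)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def copy(self) -> "Volume3D":
        return Volume3D(self.data.copy(), self.voxel_size, self.origin)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Volume3D):
            return NotImplemented
        return (
            self.data.shape == other.data.shape
            and np.array_equal(self.data, other.data)
            and math.isclose(self.voxel_size, other.voxel_size, rel_tol=1e-6)
            and np.allclose(self.origin, other.origin, atol=1e-4)
        )


def read_volume(path) -> Volume3D:
    """Read an MRC2014 map into a :class:`Volume3D`.

    Raises
    ------
    FormatError
        If the file cannot be parsed, has an unsupported data mode, or does
        not hold a genuinely 3-D grid (every dimension must be >= 2).
    """
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise FormatError(f"cannot read MRC map {path}: {exc}") from exc
    grid = ccp4.grid
    # gemmi exposes the grid as (nx, ny, nz) with x fastest; transpose to (z,y,x)
    data = np.array(grid, copy=True).T
    if data.ndim != 3 or min(data.shape) < 2:
        raise FormatError(
            f"field nz/ny/nx: expected 3-D data, got grid shape {data.shape[::-1]}"
        )
    if not np.all(np.isfinite(data)):
        raise FormatError("field data: map contains non-finite values")
    cell = grid.unit_cell
    nx, ny, nz = grid.nu, grid.nv, grid.nw
    vx, vy, vz = cell.a / nx, cell.b / ny, cell.c / nz
    if not (
        math.isclose(vx, vy, rel_tol=1e-4) and math.isclose(vx, vz, rel_tol=1e-4)
    ):
        raise FormatError(
            f"field cell: anisotropic voxel size ({vx:.4g}, {vy:.4g}, {vz:.4g}) "
            "is not supported"
        )
    origin = tuple(ccp4.header_float(w) for w in (50, 51, 52))
    return Volume3D(data.astype(np.float32), float(vx), origin)


def write_volume(vol: Volume3D, path):
    """Write a :class:`Volume3D` as an MRC2014 map (mode 2, float32).

    Returns the path written. ``write_volume`` followed by :func:`read_volume`
    is the identity on data, voxel size and origin.
    """
    nz, ny, nx = vol.data.shape
    grid = gemmi.FloatGrid(np.ascontiguousarray(vol.data.T))
    grid.unit_cell = gemmi.UnitCell(
        nx * vol.voxel_size, ny * vol.voxel_size, nz * vol.voxel_size, 90, 90, 90
    )
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    for word, value in zip((50, 51, 52), vol.origin):
        ccp4.set_header_float(word, float(value))
    ccp4.write_ccp4_map(str(path))
    return path
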