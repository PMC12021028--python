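"""Particle tables: positions, ZYZ orientations and matching scores.

A :class:`ParticleTable` is a thin, validated wrapper around a pandas
DataFrame with the seven canonical columns::

    x, y, z      voxel coordinates (0-based, voxel-centered, float)
    rot, tilt, psi   ZYZ intrinsic Euler angles in degrees (RELION convention)
    score        normalized cross-correlation in [-1, 1]

Tables round-trip exactly through TSV and through a STAR dialect
(``_rlnCoordinateX/Y/Z``, ``_rlnAngleRot/Tilt/Psi``,
``_rlnAutopickFigureOfMerit``).  STAR files store 1-based coordinates, the
convention of most subtomogram tools; :func:`to_star_coords` /
:func:`from_star_coords` are the explicit converters used internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "COLUMNS",
    "ParticleTable",
    "read_particles",
    "write_particles",
    "to_star_coords",
    "from_star_coords",
]

COLUMNS = ("x", "y", "z", "rot", "tilt", "psi", "score")

_STAR_NAMES = {
    "x": "_rlnCoordinateX",
    "y": "_rlnCoordinateY",
    "z": "_rlnCoordinateZ",
    "rot": "_rlnAngleRot",
    "tilt": "_rlnAngleTilt",
    "psi": "_rlnAnglePsi",
    "score": "_rlnAutopickFigureOfMerit",
}


def to_star_coords(value):
    """0-based voxel coordinate -> 1-based STAR coordinate."""
    return value + 1.0


def from_star_coords(value):
    """1-based STAR coordinate -> 0-based voxel coordinate."""
    return value - 1.0


@dataclass
class ParticleTable:
    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"missing column(s): {', '.join(missing)}")
        self.df = self.df.loc[:, list(COLUMNS)].astype(float).reset_index(drop=True)
        if len(self.df):
            score = self.df["score"].to_numpy()
            if np.any(score < -1 - 1e-9) or np.any(score > 1 + 1e-9):
                bad = score[(score < -1 - 1e-9) | (score > 1 + 1e-9)][0]
                raise ValidationError(f"score {bad} outside [-1, 1]")
            if not np.all(np.isfinite(self.df.to_numpy())):
                raise ValidationError("particle table contains non-finite values")

    def __len__(self) -> int:
        return len(self.df)

    def positions(self) -> np.ndarray:
        """(n, 3) array of positions in (z, y, x) voxel order."""
        return self.df[["z", "y", "x"]].to_numpy()

    def angles(self) -> np.ndarray:
        """(n, 3) array of (rot, tilt, psi) in degrees."""
        return self.df[["rot", "tilt", "psi"]].to_numpy()

    def validate_bounds(self, shape: tuple[int, int, int]) -> None:
        """Check every coordinate lies inside a (z, y, x) volume shape."""
        nz, ny, nx = shape
        pos = self.df[["x", "y", "z"]].to_numpy()
        lim = np.array([nx, ny, nz], dtype=float)
        if len(pos) and (np.any(pos < -0.5) or np.any(pos > lim - 0.5)):
            raise ValidationError(f"particle coordinates outside volume shape {shape}")

    @classmethod
    def empty(cls) -> "ParticleTable":
        return cls(pd.DataFrame({c: pd.Series(dtype=float) for c in COLUMNS}))


def read_particles(path) -> ParticleTable:
    """Read a TSV or STAR particle table (dialect chosen by extension)."""
    path = Path(path)
    if path.suffix.lower() == ".star":
        return _read_star(path)
    df = pd.read_csv(path, sep="\t")
    return ParticleTable(df)


def write_particles(table: ParticleTable, path):
    """Write a particle table as TSV or STAR (dialect chosen by extension)."""
    path = Path(path)
    if path.suffix.lower() == ".star":
        _write_star(table, path)
    else:
        table.df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def _read_star(path: Path) -> ParticleTable:
    try:
        doc = gemmi.cif.read_file(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse STAR file {path}: {exc}") from exc
    block = doc.sole_block()
    declared = block.find_value("_ciliacoatParticleCount")
    if declared is not None and int(declared) == 0:
        return ParticleTable.empty()
    cols = {}
    for key, tag in _STAR_NAMES.items():
        values = block.find_loop(tag)
        if not values:
            raise FormatError(f"missing column: {tag}")
        cols[key] = np.array([float(v) for v in values])
    for axis in ("x", "y", "z"):
        cols[axis] = from_star_coords(cols[axis])
    return ParticleTable(pd.DataFrame(cols))


def _write_star(table: ParticleTable, path: Path) -> None:
    doc = gemmi.cif.Document()
    block = doc.add_new_block("particles")
    # explicit count: gemmi drops row-less loops, so empty tables need it
    block.set_pair("_ciliacoatParticleCount", str(len(table)))
    loop = block.init_loop("", [_STAR_NAMES[c] for c in COLUMNS])
    for _, row in table.df.iterrows():
        values = []
        for c in COLUMNS:
            v = to_star_coords(row[c]) if c in ("x", "y", "z") else row[c]
            values.append(f"{v:.10g}")
        loop.add_row(values)
    doc.write_file(str(path))
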