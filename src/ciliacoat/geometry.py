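"""Rotation conventions and small-volume resampling shared across stages.

Orientations are ZYZ intrinsic Euler angles in degrees (RELION convention):
``R = Rz(rot) @ Ry(tilt) @ Rz(psi)`` applied to template-frame vectors gives
world-frame vectors.  Volumes rotate about their geometric center
``(n - 1) / 2`` per axis.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

__all__ = [
    "euler_to_matrix",
    "matrix_to_euler",
    "rotation_from_z_axis",
    "rotate_volume",
    "angular_distance",
]


def euler_to_matrix(rot: float, tilt: float, psi: float) -> np.ndarray:
    """ZYZ intrinsic Euler angles (degrees) -> 3x3 rotation matrix (x,y,z frame)."""
    return Rotation.from_euler("ZYZ", [rot, tilt, psi], degrees=True).as_matrix()


def matrix_to_euler(matrix: np.ndarray) -> tuple[float, float, float]:
    """3x3 rotation matrix -> ZYZ intrinsic Euler angles in degrees."""
    rot, tilt, psi = Rotation.from_matrix(matrix).as_euler("ZYZ", degrees=True)
    return float(rot), float(tilt), float(psi)


def rotation_from_z_axis(direction: np.ndarray, spin: float = 0.0) -> np.ndarray:
    """Rotation taking the +z template axis onto ``direction`` (x,y,z order).

    ``spin`` (degrees) applies an extra rotation about the template z axis
    first, so templates with identical ``direction`` can differ by in-plane
    angle.  The remaining freedom is fixed by the minimal rotation from z to
    ``direction``.
    """
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, d)
    s = np.linalg.norm(v)
    c = float(np.dot(z, d))
    if s < 1e-12:
        align = np.eye(3) if c > 0 else Rotation.from_euler("x", 180, degrees=True).as_matrix()
    else:
        axis = v / s
        angle = np.arctan2(s, c)
        align = Rotation.from_rotvec(axis * angle).as_matrix()
    spin_m = Rotation.from_euler("z", spin, degrees=True).as_matrix()
    return align @ spin_m


def rotate_volume(
    vol: np.ndarray,
    angles: tuple[float, float, float],
    order: int = 1,
    shift: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> np.ndarray:
    """Rotate a small (z,y,x) volume about its center by ZYZ angles (degrees).

    ``shift`` is an optional post-rotation subvoxel translation in (z,y,x)
    voxels, so generators can place templates at continuous positions with a
    single interpolation pass.  Linear interpolation by default; voxels
    rotated in from outside are zero.
    """
    R = euler_to_matrix(*angles)
    # ndimage works in (z,y,x) index space; our matrix acts on (x,y,z) vectors.
    perm = R[::-1, ::-1]  # same rotation expressed for (z,y,x) coordinates
    center = (np.array(vol.shape) - 1) / 2.0
    # affine_transform maps output coords -> input coords: inverse rotation
    inv = perm.T
    offset = center - inv @ (center + np.asarray(shift, dtype=float))
    return ndimage.affine_transform(
        vol, inv, offset=offset, order=order, mode="constant", cval=0.0,
        prefilter=(order > 1),
    )


def angular_distance(mat_a: np.ndarray, mat_b: np.ndarray) -> float:
    """Geodesic angle (degrees) between two rotations."""
    r = Rotation.from_matrix(mat_a.T @ mat_b)
    return float(np.degrees(np.linalg.norm(r.as_rotvec())))
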