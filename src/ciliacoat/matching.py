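"""Coat-particle localization: rotation-searched normalized cross-correlation
inside a shell mask, peak extraction, and greedy overlap-exclusion filtering.

The matcher scores every masked voxel with the maximum, over a deterministic
SO(3) grid, of the locally normalized cross-correlation between the volume
and the rotated template — mean and variance taken under the rotated
template's own footprint (Roseman-style masked NCC, computed with FFTs).
An optional missing-wedge filter is applied to each rotated template before
scoring so the reference suffers the same anisotropy as the tomogram.

Peaks are thresholded local maxima, pruned greedily by distance, and finally
filtered by simulated-density fill-in: candidates are visited in descending
score, each one's binarized rotated-template footprint is compared against
the voxels already claimed by accepted particles, and a candidate is
rejected when the claimed fraction of its footprint exceeds the overlap
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft as sfft
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .errors import ParameterError, ValidationError
from .geometry import euler_to_matrix, rotate_volume
from .membrane import ShellMask, TubeModel
from .particles import ParticleTable
from .synthetic.tomogram import missing_wedge_mask
from .volume import Volume3D

__all__ = [
    "RotationGrid",
    "make_rotation_grid",
    "ScoreMap",
    "match_template",
    "Candidate",
    "extract_peaks",
    "refine_positions",
    "overlap_filter",
    "template_footprint",
    "coat_statistics",
]

SENTINEL = -2.0  # score value outside the mask
FOOTPRINT_LEVEL = 0.1  # binarization level, fraction of template max


@dataclass
class RotationGrid:
    """Deterministic near-uniform SO(3) sampling as ZYZ Euler triplets."""

    angles: np.ndarray  # (n, 3) degrees
    step: float

    def __len__(self) -> int:
        return len(self.angles)

    def matrices(self) -> np.ndarray:
        return Rotation.from_euler("ZYZ", self.angles, degrees=True).as_matrix()


def make_rotation_grid(step: float) -> RotationGrid:
    """Near-uniform SO(3) covering with the given nominal angular step.

    Tilt rings are spaced by ``step``; the azimuth count per ring scales with
    sin(tilt) so the covering stays near-uniform; the in-plane angle is
    sampled every ``step`` everywhere.  Duplicate rotations (the degenerate
    rings at tilt 0 and 180) are removed by quaternion comparison.  The
    identity is always included and the construction is deterministic.
    """
    if not (0 < step <= 360):
        raise ParameterError(f"step must be in (0, 360], got {step}")
    tilts = np.arange(0.0, 180.0 + 1e-9, step)
    if tilts[-1] < 180.0 - 1e-9 and len(tilts) > 1:
        tilts = np.append(tilts, 180.0)
    triplets = []
    n_psi = max(1, int(round(360.0 / step)))
    psis = np.arange(n_psi) * (360.0 / n_psi)
    for tilt in tilts:
        s = np.sin(np.radians(tilt))
        n_rot = max(1, int(round(n_psi * s)))
        rots = np.arange(n_rot) * (360.0 / n_rot)
        for rot in rots:
            for psi in psis:
                triplets.append((rot, tilt, psi))
    angles = np.array(triplets)
    quats = Rotation.from_euler("ZYZ", angles, degrees=True).as_quat()
    # canonicalize sign (q and -q are the same rotation), round, deduplicate
    rounded = np.round(quats, 5)
    lead = np.argmax(np.abs(rounded) > 1e-4, axis=1)
    signs = np.sign(rounded[np.arange(len(rounded)), lead])
    rounded *= signs[:, None]
    _, first = np.unique(rounded, axis=0, return_index=True)
    angles = angles[np.sort(first)]
    # put the identity first
    mats = Rotation.from_euler("ZYZ", angles, degrees=True).as_matrix()
    ident = np.argmin([np.linalg.norm(m - np.eye(3)) for m in mats])
    order = [int(ident)] + [i for i in range(len(angles)) if i != ident]
    return RotationGrid(angles[order], float(step))


@dataclass
class ScoreMap:
    """Best normalized cross-correlation per masked voxel.

    ``scores`` holds ``SENTINEL`` outside the mask; ``best_orientation`` is
    the rotation-grid row index of the best orientation (-1 outside).
    """

    scores: np.ndarray
    best_orientation: np.ndarray
    grid: RotationGrid
    mask: np.ndarray
    voxel_size: float

    def max_score(self) -> float:
        inside = self.scores[self.mask]
        return float(inside.max()) if inside.size else float("nan")


def template_footprint(template: Volume3D | np.ndarray, level: float = FOOTPRINT_LEVEL) -> np.ndarray:
    """Binarize a template at ``level`` × its maximum (the 'predicted density')."""
    data = template.data if isinstance(template, Volume3D) else template
    return data > level * float(data.max())


def _corr_kernel_fft(kernel: np.ndarray, shape) -> np.ndarray:
    """FFT of a small kernel embedded so correlation output is centered.

    With the kernel's center voxel placed at index 0 (wrapped), the inverse
    transform of ``V * conj(K)`` evaluated at p equals
    ``sum_q vol[p + q - c] * kernel[q]``.
    """
    pad = np.zeros(shape, dtype=np.float32)
    kz, ky, kx = kernel.shape
    pad[:kz, :ky, :kx] = kernel
    center = (np.array(kernel.shape) - 1) // 2
    pad = np.roll(pad, -center, axis=(0, 1, 2))
    return sfft.rfftn(pad)


def match_template(
    vol: Volume3D,
    template: Volume3D,
    mask: ShellMask | np.ndarray,
    grid: RotationGrid,
    wedge: float | None = None,
    footprint_level: float = FOOTPRINT_LEVEL,
) -> ScoreMap:
    """Rotation-searched, locally normalized cross-correlation inside a mask.

    For each orientation the rotated template is correlated against the
    volume; normalization uses the mean and variance of the volume under the
    rotated template's binarized footprint, so scores are true correlation
    coefficients in [-1, 1].  ``wedge`` (degrees, e.g. 60) applies a binary
    missing-wedge filter to each rotated template before scoring.
    """
    if isinstance(mask, ShellMask):
        if abs(mask.voxel_size - vol.voxel_size) > 1e-6 * vol.voxel_size:
            raise ParameterError(
                f"voxel size mismatch: volume {vol.voxel_size} Å vs mask {mask.voxel_size} Å"
            )
        mask_arr = mask.mask
    else:
        mask_arr = np.asarray(mask, dtype=bool)
    if abs(template.voxel_size - vol.voxel_size) > 1e-6 * vol.voxel_size:
        raise ParameterError(
            f"voxel size mismatch: volume {vol.voxel_size} Å vs template {template.voxel_size} Å"
        )
    if any(t > s for t, s in zip(template.data.shape, vol.data.shape)):
        raise ParameterError("template must be smaller than the volume")
    if mask_arr.shape != vol.data.shape:
        raise ParameterError("mask shape does not match volume shape")

    shape = vol.data.shape
    data = vol.data.astype(np.float32)
    V = sfft.rfftn(data)
    V2 = sfft.rfftn(data * data)

    wedge_filter = None
    if wedge is not None:
        wedge_filter = missing_wedge_mask(template.data.shape, float(wedge))

    best = np.full(shape, -np.inf, dtype=np.float32)
    best_idx = np.full(shape, -1, dtype=np.int32)
    tiny = 1e-8
    for idx, angles in enumerate(grid.angles):
        t_rot = rotate_volume(template.data, tuple(angles))
        foot = template_footprint(t_rot, footprint_level).astype(np.float32)
        if wedge_filter is not None:
            spec = sfft.rfftn(t_rot)
            spec[~wedge_filter] = 0
            t_rot = sfft.irfftn(spec, s=t_rot.shape).astype(np.float32)
        t_rot = t_rot * (foot > 0)  # score under the footprint only
        n = float(foot.sum())
        if n < 1:
            continue
        t_sum = float(t_rot.sum())
        t2_sum = float((t_rot * t_rot).sum())
        t_var = t2_sum - t_sum * t_sum / n
        if t_var <= tiny:
            continue
        K_t = _corr_kernel_fft(t_rot, shape)
        K_f = _corr_kernel_fft(foot, shape)
        corr_vt = sfft.irfftn(V * np.conj(K_t), s=shape)
        sum_v = sfft.irfftn(V * np.conj(K_f), s=shape)
        sum_v2 = sfft.irfftn(V2 * np.conj(K_f), s=shape)
        v_var = sum_v2 - sum_v * sum_v / n
        np.maximum(v_var, 0.0, out=v_var)
        denom = np.sqrt(v_var * t_var)
        score = (corr_vt - sum_v * (t_sum / n)) / np.maximum(denom, tiny)
        score[denom <= tiny] = 0.0
        improved = score > best
        best[improved] = score[improved]
        best_idx[improved] = idx

    np.clip(best, -1.0, 1.0, out=best)
    best[~mask_arr] = SENTINEL
    best_idx[~mask_arr] = -1
    return ScoreMap(best, best_idx, grid, mask_arr, vol.voxel_size)


@dataclass(order=True)
class Candidate:
    """A scored match: position (z, y, x ints), orientation, score."""

    sort_key: tuple = field(init=False, repr=False, compare=True)
    position: tuple[int, int, int] = field(compare=False)
    angles: tuple[float, float, float] = field(compare=False)
    orientation_index: int = field(compare=False)
    score: float = field(compare=False)

    def __post_init__(self) -> None:
        # deterministic visit order: score descending, then z, y, x, then
        # orientation index
        self.sort_key = (-self.score, *self.position, self.orientation_index)


def extract_peaks(
    scores: ScoreMap, min_distance: float, threshold: float
) -> list[Candidate]:
    """Thresholded local maxima, greedily pruned by an exclusion radius.

    Local maxima (26-connectivity plateaus included) above ``threshold`` are
    visited in descending score (ties: z, y, x ascending); each kept peak
    suppresses all later peaks within ``min_distance`` voxels (Euclidean).
    """
    if min_distance < 1:
        raise ParameterError("min_distance must be >= 1")
    s = scores.scores
    local_max = s == ndimage.maximum_filter(s, size=3, mode="nearest")
    eligible = local_max & scores.mask & (s >= threshold)
    coords = np.argwhere(eligible)
    if len(coords) == 0:
        return []
    cands = [
        Candidate(
            position=tuple(int(v) for v in c),
            angles=tuple(scores.grid.angles[scores.best_orientation[tuple(c)]]),
            orientation_index=int(scores.best_orientation[tuple(c)]),
            score=float(s[tuple(c)]),
        )
        for c in coords
    ]
    cands.sort()
    kept: list[Candidate] = []
    kept_pos: list[np.ndarray] = []
    for cand in cands:
        p = np.array(cand.position, dtype=float)
        if kept_pos and np.min(np.linalg.norm(np.array(kept_pos) - p, axis=1)) < min_distance:
            continue
        kept.append(cand)
        kept_pos.append(p)
    return kept


def refine_positions(scores: ScoreMap, candidates) -> np.ndarray:
    """Sub-voxel peak positions by separable parabolic fit on the score map.

    For each candidate, a quadratic is fitted through the three scores along
    each axis; the apex offset (clipped to ±1 voxel) is added to the integer
    peak.  Returns an (n, 3) float array of (z, y, x) positions.
    """
    s = scores.scores
    out = np.empty((len(candidates), 3))
    for i, cand in enumerate(candidates):
        p = np.array(cand.position)
        for ax in range(3):
            lo = p.copy(); lo[ax] -= 1
            hi = p.copy(); hi[ax] += 1
            if lo[ax] < 0 or hi[ax] >= s.shape[ax]:
                out[i, ax] = p[ax]
                continue
            a, b, c = s[tuple(lo)], s[tuple(p)], s[tuple(hi)]
            denom = a - 2 * b + c
            if denom >= -1e-12 or a == SENTINEL or c == SENTINEL:
                out[i, ax] = p[ax]
                continue
            out[i, ax] = p[ax] + float(np.clip(0.5 * (a - c) / denom, -1.0, 1.0))
    return out


def _footprint_voxels(cand: Candidate, template: np.ndarray, shape, level: float):
    """Flat indices of the candidate's binarized rotated-template footprint,
    clipped to the volume."""
    foot = template_footprint(rotate_volume(template, cand.angles), level)
    box = np.array(foot.shape)
    lo = np.array(cand.position) - box // 2
    zz, yy, xx = np.nonzero(foot)
    z, y, x = zz + lo[0], yy + lo[1], xx + lo[2]
    ok = (
        (z >= 0) & (z < shape[0]) & (y >= 0) & (y < shape[1]) & (x >= 0) & (x < shape[2])
    )
    return np.ravel_multi_index((z[ok], y[ok], x[ok]), shape)


def overlap_filter(
    candidates,
    template: Volume3D | np.ndarray,
    overlap_threshold: float,
    shape: tuple[int, int, int],
    footprint_level: float = FOOTPRINT_LEVEL,
) -> list[Candidate]:
    """Greedy overlap-exclusion by simulated-density fill-in.

    Candidates are visited in descending score (deterministic tie rule);
    each candidate's binarized rotated-template footprint is compared with
    the occupancy volume of already-accepted particles and the candidate is
    accepted iff ``|claimed ∩ footprint| / |footprint| <= overlap_threshold``,
    after which its footprint is claimed.  Visit order is preserved in the
    output.
    """
    if not (0 <= overlap_threshold < 1):
        raise ParameterError("overlap threshold must be in [0, 1)")
    tdata = template.data if isinstance(template, Volume3D) else np.asarray(template)
    occupancy = np.zeros(int(np.prod(shape)), dtype=bool)
    accepted: list[Candidate] = []
    for cand in sorted(candidates):
        vox = _footprint_voxels(cand, tdata, shape, footprint_level)
        if len(vox) == 0:
            continue
        frac = float(occupancy[vox].sum()) / len(vox)
        if frac <= overlap_threshold:
            accepted.append(cand)
            occupancy[vox] = True
    return accepted


def candidates_to_table(candidates) -> ParticleTable:
    import pandas as pd

    rows = {
        "x": [c.position[2] for c in candidates],
        "y": [c.position[1] for c in candidates],
        "z": [c.position[0] for c in candidates],
        "rot": [c.angles[0] for c in candidates],
        "tilt": [c.angles[1] for c in candidates],
        "psi": [c.angles[2] for c in candidates],
        "score": [min(max(c.score, -1.0), 1.0) for c in candidates],
    }
    return ParticleTable(pd.DataFrame(rows)) if rows["x"] else ParticleTable.empty()


def coat_statistics(
    particles: ParticleTable,
    tube: TubeModel,
    voxel_size: float,
) -> dict:
    """Summary of a mapped coat: count, surface density, spacing, tilt.

    Surface density is particles per µm² of a cylinder at the mean particle
    radius over the tube's fitted z extent; the orientation-to-normal angle
    is between each particle's template z axis and the outward radial
    direction from the local contour centroid.
    """
    n = len(particles)
    if n == 0:
        return {
            "count": 0,
            "surface_density_per_um2": 0.0,
            "nn_distances_angstrom": np.array([]),
            "normal_angles_deg": np.array([]),
            "mean_shell_radius_angstrom": 0.0,
        }
    pos = particles.positions()  # (n, 3) z,y,x voxels
    z0, z1 = tube.slice_range
    radii = np.empty(n)
    normal_angles = np.empty(n)
    mats = [euler_to_matrix(*a) for a in particles.angles()]
    for i, (p, R) in enumerate(zip(pos, mats)):
        ring = tube.contour_points_at(p[0])
        c = ring.mean(axis=0)
        radial = np.array([p[2] - c[1], p[1] - c[0], 0.0])  # (x, y, z)
        radii[i] = np.linalg.norm(radial[:2])
        if radii[i] > 1e-9:
            axis = R @ np.array([0.0, 0.0, 1.0])
            cosang = np.dot(axis, radial / radii[i])
            normal_angles[i] = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
        else:
            normal_angles[i] = np.nan
    mean_radius = float(radii.mean()) * voxel_size
    height = max((z1 - z0), 1) * voxel_size
    area_um2 = 2 * np.pi * (mean_radius * 1e-4) * (height * 1e-4)
    if n >= 2:
        tree = cKDTree(pos * voxel_size)
        nn, _ = tree.query(pos * voxel_size, k=2)
        nn_dist = nn[:, 1]
    else:
        nn_dist = np.array([])
    return {
        "count": n,
        "surface_density_per_um2": n / area_um2 if area_um2 > 0 else 0.0,
        "nn_distances_angstrom": nn_dist,
        "normal_angles_deg": normal_angles,
        "mean_shell_radius_angstrom": mean_radius,
    }
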