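"""Membrane contour fitting and glycocalyx shell masks.

The membrane of the cilium is modelled per cross-sectional slice as a closed
periodic cubic spline fitted to clicked (or phantom-truth) points, the fitted
contours are stacked and interpolated into a tube, and the coat band is the
set of voxels *outside* the membrane whose distance to the contour lies in
``[d_in, d_out]`` Å.  Offsetting is done with a distance field rather than
analytic normal displacement, so concave contours cannot produce
self-intersection artifacts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import interpolate
from scipy.spatial import cKDTree
from shapely.geometry import Polygon
from shapely import contains_xy

from .errors import FitError, ParameterError, ValidationError
from .volume import Volume3D

__all__ = [
    "ClosedContour",
    "TubeModel",
    "ShellMask",
    "fit_closed_contour",
    "build_tube",
    "build_shell_mask",
    "read_membrane_points",
]


@dataclass
class ClosedContour:
    """Periodic cubic spline in one slice, in (y, x) voxel coordinates."""

    tck: tuple
    slice_index: int = 0
    smoothing: float = 0.0

    def evaluate(self, n: int = 256) -> np.ndarray:
        """(n, 2) array of (y, x) points along the closed curve."""
        u = np.linspace(0.0, 1.0, n, endpoint=False)
        y, x = interpolate.splev(u, self.tck)
        return np.stack([y, x], axis=1)

    def resample_arclength(self, n: int = 128) -> np.ndarray:
        """(n, 2) points equally spaced in arc length, CCW, starting at the
        point nearest direction +x from the centroid (a twist-free, matched
        parameterization for inter-slice interpolation)."""
        dense = self.evaluate(2048)
        c = dense.mean(axis=0)
        rel = dense - c
        # enforce counter-clockwise order in (y, x)
        area2 = np.sum(dense[:, 1] * np.roll(dense[:, 0], -1) - np.roll(dense[:, 1], -1) * dense[:, 0])
        if area2 < 0:
            dense = dense[::-1]
            rel = rel[::-1]
        start = int(np.argmin(np.abs(np.arctan2(rel[:, 0], rel[:, 1]))))
        dense = np.roll(dense, -start, axis=0)
        seg = np.linalg.norm(np.diff(dense, axis=0, append=dense[:1]), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])[:-1]
        targets = np.linspace(0.0, arc[-1] + seg[-1], n, endpoint=False)
        out = np.empty((n, 2))
        closed = np.vstack([dense, dense[:1]])
        arc_c = np.concatenate([arc, [arc[-1] + seg[-1]]])
        for k in range(2):
            out[:, k] = np.interp(targets, arc_c, closed[:, k])
        return out

    @property
    def centroid(self) -> np.ndarray:
        return self.evaluate(1024).mean(axis=0)

    def is_simple(self) -> bool:
        return Polygon(self.evaluate(512)[:, ::-1]).is_valid


def fit_closed_contour(points, smoothing: float = 0.0, slice_index: int = 0) -> ClosedContour:
    """Fit a periodic cubic smoothing spline through 2-D membrane points.

    ``points`` is an (n, 2) array of (y, x) coordinates, n >= 4, not
    collinear; points may be in any order (they are sorted by angle about
    their centroid before fitting).  ``smoothing`` is the scipy ``splprep``
    ``s`` parameter (0 interpolates).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 4:
        raise FitError(f"need >= 4 (y, x) points, got shape {pts.shape}")
    centered = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[1] < 1e-6 * max(sv[0], 1.0):
        raise FitError("points are collinear; cannot fit a closed contour")
    order = np.argsort(np.arctan2(centered[:, 0], centered[:, 1]))
    pts = pts[order]
    closed = np.vstack([pts, pts[:1]])
    k = 3 if len(pts) >= 4 else len(pts) - 1
    tck, _ = interpolate.splprep([closed[:, 0], closed[:, 1]], s=smoothing, per=True, k=k)
    contour = ClosedContour(tck=tck, slice_index=slice_index, smoothing=smoothing)
    if not contour.is_simple():
        raise FitError("fitted contour is self-intersecting")
    return contour


@dataclass
class TubeModel:
    """Stack of per-slice contours with linear inter-slice interpolation.

    ``slices`` are the fitted slice indices (strictly increasing);
    ``rings`` is an (n_slices, m, 2) array of matched arc-length-resampled
    control points per fitted slice.
    """

    slices: np.ndarray
    rings: np.ndarray

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices, dtype=float)
        self.rings = np.asarray(self.rings, dtype=float)
        if np.any(np.diff(self.slices) <= 0):
            raise ValidationError("slice indices must be strictly increasing")
        if self.rings.ndim != 3 or self.rings.shape[0] != len(self.slices):
            raise ValidationError("rings must be (n_slices, m, 2)")

    @property
    def slice_range(self) -> tuple[int, int]:
        return int(np.ceil(self.slices[0])), int(np.floor(self.slices[-1]))

    def contour_points_at(self, z: float) -> np.ndarray:
        """(m, 2) interpolated contour at slice ``z`` (clamped to the fitted
        range), by control-point-wise linear interpolation."""
        z = float(np.clip(z, self.slices[0], self.slices[-1]))
        i = int(np.searchsorted(self.slices, z, side="right") - 1)
        i = min(max(i, 0), len(self.slices) - 2) if len(self.slices) > 1 else 0
        z0, z1 = self.slices[i], self.slices[i + 1]
        w = 0.0 if z1 == z0 else (z - z0) / (z1 - z0)
        return (1 - w) * self.rings[i] + w * self.rings[i + 1]

    def centroid_path(self) -> np.ndarray:
        return self.rings.mean(axis=1)

    def to_json(self, path):
        payload = {"slices": self.slices.tolist(), "rings": self.rings.tolist()}
        with open(path, "w") as fh:
            json.dump(payload, fh)
        return path

    @classmethod
    def from_json(cls, path) -> "TubeModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(np.array(payload["slices"]), np.array(payload["rings"]))


def build_tube(contours) -> TubeModel:
    """Stack fitted contours into a tube model.

    Contours are re-parameterized to matched arc-length control points so
    that interpolation between fitted slices is control-point-wise linear.
    """
    if len(contours) < 2:
        raise FitError(
            "a tube needs contours in at least 2 slices; for single-slice "
            "work use the ClosedContour directly"
        )
    ordered = sorted(contours, key=lambda c: c.slice_index)
    slices = np.array([c.slice_index for c in ordered], dtype=float)
    if np.any(np.diff(slices) <= 0):
        raise ValidationError("duplicate slice indices in tube")
    rings = np.stack([c.resample_arclength(128) for c in ordered])
    return TubeModel(slices, rings)


@dataclass
class ShellMask:
    """Boolean glycocalyx band between two offsets of the membrane."""

    mask: np.ndarray
    d_in: float
    d_out: float
    voxel_size: float

    def as_volume(self) -> Volume3D:
        return Volume3D(self.mask.astype(np.float32), self.voxel_size)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def _slice_shell(ring: np.ndarray, d_in_px: float, d_out_px: float, shape2d, mode: str):
    ny, nx = shape2d
    dense = _densify(ring, 4096)
    tree = cKDTree(dense)
    lo = np.maximum(np.floor(dense.min(axis=0) - d_out_px - 2), 0).astype(int)
    hi = np.minimum(np.ceil(dense.max(axis=0) + d_out_px + 3), [ny, nx]).astype(int)
    if np.any(lo >= hi):
        return np.zeros(shape2d, dtype=bool)
    yy, xx = np.mgrid[lo[0]: hi[0], lo[1]: hi[1]]
    pts = np.stack([yy.ravel(), xx.ravel()], axis=1).astype(float)
    dist, _ = tree.query(pts, workers=-1)
    poly = Polygon(dense[:, ::-1])  # shapely wants (x, y)
    inside = contains_xy(poly, pts[:, 1], pts[:, 0])
    if mode == "band":
        keep = (~inside) & (dist >= d_in_px) & (dist <= d_out_px)
    else:  # half-space: everything outside beyond d_in
        keep = (~inside) & (dist >= d_in_px)
    out = np.zeros(shape2d, dtype=bool)
    out[yy.ravel()[keep], xx.ravel()[keep]] = True
    return out


def _densify(ring: np.ndarray, n: int) -> np.ndarray:
    closed = np.vstack([ring, ring[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, arc[-1], n, endpoint=False)
    out = np.empty((n, 2))
    for k in range(2):
        out[:, k] = np.interp(targets, arc, closed[:, k])
    return out


def build_shell_mask(
    tube: TubeModel,
    d_in: float,
    d_out: float,
    shape: tuple[int, int, int],
    voxel_size: float,
    mode: str = "band",
) -> ShellMask:
    """Rasterize the band ``[d_in, d_out]`` Å outside the membrane tube.

    Per slice, the unsigned distance of every voxel center to the (densely
    resampled) contour is measured exactly with a KD-tree; voxels inside the
    contour are never marked.  ``mode='halfspace'`` drops the outer bound.
    Slices outside the fitted range use the nearest fitted contour.
    """
    if mode == "band" and not (0 <= d_in < d_out):
        raise ParameterError(f"need 0 <= d_in < d_out, got {d_in}, {d_out}")
    if mode not in ("band", "halfspace"):
        raise ParameterError(f"unknown mode {mode!r}")
    nz, ny, nx = shape
    d_in_px = d_in / voxel_size
    d_out_px = d_out / voxel_size if mode == "band" else np.inf
    mask = np.zeros(shape, dtype=bool)
    for z in range(nz):
        ring = tube.contour_points_at(z)
        mask[z] = _slice_shell(ring, d_in_px, d_out_px, (ny, nx), mode)
    return ShellMask(mask, d_in, d_out, voxel_size)


def read_membrane_points(path):
    """Read a membrane-points CSV with columns slice,y,x -> dict slice -> (n,2)."""
    import pandas as pd

    df = pd.read_csv(path)
    need = {"slice", "y", "x"}
    if not need.issubset(df.columns):
        raise ParameterError(f"membrane points CSV needs columns {sorted(need)}")
    groups = {}
    for s, sub in df.groupby("slice"):
        groups[int(s)] = sub[["y", "x"]].to_numpy(dtype=float)
    return groups
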