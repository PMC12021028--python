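"""Tomogram phantom: a coated membrane tube imaged with a missing wedge.

The phantom emulates the geometry seen in cryo-electron tomograms of intact
cilia: a tubular membrane (Gaussian shell around a smooth centerline), nine
axonemal rods inside it for visual realism, and a coat of small asymmetric
particles placed on outward surface normals inside a band at a defined
offset from the membrane — the scale-like outer glycocalyx layer.  Imaging
is modelled as additive Gaussian noise followed by a binary Fourier missing
wedge for a limited tilt series (±60° in 2° steps by default, matching
dose-symmetric acquisition from -60° to +60°).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import ParameterError, ValidationError
from ..geometry import euler_to_matrix, matrix_to_euler, rotation_from_z_axis, rotate_volume
from ..volume import Volume3D

__all__ = [
    "TomoPhantomSpec",
    "GroundTruthParticle",
    "default_template",
    "simulate_tomogram",
    "apply_missing_wedge",
    "missing_wedge_mask",
    "membrane_points",
]


def default_template(voxel_size: float = 10.0, box: int = 17) -> Volume3D:
    """Small asymmetric L-shaped particle template (three fused Gaussians).

    The three lobes break every rotational symmetry so that orientation is
    identifiable; the lobe layout extends mostly along the template z axis,
    the axis aligned with the outward membrane normal when placed.  Peak
    amplitude is normalized to 1.
    """
    zz, yy, xx = np.indices((box, box, box), dtype=float)
    c = (box - 1) / 2.0
    lobes = [  # (dz, dy, dx, sigma, amplitude) in voxels
        (-2.5, 0.0, 0.0, 2.0, 1.0),
        (2.0, 0.0, 0.0, 1.7, 0.9),
        (0.5, 2.4, 0.8, 1.4, 0.8),
    ]
    data = np.zeros((box, box, box))
    for dz, dy, dx, s, a in lobes:
        r2 = (zz - c - dz) ** 2 + (yy - c - dy) ** 2 + (xx - c - dx) ** 2
        data += a * np.exp(-r2 / (2 * s * s))
    data /= data.max()
    return Volume3D(data.astype(np.float32), voxel_size)


@dataclass
class GroundTruthParticle:
    """Planted particle: continuous (z,y,x) voxel position + ZYZ degrees."""

    position: tuple[float, float, float]
    angles: tuple[float, float, float]


@dataclass
class TomoPhantomSpec:
    """Conditions for one coat-bearing tomogram phantom.

    Geometry is in voxels for the grid and Å for physical lengths.  The
    membrane is a tube of radius ``tube_radius`` Å around a centerline that
    runs along z with an optional gentle lateral bow; coat particles sit at
    a radial offset inside the band ``[d_in, d_out]`` Å measured from the
    membrane surface, oriented with the template z axis along the outward
    normal plus a random spin.
    """

    shape: tuple[int, int, int] = (128, 128, 128)
    voxel_size: float = 10.0
    tube_radius: float = 300.0
    membrane_thickness: float = 50.0
    centerline_amplitude: float = 40.0  # Å lateral bow of the centerline
    d_in: float = 50.0
    d_out: float = 250.0
    n_particles: int = 50
    min_spacing: float = 120.0
    radial_jitter: float = 30.0  # Å around the mid-band placement radius
    noise_sigma: float = 0.3  # fraction of the template peak
    tilt_range: float = 60.0  # degrees, wedge is ±tilt_range
    tilt_increment: float = 2.0
    membrane_amplitude: float = 1.0
    rod_amplitude: float = 0.6
    with_axoneme: bool = True
    apply_wedge: bool = True
    z_margin: int = 12
    template: Volume3D | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.d_in < self.d_out):
            raise ValidationError(f"need 0 <= d_in < d_out, got {self.d_in}, {self.d_out}")
        if self.min_spacing <= 0:
            raise ValidationError("min_spacing must be > 0")
        if not (0.0 < self.tilt_range <= 90.0):
            raise ValidationError("tilt range must be in (0, 90] degrees")
        if self.template is None:
            self.template = default_template(self.voxel_size)

    def centerline_at(self, z: float) -> tuple[float, float]:
        """(y, x) voxel coordinates of the tube centerline at slice z."""
        nz, ny, nx = self.shape
        amp = self.centerline_amplitude / self.voxel_size
        y = (ny - 1) / 2.0 + amp * np.sin(2 * np.pi * z / max(nz, 1))
        x = (nx - 1) / 2.0 + amp * np.cos(2 * np.pi * z / max(nz, 1) + 1.0)
        return float(y), float(x)


def missing_wedge_mask(shape, tilt_range: float) -> np.ndarray:
    """Boolean Fourier-space mask of sampled coefficients for rfftn layout.

    The tilt axis is y: a tilt series covering ±``tilt_range`` degrees samples
    every spatial frequency whose direction in the (x, z) plane lies within
    ``tilt_range`` of the x axis.  The unsampled wedge is the complement;
    its fraction of Fourier space is ``(90 - tilt_range) / 90``.
    """
    nz, ny, nx = shape
    kz = np.fft.fftfreq(nz)[:, None, None]
    kx = np.fft.rfftfreq(nx)[None, None, :]
    angle = np.degrees(np.arctan2(np.abs(kz), np.abs(kx)))
    mask = angle <= tilt_range + 1e-9
    return np.broadcast_to(mask, (nz, ny, nx // 2 + 1)).copy()


def apply_missing_wedge(vol: Volume3D, tilt_range: float, increment: float = 2.0) -> Volume3D:
    """Zero all Fourier coefficients outside the sampled tilt wedge.

    Binary-mask wedge model (no CTF, no dose weighting): coefficients whose
    (x, z)-plane direction is further than ``tilt_range`` degrees from the x
    axis are set to zero.  Idempotent; ±90° is the identity.  ``increment``
    is accepted for provenance (the binary wedge depends only on the range).
    """
    if not (0.0 < tilt_range <= 90.0):
        raise ParameterError(f"tilt range must be in (0, 90], got {tilt_range}")
    if increment <= 0:
        raise ParameterError("tilt increment must be > 0")
    data = vol.data
    if data.ndim != 3:
        raise ParameterError("missing wedge needs a 3-D volume")
    if tilt_range >= 90.0:
        return vol.copy()
    spectrum = np.fft.rfftn(data)
    spectrum[~missing_wedge_mask(data.shape, tilt_range)] = 0.0
    out = np.fft.irfftn(spectrum, s=data.shape, axes=(0, 1, 2)).astype(np.float32)
    return Volume3D(out, vol.voxel_size, vol.origin)


def _place_particles(spec: TomoPhantomSpec, rng: np.random.Generator):
    nz, ny, nx = spec.shape
    vx = spec.voxel_size
    r_mem = spec.tube_radius / vx
    mid = (spec.d_in + spec.d_out) / 2.0
    jitter = min(spec.radial_jitter, (spec.d_out - spec.d_in) / 2.0 * 0.8)
    min_space_vox = spec.min_spacing / vx
    margin = spec.z_margin
    placed: list[GroundTruthParticle] = []
    positions: list[np.ndarray] = []
    max_tries = 200 * max(spec.n_particles, 1)
    tries = 0
    while len(placed) < spec.n_particles and tries < max_tries:
        tries += 1
        z = rng.uniform(margin, nz - 1 - margin)
        theta = rng.uniform(0, 2 * np.pi)
        r_off = (mid + rng.uniform(-jitter, jitter)) / vx
        cy, cx = spec.centerline_at(z)
        normal = np.array([np.cos(theta), np.sin(theta), 0.0])  # (x, y, z)
        y = cy + (r_mem + r_off) * normal[1]
        x = cx + (r_mem + r_off) * normal[0]
        if not (margin <= y <= ny - 1 - margin and margin <= x <= nx - 1 - margin):
            continue
        pos = np.array([z, y, x])
        if positions and np.min(np.linalg.norm(np.array(positions) - pos, axis=1)) < min_space_vox:
            continue
        spin = rng.uniform(0, 360.0)
        R = rotation_from_z_axis(normal, spin)
        angles = matrix_to_euler(R)
        placed.append(GroundTruthParticle(tuple(pos), angles))
        positions.append(pos)
    if len(placed) < spec.n_particles:
        raise ParameterError(
            f"could only place {len(placed)} of {spec.n_particles} particles "
            f"at min spacing {spec.min_spacing} Å"
        )
    return placed


def _render_membrane(spec: TomoPhantomSpec) -> np.ndarray:
    nz, ny, nx = spec.shape
    vx = spec.voxel_size
    r_mem = spec.tube_radius / vx
    sigma = spec.membrane_thickness / (2.0 * vx)
    yy, xx = np.indices((ny, nx), dtype=float)
    out = np.zeros(spec.shape, dtype=np.float32)
    for z in range(nz):
        cy, cx = spec.centerline_at(z)
        rho = np.hypot(yy - cy, xx - cx)
        out[z] = spec.membrane_amplitude * np.exp(-((rho - r_mem) ** 2) / (2 * sigma**2))
    return out


def _render_axoneme(spec: TomoPhantomSpec) -> np.ndarray:
    # nine parallel rods inside the tube; visual realism only
    nz, ny, nx = spec.shape
    vx = spec.voxel_size
    r_ring = 0.55 * spec.tube_radius / vx
    sigma = 25.0 / vx
    yy, xx = np.indices((ny, nx), dtype=float)
    out = np.zeros(spec.shape, dtype=np.float32)
    angles = np.linspace(0, 2 * np.pi, 9, endpoint=False)
    for z in range(nz):
        cy, cx = spec.centerline_at(z)
        plane = np.zeros((ny, nx))
        for a in angles:
            ry, rx = cy + r_ring * np.sin(a), cx + r_ring * np.cos(a)
            rho2 = (yy - ry) ** 2 + (xx - rx) ** 2
            plane += np.exp(-rho2 / (2 * sigma**2))
        out[z] = spec.rod_amplitude * plane
    return out


def _paste_template(canvas: np.ndarray, template: np.ndarray, particle: GroundTruthParticle):
    """Insert the rotated template at a continuous position.

    The subvoxel shift goes into the same interpolation pass as the rotation,
    so with zero noise the local density around a truth position equals
    ``rotate_volume(template, angles, shift=frac)`` exactly.
    """
    box = np.array(template.shape)
    pos = np.array(particle.position)
    base = np.round(pos).astype(int)
    frac = pos - base
    patch = rotate_volume(template, particle.angles, shift=tuple(frac))
    lo = base - box // 2
    hi = lo + box
    lo_c = np.maximum(lo, 0)
    hi_c = np.minimum(hi, canvas.shape)
    if np.any(lo_c >= hi_c):
        return
    sl_canvas = tuple(slice(a, b) for a, b in zip(lo_c, hi_c))
    sl_patch = tuple(slice(a - b, a - b + (d - c)) for a, b, c, d in zip(lo_c, lo, lo_c, hi_c))
    canvas[sl_canvas] += patch[sl_patch]


def simulate_tomogram(spec: TomoPhantomSpec):
    """Generate a coat-bearing tomogram phantom and its ground truth.

    Returns ``(Volume3D, list[GroundTruthParticle])``.  Deterministic in the
    spec (including its seed).
    """
    template = spec.template
    if any(t > s for t, s in zip(template.data.shape, spec.shape)):
        raise ParameterError("template does not fit inside the volume")
    rng = np.random.default_rng(spec.seed)
    particles = _place_particles(spec, rng)
    canvas = _render_membrane(spec)
    if spec.with_axoneme:
        canvas += _render_axoneme(spec)
    for p in particles:
        _paste_template(canvas, template.data, p)
    peak = float(template.data.max())
    if spec.noise_sigma > 0:
        canvas = canvas + rng.normal(
            0.0, spec.noise_sigma * peak, size=canvas.shape
        ).astype(np.float32)
    vol = Volume3D(canvas.astype(np.float32), spec.voxel_size)
    if spec.apply_wedge and spec.tilt_range < 90.0:
        vol = apply_missing_wedge(vol, spec.tilt_range, spec.tilt_increment)
    return vol, particles


def membrane_points(spec: TomoPhantomSpec, slices=None, n_points: int = 24, rng=None):
    """Sample truth membrane-surface points, as a stand-in for clicked points.

    Returns a list of ``(slice, y, x)`` rows covering each requested slice
    with ``n_points`` points on the membrane circle (optionally jittered by
    ``rng`` with ~0.5 px noise, emulating manual clicking).
    """
    nz = spec.shape[0]
    if slices is None:
        slices = range(0, nz, max(nz // 8, 1))
    r_mem = spec.tube_radius / spec.voxel_size
    rows = []
    for z in slices:
        cy, cx = spec.centerline_at(z)
        for theta in np.linspace(0, 2 * np.pi, n_points, endpoint=False):
            y = cy + r_mem * np.sin(theta)
            x = cx + r_mem * np.cos(theta)
            if rng is not None:
                y += rng.normal(0, 0.5)
                x += rng.normal(0, 0.5)
            rows.append((int(z), float(y), float(x)))
    return rows
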