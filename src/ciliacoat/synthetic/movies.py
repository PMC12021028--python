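"""Time-lapse phantoms: gliding spots and flow-driven cell detachment.

Gliding movies emulate TIRF recordings of fluorescently labelled IFT in
surface-adhered cells: Gaussian spots translating along the image x axis at
constant velocities on the ~1 µm/s scale, sampled at 10 fps.  Detachment
movies emulate bright(-er) cell disks on a microchannel surface that vanish
stochastically as a stepwise flow schedule ramps up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile

from ..errors import ValidationError
from ..flow import FlowSchedule

__all__ = [
    "ImageStack",
    "GlidingEventSpec",
    "CellDiskSpec",
    "MotilityPhantomSpec",
    "simulate_motility_movie",
    "simulate_detachment_movie",
]


@dataclass
class ImageStack:
    """A (frames, y, x) float stack with physical calibration."""

    data: np.ndarray
    pixel_size_um: float
    frame_interval_s: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValidationError("image stack must be (frames, y, x)")
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ValidationError("pixel size and frame interval must be > 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s

    def write_tiff(self, path):
        tifffile.imwrite(str(path), self.data, metadata={
            "pixel_size_um": self.pixel_size_um,
            "frame_interval_s": self.frame_interval_s,
        })
        return path


@dataclass
class GlidingEventSpec:
    """One moving spot: starts at (y0, x0) px, moves along +x."""

    start_frame: int
    duration_s: float
    velocity_um_s: float
    y0: float
    x0: float

    def __post_init__(self) -> None:
        if self.velocity_um_s < 0:
            raise ValidationError("velocities must be >= 0")


@dataclass
class CellDiskSpec:
    """One adherent cell for detachment movies."""

    y: float
    x: float
    radius_px: float
    step_probabilities: tuple[float, ...] = ()  # detachment prob per flow step
    detach_time_s: float | None = None  # deterministic override

    def __post_init__(self) -> None:
        for p in self.step_probabilities:
            if not (0.0 <= p <= 1.0):
                raise ValidationError("probabilities must be in [0, 1]")


@dataclass
class MotilityPhantomSpec:
    shape: tuple[int, int, int] = (300, 64, 256)  # frames, y, x
    frame_interval_s: float = 0.1  # 10 fps
    pixel_size_um: float = 0.1
    events: list[GlidingEventSpec] = field(default_factory=list)
    cells: list[CellDiskSpec] = field(default_factory=list)
    spot_sigma_px: float = 1.5
    background: float = 20.0
    foreground: float = 200.0
    noise_sigma: float = 0.0
    seed: int = 0


def _validate_events(spec: MotilityPhantomSpec) -> None:
    n_frames, ny, nx = spec.shape
    for ev in spec.events:
        if not (0 <= ev.start_frame < n_frames):
            raise ValidationError(f"event start frame {ev.start_frame} outside movie")
        end_x = ev.x0 + ev.velocity_um_s * ev.duration_s / spec.pixel_size_um
        if not (0 <= ev.x0 < nx and 0 <= end_x < nx and 0 <= ev.y0 < ny):
            raise ValidationError("event path leaves the field of view")


def simulate_motility_movie(spec: MotilityPhantomSpec):
    """Render gliding spots; returns ``(ImageStack, truth)``.

    Truth is a list of dicts with the exact velocity (µm/s) and path distance
    (µm) of each event.  Deterministic in the spec.
    """
    _validate_events(spec)
    n_frames, ny, nx = spec.shape
    rng = np.random.default_rng(spec.seed)
    yy, xx = np.indices((ny, nx), dtype=float)
    data = np.full(spec.shape, spec.background, dtype=np.float32)
    s2 = 2 * spec.spot_sigma_px**2
    for ev in spec.events:
        n_span = int(round(ev.duration_s / spec.frame_interval_s))
        for f in range(ev.start_frame, min(ev.start_frame + n_span + 1, n_frames)):
            t = (f - ev.start_frame) * spec.frame_interval_s
            x = ev.x0 + ev.velocity_um_s * t / spec.pixel_size_um
            data[f] += spec.foreground * np.exp(
                -((yy - ev.y0) ** 2 + (xx - x) ** 2) / s2
            )
    if spec.noise_sigma > 0:
        data += rng.normal(0, spec.noise_sigma, size=spec.shape).astype(np.float32)
    truth = [
        {
            "start_frame": ev.start_frame,
            "duration_s": ev.duration_s,
            "velocity_um_s": ev.velocity_um_s,
            "distance_um": ev.velocity_um_s * ev.duration_s,
        }
        for ev in spec.events
    ]
    return ImageStack(data, spec.pixel_size_um, spec.frame_interval_s), truth


def _draw_detach_frame(
    cell: CellDiskSpec, schedule: FlowSchedule, spec: MotilityPhantomSpec, rng
) -> int | None:
    """Frame index at which the cell disappears, or None if it stays."""
    n_frames = spec.shape[0]
    dt = spec.frame_interval_s
    if cell.detach_time_s is not None:
        f = int(round(cell.detach_time_s / dt))
        return f if f < n_frames else None
    starts = schedule.boundaries
    for i, (p, step) in enumerate(zip(cell.step_probabilities, schedule.steps)):
        if rng.random() < p:
            t0 = starts[i]
            dur = step.duration_s
            if np.isinf(dur):
                dur = max(n_frames * dt - t0, dt)
            t = rng.uniform(t0, t0 + dur)
            f = int(round(t / dt))
            return f if f < n_frames else None
    return None


def simulate_detachment_movie(spec: MotilityPhantomSpec, schedule: FlowSchedule):
    """Render adherent cell disks vanishing under a flow schedule.

    Each cell's detachment step is drawn from its per-step probabilities
    (aligned with the schedule), with a uniform frame within the step; a
    fixed ``detach_time_s`` overrides the draw.  Returns
    ``(ImageStack, truth)`` where truth holds the per-frame fraction of the
    initial cells remaining and the per-cell detach frames.
    """
    n_frames, ny, nx = spec.shape
    movie_duration = n_frames * spec.frame_interval_s
    if not schedule.covers(movie_duration):
        raise ValidationError("flow schedule does not cover the movie duration")
    if not spec.cells:
        raise ValidationError("detachment movie needs at least one cell disk")
    rng = np.random.default_rng(spec.seed)
    detach_frames = [
        _draw_detach_frame(cell, schedule, spec, rng) for cell in spec.cells
    ]
    yy, xx = np.indices((ny, nx), dtype=float)
    data = np.full(spec.shape, spec.background, dtype=np.float32)
    for cell, df in zip(spec.cells, detach_frames):
        disk = (yy - cell.y) ** 2 + (xx - cell.x) ** 2 <= cell.radius_px**2
        last = n_frames if df is None else df
        data[:last, disk] = spec.foreground
    if spec.noise_sigma > 0:
        data += rng.normal(0, spec.noise_sigma, size=spec.shape).astype(np.float32)
    remaining = np.empty(n_frames)
    n_cells = len(spec.cells)
    for f in range(n_frames):
        gone = sum(1 for df in detach_frames if df is not None and df <= f)
        remaining[f] = (n_cells - gone) / n_cells
    truth = {
        "times_s": np.arange(n_frames) * spec.frame_interval_s,
        "remaining_fraction": remaining,
        "detach_frames": detach_frames,
    }
    return ImageStack(data, spec.pixel_size_um, spec.frame_interval_s), truth
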