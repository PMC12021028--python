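"""Gliding-motility and flow-detachment quantification.

Gliding is read from kymographs: a line region of interest is resampled over
time into a (time x position) image, moving spots become slanted tracks, and
each track's velocity is the fitted slope scaled by pixel size and frame
interval.  Events with zero velocity are reported but flagged excluded,
matching the inclusion rule "all gliding events (velocity > 0 µm/s)".

Detachment is read from bright-field style movies: frames are binarized
(Otsu), the foreground area fraction is normalized to the first frame, and
replicate curves are compared group-wise with Student t tests at fixed
timepoints (50/100/150/200 s), reported as mean ± SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal
from skimage.filters import threshold_otsu

from .errors import ParameterError, ValidationError
from .flow import FlowSchedule
from .stats import TestResult, mann_whitney_u, student_t
from .synthetic.movies import ImageStack

__all__ = [
    "Kymograph",
    "build_kymograph",
    "GlidingEvent",
    "trace_events",
    "binarize_frames",
    "DetachmentCurve",
    "detachment_curve",
    "compare_curves",
    "mann_whitney_u",
    "student_t",
    "TestResult",
]

VELOCITY_EPS = 1e-6  # µm/s; "velocity > 0" inclusion rule, numerically


@dataclass
class Kymograph:
    """(time x position) intensity image sampled along a line ROI."""

    data: np.ndarray
    pixel_size_um: float
    frame_interval_s: float

    def __post_init__(self) -> None:
        if self.data.ndim != 2:
            raise ValidationError("kymograph must be 2-D (time x position)")


def build_kymograph(stack: ImageStack, roi_line, width: int = 1) -> Kymograph:
    """Sample a movie along a line ROI into a kymograph.

    ``roi_line`` is ``((y0, x0), (y1, x1))`` in pixels.  Intensities are
    sampled at unit spacing along the line (linear interpolation) and
    max-projected across ``width`` parallel offsets perpendicular to it —
    one kymograph row per frame.
    """
    if width < 1:
        raise ParameterError("width must be >= 1")
    (y0, x0), (y1, x1) = roi_line
    n_frames, ny, nx = stack.data.shape
    for y, x in ((y0, x0), (y1, x1)):
        if not (0 <= y <= ny - 1 and 0 <= x <= nx - 1):
            raise ParameterError(f"ROI endpoint ({y}, {x}) outside frame bounds")
    length = float(np.hypot(y1 - y0, x1 - x0))
    n_samples = int(np.floor(length)) + 1
    t = np.linspace(0.0, 1.0, n_samples)
    ys = y0 + t * (y1 - y0)
    xs = x0 + t * (x1 - x0)
    # unit normal for the width offsets
    if length > 0:
        nvec = np.array([-(x1 - x0), y1 - y0]) / length
    else:
        nvec = np.array([0.0, 0.0])
    offsets = (np.arange(width) - (width - 1) / 2.0)[:, None]
    sample_y = ys[None, :] + offsets * nvec[0]
    sample_x = xs[None, :] + offsets * nvec[1]
    rows = np.empty((n_frames, n_samples), dtype=np.float32)
    coords = np.stack([sample_y.ravel(), sample_x.ravel()])
    for f in range(n_frames):
        vals = ndimage.map_coordinates(
            stack.data[f], coords, order=1, mode="nearest"
        ).reshape(width, n_samples)
        rows[f] = vals.max(axis=0)
    return Kymograph(rows, stack.pixel_size_um, stack.frame_interval_s)


@dataclass
class GlidingEvent:
    """One tracked spot: velocity (µm/s) and distance (µm) from the fitted
    constant-velocity segment.  ``included`` follows the velocity > 0 rule."""

    start_frame: int
    end_frame: int
    velocity_um_s: float
    distance_um: float
    included: bool = field(init=False)

    def __post_init__(self) -> None:
        if self.velocity_um_s < 0:
            raise ValidationError("velocity must be >= 0")
        self.included = self.velocity_um_s > VELOCITY_EPS
        dur = (self.end_frame - self.start_frame)
        if dur < 0:
            raise ValidationError("event ends before it starts")


def trace_events(
    kymo: Kymograph,
    min_rel_height: float = 0.5,
    max_step_px: float = 8.0,
    min_frames: int = 5,
) -> list[GlidingEvent]:
    """Detect constant-velocity tracks in a kymograph.

    Per frame, peaks above ``min_rel_height`` of the kymograph's dynamic
    range are linked to the nearest peak of the previous frame within
    ``max_step_px``; tracks lasting >= ``min_frames`` are fitted with a
    least-squares line, whose |slope| gives the velocity.  The distance is
    |velocity| x duration, so the two are consistent by construction.
    Returns an empty list for a blank kymograph.
    """
    data = kymo.data
    lo, hi = float(data.min()), float(data.max())
    if hi - lo <= 1e-12:
        return []
    thresh = lo + min_rel_height * (hi - lo)
    tracks: list[list[tuple[int, float]]] = []
    open_tracks: list[list[tuple[int, float]]] = []
    for f in range(data.shape[0]):
        row = data[f]
        peaks, _ = signal.find_peaks(row, height=thresh)
        cols = [float(p) for p in peaks]
        # refine peak position by parabolic interpolation
        refined = []
        for p in peaks:
            if 0 < p < len(row) - 1:
                a, b, c = row[p - 1], row[p], row[p + 1]
                d = a - 2 * b + c
                refined.append(p + (0.5 * (a - c) / d if d < 0 else 0.0))
            else:
                refined.append(float(p))
        cols = refined
        still_open = []
        used = set()
        for tr in open_tracks:
            last_f, last_x = tr[-1]
            best, best_d = None, max_step_px
            for i, c in enumerate(cols):
                if i in used:
                    continue
                d = abs(c - last_x)
                if d <= best_d:
                    best, best_d = i, d
            if best is not None and f - last_f <= 2:
                tr.append((f, cols[best]))
                used.add(best)
                still_open.append(tr)
            elif f - last_f <= 2:
                still_open.append(tr)  # allow a short gap
            else:
                tracks.append(tr)
        for i, c in enumerate(cols):
            if i not in used:
                still_open.append([(f, c)])
        open_tracks = still_open
    tracks.extend(open_tracks)

    events = []
    for tr in tracks:
        if len(tr) < min_frames:
            continue
        f = np.array([p[0] for p in tr], dtype=float)
        x = np.array([p[1] for p in tr], dtype=float)
        slope, _ = np.polyfit(f, x, 1)  # px per frame
        velocity = abs(slope) * kymo.pixel_size_um / kymo.frame_interval_s
        duration_s = (f[-1] - f[0]) * kymo.frame_interval_s
        # stationarity floor: total fitted displacement under ~2 px is not a
        # resolvable motion; report it as a zero-velocity (excluded) event
        if duration_s > 0 and velocity < 2.0 * kymo.pixel_size_um / duration_s:
            velocity = 0.0
        events.append(
            GlidingEvent(
                start_frame=int(f[0]),
                end_frame=int(f[-1]),
                velocity_um_s=float(velocity),
                distance_um=float(velocity * duration_s),
            )
        )
    events.sort(key=lambda e: (e.start_frame, -e.velocity_um_s))
    return events


def binarize_frames(
    stack: ImageStack, polarity: str = "bright", min_separation: float = 4.0
) -> np.ndarray:
    """Per-frame Otsu binarization; foreground marks cells.

    ``polarity='bright'`` keeps pixels above the threshold (fluorescent or
    phase-bright cells), ``'dark'`` keeps pixels below it.  Degenerate frames
    are all background: constant frames (with a warning), and unimodal frames
    where the Otsu classes are separated by less than ``min_separation``
    pooled within-class standard deviations — splitting pure noise in half
    would otherwise report half the frame as cells.
    """
    if polarity not in ("bright", "dark"):
        raise ParameterError(f"polarity must be 'bright' or 'dark', got {polarity!r}")
    out = np.zeros(stack.data.shape, dtype=bool)
    for f in range(stack.data.shape[0]):
        frame = stack.data[f]
        if np.ptp(frame) <= 1e-12:
            warnings.warn(f"frame {f} is constant; treating as all background")
            continue
        t = threshold_otsu(frame)
        fg = frame > t if polarity == "bright" else frame < t
        lo, hi = frame[~fg], frame[fg]
        if lo.size and hi.size:
            pooled = np.sqrt((lo.var() + hi.var()) / 2.0)
            if abs(hi.mean() - lo.mean()) < min_separation * max(pooled, 1e-12):
                continue  # unimodal frame: no cells
        out[f] = fg
    return out


@dataclass
class DetachmentCurve:
    """Occupied-area fraction over time, normalized to the first frame."""

    times_s: np.ndarray
    values: np.ndarray
    replicate_id: str = ""
    flow_steps: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times_s.shape != self.values.shape:
            raise ValidationError("times and values must match")

    def value_at(self, t: float) -> float:
        """Curve value at time ``t`` (linear interpolation inside range)."""
        if t < self.times_s[0] - 1e-9 or t > self.times_s[-1] + 1e-9:
            raise ParameterError(f"timepoint {t} s outside curve range")
        return float(np.interp(t, self.times_s, self.values))


def detachment_curve(
    binary_stack: np.ndarray,
    schedule: FlowSchedule,
    frame_interval_s: float,
    replicate_id: str = "",
) -> DetachmentCurve:
    """Normalized occupancy per frame, annotated with the active flow step.

    Occupancy is the foreground-pixel fraction; values are normalized to
    frame 0 (an empty first frame is an error).
    """
    if binary_stack.ndim != 3:
        raise ParameterError("binary stack must be (frames, y, x)")
    occ = binary_stack.reshape(binary_stack.shape[0], -1).mean(axis=1)
    if occ[0] <= 0:
        raise ParameterError("frame 0 has zero occupancy; cannot normalize")
    times = np.arange(len(occ)) * frame_interval_s
    if not schedule.covers(times[-1]):
        raise ParameterError("flow schedule does not cover the movie")
    steps = np.array([schedule.step_at(t) for t in times])
    return DetachmentCurve(times, occ / occ[0], replicate_id, steps)


DEFAULT_TEST_TIMEPOINTS = (50.0, 100.0, 150.0, 200.0)


def compare_curves(
    group_a: list[DetachmentCurve],
    group_b: list[DetachmentCurve],
    timepoints=DEFAULT_TEST_TIMEPOINTS,
) -> list[dict]:
    """Student t tests between replicate groups at fixed timepoints.

    For each timepoint the replicate values of both groups are compared with
    an equal-variance two-sample t test (Welch alongside); group mean ± SD
    are reported for plotting as averaged detachment curves.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ParameterError("need >= 2 replicate curves per group")
    out = []
    for t in timepoints:
        va = np.array([c.value_at(t) for c in group_a])
        vb = np.array([c.value_at(t) for c in group_b])
        res = student_t(va, vb, equal_var=True)
        out.append(
            {
                "time_s": t,
                "test": res,
                "mean_a": float(va.mean()),
                "sd_a": float(va.std(ddof=1)),
                "mean_b": float(vb.mean()),
                "sd_b": float(vb.std(ddof=1)),
            }
        )
    return out
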