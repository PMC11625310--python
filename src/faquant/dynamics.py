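"""Time-lapse analysis: kymographs, adhesion lifetimes, migration metrics.

Lifetimes are "minimum lifetimes" in the censoring sense: an object whose
presence touches the first or last frame of the movie is flagged censored
and its recorded lifetime is the observed lower bound. The lifetime
convention is frames-present × frame interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .errors import ValidationError
from .imageops import ImageStack, MicroImage, otsu_threshold
from .profiles import extract_line_profile

__all__ = [
    "Kymograph",
    "LifetimeRecord",
    "Track",
    "MigrationMetrics",
    "build_kymograph",
    "presence_from_stack",
    "measure_lifetimes",
    "link_tracks",
    "migration_metrics",
]


@dataclass(frozen=True)
class Kymograph:
    """Space × time raster sampled along a line (rows = space, cols = time)."""

    data: np.ndarray
    space_step: float      # µm per row
    time_step: float       # s per column
    source_line: tuple[tuple[float, float], tuple[float, float]]

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class LifetimeRecord:
    object_id: int
    min_lifetime: float     # s, frames present × dt
    censored: bool
    censored_start: bool
    censored_end: bool
    formation_frame: int | None   # first frame, None when start-censored


@dataclass(frozen=True)
class Track:
    """One linked trajectory: frame indices and positions in µm."""

    frames: np.ndarray
    positions: np.ndarray   # (n, 2) µm
    dt: float               # s between consecutive frames

    def __post_init__(self):
        frames = np.asarray(self.frames, dtype=np.int64)
        pos = np.asarray(self.positions, dtype=np.float64)
        if frames.ndim != 1 or np.any(np.diff(frames) <= 0):
            raise ValidationError("frames must be strictly increasing")
        if pos.shape != (frames.size, 2):
            raise ValidationError("positions must be (n_frames, 2)")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "positions", pos)

    @property
    def duration(self) -> float:
        """Track duration in seconds."""
        return float((self.frames[-1] - self.frames[0]) * self.dt)


@dataclass(frozen=True)
class MigrationMetrics:
    speed: float             # µm/s, path length / duration
    persistence: float       # net displacement / path length, in [0, 1]
    forward_progress: float  # µm/s, net displacement / duration
    duration: float          # s


def build_kymograph(stack: ImageStack, p0, p1, width: int = 1) -> Kymograph:
    """Column t of the result is the width-averaged line profile of frame t."""
    if stack.n_frames < 2:
        raise ValidationError("kymograph needs a stack of >= 2 frames")
    columns = []
    for t in range(stack.n_frames):
        prof = extract_line_profile({"ch": stack.frame(t)}, p0, p1, width)
        columns.append(prof.intensities["ch"])
    data = np.column_stack(columns)
    return Kymograph(data=data, space_step=stack.pixel_size,
                     time_step=stack.frame_interval,
                     source_line=(tuple(p0), tuple(p1)))


def presence_from_stack(stack: ImageStack, threshold: float | None = None
                        ) -> np.ndarray:
    """Detect objects in a time-lapse and return presence (objects × frames).

    Frames are thresholded at a single fixed level derived from frame 0
    (Otsu, unless given), which avoids per-frame threshold flicker being
    read as turnover. Objects are identified as spatiotemporally connected
    components (adjacent frames linked through spatial overlap), so one
    physical adhesion blinking within the gap tolerance of
    :func:`measure_lifetimes` still counts as one object.
    """
    if threshold is None:
        threshold = otsu_threshold(stack.frame(0))
    binary = stack.data > threshold
    structure = np.ones((3, 3, 3), dtype=bool)
    labels, n = ndi.label(binary, structure=structure)
    presence = np.zeros((n, stack.n_frames), dtype=bool)
    for t in range(stack.n_frames):
        present = np.unique(labels[t])
        present = present[present > 0]
        presence[present - 1, t] = True
    return presence


def _runs(present: np.ndarray, gap_frames: int) -> list[tuple[int, int]]:
    """Contiguous presence runs, bridging interruptions of <= gap_frames."""
    idx = np.flatnonzero(present)
    if idx.size == 0:
        return []
    runs = []
    start = prev = idx[0]
    for i in idx[1:]:
        if i - prev - 1 <= gap_frames:
            prev = i
        else:
            runs.append((start, prev))
            start = prev = i
    runs.append((start, prev))
    return runs


def measure_lifetimes(presence: np.ndarray, dt: float, gap_frames: int = 1
                      ) -> tuple[list[LifetimeRecord], float]:
    """Minimum lifetimes and formation rate from a presence matrix.

    Parameters
    ----------
    presence : bool array, shape (n_objects, n_frames)
        True where an object is detected in a frame.
    dt : frame interval in seconds.
    gap_frames : interruptions of at most this many frames are bridged
        (blinking robustness); 0 for strict contiguity.

    Returns
    -------
    records : one :class:`LifetimeRecord` per presence run;
        ``min_lifetime`` = frames present × dt, with runs touching the
        movie start/end flagged censored.
    formation_rate : newly formed objects (first appearance after frame 0)
        per minute of observation.
    """
    presence = np.asarray(presence, dtype=bool)
    if presence.ndim != 2 or presence.shape[1] == 0:
        raise ValidationError("presence must be a non-empty (objects, frames) array")
    if dt <= 0:
        raise ValidationError("dt must be > 0")
    n_obj, n_frames = presence.shape
    records: list[LifetimeRecord] = []
    formations = 0
    for k in range(n_obj):
        for (a, b) in _runs(presence[k], gap_frames):
            cs = a == 0
            ce = b == n_frames - 1
            if not cs:
                formations += 1
            records.append(LifetimeRecord(
                object_id=k + 1,
                min_lifetime=(b - a + 1) * dt,
                censored=cs or ce,
                censored_start=cs,
                censored_end=ce,
                formation_frame=None if cs else a,
            ))
    duration_min = n_frames * dt / 60.0
    return records, formations / duration_min


def link_tracks(detections: list[np.ndarray], max_disp: float, dt: float = 1.0
                ) -> list[Track]:
    """Greedy nearest-neighbour frame-to-frame linking, no gap closing.

    ``detections`` is a list (one entry per frame) of (n, 2) position
    arrays in µm. Candidate links are taken in order of increasing
    distance and accepted while below ``max_disp``; unmatched detections
    start new tracks, unmatched tracks terminate.
    """
    if max_disp <= 0:
        raise ValidationError("max_disp must be > 0")
    active: list[tuple[list[int], list[np.ndarray]]] = []
    finished: list[tuple[list[int], list[np.ndarray]]] = []
    for t, pts in enumerate(detections):
        pts = np.asarray(pts, dtype=np.float64).reshape(-1, 2)
        assigned_tracks: set[int] = set()
        assigned_pts: set[int] = set()
        if active and pts.shape[0]:
            last = np.array([trk[1][-1] for trk in active])
            dist = np.linalg.norm(last[:, None, :] - pts[None, :, :], axis=2)
            order = np.dstack(np.unravel_index(np.argsort(dist, axis=None),
                                               dist.shape))[0]
            for i, j in order:
                if dist[i, j] > max_disp:
                    break
                if i in assigned_tracks or j in assigned_pts:
                    continue
                active[i][0].append(t)
                active[i][1].append(pts[j])
                assigned_tracks.add(i)
                assigned_pts.add(j)
        still_active = []
        for i, trk in enumerate(active):
            (still_active if i in assigned_tracks else finished).append(trk)
        active = still_active
        for j in range(pts.shape[0]):
            if j not in assigned_pts:
                active.append(([t], [pts[j]]))
    finished.extend(active)
    return [Track(frames=np.array(f), positions=np.array(p), dt=dt)
            for f, p in finished]


def migration_metrics(track: Track, min_duration_h: float = 8.0
                      ) -> MigrationMetrics | None:
    """Speed, persistence and forward progress of one track.

    Tracks observed for less than ``min_duration_h`` hours are excluded
    (returns None). Persistence is net displacement over path length,
    forward progress is net displacement per unit time.
    """
    if track.frames.size < 2:
        raise ValidationError("track must have >= 2 points")
    duration = track.duration
    if duration < min_duration_h * 3600.0:
        return None
    steps = np.diff(track.positions, axis=0)
    path = float(np.linalg.norm(steps, axis=1).sum())
    net = float(np.linalg.norm(track.positions[-1] - track.positions[0]))
    persistence = net / path if path > 0 else float("nan")
    return MigrationMetrics(
        speed=path / duration,
        persistence=persistence,
        forward_progress=net / duration,
        duration=duration,
    )
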