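"""Cross-adhesion line-scan intensity profiles.

Profiles are sampled by bilinear interpolation along a user-chosen
segment, min-max normalized per channel, aligned on the reference
channel's peak and averaged across scans; LOESS provides the smooth
display fit. This reproduces the classical "intensity across the
adhesion" plot showing where one marker sits relative to another.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .errors import DegenerateProfileError, ValidationError
from .imageops import MicroImage

__all__ = [
    "LineProfile",
    "extract_line_profile",
    "normalize_profile",
    "align_and_average",
    "loess_smooth",
]


@dataclass(frozen=True)
class LineProfile:
    """Intensity of one or more channels along a scan line.

    positions are in µm along the scan; intensities maps channel name to
    the sampled values.
    """

    positions: np.ndarray
    intensities: dict[str, np.ndarray]
    normalized: bool = False

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=np.float64)
        if pos.ndim != 1 or pos.size < 2:
            raise ValidationError("positions must be a 1D array of >= 2 samples")
        if np.any(np.diff(pos) <= 0):
            raise ValidationError("positions must be strictly increasing")
        for name, vals in self.intensities.items():
            if np.asarray(vals).shape != pos.shape:
                raise ValidationError(f"channel {name!r} length mismatch")
        object.__setattr__(self, "positions", pos)


def _check_inside(p, shape, name):
    if not (0 <= p[0] <= shape[0] - 1 and 0 <= p[1] <= shape[1] - 1):
        raise ValidationError(f"{name}={p} outside image of shape {shape}")


def extract_line_profile(
    channels: dict[str, MicroImage],
    p0: tuple[float, float],
    p1: tuple[float, float],
    width: int = 1,
) -> LineProfile:
    """Sample channels along p0→p1 (pixel coordinates, (row, col)).

    Samples are taken at unit-pixel spacing by bilinear interpolation;
    ``width`` (odd, >= 1) parallel lines offset perpendicular to the scan
    are averaged. Positions are reported in µm from p0.
    """
    if width < 1 or width % 2 == 0:
        raise ValidationError("width must be an odd integer >= 1")
    if not channels:
        raise ValidationError("no channels given")
    first = next(iter(channels.values()))
    shape = first.shape
    for img in channels.values():
        if img.shape != shape:
            raise ValidationError("channel geometries differ")
    _check_inside(p0, shape, "p0")
    _check_inside(p1, shape, "p1")

    p0 = np.asarray(p0, dtype=np.float64)
    p1 = np.asarray(p1, dtype=np.float64)
    length = float(np.hypot(*(p1 - p0)))
    if length == 0:
        raise ValidationError("p0 and p1 coincide")
    n = int(np.floor(length)) + 1
    ts = np.arange(n, dtype=np.float64)
    direction = (p1 - p0) / length
    normal = np.array([-direction[1], direction[0]])
    offsets = np.arange(width) - width // 2

    intensities = {}
    for name, img in channels.items():
        acc = np.zeros(n, dtype=np.float64)
        for o in offsets:
            pts = p0[None, :] + ts[:, None] * direction[None, :] + o * normal[None, :]
            acc += ndi.map_coordinates(np.asarray(img.data, np.float64),
                                       pts.T, order=1, mode="nearest")
        intensities[name] = acc / width
    positions = ts * first.pixel_size
    return LineProfile(positions=positions, intensities=intensities)


def normalize_profile(profile: LineProfile) -> LineProfile:
    """Min-max scale each channel to [0, 1]: (i − min) / (max − min)."""
    out = {}
    for name, vals in profile.intensities.items():
        vals = np.asarray(vals, dtype=np.float64)
        lo, hi = vals.min(), vals.max()
        if hi == lo:
            raise DegenerateProfileError(f"channel {name!r} is constant")
        out[name] = (vals - lo) / (hi - lo)
    return LineProfile(positions=profile.positions.copy(),
                       intensities=out, normalized=True)


def align_and_average(profiles: list[LineProfile], reference_channel: str
                      ) -> pd.DataFrame:
    """Peak-align normalized profiles and average pointwise.

    Each profile is shifted so the reference channel's maximum sits at
    position 0, all profiles are resampled onto a common grid (step =
    median sample spacing) spanning their shared support, and the
    pointwise mean and SD per channel are returned as a tidy frame with
    columns ``position``, ``<ch>_mean``, ``<ch>_sd``.
    """
    if not profiles:
        raise ValidationError("need at least one profile")
    channels = set(profiles[0].intensities)
    for p in profiles:
        if reference_channel not in p.intensities:
            raise ValidationError(f"reference channel {reference_channel!r} absent")
        if set(p.intensities) != channels:
            raise ValidationError("profiles carry different channel sets")
        if not p.normalized:
            raise ValidationError("profiles must be normalized before averaging")

    shifted = []
    for p in profiles:
        peak = p.positions[int(np.argmax(p.intensities[reference_channel]))]
        shifted.append((p.positions - peak, p.intensities))

    step = float(np.median(np.diff(profiles[0].positions)))
    lo = max(pos[0] for pos, _ in shifted)
    hi = min(pos[-1] for pos, _ in shifted)
    if hi <= lo:
        raise ValidationError("profiles share no common support after alignment")
    grid = np.arange(0.0, hi - lo + 0.5 * step, step) + lo
    # keep 0 on the grid when possible
    grid = grid - grid[np.argmin(np.abs(grid))]
    grid = grid[(grid >= lo) & (grid <= hi)]

    data = {"position": grid}
    for ch in sorted(channels):
        stack = np.vstack([np.interp(grid, pos, inten[ch]) for pos, inten in shifted])
        data[f"{ch}_mean"] = stack.mean(axis=0)
        data[f"{ch}_sd"] = stack.std(axis=0, ddof=0)
    return pd.DataFrame(data)


def loess_smooth(x, y, span: float = 0.75, degree: int = 2) -> np.ndarray:
    """Locally estimated scatterplot smoothing (LOESS).

    At each x the nearest ``ceil(span·n)`` points are fit by weighted
    polynomial regression (default local quadratics) with tricube weights
    and the fit is evaluated at that x.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1D arrays of equal length")
    if x.size < 5:
        raise ValidationError("loess_smooth needs at least 5 points")
    if not (0.0 < span <= 1.0):
        raise ValidationError("span must be in (0, 1]")
    n = x.size
    k = max(degree + 1, int(np.ceil(span * n)))
    k = min(k, n)
    out = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        idx = np.argsort(d, kind="stable")[:k]
        dmax = d[idx].max()
        if dmax == 0:
            out[i] = y[idx].mean()
            continue
        w = (1.0 - (d[idx] / dmax) ** 3) ** 3
        w = np.clip(w, 0.0, None)
        xs = x[idx] - x[i]           # center for conditioning
        design = np.vander(xs, degree + 1, increasing=True)
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(design * sw[:, None], y[idx] * sw, rcond=None)
        out[i] = coef[0]
    return out
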