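"""Seeded synthetic microscopy scenes with complete ground truth.

This module emulates the image material the analysis stages consume:

* TIRF-like focal-adhesion (FA) scenes — elongated plateau-profile ellipses
  with intra-object texture, split between a perinuclear (inner) and a
  peripheral (outer) cell compartment, with a tunable true per-object
  Pearson correlation between the two channels;
* filament fields for anisotropy scoring;
* time-lapses with objects appearing and disappearing at known frames;
* wide-field clearance scenes (bright fibronectin lawn with dark holes of
  exactly known pixel area, plus countable nuclei);
* 2D migration tracks under straight, random-walk or biased-walk models.

Everything is generated from a single :class:`numpy.random.Generator`
seeded by the caller, so identical parameters and seed give bit-identical
output.

Correlation construction
------------------------
Within each object the first channel's texture is a rank-uniformized
smooth random field scaled into a fixed intensity band; the second channel
is an exact sample-correlation mixture ``c·u + sqrt(1-c²)·w⊥`` of the
standardized first-channel texture ``u`` and an orthogonalized independent
field ``w⊥``. Because additive sensor noise of known σ attenuates the
pixel-wise sample correlation by a factor ``f² = s²/(s²+σ²)`` (``s`` the
within-object signal SD), the mixing coefficient is set to
``c = ρ / f²`` (clipped to [−1, 1]) so that the *expected measured*
correlation of the noisy channels equals the requested ρ. At the default
SNR of 10 this calibration is exact for every ρ in [−1, 1] up to ~0.92;
beyond that the clip makes the generator deliver the closest achievable
correlation (at SNR 10 the full grid {0, 0.3, 0.6, 0.9} is achievable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .errors import PlacementError, ValidationError
from .imageops import ImageStack, LabelMask, MicroImage

__all__ = [
    "SceneParams",
    "SyntheticScene",
    "FAEvent",
    "TruthEvent",
    "SyntheticTimelapse",
    "ClearanceScene",
    "generate_fa_scene",
    "generate_timelapse",
    "generate_clearance_scene",
    "generate_tracks",
    "generate_filament_scene",
    "make_cell_mask",
    "inner_region_mask",
]

# Dimensionless intensity band of the in-object signal, in units of the
# nominal amplitude. The lower edge sits well above half the band mean so
# a histogram threshold landing anywhere in the background/object gap
# keeps the whole object interior; the width gives the texture a
# within-object SD of ~0.32 amplitude, enough contrast to carry
# correlations up to ~0.9 through SNR-10 sensor noise.
_BAND_LO = 0.70
_BAND_HI = 1.80
_BAND_MID = 0.5 * (_BAND_LO + _BAND_HI)

_TEXTURE_SMOOTH_SIGMA = 1.2  # px; correlation length of in-object texture


@dataclass(frozen=True)
class SceneParams:
    """Parameters of a synthetic two-channel focal-adhesion scene.

    Attributes
    ----------
    image_shape : (rows, cols) in pixels.
    pixel_size : µm per pixel (default 0.11, a 100× TIRF-like sampling).
    n_objects_inner, n_objects_outer : object counts per compartment.
    area_range : (min, max) object area in µm².
    axis_ratio_range : (min, max) major/minor axis ratio.
    rho_inner, rho_outer : target per-object Pearson correlation in [−1, 1].
    snr : nominal object amplitude divided by the noise SD; may be ``inf``.
    background_level : constant background intensity.
    amplitude : nominal object intensity amplitude above background.
    region_fraction : edge-distance fraction defining the inner region
        (same rule as :func:`faquant.adhesions.partition_regions`).
    inner_offset_um : if set, the second channel's inner-compartment blobs
        are rendered displaced by this distance instead of colocalized,
        so the correlation inside the first-channel mask is ~0.
    poisson : if True, apply Poisson resampling of the clean intensities
        before adding Gaussian read noise.
    seed : RNG seed; same params + seed ⇒ bit-identical scene.
    """

    image_shape: tuple[int, int] = (400, 400)
    pixel_size: float = 0.11
    n_objects_inner: int = 6
    n_objects_outer: int = 6
    area_range: tuple[float, float] = (0.5, 4.0)
    axis_ratio_range: tuple[float, float] = (1.5, 4.0)
    rho_inner: float = 0.7
    rho_outer: float = 0.7
    snr: float = 10.0
    background_level: float = 100.0
    amplitude: float = 1000.0
    region_fraction: float = 0.5
    inner_offset_um: float | None = None
    poisson: bool = False
    seed: int = 0
    channel_names: tuple[str, str] = ("paxillin", "septin")

    def __post_init__(self):
        if not (-1.0 <= self.rho_inner <= 1.0 and -1.0 <= self.rho_outer <= 1.0):
            raise ValidationError("rho values must lie in [-1, 1]")
        if not self.snr > 0:
            raise ValidationError("snr must be > 0")
        if not self.area_range[0] < self.area_range[1]:
            raise ValidationError("area_range must satisfy min < max")
        if self.axis_ratio_range[0] < 1.0:
            raise ValidationError("axis ratios must be >= 1")
        if self.n_objects_inner < 0 or self.n_objects_outer < 0:
            raise ValidationError("object counts must be >= 0")
        if self.pixel_size <= 0:
            raise ValidationError("pixel_size must be > 0")
        if not (0.0 <= self.region_fraction <= 1.0):
            raise ValidationError("region_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticScene:
    """A generated scene plus its complete ground truth."""

    channels: dict[str, MicroImage]
    truth_labels: LabelMask
    truth_inner: np.ndarray
    truth_outer: np.ndarray
    cell_mask: np.ndarray
    truth_rho: dict[int, float]
    truth_areas: dict[int, float]       # µm², rasterized pixel count × px area
    truth_regions: dict[int, str]       # "inner" | "outer"
    truth_centroids: dict[int, tuple[float, float]]
    params: SceneParams


def make_cell_mask(shape: tuple[int, int], radius_frac: float = 0.45) -> np.ndarray:
    """Centered disk cell mask with radius = radius_frac × min(shape)."""
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    r0, c0 = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    radius = radius_frac * min(shape)
    return (rr - r0) ** 2 + (cc - c0) ** 2 <= radius ** 2


def inner_region_mask(cell_mask: np.ndarray, fraction: float) -> np.ndarray:
    """Inner region: pixels whose distance to the cell edge is at least
    ``fraction`` of the maximum such distance. Mirrors the analysis-side
    partition rule so generated compartments and recovered compartments
    agree by construction."""
    edt = ndi.distance_transform_edt(cell_mask)
    return cell_mask & (edt >= fraction * edt.max())


def _ellipse_coverage(center, semi_major, semi_minor, theta, shape, subsamples=4):
    """Pixel coordinates overlapping a rotated ellipse with coverage fractions.

    Coverage is estimated on a ``subsamples × subsamples`` subgrid per
    pixel. Returns (rows, cols, coverage) for pixels with coverage > 0.
    Pixels with coverage >= 0.5 form the object core (the ground-truth
    mask); partially covered rim pixels give the rendered object a
    subpixel-smooth edge so that thresholding recovers the core area
    without a systematic bias.
    """
    r0, c0 = center
    extent = int(math.ceil(semi_major)) + 2
    rmin, rmax = int(r0) - extent, int(r0) + extent
    cmin, cmax = int(c0) - extent, int(c0) + extent
    rmin, cmin = max(rmin, 0), max(cmin, 0)
    rmax, cmax = min(rmax, shape[0] - 1), min(cmax, shape[1] - 1)
    if rmin > rmax or cmin > cmax:
        empty = np.empty(0)
        return empty.astype(int), empty.astype(int), empty
    rr, cc = np.mgrid[rmin : rmax + 1, cmin : cmax + 1]
    offs = (np.arange(subsamples) + 0.5) / subsamples - 0.5
    cov = np.zeros(rr.shape, dtype=np.float64)
    ct, st = math.cos(theta), math.sin(theta)
    for dr in offs:
        for dc in offs:
            drr, dcc = rr + dr - r0, cc + dc - c0
            u = dcc * ct + drr * st
            v = -dcc * st + drr * ct
            cov += (u / semi_major) ** 2 + (v / semi_minor) ** 2 <= 1.0
    cov /= subsamples ** 2
    keep = cov > 0
    return rr[keep], cc[keep], cov[keep]


def _ellipse_pixels(center, semi_major, semi_minor, theta, shape):
    """Integer pixel coordinates strictly inside a rotated ellipse."""
    r0, c0 = center
    extent = int(math.ceil(semi_major)) + 1
    rmin, rmax = int(r0) - extent, int(r0) + extent
    cmin, cmax = int(c0) - extent, int(c0) + extent
    rmin, cmin = max(rmin, 0), max(cmin, 0)
    rmax, cmax = min(rmax, shape[0] - 1), min(cmax, shape[1] - 1)
    if rmin > rmax or cmin > cmax:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    rr, cc = np.mgrid[rmin : rmax + 1, cmin : cmax + 1]
    dr, dc = rr - r0, cc - c0
    u = dc * math.cos(theta) + dr * math.sin(theta)
    v = -dc * math.sin(theta) + dr * math.cos(theta)
    inside = (u / semi_major) ** 2 + (v / semi_minor) ** 2 <= 1.0
    return rr[inside], cc[inside]


def _rank_uniform(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Map a sample to an exact uniform grid on (0,1) by rank; ties are
    broken by a random permutation so the output is always a permutation
    of (i+0.5)/n."""
    n = values.size
    perm = rng.permutation(n)
    order = np.argsort(values[perm], kind="stable")
    ranks = np.empty(n, dtype=np.int64)
    ranks[perm[order]] = np.arange(n)
    return (ranks + 0.5) / n


def _standardize(x: np.ndarray) -> np.ndarray:
    s = x.std()
    if s == 0:
        raise ValidationError("cannot standardize a constant sample")
    return (x - x.mean()) / s


def _correlated_texture(u: np.ndarray, w_raw: np.ndarray, c: float) -> np.ndarray:
    """Unit-variance sample with exact sample correlation ``c`` to ``u``.

    ``w_raw`` is orthogonalized against ``u`` (Gram–Schmidt on the sample)
    and re-standardized, so corr(u, result) equals ``c`` to float precision.
    """
    if abs(c) >= 1.0:
        return math.copysign(1.0, c) * u
    w = w_raw - w_raw.mean()
    w = w - (w @ u) / (u @ u) * u
    s = w.std()
    if s == 0:  # pathological tiny object; fall back to pure u
        return u.copy()
    w /= s
    return c * u + math.sqrt(1.0 - c * c) * w


def _place_objects(rng, n_inner, n_outer, params, inner_mask, outer_mask,
                   max_attempts=10_000):
    """Rejection-sample non-overlapping ellipses confined to their region.

    Returns a list of dicts with keys region, pixels, center, area_px.
    """
    shape = params.image_shape
    px_area = params.pixel_size ** 2
    occupied = np.zeros(shape, dtype=bool)
    spacing = ndi.generate_binary_structure(2, 2)
    objects = []
    todo = [("inner", inner_mask)] * n_inner + [("outer", outer_mask)] * n_outer
    for region_name, region_mask in todo:
        region_idx = np.flatnonzero(region_mask)
        if region_idx.size == 0:
            raise PlacementError(f"{region_name} region is empty at these parameters")
        placed = False
        for _ in range(max_attempts):
            area_um = rng.uniform(*params.area_range)
            ratio = rng.uniform(*params.axis_ratio_range)
            theta = rng.uniform(0, math.pi)
            area_px = area_um / px_area
            semi_major = math.sqrt(area_px * ratio / math.pi)
            semi_minor = semi_major / ratio
            flat = region_idx[rng.integers(region_idx.size)]
            center = np.unravel_index(flat, shape)
            rr, cc, cov = _ellipse_coverage(center, semi_major, semi_minor,
                                            theta, shape)
            core = cov >= 0.5
            if core.sum() < 8:
                continue
            if not region_mask[rr, cc].all():
                continue
            if occupied[rr, cc].any():
                continue
            blob = np.zeros(shape, dtype=bool)
            blob[rr, cc] = True
            # reserve a 2-px halo so neighbouring objects never merge
            occupied |= ndi.binary_dilation(blob, structure=spacing, iterations=2)
            objects.append(
                dict(region=region_name, rows=rr[core], cols=cc[core],
                     rim_rows=rr[~core], rim_cols=cc[~core], rim_cov=cov[~core],
                     center=center, area_px=int(core.sum()))
            )
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place a {region_name} object after {max_attempts} "
                "attempts; reduce object count or size"
            )
    return objects


def generate_fa_scene(params: SceneParams) -> SyntheticScene:
    """Generate a two-channel FA scene with known per-object correlation.

    See the module docstring for the correlation construction. The first
    channel plays the role of the segmentation channel (paxillin); the
    second carries the correlated partner signal (septin).
    """
    rng = np.random.default_rng(params.seed)
    shape = params.image_shape
    px_area = params.pixel_size ** 2

    cell = make_cell_mask(shape)
    inner = inner_region_mask(cell, params.region_fraction)
    outer = cell & ~inner

    objects = _place_objects(rng, params.n_objects_inner, params.n_objects_outer,
                             params, inner, outer)

    chan_a = np.full(shape, params.background_level, dtype=np.float64)
    chan_b = np.full(shape, params.background_level, dtype=np.float64)
    labels = np.zeros(shape, dtype=np.int32)

    # smooth fields supplying texture ranks / independent components
    field_a = ndi.gaussian_filter(rng.standard_normal(shape), _TEXTURE_SMOOTH_SIGMA)
    field_w = ndi.gaussian_filter(rng.standard_normal(shape), _TEXTURE_SMOOTH_SIGMA)

    sigma_noise = 0.0 if np.isinf(params.snr) else params.amplitude / params.snr

    truth_rho, truth_areas, truth_regions, truth_centroids = {}, {}, {}, {}
    for k, obj in enumerate(objects, start=1):
        rr, cc = obj["rows"], obj["cols"]
        n = rr.size
        labels[rr, cc] = k
        rho = params.rho_inner if obj["region"] == "inner" else params.rho_outer
        offset_mode = (obj["region"] == "inner"
                       and params.inner_offset_um is not None)

        t = _rank_uniform(field_a[rr, cc], rng)
        a_vals = params.amplitude * (_BAND_LO + (_BAND_HI - _BAND_LO) * t)
        chan_a[rr, cc] += a_vals
        s = a_vals.std()

        # subpixel-smooth rim outside the ground-truth core
        rim_r, rim_c = obj["rim_rows"], obj["rim_cols"]
        rim_vals = params.amplitude * _BAND_MID * obj["rim_cov"]
        chan_a[rim_r, rim_c] += rim_vals

        if offset_mode:
            # septin rendered as a displaced blob: inside the paxillin mask
            # the second channel is background + noise only
            shift_px = params.inner_offset_um / params.pixel_size
            ang = rng.uniform(0, 2 * math.pi)
            dr = int(round(shift_px * math.sin(ang)))
            dc = int(round(shift_px * math.cos(ang)))
            rs, cs = rr + dr, cc + dc
            keep = (rs >= 0) & (rs < shape[0]) & (cs >= 0) & (cs < shape[1])
            chan_b[rs[keep], cs[keep]] += a_vals[keep]
            rs, cs = rim_r + dr, rim_c + dc
            keep = (rs >= 0) & (rs < shape[0]) & (cs >= 0) & (cs < shape[1])
            chan_b[rs[keep], cs[keep]] += rim_vals[keep]
            truth_rho[k] = 0.0
        else:
            if sigma_noise > 0:
                f2 = s * s / (s * s + sigma_noise * sigma_noise)
            else:
                f2 = 1.0
            c = float(np.clip(rho / f2, -1.0, 1.0))
            u = _standardize(a_vals)
            z = _correlated_texture(u, field_w[rr, cc], c)
            chan_b[rr, cc] += params.amplitude * _BAND_MID + s * z
            chan_b[rim_r, rim_c] += rim_vals
            truth_rho[k] = rho

        truth_areas[k] = n * px_area
        truth_regions[k] = obj["region"]
        truth_centroids[k] = (float(rr.mean()), float(cc.mean()))

    for chan in (chan_a, chan_b):
        if params.poisson:
            chan[:] = rng.poisson(np.clip(chan, 0, None)).astype(np.float64)
        if sigma_noise > 0:
            chan += rng.normal(0.0, sigma_noise, size=shape)
        np.clip(chan, 0.0, None, out=chan)

    name_a, name_b = params.channel_names
    channels = {
        name_a: MicroImage(chan_a, params.pixel_size, name_a),
        name_b: MicroImage(chan_b, params.pixel_size, name_b),
    }
    return SyntheticScene(
        channels=channels,
        truth_labels=LabelMask(labels, params.pixel_size),
        truth_inner=inner,
        truth_outer=outer,
        cell_mask=cell,
        truth_rho=truth_rho,
        truth_areas=truth_areas,
        truth_regions=truth_regions,
        truth_centroids=truth_centroids,
        params=params,
    )


# ---------------------------------------------------------------------------
# time-lapse generation

@dataclass(frozen=True)
class FAEvent:
    """Specification of one object in a synthetic time-lapse."""

    appear_frame: int
    disappear_frame: int
    position: tuple[float, float]   # (row, col) pixels
    area_um2: float = 1.0
    axis_ratio: float = 2.0
    angle: float = 0.0              # radians

    def __post_init__(self):
        if self.appear_frame > self.disappear_frame:
            raise ValidationError("appear_frame must be <= disappear_frame")


@dataclass(frozen=True)
class TruthEvent:
    object_id: int
    first_frame: int
    last_frame: int
    censored_start: bool
    censored_end: bool
    lifetime_s: float               # frames present × dt


@dataclass(frozen=True)
class SyntheticTimelapse:
    stack: ImageStack
    truth_labels: np.ndarray        # (t, r, c) int
    truth_events: list[TruthEvent]
    truth_tracks: dict[int, list[tuple[int, tuple[float, float]]]]


def generate_timelapse(
    events_spec: list[FAEvent],
    n_frames: int,
    dt: float,
    image_shape: tuple[int, int] = (128, 128),
    pixel_size: float = 0.11,
    background_level: float = 100.0,
    amplitude: float = 1000.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> SyntheticTimelapse:
    """Render objects present exactly during [appear, disappear] frames.

    Lifetime convention: lifetime = number of frames present × dt. An
    event is start-censored iff it is present in frame 0 and end-censored
    iff present in the last frame.
    """
    if dt <= 0:
        raise ValidationError("dt must be > 0")
    if n_frames < 1:
        raise ValidationError("n_frames must be >= 1")
    for ev in events_spec:
        if ev.appear_frame < 0 or ev.disappear_frame >= n_frames:
            raise ValidationError(
                f"event frames [{ev.appear_frame}, {ev.disappear_frame}] "
                f"outside stack range [0, {n_frames - 1}]"
            )

    rng = np.random.default_rng(seed)
    px_area = pixel_size ** 2
    data = np.full((n_frames,) + tuple(image_shape), background_level, np.float64)
    labels = np.zeros((n_frames,) + tuple(image_shape), dtype=np.int32)
    events, tracks = [], {}
    for k, ev in enumerate(events_spec, start=1):
        area_px = ev.area_um2 / px_area
        semi_major = math.sqrt(area_px * ev.axis_ratio / math.pi)
        semi_minor = semi_major / ev.axis_ratio
        rr, cc = _ellipse_pixels(ev.position, semi_major, semi_minor,
                                 ev.angle, image_shape)
        if rr.size == 0:
            raise ValidationError(f"event {k} renders no pixels inside the image")
        frames = range(ev.appear_frame, ev.disappear_frame + 1)
        for t in frames:
            data[t, rr, cc] = background_level + amplitude
            labels[t, rr, cc] = k
        centroid = (float(rr.mean()), float(cc.mean()))
        tracks[k] = [(t, centroid) for t in frames]
        events.append(TruthEvent(
            object_id=k,
            first_frame=ev.appear_frame,
            last_frame=ev.disappear_frame,
            censored_start=ev.appear_frame == 0,
            censored_end=ev.disappear_frame == n_frames - 1,
            lifetime_s=(ev.disappear_frame - ev.appear_frame + 1) * dt,
        ))
    if noise_sigma > 0:
        data += rng.normal(0.0, noise_sigma, size=data.shape)
        np.clip(data, 0.0, None, out=data)
    stack = ImageStack(data, pixel_size, frame_interval=dt, channel_name="paxillin")
    return SyntheticTimelapse(stack=stack, truth_labels=labels,
                              truth_events=events, truth_tracks=tracks)


# ---------------------------------------------------------------------------
# clearance scenes

@dataclass(frozen=True)
class ClearanceScene:
    """Wide-field fibronectin lawn with dark holes plus countable nuclei."""

    channels: dict[str, MicroImage]
    hole_mask: np.ndarray
    truth_cleared_px: int
    truth_cleared_area_um2: float
    truth_n_cells: int
    truth_clearance_per_cell_um2: float


def generate_clearance_scene(
    holes: list[tuple[int, int, int, int]],
    n_cells: int,
    image_shape: tuple[int, int] = (300, 300),
    pixel_size: float = 0.325,
    field_level: float = 1000.0,
    hole_level: float = 0.0,
    cell_radius_px: int = 6,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> ClearanceScene:
    """Fibronectin channel = bright lawn with rectangular dark holes.

    ``holes`` is a list of (row0, col0, height, width) rectangles, so the
    cleared pixel area is known exactly by construction. The nuclei
    channel contains ``n_cells`` disjoint bright discs.
    """
    if n_cells < 0:
        raise ValidationError("n_cells must be >= 0")
    rng = np.random.default_rng(seed)
    shape = tuple(image_shape)
    fn = np.full(shape, field_level, dtype=np.float64)
    hole_mask = np.zeros(shape, dtype=bool)
    for (r0, c0, h, w) in holes:
        if r0 < 0 or c0 < 0 or r0 + h > shape[0] or c0 + w > shape[1] or h <= 0 or w <= 0:
            raise ValidationError(f"hole ({r0},{c0},{h},{w}) outside image {shape}")
        hole_mask[r0 : r0 + h, c0 : c0 + w] = True
    if hole_mask.sum() > 0.9 * hole_mask.size:
        raise ValidationError("holes cover nearly the whole image")
    fn[hole_mask] = hole_level

    nuclei = np.zeros(shape, dtype=np.float64)
    placed = 0
    occupied = np.zeros(shape, dtype=bool)
    attempts = 0
    while placed < n_cells:
        attempts += 1
        if attempts > 10_000:
            raise PlacementError("could not place the requested nuclei")
        r = rng.integers(cell_radius_px + 1, shape[0] - cell_radius_px - 1)
        c = rng.integers(cell_radius_px + 1, shape[1] - cell_radius_px - 1)
        rr, cc = _ellipse_pixels((r, c), cell_radius_px, cell_radius_px, 0.0, shape)
        if occupied[rr, cc].any():
            continue
        nuclei[rr, cc] = field_level
        blob = np.zeros(shape, dtype=bool)
        blob[rr, cc] = True
        occupied |= ndi.binary_dilation(blob, iterations=3)
        placed += 1

    if noise_sigma > 0:
        fn += rng.normal(0.0, noise_sigma, size=shape)
        nuclei += rng.normal(0.0, noise_sigma, size=shape)
        np.clip(fn, 0.0, None, out=fn)
        np.clip(nuclei, 0.0, None, out=nuclei)

    cleared_px = int(hole_mask.sum())
    cleared_um2 = cleared_px * pixel_size ** 2
    per_cell = cleared_um2 / n_cells if n_cells > 0 else float("nan")
    return ClearanceScene(
        channels={
            "fibronectin": MicroImage(fn, pixel_size, "fibronectin"),
            "nuclei": MicroImage(nuclei, pixel_size, "nuclei"),
        },
        hole_mask=hole_mask,
        truth_cleared_px=cleared_px,
        truth_cleared_area_um2=cleared_um2,
        truth_n_cells=n_cells,
        truth_clearance_per_cell_um2=per_cell,
    )


# ---------------------------------------------------------------------------
# migration tracks

def generate_tracks(
    n_tracks: int,
    n_frames: int,
    dt: float,
    step_model: str = "random_walk",
    step_um: float = 1.0,
    bias_angle: float = 0.0,
    bias_strength: float = 2.0,
    detection_noise_um: float = 0.0,
    field_um: float = 500.0,
    seed: int = 0,
):
    """Simulate 2D migration tracks and the per-frame detections they imply.

    step_model:
        ``straight`` — constant step along a per-track random heading;
        ``random_walk`` — i.i.d. uniform heading each frame;
        ``biased_walk`` — von Mises headings concentrated around bias_angle.

    Returns
    -------
    tracks : list of (n_frames, 2) float arrays, positions in µm
    detections : list (length n_frames) of (n_tracks, 2) arrays
    """
    if step_model not in ("straight", "random_walk", "biased_walk"):
        raise ValidationError(f"unknown step_model {step_model!r}")
    if dt <= 0:
        raise ValidationError("dt must be > 0")
    rng = np.random.default_rng(seed)
    tracks = []
    for _ in range(n_tracks):
        start = rng.uniform(0.2 * field_um, 0.8 * field_um, size=2)
        if step_model == "straight":
            heading = np.full(n_frames - 1, rng.uniform(0, 2 * math.pi))
        elif step_model == "random_walk":
            heading = rng.uniform(0, 2 * math.pi, size=n_frames - 1)
        else:
            heading = rng.vonmises(bias_angle, bias_strength, size=n_frames - 1)
        steps = step_um * np.column_stack([np.cos(heading), np.sin(heading)])
        pos = np.vstack([start, start + np.cumsum(steps, axis=0)])
        tracks.append(pos)
    detections = []
    for t in range(n_frames):
        if n_tracks == 0:
            detections.append(np.empty((0, 2)))
            continue
        pts = np.array([trk[t] for trk in tracks])
        if detection_noise_um > 0:
            pts = pts + rng.normal(0, detection_noise_um, size=pts.shape)
        detections.append(pts)
    return tracks, detections


# ---------------------------------------------------------------------------
# filament fields for anisotropy

def generate_filament_scene(
    image_shape: tuple[int, int] = (256, 256),
    n_filaments: int = 60,
    orientation: float = 0.0,
    angle_jitter: float = 0.05,
    aligned_fraction: float = 1.0,
    pixel_size: float = 0.11,
    seed: int = 0,
) -> MicroImage:
    """Bundle-like filament field mixed with isotropic noise.

    Filaments are long straight segments at ``orientation`` ± von Mises
    jitter, blurred to ~2 px width. ``aligned_fraction`` linearly mixes
    the (standardized) filament image with standardized white noise:
    1.0 → pure aligned filaments, 0.0 → pure isotropic noise.
    """
    if not (0.0 <= aligned_fraction <= 1.0):
        raise ValidationError("aligned_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    shape = tuple(image_shape)
    fil = np.zeros(shape, dtype=np.float64)
    diag = math.hypot(*shape)
    for _ in range(n_filaments):
        ang = orientation + rng.vonmises(0.0, 1.0 / max(angle_jitter, 1e-6) ** 2) \
            if angle_jitter > 0 else orientation
        r0 = rng.uniform(0, shape[0])
        c0 = rng.uniform(0, shape[1])
        length = rng.uniform(0.3, 0.9) * diag
        ts = np.arange(-length / 2, length / 2, 0.5)
        rr = np.round(r0 + ts * math.sin(ang)).astype(int)
        cc = np.round(c0 + ts * math.cos(ang)).astype(int)
        keep = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
        fil[rr[keep], cc[keep]] += 1.0
    fil = ndi.gaussian_filter(fil, 1.0)
    if fil.std() > 0:
        fil = (fil - fil.mean()) / fil.std()
    noise = rng.standard_normal(shape)
    noise = (noise - noise.mean()) / noise.std()
    img = aligned_fraction * fil + (1.0 - aligned_fraction) * noise
    img = img - img.min()
    return MicroImage(img, pixel_size, "septin")
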