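"""TIFF / JSON round-tripping for scenes, stacks and ground truth."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .imageops import ImageStack, MicroImage
from .synthetic import SyntheticScene, SyntheticTimelapse

__all__ = [
    "read_image",
    "write_image",
    "write_stack",
    "read_stack",
    "write_scene",
    "write_timelapse",
]


def read_image(path, pixel_size: float, channel_name: str = "") -> MicroImage:
    data = tifffile.imread(str(path))
    return MicroImage(np.asarray(data), pixel_size, channel_name)


def write_image(img: MicroImage, path) -> None:
    tifffile.imwrite(str(path), np.asarray(img.data, dtype=np.float32))


def write_stack(stack: ImageStack, path) -> None:
    tifffile.imwrite(str(path), np.asarray(stack.data, dtype=np.float32))


def read_stack(path, pixel_size: float, frame_interval: float,
               channel_name: str = "") -> ImageStack:
    data = tifffile.imread(str(path))
    return ImageStack(np.asarray(data), pixel_size, frame_interval, channel_name)


def write_scene(scene: SyntheticScene, outdir) -> None:
    """Write one TIFF per channel, the truth label TIFF, and a truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, img in scene.channels.items():
        write_image(img, outdir / f"{name}.tif")
    tifffile.imwrite(str(outdir / "truth_labels.tif"),
                     scene.truth_labels.labels.astype(np.uint16))
    tifffile.imwrite(str(outdir / "truth_inner.tif"),
                     scene.truth_inner.astype(np.uint8))
    tifffile.imwrite(str(outdir / "truth_outer.tif"),
                     scene.truth_outer.astype(np.uint8))
    tifffile.imwrite(str(outdir / "cell_mask.tif"),
                     scene.cell_mask.astype(np.uint8))
    truth = {
        "pixel_size_um": scene.params.pixel_size,
        "rho": {str(k): v for k, v in scene.truth_rho.items()},
        "areas_um2": {str(k): v for k, v in scene.truth_areas.items()},
        "regions": {str(k): v for k, v in scene.truth_regions.items()},
        "centroids": {str(k): list(v) for k, v in scene.truth_centroids.items()},
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2))


def write_timelapse(tl: SyntheticTimelapse, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_stack(tl.stack, outdir / "stack.tif")
    tifffile.imwrite(str(outdir / "truth_labels.tif"),
                     tl.truth_labels.astype(np.uint16))
    truth = {
        "dt_s": tl.stack.frame_interval,
        "events": [
            {
                "object_id": ev.object_id,
                "first_frame": ev.first_frame,
                "last_frame": ev.last_frame,
                "censored_start": ev.censored_start,
                "censored_end": ev.censored_end,
                "lifetime_s": ev.lifetime_s,
            }
            for ev in tl.truth_events
        ],
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2))
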