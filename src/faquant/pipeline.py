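"""End-to-end scene analysis: segmentation → regions → colocalization.

This is the high-level entry the CLI and batch scripts use; everything it
does is composed from the lower-level modules.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .adhesions import (FAObject, MorphologyConfig, classify_region,
                        objects_to_frame, partition_regions,
                        pearson_per_object, segment_fas)
from .errors import UnassignedRegionError
from .imageops import MicroImage

__all__ = ["analyze_scene"]


def analyze_scene(
    channels: dict[str, MicroImage],
    segmentation_channel: str,
    cfg: MorphologyConfig = MorphologyConfig(),
    cell_mask: np.ndarray | None = None,
    region_fraction: float = 0.5,
) -> pd.DataFrame:
    """Segment on one channel, measure all channels, classify regions.

    The segmentation channel's mask is used to extract per-object data in
    every other channel; Pearson r is computed for each (segmentation,
    other) channel pair over the object's pixels. When no cell mask is
    given, one is approximated as the convex hull of the channels' Otsu
    foregrounds — a coarse stand-in; real workflows should pass the
    measured cell mask.

    Returns the tidy per-object table from :func:`objects_to_frame`.
    """
    seg_img = channels[segmentation_channel]
    labels, objects = segment_fas(seg_img, cfg)

    if cell_mask is None:
        from .imageops import otsu_threshold
        fg = np.zeros(seg_img.shape, dtype=bool)
        for img in channels.values():
            fg |= img.data > otsu_threshold(img)
        from skimage.morphology import convex_hull_image
        fg = ndi.binary_closing(fg, iterations=5)
        cell_mask = convex_hull_image(ndi.binary_fill_holes(fg))
    part = partition_regions(cell_mask, region_fraction)

    for obj in objects:
        try:
            obj.region = classify_region(obj, part)
        except UnassignedRegionError:
            obj.region = None

    seg_data = seg_img.data
    for name, img in channels.items():
        for obj in objects:
            sel = labels.labels == obj.label
            obj.mean_intensity[name] = float(img.data[sel].mean())
        if name == segmentation_channel:
            continue
        r = pearson_per_object(labels, seg_img, img)
        for obj in objects:
            obj.pearson[(segmentation_channel, name)] = r[obj.label]
    return objects_to_frame(objects)
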