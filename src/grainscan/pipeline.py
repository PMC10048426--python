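"""End-to-end conveniences tying the stages together.

These helpers are what the CLI, the test suite and reproduction scripts
drive: render labeled scenes, segment them, transfer ground-truth variety
labels onto segmented regions by majority pixel overlap, and assemble a
labeled feature table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .features import FeatureConfig, build_feature_table
from .segment import GrainRegion, segment_scene
from .synth import GroundTruth, SceneSpec, render_scene

__all__ = [
    "match_region_to_truth",
    "label_regions",
    "scene_feature_table",
    "dataset_feature_table",
]


def match_region_to_truth(region: GrainRegion, gt: GroundTruth) -> tuple[int, float]:
    """Ground-truth grain id covering the region, with the overlap IoU.

    Returns ``(0, 0.0)`` for a region that overlaps no ground-truth grain.
    """
    r0, c0, r1, c1 = region.bbox
    truth = gt.label_raster[r0:r1, c0:c1]
    overlap = truth[region.mask_crop]
    overlap = overlap[overlap > 0]
    if overlap.size == 0:
        return 0, 0.0
    gid = int(np.bincount(overlap).argmax())
    inter = int((overlap == gid).sum())
    gt_area = int((gt.label_raster == gid).sum())
    union = gt_area + region.area_px - inter
    return gid, inter / union


def label_regions(
    regions: list[GrainRegion], gt: GroundTruth
) -> tuple[list[GrainRegion], np.ndarray]:
    """Attach ground-truth variety labels to regions in place.

    Returns the regions that matched a grain, plus their IoUs.  Regions
    matching no grain (pure-noise blobs) are dropped.
    """
    kept = []
    ious = []
    for region in regions:
        gid, iou = match_region_to_truth(region, gt)
        if gid == 0:
            continue
        region.variety = gt.variety_of[gid]
        kept.append(region)
        ious.append(iou)
    return kept, np.asarray(ious)


def scene_feature_table(
    spec: SceneSpec,
    config: FeatureConfig = FeatureConfig(),
    scene_name: str = "",
) -> tuple[pd.DataFrame, np.ndarray]:
    """Render one scene, segment it, and return the labeled feature table
    plus per-region IoUs against ground truth."""
    image, gt = render_scene(spec)
    regions, _, _ = segment_scene(image, scene=scene_name)
    regions, ious = label_regions(regions, gt)
    return build_feature_table(regions, config), ious


def dataset_feature_table(
    specs: list[SceneSpec],
    config: FeatureConfig = FeatureConfig(),
) -> pd.DataFrame:
    """Labeled feature table across several rendered scenes."""
    tables = []
    for i, spec in enumerate(specs):
        table, _ = scene_feature_table(spec, config, scene_name=f"scene_{i:03d}")
        tables.append(table)
    return pd.concat(tables, ignore_index=True)
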