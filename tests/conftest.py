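import numpy as np
import pytest

from grainscan.contours import trace_contour
from grainscan.pipeline import dataset_feature_table
from grainscan.segment import GrainRegion
from grainscan.synth import DEFAULT_PROFILES, SceneSpec


def make_region(mask, rgb=None, label=1, scene="test"):
    """Wrap a boolean mask (and optional RGB crop) as a GrainRegion."""
    mask = np.asarray(mask, bool)
    if rgb is None:
        rgb = np.zeros(mask.shape + (3,), np.uint8)
        rgb[mask] = 200
    return GrainRegion(
        label=label,
        bbox=(0, 0, mask.shape[0], mask.shape[1]),
        mask_crop=mask,
        rgb_crop=np.asarray(rgb, np.uint8),
        contour=trace_contour(mask),
        area_px=int(mask.sum()),
        scene=scene,
    )


def disk_mask(radius, pad=2):
    n = 2 * (radius + pad) + 1
    yy, xx = np.mgrid[:n, :n] - (radius + pad)
    return xx**2 + yy**2 <= radius**2


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def eight_variety_table():
    """Labeled feature table from eight single-variety scenes (40 grains
    each), produced by the full render -> segment -> extract pipeline."""
    specs = [
        SceneSpec(
            grains=[(profile, 40)],
            width=1200,
            height=900,
            noise_density=0.005,
            min_gap=4,
            seed=100 + i,
        )
        for i, profile in enumerate(DEFAULT_PROFILES.values())
    ]
    return dataset_feature_table(specs)
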