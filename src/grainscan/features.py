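"""Per-grain feature extraction: geometry, color histograms and GLCM texture.

The default feature vector concatenates three blocks in fixed registry
order:

* geometry/morphology — 18 scalars from the grain mask (area, perimeter,
  fitted-ellipse axes, solidity, roundness, compactness, shape factor, ...),
* color — 48-bin histograms of the six channels R, G, B, H, S, V computed
  over the grain's pixels (288 counts),
* texture — six Haralick statistics of the 256-level gray-level
  co-occurrence matrix (contrast, dissimilarity, homogeneity, angular
  second moment, energy, correlation) at the four unit offsets 0, 45, 90
  and 135 degrees (24 scalars),

for 330 features per grain.  The registry (names, block layout, binning and
angles) is serialized next to every feature table so column meaning is
always recoverable.

The GLCM is built by hand rather than with ``skimage.feature.graycomatrix``
because co-occurrence pairs must be restricted to pixels inside the grain
mask; the bounding box would otherwise contaminate texture with background.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skimage import measure

from .contours import trace_contour
from .errors import (
    DegenerateShapeError,
    EmptyPairsError,
    InvalidDistributionError,
    InvalidRegionError,
)
from .segment import GrainRegion, to_grayscale

__all__ = [
    "FeatureConfig",
    "GEOMETRY_NAMES",
    "TEXTURE_STAT_NAMES",
    "trace_contour",
    "geometry_features",
    "rgb_to_hsv",
    "channel_histograms",
    "glcm",
    "GlcmMatrix",
    "glcm_stats",
    "texture_features",
    "feature_registry",
    "feature_vector",
    "build_feature_table",
]

GEOMETRY_NAMES = [
    "area",
    "perimeter",
    "equivalent_diameter",
    "length",
    "width",
    "aspect_ratio",
    "convex_area",
    "solidity",
    "extent",
    "bbox_w",
    "bbox_h",
    "roundness",
    "compactness",
    "shape_factor",
    "eccentricity",
    "orientation",
    "hull_perimeter",
    "perimeter_ratio",
]

COLOR_CHANNELS = ("R", "G", "B", "H", "S", "V")
TEXTURE_STAT_NAMES = ("CON", "DIS", "HO", "ASM", "EN", "CORR")

#: (row, col) unit offsets for the four co-occurrence directions
ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass(frozen=True)
class FeatureConfig:
    """Registry configuration; the default reproduces the 330-long vector."""

    hist_bins: int = 48
    glcm_levels: int = 256
    angles: tuple[int, ...] = (0, 45, 90, 135)
    masked_histograms: bool = True  # False = histogram the full bounding box

    def to_json(self) -> dict:
        return {
            "hist_bins": self.hist_bins,
            "glcm_levels": self.glcm_levels,
            "angles": list(self.angles),
            "masked_histograms": self.masked_histograms,
        }


def feature_registry(config: FeatureConfig = FeatureConfig()) -> list[str]:
    """Ordered feature names: geometry | color | texture."""
    names = list(GEOMETRY_NAMES)
    for ch in COLOR_CHANNELS:
        names += [f"hist_{ch}_{i:02d}" for i in range(config.hist_bins)]
    for ang in config.angles:
        names += [f"glcm_{stat}_{ang:03d}" for stat in TEXTURE_STAT_NAMES]
    return names


# ---------------------------------------------------------------------------
# geometry block


def geometry_features(region: GrainRegion) -> dict[str, float]:
    """The 18 geometry/morphology scalars of a grain mask.

    The best-fit ellipse comes from second-order image moments
    (``skimage.measure.regionprops``); ``length``/``width`` are its major
    and minor axis lengths, the standard proxies for grain length and
    width.
    """
    mask = np.asarray(region.mask_crop, bool)
    if not mask.any():
        raise InvalidRegionError("empty region")
    props = measure.regionprops(mask.astype(np.uint8))[0]
    length = float(props.axis_major_length)
    width = float(props.axis_minor_length)
    if width <= 0:
        raise DegenerateShapeError("line-like region: minor axis is zero")
    area = float(props.area)
    # Crofton estimate: far less biased than the chain-code perimeter on
    # smooth convex shapes, so roundness of a disk stays near 1
    perimeter = float(measure.perimeter_crofton(mask, directions=4))
    hull_perimeter = float(
        measure.perimeter_crofton(props.image_convex, directions=4)
    )
    bbox_h, bbox_w = mask.shape
    return {
        "area": area,
        "perimeter": perimeter,
        "equivalent_diameter": float(np.sqrt(4 * area / np.pi)),
        "length": length,
        "width": width,
        "aspect_ratio": length / width,
        "convex_area": float(props.area_convex),
        "solidity": float(props.solidity),
        "extent": area / (bbox_h * bbox_w),
        "bbox_w": float(bbox_w),
        "bbox_h": float(bbox_h),
        "roundness": 4 * np.pi * area / perimeter**2 if perimeter > 0 else 0.0,
        "compactness": perimeter**2 / area,
        "shape_factor": area / (length * width),
        "eccentricity": float(props.eccentricity),
        "orientation": float(props.orientation),
        "hull_perimeter": hull_perimeter,
        "perimeter_ratio": perimeter / hull_perimeter if hull_perimeter > 0 else 1.0,
    }


# ---------------------------------------------------------------------------
# color block


def rgb_to_hsv(r, g, b):
    """Sector-formula RGB -> HSV conversion.

    Accepts scalars or arrays with channels in [0, 255].  Returns
    ``(h, s, v)`` with hue in degrees [0, 360), saturation in [0, 1] and
    value on the input 0-255 scale.
    """
    r = np.asarray(r, float)
    g = np.asarray(g, float)
    b = np.asarray(b, float)
    v = np.maximum(np.maximum(r, g), b)
    m = np.minimum(np.minimum(r, g), b)
    delta = v - m
    s = np.where(v > 0, delta / np.where(v > 0, v, 1), 0.0)

    h = np.zeros_like(v)
    nz = delta > 0
    dl = np.where(nz, delta, 1)
    r_max = nz & (v == r)
    g_max = nz & (v == g) & ~r_max
    b_max = nz & (v == b) & ~r_max & ~g_max
    h = np.where(r_max, 60.0 * ((g - b) / dl), h)
    h = np.where(g_max, 60.0 * (2.0 + (b - r) / dl), h)
    h = np.where(b_max, 60.0 * (4.0 + (r - g) / dl), h)
    h = np.where(h < 0, h + 360.0, h)
    if h.ndim == 0:
        return float(h), float(s), float(v)
    return h, s, v


def _six_channel_bytes(rgb_pixels: np.ndarray) -> np.ndarray:
    """(n, 6) float array of R,G,B,H,S,V per pixel, all on a 0-255 scale.

    Hue is rescaled from [0, 360) and saturation from [0, 1] so a single
    uniform binning applies to every channel.
    """
    r, g, b = rgb_pixels[:, 0], rgb_pixels[:, 1], rgb_pixels[:, 2]
    h, s, v = rgb_to_hsv(r, g, b)
    return np.stack(
        [r, g, b, h * (255.0 / 360.0), s * 255.0, v], axis=1
    ).astype(float)


def channel_histograms(
    region: GrainRegion, config: FeatureConfig = FeatureConfig()
) -> np.ndarray:
    """48-bin histograms of R, G, B, H, S, V over the grain pixels.

    Bin index is ``floor(value * bins / 256)`` on the 0-255 scale.  Returns
    the concatenated integer counts in channel-major order; each channel's
    bins sum to the number of pixels histogrammed.
    """
    mask = np.asarray(region.mask_crop, bool)
    if not mask.any():
        raise InvalidRegionError("empty region has no color histogram")
    rgb = np.asarray(region.rgb_crop, float)
    pixels = rgb[mask] if config.masked_histograms else rgb.reshape(-1, 3)
    channels = _six_channel_bytes(pixels)
    bins = config.hist_bins
    idx = np.clip((channels * bins / 256.0).astype(int), 0, bins - 1)
    out = np.empty(6 * bins, int)
    for c in range(6):
        out[c * bins : (c + 1) * bins] = np.bincount(idx[:, c], minlength=bins)
    return out


# ---------------------------------------------------------------------------
# texture block


@dataclass
class GlcmMatrix:
    """Gray-level co-occurrence counts at one offset, plus the normalized
    distribution p = G / sum(G)."""

    G: np.ndarray
    p: np.ndarray
    offset: tuple[int, int]
    angle: int
    n_pairs: int


def glcm(
    gray_crop: np.ndarray,
    mask_crop: np.ndarray,
    angle: int,
    levels: int = 256,
) -> GlcmMatrix:
    """Masked co-occurrence matrix at unit distance for one angle.

    ``G[i, j]`` counts ordered pixel pairs (p, p + offset) with intensities
    (i, j) where both pixels lie inside the grain mask.  Not symmetrized
    and not averaged over angles.
    """
    if angle not in ANGLE_OFFSETS:
        raise InvalidRegionError(f"angle must be one of {sorted(ANGLE_OFFSETS)}")
    gray = np.asarray(gray_crop)
    mask = np.asarray(mask_crop, bool)
    if gray.shape != mask.shape:
        raise InvalidRegionError("gray crop and mask shapes differ")
    d1, d2 = ANGLE_OFFSETS[angle]
    h, w = gray.shape

    # source window and offset window, both clipped to the raster
    r0, r1 = max(0, -d1), min(h, h - d1)
    c0, c1 = max(0, -d2), min(w, w - d2)
    src = (slice(r0, r1), slice(c0, c1))
    dst = (slice(r0 + d1, r1 + d1), slice(c0 + d2, c1 + d2))
    valid = mask[src] & mask[dst]
    i = gray[src][valid].astype(np.int64)
    j = gray[dst][valid].astype(np.int64)
    if i.size == 0:
        raise EmptyPairsError(f"no valid co-occurrence pairs at {angle} degrees")
    G = np.bincount(i * levels + j, minlength=levels * levels).reshape(levels, levels)
    return GlcmMatrix(G, G / G.sum(), (d1, d2), angle, int(i.size))


def glcm_stats(p: np.ndarray) -> dict[str, float]:
    """Six Haralick statistics of a normalized co-occurrence matrix.

    CON  = sum (i-j)^2 p(i,j)          contrast
    DIS  = sum |i-j| p(i,j)            dissimilarity
    HO   = sum p(i,j) / (1 + |i-j|)    homogeneity
    ASM  = sum p(i,j)^2                angular second moment
    EN   = sqrt(ASM)                   energy
    CORR = sum (i-mu_i)(j-mu_j) p(i,j) / (sigma_i sigma_j)

    with mu/sigma taken from the row and column marginals of p.  CORR is
    defined as 1 for a degenerate (zero-variance) distribution.
    """
    p = np.asarray(p, float)
    if p.ndim != 2 or (p < 0).any():
        raise InvalidDistributionError("p must be a non-negative matrix")
    if abs(p.sum() - 1.0) > 1e-6:
        raise InvalidDistributionError("p must sum to 1")
    n, m = p.shape
    i = np.arange(n)[:, None]
    j = np.arange(m)[None, :]
    diff = i - j
    con = float(((diff**2) * p).sum())
    dis = float((np.abs(diff) * p).sum())
    ho = float((p / (1.0 + np.abs(diff))).sum())
    asm = float((p**2).sum())
    en = float(np.sqrt(asm))
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    mu_i = float((np.arange(n) * pi).sum())
    mu_j = float((np.arange(m) * pj).sum())
    var_i = float(((np.arange(n) - mu_i) ** 2 * pi).sum())
    var_j = float(((np.arange(m) - mu_j) ** 2 * pj).sum())
    denom = np.sqrt(var_i * var_j)
    if denom == 0:
        corr = 1.0
    else:
        corr = float((((i - mu_i) * (j - mu_j)) * p).sum() / denom)
    return {"CON": con, "DIS": dis, "HO": ho, "ASM": asm, "EN": en, "CORR": corr}


def texture_features(
    region: GrainRegion, config: FeatureConfig = FeatureConfig()
) -> dict[str, float]:
    """Six GLCM statistics at each configured angle (24 values by default)."""
    gray = to_grayscale(np.asarray(region.rgb_crop, np.uint8))
    out: dict[str, float] = {}
    for ang in config.angles:
        mat = glcm(gray, region.mask_crop, ang, levels=config.glcm_levels)
        stats = glcm_stats(mat.p)
        for name in TEXTURE_STAT_NAMES:
            out[f"glcm_{name}_{ang:03d}"] = stats[name]
    return out


# ---------------------------------------------------------------------------
# assembly


def feature_vector(
    region: GrainRegion, config: FeatureConfig = FeatureConfig()
) -> np.ndarray:
    """Full feature vector in registry order (330 values by default)."""
    geo = geometry_features(region)
    values = [geo[name] for name in GEOMETRY_NAMES]
    values += list(channel_histograms(region, config).astype(float))
    tex = texture_features(region, config)
    for ang in config.angles:
        values += [tex[f"glcm_{stat}_{ang:03d}"] for stat in TEXTURE_STAT_NAMES]
    vec = np.asarray(values, float)
    if not np.isfinite(vec).all():
        raise InvalidRegionError(
            f"non-finite feature for grain {region.label} in {region.scene!r}"
        )
    return vec


def build_feature_table(
    regions: Iterable[GrainRegion],
    config: FeatureConfig = FeatureConfig(),
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """One row per grain: provenance columns + the registry features.

    ``labels`` optionally supplies a variety label per region (in order);
    regions carrying their own ``variety`` are used otherwise.
    """
    names = feature_registry(config)
    rows = []
    meta = []
    regions = list(regions)
    if labels is not None and len(labels) != len(regions):
        raise InvalidRegionError("labels length does not match regions")
    for idx, region in enumerate(regions):
        try:
            vec = feature_vector(region, config)
        except InvalidRegionError as err:
            raise InvalidRegionError(
                f"grain {region.label} in {region.scene!r}: {err}"
            ) from err
        rows.append(vec)
        meta.append(
            {
                "scene": region.scene,
                "grain_id": region.label,
                "variety": labels[idx] if labels is not None else region.variety,
            }
        )
    table = pd.DataFrame(rows, columns=names)
    for col in ("variety", "grain_id", "scene"):
        table.insert(0, col, [m[col] for m in meta])
    return table


def save_feature_table(
    table: pd.DataFrame,
    csv_path: str | Path,
    config: FeatureConfig = FeatureConfig(),
) -> None:
    """Write the table as CSV plus a JSON registry manifest alongside."""
    csv_path = Path(csv_path)
    # %.17g guarantees bit-exact float64 round-trips through the CSV
    table.to_csv(csv_path, index=False, lineterminator="\n", float_format="%.17g")
    manifest = {
        "features": feature_registry(config),
        "blocks": {
            "geometry": len(GEOMETRY_NAMES),
            "color": 6 * config.hist_bins,
            "texture": len(TEXTURE_STAT_NAMES) * len(config.angles),
        },
        "config": config.to_json(),
    }
    csv_path.with_suffix(".registry.json").write_text(
        json.dumps(manifest, indent=2) + "\n"
    )


def feature_matrix(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Split a feature table into (X, y, feature_names)."""
    meta_cols = [c for c in ("scene", "grain_id", "variety") if c in table.columns]
    names = [c for c in table.columns if c not in meta_cols]
    X = table[names].to_numpy(float)
    y = table["variety"].to_numpy() if "variety" in table.columns else None
    return X, y, names
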