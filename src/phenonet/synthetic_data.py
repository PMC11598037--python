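"""Seeded generator of lettuce-like RGB-D samples.

Each sample is one rosette plant: overlapping elliptical leaves around a
centre, rendered over a textured soil background with a radial colour
gradient per variety.  The ideal depth map is the camera height minus a
spherical-dome canopy profile; the corrupted copy adds Bernoulli speckle
holes plus missing pixels along the leaf boundary, the two failure modes of
consumer structured-light sensors.  Traits are computed from the rendered
geometry, so every downstream stage (annotation IO, depth completion,
detection, trait regression, metrics) can be exercised without a download.

The fresh-weight allometry fw = a * (la * h)^b with multiplicative lognormal
noise is synthetic-only plumbing: it gives the trait head a learnable,
geometry-linked signal and does not model real lettuce growth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path as FsPath

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon as ShapelyPolygon
from shapely.ops import unary_union
from PIL import Image

from . import dataio
from .geometry import max_caliper_extent_px, rasterize_polygon
from .samples import VARIETIES, AnnotatedSample, Instance, TraitVector

#: per-variety leaf base colour (R, G, B) — distinct tints so variety
#: classification has signal in the synthetic world
_VARIETY_TINT = {
    "Lugano": (40, 118, 46),
    "Salanova": (72, 150, 58),
    "Aphylion": (46, 136, 84),
    "Satine": (96, 124, 40),
}


@dataclass(frozen=True)
class SynthConfig:
    """Scene parameters for one synthetic RGB-D acquisition.

    Defaults emulate the benchmark rig: 1920x1080 frames from a camera
    suspended 0.9 m above the crop; at that distance a RealSense-class
    sensor covers roughly 16 px per cm on the ground plane.
    """

    image_width: int = 1920
    image_height: int = 1080
    n_leaves: int = 12
    plant_radius_px: int = 260
    dome_height_m: float = 0.12
    camera_height_m: float = 0.9
    px_per_cm: float = 16.0
    hole_fraction: float = 0.15
    boundary_hole_px: int = 2
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.hole_fraction <= 1.0:
            raise ValueError("hole_fraction must be in [0, 1]")
        if self.px_per_cm <= 0:
            raise ValueError("px_per_cm must be positive")
        if self.plant_radius_px > min(self.image_width, self.image_height) / 2:
            raise ValueError("plant radius exceeds half the frame")
        if self.dome_height_m < 0 or self.camera_height_m <= self.dome_height_m:
            raise ValueError("camera must be above the canopy dome")
        if self.n_leaves < 3:
            raise ValueError("need at least 3 leaves")


def _ellipse_polygon(cx, cy, a, b, angle, n=48) -> ShapelyPolygon:
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    x = a * np.cos(t)
    y = b * np.sin(t)
    ca, sa = np.cos(angle), np.sin(angle)
    return ShapelyPolygon(np.column_stack([cx + ca * x - sa * y,
                                           cy + sa * x + ca * y]))


def _plant_polygon(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    w, h = cfg.image_width, cfg.image_height
    cx = w / 2 + rng.uniform(-0.05, 0.05) * cfg.plant_radius_px
    cy = h / 2 + rng.uniform(-0.05, 0.05) * cfg.plant_radius_px
    r = cfg.plant_radius_px
    parts = [_ellipse_polygon(cx, cy, 0.35 * r, 0.35 * r, 0.0)]  # core rosette
    for k in range(cfg.n_leaves):
        ang = 2 * np.pi * k / cfg.n_leaves + rng.uniform(-0.25, 0.25)
        length = r * rng.uniform(0.72, 1.0)
        width = length * rng.uniform(0.38, 0.55)
        lx = cx + 0.5 * length * np.cos(ang)
        ly = cy + 0.5 * length * np.sin(ang)
        parts.append(_ellipse_polygon(lx, ly, length / 2, width / 2, ang))
    merged = unary_union(parts)
    if merged.geom_type == "MultiPolygon":
        merged = max(merged.geoms, key=lambda g: g.area)
    merged = merged.simplify(0.4)
    poly = np.asarray(merged.exterior.coords)[:-1]
    poly[:, 0] = np.clip(poly[:, 0], 0, w - 1)
    poly[:, 1] = np.clip(poly[:, 1], 0, h - 1)
    return poly


def generate_sample(config: SynthConfig, variety: str = "Lugano",
                    fw_coeff: float = 0.05, fw_exp: float = 0.8,
                    fw_sigma: float = 0.05, dw_ratio_mean: float = 0.05,
                    dw_ratio_sd: float = 0.005,
                    dw_ratio_bounds=(0.03, 0.07),
                    image_id: str = "synthetic") -> AnnotatedSample:
    """Render one annotated RGB-D plant sample, fully seeded by the config."""
    if variety not in VARIETIES:
        raise ValueError(f"unknown variety {variety!r}")
    rng = np.random.default_rng(config.seed)
    h, w = config.image_height, config.image_width
    polygon = _plant_polygon(config, rng)
    mask = rasterize_polygon(polygon, h, w)
    if not mask.any():
        raise RuntimeError("degenerate plant mask")

    # --- RGB --------------------------------------------------------------
    soil = np.array([92, 70, 52], dtype=np.float64)
    tex = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (h, w)), 3.0)
    rgb = soil[None, None, :] + tex[:, :, None] * np.array([14.0, 11.0, 8.0])
    rgb += rng.normal(0.0, 3.0, (h, w, 3))

    ys, xs = np.nonzero(mask)
    cx, cy = polygon[:, 0].mean(), polygon[:, 1].mean()
    rr = np.sqrt((xs - cx) ** 2 + (ys - cy) ** 2)
    t = np.clip(rr / max(config.plant_radius_px, 1), 0.0, 1.0)
    tint = np.array(_VARIETY_TINT[variety], dtype=np.float64)
    inner, outer = tint * 0.65, np.minimum(tint * 1.3, 255)
    leaf_col = inner[None, :] * (1 - t[:, None]) + outer[None, :] * t[:, None]
    leaf_col += rng.normal(0.0, 4.0, leaf_col.shape)
    rgb[ys, xs] = leaf_col
    rgb = np.clip(rgb, 0, 255).astype(np.uint8)

    # --- depth ------------------------------------------------------------
    depth = np.full((h, w), config.camera_height_m, dtype=np.float32)
    dome = np.zeros_like(rr)
    rnorm = np.clip(rr / max(config.plant_radius_px, 1), 0.0, 1.0)
    dome = config.dome_height_m * np.sqrt(np.clip(1.0 - rnorm ** 2, 0.0, 1.0))
    depth[ys, xs] = config.camera_height_m - dome.astype(np.float32)

    raw = depth.copy()
    if config.hole_fraction > 0:
        speckle = rng.random((h, w)) < config.hole_fraction
        raw[speckle] = 0.0
    if config.boundary_hole_px > 0:
        it = config.boundary_hole_px
        band = ndimage.binary_dilation(mask, iterations=it) ^ \
            ndimage.binary_erosion(mask, iterations=it)
        raw[band] = 0.0

    # --- traits from rendered geometry -------------------------------------
    la = float(mask.sum()) / config.px_per_cm ** 2
    d = max_caliper_extent_px(mask) / config.px_per_cm
    h_cm = 100.0 * config.dome_height_m
    fw = fw_coeff * (la * h_cm) ** fw_exp * float(np.exp(rng.normal(0.0, fw_sigma)))
    ratio = float(np.clip(rng.normal(dw_ratio_mean, dw_ratio_sd), *dw_ratio_bounds))
    traits = TraitVector(fw=fw, dw=ratio * fw, h=h_cm, d=d, la=la)

    return AnnotatedSample(image_id=image_id, rgb=rgb, depth=depth,
                           instances=[Instance(polygon, variety)],
                           traits=traits, raw_depth=raw, mask=mask)


def vary_config(config: SynthConfig, rng: np.random.Generator) -> SynthConfig:
    """Per-sample scene variation used by :func:`generate_dataset`.

    Radius, leaf count and dome height are drawn around the base config so
    that traits vary across a dataset (a fixed config would make height a
    constant and trait regression degenerate).
    """
    radius = int(config.plant_radius_px * rng.uniform(0.55, 1.0))
    dome = config.dome_height_m * rng.uniform(0.6, 1.3)
    n_leaves = int(np.clip(config.n_leaves + rng.integers(-3, 4), 4, None))
    return replace(config, plant_radius_px=max(radius, 8), dome_height_m=dome,
                   n_leaves=n_leaves, seed=int(rng.integers(2 ** 31)))


def generate_dataset(n: int, config: SynthConfig, out_dir) -> list:
    """Write `n` synthetic samples in the layout the dataset readers expect.

    Returns the list of image ids.  Variety labels cycle over the four
    benchmark varieties.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out = FsPath(out_dir)
    (out / "rgb").mkdir(parents=True, exist_ok=True)
    (out / "depth").mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(config.seed)
    ids, via_entries, trait_rows = [], [], []
    for i in range(n):
        cfg_i = vary_config(config, master)
        variety = VARIETIES[i % len(VARIETIES)]
        iid = f"plant_{i:04d}"
        sample = generate_sample(cfg_i, variety=variety, image_id=iid)
        Image.fromarray(sample.rgb).save(out / "rgb" / f"{iid}.png")
        dataio.write_depth(out / "depth" / f"{iid}.png", sample.raw_depth)
        via_entries.append((f"{iid}.png", sample.instances))
        trait_rows.append((iid, sample.traits))
        ids.append(iid)
    dataio.write_via_annotations(out / "annotations.json", via_entries)
    dataio.write_trait_csv(out / "traits.csv", trait_rows)
    return ids
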