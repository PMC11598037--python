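"""Dataset readers/writers, geometric preprocessing, augmentation, folds.

The on-disk layout mirrors the greenhouse benchmark this package targets:
PNG RGB images, 16-bit millimetre depth PNGs with a float32 sidecar in
meters, VIA 2.x polygon annotations with a ``variety`` region attribute,
and a trait CSV with columns ``image_id,fw,dw,h,d,la``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path as FsPath

import numpy as np
import pandas as pd
from PIL import Image

from .samples import VARIETIES, TRAIT_NAMES, AnnotatedSample, Instance, TraitVector

AUGMENT_SUFFIXES = ("__hflip", "__vflip", "__bright")


# ---------------------------------------------------------------------------
# VIA 2.x annotations
# ---------------------------------------------------------------------------

def write_via_annotations(path, entries) -> None:
    """Write a VIA 2.x project JSON.

    entries: iterable of (filename, list[Instance]).
    """
    metadata = {}
    for filename, instances in entries:
        regions = []
        for inst in instances:
            regions.append({
                "shape_attributes": {
                    "name": "polygon",
                    "all_points_x": [float(v) for v in inst.polygon[:, 0]],
                    "all_points_y": [float(v) for v in inst.polygon[:, 1]],
                },
                "region_attributes": {"variety": inst.label},
            })
        metadata[f"{filename}-1"] = {
            "filename": filename,
            "size": -1,
            "regions": regions,
            "file_attributes": {},
        }
    project = {
        "_via_settings": {"project": {"name": "phenonet"}},
        "_via_img_metadata": metadata,
        "_via_attributes": {
            "region": {"variety": {"type": "dropdown",
                                   "options": {v: v for v in VARIETIES}}},
            "file": {},
        },
    }
    with open(path, "w") as fh:
        json.dump(project, fh)


def read_via_annotations(path):
    """Parse a VIA 2.x project JSON.

    Returns a list of (image_id, polygons, classes) where polygons is a list
    of (V, 2) float arrays in 0-based pixel coordinates and image_id is the
    filename without extension.  Accepts both a full project file and a bare
    image-metadata mapping.
    """
    with open(path) as fh:
        raw = json.load(fh)
    metadata = raw.get("_via_img_metadata", raw)
    out = []
    for entry in metadata.values():
        filename = entry["filename"]
        image_id = FsPath(filename).stem
        regions = entry.get("regions", [])
        if not regions:
            raise ValueError(f"image {filename!r} has no annotated regions")
        polygons, classes = [], []
        for region in regions:
            shape = region["shape_attributes"]
            if shape.get("name") != "polygon":
                raise ValueError(f"image {filename!r}: non-polygon region")
            poly = np.column_stack([shape["all_points_x"],
                                    shape["all_points_y"]]).astype(np.float64)
            attrs = region.get("region_attributes", {})
            if "variety" not in attrs:
                raise ValueError(
                    f"image {filename!r}: region missing 'variety' attribute")
            polygons.append(poly)
            classes.append(attrs["variety"])
        out.append((image_id, polygons, classes))
    return out


# ---------------------------------------------------------------------------
# rasters and traits
# ---------------------------------------------------------------------------

def write_depth(path_png, depth_m: np.ndarray) -> None:
    """16-bit millimetre PNG plus a lossless float32 sidecar in meters."""
    mm = np.round(np.asarray(depth_m, dtype=np.float64) * 1000.0)
    Image.fromarray(np.clip(mm, 0, 65535).astype(np.uint16)).save(path_png)
    np.save(str(path_png) + ".npy", np.asarray(depth_m, dtype=np.float32))


def read_depth(path_png) -> np.ndarray:
    """Read depth in meters, preferring the lossless sidecar."""
    sidecar = FsPath(str(path_png) + ".npy")
    if sidecar.exists():
        return np.load(sidecar).astype(np.float32)
    arr = np.asarray(Image.open(path_png), dtype=np.float32)
    return arr / 1000.0


def write_trait_csv(path, rows) -> None:
    """rows: iterable of (image_id, TraitVector)."""
    records = [{"image_id": iid, **dict(zip(TRAIT_NAMES, tv.as_array()))}
               for iid, tv in rows]
    pd.DataFrame.from_records(records).to_csv(path, index=False)


def read_trait_csv(path) -> dict:
    df = pd.read_csv(path)
    out = {}
    for _, row in df.iterrows():
        out[str(row["image_id"])] = TraitVector(
            *[float(row[c]) for c in TRAIT_NAMES])
    return out


def load_dataset(root) -> list:
    """Read a dataset directory written by the synthetic generator."""
    root = FsPath(root)
    annos = {iid: (polys, classes)
             for iid, polys, classes in read_via_annotations(root / "annotations.json")}
    traits = read_trait_csv(root / "traits.csv")
    samples = []
    for iid in sorted(annos):
        rgb = np.asarray(Image.open(root / "rgb" / f"{iid}.png").convert("RGB"))
        depth = read_depth(root / "depth" / f"{iid}.png")
        polys, classes = annos[iid]
        instances = [Instance(p, c) for p, c in zip(polys, classes)]
        samples.append(AnnotatedSample(
            image_id=iid, rgb=rgb, depth=depth, instances=instances,
            traits=traits.get(iid)))
    return samples


# ---------------------------------------------------------------------------
# geometric preprocessing
# ---------------------------------------------------------------------------

def center_crop_resize(sample: AnnotatedSample, crop: int = 1024,
                       out: int = 800) -> AnnotatedSample:
    """Centre-crop to `crop` square then resize to `out` square.

    RGB is resampled bilinearly; depth nearest-neighbour (depth values are
    distances and must not be blended across object boundaries).  Polygon
    vertices map as v' = (v - offset) * (out / crop).
    """
    h, w = sample.rgb.shape[:2]
    if h < crop or w < crop:
        raise ValueError(f"image {w}x{h} smaller than crop {crop}")
    ox, oy = (w - crop) // 2, (h - crop) // 2
    scale = out / crop
    rgb = np.asarray(Image.fromarray(
        sample.rgb[oy:oy + crop, ox:ox + crop]).resize((out, out), Image.BILINEAR))

    def _resize_depth(d):
        return np.asarray(Image.fromarray(d[oy:oy + crop, ox:ox + crop]).resize(
            (out, out), Image.NEAREST))

    depth = _resize_depth(sample.depth)
    raw = _resize_depth(sample.raw_depth) if sample.raw_depth is not None else None
    instances = []
    for inst in sample.instances:
        poly = (inst.polygon - np.array([ox, oy])) * scale
        poly = np.clip(poly, 0, out - 1)
        instances.append(Instance(poly, inst.label))
    return AnnotatedSample(image_id=sample.image_id, rgb=rgb, depth=depth,
                           instances=instances, traits=sample.traits,
                           raw_depth=raw)


def _flip_sample(sample: AnnotatedSample, axis: str) -> AnnotatedSample:
    h, w = sample.rgb.shape[:2]
    if axis == "h":
        rgb = sample.rgb[:, ::-1].copy()
        depth = sample.depth[:, ::-1].copy()
        raw = sample.raw_depth[:, ::-1].copy() if sample.raw_depth is not None else None

        def tf(poly):
            out = poly.copy()
            out[:, 0] = (w - 1) - out[:, 0]
            return out
        suffix = "__hflip"
    else:
        rgb = sample.rgb[::-1].copy()
        depth = sample.depth[::-1].copy()
        raw = sample.raw_depth[::-1].copy() if sample.raw_depth is not None else None

        def tf(poly):
            out = poly.copy()
            out[:, 1] = (h - 1) - out[:, 1]
            return out
        suffix = "__vflip"
    instances = [Instance(tf(i.polygon), i.label) for i in sample.instances]
    return AnnotatedSample(image_id=sample.image_id + suffix, rgb=rgb,
                           depth=depth, instances=instances,
                           traits=sample.traits, raw_depth=raw)


def _brighten_sample(sample: AnnotatedSample, factor: float = 1.10) -> AnnotatedSample:
    rgb = np.clip(np.round(sample.rgb.astype(np.float64) * factor),
                  0, 255).astype(np.uint8)
    instances = [Instance(i.polygon.copy(), i.label) for i in sample.instances]
    return AnnotatedSample(image_id=sample.image_id + "__bright", rgb=rgb,
                           depth=sample.depth.copy(), instances=instances,
                           traits=sample.traits,
                           raw_depth=None if sample.raw_depth is None
                           else sample.raw_depth.copy())


def augment(sample: AnnotatedSample) -> list:
    """Standard 4x augmentation: original, h-flip, v-flip, +10% brightness.

    Brightness is multiplicative on RGB only; depth is a distance, not a
    radiance, and is left untouched.
    """
    return [sample,
            _flip_sample(sample, "h"),
            _flip_sample(sample, "v"),
            _brighten_sample(sample)]


def base_id(image_id: str) -> str:
    """Strip any augmentation suffix, returning the base image id."""
    for suf in AUGMENT_SUFFIXES:
        if image_id.endswith(suf):
            return image_id[: -len(suf)]
    return image_id


# ---------------------------------------------------------------------------
# K-fold construction
# ---------------------------------------------------------------------------

@dataclass
class FoldSplit:
    """5-fold split with a held-out validation slice per fold.

    Augmented variants of a base image always inherit the base image's role,
    so no augmented copy of a test image ever leaks into training.
    """

    k: int
    fold_assignments: dict          # base image id -> fold index
    folds: list = field(default_factory=list)  # per fold: dict(train/val/test)

    def role_of(self, image_id: str, fold: int) -> str:
        base = base_id(image_id)
        for role in ("train", "val", "test"):
            if base in self._sets[fold][role]:
                return role
        raise KeyError(f"{image_id!r} not in split")

    def __post_init__(self):
        self._sets = [{role: set(f[role]) for role in ("train", "val", "test")}
                      for f in self.folds]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"k": self.k,
                       "fold_assignments": self.fold_assignments,
                       "folds": self.folds}, fh, indent=1)

    @staticmethod
    def from_json(path) -> "FoldSplit":
        with open(path) as fh:
            raw = json.load(fh)
        return FoldSplit(raw["k"], raw["fold_assignments"], raw["folds"])


def make_folds(ids, k: int = 5, val_frac: float = 0.10, seed: int = 0) -> FoldSplit:
    """Shuffled near-equal K-fold partition of base image ids.

    For each fold f: test = fold f, val = round(val_frac * |rest|) of the
    remaining ids, train = the rest.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    ids = [base_id(i) for i in ids]
    if len(set(ids)) != len(ids):
        ids = sorted(set(ids))
    if len(ids) < k:
        raise ValueError(f"need at least k={k} base ids, got {len(ids)}")
    rng = np.random.default_rng(seed)
    order = list(np.array(ids, dtype=object)[rng.permutation(len(ids))])
    fold_lists = [list(part) for part in np.array_split(np.array(order, dtype=object), k)]
    assignments = {iid: f for f, part in enumerate(fold_lists) for iid in part}
    folds = []
    for f in range(k):
        test = list(fold_lists[f])
        rest = [iid for g in range(k) if g != f for iid in fold_lists[g]]
        rest = list(np.array(rest, dtype=object)[rng.permutation(len(rest))])
        n_val = int(round(val_frac * len(rest)))
        val = rest[:n_val]
        train = rest[n_val:]
        folds.append({"train": train, "val": val, "test": test})
    return FoldSplit(k, assignments, folds)
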