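"""Annotation IO, preprocessing geometry, augmentation and fold discipline."""

import json

import numpy as np
import pytest

from phenonet import dataio
from phenonet.geometry import rasterize_polygon
from phenonet.samples import AnnotatedSample, Instance, TraitVector
from phenonet.synthetic_data import generate_dataset


# ---------------------------------------------------------------------------
# VIA annotations
# ---------------------------------------------------------------------------

def test_via_roundtrip(tmp_path):
    poly = np.array([[10.0, 20.0], [40.0, 25.0], [30.0, 50.0]])
    dataio.write_via_annotations(
        tmp_path / "via.json", [("img0.png", [Instance(poly, "Lugano")])])
    out = dataio.read_via_annotations(tmp_path / "via.json")
    assert len(out) == 1
    iid, polys, classes = out[0]
    assert iid == "img0" and classes == ["Lugano"]
    assert np.array_equal(polys[0], poly)  # vertex order preserved


def test_via_zero_regions_errors(tmp_path):
    project = {"_via_img_metadata": {
        "a.png-1": {"filename": "a.png", "size": -1, "regions": [],
                    "file_attributes": {}}}}
    path = tmp_path / "bad.json"
    path.write_text(json.dumps(project))
    with pytest.raises(ValueError, match="a.png"):
        dataio.read_via_annotations(path)


def test_via_missing_variety_attribute_names_image(tmp_path):
    project = {"_via_img_metadata": {
        "b.png-1": {"filename": "b.png", "size": -1, "regions": [
            {"shape_attributes": {"name": "polygon",
                                  "all_points_x": [0, 5, 3],
                                  "all_points_y": [0, 0, 4]},
             "region_attributes": {}}]}}}
    path = tmp_path / "bad.json"
    path.write_text(json.dumps(project))
    with pytest.raises(ValueError, match="b.png"):
        dataio.read_via_annotations(path)


# ---------------------------------------------------------------------------
# centre crop + resize
# ---------------------------------------------------------------------------

def _sample_with_vertex(w, h, vertices):
    rgb = np.zeros((h, w, 3), dtype=np.uint8)
    depth = np.ones((h, w), dtype=np.float32)
    return AnnotatedSample("t", rgb, depth,
                           [Instance(np.array(vertices, float), "Satine")])


def test_crop_resize_center_vertex():
    s = _sample_with_vertex(1920, 1080,
                            [[960, 540], [1000, 540], [960, 600]])
    out = dataio.center_crop_resize(s)
    assert out.rgb.shape == (800, 800, 3)
    # offsets (448, 28); (512, 512) * 800/1024 = (400, 400)
    assert np.allclose(out.instances[0].polygon[0], [400.0, 400.0])


def test_crop_resize_corner_vertex_maps_to_origin():
    s = _sample_with_vertex(1920, 1080, [[448, 28], [600, 100], [500, 300]])
    out = dataio.center_crop_resize(s)
    assert np.allclose(out.instances[0].polygon[0], [0.0, 0.0])


def test_crop_equal_size_is_pure_resize():
    s = _sample_with_vertex(1024, 1024, [[512, 512], [600, 520], [550, 700]])
    out = dataio.center_crop_resize(s)
    assert np.allclose(out.instances[0].polygon[0], [400.0, 400.0])


def test_crop_smaller_image_errors():
    s = _sample_with_vertex(800, 800, [[100, 100], [200, 100], [150, 200]])
    with pytest.raises(ValueError):
        dataio.center_crop_resize(s)


def test_depth_values_unchanged_in_magnitude(small_sample):
    # upscale the small sample into a croppable canvas by tiling values
    rgb = np.zeros((1100, 1930, 3), dtype=np.uint8)
    depth = np.full((1100, 1930), 0.73, dtype=np.float32)
    depth[500:600, 900:1000] = 0.51
    s = AnnotatedSample("d", rgb, depth,
                        [Instance(np.array([[900, 500], [1000, 500],
                                            [950, 600]], float), "Lugano")])
    out = dataio.center_crop_resize(s)
    assert set(np.unique(out.depth)).issubset({np.float32(0.73), np.float32(0.51)})


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def test_augment_produces_four_variants(small_sample):
    variants = dataio.augment(small_sample)
    assert len(variants) == 4
    ids = [v.image_id for v in variants]
    assert ids[0] == small_sample.image_id
    assert {i.split("__")[-1] for i in ids[1:]} == {"hflip", "vflip", "bright"}


def test_augmentation_scales_any_count(small_sample):
    # the published 387 base pairs -> 1548 relation is the N -> 4N contract
    n_base = 387
    assert n_base * len(dataio.augment(small_sample)) == 1548


def test_hflip_is_involution(small_sample):
    once = dataio._flip_sample(small_sample, "h")
    twice = dataio._flip_sample(once, "h")
    assert np.array_equal(twice.rgb, small_sample.rgb)
    assert np.array_equal(twice.depth, small_sample.depth)
    assert np.allclose(twice.instances[0].polygon,
                       small_sample.instances[0].polygon)


def test_brightness_clamps_and_scales():
    rgb = np.zeros((4, 4, 3), dtype=np.uint8)
    rgb[0, 0] = 250
    rgb[0, 1] = 100
    s = AnnotatedSample("b", rgb, np.ones((4, 4), np.float32),
                        [Instance(np.array([[0, 0], [3, 0], [2, 3]], float),
                                  "Lugano")])
    out = dataio._brighten_sample(s)
    assert out.rgb[0, 0, 0] == 255   # clamped
    assert out.rgb[0, 1, 0] == 110
    assert np.array_equal(out.depth, s.depth)  # depth untouched


def test_flipped_polygon_mask_equals_flipped_mask(small_sample):
    h, w = small_sample.rgb.shape[:2]
    mask = rasterize_polygon(small_sample.instances[0].polygon, h, w)
    flipped = dataio._flip_sample(small_sample, "h")
    mask_f = rasterize_polygon(flipped.instances[0].polygon, h, w)
    assert np.array_equal(mask_f, mask[:, ::-1])
    flipped_v = dataio._flip_sample(small_sample, "v")
    mask_v = rasterize_polygon(flipped_v.instances[0].polygon, h, w)
    assert np.array_equal(mask_v, mask[::-1])


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------

def test_fold_sizes_for_100_ids():
    ids = [f"im{i}" for i in range(100)]
    split = dataio.make_folds(ids, k=5, val_frac=0.10, seed=3)
    for fold in split.folds:
        assert len(fold["test"]) == 20
        assert len(fold["val"]) == 8
        assert len(fold["train"]) == 72


def test_every_id_in_exactly_one_test_fold():
    ids = [f"im{i}" for i in range(53)]
    split = dataio.make_folds(ids, k=5, seed=0)
    seen = []
    for fold in split.folds:
        seen.extend(fold["test"])
        assert set(fold["train"]) | set(fold["val"]) | set(fold["test"]) == set(ids)
        assert not set(fold["train"]) & set(fold["test"])
        assert not set(fold["val"]) & set(fold["test"])
        assert not set(fold["train"]) & set(fold["val"])
    assert sorted(seen) == sorted(ids)


def test_folds_deterministic_and_k_validation():
    ids = [f"im{i}" for i in range(30)]
    a = dataio.make_folds(ids, seed=9)
    b = dataio.make_folds(ids, seed=9)
    assert a.folds == b.folds and a.fold_assignments == b.fold_assignments
    with pytest.raises(ValueError):
        dataio.make_folds(ids, k=1)


def test_augmented_variants_inherit_fold_role():
    ids = [f"im{i}" for i in range(20)]
    split = dataio.make_folds(ids, seed=1)
    for fold_idx, fold in enumerate(split.folds):
        for iid in fold["test"]:
            for suf in dataio.AUGMENT_SUFFIXES:
                assert split.role_of(iid + suf, fold_idx) == "test"


def test_no_augmentation_leakage_across_folds():
    """No augmented variant of a test base image reaches train or val."""
    ids = [f"im{i}" for i in range(25)]
    split = dataio.make_folds(ids, seed=4)
    for fold_idx, fold in enumerate(split.folds):
        augmented_test = {iid + suf for iid in fold["test"]
                          for suf in dataio.AUGMENT_SUFFIXES}
        trainval = {dataio.base_id(i) for i in fold["train"] + fold["val"]}
        assert not {dataio.base_id(a) for a in augmented_test} & trainval


def test_fold_split_json_roundtrip(tmp_path):
    split = dataio.make_folds([f"im{i}" for i in range(12)], seed=2)
    split.to_json(tmp_path / "folds.json")
    back = dataio.FoldSplit.from_json(tmp_path / "folds.json")
    assert back.folds == split.folds
    assert back.fold_assignments == split.fold_assignments
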