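"""FPN, heads, model wiring and loss behaviour."""

import numpy as np
import pytest
from scipy import ndimage

from phenonet.geometry import nms
from phenonet.network import (ImprovedFPN, PhenoNet, PlainTraitHead,
                              ResidualTraitHead, InstancePrediction,
                              count_parameters, decode_boxes, encode_boxes,
                              generate_anchors)
from phenonet.nn import Tensor, ConvTranspose2d
from oracles import conv_transpose2d_oracle
from conftest import make_tiny_items


@pytest.fixture
def rng():
    return np.random.default_rng(17)


@pytest.fixture
def tiny_model():
    return PhenoNet(widths=(8, 16, 32, 64), depths=(1, 1, 1, 1),
                    fpn_channels=16, seed=3)


# ---------------------------------------------------------------------------
# improved FPN
# ---------------------------------------------------------------------------

def _pyramid(rng, base=32, chans=(8, 16, 32, 64)):
    return [Tensor(rng.normal(size=(1, c, base // 2 ** i, base // 2 ** i))
                   .astype(np.float32))
            for i, c in enumerate(chans)]


def test_fpn_output_shapes(rng):
    fpn = ImprovedFPN((8, 16, 32, 64), out_channels=16, rng=rng)
    outs = fpn(_pyramid(rng))
    assert [o.shape for o in outs] == [(1, 16, 32, 32), (1, 16, 16, 16),
                                       (1, 16, 8, 8), (1, 16, 4, 4)]


def test_fpn_rejects_non_dyadic_chain(rng):
    fpn = ImprovedFPN((8, 16), out_channels=8, rng=rng)
    feats = [Tensor(np.zeros((1, 8, 30, 30), np.float32)),
             Tensor(np.zeros((1, 16, 16, 16), np.float32))]
    with pytest.raises(ValueError):
        fpn(feats)
    with pytest.raises(ValueError):
        fpn([])


def test_transposed_conv_upsamples_25_to_50(rng):
    up = ConvTranspose2d(4, 4, 2, stride=2, rng=rng)
    y = up(Tensor(np.zeros((1, 4, 25, 25), np.float32)))
    assert y.shape == (1, 4, 50, 50)


def test_transposed_conv_matches_brute_force_oracle(rng):
    for k, s, p in [(2, 2, 0), (4, 2, 1)]:
        up = ConvTranspose2d(3, 5, k, stride=s, padding=p, rng=rng)
        x = rng.normal(size=(2, 3, 6, 6)).astype(np.float32)
        ours = up(Tensor(x)).data
        ref = conv_transpose2d_oracle(x.astype(np.float64),
                                      up.weight.data.astype(np.float64),
                                      up.bias.data.astype(np.float64),
                                      stride=s, padding=p)
        assert np.abs(ours - ref).max() < 1e-4


def test_bilinear_initialised_deconv_interpolates(rng):
    """Kernel 4 / stride 2 / pad 1 with the classic bilinear weights equals
    bilinear interpolation away from the border."""
    up = ConvTranspose2d(1, 1, 4, stride=2, padding=1)
    up.set_bilinear()
    x = rng.normal(size=(1, 1, 7, 7)).astype(np.float32)
    y = up(Tensor(x)).data[0, 0]
    oy, ox = np.meshgrid(np.arange(14), np.arange(14), indexing="ij")
    ref = ndimage.map_coordinates(x[0, 0].astype(np.float64),
                                  [(oy + 0.5) / 2 - 0.5, (ox + 0.5) / 2 - 0.5],
                                  order=1, mode="constant")
    assert np.abs(y[1:-1, 1:-1] - ref[1:-1, 1:-1]).max() < 1e-5


def test_fpn_zero_laterals_propagate_top_only(rng):
    fpn = ImprovedFPN((8, 16, 32, 64), out_channels=8, rng=rng)
    for lat in list(fpn.laterals)[:-1]:   # zero all laterals except the top
        lat.weight.data[:] = 0
        lat.bias.data[:] = 0
    feats = _pyramid(rng, chans=(8, 16, 32, 64))
    outs = fpn(feats)
    # expected: pure top-down chain of the coarsest lateral, smoothed per level
    x = fpn.laterals[-1](feats[-1])
    expect = [None] * 4
    expect[3] = fpn.smooths[3](x)
    for i in (2, 1, 0):
        x = fpn.upsamples[i](x)
        expect[i] = fpn.smooths[i](x)
    for o, e in zip(outs, expect):
        assert np.allclose(o.data, e.data, atol=1e-5)


# ---------------------------------------------------------------------------
# boxes / anchors
# ---------------------------------------------------------------------------

def test_box_encoding_roundtrip(rng):
    anchors = generate_anchors((6, 6), stride=8)
    boxes = anchors + rng.uniform(-3, 3, anchors.shape)
    boxes[:, 2:] = np.maximum(boxes[:, 2:], boxes[:, :2] + 4)
    deltas = encode_boxes(anchors, boxes)
    back = decode_boxes(anchors, deltas)
    assert np.abs(back - boxes).max() < 1e-3


def test_nms_identical_boxes_keep_one():
    boxes = np.array([[0, 0, 10, 10], [0, 0, 10, 10.]])
    keep = nms(boxes, np.array([0.9, 0.8]))
    assert len(keep) == 1 and keep[0] == 0


# ---------------------------------------------------------------------------
# trait heads
# ---------------------------------------------------------------------------

def test_trait_heads_have_identical_parameter_count(rng):
    plain = PlainTraitHead(16, rng=rng)
    res = ResidualTraitHead(16, rng=rng)
    assert count_parameters(res) == count_parameters(plain)


def test_trait_head_outputs_five_values(rng):
    head = ResidualTraitHead(8, rng=rng)
    out = head(Tensor(rng.normal(size=(3, 8, 14, 14)).astype(np.float32)))
    assert out.shape == (3, 5)


def test_zero_residual_branches_reduce_to_pooled_linear(rng):
    head = ResidualTraitHead(8, rng=rng)
    for blk in head.blocks:
        blk.conv2.weight.data[:] = 0
        blk.conv2.bias.data[:] = 0
        blk.bn2.weight.data[:] = 0
        blk.bn2.bias.data[:] = 0
    x = rng.normal(size=(2, 8, 6, 6)).astype(np.float32)
    out = head(Tensor(x)).data
    pooled = x.mean(axis=(2, 3))
    expect = pooled @ head.fc.weight.data.T + head.fc.bias.data
    assert np.abs(out - expect).max() < 1e-5


# ---------------------------------------------------------------------------
# model assembly
# ---------------------------------------------------------------------------

def test_forward_shape_contract_reduced(tiny_model, rng):
    rgb = Tensor(rng.normal(size=(2, 3, 160, 160)).astype(np.float32))
    depth = Tensor(rng.normal(size=(2, 1, 160, 160)).astype(np.float32))
    pyr = tiny_model.extract_pyramid(rgb, depth)
    assert [p.shape for p in pyr] == [(2, 16, 40, 40), (2, 16, 20, 20),
                                      (2, 16, 10, 10), (2, 16, 5, 5)]


def test_corrected_features_feed_both_next_stage_and_fusion(tiny_model, rng):
    """The FRM-corrected pair is exactly what SEF consumes, and the next
    stage's output depends on it (ancestry in the autodiff graph)."""
    rgb = Tensor(rng.normal(size=(1, 3, 96, 96)).astype(np.float32))
    depth = Tensor(rng.normal(size=(1, 1, 96, 96)).astype(np.float32))
    trace = {}
    tiny_model.extract_pyramid(rgb, depth, trace=trace)
    assert len(trace["corrected"]) == 4
    for (cr, cd), (sr, sd) in zip(trace["corrected"], trace["sef_inputs"]):
        assert cr is sr and cd is sd

    def ancestors(t, seen=None):
        seen = seen if seen is not None else set()
        for p in t._parents:
            if id(p) not in seen:
                seen.add(id(p))
                ancestors(p, seen)
        return seen

    for s in range(3):
        nxt_rgb = trace["corrected"][s + 1][0]
        assert id(trace["corrected"][s][0]) in ancestors(nxt_rgb)


def test_loss_requires_trait_stats(tiny_model):
    _, items = make_tiny_items(1, seed=2)
    with pytest.raises(ValueError, match="unnormalised"):
        tiny_model.loss(items)


def test_one_adam_step_decreases_loss():
    from phenonet.nn import Adam

    samples, items = make_tiny_items(2, seed=4)
    model = PhenoNet(widths=(8, 8, 8, 8), depths=(1, 1, 1, 1),
                     fpn_channels=8, seed=1)
    model.fit_trait_stats([s.traits for s in samples])
    opt = Adam(list(model.parameters()), lr=3e-4)

    model._rng = np.random.default_rng(0)
    l0, _ = model.loss(items)
    opt.zero_grad()
    model._rng = np.random.default_rng(0)
    loss, _ = model.loss(items)
    loss.backward()
    opt.step()
    model._rng = np.random.default_rng(0)
    l1, _ = model.loss(items)
    assert float(l1.data) < float(l0.data)


def test_score_threshold_above_one_gives_no_detections(tiny_model):
    samples, items = make_tiny_items(1, seed=6)
    tiny_model.fit_trait_stats([samples[0].traits])
    preds = tiny_model.predict(items[0]["rgb"], items[0]["depth"],
                               score_threshold=1.1)
    assert preds == []


def test_instance_prediction_validation():
    with pytest.raises(ValueError):
        InstancePrediction(box=np.array([5.0, 5, 5, 10]), label="Lugano",
                           score=0.5, mask=np.zeros((4, 4), bool))
    with pytest.raises(ValueError):
        InstancePrediction(box=np.array([0.0, 0, 5, 5]), label="Lugano",
                           score=1.5, mask=np.zeros((4, 4), bool))


def test_trait_stats_fitted_on_train_split_only():
    samples, _ = make_tiny_items(6, seed=8)
    train, test = samples[:4], samples[4:]
    m1 = PhenoNet(widths=(8, 8, 8, 8), depths=(1, 1, 1, 1), fpn_channels=8)
    m1.fit_trait_stats([s.traits for s in train])
    arr = np.stack([s.traits.as_array() for s in train])
    assert np.allclose(m1.trait_mean, arr.mean(axis=0))
    # test-split traits have no influence
    m2 = PhenoNet(widths=(8, 8, 8, 8), depths=(1, 1, 1, 1), fpn_channels=8)
    m2.fit_trait_stats([s.traits for s in train])
    assert np.array_equal(m1.trait_mean, m2.trait_mean)
    assert not np.allclose(
        m1.trait_mean, np.stack([s.traits.as_array() for s in samples]).mean(0))
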