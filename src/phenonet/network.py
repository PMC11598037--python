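"""Model assembly: improved FPN, detection/segmentation heads, residual
phenotypic-trait head, losses, and inference.

The full model runs two RepVGG streams stage by stage; after every stage the
cross-modal rectification (FRM) corrects the pair, the corrected pair both
continues into the next backbone stage and enters the stage's fusion module
(SEF), and the four fused maps feed a feature pyramid whose top-down
upsampling uses transposed convolutions.  Detection follows the classic
two-stage recipe (RPN proposals, ROI align, class/box refinement, per-ROI
mask), and a parallel residual head regresses the five phenotypic traits in
z-scored space from the same ROI features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image

from . import nn
from .nn import Tensor, concat
from .backbone import DualBackbone
from .fusion import FeatureRectification, SqueezeExciteFusion
from .geometry import box_iou, nms
from .samples import TRAIT_NAMES, VARIETIES, TraitVector


# ---------------------------------------------------------------------------
# small loss helpers
# ---------------------------------------------------------------------------

def smooth_l1(pred: Tensor, target: np.ndarray) -> Tensor:
    diff = pred - Tensor(target)
    ad = diff.abs()
    quad = (ad.data < 1.0).astype(np.float32)
    return (Tensor(quad) * 0.5 * diff * diff
            + Tensor(1.0 - quad) * (ad - 0.5)).mean()


def bce_with_logits(logits: Tensor, target: np.ndarray,
                    weights: np.ndarray | None = None) -> Tensor:
    t = Tensor(np.asarray(target, dtype=np.float32))
    per = logits.softplus() - t * logits
    if weights is None:
        return per.mean()
    return (per * Tensor(np.asarray(weights, dtype=np.float32))).sum()


def cross_entropy(logits: Tensor, target: np.ndarray) -> Tensor:
    target = np.asarray(target, dtype=int)
    m = Tensor(logits.data.max(axis=1, keepdims=True))
    lse = ((logits - m).exp().sum(axis=1, keepdims=True)).log() + m
    picked = logits[np.arange(len(target)), target]
    return (lse.reshape(len(target)) - picked).mean()


# ---------------------------------------------------------------------------
# improved FPN
# ---------------------------------------------------------------------------

class ImprovedFPN(nn.Module):
    """FPN whose top-down upsampling is a learned transposed convolution.

    The default kernel is 2 (stride 2); kernel 4 with padding 1 reproduces
    bilinear interpolation exactly when initialised with the classic
    bilinear kernel.
    """

    def __init__(self, in_channels, out_channels: int = 64, up_kernel: int = 2,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.out_channels = out_channels
        self.laterals = nn.ModuleList(
            [nn.Conv2d(c, out_channels, 1, rng=rng) for c in in_channels])
        pad = (up_kernel - 2) // 2
        self.upsamples = nn.ModuleList(
            [nn.ConvTranspose2d(out_channels, out_channels, up_kernel,
                                stride=2, padding=pad, rng=rng)
             for _ in in_channels[1:]])
        self.smooths = nn.ModuleList(
            [nn.Conv2d(out_channels, out_channels, 3, padding=1, rng=rng)
             for _ in in_channels])

    def forward(self, features):
        """features: list of 4 maps, fine to coarse (strides 4..32)."""
        if not features:
            raise ValueError("empty feature list")
        for lo, hi in zip(features[:-1], features[1:]):
            if (lo.shape[2] != 2 * hi.shape[2]
                    or lo.shape[3] != 2 * hi.shape[3]):
                raise ValueError("feature shapes must halve at each level")
        lats = [lat(f) for lat, f in zip(self.laterals, features)]
        outs = [None] * len(lats)
        x = lats[-1]
        outs[-1] = self.smooths[-1](x)
        for i in range(len(lats) - 2, -1, -1):
            x = lats[i] + self.upsamples[i](x)
            outs[i] = self.smooths[i](x)
        return outs


# ---------------------------------------------------------------------------
# anchors / boxes
# ---------------------------------------------------------------------------

def generate_anchors(feat_shape, stride: int, scales=(8.0,),
                     ratios=(0.5, 1.0, 2.0)) -> np.ndarray:
    """Anchor boxes (A*H*W, 4) for one level, centred on pixel centres.

    One anchor per (scale, ratio) pair; anchor side = scale * stride,
    stretched by sqrt(ratio)."""
    h, w = feat_shape
    ys = (np.arange(h) + 0.5) * stride
    xs = (np.arange(w) + 0.5) * stride
    cx, cy = np.meshgrid(xs, ys)
    anchors = []
    for s in scales:
        size = s * stride
        for r in ratios:
            aw = size * np.sqrt(1.0 / r)
            ah = size * np.sqrt(r)
            anchors.append(np.stack([cx - aw / 2, cy - ah / 2,
                                     cx + aw / 2, cy + ah / 2], axis=-1))
    return np.stack(anchors, axis=2).reshape(-1, 4)


def encode_boxes(anchors: np.ndarray, boxes: np.ndarray) -> np.ndarray:
    aw = anchors[:, 2] - anchors[:, 0]
    ah = anchors[:, 3] - anchors[:, 1]
    ax = anchors[:, 0] + aw / 2
    ay = anchors[:, 1] + ah / 2
    bw = boxes[:, 2] - boxes[:, 0]
    bh = boxes[:, 3] - boxes[:, 1]
    bx = boxes[:, 0] + bw / 2
    by = boxes[:, 1] + bh / 2
    return np.stack([(bx - ax) / aw, (by - ay) / ah,
                     np.log(bw / aw), np.log(bh / ah)], axis=1).astype(np.float32)


def decode_boxes(anchors: np.ndarray, deltas: np.ndarray,
                 clip_shape=None) -> np.ndarray:
    aw = anchors[:, 2] - anchors[:, 0]
    ah = anchors[:, 3] - anchors[:, 1]
    ax = anchors[:, 0] + aw / 2
    ay = anchors[:, 1] + ah / 2
    dx, dy, dw, dh = deltas.T
    dw = np.clip(dw, -4, 4)
    dh = np.clip(dh, -4, 4)
    cx = ax + dx * aw
    cy = ay + dy * ah
    w = aw * np.exp(dw)
    h = ah * np.exp(dh)
    boxes = np.stack([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2], axis=1)
    if clip_shape is not None:
        ih, iw = clip_shape
        boxes[:, 0::2] = np.clip(boxes[:, 0::2], 0, iw)
        boxes[:, 1::2] = np.clip(boxes[:, 1::2], 0, ih)
    return boxes


# ---------------------------------------------------------------------------
# heads
# ---------------------------------------------------------------------------

class RPNHead(nn.Module):
    def __init__(self, channels: int, n_anchors: int = 3,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.conv = nn.Conv2d(channels, channels, 3, padding=1, rng=rng)
        self.cls = nn.Conv2d(channels, n_anchors, 1, rng=rng)
        self.box = nn.Conv2d(channels, 4 * n_anchors, 1, rng=rng)
        self.n_anchors = n_anchors

    def forward(self, feats):
        """Returns per-level (objectness (N, A*H*W), deltas (N, A*H*W, 4))."""
        outs = []
        for f in feats:
            h = self.conv(f).silu()
            n, _, fh, fw = f.shape
            obj = self.cls(h).transpose(0, 2, 3, 1).reshape(n, fh * fw * self.n_anchors)
            dl = self.box(h).transpose(0, 2, 3, 1).reshape(n, fh * fw * self.n_anchors, 4)
            outs.append((obj, dl))
        return outs


class BoxHead(nn.Module):
    def __init__(self, channels: int, num_classes: int, roi_size: int = 7,
                 hidden: int = 256, rng: np.random.Generator | None = None):
        super().__init__()
        self.fc1 = nn.Linear(channels * roi_size * roi_size, hidden, rng=rng)
        self.fc2 = nn.Linear(hidden, hidden, rng=rng)
        self.cls = nn.Linear(hidden, num_classes + 1, rng=rng)
        self.box = nn.Linear(hidden, 4, rng=rng)  # class-agnostic refinement
        self.roi_size = roi_size

    def forward(self, roi_feats: Tensor):
        n = roi_feats.shape[0]
        h = self.fc2(self.fc1(roi_feats.reshape(n, -1)).silu()).silu()
        return self.cls(h), self.box(h)


class MaskHead(nn.Module):
    def __init__(self, channels: int, rng: np.random.Generator | None = None):
        super().__init__()
        self.conv1 = nn.Conv2d(channels, channels, 3, padding=1, rng=rng)
        self.conv2 = nn.Conv2d(channels, channels, 3, padding=1, rng=rng)
        self.up = nn.ConvTranspose2d(channels, channels, 2, stride=2, rng=rng)
        self.logit = nn.Conv2d(channels, 1, 1, rng=rng)

    def forward(self, roi_feats: Tensor) -> Tensor:
        h = self.conv2(self.conv1(roi_feats).silu()).silu()
        return self.logit(self.up(h).silu())[:, 0]   # (R, 2s, 2s)


class PlainTraitHead(nn.Module):
    """Baseline 8x (3x3 conv + BN + SiLU) trait head."""

    def __init__(self, channels: int, n_traits: int = 5,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.convs = nn.ModuleList()
        for _ in range(8):
            self.convs.append(nn.Sequential([
                nn.Conv2d(channels, channels, 3, padding=1, rng=rng),
                nn.BatchNorm2d(channels), nn.SiLU()]))
        self.fc = nn.Linear(channels, n_traits, rng=rng)

    def forward(self, roi_feats: Tensor) -> Tensor:
        h = roi_feats
        for c in self.convs:
            h = c(h)
        return self.fc(h.mean(axis=(2, 3)))


class TraitResBlock(nn.Module):
    """Pre-activation style conv-BN-SiLU-conv-BN branch with an identity
    skip; zeroing the branch makes the block an exact identity."""

    def __init__(self, channels: int, rng: np.random.Generator | None = None):
        super().__init__()
        self.conv1 = nn.Conv2d(channels, channels, 3, padding=1, rng=rng)
        self.bn1 = nn.BatchNorm2d(channels)
        self.conv2 = nn.Conv2d(channels, channels, 3, padding=1, rng=rng)
        self.bn2 = nn.BatchNorm2d(channels)

    def forward(self, x: Tensor) -> Tensor:
        h = self.bn2(self.conv2(self.bn1(self.conv1(x)).silu()))
        return h + x


class ResidualTraitHead(nn.Module):
    """Four residual blocks (eight 3x3 convolutions in total): exactly the
    same trainable parameter count as the plain eight-conv head."""

    def __init__(self, channels: int, n_traits: int = 5,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.blocks = nn.ModuleList(
            [TraitResBlock(channels, rng=rng) for _ in range(4)])
        self.fc = nn.Linear(channels, n_traits, rng=rng)

    def forward(self, roi_feats: Tensor) -> Tensor:
        h = roi_feats
        for b in self.blocks:
            h = b(h)
        return self.fc(h.mean(axis=(2, 3)))


# ---------------------------------------------------------------------------
# prediction container / loss breakdown
# ---------------------------------------------------------------------------

@dataclass
class InstancePrediction:
    box: np.ndarray            # (x0, y0, x1, y1), half-open pixels
    label: str
    score: float
    mask: np.ndarray           # (H, W) bool
    traits: TraitVector | None = None

    def __post_init__(self):
        x0, y0, x1, y1 = self.box
        if not (x0 < x1 and y0 < y1):
            raise ValueError("degenerate box")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score outside [0, 1]")


@dataclass
class LossBreakdown:
    rpn_cls: float
    rpn_box: float
    roi_cls: float
    roi_box: float
    mask: float
    trait: float
    weights: dict = field(default_factory=lambda: {
        "rpn_cls": 1.0, "rpn_box": 1.0, "roi_cls": 1.0,
        "roi_box": 1.0, "mask": 1.0, "trait": 1.0})

    @property
    def total(self) -> float:
        return sum(self.weights[k] * getattr(self, k) for k in self.weights)


# ---------------------------------------------------------------------------
# full model
# ---------------------------------------------------------------------------

class PhenoNet(nn.Module):
    """Dual-backbone RGB-D instance segmentation + trait regression model."""

    STRIDES = (4, 8, 16, 32)

    def __init__(self, num_classes: int = 4, widths=(48, 96, 192, 384),
                 depths=(2, 2, 2, 2), fpn_channels: int = 64,
                 up_kernel: int = 2, anchor_scales=(8.0,),
                 anchor_ratios=(0.5, 1.0, 2.0), seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.num_classes = num_classes
        self.class_names = list(VARIETIES[:num_classes])
        self.anchor_scales = tuple(np.atleast_1d(anchor_scales).tolist())
        self.anchor_ratios = tuple(anchor_ratios)
        self.backbone = DualBackbone(widths, depths, rng=rng)
        self.frms = nn.ModuleList([FeatureRectification(w, rng=rng) for w in widths])
        self.sefs = nn.ModuleList([SqueezeExciteFusion(w, rng=rng) for w in widths])
        self.fpn = ImprovedFPN(widths, fpn_channels, up_kernel=up_kernel, rng=rng)
        self.rpn = RPNHead(fpn_channels,
                           len(self.anchor_scales) * len(anchor_ratios),
                           rng=rng)
        self.box_head = BoxHead(fpn_channels, num_classes, rng=rng)
        self.mask_head = MaskHead(fpn_channels, rng=rng)
        self.trait_head = ResidualTraitHead(fpn_channels, rng=rng)
        self.trait_mean = None   # (5,) train-split statistics; must be set
        self.trait_std = None
        self._rng = np.random.default_rng(rng.integers(2 ** 31))
        # Every stage trains on single-image batches (backbone) or on the
        # image's ROI batch (heads); inference mirrors those batch shapes,
        # so batch statistics are the right normaliser at eval time too.
        for m in self.modules():
            if isinstance(m, nn.BatchNorm2d):
                m.use_batch_stats_in_eval = True

    # -- trait normalisation --------------------------------------------------
    def set_trait_stats(self, mean, std):
        self.trait_mean = np.asarray(mean, dtype=np.float64)
        self.trait_std = np.asarray(std, dtype=np.float64)
        if np.any(self.trait_std <= 0):
            raise ValueError("trait std must be positive")

    def fit_trait_stats(self, traits):
        """traits: iterable of TraitVector from the TRAINING split only."""
        arr = np.stack([t.as_array() for t in traits])
        self.set_trait_stats(arr.mean(axis=0), arr.std(axis=0) + 1e-9)

    # -- input normalisation --------------------------------------------------
    @staticmethod
    def _prep_inputs(rgb: np.ndarray, depth: np.ndarray):
        r = rgb.astype(np.float32).transpose(2, 0, 1)[None] / 127.5 - 1.0
        d = depth.astype(np.float32)
        d = (d - d.mean()) / (d.std() + 1e-6)
        return Tensor(r), Tensor(d[None, None])

    # -- feature pipeline -----------------------------------------------------
    def extract_pyramid(self, rgb_t: Tensor, depth_t: Tensor, trace: dict | None = None):
        bb = self.backbone
        x_rgb = bb.rgb_stream.forward_stage(rgb_t, -1)
        x_d = bb.depth_stream.forward_stage(bb.depth_stem(depth_t), -1)
        fused = []
        for s in range(4):
            x_rgb = bb.rgb_stream.forward_stage(x_rgb, s)
            x_d = bb.depth_stream.forward_stage(x_d, s)
            x_rgb, x_d = self.frms[s](x_rgb, x_d)
            if trace is not None:
                trace.setdefault("corrected", []).append((x_rgb, x_d))
                trace.setdefault("sef_inputs", []).append((x_rgb, x_d))
            fused.append(self.sefs[s](x_rgb, x_d))
        return self.fpn(fused)

    # -- proposals ------------------------------------------------------------
    def _level_anchors(self, pyramid):
        return [generate_anchors(p.shape[2:], s, self.anchor_scales,
                                 self.anchor_ratios)
                for p, s in zip(pyramid, self.STRIDES)]

    def _proposals(self, pyramid, image_shape, pre_nms: int = 256,
                   post_nms: int = 16, nms_iou: float = 0.7):
        rpn_out = self.rpn(pyramid)
        anchors = np.concatenate(self._level_anchors(pyramid))
        obj = np.concatenate([o.data[0] for o, _ in rpn_out])
        deltas = np.concatenate([d.data[0] for _, d in rpn_out])
        order = np.argsort(-obj)[:pre_nms]
        boxes = decode_boxes(anchors[order], deltas[order], clip_shape=image_shape)
        ok = (boxes[:, 2] - boxes[:, 0] > 2) & (boxes[:, 3] - boxes[:, 1] > 2)
        boxes, scores = boxes[ok], obj[order][ok]
        if len(boxes) == 0:
            return np.zeros((0, 4)), np.zeros(0)
        keep = nms(boxes, scores, nms_iou)[:post_nms]
        return boxes[keep], scores[keep]

    def _roi_features(self, pyramid, boxes: np.ndarray, out_size: int):
        """ROI align from the finest pyramid level (stride 4)."""
        stride = self.STRIDES[0]
        rois = np.zeros((len(boxes), 5), dtype=np.float64)
        rois[:, 1:] = boxes / stride
        return pyramid[0].roi_align(rois, out_size, sampling=2)

    # -- training loss --------------------------------------------------------
    def _rpn_targets(self, anchors, gt_boxes, pos_iou=0.5, neg_iou=0.3):
        """Anchor labels for the RPN: 1 positive, 0 negative, -1 ignore.

        All anchors outside the ignore band are supervised (class-balanced
        in the loss) — with few images, dense objectness supervision gives a
        far better-calibrated proposal ranking than random sampling.
        """
        iou = box_iou(anchors, gt_boxes)   # (A, G)
        best_gt = iou.argmax(axis=1)
        best_iou = iou.max(axis=1)
        labels = np.full(len(anchors), -1, dtype=int)
        labels[best_iou < neg_iou] = 0
        labels[best_iou >= pos_iou] = 1
        for g in range(gt_boxes.shape[0]):              # best anchor per GT
            labels[iou[:, g].argmax()] = 1
        return labels, best_gt

    def loss(self, batch) -> tuple:
        """Compute the weighted multi-task loss on a batch.

        batch: list of dicts with keys rgb (H,W,3 uint8), depth (H,W float,
        completed), boxes (G,4), labels (G,) int in [0,num_classes),
        masks (G,H,W) bool, traits (5,) raw trait units.
        Returns (total_loss_tensor, LossBreakdown).
        """
        if self.trait_mean is None:
            raise ValueError("trait targets are unnormalised: call "
                             "fit_trait_stats on the training split first")
        terms = {k: [] for k in ("rpn_cls", "rpn_box", "roi_cls", "roi_box",
                                 "mask", "trait")}
        for item in batch:
            rgb_t, depth_t = self._prep_inputs(item["rgb"], item["depth"])
            image_shape = item["rgb"].shape[:2]
            pyramid = self.extract_pyramid(rgb_t, depth_t)
            gt_boxes = np.atleast_2d(np.asarray(item["boxes"], dtype=np.float64))
            gt_labels = np.asarray(item["labels"], dtype=int)

            # --- RPN ---
            rpn_out = self.rpn(pyramid)
            anchors = np.concatenate(self._level_anchors(pyramid))
            obj = concat([o.reshape(o.shape[1]) for o, _ in rpn_out])
            deltas = concat([d.reshape(d.shape[1], 4) for _, d in rpn_out])
            labels_a, best_gt = self._rpn_targets(anchors, gt_boxes)
            pos = np.flatnonzero(labels_a == 1)
            neg = np.flatnonzero(labels_a == 0)
            sel = np.concatenate([pos, neg])
            tgt = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
            w = np.concatenate([np.full(len(pos), 0.5 / max(len(pos), 1)),
                                np.full(len(neg), 0.5 / max(len(neg), 1))])
            terms["rpn_cls"].append(bce_with_logits(obj[sel], tgt, weights=w))
            if len(pos):
                enc = encode_boxes(anchors[pos], gt_boxes[best_gt[pos]])
                terms["rpn_box"].append(smooth_l1(deltas[pos], enc))

            # --- proposals + GT boxes for the ROI heads ---
            # jittered GT copies span a range of overlaps so the box head
            # learns genuine refinement, not identity on perfect boxes
            prop, _ = self._proposals(pyramid, image_shape, post_nms=12)
            sizes = np.maximum(gt_boxes[:, 2:] - gt_boxes[:, :2], 4.0)
            jitters = []
            for frac in (0.05, 0.10, 0.15, 0.20):
                noise = self._rng.normal(0, frac, gt_boxes.shape) \
                    * np.tile(sizes, (1, 2))
                jitters.append(gt_boxes + noise)
            jitter = np.concatenate(jitters)
            jitter[:, 0::2] = np.clip(jitter[:, 0::2], 0, image_shape[1])
            jitter[:, 1::2] = np.clip(jitter[:, 1::2], 0, image_shape[0])
            rois = np.concatenate([prop, gt_boxes, jitter]) if len(prop) \
                else np.concatenate([gt_boxes, jitter])
            ok = (rois[:, 2] - rois[:, 0] > 2) & (rois[:, 3] - rois[:, 1] > 2)
            rois = rois[ok]
            iou = box_iou(rois, gt_boxes)
            roi_best = iou.argmax(axis=1)
            roi_iou = iou.max(axis=1)
            # foreground threshold 0.45: RPN proposals hover around 0.5 IoU
            # early in training, and the classifier must accept them for the
            # box head to learn refinement on realistic candidates
            roi_labels = np.where(roi_iou >= 0.45,
                                  gt_labels[roi_best] + 1, 0)  # 0 = background

            roi_feats = self._roi_features(pyramid, rois, self.box_head.roi_size)
            cls_logits, box_deltas = self.box_head(roi_feats)
            terms["roi_cls"].append(cross_entropy(cls_logits, roi_labels))
            fg = np.flatnonzero(roi_labels > 0)
            if len(fg):
                enc = encode_boxes(rois[fg], gt_boxes[roi_best[fg]])
                terms["roi_box"].append(smooth_l1(box_deltas[fg], enc))

                # --- mask + trait heads on foreground ROIs ---
                big_feats = self._roi_features(pyramid, rois[fg], 14)
                mask_logits = self.mask_head(big_feats)   # (F, 28, 28)
                msz = mask_logits.shape[-1]
                mtargets = []
                for fi, ri in enumerate(fg):
                    gt_mask = item["masks"][roi_best[ri]].astype(np.float32)
                    roi = np.concatenate([[0], rois[ri]])[None]
                    crop = Tensor(gt_mask[None, None]).roi_align(roi, msz, sampling=2)
                    mtargets.append((crop.data[0, 0] >= 0.5).astype(np.float32))
                terms["mask"].append(
                    bce_with_logits(mask_logits, np.stack(mtargets)))

                traits_pred = self.trait_head(big_feats)  # (F, 5)
                z = ((np.asarray(item["traits"], dtype=np.float64)
                      - self.trait_mean) / self.trait_std)
                ztgt = np.tile(z.astype(np.float32), (len(fg), 1))
                terms["trait"].append(smooth_l1(traits_pred, ztgt))

        def _mean(key):
            vals = terms[key]
            if not vals:
                return Tensor(np.zeros(()))
            out = vals[0]
            for v in vals[1:]:
                out = out + v
            return out * (1.0 / len(vals))

        parts = {k: _mean(k) for k in terms}
        total = parts["rpn_cls"]
        for k in ("rpn_box", "roi_cls", "roi_box", "mask", "trait"):
            total = total + parts[k]
        breakdown = LossBreakdown(**{k: float(parts[k].data) for k in parts})
        return total, breakdown

    # -- inference ------------------------------------------------------------
    def predict(self, rgb: np.ndarray, depth: np.ndarray,
                score_threshold: float = 0.5, nms_iou: float = 0.5,
                max_dets: int = 4, post_nms: int = 16) -> list:
        """Detect instances and regress traits on one RGB-D pair.

        Candidate boxes go through one delta refinement, are snapped to the
        bounding box of their predicted mask (the mask head, trained on
        jittered boxes, localises the plant outline more reliably than the
        delta regression alone), and are re-scored by the classifier on the
        snapped box.  The final score is the class confidence tempered by
        the proposal's objectness, which breaks ties between saturated
        class scores without sinking weak-objectness true positives.
        """
        from .geometry import mask_bbox

        self.eval()
        rgb_t, depth_t = self._prep_inputs(rgb, depth)
        image_shape = rgb.shape[:2]
        pyramid = self.extract_pyramid(rgb_t, depth_t)
        prop, obj_logits = self._proposals(pyramid, image_shape,
                                           post_nms=post_nms, nms_iou=0.7)
        if len(prop) == 0:
            return []
        objectness = 1.0 / (1.0 + np.exp(-obj_logits))
        roi_feats = self._roi_features(pyramid, prop, self.box_head.roi_size)
        _, box_deltas = self.box_head(roi_feats)
        boxes = decode_boxes(prop, box_deltas.data, clip_shape=image_shape)
        ok = ((boxes[:, 2] - boxes[:, 0] > 2)
              & (boxes[:, 3] - boxes[:, 1] > 2))
        boxes, objectness = boxes[ok], objectness[ok]
        if len(boxes) == 0:
            return []
        for i in range(len(boxes)):   # snap to the predicted mask footprint
            ml = self.mask_head(self._roi_features(pyramid,
                                                   boxes[i:i + 1], 14)).data[0]
            m = self._paste_mask(ml, boxes[i], image_shape)
            if m.any():
                boxes[i] = mask_bbox(m)
        cls_logits, _ = self.box_head(
            self._roi_features(pyramid, boxes, self.box_head.roi_size))
        z = cls_logits.data
        z = z - z.max(axis=1, keepdims=True)
        probs = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
        labels = probs[:, 1:].argmax(axis=1)
        scores = (probs[np.arange(len(boxes)), labels + 1]
                  * (0.5 + 0.5 * objectness))
        keepable = scores >= score_threshold
        boxes, scores, labels = boxes[keepable], scores[keepable], labels[keepable]
        if len(boxes) == 0:
            return []
        keep = nms(boxes, scores, nms_iou)[:max_dets]
        boxes, scores, labels = boxes[keep], scores[keep], labels[keep]

        big_feats = self._roi_features(pyramid, boxes, 14)
        mask_logits = self.mask_head(big_feats).data   # (R, 28, 28)
        # the trait head normalises over its ROI batch; evaluate it on the
        # kept boxes together with jittered copies so the batch statistics
        # match the multi-ROI batches it was trained on
        jit_rng = np.random.default_rng(0)
        sizes = np.maximum(boxes[:, 2:] - boxes[:, :2], 4.0)
        tbatch = [boxes]
        for frac in (0.05, 0.10, 0.15, 0.20):
            noise = jit_rng.normal(0, frac, boxes.shape) * np.tile(sizes, (1, 2))
            jb = boxes + noise
            jb[:, 0::2] = np.clip(jb[:, 0::2], 0, image_shape[1])
            jb[:, 1::2] = np.clip(jb[:, 1::2], 0, image_shape[0])
            ok_j = (jb[:, 2] - jb[:, 0] > 2) & (jb[:, 3] - jb[:, 1] > 2)
            tbatch.append(np.where(ok_j[:, None], jb, boxes))
        trait_boxes = np.concatenate(tbatch)
        traits_all = self.trait_head(
            self._roi_features(pyramid, trait_boxes, 14)).data
        traits_z = traits_all[:len(boxes)]             # (R, 5)
        preds = []
        for i in range(len(boxes)):
            mask = self._paste_mask(mask_logits[i], boxes[i], image_shape)
            traits = None
            if self.trait_mean is not None:
                raw = traits_z[i] * self.trait_std + self.trait_mean
                raw = np.clip(raw, 0, None)
                raw[1] = min(raw[1], raw[0])   # dw cannot exceed fw
                traits = TraitVector.from_array(raw)
            preds.append(InstancePrediction(
                box=boxes[i], label=self.class_names[labels[i]],
                score=float(scores[i]), mask=mask, traits=traits))
        return preds

    @staticmethod
    def _paste_mask(logits: np.ndarray, box: np.ndarray, image_shape) -> np.ndarray:
        h, w = image_shape
        x0, y0 = int(np.floor(box[0])), int(np.floor(box[1]))
        x1, y1 = int(np.ceil(box[2])), int(np.ceil(box[3]))
        x0, y0 = max(x0, 0), max(y0, 0)
        x1, y1 = min(x1, w), min(y1, h)
        out = np.zeros((h, w), dtype=bool)
        if x1 <= x0 or y1 <= y0:
            return out
        prob = 1.0 / (1.0 + np.exp(-logits))
        img = Image.fromarray(prob.astype(np.float32))
        resized = np.asarray(img.resize((x1 - x0, y1 - y0), Image.BILINEAR))
        out[y0:y1, x0:x1] = resized >= 0.5
        return out


def count_parameters(module: nn.Module) -> int:
    return module.num_parameters(trainable_only=False)
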