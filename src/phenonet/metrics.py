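"""Detection/segmentation metrics (COCO AP/AR, F1) and trait regression
metrics (R2, MAPE, NRMSE), with K-fold aggregation.

The COCO protocol is implemented directly: greedy score-ordered matching per
category and IoU threshold, 101-point interpolated average precision, AP
averaged over the ten IoU thresholds 0.50:0.05:0.95, and average recall at a
maximum number of detections.  Instances carry half-open pixel boxes and,
for mask IoU, binary masks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import box_iou, mask_iou

IOU_THRESHOLDS = np.round(np.arange(0.5, 1.0, 0.05), 2)


# ---------------------------------------------------------------------------
# trait regression metrics
# ---------------------------------------------------------------------------

def r2(y_true, y_pred) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot."""
    y, yp = np.asarray(y_true, float), np.asarray(y_pred, float)
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("y_true is constant; R2 undefined")
    ss_res = float(((y - yp) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def mape(y_true, y_pred) -> float:
    """Mean absolute percentage error, reported as a fraction (0.10 = 10%)."""
    y, yp = np.asarray(y_true, float), np.asarray(y_pred, float)
    if np.any(y == 0):
        raise ValueError("y_true contains zeros; MAPE undefined")
    return float(np.mean(np.abs(y - yp) / np.abs(y)))


def nrmse(y_true, y_pred) -> float:
    """Root-mean-square error normalised by the true-value range."""
    y, yp = np.asarray(y_true, float), np.asarray(y_pred, float)
    rng = float(y.max() - y.min())
    if rng == 0:
        raise ValueError("y_true has zero range; NRMSE undefined")
    return float(np.sqrt(np.mean((yp - y) ** 2)) / rng)


def f1(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 (with a warning) if both are 0."""
    if not (0 <= precision <= 1 and 0 <= recall <= 1):
        raise ValueError("precision and recall must be in [0, 1]")
    if precision == 0 and recall == 0:
        warnings.warn("precision and recall both zero; F1 defined as 0",
                      RuntimeWarning, stacklevel=2)
        return 0.0
    return 2 * precision * recall / (precision + recall)


# ---------------------------------------------------------------------------
# COCO-style AP / AR
# ---------------------------------------------------------------------------

def _pair_iou(det, gt, iou_type: str) -> float:
    if iou_type == "mask":
        return mask_iou(det["mask"], gt["mask"])
    return float(box_iou(det["box"], gt["box"])[0, 0])


def _match_category(dets, gts, thr: float, iou_type: str):
    """Greedy COCO matching: dets in score order take the best unmatched GT.

    Returns boolean TP flags aligned with score-sorted dets.
    """
    matched = [False] * len(gts)
    tp = np.zeros(len(dets), dtype=bool)
    for di, det in enumerate(dets):
        best_iou, best_gi = thr, -1
        for gi, gt in enumerate(gts):
            if matched[gi] or gt["image_id"] != det["image_id"]:
                continue
            iou = _pair_iou(det, gt, iou_type)
            if iou >= best_iou:
                best_iou, best_gi = iou, gi
        if best_gi >= 0:
            matched[best_gi] = True
            tp[di] = True
    return tp


def _ap_101(tp: np.ndarray, n_gt: int) -> float:
    """101-point interpolated AP from score-ordered TP flags."""
    if n_gt == 0:
        return float("nan")
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(~tp)
    recall = cum_tp / n_gt
    precision = cum_tp / np.maximum(cum_tp + cum_fp, 1)
    # precision envelope (max to the right)
    prec_env = np.maximum.accumulate(precision[::-1])[::-1] if len(precision) else precision
    rec_pts = np.linspace(0, 1, 101)
    ap = 0.0
    for r in rec_pts:
        idx = np.searchsorted(recall, r, side="left")
        ap += prec_env[idx] if idx < len(prec_env) else 0.0
    return ap / 101.0


def coco_eval(predictions, ground_truth, iou_type: str = "box",
              max_dets: int = 100, per_class: bool = False) -> dict:
    """COCO-protocol AP/AR over instances.

    predictions: dicts with image_id, category, score, box, [mask].
    ground_truth: dicts with image_id, category, box, [mask].
    Returns AP50:95, AP50, AP75, AR (and optionally a per-class breakdown).
    """
    if iou_type not in ("box", "mask"):
        raise ValueError("iou_type must be 'box' or 'mask'")
    if not ground_truth:
        raise ValueError("empty ground truth")
    categories = sorted({g["category"] for g in ground_truth})
    # per-image max_dets cap, by score
    capped = []
    for img in sorted({p["image_id"] for p in predictions}):
        img_dets = sorted([p for p in predictions if p["image_id"] == img],
                          key=lambda p: -p["score"])
        capped.extend(img_dets[:max_dets])

    ap_per_thr_cat = {}
    recall_per_thr_cat = {}
    for cat in categories:
        gts = [g for g in ground_truth if g["category"] == cat]
        dets = sorted([p for p in capped if p["category"] == cat],
                      key=lambda p: -p["score"])
        for thr in IOU_THRESHOLDS:
            tp = _match_category(dets, gts, thr, iou_type)
            ap_per_thr_cat[(thr, cat)] = _ap_101(tp, len(gts))
            recall_per_thr_cat[(thr, cat)] = (tp.sum() / len(gts)) if gts else np.nan

    def _mean(d, thr=None):
        vals = [v for (t, c), v in d.items() if thr is None or t == thr]
        return float(np.mean(vals))

    out = {
        "AP50:95": _mean(ap_per_thr_cat),
        "AP50": _mean(ap_per_thr_cat, 0.5),
        "AP75": _mean(ap_per_thr_cat, 0.75),
        "AR": _mean(recall_per_thr_cat),
    }
    if per_class:
        out["per_class"] = {
            cat: {
                "AP50:95": float(np.mean([v for (t, c), v in ap_per_thr_cat.items()
                                          if c == cat])),
                "AR": float(np.mean([v for (t, c), v in recall_per_thr_cat.items()
                                     if c == cat])),
            }
            for cat in categories
        }
    return out


def detection_f1(predictions, ground_truth, iou_type: str = "box",
                 iou_threshold: float = 0.5, score_threshold: float = 0.5) -> float:
    """F1 at a fixed operating point (default IoU 0.5, score 0.5)."""
    dets = sorted([p for p in predictions if p["score"] >= score_threshold],
                  key=lambda p: -p["score"])
    # class-aware greedy matching at the single threshold
    tp_total = 0
    for cat in sorted({g["category"] for g in ground_truth}):
        gts = [g for g in ground_truth if g["category"] == cat]
        cat_dets = [p for p in dets if p["category"] == cat]
        tp = _match_category(cat_dets, gts, iou_threshold, iou_type)
        tp_total += int(tp.sum())
    n_det, n_gt = len(dets), len(ground_truth)
    precision = tp_total / n_det if n_det else 0.0
    recall = tp_total / n_gt if n_gt else 0.0
    return f1(precision, recall)


# ---------------------------------------------------------------------------
# COCO-style export
# ---------------------------------------------------------------------------

def _mask_to_rle(mask: np.ndarray) -> dict:
    """Uncompressed column-major run-length encoding (COCO convention)."""
    flat = np.asarray(mask, dtype=bool).T.ravel()
    counts, run, current = [], 0, False
    for v in flat:
        if v == current:
            run += 1
        else:
            counts.append(run)
            run, current = 1, v
    counts.append(run)
    return {"size": [int(mask.shape[0]), int(mask.shape[1])],
            "counts": counts}


def export_coco_results(predictions, path) -> None:
    """Write predictions as a COCO-style result JSON (xywh boxes, RLE masks)."""
    import json

    out = []
    for p in predictions:
        x0, y0, x1, y1 = [float(v) for v in p["box"]]
        rec = {"image_id": p["image_id"], "category_id": int(p["category"]),
               "bbox": [x0, y0, x1 - x0, y1 - y0],
               "score": float(p["score"])}
        if p.get("mask") is not None:
            rec["segmentation"] = _mask_to_rle(p["mask"])
        out.append(rec)
    with open(path, "w") as fh:
        json.dump(out, fh)


# ---------------------------------------------------------------------------
# K-fold aggregation and reports
# ---------------------------------------------------------------------------

def aggregate_folds(fold_values, ndigits: int | None = None):
    """Arithmetic mean and sample (n-1) standard deviation across folds."""
    vals = np.asarray(list(fold_values), dtype=float)
    if vals.size < 2:
        raise ValueError("need at least 2 fold values")
    mean = float(vals.mean())
    std = float(vals.std(ddof=1))
    if ndigits is not None:
        mean, std = round(mean, ndigits), round(std, ndigits)
    return mean, std


@dataclass
class EvalReport:
    """Per-fold and aggregated metrics for one cross-validation run.

    folds: list of flat {metric_name: value} dicts, one per fold.  Metric
    names follow ``det/AP50:95``-style and ``trait/fw/r2``-style keys.
    """

    folds: list = field(default_factory=list)

    def add_fold(self, metrics: dict):
        self.folds.append(dict(metrics))

    def metric_names(self):
        names = []
        for f in self.folds:
            for k in f:
                if k not in names:
                    names.append(k)
        return names

    def aggregate(self, ndigits: int | None = 4) -> dict:
        out = {}
        for name in self.metric_names():
            vals = [f[name] for f in self.folds if name in f]
            if len(vals) >= 2:
                mean, std = aggregate_folds(vals, ndigits=ndigits)
            else:
                mean, std = (round(vals[0], ndigits) if ndigits else vals[0]), None
            out[name] = {"mean": mean, "std": std}
        return out

    def to_frame(self):
        import pandas as pd
        rows = []
        for i, f in enumerate(self.folds):
            rows.append({"fold": f"k{i + 1}", **f})
        agg = self.aggregate()
        rows.append({"fold": "average",
                     **{k: v["mean"] for k, v in agg.items()}})
        rows.append({"fold": "std_dev",
                     **{k: v["std"] for k, v in agg.items()}})
        return pd.DataFrame(rows)
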