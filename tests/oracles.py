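"""Independent straight-line/brute-force reference implementations used to
cross-check the network modules.  Everything here is plain numpy with
explicit loops — deliberately free of the package's autodiff tensor ops."""

import numpy as np


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def silu(x):
    return x * sigmoid(x)


# ---------------------------------------------------------------------------
# feature-rectification equations
# ---------------------------------------------------------------------------

def frm_channel_weights_oracle(frm, f_rgb, f_d):
    """Channel-weight path computed as a straight line of pooled MLPs."""
    n, c = f_rgb.shape[:2]
    stacked = np.concatenate([f_rgb, f_d], axis=1)           # (N, 2C, H, W)
    w_avg = stacked.mean(axis=(2, 3))                        # (N, 2C)
    w_max = stacked.max(axis=(2, 3))
    pooled = np.concatenate([w_avg, w_max], axis=1)          # (N, 4C)
    h = silu(pooled @ frm.fc1.weight.data.T + frm.fc1.bias.data)
    w = sigmoid(h @ frm.fc2.weight.data.T + frm.fc2.bias.data)
    return w[:, :c], w[:, c:]


def conv1x1_oracle(x, weight, bias):
    """Pointwise convolution as an explicit loop."""
    n, cin, h, w = x.shape
    cout = weight.shape[0]
    out = np.zeros((n, cout, h, w))
    for b in range(n):
        for o in range(cout):
            acc = np.zeros((h, w))
            for i in range(cin):
                acc += weight[o, i, 0, 0] * x[b, i]
            out[b, o] = acc + bias[o]
    return out


def frm_spatial_weights_oracle(frm, f_rgb, f_d):
    stacked = np.concatenate([f_rgb, f_d], axis=1)
    h = silu(conv1x1_oracle(stacked, frm.sconv1.weight.data, frm.sconv1.bias.data))
    w = sigmoid(conv1x1_oracle(h, frm.sconv2.weight.data, frm.sconv2.bias.data))
    return w[:, 0:1], w[:, 1:2]


def frm_forward_oracle(frm, f_rgb, f_d):
    """Full rectification with explicit per-element loops."""
    w_rgb_c, w_d_c = frm_channel_weights_oracle(frm, f_rgb, f_d)
    w_rgb_s, w_d_s = frm_spatial_weights_oracle(frm, f_rgb, f_d)
    n, c, hh, ww = f_rgb.shape
    out_rgb = np.zeros_like(f_rgb)
    out_d = np.zeros_like(f_d)
    for b in range(n):
        for ch in range(c):
            for i in range(hh):
                for j in range(ww):
                    out_rgb[b, ch, i, j] = (
                        f_rgb[b, ch, i, j]
                        + 0.5 * f_d[b, ch, i, j] * w_d_c[b, ch]
                        + 0.5 * f_d[b, ch, i, j] * w_d_s[b, 0, i, j])
                    out_d[b, ch, i, j] = (
                        f_d[b, ch, i, j]
                        + 0.5 * f_rgb[b, ch, i, j] * w_rgb_c[b, ch]
                        + 0.5 * f_rgb[b, ch, i, j] * w_rgb_s[b, 0, i, j])
    return out_rgb, out_d


# ---------------------------------------------------------------------------
# squeeze-and-excitation fusion
# ---------------------------------------------------------------------------

def se_weights_oracle(se, f):
    g = f.mean(axis=(2, 3))
    h = silu(g @ se.fc1.weight.data.T + se.fc1.bias.data)
    return sigmoid(h @ se.fc2.weight.data.T + se.fc2.bias.data)


def bn_eval_oracle(bn, x):
    m = bn.running_mean.reshape(1, -1, 1, 1)
    v = bn.running_var.reshape(1, -1, 1, 1)
    g = bn.weight.data.reshape(1, -1, 1, 1)
    b = bn.bias.data.reshape(1, -1, 1, 1)
    return (x - m) / np.sqrt(v + bn.eps) * g + b


def sef_forward_oracle(sef, f_rgb, f_d):
    """Fusion straight line; the SCConv operator is used as a fixed callable."""
    from phenonet.nn import Tensor

    w_rgb = se_weights_oracle(sef.se_rgb, f_rgb)[:, :, None, None]
    w_d = se_weights_oracle(sef.se_d, f_d)[:, :, None, None]
    w_mid = f_rgb * w_d + f_d * w_rgb
    sc = sef.scconv(Tensor(w_mid.astype(np.float32))).data.astype(np.float64)
    main = conv1x1_oracle(sc, sef.conv.weight.data, sef.conv.bias.data)
    main = silu(bn_eval_oracle(sef.bn_main, main))
    return main + bn_eval_oracle(sef.bn_skip, w_mid)


def sru_forward_oracle(sru, x):
    """Hand-rolled spatial reconstruction unit (matches the module contract)."""
    n, c, h, w = x.shape
    g = sru.gn.groups
    xg = x.reshape(n, g, -1)
    m = xg.mean(axis=2, keepdims=True)
    v = ((xg - m) ** 2).mean(axis=2, keepdims=True)
    gn_x = ((xg - m) / np.sqrt(v + sru.gn.eps)).reshape(n, c, h, w)
    gn_x = gn_x * sru.gn.weight.data.reshape(1, c, 1, 1) \
        + sru.gn.bias.data.reshape(1, c, 1, 1)
    gamma = sru.gn.weight.data
    w_gamma = gamma / (np.abs(gamma).sum() + 1e-12)
    rew = sigmoid(gn_x * w_gamma.reshape(1, c, 1, 1))
    info = (rew >= sru.gate_threshold).astype(float)
    x1 = rew * info * gn_x
    x2 = rew * (1 - info) * gn_x
    half = c // 2
    return np.concatenate([x1[:, :half] + x2[:, half:],
                           x1[:, half:] + x2[:, :half]], axis=1)


# ---------------------------------------------------------------------------
# convolution / transposed convolution
# ---------------------------------------------------------------------------

def conv2d_oracle(x, weight, bias=None, stride=1, padding=1):
    n, cin, h, w = x.shape
    cout, _, kh, kw = weight.shape
    xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    ho = (h + 2 * padding - kh) // stride + 1
    wo = (w + 2 * padding - kw) // stride + 1
    out = np.zeros((n, cout, ho, wo))
    for b in range(n):
        for o in range(cout):
            for i in range(ho):
                for j in range(wo):
                    patch = xp[b, :, i * stride:i * stride + kh,
                               j * stride:j * stride + kw]
                    out[b, o, i, j] = (patch * weight[o]).sum()
            if bias is not None:
                out[b, o] += bias[o]
    return out


def conv_transpose2d_oracle(x, weight, bias=None, stride=2, padding=0):
    n, cin, h, w = x.shape
    _, cout, kh, kw = weight.shape
    hf, wf = (h - 1) * stride + kh, (w - 1) * stride + kw
    out = np.zeros((n, cout, hf, wf))
    for b in range(n):
        for c in range(cin):
            for i in range(h):
                for j in range(w):
                    out[b, :, i * stride:i * stride + kh,
                        j * stride:j * stride + kw] += x[b, c, i, j] * weight[c]
    out = out[:, :, padding:hf - padding, padding:wf - padding]
    if bias is not None:
        out += bias.reshape(1, -1, 1, 1)
    return out


# ---------------------------------------------------------------------------
# COCO protocol on toy scenes
# ---------------------------------------------------------------------------

def coco_toy_oracle(predictions, ground_truth, iou_fn):
    """Exhaustive re-walk of the matching / precision-recall protocol for
    tiny scenes.  iou_fn(det, gt) -> float."""
    thresholds = np.round(np.arange(0.5, 1.0, 0.05), 2)
    cats = sorted({g["category"] for g in ground_truth})
    aps, recalls = [], []
    for cat in cats:
        gts = [g for g in ground_truth if g["category"] == cat]
        dets = sorted([p for p in predictions if p["category"] == cat],
                      key=lambda p: -p["score"])
        for thr in thresholds:
            used = set()
            tps = []
            for det in dets:
                best, best_g = thr, None
                for gi, gt in enumerate(gts):
                    if gi in used or gt["image_id"] != det["image_id"]:
                        continue
                    iou = iou_fn(det, gt)
                    if iou >= best:
                        best, best_g = iou, gi
                if best_g is not None:
                    used.add(best_g)
                    tps.append(True)
                else:
                    tps.append(False)
            # precision-recall sweep, 101-point interpolation
            tp = fp = 0
            pr = []
            for flag in tps:
                tp += flag
                fp += not flag
                pr.append((tp / len(gts), tp / (tp + fp)))
            ap = 0.0
            for r in np.linspace(0, 1, 101):
                best_p = 0.0
                for rec, prec in pr:
                    if rec >= r - 1e-12:
                        best_p = max(best_p, prec)
                # envelope: max precision at any recall >= r
                ap += best_p
            aps.append(ap / 101)
            recalls.append(tp / len(gts))
    return {"AP50:95": float(np.mean(aps)),
            "AR": float(np.mean(recalls))}
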