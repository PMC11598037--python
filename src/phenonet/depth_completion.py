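"""Classical, training-free hole filling of raw depth maps.

The pipeline runs in *inverted* depth space (v -> 100 - v) so that every
morphological fill takes the neighbourhood maximum of inverted depth, i.e.
the *nearest* surface.  In a near/far ambiguity the completed pixel is
therefore biased to the foreground object, which is the right prior for a
top-down camera looking at a plant over soil.

Steps, in order: invert; fill-dilation with a 5x5 diamond (rhombic) kernel;
small-hole closure (grey closing, full kernel); small-hole fill-dilation
(medium full kernel); per-column extension of the topmost valid value to the
frame top; iterated large-kernel fill-dilation until dense; median blur;
Gaussian blur; revert.  Every morphological step only writes missing
pixels, so with blurs disabled valid measurements pass through exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

MAX_DEPTH = 100.0
_EPS = 1e-3


def diamond_kernel(size: int = 5) -> np.ndarray:
    """Rhombic (L1-ball) footprint."""
    r = size // 2
    y, x = np.ogrid[-r:r + 1, -r:r + 1]
    return (np.abs(y) + np.abs(x)) <= r


@dataclass
class DepthImage:
    """Single-channel depth grid in meters; 0.0 encodes a missing pixel.

    `valid` distinguishes a saturated measurement at (or clamped near) zero
    in inverted space from a genuinely missing pixel.
    """

    values: np.ndarray
    valid: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 2:
            raise ValueError("depth must be a 2-D grid")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("depth contains non-finite values")
        if np.any(self.values < 0):
            raise ValueError("depth contains negative values")
        if self.valid is None:
            self.valid = self.values > 0
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.values.shape:
                raise ValueError("valid mask shape mismatch")

    @property
    def n_missing(self) -> int:
        return int((~self.valid).sum())


@dataclass
class CompletionOptions:
    """Kernel sizes of the completion pipeline.

    Only the initial 5x5 diamond is prescribed by the method; the remaining
    sizes are conventional fast-completion defaults and are all adjustable.
    """

    dilation_kernel: int = 5        # diamond, the prescribed first fill
    closure_kernel: int = 5         # full, small-hole closure
    small_fill_kernel: int = 7      # full, small-hole fill
    large_fill_kernel: int = 17     # full, iterated until dense
    median_kernel: int = 5
    gaussian_kernel: int = 5
    blur: bool = True

    @property
    def gaussian_sigma(self) -> float:
        k = self.gaussian_kernel
        return 0.3 * ((k - 1) * 0.5 - 1) + 0.8


def invert_depth(d: DepthImage) -> DepthImage:
    """Map valid pixels v -> 100 - v; missing pixels stay missing.

    Valid input is clamped to [eps, 100 - eps] first so a saturated reading
    at exactly 100 m cannot collide with the missing-pixel sentinel.
    """
    v = d.values
    if np.any(v[d.valid] > MAX_DEPTH):
        raise ValueError(f"depth values exceed {MAX_DEPTH}")
    out = np.zeros_like(v)
    clamped = np.clip(v[d.valid], _EPS, MAX_DEPTH - _EPS)
    out[d.valid] = MAX_DEPTH - clamped
    return DepthImage(out, valid=d.valid.copy())


def _fill_dilate(values: np.ndarray, valid: np.ndarray, footprint: np.ndarray):
    """Fill missing pixels with the footprint max over valid neighbours."""
    work = np.where(valid, values, -np.inf)
    dil = ndimage.maximum_filter(work, footprint=footprint, mode="nearest")
    newly = (~valid) & np.isfinite(dil)
    values = values.copy()
    values[newly] = dil[newly]
    return values, valid | newly


def complete_depth(d: DepthImage, opts: CompletionOptions | None = None) -> DepthImage:
    """Run the full completion pipeline; output has zero missing pixels."""
    opts = opts or CompletionOptions()
    if not d.valid.any():
        raise ValueError("no valid pixels")
    inv = invert_depth(d)
    v, valid = inv.values.copy(), inv.valid.copy()

    # 1. prescribed diamond-kernel fill
    v, valid = _fill_dilate(v, valid, diamond_kernel(opts.dilation_kernel))

    # 2. small hole closure, applied fill-only: the closing of the
    #    zero-filled field bridges residual small holes, but measured pixels
    #    are never overwritten (border artifacts of a full closing would
    #    corrupt valid readings)
    k = opts.closure_kernel
    closed = ndimage.grey_closing(np.where(valid, v, 0.0), size=(k, k),
                                  mode="nearest")
    newly = (~valid) & (closed > 0)
    v = v.copy()
    v[newly] = closed[newly]
    valid = valid | newly

    # 3. small hole fill
    v, valid = _fill_dilate(
        v, valid, np.ones((opts.small_fill_kernel,) * 2, dtype=bool))

    # 4. extend topmost valid value to the top of the frame
    has_any = valid.any(axis=0)
    top_idx = np.argmax(valid, axis=0)
    rows = np.arange(v.shape[0])[:, None]
    above = (rows < top_idx[None, :]) & has_any[None, :]
    v = np.where(above, v[top_idx, np.arange(v.shape[1])][None, :], v)
    valid = valid | above

    # 5. iterated large-kernel fill until dense
    big = np.ones((opts.large_fill_kernel,) * 2, dtype=bool)
    while not valid.all():
        v, new_valid = _fill_dilate(v, valid, big)
        if new_valid.sum() == valid.sum():  # pragma: no cover - unreachable
            raise RuntimeError("completion stalled")
        valid = new_valid

    # 6. blurs
    if opts.blur:
        v = ndimage.median_filter(v, size=opts.median_kernel, mode="nearest")
        sigma = opts.gaussian_sigma
        truncate = (opts.gaussian_kernel - 1) / 2 / sigma
        v = ndimage.gaussian_filter(v, sigma=sigma, truncate=truncate,
                                    mode="nearest")

    out = (MAX_DEPTH - v).astype(np.float32)
    return DepthImage(out, valid=np.ones_like(valid))
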