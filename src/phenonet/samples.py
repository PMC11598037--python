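"""Core sample containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The four lettuce varieties of the greenhouse benchmark, in canonical order.
VARIETIES = ("Lugano", "Salanova", "Aphylion", "Satine")

#: Trait column order used everywhere (CSV, vectors, reports).
TRAIT_NAMES = ("fw", "dw", "h", "d", "la")


@dataclass(frozen=True)
class TraitVector:
    """Plant-level phenotypic traits.

    fw/dw are fresh and dry mass in g/plant, h is plant height in cm, d is
    canopy diameter in cm, la is leaf area in cm^2.  All are nonnegative and
    dry weight can never exceed fresh weight.
    """

    fw: float
    dw: float
    h: float
    d: float
    la: float

    def __post_init__(self):
        vals = self.as_array()
        if np.any(vals < 0) or not np.all(np.isfinite(vals)):
            raise ValueError(f"traits must be finite and nonnegative, got {vals}")
        if self.dw > self.fw:
            raise ValueError(f"dry weight {self.dw} exceeds fresh weight {self.fw}")

    def as_array(self) -> np.ndarray:
        return np.array([self.fw, self.dw, self.h, self.d, self.la], dtype=np.float64)

    @staticmethod
    def from_array(a) -> "TraitVector":
        a = np.asarray(a, dtype=np.float64)
        return TraitVector(*[float(v) for v in a])


@dataclass
class Instance:
    """One annotated plant: a polygon outline and its variety label."""

    polygon: np.ndarray  # (V, 2) float, 0-based (x, y) pixel coordinates
    label: str

    def __post_init__(self):
        self.polygon = np.asarray(self.polygon, dtype=np.float64)
        if self.polygon.ndim != 2 or self.polygon.shape[1] != 2 or len(self.polygon) < 3:
            raise ValueError("polygon must be (V>=3, 2)")
        if self.label not in VARIETIES:
            raise ValueError(f"unknown variety {self.label!r}")


@dataclass
class AnnotatedSample:
    """RGB image + depth map + instance annotations + traits for one plant."""

    image_id: str
    rgb: np.ndarray                 # (H, W, 3) uint8
    depth: np.ndarray               # (H, W) float32 meters, 0 = missing
    instances: list                 # list[Instance], >= 1
    traits: TraitVector | None = None
    raw_depth: np.ndarray | None = None   # hole-corrupted depth, if distinct
    mask: np.ndarray | None = None        # (H, W) bool rendering of instance 0

    def __post_init__(self):
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise ValueError("rgb must be HxWx3")
        if self.depth.shape != self.rgb.shape[:2]:
            raise ValueError("rgb and depth must share H, W")
        if not self.instances:
            raise ValueError("sample needs at least one instance")
        h, w = self.rgb.shape[:2]
        for inst in self.instances:
            poly = inst.polygon
            if (poly[:, 0].min() < -0.5 or poly[:, 0].max() > w - 0.5
                    or poly[:, 1].min() < -0.5 or poly[:, 1].max() > h - 0.5):
                raise ValueError(f"polygon outside image bounds for {self.image_id}")

    @property
    def height(self) -> int:
        return self.rgb.shape[0]

    @property
    def width(self) -> int:
        return self.rgb.shape[1]
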