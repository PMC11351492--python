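"""Color-threshold segmentation of stained fibers.

Stained tissue classes (fibrous ECM, nuclei, artifact structures)
separate primarily by hue under brightfield illumination, so
segmentation is done by per-class hue/saturation/value box thresholds
in cylindrical HSV space, followed by a small morphological opening of
the fiber mask. Per-stain default profiles are shipped as configuration,
calibrated against the synthetic renderer's palettes, and are meant to
be overridden for real material. A file-based manual-override mask can
reassign any pixel's class, mirroring the manual correction step of an
interactive workflow.

Class-map label convention: 0 = background, 1 = fiber, 2 = nucleus,
3 = artifact (structures excluded from fiber analysis).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from skimage import measure, morphology
from skimage.color import rgb2hsv
from sklearn.base import BaseEstimator

from .image import StainImage
from .palettes import CLASS_DISPLAY_COLORS

__all__ = [
    "HSVRange",
    "StainProfile",
    "SegmentationResult",
    "ComponentTable",
    "StainSegmenter",
    "segment_stain",
    "apply_overrides",
    "label_components",
    "default_profile",
]

BACKGROUND, FIBER, NUCLEUS, ARTIFACT = 0, 1, 2, 3

# Override-mask codes (single-channel PNG): 0 leaves the pixel unchanged.
OVERRIDE_SENTINEL = 0
_OVERRIDE_TO_CLASS = {1: BACKGROUND, 2: FIBER, 3: NUCLEUS, 4: ARTIFACT}


@dataclass
class HSVRange:
    """A box in HSV space; the hue interval may wrap around 0.

    All bounds are on [0, 1]. ``h=(0.9, 0.1)`` selects reds across the
    hue seam; saturation and value intervals must have low <= high.
    """

    h: tuple[float, float]
    s: tuple[float, float] = (0.0, 1.0)
    v: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        for name, (lo, hi) in (("h", self.h), ("s", self.s), ("v", self.v)):
            if not (0 <= lo <= 1 and 0 <= hi <= 1):
                raise ValueError(f"{name} bounds must lie in [0, 1]")
        if self.s[0] > self.s[1] or self.v[0] > self.v[1]:
            raise ValueError("s and v ranges must have low <= high")

    def contains(self, hsv: np.ndarray) -> np.ndarray:
        h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
        lo, hi = self.h
        if lo <= hi:
            in_h = (h >= lo) & (h <= hi)
        else:  # wrapped hue interval
            in_h = (h >= lo) | (h <= hi)
        return (
            in_h
            & (s >= self.s[0])
            & (s <= self.s[1])
            & (v >= self.v[0])
            & (v <= self.v[1])
        )


@dataclass
class StainProfile:
    """Per-class HSV threshold ranges for one stain type."""

    stain_type: str
    fiber: HSVRange
    nucleus: HSVRange
    artifact: Optional[HSVRange] = None

    def to_dict(self) -> dict:
        d = {"stain_type": self.stain_type}
        for cls in ("fiber", "nucleus", "artifact"):
            rng = getattr(self, cls)
            if rng is not None:
                d[cls] = {"h": list(rng.h), "s": list(rng.s), "v": list(rng.v)}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StainProfile":
        def mk(key):
            if key not in d:
                return None
            r = d[key]
            return HSVRange(h=tuple(r["h"]), s=tuple(r["s"]), v=tuple(r["v"]))

        return cls(
            stain_type=d["stain_type"],
            fiber=mk("fiber"),
            nucleus=mk("nucleus"),
            artifact=mk("artifact"),
        )

    @classmethod
    def from_json(cls, path) -> "StainProfile":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


_ARTIFACT_RANGE = HSVRange(h=(0.15, 0.45), s=(0.10, 0.80), v=(0.30, 0.85))

#: Default per-stain profiles, calibrated on the synthetic render palettes.
DEFAULT_PROFILES: dict[str, StainProfile] = {
    "he": StainProfile(
        stain_type="he",
        fiber=HSVRange(h=(0.85, 0.08), s=(0.20, 1.0), v=(0.25, 0.97)),
        nucleus=HSVRange(h=(0.58, 0.82), s=(0.25, 1.0), v=(0.20, 0.92)),
        artifact=_ARTIFACT_RANGE,
    ),
    "mallory": StainProfile(
        stain_type="mallory",
        fiber=HSVRange(h=(0.54, 0.70), s=(0.30, 1.0), v=(0.30, 0.97)),
        nucleus=HSVRange(h=(0.72, 0.88), s=(0.25, 1.0), v=(0.30, 0.95)),
        artifact=_ARTIFACT_RANGE,
    ),
    "silver": StainProfile(
        stain_type="silver",
        # argyrophilic fibers are near-black: select by low value alone
        fiber=HSVRange(h=(0.0, 1.0), s=(0.0, 1.0), v=(0.0, 0.35)),
        nucleus=HSVRange(h=(0.58, 0.82), s=(0.25, 1.0), v=(0.40, 0.92)),
        artifact=_ARTIFACT_RANGE,
    ),
    "weigert_orcein": StainProfile(
        stain_type="weigert_orcein",
        fiber=HSVRange(h=(0.80, 0.97), s=(0.20, 0.90), v=(0.18, 0.75)),
        nucleus=HSVRange(h=(0.58, 0.78), s=(0.25, 1.0), v=(0.40, 0.92)),
        artifact=_ARTIFACT_RANGE,
    ),
}


def default_profile(stain_type: str) -> StainProfile:
    """The shipped HSV threshold profile for *stain_type*."""
    try:
        return DEFAULT_PROFILES[stain_type]
    except KeyError:
        raise ValueError(f"no default profile for stain_type {stain_type!r}") from None


@dataclass
class SegmentationResult:
    """Per-pixel class labels plus the derived binary fiber mask."""

    class_map: np.ndarray  # H x W uint8 in {0..3}
    fiber_mask: np.ndarray  # class_map == FIBER

    def class_counts(self) -> dict[int, int]:
        vals, counts = np.unique(self.class_map, return_counts=True)
        out = {int(c): 0 for c in (BACKGROUND, FIBER, NUCLEUS, ARTIFACT)}
        out.update({int(v): int(c) for v, c in zip(vals, counts)})
        return out

    def display_rgb(self) -> np.ndarray:
        """Render the class map in the red-fiber / blue-nucleus /
        green-artifact display convention."""
        out = np.zeros(self.class_map.shape + (3,), dtype=np.uint8)
        for cls, color in CLASS_DISPLAY_COLORS.items():
            out[self.class_map == cls] = color
        return out


@dataclass
class ComponentTable:
    """Per-bundle records plus the labeled image they index into.

    ``table`` columns: ``component_id``, ``area_px``, ``centroid_row``,
    ``centroid_col`` and, once widths are measured,
    ``max_thickness_px``. Rows are sorted by descending area, ties
    broken by the component's top-left-most pixel in row-major order,
    and ``component_id`` is assigned 1..n in that order. ``labels`` uses
    the same ids (0 = background).
    """

    table: pd.DataFrame
    labels: np.ndarray

    def __len__(self) -> int:
        return len(self.table)

    @property
    def areas(self) -> np.ndarray:
        return self.table["area_px"].to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


class StainSegmenter(BaseEstimator):
    """HSV color-threshold segmenter for stained micrographs.

    A stateless scikit-learn-style transformer: ``fit`` only resolves
    the profile (no learning from data), ``transform`` maps an RGB
    micrograph to a :class:`SegmentationResult`. Pixel classes are
    assigned with precedence nucleus > artifact > fiber, so the fiber
    class is exactly "inside the fiber color ranges and outside the
    nucleus (and artifact) ranges"; the fiber mask then receives a
    morphological opening with a disk of ``opening_radius`` pixels
    (``0`` disables cleanup).
    """

    def __init__(
        self,
        stain_type: str = "he",
        profile: Optional[StainProfile] = None,
        opening_radius: int = 1,
    ):
        self.stain_type = stain_type
        self.profile = profile
        self.opening_radius = opening_radius

    def _resolved_profile(self) -> StainProfile:
        prof = self.profile if self.profile is not None else default_profile(self.stain_type)
        if prof.stain_type != self.stain_type:
            raise ValueError(
                f"profile is for stain {prof.stain_type!r} but segmenter is "
                f"configured for {self.stain_type!r}"
            )
        return prof

    def fit(self, X=None, y=None):
        self.profile_ = self._resolved_profile()
        return self

    def transform(self, X) -> SegmentationResult:
        if not hasattr(self, "profile_"):
            self.fit()
        if isinstance(X, StainImage):
            if X.stain_type != self.stain_type:
                raise ValueError(
                    f"image stain {X.stain_type!r} does not match segmenter "
                    f"stain {self.stain_type!r}"
                )
            px = X.pixels
        else:
            px = np.asarray(X)
        if px.ndim != 3 or px.shape[-1] != 3:
            raise ValueError(f"expected an H x W x 3 RGB image, got shape {px.shape}")
        if px.dtype != np.uint8:
            raise ValueError(f"expected 8-bit/channel RGB input, got dtype {px.dtype}")

        hsv = rgb2hsv(px)
        prof = self.profile_
        nucleus = prof.nucleus.contains(hsv)
        artifact = np.zeros_like(nucleus)
        if prof.artifact is not None:
            artifact = prof.artifact.contains(hsv) & ~nucleus
        fiber = prof.fiber.contains(hsv) & ~nucleus & ~artifact
        if self.opening_radius > 0:
            fiber = morphology.opening(fiber, morphology.disk(self.opening_radius))

        class_map = np.zeros(px.shape[:2], dtype=np.uint8)
        class_map[nucleus] = NUCLEUS
        class_map[artifact] = ARTIFACT
        class_map[fiber] = FIBER  # fiber is disjoint from the other two
        return SegmentationResult(class_map=class_map, fiber_mask=class_map == FIBER)

    def fit_transform(self, X, y=None) -> SegmentationResult:
        return self.fit().transform(X)


def segment_stain(image, profile: Optional[StainProfile] = None, opening_radius: int = 1) -> SegmentationResult:
    """Segment a stained micrograph into fiber / nucleus / artifact /
    background classes by HSV thresholding."""
    stain = image.stain_type if isinstance(image, StainImage) else (
        profile.stain_type if profile is not None else "he"
    )
    seg = StainSegmenter(stain_type=stain, profile=profile, opening_radius=opening_radius)
    return seg.fit_transform(image)


def apply_overrides(result: SegmentationResult, override: np.ndarray) -> SegmentationResult:
    """Apply a manual-correction mask to a segmentation.

    ``override`` uses codes {0 = no change, 1 = background, 2 = fiber,
    3 = nucleus, 4 = artifact}; non-sentinel pixels replace the class
    map and the fiber mask is recomputed.
    """
    override = np.asarray(override)
    if override.shape != result.class_map.shape:
        raise ValueError(
            f"override shape {override.shape} does not match class map "
            f"shape {result.class_map.shape}"
        )
    bad = ~np.isin(override, [OVERRIDE_SENTINEL, *list(_OVERRIDE_TO_CLASS)])
    if bad.any():
        raise ValueError("override mask contains codes outside 0..4")
    class_map = result.class_map.copy()
    for code, cls in _OVERRIDE_TO_CLASS.items():
        class_map[override == code] = cls
    return SegmentationResult(class_map=class_map, fiber_mask=class_map == FIBER)


def label_components(mask: np.ndarray, min_area: float = 10.0) -> ComponentTable:
    """8-connected components of a binary mask, as a sorted table.

    Components with area below ``min_area`` (px^2) are dropped —
    suppressing speckle noise. Rows are ordered by descending area with
    ties broken by the top-left-most member pixel in row-major order;
    ids are reassigned 1..n in that order in both the table and the
    returned labeled image.
    """
    if min_area < 0:
        raise ValueError("min_area must be non-negative")
    mask = np.asarray(mask, dtype=bool)
    raw = measure.label(mask, connectivity=2)
    props = measure.regionprops(raw)
    W = mask.shape[1]
    rows = []
    for p in props:
        if p.area < min_area:
            continue
        coords = p.coords
        first = int(np.min(coords[:, 0] * W + coords[:, 1]))
        rows.append((p.label, int(p.area), p.centroid[0], p.centroid[1], first))
    rows.sort(key=lambda r: (-r[1], r[4]))

    remap = np.zeros(raw.max() + 1, dtype=np.int32)
    records = []
    for new_id, (old, area, cy, cx, _first) in enumerate(rows, start=1):
        remap[old] = new_id
        records.append((new_id, area, cy, cx))
    labels = remap[raw]
    table = pd.DataFrame(
        records, columns=["component_id", "area_px", "centroid_row", "centroid_col"]
    )
    return ComponentTable(table=table, labels=labels)
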