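"""Synthetic stained-micrograph generation with ground truth.

The measurements this package targets were developed on brightfield
micrographs of stained human dermis that are not publicly deposited, so
this module emulates them: elongated fiber bundles whose per-bundle
pixel areas follow a two-parameter generalized Pareto distribution
(GPD), rendered in stain-appropriate colors together with nuclei and
artifact structures, plus exact ground-truth masks.

Design points:

* Areas are drawn first and shapes are scaled to match, so the truth
  area distribution is exactly GPD (not distorted by rasterization).
* Bundles are placed without overlap by dart throwing with a bounded
  number of attempts per bundle; overlapping placement would merge
  connected components and corrupt the area distribution.
* One seeded generator per spec, with deterministic sub-streams for
  areas, geometry, nuclei/artifacts and pixel noise, so an identical
  spec reproduces a bit-identical image and truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .image import StainImage, STAIN_TYPES, MIN_IMAGE_DIM
from .palettes import STAIN_PALETTES

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "sample_gpd",
    "render_micrograph",
    "make_geometric_fixture",
    "ribbon_width",
]

_K_EPS = 1e-8
MAX_PLACEMENT_ATTEMPTS = 200
_MAX_AREA_FRACTION = 0.25  # single bundle may cover at most this canvas share


def sample_gpd(shape_k: float, scale_sigma: float, n: int, seed=None) -> np.ndarray:
    """Draw ``n`` i.i.d. values from GPD(k, sigma) with location 0.

    Inverse-transform sampling against the survival function
    ``S(x) = (1 + k x / sigma)^(-1/k)`` (``exp(-x/sigma)`` at k = 0).
    ``seed`` may be an integer or an existing :class:`numpy.random.Generator`.
    """
    if scale_sigma <= 0:
        raise ValueError("scale_sigma must be positive")
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n == 0:
        return np.empty(0, dtype=float)
    u = rng.random(n)  # uniform(0, 1); u plays the role of S(x)
    if abs(shape_k) < _K_EPS:
        return -scale_sigma * np.log(u)
    return scale_sigma * np.expm1(-shape_k * np.log(u)) / shape_k


@dataclass
class SyntheticSpec:
    """Full recipe for one synthetic micrograph.

    Parameters
    ----------
    shape_k : float
        GPD tail index of the per-bundle pixel-area distribution.
    scale_sigma : float
        GPD scale, in squared pixels.
    n_bundles : int
        Number of fiber bundles to attempt to place.
    image_size : (height, width)
        Canvas size in pixels, each at least 32.
    stain_type : str
        Render palette: ``he``, ``mallory``, ``silver`` or
        ``weigert_orcein``.
    fiber_aspect : float
        Elongation (end-to-end length over width) of each bundle, >= 1.
    n_nuclei, n_artifacts : int
        Counts of nucleus ellipses and artifact blobs to place in the
        inter-bundle space.
    noise_sd : float
        Standard deviation of additive Gaussian pixel noise (8-bit
        intensity units), clipped to [0, 255].
    seed : int
        Master seed; all randomness derives from it.
    """

    shape_k: float = 0.7
    scale_sigma: float = 2.4
    n_bundles: int = 100
    image_size: tuple[int, int] = (512, 512)
    stain_type: str = "he"
    fiber_aspect: float = 4.0
    n_nuclei: int = 0
    n_artifacts: int = 0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scale_sigma <= 0:
            raise ValueError("scale_sigma must be positive")
        if self.n_bundles < 0 or self.n_nuclei < 0 or self.n_artifacts < 0:
            raise ValueError("object counts must be non-negative")
        h, w = self.image_size
        if h < MIN_IMAGE_DIM or w < MIN_IMAGE_DIM:
            raise ValueError(f"image_size components must be >= {MIN_IMAGE_DIM}")
        if self.stain_type not in STAIN_TYPES:
            raise ValueError(f"stain_type must be one of {STAIN_TYPES}")
        if self.fiber_aspect < 1:
            raise ValueError("fiber_aspect must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        self.image_size = (int(h), int(w))

    # -- flat key-value serialization, round-trippable ------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["image_size"] = list(d["image_size"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        d = dict(d)
        d["image_size"] = tuple(d["image_size"])
        return cls(**d)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "SyntheticSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class GroundTruth:
    """Exact per-class truth for one rendered micrograph."""

    fiber_mask: np.ndarray
    nucleus_mask: np.ndarray
    artifact_mask: np.ndarray
    bundle_areas: np.ndarray  # continuous GPD draws, aligned with labels 1..n
    bundle_labels: np.ndarray
    n_requested: int = 0
    n_placed: int = 0

    def areas_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bundle_id": np.arange(1, len(self.bundle_areas) + 1),
                "area_px": self.bundle_areas,
            }
        )


def ribbon_width(area: float, aspect: float) -> float:
    """Stroke width of a rendered bundle of the given target area.

    Bundles are capsules (two-segment spines with round caps) of
    end-to-end extent ``aspect * width``, so
    ``area = (aspect - 1 + pi/4) * width^2``.
    """
    return float(np.sqrt(area / (aspect - 1.0 + np.pi / 4.0)))


def _segment_distance(py, px, ay, ax, by, bx):
    """Distance from pixels (py, px) to segment (a, b)."""
    dy, dx = by - ay, bx - ax
    seg2 = dy * dy + dx * dx
    if seg2 == 0:
        return np.hypot(py - ay, px - ax)
    t = ((py - ay) * dy + (px - ax) * dx) / seg2
    t = np.clip(t, 0.0, 1.0)
    return np.hypot(py - (ay + t * dy), px - (ax + t * dx))


def _bundle_pixels(area, aspect, cy, cx, theta, bend, shape):
    """Pixel coordinates of one bundle: the round(area) grid points
    nearest a two-segment spine, giving an elongated capsule whose pixel
    count equals round(area) exactly.

    Returns (rows, cols) or None if the shape leaves the canvas.
    """
    m = max(1, int(round(area)))
    w = ribbon_width(area, aspect)
    body = (aspect - 1.0) * w  # straight spine length

    half = body / 2.0
    c, s = np.cos(theta), np.sin(theta)
    cb, sb = np.cos(theta + bend), np.sin(theta + bend)
    # spine: end A -- center -- end B, with a small bend at the center
    ay, ax = cy - half * s, cx - half * c
    by, bx = cy + half * sb, cx + half * cb
    segs = [(ay, ax, cy, cx), (cy, cx, by, bx)]

    margin = w / 2.0 + 2.0
    r0 = int(np.floor(min(ay, by, cy) - margin))
    r1 = int(np.ceil(max(ay, by, cy) + margin))
    c0 = int(np.floor(min(ax, bx, cx) - margin))
    c1 = int(np.ceil(max(ax, bx, cx) + margin))
    H, W = shape
    if r0 < 0 or c0 < 0 or r1 >= H or c1 >= W:
        return None

    rr, cc = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
    rr = rr.ravel()
    cc = cc.ravel()
    dist = np.full(rr.shape, np.inf)
    for sy0, sx0, sy1, sx1 in segs:
        dist = np.minimum(dist, _segment_distance(rr, cc, sy0, sx0, sy1, sx1))
    if m > rr.size:
        return None
    # ties broken by row-major order for determinism
    order = np.lexsort((cc, rr, dist))[:m]
    return rr[order], cc[order]


def _ellipse_pixels(cy, cx, ra, rb, theta, shape):
    H, W = shape
    margin = max(ra, rb) + 1.0
    r0, r1 = int(np.floor(cy - margin)), int(np.ceil(cy + margin))
    c0, c1 = int(np.floor(cx - margin)), int(np.ceil(cx + margin))
    if r0 < 0 or c0 < 0 or r1 >= H or c1 >= W:
        return None
    rr, cc = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
    y = rr - cy
    x = cc - cx
    u = x * np.cos(theta) + y * np.sin(theta)
    v = -x * np.sin(theta) + y * np.cos(theta)
    inside = (u / ra) ** 2 + (v / rb) ** 2 <= 1.0
    return rr[inside], cc[inside]


def _mark_forbidden(forbidden, rows, cols):
    """Mark the 8-neighborhood of the given pixels as occupied so later
    objects keep a one-pixel gap (preserves 8-connectivity separation)."""
    H, W = forbidden.shape
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            r = np.clip(rows + dr, 0, H - 1)
            c = np.clip(cols + dc, 0, W - 1)
            forbidden[r, c] = True


def render_micrograph(spec: SyntheticSpec) -> tuple[StainImage, GroundTruth]:
    """Render one synthetic micrograph and its exact ground truth.

    Bundles whose placement fails after :data:`MAX_PLACEMENT_ATTEMPTS`
    dart throws are skipped; ``GroundTruth.n_placed`` reports how many
    of ``spec.n_bundles`` were actually placed, and truth arrays cover
    only the placed bundles.
    """
    H, W = spec.image_size
    ss = np.random.SeedSequence(spec.seed)
    rng_areas, rng_geom, rng_cells, rng_noise = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )

    # draw target areas first; oversized draws are rejected and redrawn
    max_area = _MAX_AREA_FRACTION * H * W
    areas = sample_gpd(spec.shape_k, spec.scale_sigma, spec.n_bundles, rng_areas)
    for i in range(areas.size):
        tries = 0
        while areas[i] > max_area:
            areas[i] = sample_gpd(spec.shape_k, spec.scale_sigma, 1, rng_areas)[0]
            tries += 1
            if tries > 1000:
                raise RuntimeError(
                    "could not draw a bundle area within the canvas budget; "
                    "scale_sigma/shape_k are too large for this image_size"
                )

    labels = np.zeros((H, W), dtype=np.int32)
    forbidden = np.zeros((H, W), dtype=bool)
    placed_areas: list[float] = []

    # place big bundles first: they are the hardest to fit
    next_label = 1
    for area in sorted(areas, reverse=True):
        placed = False
        for _ in range(MAX_PLACEMENT_ATTEMPTS):
            cy = rng_geom.uniform(0, H)
            cx = rng_geom.uniform(0, W)
            theta = rng_geom.uniform(0, np.pi)
            bend = rng_geom.uniform(-0.3, 0.3)
            px = _bundle_pixels(area, spec.fiber_aspect, cy, cx, theta, bend, (H, W))
            if px is None:
                continue
            rows, cols = px
            if forbidden[rows, cols].any():
                continue
            labels[rows, cols] = next_label
            _mark_forbidden(forbidden, rows, cols)
            placed_areas.append(float(area))
            next_label += 1
            placed = True
            break
        if not placed:
            continue

    fiber_mask = labels > 0

    nucleus_mask = np.zeros((H, W), dtype=bool)
    for _ in range(spec.n_nuclei):
        for _ in range(MAX_PLACEMENT_ATTEMPTS):
            cy = rng_cells.uniform(0, H)
            cx = rng_cells.uniform(0, W)
            ra = rng_cells.uniform(3.0, 6.0)
            rb = ra * rng_cells.uniform(0.55, 0.95)
            theta = rng_cells.uniform(0, np.pi)
            px = _ellipse_pixels(cy, cx, ra, rb, theta, (H, W))
            if px is None:
                continue
            rows, cols = px
            if forbidden[rows, cols].any() or nucleus_mask[rows, cols].any():
                continue
            nucleus_mask[rows, cols] = True
            break

    artifact_mask = np.zeros((H, W), dtype=bool)
    taken = forbidden | nucleus_mask
    for _ in range(spec.n_artifacts):
        for _ in range(MAX_PLACEMENT_ATTEMPTS):
            cy = rng_cells.uniform(0, H)
            cx = rng_cells.uniform(0, W)
            ra = rng_cells.uniform(4.0, 10.0)
            rb = ra * rng_cells.uniform(0.5, 1.0)
            theta = rng_cells.uniform(0, np.pi)
            px = _ellipse_pixels(cy, cx, ra, rb, theta, (H, W))
            if px is None:
                continue
            rows, cols = px
            if taken[rows, cols].any() or artifact_mask[rows, cols].any():
                continue
            artifact_mask[rows, cols] = True
            break

    palette = STAIN_PALETTES[spec.stain_type]
    img = np.empty((H, W, 3), dtype=float)
    img[:] = palette["background"]
    img[fiber_mask] = palette["fiber"]
    img[nucleus_mask] = palette["nucleus"]
    img[artifact_mask] = palette["artifact"]
    if spec.noise_sd > 0:
        img = img + rng_noise.normal(0.0, spec.noise_sd, size=img.shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    stain_image = StainImage(
        pixels=pixels,
        stain_type=spec.stain_type,
        label=f"synthetic k={spec.shape_k} sigma={spec.scale_sigma} seed={spec.seed}",
    )
    truth = GroundTruth(
        fiber_mask=fiber_mask,
        nucleus_mask=nucleus_mask,
        artifact_mask=artifact_mask,
        bundle_areas=np.asarray(placed_areas, dtype=float),
        bundle_labels=labels,
        n_requested=spec.n_bundles,
        n_placed=len(placed_areas),
    )
    return stain_image, truth


def make_geometric_fixture(kind: str, params: dict, image_size=(128, 128)) -> np.ndarray:
    """Exact rasterization of a simple test shape, centered on the canvas.

    ``kind`` is one of ``disk`` (``radius``), ``bar`` (``width``,
    ``length`` — an axis-aligned width x length rectangle) or ``ring``
    (``outer``, ``inner``). Raises if the shape does not fit inside the
    canvas.
    """
    H, W = int(image_size[0]), int(image_size[1])
    out = np.zeros((H, W), dtype=bool)
    cy, cx = H // 2, W // 2

    if kind == "disk":
        r = float(params["radius"])
        if r <= 0 or 2 * r + 1 > min(H, W):
            raise ValueError("disk does not fit inside the canvas")
        yy, xx = np.ogrid[:H, :W]
        out = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
    elif kind == "bar":
        w, ln = int(params["width"]), int(params["length"])
        if w <= 0 or ln <= 0 or w > H or ln > W:
            raise ValueError("bar does not fit inside the canvas")
        r0, c0 = cy - w // 2, cx - ln // 2
        out[r0 : r0 + w, c0 : c0 + ln] = True
    elif kind == "ring":
        outer, inner = float(params["outer"]), float(params["inner"])
        if inner < 0 or outer <= inner or 2 * outer + 1 > min(H, W):
            raise ValueError("ring does not fit inside the canvas")
        yy, xx = np.ogrid[:H, :W]
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        out = (d2 <= outer * outer) & (d2 > inner * inner)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return out
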