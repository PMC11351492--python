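"""Micrograph containers and disk I/O.

Images are 8-bit RGB brightfield micrographs of stained skin sections.
The four supported stains target different fibrous components of the
dermal extracellular matrix: H&E and Mallory's trichrome for type I
collagen bundles, silver impregnation for reticular (type III collagen)
fibers, and Weigert's resorcin-fuchsin / orcein for elastic fibers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import imageio.v3 as iio
import tifffile

STAIN_TYPES = ("he", "mallory", "silver", "weigert_orcein")

MIN_IMAGE_DIM = 32


@dataclass
class StainImage:
    """An RGB micrograph plus stain-type and acquisition metadata.

    Parameters
    ----------
    pixels : (H, W, 3) uint8 array
        8-bit RGB pixel data.
    stain_type : str
        One of ``he``, ``mallory``, ``silver``, ``weigert_orcein``.
    microns_per_pixel : float, optional
        Physical pixel pitch; used only for unit conversion on output.
    label : str
        Free-text identifier, e.g. ``"2012 sample 1"``.
    """

    pixels: np.ndarray
    stain_type: str
    microns_per_pixel: Optional[float] = None
    label: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(
                f"expected an H x W x 3 RGB array, got shape {px.shape}"
            )
        if px.dtype != np.uint8:
            raise ValueError(f"expected uint8 pixels, got {px.dtype}")
        if px.shape[0] < MIN_IMAGE_DIM or px.shape[1] < MIN_IMAGE_DIM:
            raise ValueError(
                f"image must be at least {MIN_IMAGE_DIM} px on each side"
            )
        if self.stain_type not in STAIN_TYPES:
            raise ValueError(
                f"unknown stain_type {self.stain_type!r}; expected one of {STAIN_TYPES}"
            )
        if self.microns_per_pixel is not None and self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be positive")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


def read_image(path, stain_type: str, *, microns_per_pixel=None, label=None) -> StainImage:
    """Read an 8-bit RGB TIFF/PNG micrograph from *path*."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        px = tifffile.imread(path)
    else:
        px = iio.imread(path)
    px = np.asarray(px)
    if px.ndim == 3 and px.shape[2] == 4:  # drop alpha
        px = px[:, :, :3]
    if px.ndim != 3:
        raise ValueError(f"{path}: expected an RGB image, got shape {px.shape}")
    if px.dtype != np.uint8:
        raise ValueError(f"{path}: expected 8-bit/channel data, got {px.dtype}")
    return StainImage(
        pixels=px,
        stain_type=stain_type,
        microns_per_pixel=microns_per_pixel,
        label=label if label is not None else path.stem,
    )


def write_image(path, pixels: np.ndarray) -> None:
    """Write an RGB or single-channel uint8/uint16 image to PNG or TIFF."""
    path = Path(path)
    pixels = np.asarray(pixels)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, pixels)
    else:
        iio.imwrite(path, pixels)


def write_mask(path, mask: np.ndarray) -> None:
    """Write a binary mask as a single-channel 0/255 PNG."""
    write_image(path, (np.asarray(mask, bool) * np.uint8(255)))
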