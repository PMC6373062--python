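"""Colour conversion and contrast enhancement ahead of segmentation.

Bright-field cervical-cytology images are converted to grayscale with the
perceptual weighting gray = 0.3 R + 0.59 G + 0.11 B and then contrast-enhanced
with CLAHE (contrast-limited adaptive histogram equalization).  The clip limit
is expressed in the classical Zuiderveld convention — multiples of the mean
histogram bin height per tile — with 2.0 as the operating default, which darkens
nuclei and sharpens cytoplasm boundaries without amplifying background noise.

Gray values are kept as floats in [0, 255]; quantization to 8 bit happens only
on file export.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
from skimage.exposure import equalize_adapthist

from ._errors import ConfigError, DataError

#: default physical pixel size (µm per pixel edge) of the reference dataset
DEFAULT_PIXEL_SIZE_UM = 0.201

GRAY_WEIGHTS = (0.3, 0.59, 0.11)


@dataclass(frozen=True)
class RGBImage:
    """H x W x 3 image, channel order (R, G, B), intensities in [0, 255]."""

    pixels: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 3 or px.shape[2] != 3:
            raise DataError(f"expected an H x W x 3 array, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise DataError("image must contain at least one pixel")
        if self.pixel_size_um <= 0:
            raise ConfigError("pixel_size_um must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class GrayImage:
    """H x W grayscale image, real-valued intensities in [0, 255]."""

    pixels: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise DataError(f"expected an H x W array, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise DataError("image must contain at least one pixel")
        if self.pixel_size_um <= 0:
            raise ConfigError("pixel_size_um must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class EnhanceConfig:
    """CLAHE parameters.

    clip_limit
        Histogram clip level in multiples of the mean bin height of a tile
        histogram (2.0 = clip at twice the mean bin height).
    tile_grid
        Number of contextual tiles along (rows, cols).
    nbins
        Histogram resolution per tile.
    """

    clip_limit: float = 2.0
    tile_grid: tuple[int, int] = (8, 8)
    nbins: int = 256

    def __post_init__(self):
        if self.clip_limit <= 0:
            raise ConfigError("clip_limit must be > 0")
        if len(self.tile_grid) != 2 or any(t < 1 for t in self.tile_grid):
            raise ConfigError("tile_grid must be a pair of positive integers")


def rgb_to_gray(img: RGBImage) -> GrayImage:
    """Weighted grayscale conversion: 0.3 R + 0.59 G + 0.11 B.

    The output is kept real-valued (no rounding) so downstream filters see
    the full precision.
    """
    wr, wg, wb = GRAY_WEIGHTS
    px = img.pixels
    gray = wr * px[..., 0] + wg * px[..., 1] + wb * px[..., 2]
    return GrayImage(gray, pixel_size_um=img.pixel_size_um)


def clahe(img: GrayImage, cfg: EnhanceConfig | None = None) -> GrayImage:
    """Contrast-limited adaptive histogram equalization on [0, 255] grays.

    A constant image has no contrast to redistribute and is returned
    unchanged.  Otherwise the histogram of each tile is clipped at
    ``cfg.clip_limit`` times the mean bin height and tile mappings are
    bilinearly interpolated.
    """
    cfg = cfg or EnhanceConfig()
    px = img.pixels
    if np.ptp(px) == 0:
        return GrayImage(px.copy(), pixel_size_um=img.pixel_size_um)
    h, w = px.shape
    kernel = (max(h // cfg.tile_grid[0], 1), max(w // cfg.tile_grid[1], 1))
    # skimage's clip_limit is a fraction of the tile pixel count; mean bin
    # height is tile_pixels / nbins, so k x mean-bin-height == k / nbins.
    skimage_clip = min(cfg.clip_limit / cfg.nbins, 1.0)
    out = equalize_adapthist(
        px / 255.0, kernel_size=kernel, clip_limit=skimage_clip, nbins=cfg.nbins
    )
    return GrayImage(out * 255.0, pixel_size_um=img.pixel_size_um)


def imread(path, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> RGBImage | GrayImage:
    """Read a PNG/TIFF/BMP file as an RGBImage or GrayImage."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[..., :3]
        return RGBImage(arr.astype(float), pixel_size_um=pixel_size_um)
    return GrayImage(arr.astype(float), pixel_size_um=pixel_size_um)


def imwrite(path, img: RGBImage | GrayImage) -> None:
    """Write an image, quantizing float intensities to 8 bit."""
    px = np.clip(np.round(img.pixels), 0, 255).astype(np.uint8)
    iio.imwrite(path, px)
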