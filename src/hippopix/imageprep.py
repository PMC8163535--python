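"""Preprocessing chain for stained histological images.

An annotated RGB section is reduced to two grey-level images that feed
feature extraction:

* ``I_NV`` — the negated HSV value channel, in which darkly stained
  structures (the hippocampal band) become bright;
* ``I_HE`` — the background-homogenized, top-hat enhanced image, in which
  structures thinner than a disc of radius 8 px are isolated and everything
  wider is suppressed.

The chain is ``value_channel -> negated -> homogenized -> enhanced`` and each
stage is recorded on the :class:`GreyImage` it produces, so that stages cannot
be applied out of order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.morphology import opening

__all__ = [
    "RgbImage",
    "GreyImage",
    "BBoxAnnotation",
    "HomogenizationConfig",
    "PipelineOrderError",
    "AnnotationError",
    "disc",
    "to_value_channel",
    "invert",
    "homogenize_background",
    "enhance",
    "preprocess",
    "load_rgb",
    "save_grey",
]

STAGES = ("value_channel", "negated", "homogenized", "enhanced")


class PipelineOrderError(RuntimeError):
    """A stage was applied to an image produced by the wrong predecessor."""


class AnnotationError(ValueError):
    """A bounding-box annotation is inconsistent with its image."""


@dataclass(frozen=True)
class RgbImage:
    """An H x W x 3 RGB raster with channel values in [0, 255]."""

    pixels: np.ndarray

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected HxWx3 array, got shape {px.shape}")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("RGB values must lie in [0, 255]")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class GreyImage:
    """A single-channel raster with values in [0, 255] plus its pipeline stage."""

    pixels: np.ndarray
    stage: str

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError(f"expected 2-D array, got shape {px.shape}")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("grey values must lie in [0, 255]")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class BBoxAnnotation:
    """0-based half-open pixel box [x0, x1) x [y0, y1) around the target."""

    x0: int
    y0: int
    x1: int
    y1: int

    MIN_SIDE = 17

    def validate(self, height: int, width: int) -> None:
        if not (0 <= self.x0 < self.x1 <= width and 0 <= self.y0 < self.y1 <= height):
            raise AnnotationError(
                f"box {self} outside {width}x{height} image or degenerate"
            )
        if self.x1 - self.x0 < self.MIN_SIDE or self.y1 - self.y0 < self.MIN_SIDE:
            raise AnnotationError(
                f"box sides must be >= {self.MIN_SIDE} px to admit the feature window"
            )

    @classmethod
    def from_dict(cls, d: dict) -> "BBoxAnnotation":
        return cls(x0=int(d["x0"]), y0=int(d["y0"]), x1=int(d["x1"]), y1=int(d["y1"]))

    def to_dict(self) -> dict:
        return {"x0": self.x0, "y0": self.y0, "x1": self.x1, "y1": self.y1}


@dataclass(frozen=True)
class HomogenizationConfig:
    """Window sizes for background homogenization.

    The recipe is a 3x3 mean filter, a Gaussian smoothing (9x9 kernel,
    sigma 1.8), subtraction of a large-window mean-filter background
    estimate, and a histogram shift that maps the mode to mid-grey (128).
    """

    mean_size: int = 3
    gauss_size: int = 9
    gauss_sigma: float = 1.8
    background_size: int = 69
    target_mode: int = 128


def disc(radius: int) -> np.ndarray:
    """Disc structuring element {(i,j): i^2 + j^2 <= r^2}."""
    r = int(radius)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy * yy + xx * xx <= r * r).astype(np.uint8)


def to_value_channel(img: RgbImage, box: BBoxAnnotation) -> GreyImage:
    """Extract the HSV value channel V = max(R, G, B) cropped to the box.

    The value channel captures stain density independently of hue, so pink-
    and purple-stained sections reduce to the same grey representation.
    """
    box.validate(img.height, img.width)
    crop = img.pixels[box.y0 : box.y1, box.x0 : box.x1, :]
    v = crop.astype(np.float64).max(axis=2)
    return GreyImage(v, stage="value_channel")


def _require_stage(img: GreyImage, stage: str) -> None:
    if img.stage != stage:
        raise PipelineOrderError(f"expected stage {stage!r}, got {img.stage!r}")


def invert(img: GreyImage) -> GreyImage:
    """Negate the value channel: I_NV = 255 - I_V.

    Dark stained pixels (values near 0) become bright, so the band of
    interest is embossed for the later morphological enhancement.
    """
    _require_stage(img, "value_channel")
    return GreyImage(255.0 - img.pixels, stage="negated")


def homogenize_background(
    img: GreyImage, config: HomogenizationConfig | None = None
) -> GreyImage:
    """Remove slow illumination/staining gradients from I_NV, giving I_H.

    Smooths lightly (mean then Gaussian), estimates the background with a
    large mean filter, subtracts it, and shifts the result so the histogram
    mode sits at ``config.target_mode``. All filters use reflect padding.
    """
    _require_stage(img, "negated")
    cfg = config or HomogenizationConfig()
    h, w = img.pixels.shape
    if min(h, w) < cfg.background_size:
        raise ValueError(
            f"image {w}x{h} smaller than background window {cfg.background_size}"
        )
    sm = ndimage.uniform_filter(img.pixels, size=cfg.mean_size, mode="reflect")
    sm = ndimage.gaussian_filter(
        sm,
        sigma=cfg.gauss_sigma,
        truncate=(cfg.gauss_size - 1) / 2.0 / cfg.gauss_sigma,
        mode="reflect",
    )
    background = ndimage.uniform_filter(sm, size=cfg.background_size, mode="reflect")
    resid = sm - background
    # Histogram mode of the integer-rounded residual -> target grey level.
    vals, counts = np.unique(np.rint(resid).astype(np.int64), return_counts=True)
    mode = vals[np.argmax(counts)]
    out = np.clip(resid - mode + cfg.target_mode, 0.0, 255.0)
    return GreyImage(out, stage="homogenized")


def enhance(img: GreyImage, radius: int = 8) -> GreyImage:
    """White top-hat: I_HE = I_H - opening(I_H, disc(radius)).

    The opening removes every bright structure that the disc fits inside,
    so subtracting it keeps only structures thinner than ~2*radius px —
    the scale of the hippocampal band — and flattens wider tissue regions.
    """
    _require_stage(img, "homogenized")
    opened = opening(img.pixels, footprint=disc(radius))
    out = img.pixels - opened
    # opening is anti-extensive, so out >= 0 up to float round-off
    out = np.clip(out, 0.0, 255.0)
    return GreyImage(out, stage="enhanced")


def preprocess(
    img: RgbImage,
    box: BBoxAnnotation,
    config: HomogenizationConfig | None = None,
    radius: int = 8,
) -> tuple[GreyImage, GreyImage]:
    """Run the full chain; returns ``(I_NV, I_HE)`` with matching shapes."""
    i_v = to_value_channel(img, box)
    i_nv = invert(i_v)
    i_h = homogenize_background(i_nv, config)
    i_he = enhance(i_h, radius=radius)
    return i_nv, i_he


def load_rgb(path: str | Path) -> RgbImage:
    """Read a PNG/JPEG image as RGB (alpha dropped, grey replicated)."""
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return RgbImage(arr)


def save_grey(img: GreyImage, path: str | Path) -> None:
    """Write a grey image as 8-bit PNG for inspection."""
    import imageio.v3 as iio

    iio.imwrite(Path(path), np.rint(img.pixels).astype(np.uint8))
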