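"""Seeded generator of synthetic stained-section images with ground truth.

Real coronal sections stained with hematoxylin-eosin show a pinkish tissue
background with a thin (a few pixels), dark, smoothly curving hippocampal
band, other structures of similar shape and darkness, uneven illumination,
hue/saturation variation between slides, and incidental streak artifacts.
The generator emulates exactly those conditions:

* a textured pink background with a per-image brightness gradient and
  hue/saturation jitter;
* one dark, feather-edged, C/S-shaped target band (recorded in the mask);
* ``n_distractors`` look-alike bands that are *not* in the mask. Each
  distractor sits in a diffusely darkened patch of surrounding tissue, the
  way look-alike structures in real sections are embedded in neighbouring
  cell layers: after background removal the distractor band looks just like
  the target, but the pre-enhancement brightness context around it differs;
* Gaussian pixel noise and optional bright streak artifacts.

Every image carries a binary ground-truth mask (target band only) and a
bounding-box annotation enclosing the target with margin, mirroring a
manual annotation. All randomness flows from the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import interpolate, ndimage

from .imageprep import BBoxAnnotation, RgbImage

__all__ = ["SynthConfig", "SynthImage", "generate_image", "generate_dataset"]

# background / band colour ratios (max channel = 1, so the value channel is
# exactly the brightness field): pink tissue vs darker purple band
BG_RATIOS = np.array([1.0, 0.80, 0.88])
BAND_RATIOS = np.array([0.78, 0.62, 1.0])


@dataclass(frozen=True)
class SynthConfig:
    width: int = 512
    height: int = 416
    band_thickness: tuple[int, int] = (3, 8)
    band_intensity_drop: tuple[float, float] = (0.4, 0.7)
    n_distractors: int = 1
    brightness_gradient: tuple[float, float] = (0.0, 0.3)
    hue_jitter: float = 0.05
    saturation_jitter: float = 0.10
    noise_sd: float = 4.0
    artifact_rate: float = 0.3
    bbox_margin: int = 20
    feather: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if self.width < 64 or self.height < 64:
            raise ValueError("image dimensions must be >= 64")
        if self.band_thickness[0] < 1:
            raise ValueError("band thickness must be >= 1 px")
        for lo, hi in (self.band_intensity_drop, self.brightness_gradient):
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError("fraction ranges must lie in [0, 1]")


@dataclass(frozen=True)
class SynthImage:
    image: RgbImage
    mask: np.ndarray
    bbox: BBoxAnnotation
    seed: int


def _band_distance(
    rng: np.random.Generator,
    shape: tuple[int, int],
    centre: tuple[float, float],
    radius: float,
) -> np.ndarray:
    """Distance map to a random smooth C/S arc around ``centre``."""
    h, w = shape
    a0 = rng.uniform(0.0, 2.0 * np.pi)
    span = rng.uniform(np.pi, np.pi * 5.0 / 3.0)
    n_ctrl = 8
    angles = np.linspace(a0, a0 + span, n_ctrl)
    radii = radius * (1.0 + rng.uniform(-0.12, 0.12, size=n_ctrl))
    cx, cy = centre
    px = cx + radii * np.cos(angles)
    py = cy + radii * np.sin(angles)
    tck, _ = interpolate.splprep([px, py], s=0.0, k=3)
    t = np.linspace(0.0, 1.0, 4000)
    sx, sy = interpolate.splev(t, tck)
    raster = np.zeros(shape, dtype=bool)
    ix = np.clip(np.rint(sx).astype(int), 0, w - 1)
    iy = np.clip(np.rint(sy).astype(int), 0, h - 1)
    raster[iy, ix] = True
    return ndimage.distance_transform_edt(~raster)


def _band_weight(dist: np.ndarray, thickness: float, feather: float) -> np.ndarray:
    """1 inside the stroked band, linear feather falloff outside it."""
    half = thickness / 2.0
    return np.clip((half + feather - dist) / feather, 0.0, 1.0)


def generate_image(config: SynthConfig) -> SynthImage:
    """One synthetic section: (RgbImage, binary mask, bounding box)."""
    rng = np.random.default_rng(config.seed)
    h, w = config.height, config.width
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)

    # --- background brightness field -------------------------------------
    base_v = rng.uniform(215.0, 240.0)
    texture = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma=8.0)
    t_amp = texture.std()
    texture = 0.03 * texture / (t_amp if t_amp > 0 else 1.0)
    grad_amp = rng.uniform(*config.brightness_gradient)
    theta = rng.uniform(0.0, 2.0 * np.pi)
    ramp = (np.cos(theta) * xx / max(w - 1, 1)) + (np.sin(theta) * yy / max(h - 1, 1))
    ramp = (ramp - ramp.min()) / max(ramp.max() - ramp.min(), 1e-12)
    V = base_v * (1.0 + texture) * (1.0 - grad_amp * ramp)

    # --- target band ------------------------------------------------------
    if config.band_thickness[1] + 2.0 * config.feather >= min(h, w) / 4.0:
        raise ValueError("band thickness too large for the image: band does not fit")
    radius = rng.uniform(0.20, 0.30) * min(h, w)
    cx = w / 2.0 + rng.uniform(-0.08, 0.08) * w
    cy = h / 2.0 + rng.uniform(-0.08, 0.08) * h
    dist = _band_distance(rng, (h, w), (cx, cy), radius)
    thickness = rng.uniform(*config.band_thickness)
    weight = _band_weight(dist, thickness, config.feather)
    mask = dist <= thickness / 2.0
    drop = rng.uniform(*config.band_intensity_drop)

    darkening = drop * weight
    band_blend = weight.copy()

    # --- distractors: same band geometry + diffuse tissue halo ------------
    for _ in range(config.n_distractors):
        # offset from the target centre so the two structures rarely overlap
        ang = rng.uniform(0.0, 2.0 * np.pi)
        off = rng.uniform(0.55, 0.85) * radius
        dcx = np.clip(cx + off * np.cos(ang), 0.15 * w, 0.85 * w)
        dcy = np.clip(cy + off * np.sin(ang), 0.15 * h, 0.85 * h)
        ddist = _band_distance(rng, (h, w), (dcx, dcy), radius * rng.uniform(0.5, 0.8))
        dthick = rng.uniform(*config.band_thickness)
        dweight = _band_weight(ddist, dthick, config.feather)
        core = (ddist <= dthick / 2.0).astype(np.float64)
        halo = ndimage.gaussian_filter(core, sigma=7.0)
        hmax = halo.max()
        halo = halo / hmax if hmax > 0 else halo
        ddrop = rng.uniform(*config.band_intensity_drop)
        extra = np.maximum(ddrop * dweight, 0.18 * halo)
        darkening = np.maximum(darkening, np.where(mask, darkening, extra))
        band_blend = np.maximum(band_blend, dweight)

    V = V * (1.0 - darkening)

    # --- colour composition ----------------------------------------------
    jit = np.array(
        [
            0.0,
            rng.uniform(-config.saturation_jitter, config.saturation_jitter),
            rng.uniform(-config.hue_jitter, config.hue_jitter),
        ]
    )
    bg = np.clip(BG_RATIOS + jit, 0.05, 1.0)
    bg = bg / bg.max()
    band = BAND_RATIOS / BAND_RATIOS.max()
    ratios = (1.0 - band_blend[..., None]) * bg + band_blend[..., None] * band
    ratios = ratios / ratios.max(axis=2, keepdims=True)  # keep max(R,G,B) = V
    rgb = V[..., None] * ratios

    # --- artifacts: occasional bright streaks -----------------------------
    if rng.uniform() < config.artifact_rate:
        for _ in range(rng.integers(1, 3)):
            x0, x1 = rng.uniform(0, w, size=2)
            y0, y1 = rng.uniform(0, h, size=2)
            line = np.zeros((h, w), dtype=bool)
            n = int(2 * max(abs(x1 - x0), abs(y1 - y0))) + 2
            lx = np.clip(np.rint(np.linspace(x0, x1, n)).astype(int), 0, w - 1)
            ly = np.clip(np.rint(np.linspace(y0, y1, n)).astype(int), 0, h - 1)
            line[ly, lx] = True
            streak = ndimage.gaussian_filter(line.astype(np.float64), sigma=0.8)
            smax = streak.max()
            if smax > 0:
                streak = streak / smax
            rgb = rgb + 60.0 * streak[..., None]

    if config.noise_sd > 0:
        rgb = rgb + rng.normal(0.0, config.noise_sd, size=rgb.shape)
    rgb = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)

    # --- bounding box around the target with margin ------------------------
    ys, xs = np.nonzero(mask)
    if len(xs) == 0:
        raise ValueError("generated band is empty; enlarge the image or band")
    m = config.bbox_margin
    bbox = BBoxAnnotation(
        x0=max(int(xs.min()) - m, 0),
        y0=max(int(ys.min()) - m, 0),
        x1=min(int(xs.max()) + 1 + m, w),
        y1=min(int(ys.max()) + 1 + m, h),
    )
    bbox.validate(h, w)
    return SynthImage(image=RgbImage(rgb), mask=mask, bbox=bbox, seed=config.seed)


def generate_dataset(
    n: int = 25, config: SynthConfig | None = None, seed: int = 0
) -> tuple[list[SynthImage], dict]:
    """n synthetic sections with per-image derived seeds plus a manifest.

    The default corpus size of 25 mirrors a typical digitized study series.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    config = config or SynthConfig()
    child_seeds = np.random.SeedSequence(seed).generate_state(n) % (2**31)
    images = [
        generate_image(replace(config, seed=int(s))) for s in child_seeds
    ]
    manifest = {
        "n": n,
        "seed": seed,
        "positive_pixels": [int(im.mask.sum()) for im in images],
    }
    return images, manifest


def save_dataset(images: list[SynthImage], manifest: dict, out_dir: str | Path) -> None:
    """PNG images + PNG masks + JSON bbox/manifest sidecars."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    boxes = {}
    for i, im in enumerate(images):
        name = f"synth_{i:03d}"
        iio.imwrite(out / f"{name}.png", im.image.pixels.astype(np.uint8))
        iio.imwrite(out / f"{name}_mask.png", (im.mask * 255).astype(np.uint8))
        boxes[name] = im.bbox.to_dict()
    (out / "bboxes.json").write_text(json.dumps(boxes, indent=2, sort_keys=True))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
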