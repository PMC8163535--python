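"""Per-pixel 14-D feature vectors from the preprocessed image pair.

Each pixel is described by

* ``f1..f5`` — grey-level statistics of the 9x9 window around it in the
  enhanced image I_HE: value minus window minimum, window maximum minus
  value, value minus window mean, window standard deviation, and the raw
  value itself;
* ``f6, f7`` — signed logs of the first two Hu moment invariants of the
  17x17 patch around it in I_HE, after weighting the patch by a Gaussian
  (sigma 1.7) so that the invariants describe the central pixel's
  neighbourhood rather than the whole patch;
* ``f8..f14`` — the same seven quantities computed from the negated value
  channel I_NV, which retains the pre-enhancement brightness context.

Features are standardized to zero mean / unit variance with statistics
fitted on the training split only.

Moment conventions: intensity-weighted raw moments m_pq = sum i^p j^q P(i,j),
central moments about the intensity centroid, eta_pq = mu_pq / mu00^(1+(p+q)/2),
phi1 = eta20 + eta02, phi2 = (eta20 - eta02)^2 + 4 eta11^2. A zero-mass patch
yields (0, 0). Borders are handled by reflect padding, so every pixel of the
cropped region is featurizable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imageprep import GreyImage

__all__ = [
    "FEATURE_COLUMNS",
    "GaussianWindow",
    "StandardizationParams",
    "gaussian_window",
    "window_stats",
    "weighted_patch",
    "hu_first_two",
    "log_sign",
    "pixel_feature",
    "extract_features",
    "fit_standardizer",
    "standardize",
]

FEATURE_COLUMNS = [f"f{i}" for i in range(1, 15)]

#: magnitudes below this are treated as exactly zero in the signed log
LOG_EPS = 1e-30


@dataclass(frozen=True)
class GaussianWindow:
    """A size x size grid of Gaussian weights, peak-normalized to 1."""

    weights: np.ndarray
    sigma: float
    size: int

    def central_mass_fraction(self, inner: int = 9) -> float:
        """Fraction of the total weight carried by the central inner x inner block."""
        k = (self.size - inner) // 2
        core = self.weights[k : k + inner, k : k + inner]
        return float(core.sum() / self.weights.sum())


def gaussian_window(size: int = 17, sigma: float = 1.7) -> GaussianWindow:
    """Isotropic Gaussian weight matrix exp(-(i^2+j^2)/(2 sigma^2)).

    The peak (centre) weight is 1; with size 17 and sigma 1.7 the central
    9x9 block carries ~98.6% of the total weight, so the weighting
    effectively localizes the moment computation to the inner window.
    """
    if size % 2 == 0 or size < 3:
        raise ValueError("window size must be odd and >= 3")
    half = (size - 1) // 2
    idx = np.arange(-half, half + 1, dtype=np.float64)
    jj, ii = np.meshgrid(idx, idx)
    w = np.exp(-(ii * ii + jj * jj) / (2.0 * sigma * sigma))
    return GaussianWindow(weights=w, sigma=float(sigma), size=int(size))


def _reflect_pad(pixels: np.ndarray, pad: int) -> np.ndarray:
    return np.pad(pixels, pad, mode="reflect")


def _patches_at(pixels: np.ndarray, xs: np.ndarray, ys: np.ndarray, size: int) -> np.ndarray:
    """Stack of size x size patches centred at (xs, ys), reflect-padded. N x size x size."""
    half = size // 2
    padded = _reflect_pad(pixels, half)
    offs = np.arange(size)
    # rows: N x size x 1, cols: N x 1 x size
    rows = (np.asarray(ys)[:, None] + offs)[:, :, None]
    cols = (np.asarray(xs)[:, None] + offs)[:, None, :]
    return padded[rows, cols]


def window_stats_batch(
    img: GreyImage, xs: np.ndarray, ys: np.ndarray, w: int = 9
) -> np.ndarray:
    """Vectorized f1..f5 for many pixels; returns an N x 5 array."""
    if w % 2 == 0 or w < 3:
        raise ValueError("window width must be odd and >= 3")
    patches = _patches_at(img.pixels, xs, ys, w).reshape(len(xs), -1)
    centre = img.pixels[np.asarray(ys), np.asarray(xs)]
    f1 = centre - patches.min(axis=1)
    f2 = patches.max(axis=1) - centre
    f3 = centre - patches.mean(axis=1)
    f4 = patches.std(axis=1)  # population std
    return np.column_stack([f1, f2, f3, f4, centre])


def window_stats(img: GreyImage, x: int, y: int, w: int = 9) -> tuple[float, ...]:
    """f1..f5 at a single pixel (see module docstring for definitions)."""
    out = window_stats_batch(img, np.array([x]), np.array([y]), w=w)
    return tuple(float(v) for v in out[0])


def weighted_patch(
    img: GreyImage, x: int, y: int, G: GaussianWindow
) -> np.ndarray:
    """Elementwise product of the G.size patch centred at (x, y) with G."""
    patch = _patches_at(img.pixels, np.array([x]), np.array([y]), G.size)[0]
    return patch * G.weights


def hu_first_two_batch(patches: np.ndarray) -> np.ndarray:
    """First two Hu invariants for an N x s x s stack; returns N x 2."""
    patches = np.asarray(patches, dtype=np.float64)
    if patches.min() < 0:
        raise ValueError("patch intensities must be non-negative")
    n, s, _ = patches.shape
    idx = np.arange(s, dtype=np.float64)
    m00 = patches.sum(axis=(1, 2))
    # raw first moments (i = row, j = column)
    m10 = (patches * idx[None, :, None]).sum(axis=(1, 2))
    m01 = (patches * idx[None, None, :]).sum(axis=(1, 2))
    out = np.zeros((n, 2))
    ok = m00 > 0
    if not np.any(ok):
        return out
    ci = np.where(ok, m10 / np.where(ok, m00, 1.0), 0.0)
    cj = np.where(ok, m01 / np.where(ok, m00, 1.0), 0.0)
    di = idx[None, :, None] - ci[:, None, None]
    dj = idx[None, None, :] - cj[:, None, None]
    mu20 = (patches * di * di).sum(axis=(1, 2))
    mu02 = (patches * dj * dj).sum(axis=(1, 2))
    mu11 = (patches * di * dj).sum(axis=(1, 2))
    norm = np.where(ok, m00, 1.0) ** 2.0  # mu00^(1 + (p+q)/2) with p+q = 2
    eta20 = np.where(ok, mu20 / norm, 0.0)
    eta02 = np.where(ok, mu02 / norm, 0.0)
    eta11 = np.where(ok, mu11 / norm, 0.0)
    out[:, 0] = eta20 + eta02
    out[:, 1] = (eta20 - eta02) ** 2 + 4.0 * eta11 ** 2
    return out


def hu_first_two(patch: np.ndarray) -> tuple[float, float]:
    """phi1 and phi2 of a single non-negative patch; (0, 0) for zero mass."""
    phi = hu_first_two_batch(np.asarray(patch)[None, :, :])[0]
    return float(phi[0]), float(phi[1])


def log_sign(phi: float) -> float:
    """Signed log: sign(phi) * ln|phi|, with |phi| < 1e-30 mapping to 0."""
    a = abs(phi)
    if a < LOG_EPS:
        return 0.0
    return float(np.sign(phi) * np.log(a))


def _log_sign_arr(phi: np.ndarray) -> np.ndarray:
    a = np.abs(phi)
    with np.errstate(divide="ignore"):
        out = np.sign(phi) * np.log(np.where(a < LOG_EPS, 1.0, a))
    return np.where(a < LOG_EPS, 0.0, out)


def _channel_features(
    img: GreyImage, xs: np.ndarray, ys: np.ndarray, G: GaussianWindow, w: int
) -> np.ndarray:
    """The 7 per-channel features (window stats + signed-log Hu pair). N x 7."""
    stats = window_stats_batch(img, xs, ys, w=w)
    hu = np.empty((len(xs), 2))
    chunk = 8192  # bound the N x 17 x 17 temporary
    for lo in range(0, len(xs), chunk):
        hi = min(lo + chunk, len(xs))
        patches = _patches_at(img.pixels, xs[lo:hi], ys[lo:hi], G.size) * G.weights
        hu[lo:hi] = hu_first_two_batch(patches)
    return np.column_stack([stats, _log_sign_arr(hu[:, 0]), _log_sign_arr(hu[:, 1])])


def extract_features(
    ihe: GreyImage,
    inv: GreyImage,
    xs: np.ndarray,
    ys: np.ndarray,
    G: GaussianWindow | None = None,
    w: int = 9,
) -> np.ndarray:
    """14-D feature vectors for the given pixels; returns an N x 14 array.

    Columns 0-6 come from the enhanced image, columns 7-13 repeat the same
    computation on the negated value channel.
    """
    if ihe.pixels.shape != inv.pixels.shape:
        raise ValueError("I_HE and I_NV must have identical dimensions")
    xs = np.asarray(xs, dtype=np.intp)
    ys = np.asarray(ys, dtype=np.intp)
    h, wd = ihe.pixels.shape
    if len(xs) and (xs.min() < 0 or xs.max() >= wd or ys.min() < 0 or ys.max() >= h):
        raise ValueError("pixel coordinates outside image")
    G = G or gaussian_window()
    return np.hstack(
        [_channel_features(ihe, xs, ys, G, w), _channel_features(inv, xs, ys, G, w)]
    )


def pixel_feature(
    ihe: GreyImage,
    inv: GreyImage,
    x: int,
    y: int,
    G: GaussianWindow | None = None,
) -> np.ndarray:
    """The 14-vector F = (f1..f14) for one pixel."""
    return extract_features(ihe, inv, np.array([x]), np.array([y]), G=G)[0]


@dataclass(frozen=True)
class StandardizationParams:
    """Per-feature mean and population standard deviation, fitted on training data."""

    mu: np.ndarray
    sd: np.ndarray

    @property
    def degenerate(self) -> np.ndarray:
        """Boolean mask of constant (zero-variance) features."""
        return self.sd == 0


def fit_standardizer(train_features: np.ndarray | pd.DataFrame) -> StandardizationParams:
    X = _as_matrix(train_features)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training vectors to standardize")
    return StandardizationParams(mu=X.mean(axis=0), sd=X.std(axis=0))


def standardize(
    features: np.ndarray | pd.DataFrame, params: StandardizationParams
) -> np.ndarray:
    """(f - mu) / sd per feature; constant features map to 0."""
    X = _as_matrix(features)
    if X.shape[1] != params.mu.shape[0]:
        raise ValueError(
            f"feature dimension {X.shape[1]} != fitted dimension {params.mu.shape[0]}"
        )
    sd = np.where(params.sd == 0, 1.0, params.sd)
    out = (X - params.mu) / sd
    out[:, params.degenerate] = 0.0
    return out


def unstandardize(features: np.ndarray, params: StandardizationParams) -> np.ndarray:
    """Inverse affine map for non-degenerate features."""
    return np.asarray(features) * params.sd + params.mu


def _as_matrix(features: np.ndarray | pd.DataFrame) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        cols = [c for c in FEATURE_COLUMNS if c in features.columns]
        return features[cols].to_numpy(dtype=np.float64)
    return np.asarray(features, dtype=np.float64)
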