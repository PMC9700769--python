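"""Per-frame preprocessing: adaptive contrast, cropping, blur, binarization.

The chain runs in a fixed order — contrast-limited adaptive histogram
equalization (CLAHE), cropping of the growth region, Gaussian blurring,
then conversion to a binary cord mask — and every step is deterministic.

CLAHE here follows the classic tiled formulation: per-tile 256-bin
histograms are clipped at ``clahe_clip`` times the mean bin height, the
clipped excess is redistributed uniformly, and each pixel is remapped by
bilinear interpolation between the transfer functions of the four
surrounding tile centres.  With a single tile and clipping disabled the
operation reduces exactly to global histogram equalization with the
standard transfer function ``round((cdf(v) - cdf_min) / (N - cdf_min) *
255)``, which is what the unit oracles check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects

__all__ = [
    "PreprocessParams",
    "BinaryMask",
    "NoGrowthRegionError",
    "DegenerateHistogramError",
    "equalize_contrast",
    "crop_growth_boundary",
    "blur",
    "binarize",
    "preprocess",
]


class NoGrowthRegionError(ValueError):
    """Auto-crop found no bright foreground to bound."""


class DegenerateHistogramError(ValueError):
    """Otsu thresholding is undefined on a constant image."""


@dataclass(frozen=True)
class PreprocessParams:
    """Knobs of the preprocessing chain.

    clahe_tile : side length of the equalization tile, px (>= 2)
    clahe_clip : histogram clip limit as a multiple of the mean bin height;
        ``None`` disables clipping (plain adaptive equalization)
    blur_sigma : Gaussian blur scale, px; 0 is the identity
    threshold_method : "otsu" (parameter-free) or "fixed"
    fixed_threshold : intensity used iff threshold_method == "fixed"
    min_object_px : remove foreground specks smaller than this, px^2
    crop_mode : "auto" (bounding box of the dominant bright region) or
        "manual" (explicit half-open ROI)
    manual_roi : (row0, col0, row1, col1), half-open, 0-based
    """

    clahe_tile: int = 64
    clahe_clip: Optional[float] = 2.0
    blur_sigma: float = 2.0
    threshold_method: str = "otsu"
    fixed_threshold: float = 128.0
    min_object_px: int = 16
    crop_mode: str = "auto"
    manual_roi: Optional[tuple[int, int, int, int]] = None

    def validate(self, shape: Optional[tuple[int, int]] = None) -> None:
        if self.clahe_tile < 2:
            raise ValueError(f"clahe_tile must be >= 2, got {self.clahe_tile}")
        if self.blur_sigma < 0:
            raise ValueError(f"blur_sigma must be >= 0, got {self.blur_sigma}")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError(f"unknown threshold_method {self.threshold_method!r}")
        if not 0 <= self.fixed_threshold <= 255:
            raise ValueError("fixed_threshold must lie in the 8-bit range")
        if self.crop_mode not in ("auto", "manual"):
            raise ValueError(f"unknown crop_mode {self.crop_mode!r}")
        if self.crop_mode == "manual":
            if self.manual_roi is None:
                raise ValueError("manual crop requires manual_roi")
            r0, c0, r1, c1 = self.manual_roi
            if not (r0 < r1 and c0 < c1) or r0 < 0 or c0 < 0:
                raise ValueError(f"invalid manual_roi {self.manual_roi}")
            if shape is not None and (r1 > shape[0] or c1 > shape[1]):
                raise ValueError("manual_roi exceeds image bounds")


@dataclass
class BinaryMask:
    """Foreground (cord) mask plus a provenance record of how it was made."""

    pixels: np.ndarray  # bool, 2-D
    provenance: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def foreground_fraction(self) -> float:
        return float(self.pixels.mean())


def _as_uint8(img: np.ndarray) -> np.ndarray:
    """Normalize any grayscale input to 8-bit by linear rescaling of its
    dtype range (uint16 stacks are common in time-lapse microscopy)."""
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {img.shape}")
    if img.dtype == np.uint8:
        return img
    if img.dtype == np.uint16:
        return (img // 257).astype(np.uint8)
    arr = np.asarray(img, dtype=float)
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.zeros(arr.shape, dtype=np.uint8)
    return np.rint((arr - lo) / (hi - lo) * 255).astype(np.uint8)


def _tile_lut(tile: np.ndarray, clip: Optional[float]) -> np.ndarray:
    """256-entry transfer function for one tile (classic CLAHE mapping)."""
    hist = np.bincount(tile.ravel(), minlength=256).astype(np.int64)
    n = tile.size
    if np.count_nonzero(hist) <= 1:
        return np.arange(256, dtype=np.uint8)  # no contrast to redistribute
    if clip is not None:
        limit = max(int(clip * n / 256.0), 1)
        excess = np.maximum(hist - limit, 0).sum()
        hist = np.minimum(hist, limit)
        # uniform redistribution of the clipped mass (single pass)
        hist += excess // 256
        hist[: int(excess % 256)] += 1
        n = int(hist.sum())
    cdf = np.cumsum(hist)
    nz = np.nonzero(hist)[0]
    if nz.size <= 1:
        return np.arange(256, dtype=np.uint8)  # no contrast to redistribute
    cdf_min = cdf[nz[0]]
    denom = n - cdf_min
    if denom <= 0:
        return np.arange(256, dtype=np.uint8)
    return np.rint((cdf - cdf_min) / denom * 255.0).clip(0, 255).astype(np.uint8)


def equalize_contrast(img: np.ndarray, params: PreprocessParams) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization, deterministic.

    The image is padded reflectively to a whole number of
    ``clahe_tile``-sized tiles; per-tile transfer functions are blended
    bilinearly between tile centres so tile seams are invisible.
    """
    params.validate()
    img8 = _as_uint8(img)
    h, w = img8.shape
    t = params.clahe_tile
    if t > min(h, w):
        raise ValueError(
            f"clahe_tile={t} exceeds the smaller image side ({min(h, w)})"
        )
    ny, nx = -(-h // t), -(-w // t)
    pad = np.pad(img8, ((0, ny * t - h), (0, nx * t - w)), mode="reflect")

    luts = np.empty((ny, nx, 256), dtype=np.uint8)
    for iy in range(ny):
        for ix in range(nx):
            luts[iy, ix] = _tile_lut(
                pad[iy * t : (iy + 1) * t, ix * t : (ix + 1) * t], params.clahe_clip
            )
    if ny == 1 and nx == 1:
        return luts[0, 0][img8]

    rows = np.arange(h, dtype=float)
    cols = np.arange(w, dtype=float)
    fy = np.clip((rows - t / 2 + 0.5) / t, 0, ny - 1)
    fx = np.clip((cols - t / 2 + 0.5) / t, 0, nx - 1)
    y0 = np.floor(fy).astype(int)
    x0 = np.floor(fx).astype(int)
    y1 = np.minimum(y0 + 1, ny - 1)
    x1 = np.minimum(x0 + 1, nx - 1)
    wy = (fy - y0)[:, None]
    wx = (fx - x0)[None, :]

    v00 = luts[y0[:, None], x0[None, :], img8].astype(float)
    v01 = luts[y0[:, None], x1[None, :], img8].astype(float)
    v10 = luts[y1[:, None], x0[None, :], img8].astype(float)
    v11 = luts[y1[:, None], x1[None, :], img8].astype(float)
    out = (
        (1 - wy) * ((1 - wx) * v00 + wx * v01)
        + wy * ((1 - wx) * v10 + wx * v11)
    )
    return np.rint(out).clip(0, 255).astype(np.uint8)


def crop_growth_boundary(
    img: np.ndarray, params: PreprocessParams
) -> tuple[np.ndarray, tuple[int, int, int, int]]:
    """Crop to the growth region; returns (crop, roi) with the half-open ROI
    so downstream coordinates can be mapped back to frame coordinates.

    Auto mode takes the tight bounding box of the largest 8-connected
    bright region under a coarse Otsu threshold, padded by ``3 *
    blur_sigma`` and clamped to the frame.  Manual mode applies the stated
    ROI unchanged.
    """
    params.validate(img.shape)
    h, w = img.shape
    if params.crop_mode == "manual":
        r0, c0, r1, c1 = params.manual_roi
        return img[r0:r1, c0:c1], (r0, c0, r1, c1)

    arr = np.asarray(img, dtype=float)
    if arr.max() == arr.min():
        raise NoGrowthRegionError("frame is constant; no growth region found")
    fg = arr > threshold_otsu(arr)
    if not fg.any():
        raise NoGrowthRegionError("no pixels above the coarse threshold")
    lab, n = ndi.label(fg, structure=np.ones((3, 3), dtype=int))
    sizes = ndi.sum_labels(fg, lab, index=np.arange(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    rows, cols = np.nonzero(lab == largest)
    pad = int(round(3 * params.blur_sigma))
    r0 = max(int(rows.min()) - pad, 0)
    r1 = min(int(rows.max()) + 1 + pad, h)
    c0 = max(int(cols.min()) - pad, 0)
    c1 = min(int(cols.max()) + 1 + pad, w)
    return img[r0:r1, c0:c1], (r0, c0, r1, c1)


def blur(img: np.ndarray, params: PreprocessParams) -> np.ndarray:
    """Separable Gaussian blur with reflective boundary; sigma=0 is the
    identity.  Returns float64 to avoid quantizing twice."""
    params.validate()
    arr = np.asarray(img, dtype=float)
    if params.blur_sigma == 0:
        return arr.copy()
    return ndi.gaussian_filter(arr, sigma=params.blur_sigma, mode="reflect")


def binarize(img: np.ndarray, params: PreprocessParams) -> BinaryMask:
    """Threshold to a cord mask and drop speckle components.

    Otsu mode maximizes between-class variance over the intensity
    histogram; foreground is strictly above the threshold.  Components
    smaller than ``min_object_px`` (8-connected) are removed because their
    skeletons would inject spurious graph components.
    """
    params.validate()
    arr = np.asarray(img, dtype=float)
    if params.threshold_method == "otsu":
        if arr.max() == arr.min():
            raise DegenerateHistogramError(
                "constant image: Otsu threshold undefined"
            )
        thr = float(threshold_otsu(arr))
    else:
        thr = float(params.fixed_threshold)
    fg = arr > thr
    if params.min_object_px > 1:
        # drop components strictly smaller than min_object_px
        fg = remove_small_objects(
            fg, connectivity=2, max_size=params.min_object_px - 1
        )
    return BinaryMask(
        pixels=fg,
        provenance={"threshold": thr, "method": params.threshold_method,
                    "min_object_px": params.min_object_px},
    )


def preprocess(img: np.ndarray, params: PreprocessParams) -> BinaryMask:
    """Full chain in the fixed order equalize -> crop -> blur -> binarize.

    The provenance record on the returned mask stores the parameters and
    the crop ROI (frame coordinates) for reproducibility.
    """
    eq = equalize_contrast(img, params)
    cropped, roi = crop_growth_boundary(eq, params)
    smooth = blur(cropped, params)
    mask = binarize(smooth, params)
    mask.provenance.update(
        {"roi": roi, "params": params.__dict__.copy()}
    )
    return mask
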