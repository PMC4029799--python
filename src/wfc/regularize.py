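"""Image regularization: remove non-pathological variation before analysis.

Screening mammograms vary in pixel spacing, matrix size, breast orientation
and exposure.  Regularization maps every image onto a common footing:

1. resample to a common pixel spacing (default 200 um),
2. pad or crop to a square canvas (default 1024 x 1024),
3. find an intensity threshold separating tissue from background with
   Otsu's method, keep the largest connected above-threshold component as
   the tissue mask and zero everything outside it (film labels and
   scanner artifacts are disconnected from the breast and are removed here),
4. mirror the image if needed so the breast sits against the left edge,
5. rescale intensities so the maximum is exactly 1.

All downstream statistics are restricted to the tissue mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.transform import rescale as _sk_rescale
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "Mammogram",
    "TissueMask",
    "rescale_to_spacing",
    "pad_or_crop",
    "otsu_threshold",
    "segment_tissue",
    "normalize_orientation",
    "normalize_intensity",
    "regularize",
    "MammogramRegularizer",
]


@dataclass
class TissueMask:
    """Boolean foreground map restricting all statistics to breast tissue."""

    mask: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def tissue_pixel_count(self) -> int:
        return int(self.mask.sum())


@dataclass
class Mammogram:
    """A single mammogram: pixel grid plus acquisition metadata.

    ``pixels`` are non-negative finite intensities on an arbitrary scale
    before regularization and on [0, 1] after.  ``pixel_spacing`` is the
    isotropic pixel size in micrometres.  ``mask`` is attached by
    segmentation and marks the image as regularized.
    """

    pixels: np.ndarray
    pixel_spacing: float
    laterality: str = "unknown"
    view: str = "medio-lateral"
    label: str = "normal"
    image_id: str = ""
    mask: Optional[TissueMask] = field(default=None, repr=False)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2D grid")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixel intensities must be finite")
        if np.any(self.pixels < 0):
            raise ValueError("pixel intensities must be non-negative")

    @property
    def shape(self):
        return self.pixels.shape


def _as_pixels(img):
    return img.pixels if isinstance(img, Mammogram) else np.asarray(img, dtype=float)


def rescale_to_spacing(img: Mammogram, target_spacing: float = 200.0) -> Mammogram:
    """Resample so one pixel covers ``target_spacing`` micrometres.

    Downsampling applies Gaussian anti-aliasing before bilinear
    interpolation; upsampling is plain bilinear.  A constant image stays
    constant and the intensity range is preserved up to interpolation.
    """
    if img.pixel_spacing is None or not img.pixel_spacing > 0:
        raise ValueError("pixel spacing must be known and positive")
    if target_spacing <= 0:
        raise ValueError("target spacing must be positive")
    factor = img.pixel_spacing / target_spacing
    if factor == 1.0:
        return replace(img, pixels=img.pixels.copy())
    out = _sk_rescale(
        img.pixels,
        factor,
        order=1,
        mode="reflect",
        anti_aliasing=factor < 1,
        preserve_range=True,
    )
    out = np.clip(out, 0.0, None)  # interpolation may undershoot at edges
    return replace(img, pixels=out, pixel_spacing=target_spacing, mask=None)


def _foreground_centroid(pixels: np.ndarray, mask: Optional[np.ndarray]) -> tuple:
    ref = mask if mask is not None else pixels > 0
    if not ref.any():
        # degenerate blank image: treat geometric centre as the centroid
        return ((pixels.shape[0] - 1) / 2.0, (pixels.shape[1] - 1) / 2.0)
    r, c = np.nonzero(ref)
    return (r.mean(), c.mean())


def pad_or_crop(img: Mammogram, size: int = 1024) -> Mammogram:
    """Standardize the canvas to ``size`` x ``size`` pixels.

    Padding uses zeros.  Horizontally the window is anchored to the
    heavier (tissue-bearing) side so the chest-wall edge is retained;
    vertically it is centred on the foreground centroid.
    """
    px = img.pixels
    rows, cols = px.shape
    left_heavy = px[:, : cols // 2].sum() >= px[:, cols - cols // 2 :].sum()

    # columns: keep the tissue-side window (or pad on the far side)
    if cols >= size:
        c0 = 0 if left_heavy else cols - size
        px = px[:, c0 : c0 + size]
    else:
        padc = size - cols
        px = np.pad(px, ((0, 0), (0, padc) if left_heavy else (padc, 0)))

    # rows: window centred on the foreground centroid
    rows = px.shape[0]
    if rows >= size:
        rc = _foreground_centroid(px, None)[0]
        r0 = int(round(rc - size / 2))
        r0 = min(max(r0, 0), rows - size)
        px = px[r0 : r0 + size, :]
    else:
        padr = size - rows
        before = padr // 2
        px = np.pad(px, ((before, padr - before), (0, 0)))

    return replace(img, pixels=px, mask=None)


def otsu_threshold(img, n_bins: int = 256) -> float:
    """Histogram threshold maximizing between-class intensity variance."""
    px = _as_pixels(img)
    if px.max() == px.min():
        raise ValueError("constant image: no threshold separates two classes")
    return float(threshold_otsu(px, nbins=n_bins))


def segment_tissue(img: Mammogram, threshold: float):
    """Keep the largest connected above-threshold component; zero the rest.

    Returns the segmented image (pixels inside the mask untouched, all
    others set exactly to 0) and the :class:`TissueMask`.  Connectivity is
    8-neighbour, so diagonal contact joins components.
    """
    fg = img.pixels > threshold
    if not fg.any():
        raise ValueError("empty foreground: threshold above every pixel")
    structure = np.ones((3, 3), dtype=bool)
    lab, n = ndimage.label(fg, structure=structure)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
    else:
        keep = 1
    mask = lab == keep
    out = np.where(mask, img.pixels, 0.0)
    tm = TissueMask(mask)
    return replace(img, pixels=out, mask=tm), tm


def normalize_orientation(img: Mammogram) -> Mammogram:
    """Mirror horizontally when the tissue centroid lies in the right half.

    After normalization the breast abuts the left edge regardless of
    laterality; applying the operation twice changes nothing.
    """
    mask = img.mask.mask if img.mask is not None else None
    _, cc = _foreground_centroid(img.pixels, mask)
    if cc > (img.pixels.shape[1] - 1) / 2.0:
        out = img.pixels[:, ::-1].copy()
        new_mask = TissueMask(mask[:, ::-1]) if mask is not None else None
        return replace(img, pixels=out, mask=new_mask)
    return img


def normalize_intensity(img: Mammogram) -> Mammogram:
    """Divide by the maximum so the brightest pixel is exactly 1."""
    m = img.pixels.max()
    if m <= 0:
        raise ValueError("all-zero image cannot be intensity-normalized")
    if m == 1.0:
        return img
    return replace(img, pixels=img.pixels / m)


def regularize(
    img: Mammogram,
    target_spacing: float = 200.0,
    size: int = 1024,
    n_bins: int = 256,
) -> Mammogram:
    """Full regularization: resample, standardize canvas, segment, orient,
    rescale intensity.

    An image that already carries a tissue mask is treated as regularized:
    the stored mask is reused instead of being re-estimated, which makes
    the pipeline idempotent (re-running it on its own output is the
    identity).
    """
    if img.mask is not None and img.pixels.shape == (size, size) and img.pixel_spacing == target_spacing:
        out = np.where(img.mask.mask, img.pixels, 0.0)
        m = replace(img, pixels=out)
        m = normalize_orientation(m)
        return normalize_intensity(m)
    m = rescale_to_spacing(img, target_spacing)
    m = pad_or_crop(m, size)
    t = otsu_threshold(m, n_bins)
    m, _ = segment_tissue(m, t)
    m = normalize_orientation(m)
    m = normalize_intensity(m)
    return m


class MammogramRegularizer(BaseEstimator, TransformerMixin):
    """Stateless transformer applying :func:`regularize` to each image.

    Parameters
    ----------
    target_spacing : float, default 200.0
        Output pixel spacing in micrometres.
    size : int, default 1024
        Output canvas side in pixels.
    n_bins : int, default 256
        Histogram bins for Otsu thresholding.
    """

    def __init__(self, target_spacing: float = 200.0, size: int = 1024, n_bins: int = 256):
        self.target_spacing = target_spacing
        self.size = size
        self.n_bins = n_bins

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return [regularize(img, self.target_spacing, self.size, self.n_bins) for img in X]
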