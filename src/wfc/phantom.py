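"""Synthetic mammogram phantoms with controllable lesion content.

The phantom emulates exactly the structure the downstream pipeline relies
on: a zero-valued background, one connected bright tissue region (a
half-ellipse abutting the chest-wall edge) filled with spatially
correlated stromal texture, and optionally a lesion:

* ``microcalc`` — a handful of 1-4 pixel Gaussian-profile very bright
  spots grouped into small clusters, mimicking microcalcifications;
* ``mass`` — one radially smooth brighter disc with a soft margin.

Texture is isotropic power-law (1/f**beta) noise, so coarse scales carry
most of the energy, as in real stroma.  Everything is deterministic in
the seed: the same spec always yields the byte-identical image, and the
base tissue is drawn from a random stream independent of the lesion
stream, so a lesioned phantom differs from its lesion-free same-seed
twin only at the lesion pixels.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .labels import validate_label
from .regularize import Mammogram

__all__ = ["PhantomSpec", "generate_phantom", "generate_dataset", "write_dataset"]

LESIONS = ("none", "microcalc", "mass")


@dataclass
class PhantomSpec:
    """Parameters of one synthetic mammogram.

    Attributes
    ----------
    seed : int
        Seeds every random stream; identical specs give identical images.
    image_size : int
        Square image side in pixels (>= 64).
    pixel_spacing : float
        Pixel size in micrometres.
    tissue_fraction : float
        Fraction of the image width spanned by the tissue half-ellipse.
    texture_exponent : float
        Spectral slope beta of the 1/f**beta stromal noise.
    lesion : {'none', 'microcalc', 'mass'}
    calc_clusters : int
        Number of microcalcification clusters.
    calc_contrast : float
        Peak added intensity of each calcification spot.
    mass_radius : float
        Mass disc radius in pixels.
    mass_contrast : float
        Peak added intensity at the mass centre.
    prevalence : float
        Fraction of abnormal images when generating a dataset.
    """

    seed: int = 0
    image_size: int = 1024
    pixel_spacing: float = 200.0
    tissue_fraction: float = 0.55
    texture_exponent: float = 2.0
    lesion: str = "none"
    calc_clusters: int = 5
    calc_contrast: float = 0.5
    mass_radius: float = 45.0
    mass_contrast: float = 0.3
    prevalence: float = 0.05
    label: Optional[str] = None

    def validate(self) -> "PhantomSpec":
        if self.image_size < 64:
            raise ValueError("image_size must be >= 64")
        if not (0.0 < self.tissue_fraction <= 1.0):
            raise ValueError("tissue_fraction must be in (0, 1]")
        if not (0.0 <= self.prevalence <= 1.0):
            raise ValueError("prevalence must be in [0, 1]")
        if self.lesion not in LESIONS:
            raise ValueError(f"lesion must be one of {LESIONS}")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")
        return self


# intensity range of the stromal texture inside tissue (background stays 0)
_TISSUE_LO, _TISSUE_HI = 0.15, 0.85
_EDGE_MARGIN = 0.08  # lesion keep-out margin, fraction of image size


def _power_law_noise(size: int, beta: float, rng: np.random.Generator) -> np.ndarray:
    """Isotropic 1/f**beta Gaussian random field, zero mean, unit spread."""
    white = rng.standard_normal((size, size))
    f = np.fft.fftfreq(size)
    fr = np.sqrt(f[:, None] ** 2 + f[None, :] ** 2)
    fr[0, 0] = fr[0, 1]  # avoid division by zero at DC
    amp = fr ** (-beta / 2.0)
    field_ = np.real(np.fft.ifft2(np.fft.fft2(white) * amp))
    field_ -= field_.mean()
    field_ /= field_.std()
    return field_


def _tissue_mask(size: int, tissue_fraction: float, side: str) -> np.ndarray:
    """Half-ellipse abutting the left or right image edge."""
    a = tissue_fraction * size          # horizontal semi-axis
    b = 0.45 * size                     # vertical semi-axis
    cy = (size - 1) / 2.0
    rows = np.arange(size)[:, None]
    cols = np.arange(size)[None, :]
    x = cols if side == "left" else (size - 1) - cols
    return (x / a) ** 2 + ((rows - cy) / b) ** 2 <= 1.0


def _interior_points(mask: np.ndarray, margin: int, n: int, rng: np.random.Generator):
    """Sample n points at least ``margin`` pixels inside the mask boundary."""
    dist = ndimage.distance_transform_edt(mask)
    r, c = np.nonzero(dist > max(1, margin))
    if r.size == 0:
        raise ValueError("lesion placement failed: tissue too small for margin")
    idx = rng.choice(r.size, size=n, replace=False if n <= r.size else True)
    return r[idx], c[idx]


def _add_microcalcs(img, mask, spec: PhantomSpec, rng) -> None:
    margin = max(8, int(_EDGE_MARGIN * spec.image_size))
    cy, cx = _interior_points(mask, margin, spec.calc_clusters, rng)
    for yc, xc in zip(cy, cx):
        n_spots = rng.integers(2, 5)
        for _ in range(n_spots):
            dy, dx = rng.integers(-4, 5, size=2)
            y, x = int(yc + dy), int(xc + dx)
            sigma = rng.uniform(0.5, 0.9)
            rad = 3
            ys = slice(max(0, y - rad), min(img.shape[0], y + rad + 1))
            xs = slice(max(0, x - rad), min(img.shape[1], x + rad + 1))
            yy, xx = np.mgrid[ys, xs]
            bump = spec.calc_contrast * np.exp(-((yy - y) ** 2 + (xx - x) ** 2) / (2 * sigma**2))
            bump[bump < 0.05 * spec.calc_contrast] = 0.0  # tight support
            patch = img[ys, xs]
            patch += np.where(mask[ys, xs], bump, 0.0)


_MASS_MARGIN_PX = 4.0  # soft-margin width of the mass disc


def _add_mass(img, mask, spec: PhantomSpec, rng) -> None:
    """Well-circumscribed dense mass: flat disc with a soft linear margin."""
    margin = max(int(spec.mass_radius) + 5, int(_EDGE_MARGIN * spec.image_size))
    cy, cx = _interior_points(mask, margin, 1, rng)
    y, x = int(cy[0]), int(cx[0])
    R = spec.mass_radius
    rad = int(np.ceil(R))
    ys = slice(max(0, y - rad), min(img.shape[0], y + rad + 1))
    xs = slice(max(0, x - rad), min(img.shape[1], x + rad + 1))
    yy, xx = np.mgrid[ys, xs]
    r = np.sqrt((yy - y) ** 2 + (xx - x) ** 2)
    profile = spec.mass_contrast * np.clip((R - r) / _MASS_MARGIN_PX, 0.0, 1.0)
    img[ys, xs] += np.where(mask[ys, xs], profile, 0.0)


def generate_phantom(spec: PhantomSpec) -> Mammogram:
    """Render one phantom mammogram from its spec.

    The background is exactly 0, tissue intensities are strictly positive,
    and the requested lesion (if any) lies wholly inside the tissue region.
    The lesion only ever *adds* intensity, so a lesioned image is pixelwise
    >= its lesion-free same-seed twin.
    """
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    base_ss, lesion_ss, meta_ss = ss.spawn(3)
    meta_rng = np.random.default_rng(meta_ss)
    side = "left" if meta_rng.random() < 0.5 else "right"

    mask = _tissue_mask(spec.image_size, spec.tissue_fraction, side)
    noise = _power_law_noise(spec.image_size, spec.texture_exponent, np.random.default_rng(base_ss))
    lo, hi = noise[mask].min(), noise[mask].max()
    tissue = _TISSUE_LO + (_TISSUE_HI - _TISSUE_LO) * (noise - lo) / (hi - lo)
    img = np.where(mask, tissue, 0.0)

    lesion_rng = np.random.default_rng(lesion_ss)
    if spec.lesion == "microcalc":
        _add_microcalcs(img, mask, spec, lesion_rng)
    elif spec.lesion == "mass":
        _add_mass(img, mask, spec, lesion_rng)

    if spec.label is not None:
        label = validate_label(spec.label)
    elif spec.lesion == "none":
        label = "normal"
    else:
        benign = lesion_rng.random() < 0.5
        kind = "calc" if spec.lesion == "microcalc" else "mass"
        label = f"{kind}_{'benign' if benign else 'malignant'}"

    return Mammogram(
        pixels=img,
        pixel_spacing=spec.pixel_spacing,
        laterality=side,
        view="medio-lateral",
        label=label,
        image_id=f"phantom-{spec.seed:010d}",
    )


def dataset_specs(
    n: int,
    prevalence: float = 0.05,
    seed: int = 0,
    template: Optional[PhantomSpec] = None,
) -> List[Tuple[str, PhantomSpec]]:
    """Deterministic per-image ``(image_id, spec)`` plan for a dataset.

    Exactly ``round(n * prevalence)`` specs are abnormal, alternating
    microcalcification and mass lesions, shuffled into a seed-determined
    order.  Generating from the same plan always yields identical images.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    template = (template or PhantomSpec()).validate()
    if not (0.0 <= prevalence <= 1.0):
        raise ValueError("prevalence must be in [0, 1]")
    ss = np.random.SeedSequence(seed)
    order_rng = np.random.default_rng(ss.spawn(1)[0])
    child_seeds = [int(s) & 0x7FFFFFFF for s in ss.generate_state(n)]

    n_abn = int(round(n * prevalence))
    lesions = ["microcalc" if i % 2 == 0 else "mass" for i in range(n_abn)]
    lesions += ["none"] * (n - n_abn)
    order = order_rng.permutation(n)
    plan = []
    for pos, k in enumerate(order):
        sp = replace(template, seed=child_seeds[pos], lesion=lesions[k], label=None)
        plan.append((f"phantom-{seed}-{pos:04d}", sp))
    return plan


def generate_dataset(
    n: int,
    prevalence: float = 0.05,
    seed: int = 0,
    template: Optional[PhantomSpec] = None,
) -> List[Mammogram]:
    """Generate ``n`` labelled phantoms with exactly ``round(n*prevalence)``
    abnormal images, alternating microcalcification and mass lesions.

    Deterministic in ``seed``: image content, lesion assignment and the
    ordering of labels are all reproducible.  For large datasets prefer
    iterating :func:`dataset_specs` and generating one image at a time.
    """
    images = []
    for image_id, sp in dataset_specs(n, prevalence, seed, template):
        m = generate_phantom(sp)
        m.image_id = image_id
        images.append(m)
    return images


def write_dataset(images: List[Mammogram], out_dir) -> Path:
    """Write images as 16-bit PNGs plus a CSV manifest; returns the manifest path.

    Pixels are rescaled to the full 16-bit range per image (downstream
    regularization renormalizes to maximum intensity anyway).
    """
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["filename", "label", "pixel_spacing_um"])
        for m in images:
            fname = f"{m.image_id}.png"
            mx = m.pixels.max()
            scale = 65535.0 / mx if mx > 0 else 0.0
            iio.imwrite(out_dir / fname, np.round(m.pixels * scale).astype(np.uint16))
            w.writerow([fname, m.label, f"{m.pixel_spacing:g}"])
    return manifest
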