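"""Whole-map moment features restricted to the tissue area.

For each wavelet map (4 maps x 8 levels) and for the raw regularized
image, four moments of the in-tissue value distribution are computed:
mean (M), population standard deviation (SD), skewness (S, third
standardized moment) and kurtosis (K, fourth standardized moment,
non-excess: a Gaussian gives 3).  That is 4 x (32 + 1) = 132 scalar
features per image per basis.

Skewness and kurtosis are the workhorses: a few very bright
microcalcification pixels barely move the mean but inflate the tails of
fine-scale detail maps, raising K and S, while a dense mass adds
structure at coarse scales.

The tissue mask is defined at full resolution; it is carried down to a
map's resolution by repeated 2x2 block-OR (inclusive: a low-resolution
cell counts as tissue if any of its parents did, keeping boundary
coefficients that carry lesion signal).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .decompose import BASES, MAP_KEYS, canonical_basis_name, decompose_tree
from .regularize import Mammogram, TissueMask

__all__ = [
    "MOMENTS",
    "FeatureId",
    "feature_ids",
    "propagate_mask",
    "moments",
    "extract_features",
    "extract_table",
    "WaveletMomentExtractor",
    "GAUSSIAN_KURTOSIS",
]

#: Moment codes in canonical order: mean, standard deviation, skewness, kurtosis.
MOMENTS = ("M", "SD", "S", "K")

#: Kurtosis convention marker: non-excess, so a Gaussian scores 3.
GAUSSIAN_KURTOSIS = 3.0

_CODEC_RE = re.compile(r"^(?P<basis>[a-z0-9.]+):(?P<moment>M|SD|S|K)-(?:(?P<map>[ahvd])(?P<level>[1-8])|raw)$")


@dataclass(frozen=True)
class FeatureId:
    """Coded coordinates of one scalar feature: (basis, moment, map, level).

    ``map='raw'`` (with ``level=0``) denotes the raw regularized image.
    The string codec follows the field's map-level shorthand, e.g.
    ``'bior2.2:M-h5'`` for the mean of the level-5 horizontal detail map,
    ``'haar:K-raw'`` for raw-image kurtosis.
    """

    basis: str
    moment: str
    map: str
    level: int

    def __post_init__(self):
        object.__setattr__(self, "basis", canonical_basis_name(self.basis))
        if self.moment not in MOMENTS:
            raise ValueError(f"moment must be one of {MOMENTS}")
        if self.map == "raw":
            if self.level != 0:
                raise ValueError("raw-image features take level=0")
        elif self.map in MAP_KEYS:
            if not 1 <= self.level <= 8:
                raise ValueError("wavelet-map level must be in 1..8")
        else:
            raise ValueError(f"map must be one of {MAP_KEYS + ('raw',)}")

    def encode(self) -> str:
        tail = "raw" if self.map == "raw" else f"{self.map}{self.level}"
        return f"{self.basis}:{self.moment}-{tail}"

    @classmethod
    def decode(cls, s: str) -> "FeatureId":
        m = _CODEC_RE.match(s)
        if not m:
            raise ValueError(f"cannot parse feature id {s!r}")
        if m.group("map") is None:
            return cls(m.group("basis"), m.group("moment"), "raw", 0)
        return cls(m.group("basis"), m.group("moment"), m.group("map"), int(m.group("level")))

    def __str__(self):
        return self.encode()

    def sort_key(self):
        return self.encode()


def feature_ids(basis: str, n_levels: int = 8) -> List[FeatureId]:
    """The 132 feature ids of one basis in canonical (moment, map, level) order."""
    basis = canonical_basis_name(basis)
    ids = []
    for mom in MOMENTS:
        for mk in MAP_KEYS:
            for lev in range(1, n_levels + 1):
                ids.append(FeatureId(basis, mom, mk, lev))
        ids.append(FeatureId(basis, mom, "raw", 0))
    return ids


def propagate_mask(mask: TissueMask, level: int) -> TissueMask:
    """Carry a full-resolution mask down ``level`` halvings by 2x2 block-OR.

    Odd dimensions are padded with background before each halving.  A
    non-empty mask never becomes empty.
    """
    m = mask.mask if isinstance(mask, TissueMask) else np.asarray(mask, dtype=bool)
    for _ in range(level):
        r, c = m.shape
        if r % 2 or c % 2:
            m = np.pad(m, ((0, r % 2), (0, c % 2)))
            r, c = m.shape
        m = m.reshape(r // 2, 2, c // 2, 2).any(axis=(1, 3))
    return TissueMask(m)


def _align_mask(mask: np.ndarray, shape: Tuple[int, int]) -> np.ndarray:
    """Centre-pad (with background) or centre-crop a mask to ``shape``.

    Boundary extension makes subbands slightly larger than n/2^L for long
    filters; the extra boundary coefficients are treated as non-tissue.
    """
    out = mask
    for ax in (0, 1):
        diff = shape[ax] - out.shape[ax]
        if diff > 0:
            before = diff // 2
            pad = [(0, 0), (0, 0)]
            pad[ax] = (before, diff - before)
            out = np.pad(out, pad)
        elif diff < 0:
            before = (-diff) // 2
            sl = [slice(None), slice(None)]
            sl[ax] = slice(before, before + shape[ax])
            out = out[tuple(sl)]
    return out


def moments(values) -> Tuple[float, float, float, float]:
    """(mean, population SD, skewness, kurtosis) of a value sample.

    Skewness is m3/sigma**3 and kurtosis m4/sigma**4 (non-excess).
    Raises on fewer than two values or a zero-spread sample, for which
    the standardized moments are undefined.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise ValueError("need at least two values")
    m = float(v.mean())
    sd = float(v.std())
    if sd == 0.0:
        raise ValueError("zero spread: skewness and kurtosis undefined")
    s = float(stats.skew(v, bias=True))
    k = float(stats.kurtosis(v, fisher=False, bias=True))
    return m, sd, s, k


def _moments_lenient(values, where: str) -> Tuple[float, float, float, float]:
    """Batch-extraction policy: zero-spread maps yield S = K = 0 with a warning."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError(f"empty tissue mask at {where}")
    m = float(v.mean())
    sd = float(v.std()) if v.size > 1 else 0.0
    if sd == 0.0:
        warnings.warn(f"degenerate (zero-spread) map at {where}; S and K set to 0")
        return m, 0.0, 0.0, 0.0
    return (m, sd, float(stats.skew(v, bias=True)), float(stats.kurtosis(v, fisher=False, bias=True)))


def extract_features(img: Mammogram, mask: TissueMask, tree) -> pd.Series:
    """The 132-feature vector of one image under one basis.

    Moments are computed over in-mask coefficients only, with the mask
    propagated to each map's level; the raw regularized image contributes
    the 33rd "map".  Returned as a Series indexed by codec strings in
    canonical order.
    """
    basis = tree.basis.name
    n_levels = tree.n_levels
    raw_vals = img.pixels[mask.mask]

    level_masks = {}
    m = mask.mask
    for lev in range(1, n_levels + 1):
        m = propagate_mask(m, 1).mask
        level_masks[lev] = m

    per_map = {}
    for lev in range(1, n_levels + 1):
        for mk in MAP_KEYS:
            arr = tree.map(lev, mk)
            aligned = _align_mask(level_masks[lev], arr.shape)
            per_map[(mk, lev)] = _moments_lenient(arr[aligned], f"{basis}:{mk}{lev}")
    raw_moments = _moments_lenient(raw_vals, f"{basis}:raw")

    out = {}
    for i, mom in enumerate(MOMENTS):
        for mk in MAP_KEYS:
            for lev in range(1, n_levels + 1):
                out[FeatureId(basis, mom, mk, lev).encode()] = per_map[(mk, lev)][i]
        out[FeatureId(basis, mom, "raw", 0).encode()] = raw_moments[i]
    s = pd.Series(out, name=img.image_id)
    if not np.all(np.isfinite(s.values)):
        raise ValueError("non-finite feature value encountered")
    return s


def extract_table(
    images: Iterable[Mammogram],
    bases: Sequence[str] = BASES,
    n_levels: int = 8,
    mode: str = "symmetric",
) -> pd.DataFrame:
    """Feature table: one row per regularized image, one column per feature.

    Images must carry their tissue masks (i.e. be regularized).  Columns
    are the codec strings of every basis in ``bases``, preceded by
    ``image_id`` and ``label``.
    """
    bases = [canonical_basis_name(b) for b in bases]
    rows = []
    for img in images:
        if img.mask is None:
            raise ValueError(f"image {img.image_id!r} has no tissue mask; regularize first")
        parts = []
        for b in bases:
            tree = decompose_tree(img, b, n_levels=n_levels, mode=mode)
            parts.append(extract_features(img, img.mask, tree))
        row = pd.concat(parts)
        row["image_id"] = img.image_id
        row["label"] = img.label
        rows.append(row)
    df = pd.DataFrame(rows).reset_index(drop=True)
    meta = ["image_id", "label"]
    return df[meta + [c for c in df.columns if c not in meta]]


class WaveletMomentExtractor(BaseEstimator, TransformerMixin):
    """Transformer: regularized mammograms -> wavelet-moment feature table.

    Parameters
    ----------
    bases : sequence of str or 'all'
        Wavelet bases to decompose with (132 features each).
    n_levels : int, default 8
        Decomposition depth.
    mode : {'symmetric', 'periodic'}, default 'symmetric'
        Boundary extension.
    """

    def __init__(self, bases="all", n_levels: int = 8, mode: str = "symmetric"):
        self.bases = bases
        self.n_levels = n_levels
        self.mode = mode

    def _bases(self):
        return BASES if self.bases == "all" else tuple(self.bases)

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> pd.DataFrame:
        return extract_table(X, self._bases(), self.n_levels, self.mode)
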