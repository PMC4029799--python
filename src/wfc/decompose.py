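"""Multi-level separable 2D discrete wavelet decomposition.

Each level of the transform splits the current approximation into four
half-resolution maps: a new approximation (``a``, low-pass both ways) and
horizontal / vertical / diagonal detail maps (``h``, ``v``, ``d``).  Eight
levels applied serially to a 1024 x 1024 image span structure from ~2 to
~512 pixels across.  Eleven bases are supported: Haar, Daubechies 2/4/8
and the biorthogonal 1.5, 2.2, 2.8, 3.7, 4.4, 5.5, 6.8 pairs.

Filters use the orthonormal (1/sqrt(2)) normalization, so for orthogonal
bases the transform conserves energy; the boundary is extended
half-sample-symmetrically by default, with a periodic mode available
(exact dyadic shapes and perfect reconstruction for every basis).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np
import pywt

from .regularize import Mammogram

__all__ = [
    "BASES",
    "WaveletBasis",
    "WaveletMapSet",
    "dwt2_single_level",
    "decompose_tree",
    "reconstruct",
]

#: The eleven supported wavelet bases (canonical lower-case names).
BASES = (
    "haar",
    "db2",
    "db4",
    "db8",
    "bior1.5",
    "bior2.2",
    "bior2.8",
    "bior3.7",
    "bior4.4",
    "bior5.5",
    "bior6.8",
)

MAP_KEYS = ("a", "h", "v", "d")

_MODES = {"symmetric": "symmetric", "periodic": "periodization"}


def canonical_basis_name(name: str) -> str:
    """Normalize e.g. 'Bior2.2' or 'Db 2' to the canonical lower-case form."""
    key = name.strip().lower().replace(" ", "")
    if key not in BASES:
        raise ValueError(f"unknown wavelet basis {name!r}; expected one of {BASES}")
    return key


class WaveletBasis:
    """One of the eleven supported bases, wrapping its filter bank."""

    def __init__(self, name: str):
        self.name = canonical_basis_name(name)
        self.wavelet = pywt.Wavelet(self.name)

    @property
    def dec_len(self) -> int:
        return self.wavelet.dec_len

    @property
    def orthogonal(self) -> bool:
        return bool(self.wavelet.orthogonal)

    @property
    def filters(self) -> Tuple[np.ndarray, np.ndarray]:
        """Decomposition (low-pass, high-pass) filter coefficients."""
        return (np.asarray(self.wavelet.dec_lo), np.asarray(self.wavelet.dec_hi))

    def __repr__(self):
        return f"WaveletBasis({self.name!r})"

    def __eq__(self, other):
        return isinstance(other, WaveletBasis) and other.name == self.name

    def __hash__(self):
        return hash(("WaveletBasis", self.name))


def _as_basis(basis) -> WaveletBasis:
    return basis if isinstance(basis, WaveletBasis) else WaveletBasis(basis)


def _pywt_mode(mode: str) -> str:
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {tuple(_MODES)}")
    return _MODES[mode]


@dataclass
class WaveletMapSet:
    """The decomposition tree of one image under one basis.

    ``levels[L]`` holds the four maps ``{'a','h','v','d'}`` at level L
    (1-based); the level-L input is the level-(L-1) approximation.
    ``input_shapes[L]`` records the shape of that input, which the
    inverse transform needs to undo boundary extension exactly.
    """

    basis: WaveletBasis
    mode: str
    original_shape: Tuple[int, int]
    levels: Dict[int, Dict[str, np.ndarray]] = field(default_factory=dict)
    input_shapes: Dict[int, Tuple[int, int]] = field(default_factory=dict)

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def map(self, level: int, key: str) -> np.ndarray:
        return self.levels[level][key]


def dwt2_single_level(arr: np.ndarray, basis, mode: str = "symmetric"):
    """One separable analysis step with dyadic decimation.

    Returns the ``(a, h, v, d)`` quadruple at half resolution.  The input
    must be at least as large as the decomposition filter in both
    dimensions.
    """
    basis = _as_basis(basis)
    arr = np.asarray(arr, dtype=float)
    if arr.ndim != 2:
        raise ValueError("input must be 2D")
    # symmetric extension needs the full filter support; periodic wrap-around
    # stays well-defined (and invertible) down to two samples per axis
    min_side = 2 if mode == "periodic" else basis.dec_len
    if min(arr.shape) < min_side:
        raise ValueError(
            f"map of shape {arr.shape} is too small for the {basis.name} "
            f"filter (support {basis.dec_len}) in {mode} mode"
        )
    a, (h, v, d) = pywt.dwt2(arr, basis.wavelet, mode=_pywt_mode(mode))
    return a, h, v, d


def decompose_tree(img, basis, n_levels: int = 8, mode: str = "symmetric") -> WaveletMapSet:
    """Serial multi-level decomposition retaining all four maps per level."""
    basis = _as_basis(basis)
    arr = img.pixels if isinstance(img, Mammogram) else np.asarray(img, dtype=float)
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")

    min_side = 2 if mode == "periodic" else basis.dec_len
    tree = WaveletMapSet(basis=basis, mode=mode, original_shape=arr.shape)
    approx = arr
    for lev in range(1, n_levels + 1):
        if min(approx.shape) < min_side:
            raise ValueError(
                f"cannot decompose to level {lev}: level input {approx.shape} "
                f"too small for the {basis.name} filter in {mode} mode"
            )
        tree.input_shapes[lev] = approx.shape
        a, h, v, d = dwt2_single_level(approx, basis, mode)
        tree.levels[lev] = {"a": a, "h": h, "v": v, "d": d}
        approx = a
    return tree


def reconstruct(tree: WaveletMapSet) -> np.ndarray:
    """Invert the decomposition back to the original image.

    Uses the synthesis filter bank (for biorthogonal bases this differs
    from the analysis bank); exact for every basis in periodic mode.
    """
    mode = _pywt_mode(tree.mode)
    wavelet = tree.basis.wavelet
    n = tree.n_levels
    approx = tree.levels[n]["a"]
    for lev in range(n, 0, -1):
        maps = tree.levels[lev]
        out = pywt.idwt2((approx, (maps["h"], maps["v"], maps["d"])), wavelet, mode=mode)
        r, c = tree.input_shapes[lev]
        approx = out[:r, :c]
    return approx
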