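"""Multiscale wavelet decomposition of square grayscale images.

The scrambling machinery represents each detail location as a 3D
*orientation vector* whose components are the horizontal, vertical and
diagonal wavelet coefficients at that (scale, row, col).  This module
provides the lossless decompose/reconstruct round trip (built on
PyWavelets with periodic boundary handling, so coefficient counts are
exact powers of two) and the vector view of the detail bands.
"""

from __future__ import annotations

import dataclasses
from typing import Iterator

import numpy as np
import pywt

__all__ = [
    "WaveletPyramid",
    "decompose",
    "reconstruct",
    "orientation_vectors",
    "pyramid_from_vectors",
    "load_image",
    "save_image",
    "to_gray",
    "save_pyramid",
    "load_pyramid",
]

#: default orthogonal 4-tap Daubechies filter; orthogonality is what makes
#: the transform energy preserving (Parseval), which the isoenergetic
#: scrambling relies on.
DEFAULT_WAVELET = "db2"
_MODE = "periodization"


@dataclasses.dataclass
class WaveletPyramid:
    """Full dyadic wavelet decomposition of a square image.

    Attributes
    ----------
    approx : ndarray
        Coarsest low-pass (approximation) band.  Never scrambled: it
        carries the local luminance modulation that SWIFT preserves.
    details : list of (H, V, D) ndarray triples
        Detail bands ordered coarsest-first (PyWavelets convention).
        ``details[k]`` has side ``side / 2**(levels - k)``.
    wavelet : str
        PyWavelets wavelet name.
    """

    approx: np.ndarray
    details: list[tuple[np.ndarray, np.ndarray, np.ndarray]]
    wavelet: str = DEFAULT_WAVELET

    @property
    def levels(self) -> int:
        return len(self.details)

    @property
    def side(self) -> int:
        return self.details[-1][0].shape[0] * 2

    @property
    def n_detail_coefficients(self) -> int:
        return sum(3 * h.size for h, _, _ in self.details)

    def copy(self) -> "WaveletPyramid":
        return WaveletPyramid(
            self.approx.copy(),
            [(h.copy(), v.copy(), d.copy()) for h, v, d in self.details],
            self.wavelet,
        )

    def detail_energy(self) -> float:
        """Total squared magnitude of all detail coefficients."""
        return float(sum((h * h + v * v + d * d).sum() for h, v, d in self.details))

    def iter_keys(self) -> Iterator[tuple[int, int, int]]:
        """Yield (scale_index, row, col) for every detail location."""
        for s, (h, _, _) in enumerate(self.details):
            for r in range(h.shape[0]):
                for c in range(h.shape[1]):
                    yield (s, r, c)


def _check_image(image: np.ndarray, levels: int) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError(f"image must be square 2D, got shape {image.shape}")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    side = image.shape[0]
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if side % (2 ** levels) != 0:
        raise ValueError(
            f"image side {side} is not divisible by 2**levels = {2 ** levels}"
        )
    return image


def decompose(image: np.ndarray, levels: int, wavelet: str = DEFAULT_WAVELET) -> WaveletPyramid:
    """Dyadic 2D DWT with periodic boundaries.

    The image must be square with side divisible by ``2**levels``; with
    periodization each detail band at scale *s* has exactly
    ``(side / 2**s)**2`` coefficients per orientation.
    """
    image = _check_image(image, levels)
    import warnings

    with warnings.catch_warnings():
        # with periodization and a side divisible by 2**levels the deep
        # decomposition is still exactly invertible; pywt's generic
        # boundary-effect warning does not apply
        warnings.filterwarnings("ignore", message="Level value .* too high")
        coeffs = pywt.wavedec2(image, wavelet, mode=_MODE, level=levels)
    approx = coeffs[0]
    details = [(np.asarray(h), np.asarray(v), np.asarray(d)) for h, v, d in coeffs[1:]]
    return WaveletPyramid(np.asarray(approx), details, wavelet)


def reconstruct(pyramid: WaveletPyramid) -> np.ndarray:
    """Inverse transform; exact inverse of :func:`decompose` to ~1e-10."""
    side = pyramid.approx.shape[0]
    for h, v, d in pyramid.details:
        if h.shape != v.shape or h.shape != d.shape:
            raise ValueError("orientation bands within a scale differ in shape")
        if h.shape[0] != side:
            raise ValueError(
                f"scale shape {h.shape} inconsistent with expected side {side}"
            )
        side *= 2
    coeffs = [pyramid.approx] + [tuple(bands) for bands in pyramid.details]
    return pywt.waverec2(coeffs, pyramid.wavelet, mode=_MODE)


def orientation_vectors(pyramid: WaveletPyramid) -> list[np.ndarray]:
    """Detail bands as orientation-vector arrays.

    Returns one array per scale (coarsest first) of shape ``(h, w, 3)``
    where the last axis stacks the (H, V, D) coefficients.  The vector's
    Euclidean norm is the coefficient's local energy, the quantity the
    isoenergetic scrambling paths conserve.
    """
    return [np.stack([h, v, d], axis=-1) for h, v, d in pyramid.details]


def pyramid_from_vectors(
    vectors: list[np.ndarray], approx: np.ndarray, wavelet: str = DEFAULT_WAVELET
) -> WaveletPyramid:
    """Rebuild a pyramid from per-scale orientation-vector arrays."""
    details = [(a[..., 0], a[..., 1], a[..., 2]) for a in vectors]
    return WaveletPyramid(np.asarray(approx, dtype=float), details, wavelet)


# ---------------------------------------------------------------------------
# image I/O helpers

def to_gray(arr: np.ndarray) -> np.ndarray:
    """Convert an array read from an image file to [0, 1] grayscale."""
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 3:  # RGB(A) -> luma
        arr = arr[..., :3] @ np.array([0.2126, 0.7152, 0.0722])
    lo, hi = arr.min(), arr.max()
    if hi > lo:
        arr = (arr - lo) / (hi - lo)
    else:
        arr = np.zeros_like(arr)
    return arr


def _crop_power_of_two(arr: np.ndarray, side: int | None = None) -> np.ndarray:
    n = min(arr.shape)
    if side is None:
        side = 2 ** int(np.floor(np.log2(n)))
    if side > n:
        raise ValueError(f"requested side {side} exceeds image size {arr.shape}")
    r0 = (arr.shape[0] - side) // 2
    c0 = (arr.shape[1] - side) // 2
    return arr[r0 : r0 + side, c0 : c0 + side]


def load_image(path, side: int | None = None) -> np.ndarray:
    """Read PNG/JPEG/TIFF, grayscale it, normalize to [0,1], center-crop
    to a power-of-two square (largest that fits unless ``side`` given)."""
    import imageio.v3 as iio

    return _crop_power_of_two(to_gray(iio.imread(path)), side)


def save_image(path, image: np.ndarray) -> None:
    import imageio.v3 as iio

    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    iio.imwrite(path, (arr * 255).round().astype(np.uint8))


def save_pyramid(path, pyramid: WaveletPyramid) -> None:
    """Serialize a pyramid to a single .npz archive."""
    payload = {"approx": pyramid.approx, "wavelet": np.array(pyramid.wavelet)}
    for s, (h, v, d) in enumerate(pyramid.details):
        payload[f"H{s}"], payload[f"V{s}"], payload[f"D{s}"] = h, v, d
    np.savez(path, **payload)


def load_pyramid(path) -> WaveletPyramid:
    with np.load(path) as z:
        wavelet = str(z["wavelet"])
        details = []
        s = 0
        while f"H{s}" in z:
            details.append((z[f"H{s}"], z[f"V{s}"], z[f"D{s}"]))
            s += 1
        return WaveletPyramid(z["approx"], details, wavelet)
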