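"""Deterministic synthetic stimulus images.

Stand-ins for natural photographs, generated programmatically: the
"geometric-face" and "geometric-scene" kinds contain long coherent
contours with category-like layout, while "texture" is a Fourier
phase-randomized control with the same amplitude spectrum as the face
fixture (so radially averaged spectra match by construction).
"""

from __future__ import annotations

import numpy as np

__all__ = ["fixture_images", "radial_spectrum"]


def _grid(side: int):
    y, x = np.mgrid[0:side, 0:side]
    return (x - side / 2) / side, (y - side / 2) / side


def _face(side: int, rng: np.random.Generator) -> np.ndarray:
    x, y = _grid(side)
    img = np.full((side, side), 0.5)
    # head outline
    img += 0.4 * np.exp(-(((x / 0.28) ** 2 + (y / 0.36) ** 2) - 1) ** 2 / 0.004)
    # eyes
    for ex in (-0.11, 0.11):
        img -= 0.35 * np.exp(-(((x - ex) / 0.045) ** 2 + ((y + 0.10) / 0.028) ** 2))
    # nose and mouth contours
    img -= 0.2 * np.exp(-((x / 0.015) ** 2 + ((y - 0.02) / 0.09) ** 2))
    img -= 0.3 * np.exp(-((x / 0.12) ** 2 + ((y - 0.16) / 0.018) ** 2))
    img += 0.02 * rng.standard_normal((side, side))
    return np.clip(img, 0, 1)


def _scene(side: int, rng: np.random.Generator) -> np.ndarray:
    x, y = _grid(side)
    img = 0.35 + 0.3 * (y > 0.05)  # ground/sky horizon
    # a few "buildings": rectangles of coherent vertical/horizontal edges
    for _ in range(6):
        cx = rng.uniform(-0.4, 0.4)
        w = rng.uniform(0.04, 0.12)
        h = rng.uniform(0.1, 0.35)
        shade = rng.uniform(0.15, 0.75)
        img = np.where((np.abs(x - cx) < w) & (y > 0.05 - h) & (y < 0.05), shade, img)
    img = img + 0.02 * rng.standard_normal((side, side))
    return np.clip(img, 0, 1)


def _phase_scramble(img: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    f = np.fft.fft2(img - img.mean())
    # the phase of a random *real* field is Hermitian-symmetric, so the
    # scramble is exactly real and the amplitude spectrum is preserved
    phase = np.exp(1j * np.angle(np.fft.fft2(rng.standard_normal(img.shape))))
    scr = np.fft.ifft2(np.abs(f) * phase).real
    scr = scr - scr.min()
    if scr.max() > 0:
        scr /= scr.max()
    return scr


def fixture_images(kind: str, side: int = 512, seed: int = 0) -> np.ndarray:
    """Deterministic synthetic grayscale image in [0, 1].

    ``kind`` is one of "geometric-face", "geometric-scene" or "texture"
    (the phase-scrambled, spectrum-matched control of the face fixture).
    ``side`` must be a power of two.
    """
    if side < 2 or side & (side - 1):
        raise ValueError("side must be a power of two")
    rng = np.random.default_rng(seed)
    if kind == "geometric-face":
        return _face(side, rng)
    if kind == "geometric-scene":
        return _scene(side, rng)
    if kind == "texture":
        return _phase_scramble(_face(side, rng), rng)
    raise ValueError(f"unknown fixture kind {kind!r}")


def radial_spectrum(image: np.ndarray, n_bins: int = 32) -> np.ndarray:
    """Radially averaged amplitude spectrum (DC excluded)."""
    f = np.abs(np.fft.fftshift(np.fft.fft2(image - image.mean())))
    side = image.shape[0]
    y, x = np.mgrid[0:side, 0:side]
    r = np.hypot(x - side / 2, y - side / 2)
    edges = np.linspace(1, side / 2, n_bins + 1)
    out = np.empty(n_bins)
    for i in range(n_bins):
        m = (r >= edges[i]) & (r < edges[i + 1])
        out[i] = f[m].mean()
    return out
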