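"""Core SWIFT algorithm: isoenergetic circular scrambling in the wavelet domain.

Each detail location's (H, V, D) coefficient triple is a 3D orientation
vector.  For every location we draw two random vectors of the same norm;
the unique circle through the three equal-norm points lies on their common
sphere, so traversing it modulates local contour orientation while
conserving the coefficient's energy exactly (isoenergetic path).  Each
coefficient is assigned a harmonic h in {1..n_harmonics} and advances
along its circle at angle 2*pi*h*t/frames_per_cycle, so all coefficients
re-align with the original image only once per cycle — the *semantic
onset* — while intermediate frames are scrambles with identical local
luminance, local spatial frequency and global contrast.

The relative image similarity (RIS, 0-100) quantifies per-frame closeness
to the original: the mean over coefficients of (1 - |dW|), with |dW| the
coefficient deviation normalized to its maximum attainable on the path,
times 100.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .wavelet import WaveletPyramid, decompose, orientation_vectors, reconstruct

__all__ = [
    "CircularPath",
    "ScrambleSchedule",
    "SwiftMovie",
    "build_isoenergetic_path",
    "make_schedule",
    "render_frame",
    "generate_movie",
    "ris",
    "ris_curve",
]

_TINY = 1e-300


@dataclasses.dataclass
class CircularPath:
    """Isoenergetic circle(s) in (H, V, D) space, vectorized over locations.

    Arrays have shape ``(..., 3)`` for ``center``, ``u`` and ``v`` and
    ``(...,)`` for ``radius``.  The parametrization is

        path(theta) = center + radius * (u*cos(theta) + v*sin(theta))

    with ``path(0)`` equal to the anchor vector exactly.  Because the
    circle is the intersection of its plane with the sphere of the
    anchor's norm centered at the origin, every point has the anchor's
    norm.  A zero anchor yields the degenerate constant path at the
    origin (radius 0), by construction rather than as an error.
    """

    center: np.ndarray
    u: np.ndarray
    v: np.ndarray
    radius: np.ndarray

    def __call__(self, theta) -> np.ndarray:
        theta = np.asarray(theta)
        rad = self.radius[..., None]
        return self.center + rad * (
            self.u * np.cos(theta)[..., None] + self.v * np.sin(theta)[..., None]
        )

    def component_normalizers(self) -> np.ndarray:
        """Maximum |anchor_i - path_i(theta)| over theta, per component.

        With a = anchor = center + radius*u, the deviation along component
        i is radius*(u_i*(1-cos t) - v_i*sin t) whose maximum magnitude is
        radius*(|u_i| + sqrt(u_i**2 + v_i**2)).  This is the RIS
        normalizer: the largest deviation the schedule can actually
        produce for that scalar coefficient.
        """
        amp = np.sqrt(self.u ** 2 + self.v ** 2)
        return self.radius[..., None] * (np.abs(self.u) + amp)


def build_isoenergetic_path(anchor: np.ndarray, rng: np.random.Generator) -> CircularPath:
    """Circle through ``anchor`` and two random vectors of equal norm.

    ``anchor`` may be a single 3-vector or an array of shape (..., 3);
    paths are built independently per leading index.
    """
    anchor = np.asarray(anchor, dtype=float)
    squeeze = anchor.ndim == 1
    a = np.atleast_2d(anchor)
    shape = a.shape[:-1]
    r = np.linalg.norm(a, axis=-1)
    # work on the unit sphere for numerical scale invariance; rescale at
    # the end (zero anchors degenerate to the constant path at origin)
    pos = r > 0
    ah = np.where(pos[..., None], a / np.maximum(r, _TINY)[..., None], 0.0)

    def _rand_units():
        g = rng.standard_normal(shape + (3,))
        return g / np.maximum(np.linalg.norm(g, axis=-1, keepdims=True), _TINY)

    p2, p3 = _rand_units(), _rand_units()
    n = np.cross(p2 - ah, p3 - ah)
    nn = np.linalg.norm(n, axis=-1)
    # resample degenerate draws (collinear points)
    bad = (nn < 1e-12) & pos
    while np.any(bad):
        g2, g3 = _rand_units(), _rand_units()
        p2 = np.where(bad[..., None], g2, p2)
        p3 = np.where(bad[..., None], g3, p3)
        n = np.cross(p2 - ah, p3 - ah)
        nn = np.linalg.norm(n, axis=-1)
        bad = (nn < 1e-12) & pos

    nhat = n / np.maximum(nn, _TINY)[..., None]
    # circle center = foot of the perpendicular from the origin to the plane
    d = np.einsum("...i,...i->...", ah, nhat)
    center = d[..., None] * nhat
    rad_vec = ah - center
    radius = np.linalg.norm(rad_vec, axis=-1)
    ok = pos & (radius > 0)
    u = np.where(ok[..., None], rad_vec / np.maximum(radius, _TINY)[..., None], 0.0)
    v = np.where(ok[..., None], np.cross(nhat, u), 0.0)
    center = np.where(ok[..., None], center, ah)  # degenerate: constant at anchor
    radius = np.where(ok, radius, 0.0)
    # rescale from the unit sphere to the anchor norm
    center = center * r[..., None]
    radius = radius * r
    if squeeze:
        center, u, v, radius = center[0], u[0], v[0], radius[0]
    return CircularPath(center, u, v, radius)


@dataclasses.dataclass
class ScrambleSchedule:
    """Per-coefficient circular paths plus harmonic temporal assignments.

    ``paths[g][s]`` is the :class:`CircularPath` set for geometry *g* and
    scale *s* (coarsest first); ``harmonics[s]`` is the integer harmonic
    per location.  Consecutive cycles rotate through ``n_geometries``
    independently randomized path geometries, so successive cycles
    traverse different scrambles while every cycle still anchors at the
    original at frame indices that are multiples of ``frames_per_cycle``.
    """

    paths: list[list[CircularPath]]
    harmonics: list[np.ndarray]
    frames_per_cycle: int
    n_harmonics: int
    seed: int

    @property
    def n_geometries(self) -> int:
        return len(self.paths)

    def angles(self, t: int, scale: int) -> np.ndarray:
        t_eff = int(t) % self.frames_per_cycle  # exact zero at onsets
        return 2.0 * np.pi * self.harmonics[scale] * t_eff / self.frames_per_cycle

    def geometry_at(self, t: int) -> int:
        return (int(t) // self.frames_per_cycle) % self.n_geometries

    def ris_normalizers(self, geometry: int = 0) -> list[np.ndarray]:
        """Per-scale (h, w, 3) maximal attainable coefficient deviations."""
        return [p.component_normalizers() for p in self.paths[geometry]]


def make_schedule(
    pyramid: WaveletPyramid,
    n_harmonics: int = 8,
    frames_per_cycle: int = 200,
    seed: int = 0,
    n_geometries: int = 3,
) -> ScrambleSchedule:
    """Build the scrambling schedule for a pyramid.

    Harmonics are drawn independently and uniformly from
    {1..n_harmonics} per coefficient location (shared across the H/V/D
    triple, which moves as one 3D vector); the paths are drawn
    independently per geometry.
    """
    if n_harmonics < 1:
        raise ValueError("n_harmonics must be >= 1")
    if frames_per_cycle < 2:
        raise ValueError("frames_per_cycle must be >= 2")
    if n_geometries < 1:
        raise ValueError("n_geometries must be >= 1")
    rng = np.random.default_rng(seed)
    vecs = orientation_vectors(pyramid)
    harmonics = [
        rng.integers(1, n_harmonics + 1, size=a.shape[:-1]) for a in vecs
    ]
    paths = [
        [build_isoenergetic_path(a, rng) for a in vecs] for _ in range(n_geometries)
    ]
    return ScrambleSchedule(paths, harmonics, frames_per_cycle, n_harmonics, seed)


def _scrambled_vectors(schedule: ScrambleSchedule, t: int) -> list[np.ndarray]:
    g = schedule.geometry_at(t)
    out = []
    for s, path in enumerate(schedule.paths[g]):
        theta = schedule.angles(t, s)
        out.append(path(theta))
    return out


def render_frame(
    pyramid: WaveletPyramid, schedule: ScrambleSchedule, t: int
) -> np.ndarray:
    """Render movie frame ``t``: scrambled details, untouched approximation."""
    return reconstruct(scrambled_pyramid(pyramid, schedule, t))


def scrambled_pyramid(
    pyramid: WaveletPyramid, schedule: ScrambleSchedule, t: int
) -> WaveletPyramid:
    """Coefficient-domain frame ``t`` (before inverse transform)."""
    if len(schedule.harmonics) != pyramid.levels:
        raise ValueError("schedule was built for a different number of levels")
    for h_arr, (h, _, _) in zip(schedule.harmonics, pyramid.details):
        if h_arr.shape != h.shape:
            raise ValueError("schedule/pyramid shape mismatch")
    vecs = _scrambled_vectors(schedule, t)
    details = [(a[..., 0], a[..., 1], a[..., 2]) for a in vecs]
    return WaveletPyramid(pyramid.approx, details, pyramid.wavelet)


class SwiftMovie:
    """Lazy SWIFT movie: frames are rendered on demand.

    Frame indexing is 0-based; the semantic onset of cycle *k* is frame
    ``k * frames_per_cycle``, at which every coefficient sits exactly at
    its anchor and the original image is reproduced.
    """

    def __init__(self, pyramid: WaveletPyramid, schedule: ScrambleSchedule, n_cycles: int):
        self.pyramid = pyramid
        self.schedule = schedule
        self.n_cycles = int(n_cycles)

    @property
    def frames_per_cycle(self) -> int:
        return self.schedule.frames_per_cycle

    @property
    def semantic_onset_frames(self) -> list[int]:
        return [k * self.frames_per_cycle for k in range(self.n_cycles)]

    def __len__(self) -> int:
        return self.n_cycles * self.frames_per_cycle

    def __getitem__(self, t: int) -> np.ndarray:
        if not (-len(self) <= t < len(self)):
            raise IndexError(t)
        return render_frame(self.pyramid, self.schedule, t % len(self))

    def frame_pyramid(self, t: int) -> WaveletPyramid:
        return scrambled_pyramid(self.pyramid, self.schedule, t)

    def iter_frames(self):
        for t in range(len(self)):
            yield self[t]

    def materialize(self, dtype=np.float64) -> np.ndarray:
        return np.stack([f.astype(dtype) for f in self.iter_frames()])


def generate_movie(
    image: np.ndarray,
    levels: int = 9,
    n_harmonics: int = 8,
    frames_per_cycle: int = 200,
    n_cycles: int = 3,
    seed: int = 0,
    wavelet: str | None = None,
    n_geometries: int = 3,
) -> SwiftMovie:
    """Build a SWIFT movie from a grayscale image.

    Defaults follow the stimulus-generation configuration used
    throughout: 9 decomposition levels, 8 harmonics, 200 frames per
    cycle, 3 independently randomized scrambling geometries.
    """
    kwargs = {} if wavelet is None else {"wavelet": wavelet}
    pyramid = decompose(image, levels, **kwargs)
    schedule = make_schedule(
        pyramid, n_harmonics, frames_per_cycle, seed=seed, n_geometries=n_geometries
    )
    return SwiftMovie(pyramid, schedule, n_cycles)


def ris(
    reference: WaveletPyramid,
    frame_pyramid: WaveletPyramid,
    normalizer: list[np.ndarray],
) -> float:
    """Relative image similarity between a reference and a rendered frame.

    RIS = (100/n) * sum_c (1 - |dW_c|) with
    |dW_c| = min(1, |W_c^ref - W_c^frame| / normalizer_c), summed over
    the n detail coefficients (the approximation band, being never
    scrambled, is excluded).  100 at identity, 0 when every coefficient
    sits at its maximal attainable deviation.  Coefficients whose path
    cannot deviate (zero normalizer) contribute perfect similarity.
    """
    ref_v = orientation_vectors(reference)
    frm_v = orientation_vectors(frame_pyramid)
    if len(ref_v) != len(frm_v):
        raise ValueError("pyramids have different numbers of levels")
    total = 0.0
    n = 0
    for rv, fv, nz in zip(ref_v, frm_v, normalizer):
        if rv.shape != fv.shape:
            raise ValueError("pyramid scale shapes differ")
        diff = np.abs(rv - fv)
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.where(nz > 0, diff / np.where(nz > 0, nz, 1.0), 0.0)
        rel = np.minimum(rel, 1.0)
        total += float((1.0 - rel).sum())
        n += rv.size
    return 100.0 * total / n


def ris_curve(movie: SwiftMovie) -> np.ndarray:
    """Per-frame RIS of a movie against its own source pyramid."""
    norms = {
        g: movie.schedule.ris_normalizers(g) for g in range(movie.schedule.n_geometries)
    }
    out = np.empty(len(movie))
    for t in range(len(movie)):
        g = movie.schedule.geometry_at(t)
        out[t] = ris(movie.pyramid, movie.frame_pyramid(t), norms[g])
    return out
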