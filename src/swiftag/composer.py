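"""Composite SWIFT runs: alpha-blended multi-stream movies.

Two or three category streams (e.g. a face, a scene, an object), each an
isoenergetic SWIFT movie at its own tagging frequency, are superimposed
by alpha blending so every frame carries all categories' low-level
features while each category's semantic content is revealed periodically
at its own rate (0.06 / 0.08 / 0.10 Hz in the reference configuration).
Runs are divided into segments that switch image exemplars without
resetting the scrambling-cycle phase, so semantic onsets stay strictly
periodic across the whole run while exemplar changes recur only at the
very low segment frequency (1/180 s ~ 0.0056 Hz), far from the tagging
frequencies.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np

from .scramble import SwiftMovie, generate_movie

__all__ = ["StreamSpec", "CompositeRun", "blend", "schedule_run", "render_run", "export_run"]


@dataclasses.dataclass
class StreamSpec:
    """One category stream of a composite run.

    ``images`` lists one exemplar per segment (an entry may repeat); the
    stream is tagged at ``tagging_frequency`` Hz and contributes with
    blend weight ``alpha``.
    """

    images: list
    tagging_frequency: float
    alpha: float
    name: str = ""

    def __post_init__(self):
        if self.tagging_frequency <= 0:
            raise ValueError("tagging_frequency must be positive")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")


@dataclasses.dataclass
class StreamSchedule:
    spec: StreamSpec
    frames_per_cycle: int
    start_frame: int
    onset_times: np.ndarray  # seconds


@dataclasses.dataclass
class CompositeRun:
    """Scheduled (and optionally rendered) composite SWIFT run."""

    streams: list[StreamSchedule]
    fps: float
    duration: float
    segment_duration: float
    seed: int
    frames: np.ndarray | None = None  # (n_frames, side, side) once rendered

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.fps))

    @property
    def segment_boundaries(self) -> np.ndarray:
        """Times (s) at which the exemplar segment changes."""
        n_seg = int(round(self.duration / self.segment_duration))
        return np.arange(1, n_seg) * self.segment_duration

    @property
    def segment_recurrence_hz(self) -> float:
        """Fundamental frequency of exemplar-change events (1/segment)."""
        return 1.0 / self.segment_duration

    def onset_times(self, stream: int) -> np.ndarray:
        return self.streams[stream].onset_times


def blend(frame_sets: list[np.ndarray], alphas: list[float]) -> np.ndarray:
    """Pixelwise alpha blend of equally shaped frame stacks."""
    if len(frame_sets) != len(alphas):
        raise ValueError("one alpha per frame set required")
    if any(a <= 0 for a in alphas):
        raise ValueError("alphas must be positive")
    if sum(alphas) > 1 + 1e-9:
        raise ValueError("alphas sum to more than 1")
    shapes = {np.asarray(f).shape for f in frame_sets}
    if len(shapes) != 1:
        raise ValueError(f"frame sets differ in shape/length: {shapes}")
    out = np.zeros_like(np.asarray(frame_sets[0], dtype=float))
    for f, a in zip(frame_sets, alphas):
        out += a * np.asarray(f, dtype=float)
    return out


def _stream_fpc(freq: float, fps: float) -> int:
    fpc = fps / freq
    if abs(fpc - round(fpc)) > 1e-9:
        good = round(fpc) * freq
        raise ValueError(
            f"fps {fps} gives a non-integer {fpc:.3f} frames per cycle at "
            f"{freq} Hz; try fps = {good:g}"
        )
    return int(round(fpc))


def schedule_run(
    streams: list[StreamSpec],
    run_duration: float,
    segment_duration: float,
    fps: float = 12.0,
    seed: int = 0,
    start_frames: list[int] | None = None,
) -> CompositeRun:
    """Plan a composite run: start phases and semantic-onset times.

    Each stream's initial cycle phase is drawn uniformly from frames
    [30, 100] of a 200-frame cycle (rescaled proportionally for other
    cycle lengths), which keeps the first semantic onset away from the
    run start.  Rendering is deferred to :func:`render_run`.
    """
    if run_duration <= 0 or segment_duration <= 0:
        raise ValueError("durations must be positive")
    n_seg = run_duration / segment_duration
    if abs(n_seg - round(n_seg)) > 1e-9:
        raise ValueError("run_duration must be a multiple of segment_duration")
    if sum(s.alpha for s in streams) > 1 + 1e-9:
        raise ValueError("stream alphas sum to more than 1")
    rng = np.random.default_rng(seed)
    n_frames = int(round(run_duration * fps))
    scheds = []
    for i, spec in enumerate(streams):
        fpc = _stream_fpc(spec.tagging_frequency, fps)
        lo = int(round(30 * fpc / 200))
        hi = int(round(100 * fpc / 200))
        if start_frames is None:
            start = int(rng.integers(lo, hi + 1))
        else:
            start = int(start_frames[i])
            if not (lo <= start <= hi):
                raise ValueError(
                    f"start frame {start} outside the randomization range "
                    f"[{lo}, {hi}] (an onset would fall at or near the run start)"
                )
        first = (-start) % fpc
        onset_frames = np.arange(first, n_frames, fpc)
        scheds.append(
            StreamSchedule(spec, fpc, start, onset_frames / fps)
        )
    return CompositeRun(scheds, fps, run_duration, segment_duration, seed)


def render_run(
    run: CompositeRun,
    levels: int = 4,
    n_harmonics: int = 8,
    n_geometries: int = 3,
) -> CompositeRun:
    """Materialize the frames of a scheduled run.

    Each stream's exemplars are scrambled with schedules drawn from the
    same per-stream seed, so the path randomization and harmonic
    assignment are shared across segments of a category and the cycle
    phase runs uninterrupted through exemplar switches.
    """
    n_seg = int(round(run.duration / run.segment_duration))
    seg_frames = run.n_frames // n_seg
    per_stream_frames = []
    rng = np.random.default_rng(run.seed)
    for sched in run.streams:
        stream_seed = int(rng.integers(0, 2 ** 31))
        images = list(sched.spec.images)
        if len(images) == 1:
            images = images * n_seg
        if len(images) != n_seg:
            raise ValueError(
                f"stream needs 1 or {n_seg} exemplars, got {len(images)}"
            )
        movies: dict[int, SwiftMovie] = {}
        frames = np.empty((run.n_frames,) + np.asarray(images[0]).shape)
        for k in range(run.n_frames):
            seg = min(k // seg_frames, n_seg - 1)
            if seg not in movies:
                movies[seg] = generate_movie(
                    images[seg],
                    levels=levels,
                    n_harmonics=n_harmonics,
                    frames_per_cycle=sched.frames_per_cycle,
                    n_cycles=n_geometries,
                    seed=stream_seed,
                    n_geometries=n_geometries,
                )
            movie = movies[seg]
            frames[k] = movie[(sched.start_frame + k) % len(movie)]
        per_stream_frames.append(frames)
    blended = blend(per_stream_frames, [s.spec.alpha for s in run.streams])
    return dataclasses.replace(run, frames=blended)


def export_run(run: CompositeRun, path, format: str = "npz") -> Path:
    """Write a rendered run plus a JSON sidecar with its schedule.

    ``format``: "npz" (lossless frame archive) or "gif".  A sidecar
    ``<path>.json`` records fps, seed, per-stream tagging frequencies,
    start frames and onset times.
    """
    if run.frames is None:
        raise ValueError("run has no rendered frames; call render_run first")
    path = Path(path)
    if format == "npz":
        np.savez(path, frames=run.frames, fps=run.fps)
    elif format == "gif":
        import imageio.v3 as iio

        arr = (np.clip(run.frames, 0, 1) * 255).round().astype(np.uint8)
        iio.imwrite(path, arr, duration=1000.0 / run.fps, loop=0)
    else:
        raise ValueError(
            f"unsupported export format {format!r}; use 'npz' or 'gif' "
            "(no MP4 encoder is bundled)"
        )
    sidecar = {
        "fps": run.fps,
        "duration_s": run.duration,
        "segment_duration_s": run.segment_duration,
        "seed": run.seed,
        "streams": [
            {
                "name": s.spec.name,
                "tagging_frequency_hz": s.spec.tagging_frequency,
                "alpha": s.spec.alpha,
                "frames_per_cycle": s.frames_per_cycle,
                "start_frame": s.start_frame,
                "onset_times_s": [float(t) for t in s.onset_times],
            }
            for s in run.streams
        ],
    }
    side_path = path.with_suffix(path.suffix + ".json")
    side_path.write_text(json.dumps(sidecar, indent=1))
    return path


def read_run_frames(path) -> tuple[np.ndarray, float]:
    """Read back an .npz frame archive; returns (frames, fps)."""
    with np.load(path) as z:
        return z["frames"], float(z["fps"])
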