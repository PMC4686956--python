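"""Synthetic BOLD studies for exercising the frequency-tagging analysis.

Emulates the structure of a tagging experiment without scan data: runs
of 216 volumes at TR = 2.46 s, named ROI masks, voxels that respond
periodically at a tagging frequency (impulse train at semantic onsets
convolved with a canonical double-gamma HRF) in category-selective ROIs,
constant-plus-noise voxels in early visual ROIs, and a graded fraction
of tagged voxels along a V1 -> V2 -> V3 -> V4 -> high-level ordering.
Ground truth (which voxel is tagged, at what frequency/amplitude/phase)
is carried alongside for recovery tests and is never an analysis input.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "HrfKernel",
    "canonical_hrf",
    "hrf_function",
    "simulate_voxel",
    "RoiSpec",
    "BoldStudy",
    "generate_study",
    "default_gradient_spec",
    "write_study",
    "read_study",
]

TR_DEFAULT = 2.46          # s, echo-planar repetition time
N_VOLUMES_DEFAULT = 216    # volumes per 9-minute run
TAG_FREQS_DEFAULT = (0.06, 0.08, 0.10)  # Hz


@dataclasses.dataclass
class HrfKernel:
    """Hemodynamic response sampled at TR resolution."""

    samples: np.ndarray
    tr: float

    @property
    def peak_time(self) -> float:
        return float(np.argmax(self.samples) * self.tr)


def _gamma_pdf(t: np.ndarray, shape: float, scale: float = 1.0) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos] / scale
    out[pos] = np.exp(
        (shape - 1) * np.log(tp) - tp - gammaln(shape) - np.log(scale)
    )
    return out


def hrf_function(
    t: np.ndarray,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    ratio: float = 6.0,
    amplitude: float = 1.0,
) -> np.ndarray:
    """Canonical double-gamma HRF evaluated at times ``t`` (seconds).

    Difference of two gamma densities with modes at ``peak_delay`` and
    ``undershoot_delay`` (unit dispersion), the undershoot scaled down by
    ``ratio``; normalized to unit peak then scaled by ``amplitude``.
    Zero at t <= 0.
    """
    h = _gamma_pdf(t, peak_delay + 1.0) - _gamma_pdf(t, undershoot_delay + 1.0) / ratio
    fine = np.arange(0, undershoot_delay + 16.0, 0.01)
    peak = (
        _gamma_pdf(fine, peak_delay + 1.0)
        - _gamma_pdf(fine, undershoot_delay + 1.0) / ratio
    ).max()
    return amplitude * h / peak


def canonical_hrf(
    tr: float,
    duration: float = 32.0,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    ratio: float = 6.0,
    amplitude: float = 1.0,
) -> HrfKernel:
    """Canonical HRF sampled every ``tr`` seconds over ``duration``."""
    if tr <= 0:
        raise ValueError("tr must be positive")
    t = np.arange(0.0, duration, tr)
    return HrfKernel(hrf_function(t, peak_delay, undershoot_delay, ratio, amplitude), tr)


def _response(t: np.ndarray, onsets: np.ndarray, **hrf_kw) -> np.ndarray:
    resp = np.zeros_like(t)
    for on in np.atleast_1d(onsets):
        resp += hrf_function(t - on, **hrf_kw)
    return resp


def simulate_voxel(
    onsets,
    amplitude: float,
    baseline: float = 500.0,
    tr: float = TR_DEFAULT,
    n_volumes: int = N_VOLUMES_DEFAULT,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    ar1: float = 0.0,
) -> np.ndarray:
    """Simulate one voxel time series.

    series = baseline * (1 + sum_onsets amplitude/100 * HRF(t - onset))
    plus Gaussian noise of standard deviation ``noise_sd`` (raw units,
    optionally AR(1)-correlated with coefficient ``ar1``).
    ``amplitude`` is percent signal change at the HRF peak.
    """
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    run_len = n_volumes * tr
    if onsets.size and (onsets.min() < 0 or onsets.max() >= run_len):
        raise ValueError("onsets must lie within the run")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = np.arange(n_volumes) * tr
    series = baseline * (1.0 + amplitude / 100.0 * _response(t, onsets))
    if noise_sd > 0:
        eps = rng.standard_normal(n_volumes)
        if ar1:
            for i in range(1, n_volumes):
                eps[i] += ar1 * eps[i - 1]
            eps *= np.sqrt(1 - ar1 ** 2)
        series = series + noise_sd * eps
    return series


@dataclasses.dataclass
class RoiSpec:
    """Specification of one synthetic ROI."""

    n_voxels: int
    tagged_fraction: float = 0.0
    amplitude: float = 1.0      # % signal change for tagged voxels
    frequency: float = 0.1      # Hz, tagging frequency of this ROI's category

    def __post_init__(self):
        if not (0 <= self.tagged_fraction <= 1):
            raise ValueError("tagged_fraction must lie in [0, 1]")


@dataclasses.dataclass
class BoldStudy:
    """Synthetic multi-run BOLD study with ROI masks and ground truth."""

    runs: list[np.ndarray]              # each (x, y, z, t)
    tr: float
    roi_masks: dict[str, np.ndarray]    # name -> boolean (x, y, z)
    truth: pd.DataFrame                 # one row per voxel (flat index)
    seed: int

    @property
    def n_volumes(self) -> int:
        return self.runs[0].shape[-1]

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.runs[0].shape[:3]

    def roi_series(self, name: str, run: int = 0) -> np.ndarray:
        """Time series of an ROI's voxels, shape (n_voxels, t)."""
        return self.runs[run][self.roi_masks[name]]


def default_gradient_spec(
    scale: float = 1.0,
    amplitude: float = 2.0,
    face_freq: float = 0.10,
    scene_freq: float = 0.06,
    object_freq: float = 0.08,
) -> dict[str, RoiSpec]:
    """ROI layout mirroring the study's hierarchy gradient.

    Early visual areas contain no tagged voxels (constant-plus-noise);
    the tagged fraction grows along V3 -> V4 -> dorsal/ventral clusters,
    and the category ROIs (FFA/PPA/LOC) are strongly tagged at their
    category's frequency.  Voxel counts approximate 3 mm voxel ROI sizes,
    shrinkable with ``scale`` for quick tests.
    """
    def n(x):
        return max(8, int(round(x * scale)))

    return {
        "V1": RoiSpec(n(2500), 0.0, amplitude, face_freq),
        "V2": RoiSpec(n(2000), 0.0, amplitude, face_freq),
        "V3": RoiSpec(n(1500), 0.2, amplitude, face_freq),
        "V4": RoiSpec(n(1000), 0.4, amplitude, face_freq),
        "Dsl": RoiSpec(n(800), 0.6, amplitude, face_freq),
        "Vtl": RoiSpec(n(800), 0.8, amplitude, face_freq),
        "FFA": RoiSpec(n(120), 0.9, amplitude, face_freq),
        "PPA": RoiSpec(n(120), 0.9, amplitude, scene_freq),
        "LOC": RoiSpec(n(160), 0.7, amplitude, object_freq),
    }


def generate_study(
    spec: dict[str, RoiSpec],
    tr: float = TR_DEFAULT,
    n_volumes: int = N_VOLUMES_DEFAULT,
    n_runs: int = 3,
    noise_sd: float = 5.0,
    baseline: float = 500.0,
    seed: int = 0,
    ar1: float = 0.0,
) -> BoldStudy:
    """Generate a multi-run study from per-ROI specifications.

    ROIs occupy disjoint slabs of a minimal 3D volume.  Tagged voxels of
    an ROI share that ROI's semantic-onset times within a run (onset
    phase drawn per ROI and run from [0.15, 0.5] of the cycle, keeping
    the first onset away from the run start); untagged voxels are
    baseline plus noise.
    """
    rng = np.random.default_rng(seed)
    names = list(spec)
    total = sum(spec[n].n_voxels for n in names)
    ny = nz = max(4, int(np.ceil(total ** (1 / 3))))
    nx = int(np.ceil(total / (ny * nz)))
    shape = (nx, ny, nz)

    masks = {}
    flat_slices = {}
    pos = 0
    for n in names:
        m = np.zeros(shape, dtype=bool)
        m.reshape(-1)[pos : pos + spec[n].n_voxels] = True
        masks[n] = m
        flat_slices[n] = slice(pos, pos + spec[n].n_voxels)
        pos += spec[n].n_voxels

    n_total = nx * ny * nz
    truth = pd.DataFrame(
        {
            "roi": np.array([""] * n_total, dtype=object),
            "tagged": np.zeros(n_total, dtype=bool),
            "frequency": np.full(n_total, np.nan),
            "amplitude": np.zeros(n_total),
            "phase": np.full(n_total, np.nan),
        }
    )

    run_len = n_volumes * tr
    tagged_flags = {}
    for n in names:
        s = spec[n]
        n_tag = int(round(s.tagged_fraction * s.n_voxels))
        flags = np.zeros(s.n_voxels, dtype=bool)
        flags[rng.choice(s.n_voxels, size=n_tag, replace=False)] = True
        tagged_flags[n] = flags
        sl = flat_slices[n]
        truth.loc[sl.start : sl.stop - 1, "roi"] = n
        truth.loc[sl.start : sl.stop - 1, "tagged"] = flags
        truth.loc[sl.start : sl.stop - 1, "frequency"] = np.where(flags, s.frequency, np.nan)
        truth.loc[sl.start : sl.stop - 1, "amplitude"] = np.where(flags, s.amplitude, 0.0)

    runs = []
    t = np.arange(n_volumes) * tr
    for _ in range(n_runs):
        vol = baseline + noise_sd * _noise(rng, (n_total, n_volumes), ar1)
        for n in names:
            s = spec[n]
            flags = tagged_flags[n]
            if not flags.any():
                continue
            period = 1.0 / s.frequency
            phase = float(rng.uniform(0.15, 0.5)) * period
            onsets = np.arange(phase, run_len, period)
            resp = s.amplitude / 100.0 * _response(t, onsets)
            sl = flat_slices[n]
            idx = np.arange(sl.start, sl.stop)[flags]
            vol[idx] += baseline * resp
            truth.loc[idx, "phase"] = phase
        runs.append(vol.reshape(shape + (n_volumes,)))
    return BoldStudy(runs, tr, masks, truth, seed)


def _noise(rng: np.random.Generator, shape, ar1: float) -> np.ndarray:
    eps = rng.standard_normal(shape)
    if ar1:
        for i in range(1, shape[-1]):
            eps[..., i] += ar1 * eps[..., i - 1]
        eps *= np.sqrt(1 - ar1 ** 2)
    return eps


# ---------------------------------------------------------------------------
# NIfTI round trip

def write_study(study: BoldStudy, path) -> Path:
    """Write runs and masks as NIfTI-1 plus a JSON/CSV truth sidecar."""
    import nibabel as nib

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    for i, run in enumerate(study.runs):
        img = nib.Nifti1Image(run, affine)
        img.header.set_zooms((1.0, 1.0, 1.0, study.tr))
        img.header.set_xyzt_units("mm", "sec")
        nib.save(img, path / f"run-{i:02d}.nii")
    for name, mask in study.roi_masks.items():
        nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), path / f"mask-{name}.nii")
    study.truth.to_csv(path / "truth.csv", index_label="voxel")
    meta = {
        "tr": study.tr,
        "n_runs": study.n_runs,
        "seed": study.seed,
        "rois": list(study.roi_masks),
    }
    (path / "study.json").write_text(json.dumps(meta, indent=1))
    return path


def read_study(path) -> BoldStudy:
    import nibabel as nib

    path = Path(path)
    meta_file = path / "study.json"
    if not meta_file.exists():
        raise FileNotFoundError(f"missing study metadata {meta_file}")
    meta = json.loads(meta_file.read_text())
    runs = []
    for i in range(meta["n_runs"]):
        f = path / f"run-{i:02d}.nii"
        if not f.exists():
            raise FileNotFoundError(f"missing run file {f}")
        runs.append(np.asarray(nib.load(f).dataobj, dtype=np.float64))
    masks = {}
    for name in meta["rois"]:
        f = path / f"mask-{name}.nii"
        if not f.exists():
            raise FileNotFoundError(f"missing mask file {f}")
        masks[name] = np.asarray(nib.load(f).dataobj).astype(bool)
    truth = pd.read_csv(path / "truth.csv", index_col="voxel")
    truth["roi"] = truth["roi"].astype(object)
    return BoldStudy(runs, float(meta["tr"]), masks, truth, int(meta["seed"]))
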