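"""Block-design GLM benchmark (the classic functional localizer).

A minimal massively-univariate OLS: condition boxcars convolved with the
canonical HRF, an intercept, and optional discrete-cosine drift terms
mimicking a 128 s high-pass.  Contrast t-maps (e.g. faces > objects) are
the comparison benchmark against which the frequency-tagged analysis is
judged.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from .bold import BoldStudy, hrf_function

__all__ = [
    "DesignMatrix",
    "block_design",
    "glm_contrast",
    "CONTRAST_PRESETS",
    "LocalizerGLM",
    "LocalizerResults",
]

#: named category contrasts used with three-condition localizer designs
CONTRAST_PRESETS = {
    "faces-gt-objects": ("faces", "objects"),
    "scenes-gt-objects": ("scenes", "objects"),
    "objects-gt-scenes": ("objects", "scenes"),
}


@dataclasses.dataclass
class DesignMatrix:
    matrix: np.ndarray          # (n_volumes, n_columns)
    names: list[str]

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    def contrast_vector(self, weights: dict[str, float]) -> np.ndarray:
        c = np.zeros(len(self.names))
        for name, w in weights.items():
            c[self.names.index(name)] = w
        return c


def _dct_drift(n_volumes: int, tr: float, cutoff: float) -> np.ndarray:
    """Discrete-cosine drift basis for periods longer than ``cutoff`` s."""
    order = int(np.floor(2 * n_volumes * tr / cutoff))
    t = np.arange(n_volumes)
    cols = [
        np.cos(np.pi * k * (2 * t + 1) / (2 * n_volumes)) for k in range(1, order + 1)
    ]
    return np.column_stack(cols) if cols else np.empty((n_volumes, 0))


def block_design(
    conditions: dict[str, np.ndarray],
    tr: float,
    n_volumes: int,
    duration: float = 20.0,
    hrf_kwargs: dict | None = None,
    drift_cutoff: float | None = None,
) -> DesignMatrix:
    """Boxcar-convolved design matrix for a block localizer.

    ``conditions`` maps names to block-onset times (s); every block lasts
    ``duration`` s (the classic 20 s block / 15 s fixation layout).
    Columns: one regressor per condition, an intercept, and optional DCT
    drift terms with ``drift_cutoff`` s high-pass equivalent.
    """
    hrf_kwargs = hrf_kwargs or {}
    dt = 0.1  # fine grid for the boxcar convolution
    run_len = n_volumes * tr
    fine_t = np.arange(0.0, run_len, dt)
    hrf = hrf_function(np.arange(0.0, 32.0, dt), **hrf_kwargs)
    cols, names = [], []
    for name, onsets in conditions.items():
        onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
        if onsets.size and (onsets.min() < 0 or onsets.max() >= run_len):
            raise ValueError(f"condition {name!r} has onsets outside the run")
        box = np.zeros_like(fine_t)
        for on in onsets:
            box[(fine_t >= on) & (fine_t < on + duration)] = 1.0
        reg = np.convolve(box, hrf)[: fine_t.size] * dt
        cols.append(np.interp(np.arange(n_volumes) * tr, fine_t, reg))
        names.append(name)
    cols.append(np.ones(n_volumes))
    names.append("intercept")
    if drift_cutoff:
        drift = _dct_drift(n_volumes, tr, drift_cutoff)
        for k in range(drift.shape[1]):
            cols.append(drift[:, k])
            names.append(f"drift{k + 1}")
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns via QR pivoting on correlations
        corr = np.corrcoef(X.T - X.T.mean(1, keepdims=True))
        dup = [
            (names[i], names[j])
            for i in range(len(names))
            for j in range(i + 1, len(names))
            if abs(corr[i, j]) > 1 - 1e-9
        ]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {dup}")
    return DesignMatrix(X, names)


def glm_contrast(
    series: np.ndarray,
    design: DesignMatrix,
    contrast: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized OLS contrast over voxels: returns (t, p) maps.

    ``series`` has time on its last axis; ``contrast`` is a weight
    vector over design columns.  t = c'b / sqrt(s2 * c'(X'X)^-1 c) with
    two-tailed p on the residual degrees of freedom.
    """
    series = np.asarray(series, dtype=float)
    c = np.asarray(contrast, dtype=float)
    X = design.matrix
    if c.shape != (X.shape[1],):
        raise ValueError(f"contrast length {c.size} != {X.shape[1]} design columns")
    if not np.any(c):
        raise ValueError("contrast of all zeros is invalid")
    if series.shape[-1] != X.shape[0]:
        raise ValueError("series length does not match design rows")
    shape = series.shape[:-1]
    Y = series.reshape(-1, X.shape[0]).T  # (t, n_vox)
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y
    resid = Y - X @ beta
    dof = X.shape[0] - X.shape[1]
    if dof <= 0:
        raise ValueError("no residual degrees of freedom")
    sigma2 = (resid ** 2).sum(axis=0) / dof
    cvar = float(c @ xtx_inv @ c)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (c @ beta) / np.sqrt(sigma2 * cvar)
    t = np.nan_to_num(t, nan=0.0)
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    return t.reshape(shape), p.reshape(shape)


class LocalizerGLM:
    """Block-design GLM over a (synthetic or real) localizer study.

    Fits the massively-univariate OLS run by run, averages the per-run
    contrast t-maps into a fixed-effects style combined p-map via
    Stouffer's method when multiple runs are present.
    """

    def __init__(
        self,
        study: BoldStudy,
        conditions: dict[str, np.ndarray],
        block_duration: float = 20.0,
        drift_cutoff: float | None = 128.0,
    ):
        self.study = study
        self.design = block_design(
            conditions,
            study.tr,
            study.n_volumes,
            duration=block_duration,
            drift_cutoff=drift_cutoff,
        )

    def fit(self, contrasts: dict[str, dict[str, float]]) -> "LocalizerResults":
        tmaps: dict[str, np.ndarray] = {}
        pmaps: dict[str, np.ndarray] = {}
        for name, weights in contrasts.items():
            c = self.design.contrast_vector(weights)
            zs = []
            for run in self.study.runs:
                t, p = glm_contrast(run, self.design, c)
                # signed z equivalent for combination across runs
                z = stats.norm.isf(np.clip(p / 2, 1e-300, 1.0)) * np.sign(t)
                zs.append(z)
            zc = np.sum(zs, axis=0) / np.sqrt(len(zs))
            tmaps[name] = zc
            pmaps[name] = 2.0 * stats.norm.sf(np.abs(zc))
        return LocalizerResults(self, tmaps, pmaps)


@dataclasses.dataclass
class LocalizerResults:
    model: LocalizerGLM
    tmaps: dict[str, np.ndarray]
    pmaps: dict[str, np.ndarray]

    def roi_pvalues(self, contrast: str, roi: str) -> np.ndarray:
        return self.pmaps[contrast][self.model.study.roi_masks[roi]]

    def summary(self, threshold: float = 1e-3) -> "pd.DataFrame":
        import pandas as pd

        rows = []
        for cname, p in self.pmaps.items():
            for rname, roi in self.model.study.roi_masks.items():
                rows.append(
                    {
                        "contrast": cname,
                        "roi": rname,
                        "n_voxels": int(roi.sum()),
                        f"frac_p<{threshold}": float((p[roi] < threshold).mean()),
                    }
                )
        return pd.DataFrame(rows)
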