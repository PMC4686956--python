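"""ROI-level comparison statistics.

Criterion-free comparison of two voxel populations: a 20-step p-value
threshold ladder swept from very stringent (1e-10) to fully liberal (1)
traces out an ROC curve of (false-alarm, hit) proportions whose
trapezoidal area (AUC) summarizes how preferentially the signal ROI
passes thresholds relative to the reference ROI.  Also provides the two
overlap percentages between activation maps and the normalized
proportion-of-activated-voxels profile along the visual hierarchy.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "threshold_ladder",
    "RocResult",
    "roc_curve",
    "overlap_whole_brain",
    "overlap_roi",
    "normalized_proportion_profile",
    "HIERARCHY_ORDER",
]

HIERARCHY_ORDER = ("V1", "V2", "V3", "V4", "Dsl", "Vtl")


def threshold_ladder() -> np.ndarray:
    """The 20-step p-value ladder: ten log-spaced thresholds from 1e-10
    to 1e-1 and another ten log-spaced from 10**-0.9 to 1."""
    return np.concatenate(
        [np.logspace(-10, -1, 10), np.logspace(-0.9, 0, 10)]
    )


@dataclasses.dataclass
class RocResult:
    """ROC over a threshold ladder for a (signal, reference) ROI pair."""

    thresholds: np.ndarray
    fa: np.ndarray    # false-alarm proportions incl. appended (0 ... 1) endpoints
    hit: np.ndarray
    auc: float


def roc_curve(
    hit_pvals: np.ndarray,
    fa_pvals: np.ndarray,
    ladder: np.ndarray | None = None,
) -> RocResult:
    """ROC of two p-value populations over a threshold ladder.

    At each threshold the hit (false-alarm) coordinate is the proportion
    of signal-ROI (reference-ROI) voxels with p strictly below it.  The
    points are augmented with (0,0) and (1,1) and the AUC is the
    trapezoidal area over the false-alarm axis.
    """
    hit_pvals = np.asarray(hit_pvals, dtype=float).ravel()
    fa_pvals = np.asarray(fa_pvals, dtype=float).ravel()
    if hit_pvals.size == 0 or fa_pvals.size == 0:
        raise ValueError("both ROIs must be non-empty")
    if ladder is None:
        ladder = threshold_ladder()
    ladder = np.sort(np.asarray(ladder, dtype=float))
    hit = np.array([(hit_pvals < th).mean() for th in ladder])
    fa = np.array([(fa_pvals < th).mean() for th in ladder])
    fa_aug = np.concatenate([[0.0], fa, [1.0]])
    hit_aug = np.concatenate([[0.0], hit, [1.0]])
    auc = float(np.trapezoid(hit_aug, fa_aug))
    return RocResult(ladder, fa_aug, hit_aug, auc)


def overlap_whole_brain(sw_voxels, fl_voxels) -> float:
    """Percentage of SWIFT-activated voxels also activated by the
    localizer: 100 * |SW and FL| / |SW|."""
    sw, fl = set(map(tuple3, sw_voxels)), set(map(tuple3, fl_voxels))
    if not sw:
        raise ValueError("the SWIFT-activated set is empty; overlap undefined")
    return 100.0 * len(sw & fl) / len(sw)


def overlap_roi(fd_voxels, sw_voxels) -> float:
    """Percentage of a functionally-defined ROI activated by SWIFT:
    100 * |FD and SW| / |FD|."""
    fd, sw = set(map(tuple3, fd_voxels)), set(map(tuple3, sw_voxels))
    if not fd:
        raise ValueError("the functionally-defined ROI is empty; overlap undefined")
    return 100.0 * len(fd & sw) / len(fd)


def tuple3(v):
    """Hashable voxel key (accepts ints or coordinate tuples)."""
    if np.isscalar(v):
        return int(v)
    return tuple(int(x) for x in np.asarray(v).ravel())


def normalized_proportion_profile(
    pval_maps: dict[str, np.ndarray],
    order=HIERARCHY_ORDER,
    threshold: float = 1e-3,
) -> dict[str, float]:
    """Fold change of activated-voxel proportion along the hierarchy.

    Each area's proportion of voxels with p < ``threshold`` is divided
    by the mean proportion over V1 and V2 (the baseline areas expected
    to show minimal category-specific activation).
    """
    for base in ("V1", "V2"):
        if base not in pval_maps:
            raise ValueError(f"baseline area {base!r} missing from pval_maps")
    props = {
        a: float((np.asarray(pval_maps[a]).ravel() < threshold).mean()) for a in order
        if a in pval_maps
    }
    base = 0.5 * (props["V1"] + props["V2"])
    if base <= 0:
        raise ValueError(
            "no activated voxels in V1/V2 at this threshold: the baseline "
            "proportion is zero and the profile is undefined"
        )
    return {a: props[a] / base for a in props}
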