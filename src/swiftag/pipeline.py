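"""End-to-end pipeline: simulate -> analyze -> compare.

Generates a gradient synthetic study, runs the frequency-tagging
analysis and a block-design localizer simulated in the same voxel
geometry, then computes the comparison statistics (ROC/AUC for the
category ROI pairs, both overlap percentages, the hierarchy profile)
into one machine-readable report.
"""

from __future__ import annotations

import numpy as np

from . import __version__
from .bold import default_gradient_spec, generate_study
from .config import RunConfig, seed_chain
from .glm import LocalizerGLM
from .roi import (
    normalized_proportion_profile,
    roc_curve,
    overlap_roi,
    overlap_whole_brain,
)
from .tagging import FrequencyTaggingModel

__all__ = ["run_pipeline", "simulate_localizer_runs"]

#: hit-ROI vs pooled false-alarm ROIs for the three categories
ROC_PAIRS = {
    "faces": ("FFA", ("PPA", "LOC")),
    "scenes": ("PPA", ("FFA", "LOC")),
    "objects": ("LOC", ("FFA", "PPA")),
}


def simulate_localizer_runs(study, spec, block_onsets, noise_sd, baseline, seed):
    """Simulate block-design localizer runs in a study's voxel geometry.

    Voxels flagged as tagged in ``study.truth`` respond (boxcar x HRF)
    to the blocks of their ROI's category; all others are noise only.
    """
    from .glm import block_design

    rng = np.random.default_rng(seed)
    n_vol = study.n_volumes
    shape = study.shape
    n_total = int(np.prod(shape))
    design = block_design(block_onsets, study.tr, n_vol, drift_cutoff=None)
    runs = []
    freq_of = {name: spec[name].frequency for name in spec}
    cat_of_freq = {}
    for cat, (hit_roi, _) in ROC_PAIRS.items():
        if hit_roi in freq_of:
            cat_of_freq[freq_of[hit_roi]] = cat
    for _ in range(2):
        vol = baseline + noise_sd * rng.standard_normal((n_total, n_vol))
        for name in spec:
            cat = cat_of_freq.get(freq_of[name])
            if cat is None or cat not in block_onsets:
                continue
            reg = design.matrix[:, design.names.index(cat)]
            mask = (study.truth["roi"] == name) & study.truth["tagged"]
            idx = np.flatnonzero(mask.to_numpy())
            amp = spec[name].amplitude
            vol[idx] += baseline * amp / 100.0 * reg
        runs.append(vol.reshape(shape + (n_vol,)))
    return runs, design


def run_pipeline(config: RunConfig | None = None) -> dict:
    """Run the full simulate/analyze/compare pipeline; returns a report."""
    config = config or RunConfig()
    s_study, s_loc = seed_chain(config.seed, 2)

    face_f, scene_f, object_f = 0.10, 0.06, 0.08
    spec = default_gradient_spec(
        scale=config.roi_scale,
        amplitude=config.amplitude,
        face_freq=face_f,
        scene_freq=scene_f,
        object_freq=object_f,
    )
    study = generate_study(
        spec,
        tr=config.tr,
        n_volumes=config.n_volumes,
        n_runs=config.n_runs,
        noise_sd=config.noise_sd,
        baseline=config.baseline,
        seed=s_study,
    )
    if any(m.sum() == 0 for m in study.roi_masks.values()):
        empty = [n for n, m in study.roi_masks.items() if m.sum() == 0]
        raise ValueError(f"zero-size ROI(s): {empty}")

    results = FrequencyTaggingModel(
        study,
        tag_freqs=config.tag_freqs,
        half_band=config.noise_half_band,
        guard=config.noise_guard,
        snr_band_bins=config.snr_band_bins,
    ).fit()

    freq_of_cat = {"faces": face_f, "scenes": scene_f, "objects": object_f}
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_json(),
        "roc": {},
        "overlap": {},
        "profile": {},
    }

    # ROC / AUC per category (hit ROI vs pooled other category ROIs)
    for cat, (hit_roi, fa_rois) in ROC_PAIRS.items():
        f = freq_of_cat[cat]
        hit_p = results.roi_pvalues(f, hit_roi)
        fa_p = np.concatenate([results.roi_pvalues(f, r) for r in fa_rois])
        roc = roc_curve(hit_p, fa_p)
        report["roc"][cat] = {
            "hit_roi": hit_roi,
            "fa_rois": list(fa_rois),
            "auc": roc.auc,
            "fa": roc.fa.tolist(),
            "hit": roc.hit.tolist(),
        }

    # hierarchy profile at the face tagging frequency
    pmaps = {
        name: results.pmaps[face_f][mask] for name, mask in study.roi_masks.items()
    }
    report["profile"] = normalized_proportion_profile(pmaps, threshold=config.threshold)

    # localizer benchmark in the same geometry + overlap statistics
    onsets = {
        cat: np.arange(15.0 + 35.0 * i, config.n_volumes * config.tr - 35.0, 105.0)
        for i, cat in enumerate(("faces", "scenes", "objects"))
    }
    loc_runs, design = simulate_localizer_runs(
        study, spec, onsets, config.noise_sd, config.baseline, s_loc
    )
    import dataclasses as _dc

    loc_study = _dc.replace(study, runs=loc_runs)
    loc = LocalizerGLM(loc_study, onsets, drift_cutoff=None).fit(
        {
            "faces-gt-objects": {"faces": 1.0, "objects": -1.0},
            "scenes-gt-objects": {"scenes": 1.0, "objects": -1.0},
            "objects-gt-scenes": {"objects": 1.0, "scenes": -1.0},
        }
    )
    th = config.threshold
    for cat, contrast in (
        ("faces", "faces-gt-objects"),
        ("scenes", "scenes-gt-objects"),
        ("objects", "objects-gt-scenes"),
    ):
        f = freq_of_cat[cat]
        sw_act = np.flatnonzero(results.pmaps[f].ravel() < th)
        fl_act = np.flatnonzero(loc.pmaps[contrast].ravel() < th)
        hit_roi = ROC_PAIRS[cat][0]
        fd = np.flatnonzero(study.roi_masks[hit_roi].ravel())
        entry = {}
        if sw_act.size:
            entry["whole_brain_pct"] = overlap_whole_brain(sw_act, fl_act)
        entry["category_roi_pct"] = overlap_roi(fd, sw_act)
        report["overlap"][cat] = entry

    report["tagging_summary"] = results.summary(q=config.q_fdr).to_dict("records")
    return report
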