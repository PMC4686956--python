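# swiftag

Semantic wavelet-induced frequency-tagging (SWIFT) — stimulus generation
and the matching frequency-tagged BOLD analysis stack.

## The problem

Contrasting natural-image categories (faces vs. objects, say) in a
classic fMRI block design confounds high-level semantic differences
with low-level image differences, so early visual cortex lights up
along with the category-selective areas. SWIFT sidesteps the confound
at the stimulus level: a natural image is decomposed into a dyadic
wavelet pyramid, and each detail location's (horizontal, vertical,
diagonal) coefficient triple — a 3D *orientation vector* — is moved
along the unique circle through itself and two random vectors of the
same norm. Because that circle lies on the sphere of the vector's norm,
every frame conserves each coefficient's local energy exactly: local
luminance, local spatial frequency and global contrast stay constant
while local contour orientations scramble. Each coefficient cycles at a
harmonic h ∈ {1..H} of the cycle rate, so all coefficients re-align with
the original only once per cycle (the *semantic onset*). Semantic
content is thereby tagged at a chosen temporal frequency f while the
principal physical attributes never vary; neurons tuned to physical
features should respond steadily, and neurons tuned to object identity
should respond periodically at f.

Closeness of frame x to the original is quantified by the relative
image similarity

RIS_x = (100/n) · Σ_c (1 − |ΔW_c|),  |ΔW_c| = min(1, |W_c^o − W_c^x| / M_c),

summed over the n detail coefficients, where M_c is the largest
deviation coefficient c's scrambling path can produce. RIS is 100 at the
semantic onsets and 0 when every coefficient is maximally displaced.

On the analysis side, voxel time series (216 volumes, TR 2.46 s per run)
are converted to % signal change, Fourier-transformed per run, and the
power at the tagging frequency is compared with the power at 22
neighboring noise frequencies by a two-sample t-test; per-bin SNR
divides power by the mean of the 14 surrounding bins. Downstream come
Benjamini–Hochberg FDR, phase maps, onset-locked cycle averages, a
block-design GLM benchmark, overlap percentages, the normalized
proportion-of-activated-voxels profile along V1→V2→V3→V4→higher areas,
and a criterion-free ROC/AUC built from a 20-step p-value threshold
ladder (10^-10 … 1). A synthetic-BOLD generator with known ground truth
exercises the whole chain without scan data.

Intended users: visual-neuroscience groups building frequency-tagged
fMRI/EEG experiments and anyone needing a reference implementation of
the tagging statistics.

## Worked example

```python
import numpy as np
from swiftag import fixture_images, generate_movie, ris_curve
from swiftag import RunConfig, run_pipeline

# --- stimulus: a 512x512 synthetic "face", 9 levels, 8 harmonics
img = fixture_images("geometric-face", 512, seed=11)
movie = generate_movie(img, levels=9, n_harmonics=8,
                       frames_per_cycle=200, n_cycles=2, seed=11)
curve = ris_curve(movie)
print(curve[0], curve[200], round(curve[20:180].max(), 1))
# 100.0 100.0 63.8   <- original revealed only at onsets; U-shaped in between

# --- full synthetic study -> analysis -> comparison
report = run_pipeline(RunConfig(seed=1))
print(round(report["roc"]["faces"]["auc"], 3))
# 0.954
print({k: round(v, 1) for k, v in report["profile"].items()})
# {'V1': 1.3, 'V2': 0.7, 'V3': 29.0, 'V4': 56.9, 'Dsl': 84.5, 'Vtl': 112.7}
print(round(report["overlap"]["faces"]["category_roi_pct"], 1))
# 90.0
```

Reading the numbers: the ROC AUC of 0.954 says the simulated
face-selective ROI passes p-value thresholds almost strictly before the
other category ROIs do (1.0 = perfect separation, 0.5 = none). The
profile is the proportion of voxels significant at p < 0.001 in each
area divided by the V1/V2 mean: early areas sit at the baseline (≈1)
while the tagged fraction planted along the hierarchy produces a
monotone rise. The overlap says 90% of the "FFA" voxels defined by the
simulated localizer were also tagged by the frequency analysis.

A command-line interface mirrors the library:

```sh
swift simulate --seed 2 --scale 0.3 --out study/
swift analyze --study study/ --tags 0.1 --out maps/
swift report --seed 1 --out report.json
swift generate --images face.png scene.png --freqs 0.1 0.06 \
      --alphas 0.5 0.5 --duration 540 --segment 180 --out run.gif
```

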