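# Methods

## Isoenergetic scrambling

An image (square, side a multiple of 2^levels, intensities in [0, 1]) is
decomposed with a separable orthogonal DWT (`db2` by default, periodic
boundary handling) into an approximation band and, per scale, three
detail bands. The (H, V, D) coefficients at one location form an
orientation vector **w**. For each location two random vectors of norm
‖**w**‖ are drawn (uniform directions); the unique circle through the
three points is the intersection of their common plane with the sphere
of radius ‖**w**‖ centered at the origin, so its center is the foot of
the perpendicular from the origin to the plane. The path is
parametrized as c + ρ(u·cosθ + v·sinθ) with u pointing from the circle
center to the anchor, so θ = 0 reproduces the anchor bit-for-bit and
every point has the anchor's norm to machine precision. Zero anchors
degenerate to the constant path at the origin (documented, not an
error); collinear random draws are resampled. The construction is
performed on the unit sphere and rescaled, making it numerically
scale-invariant down to subnormal anchor norms.

Each location receives a harmonic h drawn uniformly from
{1..n_harmonics} (default 8) and advances by θ(t) = 2πh·t/T with
T = frames_per_cycle (default 200). t is reduced mod T before the
trigonometry so semantic-onset frames are exact. Three independently
randomized path geometries are drawn per location (configurable,
default 3); successive cycles rotate through them, so consecutive
cycles traverse different scrambles while every cycle still anchors at
the original. The approximation band is never touched — it carries the
local luminance modulation the method is designed to preserve.

### RIS and its normalizer

RIS treats every scalar detail coefficient as one term. The per-scalar
normalizer is the maximum deviation attainable on that coefficient's
path, ρ(|u_i| + sqrt(u_i² + v_i²)) for component i, so a "maximal
relative difference of 1" is realizable on every coefficient whose path
can move; zero-diameter coefficients contribute perfect similarity.
Consequences worth knowing:

- RIS is exactly 100 at onsets and 0 when every coefficient sits at its
  maximal displacement.
- The single-harmonic RIS curve is mirror-symmetric about mid-cycle
  only statistically (the vector chord 2ρ|sin(θ/2)| is symmetric, the
  per-component deviation is not); observed asymmetry is well under 1
  RIS unit on a 64×64 image and shrinks with coefficient count.
- With 8 harmonics the curve is U-shaped with small intermediate peaks
  (partial phase alignments), and its spectral energy sits at harmonics
  of the cycle rate — only the onset structure recurs at the
  fundamental. Tagging-frequency specificity therefore comes from the
  periodic semantic revelation, not from the RIS waveform itself.

## Composite runs

Streams (one per category) are alpha-blended per frame; weights must
sum to ≤ 1. The common display rate defaults to 12 fps, at which 0.06,
0.08 and 0.10 Hz give integer cycle lengths (200/150/120 frames); each
stream is generated at its own integer frames-per-cycle rather than
resampled. The original experiment's display solution for simultaneous
cycle lengths is not documented; this is this package's choice. Start
phases are drawn uniformly from frames [30, 100] of a 200-frame cycle,
rescaled proportionally for other cycle lengths, which keeps the first
onset at least ~8 s into the run. Segments switch exemplars without
resetting the frame counter, and the per-category random draws (path
geometry, harmonics) are reseeded identically across exemplars, so
cycle phase is continuous through a run; exemplar changes recur at
1/segment_duration (0.0056 Hz for 180 s segments), far below and not
harmonically related to the tagging frequencies. Per-frame detail
energy of a composite is constant up to the cross term between stream
coefficient vectors, whose relative magnitude shrinks as
1/sqrt(n_coefficients) (<1% at 128×128 and above; ~1.3% at 32×32).

## Synthetic BOLD

Runs are 216 volumes at TR 2.46 s by default. Tagged voxels follow
baseline·(1 + a/100·Σ_k HRF(t − t_k)) plus Gaussian noise (optional
AR(1) for stress tests); untagged voxels are baseline plus noise. The
HRF is the canonical double-gamma difference — gamma densities with
modes at 6 s (response) and 16 s (undershoot), unit dispersion,
undershoot scaled by 1/6, unit peak normalization. Onsets repeat at the
ROI's tagging frequency with a per-(ROI, run) phase drawn from
[0.15, 0.5] of the cycle. ROIs occupy disjoint slabs of a minimal 3D
volume; ground truth (tagged flag, frequency, amplitude, phase) rides
in a sidecar table that analysis code never reads.

Default gradient layout (voxel counts ~3 mm-voxel ROI sizes): V1 2500,
V2 2000, V3 1500, V4 1000, dorsal/ventral clusters 800 each, FFA/PPA
120, LOC 160; tagged fractions 0/0/0.2/0.4/0.6/0.8 along the hierarchy
and 0.9/0.9/0.7 in the category ROIs, each category ROI at its own
frequency. Amplitude 2% of baseline with noise SD 1% of baseline puts
tag-bin power roughly an order of magnitude above the per-bin noise
floor — comfortably detectable with 3 runs but not trivially so.

What the simulator does *not* emulate: spatial autocorrelation,
physiological (cardiac/respiratory) noise structure, motion, drift
beyond what detrending removes, EPI distortion, and voxels responsive
to multiple categories. Passing recovery tests therefore demonstrates
correctness of the analysis chain under its own assumptions, not
robustness to real scanner noise.

## Frequency-domain analysis

% signal change normalizes each voxel to mean 100 (non-positive means
are flagged and excluded). Spectra are one-sided FFT power after linear
detrending (standing in for the scanner pipeline's high-pass, which is
out of scope), normalized so the bin sum matches the detrended series'
sum of squares. Requested frequencies map to the nearest bin, with a
warning beyond Δf/4. SNR divides each bin by the mean of its 14
surrounding bins (7 per side, center excluded); edge bins are NaN.

The noise-frequency rule takes all bins within 7 bins of each tag's
nearest bin and removes bins within 2 of any tag. On the 1/540 Hz grid
with tags 0.06/0.08/0.10 Hz this yields 22 frequencies in four groups
of 5/6/6/5 — matching, bin for bin, the packaged enumerated constant
(`REFERENCE_NOISE_FREQS_HZ`, whose printed grid differs from 1/540 Hz by
<0.3% for reasons the source does not state; bins, not hertz, are
treated as authoritative). On the exact 216×2.46 s grid the same rule
yields 21 bins because the tag spacing is 10.6–10.9 bins rather than
10.8.

Per-voxel inference: two-tailed two-sample t-test with per-run tag-bin
powers as one group (n = n_runs) and all runs × noise-bin powers as the
other. Runs-as-samples is this package's reading of the replicate
structure (the source does not state it); with one tag bin per spectrum
it is the only reading that yields a two-sample test.

### Calibration of the tagging t-test

Under the null, per-run power values are approximately exponential.
With only n_runs (= 3) samples in the tag group, the pooled t-statistic
is not t-distributed: simulated null p-values show a KS distance of
~0.040 from uniform (independent of sample size), a mild *deficit* of
small-to-mid p-values — so the type-I error at α = 0.05 is accurate
(~0.044) — but an *inflated* extreme tail (P(p < 10⁻³) ≈ 0.0066,
P(p < 10⁻⁴) ≈ 0.0024). Two consequences: strict uniformity fails a KS
test at α = 0.01 once ~2000 voxels are examined, and Benjamini–Hochberg
family rejections on null families exceed q (family rejection rate
~0.40 at q = 0.05 with m = 100). The acceptance tests assert both
properties at face value and the two corresponding tests fail; they
document the statistic's real behavior rather than being relaxed.

`tagging_pvalues(..., scale="amplitude")` runs the identical test on
sqrt-power (amplitude) values, whose much smaller skewness makes the
null distribution essentially exactly uniform (KS D ≈ 0.006 at 20 000
voxels) and reduces the family rejection rate to ~0.10. The power scale
remains the default because it is the classic frequency-tagging
definition; the amplitude scale is recommended when calibrated
small-p inference matters. An exactly calibrated alternative would be
an F-ratio of tag power to mean noise power (exact under white noise),
but it is a different statistic and is not substituted anywhere.

Phase maps take the FFT phase at the stimulation bin for voxels whose
amplitude SNR clears a threshold (default 2, the phase-encoded-mapping
convention). Cycle averages interpolate onset-aligned epochs onto a
common TR grid and report mean ± SEM across cycles; windows longer than
the inter-onset gap require explicit wraparound.

## Localizer GLM

Condition boxcars (default 20 s blocks) are convolved with the
canonical HRF on a 0.1 s grid and sampled at TR; the design adds an
intercept and, optionally, a discrete-cosine drift set equivalent to a
128 s high-pass. Estimation is ordinary least squares vectorized across
voxels — algebraically identical to per-voxel statsmodels OLS, which
serves as the oracle in tests — with t = c'β̂ / sqrt(σ̂²·c'(X'X)⁻¹c) and
two-tailed p on residual df. Multiple runs are combined by Stouffer's
z. No autocorrelation whitening is applied (a known limitation; the
synthetic noise is white by default).

## ROC, overlap, profile

The threshold ladder is 10 log-spaced values 10⁻¹⁰..10⁻¹ plus 10
log-spaced 10⁻⁰·⁹..1 (20 steps, strictly increasing). Proportions use
strict inequality (p < threshold; ties are excluded), points are
augmented with (0,0) and (1,1), and AUC is the trapezoid over the
false-alarm axis; it matches the Mann–Whitney probability statistic
within 0.02 on a dense grid and within 0.05 through the 20-step ladder.
Multi-ROI false-alarm pools concatenate voxel lists rather than
averaging proportions. Overlap percentages are 100·|SW∩FL|/|SW| (whole
brain) and 100·|FD∩SW|/|FD| (category ROIs). The hierarchy profile
divides each area's proportion of p < 0.001 voxels by the V1/V2 mean
proportion; a zero baseline raises an error rather than being patched
with an epsilon. With null early areas the baseline consists of false
positives only, so individual V1/V2 fold changes scatter around 1 with
Poisson noise while their (weighted) mean is 1 by construction — the
meaningful claims are "V1/V2 at baseline" and "monotone rise from V3".

## Determinism and sizes

Every random operation flows from one integer seed; per-stage seeds are
derived through `numpy.random.SeedSequence` and stay below 2³¹.
Identical configuration and seed give byte-identical reports. Default
test-suite problem sizes (64–512 px images, ≤ 9000-voxel studies, 2–3
runs) were chosen so the full chain — including the 400-frame 512×512
isoenergy sweep and the 2000-voxel null calibration — completes in well
under a minute each.
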