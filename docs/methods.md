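# Methods

This note documents the models, parameter choices and numerical decisions
behind `beelobe`, and what the synthetic benchmarks do and do not
demonstrate about real recordings.

## Recording model and coordinate conventions

A recording is 200 double frames at 12.5 Hz (80 ms per double frame,
16 s total), odor onset 4 s into the recording, odor duration 4 s.  Frame
`i` covers the half-open interval `[i·Δ, (i+1)·Δ)`; onset at 4 s is frame
50.  Post-onset analysis windows are defined on `(start, end]` ms and
keep the frames whose interval lies wholly inside: the early-separation
window (80, 160] ms is exactly post-onset frame 1 at 80 ms frames, and
frames {2, 3} at 40 ms frames.  The ratio baseline is the mean of the
first 40 frames (3.2 s), always strictly pre-odor.

## FURA rendering and inversion

Calcium elevation raises 340 nm-excited and lowers 380 nm-excited
fluorescence.  The renderer writes, per pixel of glomerulus k,

    F340 = A(p) · b340 · (1 + α ΔR_k(t)),
    F380 = A(p) · b380 · (1 − β ΔR_k(t)),

with channel baselines `b340 = b380 = 1000`, gains `α = β = 1`, and a
static anatomy image `A(p)` (glomerular tissue 30 % brighter than
background) that gives the resting fluorescence the spatial structure
movement correction needs; being common to both channels it cancels in
the ratio.  The ratio is a monotone nonlinear map of ΔR,
`q = (1 + αΔR)/(1 − βΔR)`, with exact inverse `ΔR = (q − 1)/(α + βq)`
(`invert_ratio_movie`); recovery tests check the full chain through this
inversion to ≲1e−15.  Rendering refuses parameter combinations that
would drive F380 non-positive.  Movie drift and registration use
periodic (wrap-around) translation; pixels that wrapped are tracked in a
validity mask and excluded from segmentation.

Movement correction is rigid translation estimated by FFT phase
cross-correlation of each frame's summed channels against a reference
image (pixelwise median of the pre-odor frames), integer-pixel by
default with an optional 0.1 px subpixel mode; between-video alignment
applies one common shift per video against the first video's reference.
The order is fixed as register → ratio → baseline, since a ratio of
shifted pixels is not a shift of the ratio near edges.  Division by a
non-positive F380 is a hard error reported with pixel coordinates —
inside stained tissue it can only mean corrupted data.

## Segmentation

Glomeruli impose one characteristic time course each on their pixels, so
after per-pixel Z-scoring of the concatenated stimulus movies, spatial
Gaussian smoothing (σ = 2 px), and PCA (k = 30), "pure" pixels of
different glomeruli sit on extreme rays of the convex cone spanned by
all pixel loadings.  Generators are picked greedily by maximal residual
norm after projecting out the span of previous picks (stop: residual
< 0.2 × initial max, or 40 generators); pixels join the generator with
their largest non-negative least-squares coefficient if it reaches 50 %
of the generator's self-coefficient; connected components < 20 px are
dropped and the rest relabeled.  PCA runs on the movies of all stimuli
concatenated so one map serves the whole session.

Two numerical choices matter.  First, a *coherence floor*: Z-scoring
standardizes every pixel to unit variance, but smoothing collapses
incoherent noise pixels to SD ≈ 1/(2σ√π) ≈ 0.14 while spatially coherent
glomerular pixels stay near 1, so pixels below SD 0.3 after smoothing
are background.  This is what makes a pure-noise movie yield zero ROIs
instead of smoothing-artifact blobs; it presumes σ > 0 on noisy data.
Second, on noise-free data smoothing is counterproductive (it only blurs
exact ROI borders), so recovery benchmarks run σ = 0 there and σ = 2 on
noisy data.  Exact equivalence with any specific published
implementation of the cone-factorization family is a non-goal; the
algorithm is validated by ground-truth recovery instead.

## Metric definitions and tie-breaks

Distances are unnormalized Euclidean by default (the √n-normalized
variant is a flag) — the unnormalized scale matches the ~0.05 baseline /
>0.1 odor dissimilarity regime the defaults emulate.  The distinctness
criterion compares d(t) against baseline *mean* + 3·SD (the mean offset
prevents trivial exceedance under biased baseline noise), with the
degenerate noise-free case (mean = SD = 0) reduced to d > 0 and logged.
The responder rule uses each glomerulus's own baseline mean + 3·SD and
requires 2 consecutive supra-threshold odor frames to suppress
single-frame noise spikes; on pure noise this yields a per-glomerulus
false-positive rate near 0.06 % (bound 2 %).  "Peak response" is the
240–800 ms post-onset window (frames 3–10), configurable and always
reported; dominant-glomerulus rank ties break toward the lower
glomerulus index so outputs are deterministic.  M17 normalization is
subtractive (odor-window rate − baseline rate) because baseline rates
near zero make ratios unstable; a divisive mode exists and refuses
silent baselines.

## Statistics

The gate thresholds are fixed at p > 0.05 for both Shapiro–Wilk and the
variance F-test.  Mann–Whitney and Wilcoxon use exact p-values for
n ≤ 25 without ties and the tie-corrected normal approximation
otherwise.  Fisher's two-sided p sums all tables with probability ≤ the
observed one (with the standard 1 + 1e−7 relative guard); it is checked
exhaustively against integer hypergeometric enumeration for all tables
with margins ≤ 12.  Cohen's d uses the (n−1)-weighted pooled SD and is
attached to every comparison regardless of significance (categories
0.2/0.5/0.8).  Constant or n < 3 samples fall back to the non-parametric
branch with a note.  No multiple-testing correction is applied; the
report records the number of comparisons so users can add their own.
Empirical type-I error of the whole selection workflow on Gaussian nulls
is ~4.7 % (band 3–7 %).

## The synthetic generator

Each glomerulus trace is amplitude × temporal kernel + i.i.d. Gaussian
noise (SD 0.01 ΔR/frame).  The kernel rises linearly over 3 frames,
plateaus during the odor, and decays exponentially (τ = 1 s) after
offset — the shape is plausible but not fitted to data.  Response
amplitudes are graded multiples (0.75–1.25×) of 0.06 ΔR, which puts the
baseline distance near 0.05 and the odor-evoked distance above 0.1.  The
new odor's pattern diverges from the CS+ pattern along a non-decreasing
per-frame ramp w(t) reaching 1 two frames after onset; the mixture is
the elementwise max of the component patterns (saturation
approximation); mineral oil is noise only.  Cohort cells default to the
imaging sample sizes (paired 7/10, unpaired 6/10 for solvent/inhibitor).

Between-bee heterogeneity: a per-bee response gain (SD 0.15, emulating
staining quality), responder-count jitter (SD 2.2 glomeruli), and a
per-bee extinction-drift scale (SD 0.6 of the mean).  These exist so
planted treatment effects have realistic effect sizes instead of being
trivially separable.

Planted effects, confined to the cells where the study observed them:

* **Early pattern separation** (paired + inhibitor): the ramp is slowed
  by `separation_lag`.  The default (1.25) was calibrated once so the
  solvent-vs-inhibitor contrast has Cohen's d ≈ 1.408, the published
  magnitude; `plant_early_separation_effect` re-derives the lag for any
  target d by Monte-Carlo inversion with common random numbers.
* **New-odor recruitment** (paired + inhibitor): new-odor responder
  fraction 0.27 vs 0.6 (d ≈ 2.2).
* **New-odor response strength** (paired + inhibitor): the whole
  new-odor pattern is attenuated by `dominant_gain_new` (0.8).  Uniform
  attenuation preserves within-pattern ranking, so the measured
  dominant-glomeruli amplitude scales by exactly this factor.
* **Extinction drift** (unpaired + inhibitor): the two dominant CS+
  glomeruli gain +0.006 ΔR per trial, scaled per bee.  A linear drift
  cannot simultaneously reproduce significant dominant-peak contrasts
  and null distance contrasts as the study reports for separate
  measures; the planted magnitudes bracket the published per-trial
  effect sizes and the distance contrasts come out stronger than in the
  real data.  This is a known fidelity limit, not a pipeline property.

M17 spikes are homogeneous Poisson: baseline 0.2 Hz; odor rates anchored
at the published means (trained solvent CS+ 7.0 Hz, mineral oil ≈ 1 Hz
after normalization), with more generalization to the new odor and
slower extinction decay under the inhibitor.  No between-bee rate
heterogeneity is modeled, so M17 effect sizes are larger than published;
the Poisson closed forms are what the calibration tests check.

Randomness: one stream per (master seed, group, treatment, bee,
stimulus), so any stimulus subset reproduces bit-exactly what a full run
would have produced, and whole pipeline runs are byte-identical under a
fixed seed (reports contain no timestamps; timings live only in the run
manifest).

## What the benchmarks show — and don't

Recovery at Jaccard 1.0 / trace correlation ~1 on noise-free movies
shows the imaging chain is information-preserving; 15/15 ROIs at
Jaccard ≥ 0.6 under trace noise 0.02 + camera read noise shows graceful
degradation.  Real recordings add bleaching, focal drift, overlapping
and out-of-focus glomeruli, and non-white noise — none of which the
generator models (white Gaussian noise is an explicit assumption, with
the SD exposed as a parameter).  Passing benchmarks therefore validate
the implementation, not the biological robustness of the original
measurements.  The planted-effect power experiment (one-tailed, matching
the directional prior for the separation deficit; ≥ 80 % of 200 cohorts
at n = 7 vs 10) shows the statistics stage detects a d = 1.408 effect at
the study's sample sizes; the effect-free unpaired arm stays at the
nominal false-positive rate.

## Problem sizes

Default test and validation runs use: full-size movies (130 × 172 px,
200 frames, 15 glomeruli) for segmentation/preprocessing recovery; the
full default cohort (33 bees × 10 stimuli) for pipeline runs; 10⁴ noise
glomeruli and 500 noise cohorts for detector calibration; 200 simulated
cohorts for the power experiment; 10⁴ null comparisons for workflow
size.  Unit tests use a reduced geometry (60 × 80 px, 120 frames, 3–5
glomeruli) chosen to exercise identical code paths.
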