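# Methods

`sleepscape` implements the complete computational pipeline of a
simultaneous electrophysiology + fMRI mouse-sleep experiment: artifact
removal and channel repair on the electrophysiology, semi-automated sleep
staging, detection of NREM micro-events (spindles, hippocampal sharp-wave
ripples, slow waves), BOLD nuisance modelling and a state GLM, a two-step
group PCA of BOLD dynamics, LSTM prediction of brain-state categories from
the PCA time courses, and neural-event-triggered (NET) fMRI statistics. A
synthetic-session generator provides ground-truthed inputs with the
statistical structure each stage assumes, so the full pipeline is testable
without any raw recordings.

## Time conventions

All times are seconds from the first fMRI volume. Intervals are half-open
`[start, end)`. Volume indices are 0-based; frame `k` covers
`[k*TR, (k+1)*TR)` with TR = 2 s (frame rate 0.5 Hz). Hypnogram labels are
materialised at 1 Hz by sampling each second's midpoint.

## Synthetic sessions

Sleep architecture is a semi-Markov chain: an embedded jump chain on
{AW, NREM, REM} with zero diagonal and, by default, the observed transition
set {AW→NREM, NREM→AW, NREM→REM, REM→AW}. Dwell times are lognormal with
medians AW 46.0 s, NREM 41.0 s, REM 121.5 s (the fragmented-mouse-sleep
values), shape σ = 0.6 for AW/NREM and σ = 0.25 for REM (REM bouts are the
most stereotyped; the tighter shape also keeps the per-session REM fraction
near its expectation in desk-scale sessions). NREM→REM probability is 0.06,
putting REM at roughly 5–10 % of recording time, as in freely sleeping
mice. Dwells are rounded to integer seconds with a 5 s floor. Default
session length is 2400 s.

Electrophysiology (default 1024 Hz) is built per channel from a 1/f
background plus state-gated band oscillators. `band_gains` are **power**
multipliers relative to AW: delta (1–4 Hz band noise) ×3.5 in NREM and
×0.4 in REM; theta ×4 in REM; EMG (160–250 Hz) ×0.15 in NREM and ×0.05 in
REM. REM theta is generated as a sustained oscillation with slowly
wandering frequency (7 ± 0.8 Hz) and amplitude, not band noise — its
bin-to-bin band power is nearly constant, which is also true of real
hippocampal/cortical REM theta and which the variance-based REM criterion
needs. Events are Poisson-placed inside their permitted states without
overlap: spindles are 10–16 Hz Hann-enveloped bursts of 0.5–2.5 s on the
mPFC iEEG channel; SWRs are ~50 ms 150–200 Hz ripples riding a negative
sharp wave on the CA1 LFP channel, placed inside a random spindle interval
with probability `coupling_prob`; slow waves are biphasic deflections with
a 0.5–1.1 s negative phase. The gradient artifact is a fixed harmonic
stack tiled at the slice period (TR/22 ≈ 90.9 ms → 11 Hz fundamental) with
a slow 5 % amplitude modulation; slice triggers are always present.

BOLD volumes (default 16×16×8, 0.2×0.2×0.5 mm voxels, baseline 100) are a
sum of spatial-map × HRF-convolved drivers (NREM/REM boxcars and per-type
event impulse trains), a per-voxel quadratic drift, a motion-coupled +
slow-physiological nuisance shared with the non-brain rim voxels, and
white noise (SD 0.5). Non-brain voxels carry nuisance and noise only.

What the generator does **not** emulate: 1/f-slope changes across states,
spectral micro-structure of real ECoG, vascular and respiratory dynamics,
spatial autocorrelation of BOLD noise, registration/motion interpolation
artifacts, and electrode-specific noise. Passing tests therefore establish
that each estimator recovers what it is defined to recover under its own
generative assumptions — not field performance on real recordings.

## Ephys denoising

Gradient artifacts are removed by slice-template subtraction: the signal is
segmented at slice triggers, each segment's template is the sliding average
of the surrounding 30 segments, and subtraction is iterated twice. The
local average tracks slow artifact drift; no residual-PCA stage is applied.
A note on idempotence: the sliding-average operator is not a projection, so
re-running the algorithm perturbs stochastic signal content slightly; what
is idempotent is the artifact component itself — after one pass the
slice-locked average of the output is < 1 % of the artifact and a second
pass changes it by < 1 % (tested).

Bad channels are replaced by a distance-weighted average of good channels
with weights `Dis**λ` (λ < 0) **normalised to sum to one**. The printed
prefactor form (1/(14−k) with unnormalised powered distances) is not
invariant to the distance unit; normalisation restores scale invariance
and gives the plain-mean limit as λ → 0 (the prefactor form is recovered
when all distances are equal). λ is estimated by leave-one-out least
squares over a user grid; ties resolve to the smallest |λ|.

Downsampling (24414 → 1024 Hz) applies a zero-phase elliptic low-pass at
0.45·fs_out (passband ripple 0.002 dB, stopband ≥ 45 dB, squared by
forward–backward filtering) followed by linear-interpolation resampling —
at ≥ 24× oversampling the interpolation error for in-band content is well
below the filter ripple.

## Sleep staging

Features: multitaper spectrogram (3 s window, 1 s step, time-bandwidth 3,
5 Slepian tapers), band powers δ 1–4 Hz, θ 6–12 Hz, EMG 160–250 Hz and the
θ/δ ratio, each smoothed by a 20-point running median with the even-kernel
(mean of middle order statistics) and zero-padded-edge semantics of the
common reference implementation, for bit-comparability.

Tentative rule per second, REM evaluated first because it is the stricter
test: REM if smoothed ratio > mean + 2 SD **and** EMG below mean − 1 SD;
else NREM if smoothed delta > its mean; else AW. "Its mean" is the
session-wide mean of the smoothed series. The EMG criterion is applied on
the RMS-amplitude scale (square root of band power): EMG power is bimodal
(high AW, low sleep) and whenever AW occupies less than half the session
the power-scale mean − 1 SD falls below every sample, making the criterion
vacuous; the amplitude scale compresses the split enough for the
threshold to separate sleep from wake. This is also the scale on which EMG
traces are conventionally displayed.

Boundary refinement replaces the study's manual adjustment with a
deterministic surrogate: (1) REM hysteresis — each REM epoch is extended
while the ratio stays above mean + 1 SD with EMG below its mean, because
the 2 SD entry criterion drops out mid-bout and fragments real episodes;
(2) NREM starts/ends snap to the steepest ascent/descent of smoothed delta
within ±10 s, REM starts to the preceding NREM end, REM ends to the
steepest theta descent; (3) where an *informative* EMG boundary (local
|Δ EMG| above mean + 1 SD of all |Δ EMG|) disagrees with the ECoG boundary
by more than 2 s, the floored midpoint is used — the informativeness guard
prevents a flat EMG trace from injecting arbitrary boundaries; (4) epochs
shorter than 5 s merge into the longer flanking epoch (tie → preceding)
until stable; (5) a REM epoch directly after AW is illegal (REM is entered
from NREM): shorter than 15 s it is absorbed into AW as a spurious
detection, otherwise the preceding epoch is relabelled NREM. Scoring is
exactly invariant to global amplitude rescaling.

## Event detection

All thresholds are relative, so detection is amplitude-scale invariant.

*Spindles*: 10–16 Hz 4th-order zero-phase Butterworth, analytic-signal
magnitude smoothed 50 ms; threshold mean + 1.5 SD over NREM samples;
supra-threshold runs closer than 30 ms merged. The 0.4–3 s duration window
is applied to the supra-threshold run: the mean-crossing walk that defines
the reported bounds pads every event with background-envelope excursions
whose length is SNR-independent, so run length is the robust duration
statistic. Bounds come from the walk (down to the NREM envelope mean on
both sides of the peak), capped at 3 s around the peak.

*SWRs*: 120–250 Hz (truncated below Nyquist), envelope threshold
mean + 3 SD computed on the **unsmoothed** analytic magnitude, detection on
a 20 ms-smoothed copy, conjoined with 20 ms ripple power above its session
mean, and a 20 ms minimum event duration. Thresholding the raw envelope
while detecting on the smoothed one suppresses isolated noise excursions
(false-positive rate on pure 1/f noise ≈ 0 events/s) without moving the
threshold definition.

*Slow waves*: 0.3–4.5 Hz 2nd-order zero-phase Butterworth; NREM negative
half-waves with interval T ∈ [0.4, 2.0] s; onset/offset at the first and
third zero crossings (waves whose full extent exceeds 2 s are dropped);
per-session thresholds keep the top 35 % by trough depth **and** the top
45 % by trough-to-peak amplitude, percentiles taken over duration-valid
candidates (⌊q·n⌋ deepest kept). Fewer than 10 candidates yields an empty
table with a warning. Because the rule retains a fixed fraction of
candidates, recall against an arbitrary injected-event list is bounded by
that fraction by construction; correctness is tested against a brute-force
percentile oracle.

*Coupling*: an SWR is coupled iff its center lies in a spindle's
`[start, end)`; a spindle is coupled iff it contains ≥ 1 SWR center.

## fMRI nuisance model and QC

0.4 mm isotropic Gaussian smoothing per volume; no temporal filtering. The
nuisance design is 6 motion parameters, their backward differences (first
row zero) and the leading temporal PCs of variance-normalised non-brain
voxels (default 40, capped at rank; component signs fixed by making the
largest-|loading| voxel positive). Regression is per-brain-voxel OLS with
an intercept; the residual plus voxel mean is returned; non-brain voxels
pass through untouched; collinear columns are dropped via pivoted QR with
a warning. FD uses a 5 mm rotation radius (mouse head; config-exposed);
DVARS is the RMS over brain voxels of the frame difference of the
global-mean-normalised series; both are 0 at t = 0.

## State GLM

The HRF is a single gamma with mode 1.75 s and FWHM 1.5 s (inside the
1.5–2 s hemodynamic delay reported for mice), unit area, 20 s support;
shape/scale are solved numerically from (peak, FWHM). NREM and REM boxcars
at 1 Hz are HRF-convolved, sampled at frame onsets, and mean-centered (AW
implicit baseline). Per-voxel OLS with intercept gives beta/t maps;
Benjamini–Hochberg FDR at q = 0.05 across brain voxels per predictor.
Band-power/BOLD coupling is computed per epoch (epoch-mean HRF-convolved
power and epoch-mean BOLD, each relative to the session AW mean,
`value/AW − 1`), with Pearson r across epochs per band; fewer than 3
epochs → missing.

## Group PCA and state dynamics

Scan-level PCA reduces each centered scan to `p_scan` (default 200,
capped at rank) weighted spatial components (`diag(s)·Vt`); the stacked
reduced matrices undergo a second SVD whose top `p0` (default 100) right
singular vectors form the group spatial weights W (rows orthonormal,
deterministic sign). tPCs are the back-projection `(S − mean) @ W.T` per
scan; for a single full-rank scan this equals one-step PCA scores exactly.

Phase profiles resample each ≥ 60 s epoch's tPCs to 60 phase bins and
average; the null circularly shifts each epoch's resampled series (which
preserves autocorrelation), 1000 times, reporting 2.5/97.5 percentiles.
Transition-triggered averages align a 1 Hz-resampled series in a ±30 s
window, with a random-trigger null. The manifold uses the first 3 PCs with
a 12×12 mean one-step flow field over the first two. The asymmetry test
compares the mean AW→NREM trajectory with the time-reversed mean NREM→AW
trajectory pointwise (Euclidean distance in the first 3 dims); the null
splits same-type transitions into random halves; the per-time-point
one-tailed p uses a prediction-interval t statistic against the null
sample, which is calibrated for a single draw rather than anti-conservative
like a test of the null mean. The 2-D electrophysiological state space is
x = δ/total (1–100 Hz) power, y = θ/δ.

## LSTM state prediction

The network is the standard gated recurrence (forget/input/candidate/
output gates on `[h_{t-1}, x_t]`, cell state, tanh output) with a softmax
readout of the final hidden state over the seven categories (three "only"
states and four transitions). Forward, backpropagation-through-time and
Adam are implemented directly in numpy (no framework dependency); the
forward pass is verified against an independent scalar-loop reference and
gradients against central differences. Full-scale defaults follow the
recipe: 1 layer × 50 units, lr 0.01 halved every 1000 of 8000 steps, batch
128, 500 bootstraps, 10-fold CV; `test_profile()` holds the desk-scale
settings used by the test-suite and acceptance script (10–16 units,
120–250 steps, 2–3 folds, 20–50 bootstraps) so everything runs in minutes
on one CPU.

Clips: tPCs are z-scored per scan; transition clips cover frames
`[k_trans − gap − L, k_trans − gap)` (L = 5 steps = 10 s at TR 2 s);
"only" clips lie fully inside an epoch at least 60 s from any transition,
sampled without replacement. Each bootstrap balances every category to the
minimum count, runs stratified k-fold CV, and records per-category test
accuracy (macro); the null repeats the pipeline with shuffled labels. The
discriminate time is the farthest gap whose accuracy exceeds the null 95 %
CI upper bound with exceedance at every smaller gap (the contiguity rule
avoids isolated-gap false positives). Sensitivity maps zero one tPC at a
time in the test clips, record the accuracy drop per bootstrap, project
mean drops through W, and mask voxels by BH-FDR q < 0.05 ∧ |Cohen's
d| > 0.3 across bootstraps.

## NET-fMRI

Events are counted at the frame rate: frame k is an event frame iff ≥ 1
matching event center falls in `[k·TR, (k+1)·TR)`, duplicates collapsed.
Responses are voxelwise % change from the per-epoch baseline (frames −5…−2,
i.e. −10…−4 s) over a −5…+10-frame window; epochs overrunning the scan are
dropped. Session-level scalars are the mean over post-event frames 0…+5
(0–10 s), config-exposed. Condition contrasts use two-tailed paired or
unpaired t-tests on per-session scalars (voxelwise maps BH-FDR corrected);
the synergy analysis compares the spindle-coupled SWR response against the
sum of the solitary-spindle and solitary-SWR responses (paired t across
sessions, sessions with < 10 epochs in any class excluded). Pre-transition
event probability compares per-second event indicators before transitions
against matched offsets in sampled long NREM epochs (left-tailed
two-sample t); the earliest significant time is the start of the
contiguous significant tail ending at the transition. The time–frequency
contrast is an uncorrected per-cell two-tailed two-sample t map at
p < 0.05 by design.

## Numerical and degenerate-input choices

- Constant-zero recordings stage as all-AW (all strict thresholds fail).
- A state absent from a hypnogram gives a zero design column; the GLM uses
  a pseudoinverse and reports t = 0 there.
- Coincident channels (zero distance) degrade interpolation to a
  nearest-channel copy with a warning.
- Empty event tables round-trip as header-only TSVs.
- All stochastic procedures accept a seed or `numpy.random.Generator`;
  identical seeds give byte-identical outputs.

## Problem sizes

The test-suite and acceptance script run the generator at desk scale —
2400 s default sessions on a 16×16×8 grid, 1200 s event-detection
sessions, 5 scans × 2400 s for the LSTM gap curves with the reduced
training profile, and 16-session cohorts for the synergy inference. These
sizes were chosen so every statistical property under test (staging
agreement, detector F1, CI calibration, discriminate-time recovery) has
comfortable margins while the whole pipeline remains a minutes-scale run.

## Known limitations

- The staging thresholds inherit the study's session-wide mean/SD
  convention; sessions in which REM occupies well over ~15 % of the
  recording weaken the mean + 2 SD ratio criterion (the threshold chases
  the REM mass). The hysteresis refinement mitigates but cannot remove
  this.
- The slow-wave percentile rule makes recall against injected events
  structurally bounded by the retained fraction.
- The LSTM is CPU-bound numpy; full-scale settings (500 bootstraps ×
  10-fold CV × 8000 steps) are available but intended for longer runs.
- Second-level inference treats sessions as exchangeable units (one-sample
  or paired t); mouse-level random effects are out of scope.
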