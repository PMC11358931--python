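# Methods

`betanf` simulates and analyses a double-blind, sham-controlled EEG
neurofeedback (NF) protocol for bidirectional control of sensorimotor
beta power (14–31 Hz), the oscillatory band whose excess synchrony in
basal-ganglia–cortical circuits is a hallmark of Parkinson's disease.
The package covers the full protocol loop: synthetic C3–Cz EEG,
individualized beta calibration from a Go/No-go run, a 250 ms closed-loop
feedback engine with sham replay, and the offline spectral and
statistical analysis.

## The spectral convention

One convention is fixed once and reused by every stage, because the
feedback thresholds only make sense on a single internally consistent
scale:

- PSD of a **500 ms window** (250 samples at 500 Hz): linear detrend,
  symmetric Hamming taper (length 250), FFT, squared magnitude on the
  one-sided grid. No zero-padding — the frequency grid is exactly 2 Hz,
  and padding would silently move the bin centers used for the
  individual peak. No density scaling: only relative comparisons matter
  downstream, so raw squared magnitude is kept everywhere.
- **Band power** is the mean of the PSD bins with `lo ≤ f ≤ hi`, both
  ends inclusive (the ±5 Hz band language is a closed interval).
- The **real-time stream** emits one band-power value every 250 ms from
  the trailing 500 ms of signal; the first value exists at t = 0.5 s.
- Windows longer than 500 ms (the 1 s MRBD, 2 s PMBR and 2 s baseline
  windows) are estimated as the mean of non-overlapping 500 ms tiles, so
  the same primitive serves the real-time and offline paths.
- NaN samples are rejected, not skipped: a real-time loop must never
  silently drop a window.

## Synthetic EEG

The generator produces the statistical structure the protocol assumes
and nothing more:

- **Beta carrier**: an amplitude-modulated sinusoid at the participant's
  peak frequency (default 21 Hz, the group-mean individual peak).
  Envelope steps are smoothed with a 100 ms raised-cosine ramp; hard
  steps would splatter power across the spectrum and confound the PSD
  tests.
- **Background**: white Gaussian noise shaped to a 1/f^a power law
  (default a = 1, SD 1 µV), the standard resting-EEG assumption. No
  alpha/mu rhythm, no structured blink artifacts, no multi-channel
  volume conduction — so passing tests demonstrate the pipeline's
  correctness on the assumed signal model, not robustness to every
  feature of real EEG.
- **Movement-locked modulation** on Go trials: beta power is scaled by
  `1 − mrbd_depth` during 0–1 s after the imperative cue
  (movement-related beta desynchronization) and by `pmbr_gain` during
  1–3 s (post-movement beta rebound). The magnitudes are free
  parameters — the source observations are graphical — and default to
  `mrbd_depth = 0.4`, `pmbr_gain = 1.4`, which gives the canonical
  biphasic envelope at comfortable SNR (beta amplitude 3 µV on a 1 µV
  background).
- **Closed-loop agent**: during the pre-cue NF period (when the bar is
  controllable), beta power is scaled by `1 − desync_gain` on
  instructed-left trials and `1 + sync_gain` on instructed-right trials
  after a 0.5 s reaction lag. `sync_gain = 0` emulates the empirical
  asymmetry that beta can be suppressed on demand but not raised.
- **Artifacts**: Hann-shaped transients of 50–200 ms at 10–15× the
  signal SD, at Poisson times (rate per minute configurable, default 0).
- **Behavior**: Go-trial reaction times are drawn from a clipped normal
  (mean 0.49 s, SD 0.08 s, matching the observed ≈0.49 s group means).

Every generator is deterministic in its profile's seed. A 5 s quiet
lead-in precedes the first trial so that even its pre-trial baseline
window lies inside the recording.

## Calibration

From the 32-trial calibration run (16 Go / 16 No-go), using only correct
Go trials (a response 100–800 ms after the imperative cue; movement is
required for MRBD/PMBR to exist):

- **fmax** — mean PSD across trials in the MRBD and PMBR windows; the
  individual peak is the 14–31 Hz frequency maximizing
  `PSD_PMBR(f) − PSD_MRBD(f)`. The subtraction is taken in this order
  because it is the maximal-modulation contrast, positive at the
  modulated frequency whenever both phenomena exist. Ties break toward
  the lower frequency.
- **R_beta** — `fmax ± 5 Hz`, clipped to [14, 31] Hz.
- **Thresholds** — per trial, mean `R_beta` power in the MRBD window,
  the PMBR window and the 2 s baseline preceding pre-cue onset;
  `th_desync` and `th_sync` are the medians across trials of
  (MRBD − baseline) and (PMBR − baseline). The per-trial fixation-period
  baseline is used (rather than the eyes-open rest) because the
  thresholds are defined trial-wise.
- **QC** — at least 8 correct Go trials are required, and the biphasic
  signature must be confirmed. Presence of each phenomenon is a
  one-sided signed-rank test across per-trial deflections at α = 0.05:
  a raw sign check on the mean flips on noise whenever the true
  modulation is absent, which is exactly when the flag must say "no".

Parameter recovery at the defaults: injected peaks {16, 21, 26} Hz are
recovered within one 2 Hz bin in 100% of 20-seed batches (the tests
require ≥ 90%).

## The closed-loop engine

Per trial: the bar resets to center; `BL_beta` is the mean of the eight
250 ms-grid beta values timestamped in the 2 s before pre-cue onset (the
earliest value's 500 ms window necessarily reaches 250 ms further back —
the causal stream has no other reading); during the pre-cue period
(4.25–5 s, jittered), `D_beta` = current 500 ms window − `BL_beta` is
updated every 250 ms and moves the bar 20 px left if
`D_beta < th_desync`, 20 px right if `D_beta > th_sync`, otherwise 10 px
toward center without crossing it. The bar clamps at ±400 px (half a
nominal 800 px screen; the protocol defines step sizes but no bounds,
and a bar off-screen is meaningless). The bar freezes at imperative-cue
onset.

**Sham sessions** run the identical algorithm on values replayed
sequentially from the calibration-phase beta stream (preserving its
temporal statistics, wrapping with a notice if exhausted): each sham
trial consumes 8 values for its own replay baseline and then one per
update, baselined against that replay baseline but compared against the
current session's thresholds. Outlier interpolation is *not* applied on
the real-time path — causal interpolation is ill-defined; cleaning
belongs to the saved time courses analysed offline.

**Blinding**: session conditions come from a pre-generated
counterbalanced schedule (each participant gets (real, sham) or
(sham, real); orders balanced within one across participants) that only
the engine reads; a session's public summary does not contain the
condition.

## Offline analysis

- Epochs of [−2, +4] s around pre-cue onset (NF analysis) or the
  imperative cue (movement analysis).
- Zero-phase FIR band-pass at the individual range (Hamming-windowed
  `firwin`, 751 taps, forward–backward). No notch: the band sits well
  below mains frequency.
- Artifact rejection replaces manual inspection with a deterministic
  rule: drop epochs with peak-to-peak > 150 µV or variance > 5× the
  median epoch variance, logging every drop.
- Outlier interpolation on saved beta time courses: entries more than
  3 scaled MADs (1.4826 × MAD) from the median are replaced by linear
  interpolation of non-flagged neighbours; edge outliers take the
  nearest non-flagged value. When the MAD is zero, the strict inequality
  flags exactly the entries differing from the median, leaving constant
  series untouched. The operation is a single pass: re-thresholding on
  the cleaned series could flag new borderline entries (the MAD shrinks
  once spikes are removed), so "clean once" is part of the definition.
- STFT time–frequency maps: 2 s Hann segments at 50% overlap; the
  native 0.5 Hz bins are averaged in adjacent pairs onto a 1 Hz grid
  (out[k] pools the bins at k − 0.5 and k Hz) to stabilize per-bin
  estimates.
- **Relative beta** = `10·log10(power[0,4 s] / power[−2,0 s])` in dB.
  0 dB means no change; the dB convention is unit-stable and
  scale-free, which the raw-magnitude pipeline otherwise is not.
- Timepoint tables at {−2 … 4} s use the mean of the two 500 ms windows
  spanning each integer second (one window at the epoch edges),
  averaged within participant and then across participants.

### Statistics

- **Signed-rank tests**: two-sided Wilcoxon, zero differences dropped.
  The p-value uses the exact null distribution whenever n ≤ 25 with no
  ties (it matches brute-force enumeration of all 2^n sign assignments
  to three decimals in the tests), otherwise the normal approximation
  with tie correction. The reported statistic is always the
  tie-corrected normal-approximation Z, signed so Z < 0 means the first
  sample is lower.
- **RT–beta correlations**: per participant, Pearson r (Spearman
  switchable) between trialwise reaction time and relative beta in each
  of the four (condition × direction) cells; cells with fewer than 5
  trials or zero variance are null and flagged.
- **Repeated-measures ANOVA** over the four cells on Fisher-z
  transformed correlations (correlations are bounded, so the z scale is
  the appropriate one for linear modelling), F with (3, 3(n−1)) df.
  Post hoc, all six pairwise paired t contrasts are Tukey-corrected via
  the studentized-range distribution (p = Q_sf(|t|·√2; k = 4, df = n−1)
  — this reproduces the conventional paired-contrast Tukey p-values).

## The planted-effect cohort

Group statistics need per-trial (RT, relative beta) pairs, not EEG, so
the cohort model generates them directly: 17 participants × 4 cells ×
21 trials (84 correct Go trials split over two directions and two
sessions). Relative beta is normal (mean −1.5 dB, SD 1 dB: suppression
regardless of instruction); RT is normal (0.49 ± 0.08 s) and bivariate
with relative beta at population r = 0.4 in the real-left cell only.
The planted r is a free parameter of the simulation — the observed
effect in humans has no published generative ground truth — chosen so
the coupling is a clear but within-cell-noise-dominated effect
(per-participant sample correlations from 21 trials have SE ≈ 0.2).
With these conditions the real-left > right-cells Tukey pattern is
recovered in ≥ 80% of seeds (100% in the shipped runs).

## Problem sizes

The shipped analyses use one synthetic participant for the within-session
pipeline (32 calibration trials, two 112-trial NF sessions) and 17
synthetic participants for group statistics; calibration recovery rates
are estimated over 20 seeds per injected peak. These sizes mirror the
protocol itself and keep every run reproducible from a fixed seed.

## Known limitations

- The synthetic agent modulates oscillation amplitude instantly (after a
  fixed lag) and noiselessly within a trial; human NF learning curves,
  fatigue and strategy shifts are not modeled.
- The background model is a pure 1/f process; robustness to line noise,
  electrode pops and non-stationary rhythms is out of scope (the offline
  rejection rules exist, but their thresholds are only exercised against
  injected transients).
- Figure-axis conventions of the source observations for relative beta
  are not defined in physical units; the package's dB convention is
  internally consistent but not numerically comparable to those plots.
- Qualitative workload/feedback instruments are out of scope; only the
  descriptive shape of the behavioral summary table is produced.
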