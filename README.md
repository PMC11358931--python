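# betanf

Simulation and analysis of a double-blind, sham-controlled EEG
neurofeedback protocol for bidirectional control of sensorimotor beta
power.

Cortical beta oscillations (14–31 Hz) over sensorimotor cortex are
suppressed during movement (movement-related beta desynchronization,
MRBD) and overshoot after it (post-movement beta rebound, PMBR); excess
beta synchrony is a hallmark of Parkinson's disease, which makes
volitional beta control a candidate therapeutic target. `betanf`
implements the full protocol loop for studying that question at the
desk: synthetic C3–Cz EEG with the canonical beta dynamics, per-participant
calibration, a real-time closed-loop feedback engine with a sham-replay
arm, a Go/No-go behavioral task model, and the offline spectral and
statistical pipeline.

The core quantities, per participant:

- **fmax_β** — the individual beta peak: the 14–31 Hz frequency
  maximizing PSD_PMBR(f) − PSD_MRBD(f) across correct Go trials of a
  32-trial calibration run; **R_β** = fmax_β ± 5 Hz clipped to [14, 31].
- **th_βD, th_βS** — feedback thresholds: trial-median baselined R_β
  power in the MRBD (0–1 s post-cue) and PMBR (1–3 s post-cue) windows.
- **BL_β, D_β** — per-trial baseline (2 s before pre-cue onset) and the
  250 ms-updated deviation from it that drives the feedback bar:
  20 px left when D_β < th_βD, 20 px right when D_β > th_βS, else 10 px
  back toward center. Sham sessions replay calibration-phase beta
  through the identical algorithm.
- **Relative beta** — 10·log₁₀(NF-period power / baseline power) in dB,
  the offline per-trial outcome correlated with reaction time and
  compared across the four (condition × direction) cells with a
  repeated-measures ANOVA and Tukey-corrected contrasts.

## Worked example

The numbered scripts under `analysis/` run the whole study for one
synthetic participant plus a 17-participant group analysis; each writes
its tables under `results/` (raw EEG goes to `scratch/`):

```sh
python analysis/01_simulate_participant.py
python analysis/02_calibrate.py
python analysis/03_run_neurofeedback.py
python analysis/04_offline_analysis.py
python analysis/05_cohort_statistics.py
```

Calibration (script 02) prints:

```
fmax_beta = 20 Hz, R_beta = [15, 25] Hz (16 correct Go trials)
thresholds: th_desync = -4532.7, th_sync = 4044.8 (baselined power units)
beta signature (MRBD then PMBR) confirmed: True
```

The synthetic participant's 21 Hz peak lands in the 20 Hz bin of the
2 Hz analysis grid; the negative/positive threshold pair reflects the
MRBD dip and PMBR overshoot, and the signature check confirms both
phenomena before the thresholds are trusted.

Offline analysis (script 04) of the two NF sessions — the agent can
suppress beta on demand but cannot raise it — prints:

```
real: relative beta left -2.49 dB, right -0.02 dB
sham: relative beta left -2.47 dB, right +0.04 dB
```

i.e. clear beta suppression on instructed-left trials and none on
instructed-right trials, in both conditions (the sham session differs
only in what drives the bar, not in what the participant does).

Group statistics (script 05) on a cohort where reaction time is coupled
to relative beta only in the real-left cell:

```
repeated-measures ANOVA: F(3,48) = 11.1, p = 1.2e-05 (n = 17)
  * real-left vs real-right: t(16) = +4.04, Tukey p = 0.005
  * real-left vs sham-left: t(16) = +5.56, Tukey p = 0.000
  * real-left vs sham-right: t(16) = +4.45, Tukey p = 0.002
```

The planted cell stands out against the right-direction cells, the
pattern this design exists to detect.

## Layout

```
src/betanf/        library: recording, spectral, synthetic, task,
                   calibration, engine, offline, cohort, io
analysis/          numbered study drivers (see worked example)
scripts/           acceptance.py
tests/             pytest suite (unit, property, end-to-end)
docs/methods.md    models, conventions, parameter choices, limitations
```
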