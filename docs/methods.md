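# Methods

This note records the models, conventions and free design choices behind
`cvawear`, in the spirit of a statistics package's model documentation:
what is computed, under which assumptions, and which knobs matter.

## The measurement model

A chest patch records ECG (500 Hz), a dorsoventral SCG (1000 Hz), an
infrared PPG (67 Hz) and a triaxial accelerometer.  The cardiac timing
chain is anchored at the ECG R-peak of each beat:

* **PEP** — R-peak to aortic-valve opening (AO) on the SCG; a contractility
  marker that *lengthens* when sympathetic drive falls.
* **LVET** — AO to aortic-valve closing (AC); reported as the HR-corrected
  **LVETi** = LVET + c·HR with a Weissler-style additive slope
  c = 1.7 ms/bpm (configurable; the correction form is a convention —
  only "HR-corrected" is inherited, and c is recorded in output metadata).
* **PAT** — R-peak to the PPG pulse foot; **PTT = PAT − PEP** isolates the
  vascular transit component.  PTT is computed from the window-level PAT
  and PEP, so the identity holds exactly in every emitted row.
* **HRV** — RMSSD, SDNN and Welch band powers (LF 0.04–0.15 Hz,
  HF 0.15–0.4 Hz) of the NN tachogram, per 5-min window.

All channels are resampled to 500 Hz (polyphase FIR) and band-passed with
zero-phase forward-backward Butterworth filters (order 4 per pass; SCG
1–40 Hz, PPG 1–8 Hz).  Zero-phase filtering matters: every marker is a
*timing*, and a causal filter would bias them all.

## Beat detection and screening

Three R-peak detectors with distinct mechanisms — a smoothed
squared-gradient envelope, a stationary-wavelet detail-energy envelope
(db3, level-4 details ≈ the QRS band at 500 Hz), and a Pan–Tompkins-style
band-pass/derivative/square/integrate chain — feed a fusion rule with the
gradient detector as reference: a reference peak survives only if at least
one other detector placed a peak within 150 ms (inclusive), matched
greedily nearest-first with a one-to-one constraint per detector pair.
All three envelopes are squared, so inverted-polarity leads cost nothing.
Peaks within 200 ms of the record edges are discarded (template/filter
truncation).  The design treats the detectors as pluggable strategies;
the contract (one time per QRS, perfect recall/precision on clean
synthetic ECG within 50 ms) is what the pipeline relies on.

NN screening: intervals outside 333.3–1500 ms (40–180 bpm, closed bounds)
are masked as `physiological`; survivors pass a sliding-window robust
screen (30 beats, 90 % overlap → step 3, trailing window anchored to the
end) flagging values > 5 MADs from the window median.  A zero-MAD window
degenerates to a 1 ms absolute floor so quantised series are not
all-flagged.  Masked intervals always carry their removal reason; counts
are conserved.

## Beat quality: DTW and feature-matched DTW

SCG/PPG beats are 600 ms slices anchored at each fused R-peak.  Amplitude
screening flags beats whose peak-to-peak range deviates > 5 MADs from the
global median or from any covering 30-beat window median (step 1; a zero
MAD degenerates to a 1 % relative floor, keeping the rule invariant under
common rescaling).  Morphology screening compares each amplitude-clean
beat with its window template (pointwise mean of the non-overlapping
30-beat window's clean beats).

Distance normalisation is the load-bearing convention: beats are z-scored
and the cumulative warping cost is divided by `len(a) + len(b)`, giving a
dimensionless per-sample cost on which the fixed thresholds (0.3 SCG,
0.4 PPG) are meaningful across amplitude scales.  A Sakoe–Chiba band of
±25 % of the beat length bounds the warp; an unconstrained, unnormalised
mode is kept for the exact-oracle tests.

Plain DTW is indifferent to a rigid time shift of a waveform complex — the
warp absorbs it at no cost — which is the wrong behaviour for the SCG,
where a beat whose AO complex sits 150 ms from the template's is a
different beat, not a warped one.  The feature-matched variant (DTFM)
therefore adds two non-negative local-cost terms driven by salient extrema
(prominence ≥ 10 % of the beat range, dilated ±10 samples into feature
regions): pairing a feature sample with a non-feature sample costs a fixed
penalty (0.5), and pairing two feature samples costs
`λ·|i−j|/L` with λ = 15, so matched features displaced in time raise the
cost in proportion to the displacement.  Both terms vanish on the
diagonal, hence dtfm(x, x) = 0 and dtfm ≥ dtw for every pair.  λ and the
dilation were calibrated once on the synthetic AO-shift sweep so that a
150 ms displacement clears the 0.3 threshold while ±10 ms jitter stays
well under it; they are ordinary keyword arguments.

Surviving beats are ensemble-averaged (15-beat moving mean, step 1),
cutting uncorrelated noise by ≈ √15; the anchor time is the central
beat's.

## Fiducial extraction

**SCG.**  Because SCG morphology varies between people and over time, no
single extremum is trusted.  Candidate extrema inside physiological search
windows (AO: R + 20–180 ms; AC: R + 250–450 ms) are associated across
beats into tracks by temporal proximity (±15 ms, greedy nearest), tracks
covering < 50 % of beats are dropped, and the retained set is the largest
connected component of the "covaries" graph: two tracks covary when their
timing series correlate (Pearson r ≥ 0.5) or move in lockstep (difference
series std < 3 ms — the criterion that keeps constant and parallel tracks
whose correlation would be dominated by sample-grid jitter).  AO/AC are
per-beat medians over retained tracks.  With the synthetic packet shapes
(Gaussian-enveloped 20 Hz cosine), the candidate set is the central peak
and its flanking valleys, and the median sits on the packet centre.

**PPG.**  The pulse foot is the median of six classical onset estimators:
pulse argmax; last minimum before the peak; maximum first derivative and
maximum second derivative on the upstroke (ties broken toward the foot);
first crossing of 20 % of pulse height (sub-sample linear interpolation);
and the intersection of the upstroke tangent with the horizontal baseline
through the minimum.  The individual estimates are returned for
diagnostics.  Window-level PAT/PEP/amplitudes are medians over the
ensemble beats.

## Rest-period selection

The activity index is the per-epoch (10 s) variance of the magnitude of
the 0.5–10 Hz band-passed acceleration; filtering each axis before taking
the magnitude makes the index exactly invariant to the gravity offset.
The rest threshold is 3× the record's 10th-percentile index (the source
protocol gives no number; this adapts to the wearer's noise floor).
Posture comes from the angle between the mean acceleration and the torso
longitudinal axis: ≤ 30° upright, ≥ 60° supine, otherwise transitional;
high-activity epochs are `unstable` and never classified.  A chest sensor
cannot separate sitting from standing, so both share the upright class
and window matching is on classes.

For each dose event, candidate 5-min windows step on a 30-s grid inside
the ±90-min neighbourhood; a window qualifies if it and a 2-min guard band
before it stay under the rest threshold and hold one posture class.  The
accepted pair minimises |separation − 60 min| subject to equal posture
classes and a 45–90 min separation band; failures return a typed reason
(`posture_mismatch`, `no_rest_window`, `insufficient_recording`) rather
than silently vanishing.

## Statistics

Clinic: per-marker paired OFF/ON tests on subject means — Wilcoxon
signed-rank if Shapiro–Wilk (either state) or Levene rejects at α = 0.05,
else a paired t-test; paired Cohen's d = mean(Δ)/sd(Δ), Δ = ON − OFF.
OH vs no-OH comparisons of the deltas gate on normality only (independent
t vs Mann–Whitney U; pooled-SD d, sign OH − no-OH).  Dose correlations
gate Pearson vs Spearman on normality of either variable.  Home: linear
mixed models with a random intercept per participant (REML), testing the
state (ON − OFF) or group fixed effect with the large-sample normal
approximation; singular or non-converging fits fall back to OLS with an
explicit warning.  Benjamini–Hochberg runs within each analysis set
separately for the two marker families (HR/HRV: HR, RMSSD, SDNN, LF, HF,
LF/HF; cardiomechanical/vasomotor: PEP, LVETi, PEP/LVETi, SCGamp, PPGamp,
PAT, PTT); raw and adjusted p-values are both reported.  The BH step-up
is authored in-package (`min_{j≥i} p_(j)·m/j`, capped at 1) and verified
exactly against a brute-force oracle and against statsmodels.

## The synthetic generator

`gen_rr_series` builds RR(t) = 60000/HR + A_LF·sin(2π·0.10·t) +
A_HF·sin(2π·0.25·t) + N(0, σ²) and integrates it into beat times.  ECG
beats are a narrow biphasic QRS (6 ms Gaussian R wave, delayed negative
lobe); SCG beats are Gaussian-enveloped 20 Hz cosine packets (σ = 15 ms)
at R + PEP (AO) and R + PEP + LVET (AC, 0.6× amplitude); PPG pulses are a
unit-exponent gamma shape whose foot — a genuine slope discontinuity —
sits at R + PAT.  The accelerometer carries a posture-dependent gravity
vector (upright ≈ longitudinal axis, supine ≈ dorsoventral) plus optional
band-limited motion bursts, which also bleed into SCG/PPG as artifact
epochs.

`gen_dose_response` composes per-subject OFF/ON segments (≥ 5 min seated
rest each) with the study's effect structure: ON-state PEP rises by
8 ms per 100 mg (linear in dose — the source reports correlations, not a
functional form) plus a per-subject response spread of 4 ms; SCG/PPG
amplitudes scale by 0.85; and for OH subjects every RR-variability source
is multiplied by 0.7 in the ON state, so ground-truth RMSSD scales by
exactly that factor.  PAT shifts together with PEP (PTT held), reflecting
a cardiac rather than vascular ON effect.  Defaults (HR 70 ± 5 bpm
between subjects, LF 25 ms, HF 20 ms, RR jitter 8 ms, PEP 90 ± 10 ms,
LVET 300 ms, PAT 210 ms, 0.2 motion bursts/min, channel noise 2–5 % of
signal amplitude) are fixed realism choices: the source reports effect
sizes on its cohort, not magnitudes in physical units, so slopes and
ratios are free parameters, not calibrated claims.  All randomness flows
from one integer seed; identical configs reproduce byte-identical
records.

What the generator does **not** emulate: real ECG morphology (P/T waves),
arrhythmia, respiration-driven modulation, PPG wavelengths other than IR,
baseline wander, or sensor drift.  Passing tests therefore demonstrate
that the chain recovers what it is pointed at under controlled,
favourable morphology — not field performance on pathological waveforms.

## Verification strategy and problem sizes

Exact components are tested exactly: the DTW dynamic program against
literal enumeration of every warping path (100 seeded integer pairs,
lengths ≤ 10), BH against the brute-force step-up (1000 random vectors),
fusion against a brute-force matcher.  Estimators are tested against
generator ground truth: 20 seeded one-subject simulations at default
noise give window-level PEP MAE ≤ 10 ms, PAT within one native PPG sample
(≈ 15 ms), RMSSD within 10 %.  The statistical layer is calibrated with
marker-level replicates of the study structure (14 subjects, subject SD
15 ms, residual SD 5 ms; 60 seeded power runs, 100 null runs; mixed
models: 12 subjects × 3 pairs, 100 recovery and 300 null fits) — sizes
chosen to keep the default suite fast while the binomial error on each
rate stays well inside the asserted margins.  One full-waveform
14-subject study backs the chain end to end in `scripts/acceptance.py`.

## Known limitations

* The normal-approximation p-values of the mixed models are slightly
  liberal at very small n; measured type-I ≈ 4–6 % at 12 subjects.
* The AO/AC estimates are medians over covarying extrema tracks — on real
  SCG they track *changes* reliably but can carry a subject-specific
  offset from catheter-grade PEP/LVET; the synthetic packets are symmetric
  so no offset appears in tests.
* The six-estimator PPG foot median is robust but, on asymmetric real
  pulses, biased a few ms late relative to the intersecting-tangent foot.
* Manual NN-series review from the source protocol is replaced by the
  automated physiological + MAD cascade; there is no interactive step.
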