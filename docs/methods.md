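# Methods

This note documents the generative model behind the synthetic cohorts, the
signal-processing and statistical conventions of the analysis chain, the
calibration constants, and the limitations a user should keep in mind when
extrapolating from synthetic results to real data.

## Study design being modeled

A single-arm longitudinal neurofeedback study in chronic tinnitus: baseline
resting-state EEG and questionnaires (t1), 15 weekly 15-minute training
sessions, post-measurements one week (t2) and three months (t3) after
training, and a final online questionnaire at six months (t4).  Resting-state
EEG (64 active electrodes on the extended 10-10 layout, FCz reference, AFz
ground, 1000 Hz) is recorded twice per visit for 8 minutes with alternating
eyes-open/eyes-closed blocks: once without task instructions (NT) and once
with the instruction to attend to the tinnitus percept (WT).  Training uses a
separate 4-electrode montage (FC1, FC2, F3, F4; linked earlobes; 250 Hz); the
reward band is the individual alpha peak frequency (IAF) ±2 Hz, the inhibit
band is fixed at 3–4 Hz.  Behavioral outcomes are the THI sum score (0–100),
TQ sum score (0–84), and a 1–100 loudness rating.

## Synthetic EEG model

Each channel's target power spectral density is

```
P(f) = B / (f + 0.5)^chi                               (background)
     + h_delta * exp(-(f - 2.8)^2 / (2 * 0.8^2))       (delta bump)
     + g_ch * h_alpha * exp(-(f - IAF)^2 / (2 * 0.8^2)) (alpha bump)
```

in µV²/Hz, with `chi ~ TruncNormal(1.2, 0.15, [0.8, 1.6])`,
`IAF ~ TruncNormal(10, 1, [7.5, 12.5])`, and `g_ch` a mild posterior gradient
(up to +30 % alpha power at occipital sites; the training electrodes are
anchored at gain 1 so the calibration refers to them).  Eyes-closed blocks
multiply the alpha amplitude by `ec_alpha_gain ~ TruncNormal(1.6, 0.3,
[1.0, 2.5])` (the classic Berger effect).

Signals are synthesized by inverse FFT of the target amplitude spectrum with
uniform random phases, block by block along the EO/EC schedule, and joined
with 1 s square-root-Hann cross-fades (fade weights satisfy w1²+w2²=1, so
power is preserved and no clicks appear at block boundaries).  Channels are
not independent: two latent source sets (24 broadband background sources, 8
alpha sources) are mixed into the 64 channels through subject-stable random
mixing matrices with unit-norm rows.  Unit-norm rows keep every channel's PSD
exactly equal to the latent target PSD while making the background spatially
low-rank, as in real EEG — this is what gives a PCA-restricted ICA the room
to isolate injected artifact sources into their own components.

### Absolute calibration

Absolute dB levels are a calibration constant, not physiology.  Trained-band
levels are parameterized directly on the analysis scale
(`10*log10(PSD µV²/Hz)`), with the t1 inhibit-band (3–4 Hz) level at
51.87 ± 1.57 dB between subjects and the t1 alpha/delta ratio at 0.955 (NT) /
0.961 (WT).  Bump amplitudes are solved by bisection so the noise-free target
spectrum reproduces each subject's drawn band targets exactly on the 0.5 Hz
grid.  Two analytic corrections are folded into the solve targets:

* `LOG_MEAN_BIAS_DB = 10*gamma/ln(10) ≈ 2.51 dB` — the analysis averages dB
  across windows ("log then average"); for exponentially distributed
  periodogram bins `E[ln P_hat] = ln P − gamma`, so the estimator reads that
  constant below the true spectrum.
* `BAND_OFFSET_COMP_DB = 0.35 dB` (alpha only) — the analysis centers the
  reward band on the grid-rounded *estimated* IAF and therefore misses a
  little of the bump's tail mass on average relative to a band centered on
  the true peak.

With both constants the rewarded and inhibited band levels measured through
the full chain center on the configured targets (residual bias ≲ 0.1 dB).

### Longitudinal effects and variance structure

Band levels follow a random-intercept model: subject intercepts (between-SD
1.57 dB inhibit / 1.13 dB alpha), fixed timepoint-by-condition shifts, and
occasion residuals (within-SD 0.99 / 0.55 dB).  Default shifts encode a
training effect concentrated in the WT condition (alpha up ~0.2 dB and
trained delta down ~0.7 dB at t2, partially receding at t3), chosen so the
implied ratio trajectories match the reference levels 0.961 → 0.978 → 0.968
(WT) and 0.955 → 0.959 → 0.965 (NT).  Behavioral scores are baseline
(THI 29.33 ± 12.9, TQ 23.75 ± 10.5, loudness 53.25 ± 15.4 between subjects)
plus fixed timepoint shifts (THI −5.4/−4.5/−4.6; TQ −2.1/−2.2/−3.2; loudness
−9.6/−1.6/+2.2 at t2/t3/t4) plus within-subject residuals (SD 7 / 5 / 12).
The within/between split is reverse-engineered from the reference group SDs
together with the size of the printed contrast t statistics; it is what makes
a default cohort produce contrasts of realistic magnitude, not just realistic
marginals.  All scores are clipped to instrument ranges.

The correlation between the rewarded-band change (WT, t2−t1) and the TQ
change targets −0.4: the TQ t2 residual loads on each subject's standardized
ground-truth alpha change with weight `rho*sqrt(2)*sd_within`, which makes
the expected empirical correlation of the two difference scores equal rho.
Only |rho| ≤ 1/√2 is feasible with the coupling carried by one occasion
residual; larger targets raise an error.

### Artifacts

Injected on demand, with ground-truth annotations returned: gamma-shaped
blink pulses with a fixed frontal-gradient topography (Fp/AF full weight,
quadratic anterior-posterior decay); lateral eye movements as smooth
box-pulses with an antisymmetric left-right frontal topography; muscle bursts
(high-passed noise, 1 s, Hann-tapered) recurring on a small per-recording set
of preferentially temporal channels, as scalp EMG does; common 50 Hz line
noise; dead channels (flat) and step ("jump") channels.  Amplitudes are
expressed in multiples of the median channel SD so configurations are
independent of the absolute calibration.  Default rates (blinks 10/min, eye
movements 4/min, muscle bursts 4/min on 3 channels) are free parameters; they
are set so a default dataset yields roughly five removable ICA components,
matching the workload reported for comparable recordings.

## Preprocessing conventions

* Filters: zero-phase (forward-backward) Butterworth; slopes are specified
  per pass in dB/octave and mapped at 6 dB/octave per order (0.1 Hz
  high-pass: order 4; 80 Hz low-pass: order 8; 49.5–50.5 Hz band-stop:
  order 4).  The high-pass is applied with generous reflection padding
  (3 cutoff periods) because its impulse response rings for seconds.
* Bad channels: dead (variance < 10⁻³ µV²), outlying log-variance (robust
  z > 5, with the channel-MAD floored at 0.1 decades so homogeneous arrays do
  not over-flag), and jumps (a step in the 0.5 s-window median trace > 20×
  that channel's MAD of increments *and* > 3× the global amplitude scale, so
  blinks do not read as jumps).  More than ten flagged channels reject the
  dataset.
* ICA: extended Infomax, PCA-restricted to the numerical data rank, fixed
  seed, bad channels excluded.  Component classification is an automated
  surrogate for visual inspection: frontal-template correlation (blinks),
  high-frequency spectral excess (sustained muscle), heavy-tailed activations
  (excess kurtosis > 5 or a single 2 s window carrying > 10× the median
  window variance — transient bursts), 50 Hz dominance (line), and an
  ocular-topography rule (frontal loading share > 0.3 with slow-band
  dominance) for lateral eye movements whose antisymmetric field cancels in
  the frontal mean.  The first/last second is excluded from these statistics
  because zero-phase filter transients concentrate there.
* Interpolation: spherical splines on standard 10-05 positions (≤ 10
  channels).  Average reference reintroduces FCz as a zero channel before
  subtracting the channel mean (64 → 65 channels); the transform is
  idempotent.
* Span rejection: amplitude threshold (default ±100 µV; for synthetic data
  whose absolute scale is a calibration constant the orchestrator derives the
  threshold from the data as 8× the robust amplitude scale).  Segmentation
  assigns marker-delimited spans to EO/EC, excises rejected spans, and keeps
  pieces of at least one 2 s analysis window.  EO segments are the analysis
  default.

## Spectral conventions

2 s Hamming windows with 1 s overlap; per-window one-sided PSD in µV²/Hz;
dB first, averaged across windows second.  Band powers average dB over grid
bins with `low ≤ f ≤ high` inclusive (the 3–4 Hz inhibit band is exactly the
bins 3.0/3.5/4.0); adjacent standard bands do not share bins.  The
alpha/delta ratio is computed per channel and then averaged over channels.
The absolute dB offset matters for the ratio — adding a constant c maps it to
(A+c)/(D+c) — which is why the calibration above is part of the model.

IAF estimation ("averaging alpha peaks over 30 s"): per 2 s window, the
channel-mean dB spectrum is lightly smoothed (3-bin moving average) and
searched in 7–13 Hz for a strict interior local maximum rising ≥ 4 dB above
a linear dB-vs-log-f background trend fitted on bins ≥ 1.5 Hz away from the
candidate; window peaks within 1.5 Hz of their median are averaged and
rounded to the 0.5 Hz grid.  If more than half the windows yield no peak the
estimate falls back to a background-corrected center of gravity of the
average spectrum (tagged `gravity-fallback`).  On default synthetic subjects
(30 s eyes-closed, training montage) 97–99 % of estimates land within 0.5 Hz
of ground truth.  The reward band IAF±2 is not clipped toward the standard
alpha range; a reward band overlapping the inhibit band raises an error.
Whether IAF and spectra derive from EO or EC data is configurable; defaults
are EC for IAF (stronger peak) and EO for outcome spectra.

## Closed-loop simulation

Online band power uses the most recent 0.5 s chunk (0.25 s hop, Hamming
taper) on the 4-channel montage, with the same dB conventions as the offline
estimator (the two coincide exactly at matched window length).  The artifact
gate fires on peak-to-peak amplitude or on the hottest 45–55 Hz bin
(system-voltage rule).  Feedback maps band power relative to a baseline
(expanding average over the first 30 s, then frozen) through a bounded
logistic (2 dB slope): speed increases with reward power, autopilot accuracy
decreases with inhibit power; gated chunks freeze the outputs and carry no
power values.  The learner is deliberately minimal — a single multiplicative
alpha gain that drifts upward with received reward above the feedback
midpoint — because no learning model is claimed for the underlying protocol;
it exists to close the loop (mis-set reward bands demonstrably slow the
drift).  Session-level learning is not coupled to the cohort's longitudinal
effect sizes, which are configured in the generator; the simulator
illustrates the loop, the generator defines the study conditions.

## Statistical conventions

* Time effect: ML likelihood-ratio test of the timepoint factor in a
  random-intercept model, χ²(T−1).  Validated tables are balanced, so the
  profile ML is evaluated in closed form (between/within decomposition with
  the τ² ≥ 0 boundary handled by pooling); the result matches an iterative
  mixed-model fit to optimizer precision and cannot fail at the variance
  boundary.  The test suite cross-checks against statsmodels' MixedLM.
* Contrasts: t1 versus each later timepoint, estimated as mean(tk) −
  mean(t1) (so symptom decreases give negative t), with the within-subject
  residual SE and df = N_obs − N_subjects − (T−1) — 69 for 24×4, 46 for
  24×3.  One-tailed p in the a priori direction, Bonferroni-multiplied by
  the number of contrasts, capped at 1.  Effect size r = √(t²/(t²+df)).
  The t1-versus-mean-follow-up contrast uses weights (−1, +1/(T−1), …) and
  an uncorrected one-tailed p.
* Tukey: all pairwise timepoint comparisons, single-step adjustment via the
  studentized-range distribution (reduces to the plain paired test at T=2).
* Difference-score correlations: Pearson r on (t2−t1) pairs, one-tailed
  t-based p with df = n−2, no multiplicity correction; questionnaire
  correlation matrices instead use two-tailed p with Benjamini–Hochberg.
* Error bars: Cousineau subject-centering with the Morey factor √(T/(T−1)).
* Age control: median split (ties to the young group), time × group
  interaction model versus time-only, ML LRT with df = T.
* Under null cohorts the per-contrast uncorrected one-tailed rejection rate
  is 4–6 % at α = .05 (t-based, exact under normality); the ANOVA LRT runs
  marginally liberal (~5–7 % with 24 subjects), as expected of an asymptotic
  χ² reference at this sample size.

## Problem sizes

Defaults encode the study conditions (24 subjects; 8-minute 65-channel
1000 Hz recordings; 15 weekly 15-minute sessions).  The test suite and the
reproduction script exercise the identical code paths at reduced sizes —
96–120 s recordings at 250 Hz, shorter sessions, 400 null cohorts for the
type-I experiment and 500 cohorts for the correlation experiment — chosen so
estimation noise stays well below the tolerances being checked.  Each
reported quantity carries the problem size actually used.

## Limitations

* The generator is spectral-synthesis based, not a neural-mass model: it
  reproduces second-order structure (PSDs, EO/EC modulation, band-level
  longitudinal effects, spatial rank) but no nonlinear or cross-frequency
  dynamics, no 1/f knee variation, and no genuine tinnitus physiology.
  Passing tests demonstrate that the pipeline recovers what this model puts
  in — not that the clinical effects would replicate in patients.
* Pulse artifacts are not modeled as a separate class (folded into
  muscle/noise), and artifact rates/amplitudes are free parameters — the
  source protocol does not publish them.
* The commercial training loop's timing and power-to-game mapping are
  unpublished; only montage, bands, gating semantics, monotonicity and
  boundedness are modeled, with chunking (0.5 s / 0.25 s hop) exposed in
  configuration.
* The exact mixed-model estimator and df conventions of the original R
  analysis are not fully specified anywhere; the conventions above are fixed
  by the requirement to reproduce the printed df (69/46) and are normative
  for this package.
* EDF+ output quantizes to 16 bits over per-channel physical ranges; the
  BrainVision writer stores IEEE float32.  Round-trips are exact to
  quantization.
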