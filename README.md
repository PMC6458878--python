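# tinnifeed

Analysis pipeline for **individualized alpha/delta EEG neurofeedback** studies
in chronic tinnitus, with a fully synthetic data path so every stage can be
developed and tested without patient recordings.

Chronic tinnitus has been linked to a characteristic resting-state EEG
pattern — reduced alpha and elevated delta power over auditory/frontal
regions.  Alpha-up/delta-down neurofeedback protocols reward power in an
**individualized alpha band** (the subject's alpha peak frequency ±2 Hz,
estimated from ~30 s of resting EEG on the training montage FC1/FC2/F3/F4)
and inhibit the 3–4 Hz delta band.  The trained outcome is the
**alpha/delta ratio**

```
ratio = mean over channels of  P_dB(IAF−2 … IAF+2) / P_dB(3 … 4 Hz)
```

computed on log power (dB) from 2 s Hamming-windowed FFTs with 1 s overlap
(0.5 Hz resolution), with the division done per channel before averaging.
Longitudinal change over the study timepoints (baseline t1, post-training t2,
follow-ups t3/t4) is tested with random-intercept mixed models
(likelihood-ratio χ² for the time factor), a priori t1-vs-later contrasts
with one-tailed Bonferroni-corrected p values and the effect-size conversion
r = √(t²/(t²+df)), Tukey post hocs, and Pearson correlations between
behavioral (THI, TQ, loudness) and electrophysiological difference scores.

The package is aimed at methods researchers who want to prototype, stress-test
or power such analysis chains end to end.

## What is in the box

| module | role |
| --- | --- |
| `tinnifeed.synthgen` | synthetic cohorts: 1/f EEG with an individual alpha peak, EO/EC structure, two task conditions, training effects, artifacts, behavioral scores with a configurable alpha–TQ coupling |
| `tinnifeed.io` | EDF+ and BrainVision triplet read/write, tidy behavior CSVs |
| `tinnifeed.preprocess` | Butterworth band-pass/notch, bad-channel detection, restricted (extended) Infomax ICA with automated artifact-component classification, spherical-spline interpolation, average reference with FCz reintroduction, EO/EC segmentation |
| `tinnifeed.spectral` | log-power spectra on the 0.5 Hz grid, standard band table, IAF estimation, reward band, alpha/delta ratio |
| `tinnifeed.nfb_sim` | closed-loop training-session simulator: online band power, artifact gating, feedback mapping, a minimal reinforcement learner |
| `tinnifeed.stats` | mixed-model ANOVAs, contrasts, effect sizes, Tukey, difference-score correlations, Benjamini–Hochberg, Morey within-subject SEs, age median-split control |
| `tinnifeed.orchestrator` | end-to-end study runner with YAML config, results JSON, tables and figures |
| `tinnifeed.validation` | Monte-Carlo calibration experiments (IAF recovery, type-I error, correlation recovery) |

## Worked example

```python
from tinnifeed import channels, preprocess, spectral, synthgen
from tinnifeed.types import RawRecording
import numpy as np

cohort = synthgen.generate_cohort(
    n_subjects=24, seed=1,
    rec_spec=synthgen.RecordingSpec(duration_s=96, srate=250, eo_ec_block_s=24),
)
prof = cohort.profiles[0]
raw = cohort.recordings[(prof.subject_id, "t1", "WT")]

cfg = preprocess.PreprocessConfig(run_ica=False, reject_threshold_uv=None)
eo, ec = preprocess.preprocess_recording(raw, "WT", cfg)

tr = list(channels.TRAINING_ELECTRODES)
data = np.concatenate(ec.segments, axis=1)
idx = [ec.channel_names.index(c) for c in tr]
iaf = spectral.estimate_iaf(RawRecording(data[idx], ec.srate, tr, "average"))
ratio = spectral.alpha_delta_ratio(
    spectral.compute_psd(eo), spectral.reward_band(iaf), channels=tr
)
print(f"true IAF {prof.iaf_true:.2f} Hz, estimated {iaf.iaf:.1f} Hz ({iaf.method})")
print(f"t1 alpha/delta ratio over {tr}: {ratio:.3f}")
```

prints

```
true IAF 10.45 Hz, estimated 10.5 Hz (peak-mean)
t1 alpha/delta ratio over ['FC1', 'FC2', 'F3', 'F4']: 1.012
```

i.e. the individual alpha peak is recovered on the 0.5 Hz grid.  This
particular subject's baseline trained ratio happens to sit slightly above 1
(subjects vary around the calibrated cohort mean of ~0.96; a ratio near 1
means log alpha and log delta power are nearly equal).

The same flow is available from the shell:

```bash
tinnifeed synthgen --n 24 --seed 1 --out cohort/        # write recordings + behavior.csv
tinnifeed preprocess --in cohort/s01_t1_NT.vhdr --out clean/
tinnifeed spectral --in cohort/s01_t1_NT.vhdr --out spectra/
tinnifeed nfb-sim --seed 1 --sessions 15 --out sessions/
tinnifeed run --config study.yaml --out study_out/      # whole pipeline
```

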