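"""End-to-end study runner.

Ties the stages together: cohort generation, optional closed-loop training
simulation, preprocessing of every resting-state recording, spectral
quantification with individualized reward bands, and the full statistical
chain.  Results are written as a deterministic JSON bundle plus rendered
tables and figures.

The default configuration reproduces the study conditions (24 subjects,
8-minute 65-channel 1000 Hz recordings at t1-t3 in two conditions, 15 weekly
15-minute training sessions); tests and quick runs scale the recording and
session lengths down through the same configuration surface.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import channels as ch
from . import nfb_sim, preprocess, spectral, stats, synthgen
from .types import RawRecording, TIMEPOINTS_EEG, TRAINED_INHIBIT


class ConfigError(ValueError):
    pass


@dataclass
class StudyConfig:
    n_subjects: int = 24
    seed: int = 0
    recording: synthgen.RecordingSpec = field(default_factory=synthgen.RecordingSpec)
    artifacts: "synthgen.ArtifactConfig | None" = field(
        default_factory=synthgen.ArtifactConfig
    )
    preprocessing: preprocess.PreprocessConfig = field(
        default_factory=lambda: preprocess.PreprocessConfig(reject_threshold_uv=None)
    )
    population: synthgen.PopulationConfig = field(default_factory=synthgen.PopulationConfig)
    effects: synthgen.EffectConfig = field(default_factory=synthgen.EffectConfig)
    run_nfb_sessions: bool = True
    n_sessions: int = 15
    session_length_s: float = 900.0
    iaf_eye_state: str = "EC"  # eye state used to determine the reward band
    out_dir: "str | None" = None

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ConfigError("n_subjects must be at least 3 (paired correlations)")

    @classmethod
    def from_dict(cls, raw: dict) -> "StudyConfig":
        """Build from a (YAML-loaded) dict; unknown keys are rejected."""
        known = {f.name: f for f in dataclasses.fields(cls)}
        unknown = set(raw) - set(known)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        nested = {
            "recording": synthgen.RecordingSpec,
            "artifacts": synthgen.ArtifactConfig,
            "preprocessing": preprocess.PreprocessConfig,
            "population": synthgen.PopulationConfig,
            "effects": synthgen.EffectConfig,
        }
        for key, val in raw.items():
            if key in nested and isinstance(val, dict):
                sub_known = {f.name for f in dataclasses.fields(nested[key])}
                sub_unknown = set(val) - sub_known
                if sub_unknown:
                    raise ConfigError(f"unknown {key} keys: {sorted(sub_unknown)}")
                kwargs[key] = nested[key](**val)
            else:
                kwargs[key] = val
        return cls(**kwargs)


def _analysis_tables(cohort: synthgen.CohortDataset, config: StudyConfig) -> pd.DataFrame:
    """Preprocess + quantify every recording; returns the long EEG table.

    Outcomes: ratio/alpha (rewarded band)/delta (inhibit band) per condition
    over the training electrodes, plus the 65-electrode ratio and the
    standard-band powers used by the control comparisons.
    """
    rows = []
    training = list(ch.TRAINING_ELECTRODES)
    for profile in cohort.profiles:
        reward = None
        for tp in TIMEPOINTS_EEG:
            for cond in ("NT", "WT"):
                raw = cohort.recordings[(profile.subject_id, tp, cond)]
                if config.artifacts is not None:
                    raw, _ = synthgen.inject_artifacts(
                        raw, config.artifacts,
                        seed=synthgen._derive_seed(profile.seed, tp, cond, "artifacts"),
                    )
                eo, ec = preprocess.preprocess_recording(raw, cond, config.preprocessing)
                if reward is None:  # individualized band set once, at t1
                    src = ec if config.iaf_eye_state == "EC" else eo
                    data = np.concatenate(src.segments, axis=1)
                    idx = [src.channel_names.index(c) for c in training]
                    iaf_rec = RawRecording(
                        samples=data[idx], srate=src.srate, channel_names=training,
                        reference="average",
                    )
                    iaf_est = spectral.estimate_iaf(iaf_rec)
                    reward = spectral.reward_band(iaf_est)
                spec = spectral.compute_psd(eo)
                ratio4 = spectral.alpha_delta_ratio(spec, reward, channels=training)
                ratio65 = spectral.alpha_delta_ratio(spec, reward, channels=None)
                alpha_db = spectral.band_power(spec, reward, training)
                delta_db = spectral.band_power(spec, TRAINED_INHIBIT, training)
                base = {"subject": profile.subject_id, "timepoint": tp}
                for name, value in (
                    (f"ratio_{cond}", ratio4),
                    (f"ratio65_{cond}", ratio65),
                    (f"reward_{cond}", alpha_db),   # rewarded individual alpha band
                    (f"inhibit_{cond}", delta_db),  # trained 3-4 Hz delta band
                ):
                    rows.append({**base, "outcome": name, "value": value})
                for bname, band in spectral_standard_bands().items():
                    rows.append(
                        {**base, "outcome": f"{bname}_{cond}",
                         "value": spectral.band_power(spec, band, training)}
                    )
    return pd.DataFrame(rows)


def spectral_standard_bands() -> dict:
    from .types import STANDARD_BANDS

    return STANDARD_BANDS


_DIRECTIONS = {
    "thi": "decrease", "tq": "decrease", "loudness": "decrease",
    "ratio_NT": "increase", "ratio_WT": "increase",
    "ratio65_NT": "increase", "ratio65_WT": "increase",
    "reward_NT": "increase", "reward_WT": "increase",
    "inhibit_NT": "decrease", "inhibit_WT": "decrease",
}


def _stats_block(table: pd.DataFrame, outcome: str, direction: str) -> dict:
    anova = stats.fit_time_anova(table, outcome)
    contrasts = stats.apriori_contrasts(table, outcome, direction)
    tukey = stats.tukey_posthoc(table, outcome)
    wide = stats.pivot_outcome(table, outcome)
    return {
        "anova": {"chi_sq": anova.chi_sq, "df": anova.df, "p": anova.p},
        "contrasts": [dataclasses.asdict(c) for c in contrasts],
        "tukey": tukey.to_dict(orient="records"),
        "means": {tp: float(wide[tp].mean()) for tp in wide.columns},
        "sds": {tp: float(wide[tp].std(ddof=1)) for tp in wide.columns},
        "morey_se": {
            tp: float(v) for tp, v in stats.morey_within_se(table, outcome).items()
        },
    }


def run_study(config: "StudyConfig | None" = None) -> dict:
    """Run the full pipeline and return the results bundle.

    Fully reproducible for a fixed seed: two runs with the same config
    produce byte-identical JSON.
    """
    cfg = config or StudyConfig()
    results: dict = {"config": {"n_subjects": cfg.n_subjects, "seed": cfg.seed}}

    cohort = synthgen.generate_cohort(
        cfg.n_subjects, cfg.seed, cfg.population, cfg.effects, cfg.recording
    )

    if cfg.run_nfb_sessions:
        nfb_summary = {}
        for profile in cohort.profiles:
            spec = nfb_sim.ProtocolSpec(
                reward=spectral.reward_band(round(profile.iaf_true * 2) / 2),
                session_length_s=cfg.session_length_s,
                gate=nfb_sim.default_gate_for(profile),
            )
            learner = nfb_sim.LearnerState(alpha_gain=1.0, learning_rate=0.02, noise=0.0)
            logs, final = nfb_sim.simulate_training_course(
                profile, learner, spec, n_sessions=cfg.n_sessions,
                seed=synthgen._derive_seed(profile.seed, "nfb"),
            )
            nfb_summary[profile.subject_id] = {
                "final_alpha_gain": final.alpha_gain,
                "mean_gated_fraction": float(np.mean([l.gated_fraction for l in logs])),
            }
        results["nfb_sessions"] = nfb_summary

    eeg_table = _analysis_tables(cohort, config=cfg)
    behavior = cohort.behavior

    results["outcomes"] = {}
    for outcome in ("thi", "tq", "loudness"):
        results["outcomes"][outcome] = _stats_block(behavior, outcome, "decrease")
    for outcome in ("ratio_NT", "ratio_WT", "reward_NT", "reward_WT",
                    "inhibit_NT", "inhibit_WT", "ratio65_NT", "ratio65_WT"):
        results["outcomes"][outcome] = _stats_block(
            eeg_table, outcome, _DIRECTIONS[outcome]
        )
    results["outcomes"]["tq_mean_followup"] = dataclasses.asdict(
        stats.mean_followup_contrast(behavior, "tq")
    )

    # difference-score correlations (t2 - t1), one-tailed
    beh_wide = {o: stats.pivot_outcome(behavior, o) for o in ("thi", "tq", "loudness")}
    corr = {}
    for cond in ("NT", "WT"):
        for eeg_out in (f"ratio_{cond}", f"reward_{cond}", f"inhibit_{cond}"):
            eeg_wide = stats.pivot_outcome(eeg_table, eeg_out)
            d_eeg = eeg_wide["t2"] - eeg_wide["t1"]
            for beh_out, bw in beh_wide.items():
                d_beh = (bw["t2"] - bw["t1"]).loc[d_eeg.index]
                alt = "greater" if eeg_out.startswith("inhibit") else "less"
                r, p, df = stats.diff_corr(d_beh, d_eeg, alternative=alt)
                corr[f"{eeg_out}_vs_{beh_out}"] = {"r": r, "p_one_tailed": p, "df": df}
    results["diff_correlations"] = corr

    ages = {p.subject_id: p.age for p in cohort.profiles}
    results["age_control"] = {
        o: dataclasses.asdict(stats.age_median_split_control(
            behavior if o in ("thi", "tq", "loudness") else eeg_table, o, ages))
        for o in ("thi", "tq", "loudness", "ratio_NT", "ratio_WT")
    }

    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "results.json").write_text(dumps_stable(results))
        behavior.to_csv(out / "behavior.csv", index=False)
        eeg_table.to_csv(out / "eeg_outcomes.csv", index=False)
        make_report(results, out)
    return results


def dumps_stable(results: dict) -> str:
    """Deterministic JSON serialization (sorted keys, repr-stable floats)."""
    return json.dumps(results, sort_keys=True, indent=1, allow_nan=True)


def make_report(results: dict, out_dir: "str | Path") -> list[Path]:
    """Render summary tables and figures from a results bundle.

    Writes a contrast table CSV and per-outcome bar plots with Morey
    within-subject error bars.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []

    rows = []
    for outcome, block in results["outcomes"].items():
        if "anova" not in block:
            continue
        for c in block["contrasts"]:
            rows.append({
                "outcome": outcome, "contrast": c["label"], "t": c["t"],
                "df": c["df"], "p": c["p_one_tailed_bonf"], "r": c["r"],
                "anova_chi_sq": block["anova"]["chi_sq"],
                "anova_p": block["anova"]["p"],
            })
    table_path = out / "contrast_table.csv"
    pd.DataFrame(rows).to_csv(table_path, index=False)
    paths.append(table_path)

    for outcome, block in results["outcomes"].items():
        if "means" not in block:
            continue
        tps = list(block["means"])
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.bar(tps, [block["means"][t] for t in tps],
               yerr=[block["morey_se"][t] for t in tps], capsize=4, color="#6699cc")
        ax.set_title(outcome)
        ax.set_ylabel("score" if outcome in ("thi", "tq", "loudness") else "dB / ratio")
        fig.tight_layout()
        p = out / f"bars_{outcome}.png"
        fig.savefig(p, dpi=100)
        plt.close(fig)
        paths.append(p)
    return paths
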