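"""Closed-loop neurofeedback session simulator.

Models the training loop on the 4-electrode montage (FC1, FC2, F3, F4,
linked-earlobe reference, 250 Hz): online band-power estimation on short
Hamming-tapered chunks, reward (individual alpha) and inhibit (3-4 Hz delta)
feedback mappings onto game variables (ship speed, autopilot accuracy),
automatic artifact gating (movement amplitude and 45-55 Hz system voltage),
and a deliberately minimal one-parameter learner whose alpha amplitude drifts
with the time-averaged reward.

The numeric mapping from band power to game variables in commercial systems
is unpublished; only monotonicity and boundedness are modeled (a logistic map
around a rolling baseline estimated over the first 30 s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from . import channels as ch
from .synthgen import SubjectProfile, background_psd
from .types import Band

LINE_BAND = Band(45.0, 55.0, "system-voltage")


@dataclass
class GateConfig:
    """Artifact gate thresholds (absolute units of the incoming signal)."""

    ptp_uv: float = 200.0  # peak-to-peak movement/blink threshold
    line_db: float = 30.0  # 45-55 Hz band power threshold, dB


def default_gate_for(profile: "SubjectProfile") -> GateConfig:
    """Gate thresholds scaled to a synthetic subject's calibrated amplitudes.

    Peak-to-peak threshold at 10 sigma of the expected signal scale and the
    line threshold 15 dB above the background's 45-55 Hz level, so clean
    synthetic signal passes and injected artifacts trip the gate.
    """
    p = profile.spectral_params[("t1", "NT")]
    freqs = np.linspace(0.5, 124.5, 500)
    var = np.trapezoid(background_psd(freqs, p.background_B, p.chi), freqs)
    line_level = 10.0 * math.log10(background_psd(50.0, p.background_B, p.chi))
    return GateConfig(ptp_uv=10.0 * math.sqrt(var), line_db=line_level + 15.0)


@dataclass
class ProtocolSpec:
    """Training protocol: montage, bands, timing."""

    reward: Band
    inhibit: Band = Band(3.0, 4.0, "trained_inhibit")
    electrodes: tuple = ch.TRAINING_ELECTRODES
    reference: str = ch.TRAINING_REFERENCE
    srate: float = 250.0
    session_length_s: float = 900.0
    chunk_s: float = 0.5
    hop_s: float = 0.25
    baseline_s: float = 30.0
    gate: GateConfig = field(default_factory=GateConfig)

    def __post_init__(self) -> None:
        if self.reward.overlaps(self.inhibit):
            raise ValueError(
                f"reward band {self.reward.low}-{self.reward.high} Hz overlaps "
                f"the inhibit band {self.inhibit.low}-{self.inhibit.high} Hz"
            )
        if self.session_length_s <= 0:
            raise ValueError("session_length_s must be positive")


@dataclass
class LearnerState:
    """Minimal learner: a multiplicative alpha-amplitude gain that drifts."""

    alpha_gain: float = 1.0
    learning_rate: float = 0.0  # gain units per second at full reward
    noise: float = 0.0  # SD of multiplicative gain jitter per update

    def __post_init__(self) -> None:
        if self.alpha_gain <= 0:
            raise ValueError("alpha_gain must be positive")


@dataclass(frozen=True)
class FeedbackSample:
    time: float
    reward_power: float  # dB; NaN when gated
    inhibit_power: float
    speed: float  # [0, 1]
    autopilot_accuracy: float  # [0, 1]
    gated: bool


def online_band_power(buffer: np.ndarray, srate: float, band: Band,
                      chunk_s: float = 0.5) -> float:
    """Causal band power of the most recent chunk: Hamming FFT, dB, channel mean.

    Matches the offline estimator's conventions (dB of PSD, band bins averaged
    on the dB scale, then averaged over channels) on its shorter window.
    """
    n = int(round(chunk_s * srate))
    if buffer.ndim != 2:
        raise ValueError("buffer must be (channels, samples)")
    if buffer.shape[1] < n:
        raise ValueError(
            f"buffer of {buffer.shape[1] / srate:.2f} s shorter than the "
            f"{chunk_s} s analysis chunk"
        )
    chunk = buffer[:, -n:]
    win = sps.windows.hamming(n, sym=False)
    scale = 1.0 / (srate * (win**2).sum())
    spec = np.fft.rfft(chunk * win, axis=1)
    psd = 2.0 * scale * np.abs(spec) ** 2
    psd[:, 0] /= 2.0
    if n % 2 == 0:
        psd[:, -1] /= 2.0
    freqs = np.fft.rfftfreq(n, 1.0 / srate)
    mask = (freqs >= band.low - 1e-9) & (freqs <= band.high + 1e-9)
    if not mask.any():
        raise ValueError(f"band {band.low}-{band.high} Hz below chunk resolution")
    with np.errstate(divide="ignore"):
        db = 10.0 * np.log10(psd[:, mask])
    return float(db.mean())


def artifact_gate(buffer: np.ndarray, srate: float, gate: GateConfig,
                  chunk_s: float = 0.5) -> bool:
    """True when the chunk must be excluded from feedback.

    Fires on excessive peak-to-peak amplitude (movement, blinks) or on
    45-55 Hz system voltage: the hottest bin in that range is compared with
    the threshold, so a narrowband mains tone trips the gate even though it
    occupies a single frequency bin.
    """
    n = int(round(chunk_s * srate))
    chunk = buffer[:, -n:]
    ptp = float(np.ptp(chunk, axis=1).max())
    if ptp > gate.ptp_uv:
        return True
    win = sps.windows.hamming(n, sym=False)
    psd = 2.0 * np.abs(np.fft.rfft(chunk * win, axis=1)) ** 2 / (srate * (win**2).sum())
    freqs = np.fft.rfftfreq(n, 1.0 / srate)
    mask = (freqs >= LINE_BAND.low) & (freqs <= LINE_BAND.high)
    with np.errstate(divide="ignore"):
        peak_db = float(10.0 * np.log10(psd[:, mask] + 1e-30).max())
    return peak_db > gate.line_db


@dataclass
class LoopState:
    """Rolling baseline and frozen outputs of the feedback loop."""

    baseline_reward: float = np.nan
    baseline_inhibit: float = np.nan
    n_baseline: int = 0
    last_speed: float = 0.5
    last_autopilot: float = 0.5


_MAP_SCALE_DB = 2.0  # logistic slope of the power -> game-variable map


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def feedback_step(
    state: LoopState, buffer: np.ndarray, spec: ProtocolSpec, time_s: float
) -> FeedbackSample:
    """One feedback update: gate, estimate band powers, map to game variables.

    Speed is a bounded increasing map of reward power relative to the rolling
    baseline; autopilot accuracy a bounded decreasing map of inhibit power.
    Gated chunks freeze the outputs and carry no power values.  During the
    baseline period the outputs stay at the 0.5 midpoint while the baseline
    accumulates as an expanding average (an exponentially weighted average
    thereafter would not change within-session results; the baseline is
    frozen once the baseline period ends).
    """
    if artifact_gate(buffer, spec.srate, spec.gate, spec.chunk_s):
        return FeedbackSample(time_s, np.nan, np.nan, state.last_speed,
                              state.last_autopilot, True)
    rew = online_band_power(buffer, spec.srate, spec.reward, spec.chunk_s)
    inh = online_band_power(buffer, spec.srate, spec.inhibit, spec.chunk_s)
    if time_s < spec.baseline_s:
        k = state.n_baseline
        state.baseline_reward = rew if k == 0 else (state.baseline_reward * k + rew) / (k + 1)
        state.baseline_inhibit = inh if k == 0 else (state.baseline_inhibit * k + inh) / (k + 1)
        state.n_baseline = k + 1
        speed, autop = 0.5, 0.5
    else:
        speed = _logistic((rew - state.baseline_reward) / _MAP_SCALE_DB)
        autop = _logistic(-(inh - state.baseline_inhibit) / _MAP_SCALE_DB)
    state.last_speed, state.last_autopilot = speed, autop
    return FeedbackSample(time_s, rew, inh, speed, autop, False)


@dataclass
class SessionLog:
    samples: "list[FeedbackSample]"
    learner: LearnerState
    gated_fraction: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "time": s.time, "reward_power": s.reward_power,
                    "inhibit_power": s.inhibit_power, "speed": s.speed,
                    "autopilot_accuracy": s.autopilot_accuracy, "gated": s.gated,
                }
                for s in self.samples
            ]
        )


def _session_signal(
    profile: SubjectProfile, spec: ProtocolSpec, rng: np.random.Generator,
    n_samples: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Stationary background (incl. delta) and a unit-gain alpha oscillator.

    The alpha oscillator is an amplitude-modulated sinusoid at the subject's
    IAF (Rayleigh envelope from low-passed complex noise) whose variance
    matches the profile's t1 alpha bump; the learner's time-varying gain is
    applied outside, so feedback causality is preserved.
    """
    p = profile.spectral_params[("t1", "NT")]
    n_ch = len(spec.electrodes)
    freqs = np.fft.rfftfreq(n_samples, 1.0 / spec.srate)
    psd_bg = background_psd(freqs, p.background_B, p.chi) + p.delta_peak_psd * np.exp(
        -0.5 * ((freqs - p.delta_center) / p.delta_sigma) ** 2
    )
    amp = np.sqrt(psd_bg * spec.srate * n_samples / 2.0)
    phases = rng.uniform(0, 2 * np.pi, size=(n_ch, freqs.size))
    coef = amp[None, :] * np.exp(1j * phases)
    coef[:, 0] = 0.0
    background = np.fft.irfft(coef, n=n_samples, axis=1)

    # alpha: total power = integral of the Gaussian bump PSD
    bump_power = p.alpha_peak_psd * p.alpha_sigma * math.sqrt(2.0 * math.pi)
    sos = sps.butter(2, max(0.5, p.alpha_sigma), "lowpass", fs=spec.srate, output="sos")
    g = sps.sosfilt(sos, rng.standard_normal(n_samples) + 1j * rng.standard_normal(n_samples))
    g /= np.sqrt(np.mean(np.abs(g) ** 2))
    t = np.arange(n_samples) / spec.srate
    carrier = np.real(g * np.exp(2j * np.pi * p.iaf * t))
    alpha = math.sqrt(2.0 * bump_power) * carrier / np.sqrt(np.mean(carrier**2))
    return background, np.broadcast_to(alpha, (n_ch, n_samples))


def simulate_session(
    profile: SubjectProfile,
    learner: LearnerState,
    spec: ProtocolSpec,
    seed: int = 0,
) -> SessionLog:
    """Simulate one training session and return the feedback log.

    The learner's alpha gain drifts upward proportionally to the received
    reward above the feedback midpoint (a reinforcement abstraction: only
    rewarded episodes reinforce the alpha-generating state).  With
    learning_rate 0 the gain is unchanged; with a reward band far from the
    learner's alpha peak the reward is decoupled from the gain and the drift
    stays small.
    """
    rng = np.random.default_rng(seed)
    srate = spec.srate
    n_total = int(spec.session_length_s * srate)
    hop = int(spec.hop_s * srate)
    chunk = int(spec.chunk_s * srate)
    background, alpha = _session_signal(profile, spec, rng, n_total)

    state = LoopState()
    gain = learner.alpha_gain
    gains = np.empty(n_total)
    samples: list[FeedbackSample] = []
    n_gated = 0
    pos = 0
    while pos + chunk <= n_total:
        gains[pos : pos + chunk] = gain
        buf = background[:, pos : pos + chunk] + gain * alpha[:, pos : pos + chunk]
        t_now = (pos + chunk) / srate
        fb = feedback_step(state, buf, spec, t_now)
        samples.append(fb)
        if fb.gated:
            n_gated += 1
        elif t_now >= spec.baseline_s:
            gain += learner.learning_rate * max(fb.speed - 0.5, 0.0) * spec.hop_s
            if learner.noise > 0:
                gain *= math.exp(learner.noise * rng.standard_normal())
            gain = max(gain, 0.1)
        pos += hop
    if not samples:
        raise ValueError("session shorter than one analysis chunk")
    return SessionLog(
        samples=samples,
        learner=replace(learner, alpha_gain=gain),
        gated_fraction=n_gated / len(samples),
    )


def simulate_training_course(
    profile: SubjectProfile,
    learner: LearnerState,
    spec: ProtocolSpec,
    n_sessions: int = 15,
    seed: int = 0,
) -> "tuple[list[SessionLog], LearnerState]":
    """Run ``n_sessions`` weekly sessions, carrying the learner state over."""
    logs = []
    state = learner
    for s in range(n_sessions):
        log = simulate_session(profile, state, spec, seed=seed + 1000 * s)
        logs.append(log)
        state = log.learner
    return logs, state
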