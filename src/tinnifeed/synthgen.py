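"""Synthetic EEG / behavioral cohort generator.

Emulates the statistical structure a longitudinal alpha-up / delta-down
neurofeedback study assumes, so the whole analysis chain can be exercised
without patient data:

* resting-state EEG as colored noise (1/f^chi background) plus Gaussian
  spectral bumps for an individual alpha peak and an elevated low-frequency
  delta component, synthesized by inverse FFT of a target amplitude spectrum
  with random phases;
* eyes-open / eyes-closed block structure with a multiplicative EC alpha
  gain, two task conditions (NT: no task, WT: attend-to-tinnitus), and
  training-induced alpha/delta changes across timepoints t1-t3;
* injectable artifacts (blinks with a frontal topography, broadband muscle
  bursts, 50 Hz line noise, dead and jump channels) with ground-truth
  annotations;
* behavioral sum scores (THI, TQ, loudness) over t1-t4 with configurable
  marginal means/SDs and a configurable correlation between the change in the
  rewarded alpha band and the change in TQ.

Calibration
-----------
Absolute power is a calibration constant, not physiology: per-subject band
targets are expressed directly on the analysis dB scale so trained-band
values land near the ~52 dB range and alpha/delta log-ratios near 0.96-0.98.
Bump amplitudes are solved numerically so the noise-free target spectrum
reproduces the drawn band targets exactly on the 0.5 Hz analysis grid.  A
constant ``LOG_MEAN_BIAS_DB`` compensates the negative bias of the
log-then-average spectral estimator (E[ln P_hat] = ln P - gamma for
exponentially distributed periodogram bins), so estimated band powers center
on the configured targets.
"""

from __future__ import annotations

import math
from collections.abc import Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from . import channels as ch
from .types import (
    Band,
    CONDITIONS,
    EC_START,
    EO_START,
    Event,
    INSTRUMENT_RANGES,
    RawRecording,
    TIMEPOINTS_BEHAVIOR,
    TIMEPOINTS_EEG,
)

#: Euler-Mascheroni bias of mean-log power estimates, in dB (10*gamma/ln 10).
LOG_MEAN_BIAS_DB = 10.0 * np.euler_gamma / math.log(10.0)

#: The analysis centers the reward band on the grid-rounded *estimated* alpha
#: peak, so on average the band misses a little of the bump's tail mass
#: relative to a band centered on the true peak.  The alpha calibration
#: raises its solve target by this constant so rewarded-band levels measured
#: through the full analysis chain land on the configured targets.
BAND_OFFSET_COMP_DB = 0.35

_GRID = np.arange(0.0, 125.0 + 0.25, 0.5)  # reference 0.5 Hz grid for calibration


# --------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class TruncNormal:
    """Normal(mean, sd) truncated to [lo, hi]; sd = 0 degenerates to the mean."""

    mean: float
    sd: float
    lo: float = -np.inf
    hi: float = np.inf

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if not self.lo <= self.mean <= self.hi:
            raise ValueError("mean must lie inside [lo, hi]")

    def draw(self, rng: np.random.Generator, size: "int | None" = None) -> np.ndarray:
        if self.sd == 0:
            return np.full(size, self.mean) if size else float(self.mean)
        n = size or 1
        out = np.empty(n)
        filled = 0
        while filled < n:
            x = rng.normal(self.mean, self.sd, size=2 * (n - filled))
            x = x[(x >= self.lo) & (x <= self.hi)]
            take = min(x.size, n - filled)
            out[filled : filled + take] = x[:take]
            filled += take
        return out if size else float(out[0])


@dataclass
class PopulationConfig:
    """Population-level distributions of subject parameters.

    Defaults encode the study conditions: cohort demographics, trained-band
    dB levels, and the between/within variance split implied by the reported
    group SDs and contrast statistics.
    """

    age: TruncNormal = field(default_factory=lambda: TruncNormal(46.29, 12.22, 24, 71))
    iaf: TruncNormal = field(default_factory=lambda: TruncNormal(10.0, 1.0, 7.5, 12.5))
    background_exponent: TruncNormal = field(
        default_factory=lambda: TruncNormal(1.2, 0.15, 0.8, 1.6)
    )
    ec_alpha_gain: TruncNormal = field(
        default_factory=lambda: TruncNormal(1.6, 0.3, 1.0, 2.5)
    )
    #: inhibit (3-4 Hz) band level at t1, dB; between-subject SD.
    inhibit_db_mean: float = 51.87
    inhibit_db_between_sd: float = 1.57
    inhibit_db_within_sd: float = 0.99
    #: t1 alpha/delta ratio per condition; alpha-band between/within SD in dB.
    ratio_t1: dict = field(default_factory=lambda: {"NT": 0.955, "WT": 0.961})
    alpha_db_between_sd: float = 1.13
    alpha_db_within_sd: float = 0.55
    #: behavioral baselines (t1): mean and between-subject SD.
    behavior_baseline: dict = field(
        default_factory=lambda: {
            "thi": TruncNormal(29.33, 12.9, 0, 100),
            "tq": TruncNormal(23.75, 10.5, 0, 84),
            "loudness": TruncNormal(53.25, 15.4, 1, 100),
        }
    )
    #: Gaussian bump widths (Hz) of the oscillatory spectral components.
    alpha_bump_sigma: float = 0.8
    delta_bump_center: float = 2.8
    delta_bump_sigma: float = 0.8
    #: background level relative to the t1 inhibit-band target, dB.
    background_rel_db: float = -3.0
    #: extra alpha topography: posterior channels carry up to this gain more
    #: (training electrodes stay at 1.0 so calibration is anchored there).
    alpha_posterior_gain: float = 0.3


@dataclass
class EffectConfig:
    """Longitudinal effect structure (mean shifts relative to t1).

    ``alpha_shift_db`` / ``delta_shift_db`` map (timepoint, condition) to the
    mean trained-band power change in dB; ``behavior_effects`` maps outcome ->
    timepoint -> mean shift; ``noise_sds`` are within-subject residual SDs of
    the behavioral outcomes; ``tq_alpha_corr`` is the target Pearson
    correlation between the per-subject change (t2-t1) in the rewarded alpha
    band (WT) and the TQ change.
    """

    alpha_shift_db: dict = field(
        default_factory=lambda: {
            ("t2", "NT"): 0.25, ("t3", "NT"): 0.28,
            ("t2", "WT"): 0.22, ("t3", "WT"): 0.05,
        }
    )
    delta_shift_db: dict = field(
        default_factory=lambda: {
            ("t2", "NT"): 0.04, ("t3", "NT"): -0.25,
            ("t2", "WT"): -0.69, ("t3", "WT"): -0.32,
        }
    )
    behavior_effects: dict = field(
        default_factory=lambda: {
            "thi": {"t2": -5.41, "t3": -4.50, "t4": -4.58},
            "tq": {"t2": -2.13, "t3": -2.21, "t4": -3.17},
            "loudness": {"t2": -9.58, "t3": -1.58, "t4": 2.21},
        }
    )
    tq_alpha_corr: float = -0.4
    noise_sds: dict = field(
        default_factory=lambda: {"thi": 7.0, "tq": 5.0, "loudness": 12.0}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 <= self.tq_alpha_corr <= 1.0:
            raise ValueError("tq_alpha_corr must be in [-1, 1]")
        if any(s <= 0 for s in self.noise_sds.values()):
            raise ValueError("noise_sds must be positive")


@dataclass
class RecordingSpec:
    """Physical layout of a synthesized resting-state recording."""

    duration_s: float = 480.0
    srate: float = 1000.0
    channel_names: tuple = ch.RECORDED_64
    eo_ec_block_s: float = 30.0
    start_state: str = "EO"

    def __post_init__(self) -> None:
        if self.duration_s < 2 * self.eo_ec_block_s:
            raise ValueError("duration must cover at least one EO/EC cycle")


@dataclass
class ArtifactConfig:
    """Rates and amplitudes of injected artifacts.

    Amplitudes are expressed as multiples of the median channel standard
    deviation so the config is independent of the absolute power calibration.
    """

    blink_rate_per_min: float = 10.0
    blink_amp: float = 3.0
    eye_movement_rate_per_min: float = 4.0
    eye_movement_amp: float = 1.5
    muscle_rate_per_min: float = 4.0
    muscle_amp: float = 5.0
    muscle_dur_s: float = 1.0
    #: bursts recur on this many (preferentially temporal-row) channels per
    #: recording, as scalp EMG does; keeps the artifact subspace compact
    n_muscle_channels: int = 3
    line_noise_amp: float = 0.0
    n_dead_channels: int = 0
    n_jump_channels: int = 0
    jump_amp: float = 10.0

    def __post_init__(self) -> None:
        for name in ("blink_rate_per_min", "muscle_rate_per_min", "line_noise_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class ArtifactEvent:
    kind: str  # blink | muscle | line_noise | dead_channel | jump
    start: int  # samples (0 for channel-wide artifacts)
    stop: int
    channels: tuple


# --------------------------------------------------------------------------
# subject profiles


@dataclass
class SpectralParams:
    """Noise-free target-spectrum parameters for one (timepoint, condition)."""

    background_B: float  # PSD scale: P_bg(f) = B / (f + 0.5)^chi, µV²/Hz
    chi: float
    iaf: float
    alpha_peak_psd: float  # Gaussian bump peak, µV²/Hz (eyes-open)
    alpha_sigma: float
    delta_peak_psd: float
    delta_center: float
    delta_sigma: float
    ec_alpha_gain: float  # EO->EC alpha amplitude multiplier (>= 1)


@dataclass
class SubjectProfile:
    """Generative ground truth for one synthetic subject."""

    subject_id: str
    iaf_true: float
    alpha_amp: float  # sqrt peak PSD of the alpha bump at t1/NT (µV/sqrt(Hz))
    delta_amp: float
    background_exponent: float
    ec_alpha_gain: float
    responder_gain: dict  # timepoint -> alpha amplitude multiplier (NT)
    behavioral_baseline: dict  # outcome -> t1 score
    age: float
    #: (timepoint, condition) -> {"alpha_db", "delta_db"} EO band targets at
    #: the training electrodes (subject intercepts and residuals included).
    eeg_targets: dict = field(default_factory=dict)
    spectral_params: dict = field(default_factory=dict)  # (tp, cond) -> SpectralParams
    seed: int = 0

    def __post_init__(self) -> None:
        if not 7.5 <= self.iaf_true <= 12.5:
            raise ValueError("iaf_true must be in [7.5, 12.5]")
        if self.ec_alpha_gain < 1.0:
            raise ValueError("ec_alpha_gain must be >= 1")

    def delta_alpha_db(self, cond: str = "WT") -> float:
        """Ground-truth rewarded-band change t2 - t1 (dB)."""
        return (
            self.eeg_targets[("t2", cond)]["alpha_db"]
            - self.eeg_targets[("t1", cond)]["alpha_db"]
        )


def background_psd(f: np.ndarray, B: float, chi: float) -> np.ndarray:
    """1/f^chi background with a 0.5 Hz knee avoiding the DC divergence."""
    return B / np.power(np.asarray(f, dtype=float) + 0.5, chi)


def target_psd(f: np.ndarray, p: SpectralParams, eye_state: str = "EO") -> np.ndarray:
    """Noise-free target PSD (µV²/Hz) of the synthesis model."""
    f = np.asarray(f, dtype=float)
    alpha_peak = p.alpha_peak_psd * (p.ec_alpha_gain**2 if eye_state == "EC" else 1.0)
    return (
        background_psd(f, p.background_B, p.chi)
        + alpha_peak * np.exp(-0.5 * ((f - p.iaf) / p.alpha_sigma) ** 2)
        + p.delta_peak_psd * np.exp(-0.5 * ((f - p.delta_center) / p.delta_sigma) ** 2)
    )


def _grid_band_mask(band: Band) -> np.ndarray:
    return (_GRID >= band.low - 1e-9) & (_GRID <= band.high + 1e-9)


def _band_db_of_psd(psd_on_grid: np.ndarray, band: Band) -> float:
    mask = _grid_band_mask(band)
    return float(np.mean(10.0 * np.log10(psd_on_grid[mask])))


def _solve_bump_peak(
    base_psd: np.ndarray, shape: np.ndarray, band: Band, target_db: float
) -> float:
    """Peak PSD h >= 0 with band-mean dB of (base + h*shape) == target_db.

    Monotone in h, solved by bisection.  Returns 0 when the background alone
    already exceeds the target (the bump cannot subtract power).
    """
    mask = _grid_band_mask(band)
    base, shp = base_psd[mask], shape[mask]

    def f(h: float) -> float:
        return float(np.mean(10.0 * np.log10(base + h * shp))) - target_db

    if f(0.0) >= 0.0:
        return 0.0
    hi = 1.0
    while f(hi) < 0.0:
        hi *= 4.0
        if hi > 1e18:
            raise RuntimeError("bump calibration failed to bracket the target")
    lo = 0.0
    for _ in range(64):
        mid = 0.5 * (lo + hi)
        if f(mid) < 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _build_spectral_params(
    profile_draws: dict, targets: dict, pop: PopulationConfig
) -> dict:
    """Solve per-(timepoint, condition) bump amplitudes from band targets."""
    chi = profile_draws["chi"]
    iaf = profile_draws["iaf"]
    inhibit = Band(3.0, 4.0)
    reward = Band(iaf - 2.0, iaf + 2.0)
    # background anchored a fixed margin below the subject's t1 WT inhibit level
    bg_band_db = targets[("t1", "WT")]["delta_db"] + pop.background_rel_db
    mean_log = float(np.mean(np.log10(_GRID[_grid_band_mask(inhibit)] + 0.5)))
    B = 10.0 ** ((bg_band_db + LOG_MEAN_BIAS_DB) / 10.0 + chi * mean_log)
    bg = background_psd(_GRID, B, chi)
    delta_shape = np.exp(-0.5 * ((_GRID - pop.delta_bump_center) / pop.delta_bump_sigma) ** 2)
    alpha_shape = np.exp(-0.5 * ((_GRID - iaf) / pop.alpha_bump_sigma) ** 2)
    out = {}
    for key, tgt in targets.items():
        h_delta = _solve_bump_peak(bg, delta_shape, inhibit, tgt["delta_db"] + LOG_MEAN_BIAS_DB)
        h_alpha = _solve_bump_peak(
            bg + h_delta * delta_shape, alpha_shape, reward,
            tgt["alpha_db"] + LOG_MEAN_BIAS_DB + BAND_OFFSET_COMP_DB,
        )
        out[key] = SpectralParams(
            background_B=B,
            chi=chi,
            iaf=iaf,
            alpha_peak_psd=h_alpha,
            alpha_sigma=pop.alpha_bump_sigma,
            delta_peak_psd=h_delta,
            delta_center=pop.delta_bump_center,
            delta_sigma=pop.delta_bump_sigma,
            ec_alpha_gain=profile_draws["ec_gain"],
        )
    return out


def generate_subject_profile(
    seed: int,
    config: PopulationConfig = None,
    effects: EffectConfig = None,
    subject_id: str = "s01",
    solve_spectra: bool = True,
) -> SubjectProfile:
    """Draw one subject: demographics, spectral parameters, band targets.

    Reproducible given ``seed``.  Band targets for every (timepoint,
    condition) pair include the subject's random intercepts and
    occasion-level residuals, so the profile fully determines its noise-free
    EEG spectra.  ``solve_spectra=False`` skips the numerical bump-amplitude
    calibration (cheap profiles for behavior-only Monte-Carlo studies; such
    profiles cannot synthesize recordings).
    """
    pop = config or PopulationConfig()
    eff = effects or EffectConfig()
    rng = np.random.default_rng(seed)

    age = pop.age.draw(rng)
    iaf = pop.iaf.draw(rng)
    chi = pop.background_exponent.draw(rng)
    ec_gain = pop.ec_alpha_gain.draw(rng)

    # subject intercepts and occasion residuals of the trained-band levels
    v_delta = rng.normal(0.0, pop.inhibit_db_between_sd)
    u_alpha = rng.normal(0.0, pop.alpha_db_between_sd)
    targets = {}
    for cond in CONDITIONS:
        alpha_t1 = pop.ratio_t1[cond] * pop.inhibit_db_mean
        for tp in TIMEPOINTS_EEG:
            a_shift = eff.alpha_shift_db.get((tp, cond), 0.0)
            d_shift = eff.delta_shift_db.get((tp, cond), 0.0)
            targets[(tp, cond)] = {
                "alpha_db": alpha_t1 + u_alpha + a_shift
                + rng.normal(0.0, pop.alpha_db_within_sd),
                "delta_db": pop.inhibit_db_mean + v_delta + d_shift
                + rng.normal(0.0, pop.inhibit_db_within_sd),
            }

    baseline = {k: dist.draw(rng) for k, dist in pop.behavior_baseline.items()}
    if solve_spectra:
        spectral_params = _build_spectral_params(
            {"chi": chi, "iaf": iaf, "ec_gain": ec_gain}, targets, pop
        )
        ref = spectral_params[("t1", "NT")]
        responder_gain = {
            tp: math.sqrt(
                spectral_params[(tp, "NT")].alpha_peak_psd / ref.alpha_peak_psd
            )
            if ref.alpha_peak_psd > 0
            else 1.0
            for tp in TIMEPOINTS_EEG
        }
        alpha_amp = math.sqrt(ref.alpha_peak_psd)
        delta_amp = math.sqrt(ref.delta_peak_psd)
    else:
        spectral_params = {}
        responder_gain = {tp: 1.0 for tp in TIMEPOINTS_EEG}
        alpha_amp = delta_amp = float("nan")
    return SubjectProfile(
        subject_id=subject_id,
        iaf_true=float(iaf),
        alpha_amp=alpha_amp,
        delta_amp=delta_amp,
        background_exponent=float(chi),
        ec_alpha_gain=float(ec_gain),
        responder_gain=responder_gain,
        behavioral_baseline=baseline,
        age=float(age),
        eeg_targets=targets,
        spectral_params=spectral_params,
        seed=int(seed),
    )


# --------------------------------------------------------------------------
# signal synthesis


def _synthesize_block(
    psd: np.ndarray, freqs: np.ndarray, n_samples: int, srate: float,
    rng: np.random.Generator, n_channels: int,
    channel_gain: "np.ndarray | None" = None,
) -> np.ndarray:
    """Inverse-FFT synthesis: deterministic amplitudes, random phases.

    ``psd`` is the one-sided target PSD on the block's rfft frequencies; the
    per-bin amplitude |X_k| = sqrt(PSD * fs * N / 2) makes the block's
    one-sided periodogram reproduce the target exactly.  ``channel_gain``
    optionally scales the PSD per channel (n_channels, n_freqs).
    """
    amp = np.sqrt(psd * srate * n_samples / 2.0)
    amp = np.broadcast_to(amp, (n_channels, amp.size)).copy()
    if channel_gain is not None:
        amp *= np.sqrt(channel_gain)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=amp.shape)
    spec = amp * np.exp(1j * phases)
    spec[:, 0] = 0.0
    if n_samples % 2 == 0:
        spec[:, -1] = np.abs(spec[:, -1])  # Nyquist bin must be real
    return np.fft.irfft(spec, n=n_samples, axis=1)


#: latent source counts of the spatial model: the scalp background is a
#: low-rank mixture, as in real EEG where far fewer generators than
#: electrodes drive the recording (this leaves decomposition methods room to
#: isolate injected artifact sources)
N_BACKGROUND_SOURCES = 24
N_ALPHA_SOURCES = 8


def synthesize_recording(
    profile: SubjectProfile,
    timepoint: str,
    condition: str,
    spec: "RecordingSpec | None" = None,
    seed: "int | None" = None,
    alpha_posterior_gain: float = 0.3,
) -> RawRecording:
    """Synthesize one resting-state recording with EO/EC block structure.

    Channel signals are mixtures of low-rank latent source sets (background +
    delta, and a separate alpha set) through subject-stable random mixing
    matrices with unit-norm rows, so every channel carries exactly the
    calibrated target PSD while channels are spatially correlated.  The alpha
    set carries a mild posterior topographic gradient (training electrodes
    anchored at gain 1).  Eyes-closed blocks scale the alpha amplitude by
    ``profile.ec_alpha_gain``.
    """
    spec = spec or RecordingSpec()
    if (timepoint, condition) not in profile.spectral_params:
        raise KeyError(f"profile has no spectral parameters for {(timepoint, condition)}")
    params = profile.spectral_params[(timepoint, condition)]
    if seed is None:
        seed = _derive_seed(profile.seed, timepoint, condition)
    rng = np.random.default_rng(seed)

    names = tuple(spec.channel_names)
    n_ch = len(names)
    block_n = int(round(spec.eo_ec_block_s * spec.srate))
    total_n = int(round(spec.duration_s * spec.srate))
    freqs = np.fft.rfftfreq(block_n, d=1.0 / spec.srate)

    # posterior alpha gradient: 1 at the front, up to 1+gain at the back
    post = np.array([1.0 - ch.anterior_weight(n) for n in names if n in ch.ANALYSIS_65])
    if post.size == n_ch:
        alpha_gain_ch = 1.0 + alpha_posterior_gain * post
        anchor = np.mean([alpha_gain_ch[names.index(e)] for e in ch.TRAINING_ELECTRODES
                          if e in names]) if any(e in names for e in ch.TRAINING_ELECTRODES) else 1.0
        alpha_gain_ch = alpha_gain_ch / anchor
    else:
        alpha_gain_ch = np.ones(n_ch)

    # subject-stable spatial mixing: unit-norm rows keep every channel's PSD
    # equal to the latent target PSD
    mix_rng = np.random.default_rng(_derive_seed(profile.seed, "topography"))
    m_bg = mix_rng.standard_normal((n_ch, N_BACKGROUND_SOURCES))
    m_bg /= np.linalg.norm(m_bg, axis=1, keepdims=True)
    m_alpha = mix_rng.standard_normal((n_ch, N_ALPHA_SOURCES))
    m_alpha /= np.linalg.norm(m_alpha, axis=1, keepdims=True)

    # Blocks are synthesized with a 1 s margin and joined with square-root
    # Hann cross-fades: the fade weights satisfy w1² + w2² = 1, so summing two
    # independent realizations preserves the target PSD while avoiding step
    # discontinuities (clicks) at block boundaries.
    fade_n = min(int(round(1.0 * spec.srate)), block_n // 4)
    ramp = np.sin(0.5 * np.pi * np.linspace(0.0, 1.0, fade_n)) ** 2
    w_in, w_out = np.sqrt(ramp), np.sqrt(1.0 - ramp)

    out = np.zeros((n_ch, total_n))
    events = []
    state = spec.start_state
    pos = 0
    while pos < total_n:
        n = min(block_n, total_n - pos)
        events.append(Event(latency=pos, label=EO_START if state == "EO" else EC_START))
        alpha_peak = params.alpha_peak_psd * (
            params.ec_alpha_gain**2 if state == "EC" else 1.0
        )
        gen_n = n + (fade_n if pos > 0 else 0)
        f2 = np.fft.rfftfreq(gen_n, d=1.0 / spec.srate)
        psd_bg = background_psd(f2, params.background_B, params.chi) + (
            params.delta_peak_psd
            * np.exp(-0.5 * ((f2 - params.delta_center) / params.delta_sigma) ** 2)
        )
        psd_alpha = alpha_peak * np.exp(
            -0.5 * ((f2 - params.iaf) / params.alpha_sigma) ** 2
        )
        lat_bg = _synthesize_block(
            psd_bg, f2, gen_n, spec.srate, rng, N_BACKGROUND_SOURCES
        )
        lat_alpha = _synthesize_block(
            psd_alpha, f2, gen_n, spec.srate, rng, N_ALPHA_SOURCES
        )
        block = m_bg @ lat_bg + np.sqrt(alpha_gain_ch)[:, None] * (m_alpha @ lat_alpha)
        if pos > 0:
            lo = pos - fade_n
            out[:, lo:pos] = out[:, lo:pos] * w_out + block[:, :fade_n] * w_in
            out[:, pos : pos + n] = block[:, fade_n:]
        else:
            out[:, :n] = block
        pos += n
        state = "EC" if state == "EO" else "EO"

    return RawRecording(
        samples=out,
        srate=spec.srate,
        channel_names=list(names),
        reference=ch.RECORDING_REFERENCE,
        events=events,
    )


def _derive_seed(base: int, *parts: str) -> int:
    # zlib.crc32 is stable across processes (str hash is salted)
    import zlib

    h = np.random.SeedSequence(
        entropy=int(base) & 0x7FFFFFFF,
        spawn_key=tuple(zlib.crc32(p.encode()) for p in parts),
    )
    return int(h.generate_state(1)[0] & 0x7FFFFFFF)


# --------------------------------------------------------------------------
# artifacts


def inject_artifacts(
    raw: RawRecording, config: ArtifactConfig, seed: int = 0
) -> "tuple[RawRecording, list[ArtifactEvent]]":
    """Add blink / muscle / line-noise / dead / jump artifacts.

    Returns the contaminated recording and the ground-truth annotations.  All
    rates zero leaves the recording untouched.
    """
    rng = np.random.default_rng(seed)
    rec = raw.copy()
    x = rec.samples
    n_ch, n_samp = x.shape
    srate = rec.srate
    scale = float(np.median(np.std(x, axis=1)))
    ann: list[ArtifactEvent] = []

    # blinks: gamma-shaped pulses, frontal-dominant fixed topography
    n_blinks = rng.poisson(config.blink_rate_per_min * rec.duration / 60.0)
    if n_blinks:
        topo = np.array(ch.blink_topography(tuple(rec.channel_names)))
        tau = 0.08
        t = np.arange(0, int(0.5 * srate)) / srate
        pulse = (t / tau) ** 2 * np.exp(-t / tau)
        pulse /= pulse.max()
        for _ in range(n_blinks):
            start = int(rng.integers(0, max(1, n_samp - pulse.size)))
            amp = config.blink_amp * scale * rng.uniform(0.7, 1.3)
            x[:, start : start + pulse.size] += amp * topo[:, None] * pulse[None, :]
            ann.append(
                ArtifactEvent("blink", start, start + pulse.size, tuple(rec.channel_names))
            )

    # horizontal eye movements: smooth step potentials with an antisymmetric
    # left-right frontal topography (they cancel in the frontal mean, unlike
    # blinks)
    n_moves = rng.poisson(config.eye_movement_rate_per_min * rec.duration / 60.0)
    if n_moves:
        topo = np.array(ch.blink_topography(tuple(rec.channel_names)))
        side = np.array([
            1.0 if name[-1].isdigit() and int(name[-1]) % 2 == 1
            else (-1.0 if name[-1].isdigit() else 0.0)
            for name in rec.channel_names
        ])
        dur = int(0.6 * srate)
        t = np.linspace(-0.3, 0.3, dur)
        # smooth box: gaze deflects, holds, and returns to baseline
        pulse = 0.5 * (np.tanh((t + 0.15) / 0.03) - np.tanh((t - 0.15) / 0.03))
        for _ in range(n_moves):
            start = int(rng.integers(0, max(1, n_samp - dur)))
            amp = config.eye_movement_amp * scale * rng.uniform(0.7, 1.3)
            sgn = rng.choice([-1.0, 1.0])
            x[:, start : start + dur] += (
                sgn * amp * (topo * side)[:, None] * pulse[None, :]
            )
            ann.append(
                ArtifactEvent("eye_movement", start, start + dur,
                              tuple(rec.channel_names))
            )

    # muscle bursts: high-passed white noise recurring on a small set of
    # (preferentially temporal) channels
    n_bursts = rng.poisson(config.muscle_rate_per_min * rec.duration / 60.0)
    if n_bursts and config.n_muscle_channels > 0:
        temporal = [i for i, name in enumerate(rec.channel_names)
                    if name.startswith(("T", "FT", "TP"))]
        pool = temporal if len(temporal) >= config.n_muscle_channels else list(range(n_ch))
        muscle_chans = rng.choice(pool, size=min(config.n_muscle_channels, len(pool)),
                                  replace=False)
        sos = sps.butter(4, 20.0, btype="highpass", fs=srate, output="sos")
        for _ in range(n_bursts):
            dur = int(config.muscle_dur_s * srate)
            start = int(rng.integers(0, max(1, n_samp - dur)))
            chan = int(rng.choice(muscle_chans))
            burst = sps.sosfilt(sos, rng.standard_normal(dur))
            burst *= sps.windows.hann(dur)
            x[chan, start : start + dur] += config.muscle_amp * scale * burst
            ann.append(
                ArtifactEvent("muscle", start, start + dur, (rec.channel_names[chan],))
            )

    if config.line_noise_amp > 0:
        t = np.arange(n_samp) / srate
        phases = rng.uniform(0, 2 * np.pi, size=n_ch)
        x += config.line_noise_amp * scale * np.sin(
            2 * np.pi * 50.0 * t[None, :] + phases[:, None]
        )
        ann.append(ArtifactEvent("line_noise", 0, n_samp, tuple(rec.channel_names)))

    special = rng.choice(
        n_ch, size=min(n_ch, config.n_dead_channels + config.n_jump_channels),
        replace=False,
    )
    for i, chan in enumerate(special[: config.n_dead_channels]):
        x[chan] = 1e-6 * scale * rng.standard_normal(n_samp)
        ann.append(ArtifactEvent("dead_channel", 0, n_samp, (rec.channel_names[chan],)))
    for chan in special[config.n_dead_channels :]:
        at = int(rng.integers(n_samp // 4, 3 * n_samp // 4))
        x[chan, at:] += config.jump_amp * scale
        ann.append(ArtifactEvent("jump", at, n_samp, (rec.channel_names[chan],)))

    return rec, ann


# --------------------------------------------------------------------------
# behavior


def generate_behavior(
    profiles: "list[SubjectProfile]", effects: "EffectConfig | None" = None
) -> pd.DataFrame:
    """Long behavioral table (subject, timepoint, outcome, value).

    Scores are baseline + timepoint effect + residual; the t2 residual of TQ
    is coupled to each subject's ground-truth rewarded-band change (WT,
    t2-t1) through a shared standardized latent so that the empirical
    correlation between the two difference scores targets
    ``effects.tq_alpha_corr``.  Values are clipped to instrument ranges.
    """
    if not profiles:
        raise ValueError("profiles must be non-empty")
    eff = effects or EffectConfig()
    rho = eff.tq_alpha_corr
    # Var(dTQ) = 2*sd_w^2 and only the t2 residual is coupled, so the loading
    # is rho*sqrt(2)*sd_w; it must not exceed the residual SD.
    if abs(rho) * math.sqrt(2.0) > 1.0:
        raise ValueError(
            f"target correlation {rho} infeasible: |rho| must be <= 1/sqrt(2) "
            "when only the post-training residual carries the coupling"
        )
    rng = np.random.default_rng(eff.seed)
    n = len(profiles)

    d_alpha = np.array([p.delta_alpha_db("WT") for p in profiles])
    sd = float(d_alpha.std(ddof=0))
    z = (d_alpha - d_alpha.mean()) / sd if sd > 0 else np.zeros(n)

    rows = []
    for outcome in ("thi", "tq", "loudness"):
        lo, hi = INSTRUMENT_RANGES[outcome]
        sd_w = eff.noise_sds[outcome]
        shifts = eff.behavior_effects.get(outcome, {})
        for tp in TIMEPOINTS_BEHAVIOR:
            resid = rng.normal(0.0, sd_w, size=n)
            if outcome == "tq" and tp == "t2" and sd_w > 0:
                c = rho * math.sqrt(2.0) * sd_w
                resid = c * z + math.sqrt(max(sd_w**2 - c**2, 0.0)) * rng.standard_normal(n)
            for i, p in enumerate(profiles):
                val = p.behavioral_baseline[outcome] + shifts.get(tp, 0.0) + resid[i]
                rows.append(
                    {
                        "subject": p.subject_id,
                        "timepoint": tp,
                        "outcome": outcome,
                        "value": float(np.clip(val, lo, hi)),
                    }
                )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# cohorts


class LazyRecordings(Mapping):
    """Deterministic on-demand synthesis of the cohort's recordings.

    Keys are (subject_id, timepoint, condition).  Recordings are synthesized
    on access from the stored profiles -- bit-identical for identical seeds --
    so a full cohort never has to be held in memory.
    """

    def __init__(self, profiles: "list[SubjectProfile]", spec: RecordingSpec):
        self._profiles = {p.subject_id: p for p in profiles}
        self._spec = spec
        self._keys = [
            (p.subject_id, tp, cond)
            for p in profiles
            for tp in TIMEPOINTS_EEG
            for cond in CONDITIONS
        ]

    def __getitem__(self, key):
        sid, tp, cond = key
        return synthesize_recording(self._profiles[sid], tp, cond, self._spec)

    def __iter__(self):
        return iter(self._keys)

    def __len__(self):
        return len(self._keys)


@dataclass
class CohortDataset:
    """Profiles + lazily synthesized recordings + behavioral table."""

    profiles: "list[SubjectProfile]"
    recordings: LazyRecordings
    behavior: pd.DataFrame
    ground_truth: pd.DataFrame  # subject, timepoint, condition, alpha_db, delta_db, ratio


def generate_cohort(
    n_subjects: int = 24,
    seed: int = 0,
    population: "PopulationConfig | None" = None,
    effects: "EffectConfig | None" = None,
    rec_spec: "RecordingSpec | None" = None,
    solve_spectra: bool = True,
) -> CohortDataset:
    """Generate a full synthetic cohort (default n = 24, the study size)."""
    pop = population or PopulationConfig()
    eff = effects or EffectConfig()
    spec = rec_spec or RecordingSpec()
    ss = np.random.SeedSequence(seed)
    subject_seeds = ss.generate_state(n_subjects) & 0x7FFFFFFF
    profiles = [
        generate_subject_profile(
            int(subject_seeds[i]), pop, eff, subject_id=f"s{i + 1:02d}",
            solve_spectra=solve_spectra,
        )
        for i in range(n_subjects)
    ]
    eff_seeded = EffectConfig(
        alpha_shift_db=eff.alpha_shift_db,
        delta_shift_db=eff.delta_shift_db,
        behavior_effects=eff.behavior_effects,
        tq_alpha_corr=eff.tq_alpha_corr,
        noise_sds=eff.noise_sds,
        seed=int(ss.generate_state(n_subjects + 1)[-1] & 0x7FFFFFFF),
    )
    behavior = generate_behavior(profiles, eff_seeded)
    gt_rows = [
        {
            "subject": p.subject_id,
            "timepoint": tp,
            "condition": cond,
            "alpha_db": p.eeg_targets[(tp, cond)]["alpha_db"],
            "delta_db": p.eeg_targets[(tp, cond)]["delta_db"],
            "ratio": p.eeg_targets[(tp, cond)]["alpha_db"]
            / p.eeg_targets[(tp, cond)]["delta_db"],
            "iaf": p.iaf_true,
        }
        for p in profiles
        for tp in TIMEPOINTS_EEG
        for cond in CONDITIONS
    ]
    return CohortDataset(
        profiles=profiles,
        recordings=LazyRecordings(profiles, spec),
        behavior=behavior,
        ground_truth=pd.DataFrame(gt_rows),
    )
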