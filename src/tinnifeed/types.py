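"""Core domain containers shared across the pipeline.

Arrays are channels x time, potentials in microvolts (µV), sampling rates in
Hz, event latencies in samples.  Power spectra live on a fixed 0.5 Hz grid and
carry dB values (10*log10 of power spectral density in µV²/Hz).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

#: Eye-state marker labels used in resting-state recordings.
EO_START = "EO_start"
EC_START = "EC_start"

TIMEPOINTS_EEG = ("t1", "t2", "t3")
TIMEPOINTS_BEHAVIOR = ("t1", "t2", "t3", "t4")
CONDITIONS = ("NT", "WT")
OUTCOMES_BEHAVIOR = ("thi", "tq", "loudness")

#: Instrument score ranges: Tinnitus Handicap Inventory (sum score), Tinnitus
#: Questionnaire (sum score), and the 1-100 loudness rating.
INSTRUMENT_RANGES = {"thi": (0.0, 100.0), "tq": (0.0, 84.0), "loudness": (1.0, 100.0)}


@dataclass(frozen=True)
class Event:
    latency: int  # samples
    label: str


@dataclass
class RawRecording:
    """Multichannel EEG time series with recording metadata."""

    samples: np.ndarray  # (n_channels, n_samples), µV
    srate: float
    channel_names: list[str]
    reference: str = "FCz"
    events: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a (channels, time) array")
        if self.samples.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.samples.shape[0]} rows but {len(self.channel_names)} channel names"
            )
        lat = [e.latency for e in self.events]
        if lat != sorted(lat):
            raise ValueError("events must be sorted by latency")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.srate

    def copy(self) -> "RawRecording":
        return RawRecording(
            samples=self.samples.copy(),
            srate=self.srate,
            channel_names=list(self.channel_names),
            reference=self.reference,
            events=list(self.events),
        )

    def pick(self, names: Sequence[str]) -> "RawRecording":
        """Sub-recording restricted to ``names`` (order preserved)."""
        idx = [self.channel_names.index(n) for n in names]
        return RawRecording(
            samples=self.samples[idx].copy(),
            srate=self.srate,
            channel_names=list(names),
            reference=self.reference,
            events=list(self.events),
        )


@dataclass
class CleanSegments:
    """Artifact-cleaned, re-referenced data split by eye state."""

    condition: str  # "NT" | "WT"
    eye_state: str  # "EO" | "EC"
    segments: list[np.ndarray]  # each (n_channels, n_samples)
    srate: float
    channel_names: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n_ch = len(self.channel_names)
        for seg in self.segments:
            if seg.shape[0] != n_ch:
                raise ValueError("all segments must share the channel set")

    @property
    def total_duration(self) -> float:
        return sum(s.shape[1] for s in self.segments) / self.srate


@dataclass(frozen=True)
class Band:
    """Closed frequency interval [low, high] in Hz."""

    low: float
    high: float
    name: str = ""

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError(f"band low {self.low} > high {self.high}")

    @property
    def width(self) -> float:
        return self.high - self.low

    def overlaps(self, other: "Band") -> bool:
        return self.low <= other.high and other.low <= self.high


#: Standard frequency-band table (Hz).  Adjacent bands do not share 0.5 Hz
#: grid bins (delta ends at 4.0, theta starts at 4.5, ...).
STANDARD_BANDS: dict[str, Band] = {
    "delta": Band(0.5, 4.0, "delta"),
    "theta": Band(4.5, 8.0, "theta"),
    "lower_alpha": Band(8.5, 10.0, "lower_alpha"),
    "upper_alpha": Band(10.5, 12.0, "upper_alpha"),
    "alpha": Band(8.5, 12.0, "alpha"),
    "beta1": Band(12.5, 15.0, "beta1"),
    "beta2": Band(15.5, 23.0, "beta2"),
    "beta3": Band(23.5, 35.0, "beta3"),
    "gamma": Band(35.5, 45.0, "gamma"),
}

#: Fixed inhibit band of the neurofeedback protocol (trained delta).
TRAINED_INHIBIT = Band(3.0, 4.0, "trained_inhibit")


@dataclass(frozen=True)
class BandScheme:
    """Standard band table plus the individualized training bands."""

    trained_reward: Band
    trained_inhibit: Band = TRAINED_INHIBIT
    standard: dict[str, Band] = field(default_factory=lambda: dict(STANDARD_BANDS))

    def __post_init__(self) -> None:
        if abs(self.trained_reward.width - 4.0) > 1e-9:
            raise ValueError("trained reward band must be 4 Hz wide (IAF ± 2 Hz)")


@dataclass
class PowerSpectrum:
    """Per-channel average log-power on the 0.5 Hz analysis grid."""

    freqs: np.ndarray  # Hz, 0.5 Hz spacing
    power_db: np.ndarray  # (n_channels, n_freqs)
    channel_names: list[str]
    n_windows: int
    eye_state: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        df = np.diff(self.freqs)
        if df.size and not np.allclose(df, 0.5):
            raise ValueError("frequency grid spacing must be exactly 0.5 Hz")
        if self.n_windows < 1:
            raise ValueError("n_windows must be >= 1")


@dataclass
class IAFEstimate:
    """Individual alpha peak frequency on the 0.5 Hz grid."""

    iaf: float
    per_window_peaks: list[float]
    method: str  # "peak-mean" | "gravity-fallback"


__all__ = [
    "Band",
    "BandScheme",
    "CleanSegments",
    "CONDITIONS",
    "EC_START",
    "EO_START",
    "Event",
    "IAFEstimate",
    "INSTRUMENT_RANGES",
    "OUTCOMES_BEHAVIOR",
    "PowerSpectrum",
    "RawRecording",
    "STANDARD_BANDS",
    "TIMEPOINTS_BEHAVIOR",
    "TIMEPOINTS_EEG",
    "TRAINED_INHIBIT",
    "replace",
]
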