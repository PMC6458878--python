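"""Spectral quantification: windowed FFT power in dB, band powers on a 0.5 Hz
grid, individual alpha frequency (IAF), the individualized reward band, and
the trained alpha/delta ratio.

Conventions
-----------
* Analysis windows are 2 s Hamming windows with 1 s overlap, giving a fixed
  0.5 Hz frequency resolution at any sampling rate.
* Power spectral density is expressed in dB, ``10*log10(PSD µV²/Hz)``.  Each
  window is logarithmized first and the dB values are then averaged across
  windows ("log-then-average"), which differs from a plain Welch average and
  is preserved deliberately.
* Band powers average dB over all grid bins with ``low <= f <= high``
  (inclusive on both edges); the trained inhibit band 3-4 Hz therefore spans
  exactly the three bins 3.0, 3.5, 4.0.
* The alpha/delta ratio divides reward-band dB by inhibit-band dB *per
  channel* and then averages the per-channel ratios ("ratio-then-average").
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .types import Band, CleanSegments, IAFEstimate, PowerSpectrum, RawRecording

WINDOW_S = 2.0
OVERLAP_S = 1.0
GRID_DF = 0.5  # Hz, implied by the 2 s window
IAF_SEARCH = Band(7.0, 13.0, "iaf-search")


def _window_psd_db(data: np.ndarray, srate: float) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-window dB spectra of a (channels, time) array.

    Returns (freqs, dB array of shape (n_windows, n_channels, n_freqs),
    n_windows).  Raises if no complete 2 s window fits.
    """
    nperseg = int(round(WINDOW_S * srate))
    noverlap = int(round(OVERLAP_S * srate))
    if data.shape[1] < nperseg:
        raise ValueError(
            f"segment of {data.shape[1] / srate:.2f} s is shorter than one "
            f"{WINDOW_S:.0f} s analysis window"
        )
    freqs, _, sxx = sps.spectrogram(
        data,
        fs=srate,
        window="hamming",
        nperseg=nperseg,
        noverlap=noverlap,
        detrend=False,
        scaling="density",
        mode="psd",
    )
    # sxx: (n_channels, n_freqs, n_windows) -> (n_windows, n_channels, n_freqs)
    sxx = np.moveaxis(sxx, -1, 0)
    with np.errstate(divide="ignore"):
        db = 10.0 * np.log10(sxx)
    return freqs, db, sxx.shape[0]


def compute_psd(segments: CleanSegments) -> PowerSpectrum:
    """Average log-power spectrum of cleaned segments on the 0.5 Hz grid.

    Every 2 s Hamming window of every segment contributes one dB spectrum;
    the result is the plain mean of those dB spectra.
    """
    all_db = []
    freqs = None
    n_windows = 0
    for seg in segments.segments:
        if seg.shape[1] < WINDOW_S * segments.srate:
            continue
        f, db, nw = _window_psd_db(seg, segments.srate)
        freqs = f
        all_db.append(db)
        n_windows += nw
    if not all_db or n_windows == 0:
        raise ValueError("no complete 2 s analysis window in any segment")
    power_db = np.concatenate(all_db, axis=0).mean(axis=0)
    return PowerSpectrum(
        freqs=freqs,
        power_db=power_db,
        channel_names=list(segments.channel_names),
        n_windows=n_windows,
        eye_state=segments.eye_state,
        condition=segments.condition,
    )


def band_bins(freqs: np.ndarray, band: Band) -> np.ndarray:
    """Boolean mask of grid bins inside [band.low, band.high] (inclusive)."""
    return (freqs >= band.low - 1e-9) & (freqs <= band.high + 1e-9)


def band_power(
    spec: PowerSpectrum, band: Band, channels: "list[str] | None" = None
) -> float:
    """Mean dB over the band's grid bins, then over the requested channels."""
    mask = band_bins(spec.freqs, band)
    if not mask.any():
        raise ValueError(f"band {band.low}-{band.high} Hz contains no grid bin")
    per_channel = channel_band_power(spec, band, channels)
    return float(per_channel.mean())


def channel_band_power(
    spec: PowerSpectrum, band: Band, channels: "list[str] | None" = None
) -> np.ndarray:
    """Per-channel mean dB over the band's grid bins."""
    mask = band_bins(spec.freqs, band)
    if not mask.any():
        raise ValueError(f"band {band.low}-{band.high} Hz contains no grid bin")
    if channels is None:
        rows = np.arange(len(spec.channel_names))
    else:
        rows = np.array([spec.channel_names.index(c) for c in channels])
    return spec.power_db[rows][:, mask].mean(axis=1)


PEAK_MARGIN_DB = 4.0


def _local_max_freq(
    freqs: np.ndarray, db: np.ndarray, search: Band, margin_db: float = PEAK_MARGIN_DB
) -> "float | None":
    """Frequency of the most prominent local maximum of ``db`` in ``search``.

    A peak must (a) be a strict interior local maximum — a monotone 1/f
    spectrum has no alpha peak — and (b) rise at least ``margin_db`` above a
    linear dB-vs-log-frequency background trend fitted over the search range.
    The margin rejects the spurious local maxima single-window periodogram
    noise produces on a peakless background.  Returns None if no bin
    qualifies.
    """
    mask = band_bins(freqs, search)
    idx = np.flatnonzero(mask)
    logf = np.log10(freqs[idx])
    j_max = int(np.argmax(db[idx]))
    i_max = idx[j_max]
    if i_max == 0 or i_max == len(freqs) - 1:
        return None
    if not (db[i_max] > db[i_max - 1] and db[i_max] >= db[i_max + 1]):
        return None
    # background reference: fit the trend on bins away from the candidate
    # peak, so the bump does not raise its own reference level (an alpha
    # bump can span half the search range)
    away = np.abs(freqs[idx] - freqs[i_max]) > 1.5
    if away.sum() < 3:
        return None
    trend = np.polynomial.Polynomial.fit(logf[away], db[idx][away], deg=1)
    prominence = float(db[i_max] - trend(np.log10(freqs[i_max])))
    return float(freqs[i_max]) if prominence >= margin_db else None


def estimate_iaf(
    rec: RawRecording,
    search: Band = IAF_SEARCH,
    channels: "list[str] | None" = None,
) -> IAFEstimate:
    """Individual alpha peak frequency from >= 30 s of resting EEG.

    The channel-mean dB spectrum of each 2 s window is searched for its
    dominant local maximum inside ``search``; the IAF is the mean of the
    per-window peak frequencies, rounded to the 0.5 Hz grid.  Windows without
    an interior local maximum are dropped; if more than half the windows lack
    a peak the estimate falls back to the spectral center of gravity over the
    search range (``method="gravity-fallback"``).
    """
    data = rec.samples if channels is None else rec.pick(channels).samples
    if data.shape[1] < 30.0 * rec.srate:
        raise ValueError("IAF estimation requires at least 30 s of data")
    freqs, db, n_windows = _window_psd_db(data, rec.srate)
    mean_db = db.mean(axis=1)  # (n_windows, n_freqs): channel-mean spectrum
    # light 3-bin smoothing stabilizes the peak/no-peak decision on single
    # 2 s windows without displacing a (symmetric) alpha bump
    kernel = np.ones(3) / 3.0
    smooth = np.apply_along_axis(
        lambda v: np.convolve(np.pad(v, 1, mode="edge"), kernel, mode="valid"),
        1, mean_db,
    )
    peaks = []
    for w in range(n_windows):
        f = _local_max_freq(freqs, smooth[w], search)
        if f is not None:
            peaks.append(f)
    if len(peaks) > 0.5 * n_windows:
        # concordant-peak average: windows occasionally lock onto background
        # fluctuations far from the alpha peak; those outliers are dropped
        pk = np.asarray(peaks)
        pk = pk[np.abs(pk - np.median(pk)) <= 1.5]
        iaf = round(float(pk.mean()) / GRID_DF) * GRID_DF
        return IAFEstimate(iaf=float(iaf), per_window_peaks=peaks, method="peak-mean")
    # gravity fallback on the grand-average spectrum.  The center of gravity
    # is computed on the power *above* a robust 1/f trend so the steep
    # background does not drag the estimate toward the low edge; with no
    # excess power anywhere the plain power-weighted gravity is used.
    avg_db = mean_db.mean(axis=0)
    mask = band_bins(freqs, search)
    if not np.isfinite(avg_db[mask]).all():
        raise ValueError("no alpha peak found and center of gravity undefined")
    idx = np.flatnonzero(mask)
    logf = np.log10(freqs[idx])
    away = np.abs(freqs[idx] - freqs[idx[np.argmax(avg_db[idx])]]) > 1.5
    if away.sum() >= 3:
        trend = np.polynomial.Polynomial.fit(logf[away], avg_db[idx][away], deg=1)
    else:
        trend = np.polynomial.Polynomial.fit(logf, avg_db[idx], deg=1)
    resid = avg_db[idx] - trend(logf)
    excess = np.clip(10.0 ** (resid / 10.0) - 1.0, 0.0, None)
    if excess.sum() > 0:
        cog = float((freqs[idx] * excess).sum() / excess.sum())
    else:
        p = 10.0 ** (avg_db[mask] / 10.0)
        if p.sum() <= 0:
            raise ValueError("no alpha peak found and center of gravity undefined")
        cog = float((freqs[mask] * p).sum() / p.sum())
    iaf = round(cog / GRID_DF) * GRID_DF
    return IAFEstimate(iaf=float(iaf), per_window_peaks=peaks, method="gravity-fallback")


def reward_band(iaf: "IAFEstimate | float") -> Band:
    """Individualized reward band: IAF ± 2 Hz (always 4 Hz wide)."""
    f = iaf.iaf if isinstance(iaf, IAFEstimate) else float(iaf)
    return Band(f - 2.0, f + 2.0, "trained_reward")


def alpha_delta_ratio(
    spec: PowerSpectrum,
    reward: Band,
    inhibit: Band = Band(3.0, 4.0, "trained_inhibit"),
    channels: "list[str] | None" = None,
) -> float:
    """Trained alpha/delta ratio: per-channel reward-dB / inhibit-dB, averaged.

    The division happens on the dB scale channel by channel and the per-channel
    ratios are then averaged (ratio-then-average); with heterogeneous channels
    this differs from dividing the channel-averaged band powers.
    """
    if reward.overlaps(inhibit):
        raise ValueError(
            f"reward band {reward.low}-{reward.high} Hz overlaps the inhibit "
            f"band {inhibit.low}-{inhibit.high} Hz"
        )
    names = channels if channels is not None else list(spec.channel_names)
    num = channel_band_power(spec, reward, names)
    den = channel_band_power(spec, inhibit, names)
    bad = np.flatnonzero(den <= 0)
    if bad.size:
        raise ValueError(
            f"non-positive inhibit-band dB on channel {names[bad[0]]}; "
            "log-scale ratio undefined"
        )
    return float((num / den).mean())
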