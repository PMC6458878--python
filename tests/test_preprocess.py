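"""Preprocessing chain: filters, bad channels, ICA, interpolation,
re-referencing, segmentation."""

import numpy as np
import pytest
from scipy import signal as sps

from tinnifeed import channels as ch
from tinnifeed import preprocess as pp
from tinnifeed import synthgen as sg
from tinnifeed.types import Band, EC_START, EO_START, Event, RawRecording


def _tone(freq, srate=1000.0, dur=30.0, n_ch=2):
    t = np.arange(0, dur, 1 / srate)
    x = np.tile(np.sin(2 * np.pi * freq * t), (n_ch, 1))
    return RawRecording(x, srate, [f"C{i}" for i in range(n_ch)], "FCz")


def _single_pass_gain_db(sos, freq, srate):
    w, h = sps.sosfreqz(sos, worN=[freq], fs=srate)
    return 20 * np.log10(np.abs(h[0]))


class TestBandpass:
    def test_passband_tone_untouched(self):
        rec = _tone(10.0)
        out = pp.bandpass(rec)
        mid = slice(5000, 25000)  # avoid filter edge effects
        ratio = np.ptp(out.samples[0, mid]) / np.ptp(rec.samples[0, mid])
        assert ratio == pytest.approx(1.0, abs=0.01)

    def test_low_cutoff_gain_is_minus_3db_per_pass(self):
        sos = sps.butter(4, 0.1, "highpass", fs=1000.0, output="sos")
        g1 = _single_pass_gain_db(sos, 0.1, 1000.0)
        assert g1 == pytest.approx(-3.01, abs=0.05)
        # forward-backward application doubles the attenuation
        assert 2 * g1 == pytest.approx(-6.02, abs=0.1)

    def test_stopband_rolloff_one_octave_above_high_cutoff(self):
        sos = sps.butter(8, 80.0, "lowpass", fs=1000.0, output="sos")
        assert _single_pass_gain_db(sos, 160.0, 1000.0) <= -48.0

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            pp.bandpass(_tone(10.0, srate=100.0), high=80.0)

    def test_filters_are_linear(self):
        rng = np.random.default_rng(0)
        x = RawRecording(rng.normal(size=(2, 5000)), 250.0, ["a", "b"], "FCz")
        y = RawRecording(rng.normal(size=(2, 5000)), 250.0, ["a", "b"], "FCz")
        z = RawRecording(2.0 * x.samples + 3.0 * y.samples, 250.0, ["a", "b"], "FCz")
        lhs = pp.bandpass(z).samples
        rhs = 2.0 * pp.bandpass(x).samples + 3.0 * pp.bandpass(y).samples
        assert np.abs(lhs - rhs).max() / np.abs(lhs).max() < 1e-8


class TestBandreject:
    def test_50hz_tone_attenuated(self):
        rec = _tone(50.0)
        out = pp.bandreject(rec)
        mid = slice(5000, 25000)
        atten = 20 * np.log10(
            np.std(out.samples[0, mid]) / np.std(rec.samples[0, mid])
        )
        assert atten <= -20.0

    def test_10hz_tone_unity_gain(self):
        sos = sps.butter(4, [49.5, 50.5], "bandstop", fs=1000.0, output="sos")
        assert _single_pass_gain_db(sos, 10.0, 1000.0) == pytest.approx(0.0, abs=0.1)

    def test_notch_leaves_flanking_bins_untouched(self):
        rng = np.random.default_rng(3)
        rec = RawRecording(rng.normal(size=(1, 120_000)), 1000.0, ["c"], "FCz")
        out = pp.bandreject(rec)
        f, p_in = sps.welch(rec.samples[0], fs=1000.0, nperseg=2000)
        _, p_out = sps.welch(out.samples[0], fs=1000.0, nperseg=2000)
        db_change = 10 * np.log10(p_out / p_in)
        assert db_change[f == 50.0][0] < -10.0
        assert abs(db_change[f == 45.0][0]) < 1.0
        assert abs(db_change[f == 55.0][0]) < 1.0


class TestBadChannels:
    def test_clean_recording_has_no_bad_channels(self, recording):
        assert pp.detect_bad_channels(recording) == []

    def test_injected_dead_and_jump_channels_recovered(self, recording):
        cfg = sg.ArtifactConfig(blink_rate_per_min=0, muscle_rate_per_min=0,
                                n_dead_channels=3, n_jump_channels=2)
        dirty, ann = sg.inject_artifacts(recording, cfg, seed=11)
        truth = {a.channels[0] for a in ann if a.kind in ("dead_channel", "jump")}
        found = set(pp.detect_bad_channels(dirty))
        assert len(found & truth) >= 4
        assert not found - truth

    def test_more_than_ten_bad_channels_rejects_dataset(self, recording):
        cfg = sg.ArtifactConfig(blink_rate_per_min=0, muscle_rate_per_min=0,
                                n_dead_channels=11)
        dirty, _ = sg.inject_artifacts(recording, cfg, seed=5)
        with pytest.raises(pp.DatasetRejectionError):
            pp.detect_bad_channels(dirty)

    def test_short_recording_rejected(self):
        with pytest.raises(ValueError, match="60 s"):
            pp.detect_bad_channels(_tone(10.0, dur=10.0))


@pytest.fixture(scope="module")
def mixed_sources():
    rng = np.random.default_rng(0)
    n = 25_000
    s = np.vstack(
        [
            sps.sawtooth(2 * np.pi * 3 * np.arange(n) / 250.0),
            np.sign(np.sin(2 * np.pi * 0.7 * np.arange(n) / 250.0)),
            rng.laplace(size=n),
        ]
    )
    mix = rng.normal(size=(10, 3))
    x = mix @ s + 0.01 * rng.normal(size=(10, n))
    rec = RawRecording(x * 50, 250.0, [f"C{i}" for i in range(10)], "FCz")
    return rec, s


class TestICA:
    def test_sources_recovered(self, mixed_sources):
        rec, s = mixed_sources
        comps = pp.decompose_ica(rec, seed=0, n_components=3)
        acts = comps.activations(rec)
        hits = 0
        for src in s:
            corr = np.abs([np.corrcoef(a, src)[0, 1] for a in acts])
            hits += corr.max() > 0.95
        assert hits == 3

    def test_unmixing_then_mixing_is_identity(self, mixed_sources):
        rec, _ = mixed_sources
        comps = pp.decompose_ica(rec, seed=0)
        rebuilt = pp.remove_components(rec, comps, [])
        assert np.array_equal(rebuilt.samples, rec.samples)
        # explicit round trip through the maps at full rank
        proj = comps.mixing @ comps.unmixing
        data = rec.samples - rec.samples.mean(axis=1, keepdims=True)
        rel = np.abs(proj @ data - data).max() / np.abs(data).max()
        assert rel < 1e-6

    def test_determinism_across_runs(self, mixed_sources):
        rec, _ = mixed_sources
        a = pp.decompose_ica(rec, seed=3, n_components=3)
        b = pp.decompose_ica(rec, seed=3, n_components=3)
        assert np.array_equal(a.activations(rec), b.activations(rec))


@pytest.fixture(scope="module")
def blink_fixture(recording):
    cfg = sg.ArtifactConfig(blink_rate_per_min=12.0, muscle_rate_per_min=0,
                            eye_movement_rate_per_min=0)
    dirty, ann = sg.inject_artifacts(recording, cfg, seed=21)
    filt = pp.bandreject(pp.bandpass(dirty))
    comps = pp.decompose_ica(filt, seed=0)
    return recording, dirty, filt, comps, ann


class TestComponentClassification:
    def test_blink_component_flagged_and_removal_cleans_frontal_channels(
        self, blink_fixture
    ):
        clean_rec, dirty, filt, comps, ann = blink_fixture
        flagged = pp.classify_artifact_components(comps, filt)
        assert flagged, "no artifact component flagged on a blink fixture"
        removed = pp.remove_components(filt, comps, flagged)
        reference = pp.bandreject(pp.bandpass(clean_rec))  # same filters, no blinks
        fp = [filt.channel_names.index(c) for c in ("Fp1", "Fp2")]
        blink_energy_before = blink_energy_after = 0.0
        for a in ann:
            sl = slice(a.start, a.stop)
            blink_energy_before += float(
                ((filt.samples[fp, sl] - reference.samples[fp, sl]) ** 2).sum()
            )
            blink_energy_after += float(
                ((removed.samples[fp, sl] - reference.samples[fp, sl]) ** 2).sum()
            )
        assert blink_energy_after < 0.2 * blink_energy_before  # >= 80 % removed

    def test_energy_never_increases_when_removing_true_artifact(self, blink_fixture):
        _, _, filt, comps, _ = blink_fixture
        flagged = pp.classify_artifact_components(comps, filt)
        removed = pp.remove_components(filt, comps, flagged)
        e_before = (filt.samples**2).sum(axis=1)
        e_after = (removed.samples**2).sum(axis=1)
        assert (e_after <= e_before * 1.02).all()

    def test_artifact_free_recording_flags_nothing(self, filtered_recording):
        comps = pp.decompose_ica(filtered_recording, seed=0, n_components=20)
        assert pp.classify_artifact_components(comps, filtered_recording) == []

    def test_average_component_count_in_plausible_range(self, recording):
        """Default artifact mix yields a handful of removable components."""
        counts = []
        for seed in (31, 32):
            dirty, _ = sg.inject_artifacts(recording, sg.ArtifactConfig(), seed=seed)
            filt = pp.bandreject(pp.bandpass(dirty))
            comps = pp.decompose_ica(filt, seed=0)
            counts.append(len(pp.classify_artifact_components(comps, filt)))
        assert 3 <= np.mean(counts) <= 8


class TestInterpolation:
    def test_smooth_field_reconstructed(self):
        # smooth topographic pattern: potential = linear function of position
        pos = ch.positions_1005()
        names = list(ch.RECORDED_64)
        rng = np.random.default_rng(0)
        t = rng.normal(size=(1, 20_000))
        weights = np.array([pos[n][1] * 5 + pos[n][2] * 3 for n in names])
        x = weights[:, None] * t * 50.0
        rec = RawRecording(x, 250.0, names, "FCz")
        target = "CP1"
        truth = rec.samples[names.index(target)].copy()
        corrupted = rec.copy()
        corrupted.samples[names.index(target)] = 0.0
        fixed = pp.interpolate_channels(corrupted, [target])
        r = np.corrcoef(fixed.samples[names.index(target)], truth)[0, 1]
        assert r > 0.9
        untouched = [i for i, n in enumerate(names) if n != target]
        assert np.allclose(fixed.samples[untouched], corrupted.samples[untouched],
                           rtol=1e-9, atol=1e-6)

    def test_empty_list_is_identity(self, recording):
        out = pp.interpolate_channels(recording, [])
        assert np.array_equal(out.samples, recording.samples)

    def test_interpolated_variance_bounded_by_neighbors(self, recording):
        target = "Cz"
        fixed = pp.interpolate_channels(recording, [target])
        i = recording.channel_names.index(target)
        neighbor_vars = [
            recording.samples[recording.channel_names.index(n)].var()
            for n in ("C1", "C2", "FC1", "FC2", "CP1", "CP2")
        ]
        assert fixed.samples[i].var() <= 1.5 * max(neighbor_vars)

    def test_more_than_ten_channels_rejected(self, recording):
        with pytest.raises(pp.DatasetRejectionError):
            pp.interpolate_channels(recording, recording.channel_names[:11])

    def test_unknown_position_rejected(self):
        rec = _tone(10.0, n_ch=2)
        with pytest.raises(ValueError, match="position"):
            pp.interpolate_channels(rec, ["C0"])


class TestRereference:
    def test_channel_mean_is_zero_and_count_is_65(self, recording):
        out = pp.rereference_average(recording)
        assert out.n_channels == recording.n_channels + 1 == 65
        assert ch.RECORDING_REFERENCE in out.channel_names
        assert np.abs(out.samples.mean(axis=0)).max() < 1e-10

    def test_idempotent(self, recording):
        once = pp.rereference_average(recording)
        twice = pp.rereference_average(once)
        assert np.allclose(once.samples, twice.samples, atol=1e-12)


class TestSegmentation:
    def test_alternating_blocks_sum_to_half_duration(self):
        srate = 250.0
        n = int(480 * srate)
        events = [
            Event(int(k * 30 * srate), EO_START if k % 2 == 0 else EC_START)
            for k in range(16)
        ]
        rec = RawRecording(np.zeros((2, n)), srate, ["a", "b"], "FCz", events)
        eo, ec = pp.segment_eo_ec(rec)
        assert eo.total_duration == pytest.approx(240.0)
        assert ec.total_duration == pytest.approx(240.0)

    def test_no_markers_is_an_error(self):
        rec = RawRecording(np.zeros((1, 1000)), 250.0, ["a"], "FCz")
        with pytest.raises(ValueError, match="marker"):
            pp.segment_eo_ec(rec)

    def test_bad_spans_are_excised_and_counted(self):
        srate = 250.0
        rec = RawRecording(
            np.zeros((1, int(60 * srate))), srate, ["a"], "FCz",
            [Event(0, EO_START)],
        )
        eo, _ = pp.segment_eo_ec(rec, bad_spans=[(1000, 2000)])
        assert eo.provenance["rejected_spans"] == 1
        assert eo.total_duration < 60.0
        total = sum(s.shape[1] for s in eo.segments)
        assert total == int(60 * srate) - 1000

    def test_full_chain_reduces_artifact_power_not_posterior_alpha(
        self, profile, recording
    ):
        cfg = sg.ArtifactConfig(blink_rate_per_min=10.0, muscle_rate_per_min=0,
                                line_noise_amp=0.5)
        dirty, _ = sg.inject_artifacts(recording, cfg, seed=41)
        from tinnifeed import spectral as sp

        cleaned_eo, _ = pp.preprocess_recording(
            dirty, "NT", pp.PreprocessConfig(reject_threshold_uv=None, seed=0)
        )
        skipped = pp.rereference_average(dirty)
        skipped_eo, _ = pp.segment_eo_ec(skipped)
        spec_clean = sp.compute_psd(cleaned_eo)
        spec_skip = sp.compute_psd(skipped_eo)
        frontal = ["Fp1", "Fp2", "AF7", "AF8"]
        blink_band = Band(0.5, 2.0)
        assert sp.band_power(spec_clean, blink_band, frontal) < sp.band_power(
            spec_skip, blink_band, frontal
        )
        assert sp.band_power(spec_clean, Band(50, 50)) < sp.band_power(
            spec_skip, Band(50, 50)
        )
        posterior = ["O1", "O2", "Oz", "POz"]
        alpha = Band(profile.iaf_true - 2, profile.iaf_true + 2)
        assert (
            sp.band_power(spec_clean, alpha, posterior)
            <= sp.band_power(spec_skip, alpha, posterior) + 1.0
        )
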