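import numpy as np
import pytest

from tinnifeed import channels as ch
from tinnifeed import preprocess as pp
from tinnifeed import synthgen as sg
from tinnifeed.types import CleanSegments


@pytest.fixture(scope="session")
def profile():
    """One fully calibrated synthetic subject."""
    return sg.generate_subject_profile(42, subject_id="s42")


@pytest.fixture(scope="session")
def short_spec():
    """2-minute 64-channel recording at 250 Hz with 30 s EO/EC blocks."""
    return sg.RecordingSpec(duration_s=120.0, srate=250.0, eo_ec_block_s=30.0)


@pytest.fixture(scope="session")
def recording(profile, short_spec):
    return sg.synthesize_recording(profile, "t1", "NT", short_spec)


@pytest.fixture(scope="session")
def filtered_recording(recording):
    return pp.bandreject(pp.bandpass(recording))


@pytest.fixture(scope="session")
def dirty_recording(recording):
    """Recording with blinks, muscle bursts, dead and jump channels."""
    cfg = sg.ArtifactConfig(
        blink_rate_per_min=10.0, muscle_rate_per_min=2.0,
        n_dead_channels=3, n_jump_channels=2,
    )
    return sg.inject_artifacts(recording, cfg, seed=1)


def eo_segments(rec, condition="NT"):
    """EO-state CleanSegments straight from marker arithmetic (no cleaning)."""
    from tinnifeed.types import EO_START

    spans = []
    bounds = [(e.latency, e.label) for e in rec.events] + [(rec.n_samples, None)]
    for (start, label), (stop, _) in zip(bounds[:-1], bounds[1:]):
        if label == EO_START:
            spans.append(rec.samples[:, start:stop])
    return CleanSegments(condition, "EO", spans, rec.srate, list(rec.channel_names))


@pytest.fixture(scope="session")
def training_names():
    return list(ch.TRAINING_ELECTRODES)
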