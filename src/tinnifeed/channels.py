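"""Electrode layout of the 64-channel cap on the extended 10-10 (5/10) scheme.

The resting-state montage records 64 active electrodes referenced against FCz
with the ground at AFz; FCz is reintroduced at re-referencing, giving the 65
analysis channels.  Neurofeedback training uses a separate 4-electrode montage
(FC1, FC2, F3, F4) referenced to linked earlobes.
"""

from __future__ import annotations

import functools

#: The 64 recorded scalp electrodes (FCz is the implicit reference, AFz the
#: ground; neither carries a signal during recording).
RECORDED_64: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8",
    "PO9", "O1", "Oz", "O2", "PO10",
    "AF7", "AF3", "AF4", "AF8",
    "F5", "F1", "F2", "F6",
    "FT9", "FT7", "FC3", "FC4", "FT8", "FT10",
    "C5", "C1", "C2", "C6",
    "TP7", "CP3", "CPz", "CP4", "TP8",
    "P5", "P1", "P2", "P6",
    "PO7", "PO3", "POz", "PO4", "PO8",
)

RECORDING_REFERENCE = "FCz"
GROUND = "AFz"

#: Full 65-channel analysis set after FCz reintroduction.
ANALYSIS_65: tuple[str, ...] = RECORDED_64 + (RECORDING_REFERENCE,)

#: Neurofeedback training montage.
TRAINING_ELECTRODES: tuple[str, ...] = ("FC1", "FC2", "F3", "F4")
TRAINING_REFERENCE = "linked earlobes"

#: Frontal rows dominating the blink topography.
FRONTAL_ROWS: tuple[str, ...] = ("Fp", "AF")


@functools.lru_cache(maxsize=1)
def positions_1005() -> dict[str, "object"]:
    """3D electrode positions from the standard 10-05 montage (via MNE)."""
    import mne

    montage = mne.channels.make_standard_montage("colin27_1005")
    return montage.get_positions()["ch_pos"]


def anterior_weight(name: str) -> float:
    """Anterior-posterior weight in [0, 1] (1 = most frontal).

    Derived from the y coordinate of the standard montage; used for the
    deterministic blink topography template.
    """
    pos = positions_1005()
    if name not in pos:
        raise KeyError(f"unknown electrode position: {name}")
    y = pos[name][1]
    ys = [p[1] for n, p in pos.items() if n in ANALYSIS_65]
    lo, hi = min(ys), max(ys)
    return float((y - lo) / (hi - lo))


def blink_topography(names: tuple[str, ...]) -> "list[float]":
    """Fixed frontal-gradient blink template over ``names``.

    Fp/AF electrodes carry full weight; the weight decays quadratically with
    anterior-posterior position so posterior sites see almost nothing.
    """
    weights = []
    for n in names:
        if any(n.startswith(r) for r in FRONTAL_ROWS):
            weights.append(1.0)
        else:
            weights.append(0.6 * anterior_weight(n) ** 2)
    return weights
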