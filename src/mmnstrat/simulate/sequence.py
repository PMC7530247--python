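"""Oddball stimulus sequence generation.

Deviants are allocated by exact count (a shuffle of a fixed label
multiset), not per-trial coin flips, so a 1,200-trial 85/15 sequence
always contains exactly 1,020 standards and 180 deviants.  Onsets are
spaced by the preceding tone's duration plus the inter-stimulus
interval.  An optional constraint enforces a minimum number of standards
between successive deviants; the default is an unconstrained shuffle.
"""

from __future__ import annotations

import numpy as np

from ..preprocess import Event, ms_to_samples
from .specs import ParadigmSpec


def generate_stimulus_sequence(
    paradigm: ParadigmSpec,
    seed: int,
    start_offset_ms: float = 1000.0,
    min_standards_between_deviants: int = 0,
) -> list[Event]:
    """Randomized S1/S2 event sequence with exact-count deviant allocation.

    ``start_offset_ms`` shifts the first onset so pre-stimulus windows fit
    a continuous recording.  Reproducible for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    n_dev = paradigm.n_deviants  # raises for non-integral allocation
    labels = np.array(["S1"] * paradigm.n_standards + ["S2"] * n_dev)
    for _ in range(10_000):
        perm = rng.permutation(len(labels))
        seq = labels[perm]
        if min_standards_between_deviants <= 0 or _spacing_ok(
                seq, min_standards_between_deviants):
            break
    else:
        raise RuntimeError("could not satisfy deviant spacing constraint")

    events, onset = [], float(start_offset_ms)
    for lab in seq:
        events.append(Event(label=str(lab),
                            onset_sample=ms_to_samples(onset, paradigm.fs_hz)))
        tone = paradigm.std_tone_ms if lab == "S1" else paradigm.dev_tone_ms
        onset += tone + paradigm.isi_ms
    return events


def _spacing_ok(seq: np.ndarray, min_gap: int) -> bool:
    dev_pos = np.flatnonzero(seq == "S2")
    return len(dev_pos) < 2 or (np.diff(dev_pos) > min_gap).all()
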