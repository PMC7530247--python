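"""Canonical channel montage for the 64-channel oddball recordings.

The scalp montage follows the BioSemi 64-channel cap in its 10-10
equivalent labelling, plus two mastoid electrodes used for off-line
re-referencing and two ocular channels (vertical / horizontal EOG).
Mismatch-negativity feature extraction uses the 24 frontocentral sites
where the component is maximal; their order here fixes the column layout
of every feature matrix in the package.
"""

from __future__ import annotations

# BioSemi 64-channel cap, 10-10 equivalent labels (A1..B32 relabelled).
SCALP_64: tuple[str, ...] = (
    "Fp1", "AF7", "AF3", "F1", "F3", "F5", "F7", "FT7",
    "FC5", "FC3", "FC1", "C1", "C3", "C5", "T7", "TP7",
    "CP5", "CP3", "CP1", "P1", "P3", "P5", "P7", "P9",
    "PO7", "PO3", "O1", "Iz", "Oz", "POz", "Pz", "CPz",
    "Fpz", "Fp2", "AF8", "AF4", "AFz", "Fz", "F2", "F4",
    "F6", "F8", "FT8", "FC6", "FC4", "FC2", "FCz", "Cz",
    "C2", "C4", "C6", "T8", "TP8", "CP6", "CP4", "CP2",
    "P2", "P4", "P6", "P8", "P10", "PO8", "PO4", "O2",
)

#: 24 frontocentral sites used for MMN and band-power features, in the
#: canonical order that defines feature-vector columns everywhere.
FRONTOCENTRAL_24: tuple[str, ...] = (
    "AFz", "AF3", "AF4", "Fz", "F1", "F2", "F3", "F4", "F5", "F6",
    "FCz", "FC1", "FC2", "FC3", "FC4", "FC5", "FC6",
    "Cz", "C1", "C2", "C3", "C4", "C5", "C6",
)

MASTOIDS: tuple[str, str] = ("M1", "M2")
EOG_CHANNELS: tuple[str, str] = ("VEOG", "HEOG")

#: Full recording montage: scalp + mastoids + EOG.
FULL_MONTAGE: tuple[str, ...] = SCALP_64 + MASTOIDS + EOG_CHANNELS

assert set(FRONTOCENTRAL_24) <= set(SCALP_64)


def frontocentral_indices(channel_names: list[str] | tuple[str, ...]) -> list[int]:
    """Indices of the 24 frontocentral sites within ``channel_names``.

    Raises ``KeyError`` naming the first missing site.
    """
    lookup = {name: i for i, name in enumerate(channel_names)}
    missing = [s for s in FRONTOCENTRAL_24 if s not in lookup]
    if missing:
        raise KeyError(f"montage is missing frontocentral site(s): {missing}")
    return [lookup[s] for s in FRONTOCENTRAL_24]
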