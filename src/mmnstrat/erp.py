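"""Mismatch-negativity amplitude features.

MMN is the deviant-minus-standard difference of the condition-averaged
waveforms; the per-channel feature is its mean amplitude over the 120-250
ms post-stimulus window at the 24 frontocentral sites.  Longitudinal
change features are follow-up minus baseline amplitudes (negative change
= larger MMN at follow-up = improvement).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .montage import FRONTOCENTRAL_24, frontocentral_indices
from .preprocess import EpochSet

MMN_WINDOW_MS: tuple[float, float] = (120.0, 250.0)


@dataclass
class MMNFeatures:
    subject_id: str
    timepoint: str
    amplitudes: np.ndarray  # 24 values, canonical site order, μV
    n_S1_used: int
    n_S2_used: int
    sites: tuple[str, ...] = FRONTOCENTRAL_24

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.amplitudes.shape != (len(self.sites),):
            raise ValueError(
                f"expected {len(self.sites)} amplitudes, got {self.amplitudes.shape}"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "subject": self.subject_id,
            "timepoint": self.timepoint,
            "site": list(self.sites),
            "amplitude_uV": self.amplitudes,
        })


@dataclass
class ChangeFeatures:
    subject_id: str
    delta_amplitudes: np.ndarray  # follow-up minus baseline, μV
    sites: tuple[str, ...] = FRONTOCENTRAL_24

    def __post_init__(self) -> None:
        self.delta_amplitudes = np.asarray(self.delta_amplitudes, dtype=float)


def condition_averages(es: EpochSet) -> dict[str, np.ndarray]:
    """Mean waveform per condition over non-rejected epochs.

    Returns ``{"S1": channels x samples, "S2": ...}``; rejected epochs are
    excluded.  A condition with no surviving epochs is an error.
    """
    out: dict[str, np.ndarray] = {}
    for cond in ("S1", "S2"):
        keep = es.surviving(cond)
        n = int(keep.sum())
        if n == 0:
            counts = {c: int(es.surviving(c).sum()) for c in ("S1", "S2")}
            raise ValueError(
                f"no surviving {cond} epochs (surviving counts: {counts})"
            )
        out[cond] = es.epochs[keep].mean(axis=0)
    return out


def mmn_amplitudes(
    es: EpochSet,
    window_ms: tuple[float, float] = MMN_WINDOW_MS,
    sites: tuple[str, ...] = FRONTOCENTRAL_24,
) -> MMNFeatures:
    """Per-site mean amplitude of the difference wave over ``window_ms``.

    Averaging precedes subtraction: the S1 and S2 waveforms are averaged
    over surviving epochs first, then subtracted (S2 - S1), then the
    difference is averaged over the window samples at each site.
    """
    avgs = condition_averages(es)
    if sites is FRONTOCENTRAL_24:
        idx = frontocentral_indices(es.channel_names)
    else:
        missing = [s for s in sites if s not in es.channel_names]
        if missing:
            raise KeyError(f"missing site(s): {missing}")
        idx = [es.channel_names.index(s) for s in sites]
    sl = es.window_slice(*window_ms)
    diff = avgs["S2"][idx, sl] - avgs["S1"][idx, sl]
    return MMNFeatures(
        subject_id=es.subject_id,
        timepoint=es.timepoint,
        amplitudes=diff.mean(axis=1),
        n_S1_used=int(es.surviving("S1").sum()),
        n_S2_used=int(es.surviving("S2").sum()),
        sites=tuple(sites),
    )


def change_features(baseline: MMNFeatures, followup: MMNFeatures) -> ChangeFeatures:
    """Follow-up minus baseline amplitude per site for one subject."""
    if baseline.subject_id != followup.subject_id:
        raise ValueError(
            f"subject mismatch: {baseline.subject_id!r} vs {followup.subject_id!r}"
        )
    if baseline.sites != followup.sites:
        raise ValueError("site lists differ between timepoints")
    return ChangeFeatures(
        subject_id=baseline.subject_id,
        delta_amplitudes=followup.amplitudes - baseline.amplitudes,
        sites=baseline.sites,
    )


def features_to_matrix(feats: list[MMNFeatures] | list[ChangeFeatures]) -> pd.DataFrame:
    """Wide matrix (rows = observations, columns = sites) for clustering."""
    rows, index = [], []
    for f in feats:
        if isinstance(f, MMNFeatures):
            rows.append(f.amplitudes)
            index.append(f"{f.subject_id}@{f.timepoint}")
        else:
            rows.append(f.delta_amplitudes)
            index.append(f.subject_id)
    sites = feats[0].sites
    return pd.DataFrame(np.vstack(rows), index=index, columns=list(sites))
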