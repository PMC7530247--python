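"""Continuous-EEG preprocessing for duration-oddball recordings.

The pipeline order is: mastoid re-reference -> 0.01-20 Hz band-pass ->
segmentation around stimulus markers -> baseline correction -> regression
ocular correction -> artifact screening.  Each step is a pure function on
the ``Recording`` / ``EpochSet`` containers; artifact screening only marks
epochs (with reason codes), it never alters voltages.

Sample-index convention
-----------------------
Millisecond boundaries map to sample offsets by round-half-up,
``floor(ms * fs / 1000 + 0.5)``, and epoch windows are half-open: an epoch
of window ``(start, end)`` relative to an onset sample ``o`` spans
``[o + r(start), o + r(start) + n)`` with ``n = r(end - start)`` samples.
At 512 Hz a (-100, 400) ms window around onset 1000 therefore spans
samples [949, 1205), i.e. 256 samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal
from scipy.ndimage import maximum_filter1d, minimum_filter1d


def ms_to_samples(ms: float, fs_hz: float) -> int:
    """Round-half-up conversion of a millisecond offset to samples."""
    return int(np.floor(ms * fs_hz / 1000.0 + 0.5))


@dataclass
class Event:
    label: str  # "S1" (standard) or "S2" (deviant)
    onset_sample: int


@dataclass
class Recording:
    """Continuous multichannel EEG in microvolts."""

    data: np.ndarray  # channels x samples, μV
    fs_hz: float
    channel_names: list[str]
    events: list[Event] = field(default_factory=list)
    reference: str = "raw"  # "raw" | "mastoid-average"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length must match data rows")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        for ev in self.events:
            if not (0 <= ev.onset_sample < self.data.shape[1]):
                raise ValueError(
                    f"event onset {ev.onset_sample} outside recording bounds"
                )

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not present in recording") from None


#: reason codes an epoch can carry
REASONS = ("gradient", "amplitude", "flat", "bounds")


@dataclass
class EpochSet:
    """Stimulus-locked segments with per-epoch rejection bookkeeping."""

    epochs: np.ndarray  # trials x channels x samples, μV
    condition: np.ndarray  # per-trial "S1"/"S2"
    window_ms: tuple[float, float]
    fs_hz: float
    channel_names: list[str]
    baseline_ms: tuple[float, float] | None = None
    rejected: np.ndarray | None = None  # per-trial bool
    reasons: list[set[str]] | None = None
    subject_id: str = ""
    timepoint: str = "baseline"

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.condition = np.asarray(self.condition)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be trials x channels x samples")
        n = self.epochs.shape[0]
        if self.condition.shape[0] != n:
            raise ValueError("condition length must match trial count")
        if not (self.window_ms[0] < 0 < self.window_ms[1]):
            raise ValueError("epoch window must straddle stimulus onset")
        if self.rejected is None:
            self.rejected = np.zeros(n, dtype=bool)
        else:
            self.rejected = np.asarray(self.rejected, dtype=bool)
        if self.reasons is None:
            self.reasons = [set() for _ in range(n)]
        bad = [r for s in self.reasons for r in s if r not in REASONS]
        if bad:
            raise ValueError(f"unknown rejection reason(s): {sorted(set(bad))}")

    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_samples(self) -> int:
        return self.epochs.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        """Time of each sample relative to stimulus onset, in ms."""
        start = ms_to_samples(self.window_ms[0], self.fs_hz)
        return (start + np.arange(self.n_samples)) * 1000.0 / self.fs_hz

    def surviving(self, cond: str | None = None) -> np.ndarray:
        """Boolean mask of non-rejected trials, optionally per condition."""
        keep = ~self.rejected
        if cond is not None:
            keep = keep & (self.condition == cond)
        return keep

    def window_slice(self, lo_ms: float, hi_ms: float) -> slice:
        """Half-open sample slice for an analysis window inside the epoch."""
        if lo_ms < self.window_ms[0] or hi_ms > self.window_ms[1]:
            raise ValueError(
                f"window ({lo_ms}, {hi_ms}) ms outside epoch {self.window_ms}"
            )
        start_epoch = ms_to_samples(self.window_ms[0], self.fs_hz)
        lo = ms_to_samples(lo_ms, self.fs_hz) - start_epoch
        n = ms_to_samples(hi_ms - lo_ms, self.fs_hz)
        return slice(lo, lo + n)


@dataclass(frozen=True)
class RejectionRules:
    """Artifact screening thresholds.

    max_gradient: μV per ms between consecutive samples.
    max_abs_amplitude: μV, absolute voltage ceiling.
    flat_threshold: μV, peak-to-peak floor for the flatline rule.
    flat_min_ms: ms, a run longer than this below the floor is flat.
    """

    max_gradient: float = 50.0
    max_abs_amplitude: float = 100.0
    flat_threshold: float = 0.5
    flat_min_ms: float = 100.0

    def __post_init__(self) -> None:
        if min(self.max_gradient, self.max_abs_amplitude,
               self.flat_threshold, self.flat_min_ms) <= 0:
            raise ValueError("all rejection thresholds must be positive")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def rereference_to_mastoids(
    rec: Recording, mastoid_names: tuple[str, str] = ("M1", "M2")
) -> Recording:
    """Subtract the mastoid average from every channel.

    The common-mode reference of active-electrode systems is arbitrary;
    referencing to linked mastoids is the conventional choice for MMN.
    """
    for name in mastoid_names:
        if name not in rec.channel_names:
            raise KeyError(f"mastoid channel {name!r} not present in recording")
    i, j = (rec.channel_index(n) for n in mastoid_names)
    ref = 0.5 * (rec.data[i] + rec.data[j])
    return replace(rec, data=rec.data - ref[None, :], reference="mastoid-average")


def bandpass_filter(
    rec: Recording, low_hz: float = 0.01, high_hz: float = 20.0, order: int = 4
) -> Recording:
    """Zero-phase Butterworth band-pass (forward-backward).

    The low-pass stage is a direct SOS filter.  For a very low high-pass
    corner (0.01 Hz at 512 Hz is a normalized frequency of 4e-5, where a
    digital Butterworth is numerically unstable) the high-pass is
    realized as drift subtraction: the sub-corner drift is estimated by
    the same-order Butterworth low-pass applied at a decimated rate where
    the corner is well conditioned, interpolated back, and subtracted.
    """
    nyq = rec.fs_hz / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"invalid corner frequencies ({low_hz}, {high_hz}) at fs={rec.fs_hz}"
        )
    lp = signal.butter(order, high_hz, btype="lowpass", fs=rec.fs_hz,
                       output="sos")
    data = signal.sosfiltfilt(lp, rec.data, axis=1)

    if low_hz / nyq >= 1e-3:  # well-conditioned: direct high-pass
        hp = signal.butter(order, low_hz, btype="highpass", fs=rec.fs_hz,
                           output="sos")
        data = signal.sosfiltfilt(hp, data, axis=1)
    else:
        q = max(1, int(rec.fs_hz // (low_hz * 200.0)))
        n_dec = rec.data.shape[1] // q
        if n_dec < 12:
            # epoch-scale signal: sub-corner content is just the mean
            data = data - data.mean(axis=1, keepdims=True)
        else:
            low = signal.resample_poly(data, up=1, down=q, axis=1)
            sos_lo = signal.butter(order, low_hz, btype="lowpass",
                                   fs=rec.fs_hz / q, output="sos")
            drift = signal.sosfiltfilt(
                sos_lo, low, axis=1, padlen=min(low.shape[1] - 1, 3000))
            t_dec = np.arange(low.shape[1]) * q
            t_full = np.arange(data.shape[1])
            drift_full = np.vstack([
                np.interp(t_full, t_dec, drift[ch]) for ch in range(drift.shape[0])
            ])
            data = data - drift_full
    return replace(rec, data=data)


def segment_epochs(
    rec: Recording,
    window_ms: tuple[float, float],
    subject_id: str = "",
    timepoint: str = "baseline",
) -> EpochSet:
    """Cut one epoch per event; out-of-bounds events are kept but marked
    rejected with reason ``bounds`` (zero-filled data)."""
    if not rec.events:
        raise ValueError("recording has no events to segment")
    start_off = ms_to_samples(window_ms[0], rec.fs_hz)
    n_samp = ms_to_samples(window_ms[1] - window_ms[0], rec.fs_hz)
    n_ch = rec.data.shape[0]

    epochs = np.zeros((len(rec.events), n_ch, n_samp))
    condition = np.array([ev.label for ev in rec.events])
    rejected = np.zeros(len(rec.events), dtype=bool)
    reasons: list[set[str]] = [set() for _ in rec.events]
    for t, ev in enumerate(rec.events):
        lo = ev.onset_sample + start_off
        hi = lo + n_samp
        if lo < 0 or hi > rec.n_samples:
            rejected[t] = True
            reasons[t].add("bounds")
            continue
        epochs[t] = rec.data[:, lo:hi]
    return EpochSet(
        epochs=epochs, condition=condition, window_ms=window_ms,
        fs_hz=rec.fs_hz, channel_names=list(rec.channel_names),
        rejected=rejected, reasons=reasons,
        subject_id=subject_id, timepoint=timepoint,
    )


def baseline_correct(
    es: EpochSet, baseline_ms: tuple[float, float] = (-100.0, 0.0)
) -> EpochSet:
    """Subtract the pre-stimulus mean per epoch per channel."""
    if baseline_ms[0] < es.window_ms[0] or baseline_ms[1] > es.window_ms[1]:
        raise ValueError(
            f"baseline {baseline_ms} outside epoch window {es.window_ms}"
        )
    sl = es.window_slice(*baseline_ms)
    if sl.stop <= sl.start:
        raise ValueError("baseline window contains no samples")
    mean = es.epochs[:, :, sl].mean(axis=2, keepdims=True)
    return replace(es, epochs=es.epochs - mean, baseline_ms=baseline_ms,
                   reasons=[set(r) for r in es.reasons],
                   rejected=es.rejected.copy())


def correct_ocular(
    es: EpochSet, eog_channels: tuple[str, str] = ("VEOG", "HEOG")
) -> EpochSet:
    """Regression-based eye-blink correction.

    Ordinary least squares estimates, per EEG channel, the propagation
    coefficients of the EOG channels across all epoch samples pooled; the
    fitted EOG contribution is subtracted.  With (near-)zero EOG variance
    the coefficients are undefined and the data are returned unchanged
    with a warning.
    """
    idx = []
    for name in eog_channels:
        if name not in es.channel_names:
            raise KeyError(f"EOG channel {name!r} not present")
        idx.append(es.channel_names.index(name))
    n_tr, n_ch, n_sp = es.epochs.shape
    eog = es.epochs[:, idx, :].transpose(1, 0, 2).reshape(len(idx), -1)  # (2, N)
    if eog.var(axis=1).max() < 1e-12:
        warnings.warn("EOG variance ~0; ocular correction skipped", stacklevel=2)
        return replace(es, reasons=[set(r) for r in es.reasons],
                       rejected=es.rejected.copy())
    eeg = es.epochs.transpose(1, 0, 2).reshape(n_ch, -1)  # (C, N)
    # OLS with intercept: coefficients b solve eeg ≈ a + b @ eog
    X = np.vstack([np.ones(eog.shape[1]), eog])  # (3, N)
    beta, *_ = np.linalg.lstsq(X.T, eeg.T, rcond=None)  # (3, C)
    b = beta[1:, :]  # (2, C) propagation coefficients
    fitted = (b.T @ eog)  # (C, N) EOG contribution, no intercept removal
    corrected = (eeg - fitted).reshape(n_ch, n_tr, n_sp).transpose(1, 0, 2)
    # EOG channels themselves keep their recorded signal for diagnostics
    corrected[:, idx, :] = es.epochs[:, idx, :]
    return replace(es, epochs=corrected, reasons=[set(r) for r in es.reasons],
                   rejected=es.rejected.copy())


def crop_epochs(es: EpochSet, window_ms: tuple[float, float]) -> EpochSet:
    """Restrict epochs to a narrower window (e.g. the frequency-analysis
    window) under the package sample convention; marks carry over."""
    sl = es.window_slice(*window_ms)
    return replace(es, epochs=es.epochs[:, :, sl], window_ms=window_ms,
                   reasons=[set(r) for r in es.reasons],
                   rejected=es.rejected.copy())


def reject_artifacts(es: EpochSet, rules: RejectionRules = RejectionRules(),
                     channels: list[str] | None = None) -> EpochSet:
    """Mark epochs violating any screening rule on any screened channel.

    Rules (any channel triggers, epoch-level marking):
      gradient  -- |v[t+1] - v[t]| exceeds ``max_gradient`` μV/ms, i.e.
                   ``max_gradient * 1000 / fs`` μV between samples;
      amplitude -- any |v| above ``max_abs_amplitude`` μV;
      flat      -- peak-to-peak below ``flat_threshold`` μV over a
                   contiguous run longer than ``flat_min_ms``.

    ``channels`` restricts screening (e.g. scalp only); default screens all.
    Voltage data are never modified.
    """
    if es.n_trials == 0:
        raise ValueError("no epochs to screen")
    if channels is None:
        ch_idx = np.arange(len(es.channel_names))
    else:
        ch_idx = np.array([es.channel_names.index(c) for c in channels])
    data = es.epochs[:, ch_idx, :]

    grad_limit = rules.max_gradient * 1000.0 / es.fs_hz  # μV per sample step
    grad_bad = (np.abs(np.diff(data, axis=2)) > grad_limit).any(axis=(1, 2))
    amp_bad = (np.abs(data) > rules.max_abs_amplitude).any(axis=(1, 2))

    # flat: sliding window of L samples spanning > flat_min_ms
    # (L - 1) / fs * 1000 > flat_min_ms  =>  minimal integer L
    L = int(np.floor(rules.flat_min_ms * es.fs_hz / 1000.0)) + 2
    if L <= data.shape[2]:
        p2p = (maximum_filter1d(data, L, axis=2, mode="nearest")
               - minimum_filter1d(data, L, axis=2, mode="nearest"))
        # only windows fully inside the epoch are valid
        half_lo = (L - 1) // 2
        valid = p2p[:, :, half_lo:half_lo + (data.shape[2] - L + 1)]
        flat_bad = (valid < rules.flat_threshold).any(axis=(1, 2))
    else:
        flat_bad = np.zeros(es.n_trials, dtype=bool)

    rejected = es.rejected.copy()
    reasons = [set(r) for r in es.reasons]
    for t in range(es.n_trials):
        if grad_bad[t]:
            reasons[t].add("gradient")
        if amp_bad[t]:
            reasons[t].add("amplitude")
        if flat_bad[t]:
            reasons[t].add("flat")
        if grad_bad[t] or amp_bad[t] or flat_bad[t]:
            rejected[t] = True
    return replace(es, rejected=rejected, reasons=reasons)
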