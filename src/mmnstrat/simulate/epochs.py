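"""Synthetic EEG epoch and recording generation.

Each simulated epoch is a sum of independent components:

* 1/f-shaped Gaussian background noise (per channel, ``noise_sd`` μV);
* on deviant trials, a deviance response: a rectangular pulse over the
  MMN window at each of the 24 frontocentral sites whose window mean
  equals the subject's ``mmn_profile`` exactly (before noise);
* band-limited oscillatory bursts after stimulus onset whose amplitude
  differs between standards and deviants per ``band_power_profile``;
* eye blinks: a stereotyped biphasic template on the vertical EOG
  channel, propagated to scalp channels with fixed coefficients (so that
  regression-based ocular correction is exactly recoverable);
* injected artifacts in an ``artifact_rate`` fraction of trials, cycling
  through the three rejection rules (amplitude, gradient, flatline) so
  every screening path is exercised.

The continuous-recording variant lays the same trial components onto a
continuous 1/f background with mastoid and EOG channels and event
markers, for testing the segmentation front end.
"""

from __future__ import annotations

import numpy as np

from ..montage import EOG_CHANNELS, FRONTOCENTRAL_24, MASTOIDS, SCALP_64
from ..preprocess import EpochSet, Event, Recording, ms_to_samples
from .sequence import generate_stimulus_sequence
from .specs import ParadigmSpec, SubjectSpec

#: band name -> oscillation carrier frequency (Hz), band midpoints
BAND_CARRIER_HZ = {"delta": 2.5, "theta": 6.0, "alpha": 10.25}

#: blink propagation coefficients from VEOG to scalp, by site prefix
_BLINK_PROP = (("Fp", 0.40), ("AF", 0.30), ("FC", 0.12), ("FT", 0.10),
               ("F", 0.22), ("C", 0.06), ("T", 0.04))
BLINK_AMPLITUDE_UV = 180.0
BLINK_DURATION_MS = 260.0

EPOCH_CHANNELS: tuple[str, ...] = SCALP_64 + EOG_CHANNELS


def blink_coefficient(channel: str) -> float:
    """Fixed VEOG->channel propagation coefficient."""
    if channel == "VEOG":
        return 1.0
    if channel == "HEOG":
        return 0.08
    for prefix, coef in _BLINK_PROP:
        if channel.startswith(prefix):
            return coef
    return 0.02


def blink_template(fs_hz: float) -> np.ndarray:
    """Unit-amplitude biphasic blink: main positive lobe, small rebound."""
    n = ms_to_samples(BLINK_DURATION_MS, fs_hz)
    t = np.linspace(0.0, 1.0, n, endpoint=False)
    main = np.sin(np.pi * np.clip(t / 0.7, 0, 1)) ** 2
    rebound = -0.25 * np.sin(np.pi * np.clip((t - 0.7) / 0.3, 0, 1)) ** 2
    return main + rebound


def pink_noise(rng: np.random.Generator, shape: tuple[int, ...], sd: float,
               alpha: float = 1.0) -> np.ndarray:
    """1/f^alpha-shaped Gaussian noise, unit-variance scaled to ``sd``."""
    if sd == 0:
        return np.zeros(shape)
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0  # avoid division by zero at DC
    spec *= f ** (-alpha / 2.0)
    out = np.fft.irfft(spec, n=n, axis=-1)
    out /= out.std(axis=-1, keepdims=True).mean() or 1.0
    return out * sd


def _mmn_pulse(n_samples: int, window_ms: tuple[float, float], fs_hz: float,
               mmn_window_ms: tuple[float, float]) -> np.ndarray:
    """0/1 indicator of the MMN window samples inside the epoch."""
    start_epoch = ms_to_samples(window_ms[0], fs_hz)
    lo = ms_to_samples(mmn_window_ms[0], fs_hz) - start_epoch
    n = ms_to_samples(mmn_window_ms[1] - mmn_window_ms[0], fs_hz)
    ind = np.zeros(n_samples)
    ind[lo:lo + n] = 1.0
    return ind


def generate_subject_epochs(
    spec: SubjectSpec,
    paradigm: ParadigmSpec = ParadigmSpec(),
    seed: int = 0,
    window_ms: tuple[float, float] = (-100.0, 400.0),
    mmn_window_ms: tuple[float, float] = (120.0, 250.0),
) -> EpochSet:
    """Epoch-level synthesis of one subject/timepoint.

    The returned EpochSet is un-screened (no rejection marks); running
    the preprocessing screen recovers the planted artifact fraction.
    """
    for band in spec.band_power_profile:
        if band not in BAND_CARRIER_HZ:
            raise ValueError(f"unknown band {band!r}")
        if BAND_CARRIER_HZ[band] >= paradigm.fs_hz / 2:
            raise ValueError(
                f"fs={paradigm.fs_hz} Hz cannot resolve band {band!r}")
    rng = np.random.default_rng(seed)
    events = generate_stimulus_sequence(paradigm, seed=int(rng.integers(2**31)))
    condition = np.array([ev.label for ev in events])
    n_tr = len(events)
    n_ch = len(EPOCH_CHANNELS)
    n_sp = ms_to_samples(window_ms[1] - window_ms[0], paradigm.fs_hz)
    fs = paradigm.fs_hz

    epochs = pink_noise(rng, (n_tr, n_ch, n_sp), spec.noise_sd)

    # deviance response: exact-mean rectangular pulse on S2 trials
    pulse = _mmn_pulse(n_sp, window_ms, fs, mmn_window_ms)
    profile = spec.mmn_vector()
    fc_idx = [EPOCH_CHANNELS.index(s) for s in FRONTOCENTRAL_24]
    is_dev = condition == "S2"
    if profile.any() and is_dev.any():
        epochs[np.ix_(is_dev, fc_idx)] += profile[None, :, None] * pulse[None, None, :]

    # band-limited oscillations from stimulus onset, random phase per trial
    t_ms = ms_to_samples(window_ms[0], fs) / fs * 1000.0 + \
        np.arange(n_sp) / fs * 1000.0
    post = (t_ms >= 0).astype(float)
    scalp_idx = np.arange(len(SCALP_64))
    for band, (a_s1, a_s2) in spec.band_power_profile.items():
        f_hz = BAND_CARRIER_HZ[band]
        phases = rng.uniform(0, 2 * np.pi, n_tr)
        amps = np.where(is_dev, a_s2, a_s1)
        waves = np.sin(2 * np.pi * f_hz * t_ms[None, :] / 1000.0
                       + phases[:, None]) * post[None, :]
        epochs[:, scalp_idx, :] += (amps[:, None] * waves)[:, None, :]

    # eye blinks: template on VEOG, fixed propagation to scalp
    if spec.blink_rate > 0:
        p_blink = min(1.0, spec.blink_rate * (n_sp / fs) / 60.0)
        tmpl = blink_template(fs) * BLINK_AMPLITUDE_UV
        coefs = np.array([blink_coefficient(c) for c in EPOCH_CHANNELS])
        blink_trials = np.flatnonzero(rng.random(n_tr) < p_blink)
        for tr in blink_trials:
            start = int(rng.integers(0, max(1, n_sp - len(tmpl))))
            seg = tmpl[: n_sp - start]
            epochs[tr, :, start:start + len(seg)] += coefs[:, None] * seg[None, :]

    # injected artifacts, cycling the three rejection rules
    n_art = round(spec.artifact_rate * n_tr)
    if n_art:
        art_trials = rng.choice(n_tr, size=n_art, replace=False)
        for j, tr in enumerate(art_trials):
            ch = int(rng.integers(0, len(SCALP_64)))
            kind = ("amplitude", "gradient", "flat")[j % 3]
            if kind == "amplitude":
                center = int(rng.integers(n_sp // 4, 3 * n_sp // 4))
                width = ms_to_samples(25.0, fs)
                k = np.arange(n_sp)
                epochs[tr, ch] += 150.0 * np.exp(-0.5 * ((k - center) / width) ** 2)
            elif kind == "gradient":
                k = int(rng.integers(1, n_sp - 1))
                epochs[tr, ch, k] += 120.0  # 61 μV/ms step at 512 Hz
            else:  # flat
                run = ms_to_samples(130.0, fs)
                start = int(rng.integers(0, n_sp - run))
                epochs[tr, ch, start:start + run] = epochs[tr, ch, start]

    return EpochSet(
        epochs=epochs, condition=condition, window_ms=window_ms, fs_hz=fs,
        channel_names=list(EPOCH_CHANNELS),
        subject_id=spec.subject_id, timepoint=spec.timepoint,
    )


def generate_subject_recording(
    spec: SubjectSpec,
    paradigm: ParadigmSpec = ParadigmSpec(),
    seed: int = 0,
    mmn_window_ms: tuple[float, float] = (120.0, 250.0),
) -> Recording:
    """Continuous-recording synthesis with mastoid and EOG channels.

    Trial components (deviance pulse, oscillations) are laid onto a
    continuous 1/f background at each event onset; blinks occur at
    Poisson times throughout.  Mastoids carry background noise only.
    """
    rng = np.random.default_rng(seed)
    events = generate_stimulus_sequence(paradigm, seed=int(rng.integers(2**31)))
    fs = paradigm.fs_hz
    channels = list(SCALP_64 + MASTOIDS + EOG_CHANNELS)
    trial_span = ms_to_samples(
        max(paradigm.std_tone_ms, paradigm.dev_tone_ms) + paradigm.isi_ms, fs)
    n_total = events[-1].onset_sample + trial_span + ms_to_samples(1000.0, fs)

    data = pink_noise(rng, (len(channels), n_total), spec.noise_sd)
    profile = spec.mmn_vector()
    fc_idx = [channels.index(s) for s in FRONTOCENTRAL_24]
    lo_off = ms_to_samples(mmn_window_ms[0], fs)
    n_win = ms_to_samples(mmn_window_ms[1] - mmn_window_ms[0], fs)
    for ev in events:
        if ev.label == "S2" and profile.any():
            lo = ev.onset_sample + lo_off
            data[fc_idx, lo:lo + n_win] += profile[:, None]
        for band, (a_s1, a_s2) in spec.band_power_profile.items():
            f_hz = BAND_CARRIER_HZ[band]
            amp = a_s2 if ev.label == "S2" else a_s1
            n_osc = trial_span
            t = np.arange(n_osc) / fs
            wave = amp * np.sin(2 * np.pi * f_hz * t + rng.uniform(0, 2 * np.pi))
            sl = slice(ev.onset_sample, ev.onset_sample + n_osc)
            data[:len(SCALP_64), sl] += wave[None, :]

    if spec.blink_rate > 0:
        tmpl = blink_template(fs) * BLINK_AMPLITUDE_UV
        coefs = np.array([blink_coefficient(c) for c in channels])
        coefs[[channels.index(m) for m in MASTOIDS]] = 0.0
        n_blinks = rng.poisson(spec.blink_rate * n_total / fs / 60.0)
        for start in rng.integers(0, n_total - len(tmpl), size=n_blinks):
            data[:, start:start + len(tmpl)] += coefs[:, None] * tmpl[None, :]

    return Recording(data=data, fs_hz=fs, channel_names=channels, events=events)
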