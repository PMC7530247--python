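"""Specification types for the synthetic oddball cohort generator."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..montage import FRONTOCENTRAL_24


@dataclass(frozen=True)
class ParadigmSpec:
    """Duration-oddball stimulation parameters.

    Defaults reproduce the standard protocol: 1,200 trials, 85% standard
    tones (100 ms) and 15% duration deviants (150 ms), 200 ms
    inter-stimulus interval, 512 Hz sampling.
    """

    n_trials: int = 1200
    p_deviant: float = 0.15
    std_tone_ms: float = 100.0
    dev_tone_ms: float = 150.0
    isi_ms: float = 200.0
    fs_hz: float = 512.0

    def __post_init__(self) -> None:
        if not 0 <= self.p_deviant < 1:
            raise ValueError("p_deviant must lie in [0, 1)")
        if self.n_trials <= 0 or self.fs_hz <= 0:
            raise ValueError("n_trials and fs_hz must be positive")

    @property
    def n_deviants(self) -> int:
        """Exact deviant count; errors if the proportion is non-integral."""
        exact = self.n_trials * self.p_deviant
        n = round(exact)
        if abs(exact - n) > 1e-9:
            raise ValueError(
                f"{self.n_trials} trials x p_deviant={self.p_deviant} gives a "
                f"non-integral deviant count ({exact}); exact-count "
                "allocation requires an integral split"
            )
        return n

    @property
    def n_standards(self) -> int:
        return self.n_trials - self.n_deviants


@dataclass
class SubjectSpec:
    """Ground-truth parameters for one simulated subject/timepoint.

    ``mmn_profile`` is the per-site deviant-minus-standard mean amplitude
    (μV) over the MMN window, indexed by the canonical 24 frontocentral
    sites.  ``band_power_profile`` maps a band name to (S1 oscillation
    amplitude, S2 oscillation amplitude) in μV; unequal amplitudes plant a
    band-power differential.  ``true_cluster`` is a hidden label kept for
    test assertions only — no analysis operation reads it.
    """

    subject_id: str
    group: str = "HC"  # "HC" | "FEP"
    timepoint: str = "baseline"  # "baseline" | "followup"
    true_cluster: int = 1
    mmn_profile: dict[str, float] = field(default_factory=dict)
    band_power_profile: dict[str, tuple[float, float]] = field(default_factory=dict)
    artifact_rate: float = 0.0
    blink_rate: float = 0.0  # blinks per minute
    noise_sd: float = 1.0  # μV

    def __post_init__(self) -> None:
        if self.group not in ("HC", "FEP"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.timepoint not in ("baseline", "followup"):
            raise ValueError(f"unknown timepoint {self.timepoint!r}")
        bad = [s for s in self.mmn_profile if s not in FRONTOCENTRAL_24]
        if bad:
            raise ValueError(f"mmn_profile has unknown site(s): {bad}")
        if self.artifact_rate < 0 or self.blink_rate < 0 or self.noise_sd < 0:
            raise ValueError("rates and noise_sd must be non-negative")

    def mmn_vector(self) -> np.ndarray:
        """Profile as a 24-vector in canonical site order (0 where unset)."""
        return np.array([self.mmn_profile.get(s, 0.0) for s in FRONTOCENTRAL_24])


@dataclass
class CohortSpec:
    """A cohort of subject specs plus the clinical sampling model.

    ``clinical_model``: continuous variable -> {cluster: (mean, sd)};
    ``categorical_model``: variable -> {cluster: probability of True}.
    """

    subjects: list[SubjectSpec]
    paradigm: ParadigmSpec = ParadigmSpec()
    seed: int = 0
    clinical_model: dict[str, dict[int, tuple[float, float]]] = field(
        default_factory=dict)
    categorical_model: dict[str, dict[int, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = [(s.subject_id, s.timepoint) for s in self.subjects]
        if len(set(keys)) != len(keys):
            dups = sorted({k for k in keys if keys.count(k) > 1})
            raise ValueError(f"duplicate subject/timepoint spec(s): {dups}")
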