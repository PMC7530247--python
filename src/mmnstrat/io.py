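"""Reading recordings and serializing pipeline artifacts.

Continuous recordings are read from EDF/BDF (via MNE) or from the
package's plain-text container: a ``<stem>.csv`` of channels x samples
voltages plus a ``<stem>.json`` sidecar holding sampling rate, channel
names, reference state, and events.  Epoch sets use the same pattern
with the trial structure flattened into the CSV and described in the
sidecar.  Text containers exist so synthetic fixtures and intermediate
results stay diffable and portable; EDF/BDF input covers real data.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import EpochSet, Event, Recording


def read_recording(path: str | Path,
                   channel_map: dict[str, str] | None = None) -> Recording:
    """Read a continuous recording (EDF/BDF or text container) in μV.

    ``channel_map`` renames recorded channel labels to canonical montage
    names (e.g. ``{"EXG1": "M1"}``).  EDF/BDF annotations whose
    description contains "S1"/"S2" become events.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".edf", ".bdf"):
        return _read_edf_bdf(path, channel_map)
    if suffix in (".csv", ".json"):
        return load_recording_text(path.with_suffix(""))
    raise ValueError(f"unknown recording format {suffix!r} for {path}")


def _read_edf_bdf(path: Path, channel_map: dict[str, str] | None) -> Recording:
    import mne

    reader = mne.io.read_raw_edf if path.suffix.lower() == ".edf" \
        else mne.io.read_raw_bdf
    raw = reader(path, preload=True, verbose="error")
    names = list(raw.ch_names)
    if channel_map:
        unknown = [k for k in channel_map if k not in names]
        if unknown:
            raise KeyError(f"channel_map keys not in recording: {unknown}")
        names = [channel_map.get(n, n) for n in names]
    events = []
    for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
        label = "S2" if "S2" in desc else ("S1" if "S1" in desc else None)
        if label:
            events.append(Event(label=label,
                                onset_sample=int(round(onset * raw.info["sfreq"]))))
    if not events:
        raise ValueError(f"no S1/S2 annotations found in {path}")
    return Recording(
        data=raw.get_data() * 1e6,  # MNE uses volts internally
        fs_hz=float(raw.info["sfreq"]),
        channel_names=names,
        events=events,
    )


# ---------------------------------------------------------------------------
# plain-text containers
# ---------------------------------------------------------------------------

def save_recording_text(rec: Recording, stem: str | Path) -> None:
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rec.data.T, columns=rec.channel_names).to_csv(
        stem.with_suffix(".csv"), index=False, float_format="%.6f")
    sidecar = {
        "fs_hz": rec.fs_hz,
        "channel_names": rec.channel_names,
        "reference": rec.reference,
        "events": [{"label": e.label, "onset_sample": e.onset_sample}
                   for e in rec.events],
    }
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_recording_text(stem: str | Path) -> Recording:
    stem = Path(stem)
    meta = json.loads(stem.with_suffix(".json").read_text())
    data = pd.read_csv(stem.with_suffix(".csv")).to_numpy().T
    return Recording(
        data=data, fs_hz=meta["fs_hz"], channel_names=meta["channel_names"],
        events=[Event(**e) for e in meta["events"]],
        reference=meta.get("reference", "raw"),
    )


def save_epochs_text(es: EpochSet, stem: str | Path) -> None:
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    n_tr, n_ch, n_sp = es.epochs.shape
    flat = es.epochs.reshape(n_tr * n_ch, n_sp)
    pd.DataFrame(flat).to_csv(stem.with_suffix(".csv"), index=False,
                              float_format="%.6f")
    sidecar = {
        "shape": [n_tr, n_ch, n_sp],
        "channel_names": es.channel_names,
        "fs_hz": es.fs_hz,
        "window_ms": list(es.window_ms),
        "baseline_ms": list(es.baseline_ms) if es.baseline_ms else None,
        "condition": es.condition.tolist(),
        "rejected": es.rejected.astype(int).tolist(),
        "reasons": [sorted(r) for r in es.reasons],
        "subject_id": es.subject_id,
        "timepoint": es.timepoint,
    }
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_epochs_text(stem: str | Path) -> EpochSet:
    stem = Path(stem)
    meta = json.loads(stem.with_suffix(".json").read_text())
    n_tr, n_ch, n_sp = meta["shape"]
    flat = pd.read_csv(stem.with_suffix(".csv")).to_numpy()
    return EpochSet(
        epochs=flat.reshape(n_tr, n_ch, n_sp),
        condition=np.array(meta["condition"]),
        window_ms=tuple(meta["window_ms"]),
        fs_hz=meta["fs_hz"],
        channel_names=meta["channel_names"],
        baseline_ms=tuple(meta["baseline_ms"]) if meta["baseline_ms"] else None,
        rejected=np.array(meta["rejected"], dtype=bool),
        reasons=[set(r) for r in meta["reasons"]],
        subject_id=meta["subject_id"],
        timepoint=meta["timepoint"],
    )


def write_rejection_log(es: EpochSet, path: str | Path) -> None:
    """TSV log of rejected epochs with reason codes."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [
        {"epoch": t, "condition": es.condition[t],
         "reasons": ",".join(sorted(es.reasons[t]))}
        for t in range(es.n_trials) if es.rejected[t]
    ]
    pd.DataFrame(rows, columns=["epoch", "condition", "reasons"]).to_csv(
        path, sep="\t", index=False)
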