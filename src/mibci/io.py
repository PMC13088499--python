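"""Disk formats: recordings (FIF/EDF + JSON marker sidecar), epoch sets (HDF5)."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .containers import EpochSet, Marker, RawRecording


def write_markers(markers: list[Marker], path: str | Path) -> None:
    payload = [{"onset_s": m.onset, "label": m.label} for m in markers]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_markers(path: str | Path) -> list[Marker]:
    payload = json.loads(Path(path).read_text())
    return [Marker(float(m["onset_s"]), str(m["label"])) for m in payload]


def write_recording(rec: RawRecording, path: str | Path,
                    markers_path: str | Path | None = None) -> None:
    """Write a recording as FIF (volts on disk, µV in memory) + JSON markers."""
    import mne

    path = Path(path)
    info = mne.create_info(rec.channel_names, rec.fs, ch_types="eeg")
    raw = mne.io.RawArray(rec.data * 1e-6, info, verbose="error")
    raw.save(path, overwrite=True, verbose="error")
    if markers_path is None:
        markers_path = path.with_suffix(".markers.json")
    write_markers(rec.markers, markers_path)


def read_recording(path: str | Path, markers_path: str | Path | None = None,
                   session_id: str | None = None) -> RawRecording:
    """Read EDF or FIF continuous EEG; markers come from the JSON sidecar
    when present, else from annotations embedded in the file."""
    import mne

    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    elif suffix == ".fif":
        raw = mne.io.read_raw_fif(path, preload=True, verbose="error")
    else:
        raise ValueError(f"unsupported recording format: {path.name}")
    data = raw.get_data() * 1e6  # volts -> µV
    markers: list[Marker] = []
    if markers_path is None:
        cand = path.with_suffix(".markers.json")
        markers_path = cand if cand.exists() else None
    if markers_path is not None:
        markers = read_markers(markers_path)
    elif raw.annotations is not None:
        markers = [Marker(float(a["onset"]), str(a["description"]))
                   for a in raw.annotations]
    return RawRecording(
        data=data, fs=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names), markers=markers,
        session_id=session_id or path.stem,
    )


def write_epochs(epochs: EpochSet, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("epochs", data=epochs.epochs)
        f.create_dataset("labels", data=np.asarray(epochs.labels, dtype="S"))
        f.create_dataset("session_ids", data=np.asarray(epochs.session_ids, dtype="S"))
        f.create_dataset("trial_ids", data=epochs.trial_ids)
        if epochs.baseline_data is not None:
            f.create_dataset("baseline_data", data=epochs.baseline_data)
        f.attrs["tmin"] = epochs.tmin
        f.attrs["tmax"] = epochs.tmax
        f.attrs["fs"] = epochs.fs
        f.attrs["channel_names"] = json.dumps(epochs.channel_names)
        f.attrs["dropped"] = epochs.dropped
        if epochs.normalization_stats is not None:
            stats = {k: {"mean": v[0].tolist(), "sd": v[1].tolist()}
                     for k, v in epochs.normalization_stats.items()}
            f.attrs["normalization_stats"] = json.dumps(stats)


def read_epochs(path: str | Path) -> EpochSet:
    with h5py.File(path, "r") as f:
        stats = None
        if "normalization_stats" in f.attrs:
            raw_stats = json.loads(f.attrs["normalization_stats"])
            stats = {k: (np.array(v["mean"]), np.array(v["sd"]))
                     for k, v in raw_stats.items()}
        return EpochSet(
            epochs=f["epochs"][()],
            labels=f["labels"][()].astype(str),
            session_ids=f["session_ids"][()].astype(str),
            trial_ids=f["trial_ids"][()],
            baseline_data=f["baseline_data"][()] if "baseline_data" in f else None,
            tmin=float(f.attrs["tmin"]), tmax=float(f.attrs["tmax"]),
            fs=float(f.attrs["fs"]),
            channel_names=json.loads(f.attrs["channel_names"]),
            dropped=int(f.attrs["dropped"]),
            normalization_stats=stats,
        )
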