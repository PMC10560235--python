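"""Reading and writing recordings, events and ROI maps.

The canonical on-disk container is HDF5 with datasets ``/data`` (channels x
time), ``/fs`` and ``/labels`` and a ``units`` attribute; it round-trips
bit-exactly. EDF (European Data Format) files are read through MNE and are
subject to the format's 16-bit physical/digital quantisation.
"""

from __future__ import annotations

import json
import os

import h5py
import numpy as np
import pandas as pd

from ecognet.containers import Recording

EVENT_COLUMNS = [
    "onset_s", "duration_s", "trial_class", "word_pair", "bias",
    "vot_step", "congruency", "phase",
]


class FormatError(ValueError):
    """Raised for malformed or truncated recording files."""


def write_recording(rec: Recording, path, units: str = "uV") -> None:
    """Write a recording to the canonical HDF5 container."""
    with h5py.File(path, "w") as f:
        d = f.create_dataset("data", data=rec.samples)
        d.attrs["units"] = units
        f.create_dataset("fs", data=float(rec.fs))
        f.create_dataset(
            "labels", data=np.array(rec.labels, dtype=h5py.string_dtype())
        )
        if rec.roi_map is not None:
            f.attrs["roi_map"] = json.dumps(rec.roi_map)


def _read_hdf5(path) -> Recording:
    try:
        with h5py.File(path, "r") as f:
            for key in ("data", "fs", "labels"):
                if key not in f:
                    raise FormatError(f"{path}: missing dataset /{key}")
            data = f["data"][()]
            fs = float(f["fs"][()])
            labels = [
                s.decode() if isinstance(s, bytes) else str(s)
                for s in f["labels"][()]
            ]
            roi_map = (
                json.loads(f.attrs["roi_map"]) if "roi_map" in f.attrs else None
            )
    except OSError as err:
        raise FormatError(f"{path}: not a readable HDF5 file ({err})") from err
    if data.shape[0] != len(labels):
        raise FormatError(
            f"{path}: channel count mismatch ({data.shape[0]} rows, "
            f"{len(labels)} labels)"
        )
    return Recording(data, fs, labels, roi_map)


def _read_edf(path) -> Recording:
    import mne

    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as err:  # mne raises assorted types on bad headers
        raise FormatError(f"{path}: unreadable EDF ({err})") from err
    # mne converts EDF physical units to SI (volts); keep microvolts here.
    data = raw.get_data() * 1e6
    return Recording(data, float(raw.info["sfreq"]), list(raw.ch_names))


def read_recording(path, format: str | None = None) -> Recording:
    """Read a recording from HDF5 or EDF.

    ``format`` may be ``"hdf5"`` or ``"edf"``; when omitted it is inferred
    from the file extension.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format is None:
        ext = os.path.splitext(str(path))[1].lower()
        format = "edf" if ext == ".edf" else "hdf5"
    if format == "hdf5":
        return _read_hdf5(path)
    if format == "edf":
        return _read_edf(path)
    raise ValueError(f"unknown format {format!r}")


def read_events(path) -> pd.DataFrame:
    """Read a tab-separated event table (BIDS-events-like)."""
    ev = pd.read_csv(path, sep="\t")
    missing = [c for c in ("onset_s",) if c not in ev.columns]
    if missing:
        raise FormatError(f"{path}: missing required event columns {missing}")
    return ev


def write_events(events: pd.DataFrame, path) -> None:
    events.to_csv(path, sep="\t", index=False)


def read_roi_map(path) -> dict[str, str]:
    """Read a ``{channel: roi}`` JSON mapping."""
    with open(path) as f:
        m = json.load(f)
    if not isinstance(m, dict):
        raise FormatError(f"{path}: ROI map must be a JSON object")
    return {str(k): str(v) for k, v in m.items()}


def write_roi_map(roi_map: dict[str, str], path) -> None:
    with open(path, "w") as f:
        json.dump(roi_map, f, indent=1)
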