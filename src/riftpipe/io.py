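"""File formats: BrainVision continuous EEG, HDF5 epochs, TSV tables.

Continuous recordings are written in the BrainVision triplet (.vhdr/.vmrk
text headers plus a little-endian IEEE float32 multiplexed .eeg) and read
back through :func:`mne.io.read_raw_brainvision`.  Epochs travel as HDF5
(datasets ``data`` [trial, channel, time], ``times``, ``channels``) with the
trial metadata embedded as a TSV-encoded string; gaze and metadata tables
are plain TSV.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from riftpipe.containers import EpochSet, GazeSet

# ---------------------------------------------------------------------------
# BrainVision
# ---------------------------------------------------------------------------

_VHDR_TEMPLATE = """Brain Vision Data Exchange Header File Version 1.0
; Written by riftpipe

[Common Infos]
Codepage=UTF-8
DataFile={stem}.eeg
MarkerFile={stem}.vmrk
DataFormat=BINARY
DataOrientation=MULTIPLEXED
NumberOfChannels={n_channels}
SamplingInterval={sampling_interval_us}

[Binary Infos]
BinaryFormat=IEEE_FLOAT_32

[Channel Infos]
{channel_lines}
"""

_VMRK_TEMPLATE = """Brain Vision Data Exchange Marker File, Version 1.0

[Common Infos]
Codepage=UTF-8
DataFile={stem}.eeg

[Marker Infos]
Mk1=New Segment,,1,1,0
{marker_lines}
"""


def write_brainvision(
    path,
    data: np.ndarray,
    fs: float,
    channels: list[str],
    events: pd.DataFrame | None = None,
) -> Path:
    """Write (channels, samples) float data as a BrainVision triplet.

    ``path`` is the .vhdr path (siblings .vmrk/.eeg are derived).  ``events``
    needs columns ``sample`` (0-based) and ``trial_id``; they become Stimulus
    markers ``S<trial_id + 1>``.  Returns the .vhdr path.
    """
    path = Path(path).with_suffix(".vhdr")
    stem = path.stem
    data = np.asarray(data, dtype=np.float32)
    if data.ndim != 2 or data.shape[0] != len(channels):
        raise ValueError("data must be (channels, samples) matching the label list")
    ch_lines = "\n".join(
        # name, reference (empty), resolution in unit, unit
        f"Ch{i + 1}={name},,1,µV" for i, name in enumerate(channels)
    )
    vhdr = _VHDR_TEMPLATE.format(
        stem=stem,
        n_channels=len(channels),
        sampling_interval_us=f"{1e6 / fs:.6f}".rstrip("0").rstrip("."),
        channel_lines=ch_lines,
    )
    marker_lines = []
    if events is not None:
        for k, row in enumerate(events.itertuples(index=False)):
            # BrainVision marker positions are 1-based sample indices
            marker_lines.append(
                f"Mk{k + 2}=Stimulus,S{int(row.trial_id) + 1:>3},{int(row.sample) + 1},1,0"
            )
    vmrk = _VMRK_TEMPLATE.format(stem=stem, marker_lines="\n".join(marker_lines))
    path.write_text(vhdr)
    path.with_suffix(".vmrk").write_text(vmrk)
    data.T.astype("<f4").tofile(path.with_suffix(".eeg"))
    return path


def read_brainvision(path) -> tuple[np.ndarray, float, list[str], pd.DataFrame]:
    """Read a BrainVision file via MNE.

    Returns ``(data_uV (channels, samples), fs, channel names, events)``
    where events has ``sample`` (0-based) and ``trial_id`` recovered from the
    stimulus marker codes.
    """
    import mne

    raw = mne.io.read_raw_brainvision(Path(path).with_suffix(".vhdr"), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE loads EEG in volt
    annots = raw.annotations
    samples, trial_ids = [], []
    for onset, desc in zip(annots.onset, annots.description):
        if desc.startswith("Stimulus/S"):
            samples.append(int(round(onset * raw.info["sfreq"])))
            trial_ids.append(int(desc.split("S")[-1].strip()) - 1)
    events = pd.DataFrame({"sample": samples, "label": "cue", "trial_id": trial_ids})
    return data, float(raw.info["sfreq"]), list(raw.ch_names), events


# ---------------------------------------------------------------------------
# HDF5 epochs
# ---------------------------------------------------------------------------

def save_epochs_h5(path, epochs: EpochSet) -> Path:
    path = Path(path)
    meta_tsv = epochs.meta.to_csv(sep="\t", index=False)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data.astype(np.float32), compression="gzip", compression_opts=1)
        f.create_dataset("times", data=epochs.times)
        f.create_dataset("channels", data=np.array(epochs.channels, dtype=h5py.string_dtype()))
        f.attrs["fs"] = epochs.fs
        f.attrs["experiment"] = epochs.experiment
        f.attrs["meta_tsv"] = meta_tsv
    return path


def load_epochs_h5(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        times = f["times"][()]
        channels = [c.decode() if isinstance(c, bytes) else str(c) for c in f["channels"][()]]
        fs = float(f.attrs["fs"])
        experiment = str(f.attrs["experiment"])
        meta = pd.read_csv(_io.StringIO(f.attrs["meta_tsv"]), sep="\t")
    return EpochSet(data=data, times=times, fs=fs, channels=channels, meta=meta, experiment=experiment)


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def save_gaze_tsv(path, gaze: GazeSet) -> Path:
    """Long-format TSV: trial_id, t, eye, x_dva, y_dva (NaN marks blinks)."""
    path = Path(path)
    n_tr, n_eyes, n_t = gaze.x.shape
    trial_ids = gaze.meta["trial_id"].to_numpy()
    frames = []
    for eye in range(n_eyes):
        frames.append(
            pd.DataFrame(
                {
                    "trial_id": np.repeat(trial_ids, n_t),
                    "t": np.tile(gaze.times, n_tr),
                    "eye": eye,
                    "x_dva": gaze.x[:, eye, :].ravel(),
                    "y_dva": gaze.y[:, eye, :].ravel(),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def load_gaze_tsv(path, meta: pd.DataFrame, fs: float) -> GazeSet:
    df = pd.read_csv(path, sep="\t")
    trial_ids = meta["trial_id"].to_numpy()
    times = np.sort(df["t"].unique())
    eyes = np.sort(df["eye"].unique())
    n_tr, n_eyes, n_t = len(trial_ids), len(eyes), len(times)
    x = np.full((n_tr, n_eyes, n_t), np.nan)
    y = np.full((n_tr, n_eyes, n_t), np.nan)
    pos = {tid: i for i, tid in enumerate(trial_ids)}
    for eye_i, eye in enumerate(eyes):
        sub = df[df["eye"] == eye]
        for tid, grp in sub.groupby("trial_id"):
            i = pos[tid]
            x[i, eye_i] = grp["x_dva"].to_numpy()
            y[i, eye_i] = grp["y_dva"].to_numpy()
    return GazeSet(x=x, y=y, times=times, fs=fs, meta=meta.reset_index(drop=True))


def save_table_tsv(path, table: pd.DataFrame) -> Path:
    path = Path(path)
    table.to_csv(path, sep="\t", index=False)
    return path


def load_table_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_json(path, payload: dict) -> Path:
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=_json_default))
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
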