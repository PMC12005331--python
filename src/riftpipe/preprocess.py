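"""Deterministic EEG preprocessing: referencing, filtering, epoching, exclusions.

The stage mirrors a conventional steady-state EEG pipeline: average
re-reference over good channels, 0.01 Hz high-pass, DFT notch of line noise
and harmonics (50/100/150 Hz), fixed per-experiment epoching and baseline
correction, then rule-based trial and participant exclusion.  All rules are
pure functions of the data and the configuration — nothing depends on
inspection or hidden state.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal

from riftpipe.config import PreprocessConfig
from riftpipe.containers import EpochSet
from riftpipe.timing import timing_for


def rereference_average(eeg: np.ndarray, channels: list[str], bad_channels=()) -> np.ndarray:
    """Subtract the instantaneous mean of the good channels from each good channel.

    Bad channels are passed through unchanged.  Idempotent: the good-channel
    mean is zero at every sample afterwards.
    """
    bad = set(bad_channels)
    good_idx = [i for i, c in enumerate(channels) if c not in bad]
    if len(good_idx) < 2:
        raise ValueError("average re-referencing needs at least 2 good channels")
    out = np.array(eeg, dtype=float, copy=True)
    mean = out[good_idx].mean(axis=0, keepdims=True)
    out[good_idx] -= mean
    return out


def notch_dft(eeg: np.ndarray, fs: float, freqs=(50.0, 100.0, 150.0)) -> np.ndarray:
    """Remove pure sinusoids at the given frequencies by least-squares fit.

    For each notch frequency a sine/cosine pair over the whole window is
    regressed out of every channel.  This removes stationary line noise
    exactly while leaving nearby frequencies (e.g. the 60/64 Hz tags)
    untouched, the behaviour of a discrete-Fourier-transform filter.
    """
    eeg = np.asarray(eeg, dtype=float)
    n = eeg.shape[-1]
    if n < 2 * fs / min(freqs):
        raise ValueError("window too short for the lowest notch frequency")
    t = np.arange(n) / fs
    cols = []
    for f in freqs:
        if f >= fs / 2:
            raise ValueError(f"notch frequency {f} Hz is at or above Nyquist")
        cols += [np.sin(2 * np.pi * f * t), np.cos(2 * np.pi * f * t)]
    basis = np.stack(cols, axis=1)  # (n, 2k)
    coef, *_ = np.linalg.lstsq(basis, eeg.reshape(-1, n).T, rcond=None)
    fitted = (basis @ coef).T.reshape(eeg.shape)
    return eeg - fitted


def highpass(eeg: np.ndarray, fs: float, cutoff_hz: float = 0.01, order: int = 2) -> np.ndarray:
    """Zero-phase (two-pass) Butterworth high-pass on continuous data."""
    sos = signal.butter(order, cutoff_hz, btype="highpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(eeg, dtype=float), axis=-1)


def epoch(
    eeg: np.ndarray,
    fs: float,
    events: pd.DataFrame,
    experiment: str,
    channels: list[str],
    meta: pd.DataFrame | None = None,
    window: tuple[float, float] | None = None,
) -> tuple[EpochSet, pd.DataFrame]:
    """Cut fixed-length epochs around event samples.

    The window is half-open [start, end): the epoch covers samples
    ``round(start*fs) .. round(end*fs) - 1`` relative to the event.  Events
    too close to the recording edges are dropped with a logged reason; the
    second return value lists dropped trials.
    """
    window = window or timing_for(experiment).epoch_window
    i0 = int(round(window[0] * fs))
    i1 = int(round(window[1] * fs))
    n_t = i1 - i0
    times = np.arange(i0, i1) / fs
    n_samples = eeg.shape[-1]
    kept, dropped = [], []
    for row in events.itertuples(index=False):
        s = int(row.sample)
        if s + i0 < 0 or s + i1 > n_samples:
            dropped.append({"trial_id": row.trial_id, "reason": "event too close to recording edge"})
        else:
            kept.append((row.trial_id, s))
    data = np.empty((len(kept), eeg.shape[0], n_t), dtype=np.float32)
    for k, (_, s) in enumerate(kept):
        data[k] = eeg[:, s + i0 : s + i1]
    kept_ids = [tid for tid, _ in kept]
    if meta is not None:
        sub = meta.set_index("trial_id").loc[kept_ids].reset_index()
    else:
        sub = pd.DataFrame({"trial_id": kept_ids})
    drop_log = pd.DataFrame(dropped, columns=["trial_id", "reason"])
    es = EpochSet(
        data=data, times=times, fs=fs, channels=list(channels), meta=sub, experiment=experiment
    )
    return es, drop_log


def baseline_correct(epochs: EpochSet, window: tuple[float, float] | None = None) -> EpochSet:
    """Subtract the per-trial, per-channel mean over the baseline window."""
    window = window or timing_for(epochs.experiment).baseline_window
    if window[0] < epochs.times[0] or window[1] > epochs.times[-1] + 1.0 / epochs.fs:
        raise ValueError(f"baseline window {window} lies outside the epoch")
    sl = epochs.time_slice(*window)
    base = epochs.data[:, :, sl].mean(axis=2, keepdims=True)
    out = EpochSet(
        data=(epochs.data - base).astype(epochs.data.dtype),
        times=epochs.times,
        fs=epochs.fs,
        channels=list(epochs.channels),
        meta=epochs.meta.copy(),
        experiment=epochs.experiment,
    )
    return out


def reject_artifact_trials(
    epochs: EpochSet, amp_threshold_uv: float = 150.0, bad_channels=()
) -> np.ndarray:
    """Flag trials whose peak-to-peak amplitude exceeds the threshold.

    A trial is flagged iff any good channel's max-minus-min over the epoch
    exceeds ``amp_threshold_uv``.  This deterministic rule stands in for
    inspection-based artifact labelling.
    """
    if amp_threshold_uv <= 0:
        raise ValueError("amplitude threshold must be > 0")
    bad = set(bad_channels)
    good = [i for i, c in enumerate(epochs.channels) if c not in bad]
    ptp = epochs.data[:, good, :].max(axis=2) - epochs.data[:, good, :].min(axis=2)
    return (ptp > amp_threshold_uv).any(axis=1)


def exclude_participants(flag_table: pd.DataFrame, max_fraction: float = 0.5) -> list:
    """Participants whose flagged-trial fraction strictly exceeds ``max_fraction``.

    ``flag_table`` needs columns ``participant_id`` and ``flagged`` (bool).
    Exactly 50 % flagged is retained (strict inequality).
    """
    frac = flag_table.groupby("participant_id")["flagged"].mean()
    return sorted(frac.index[frac > max_fraction].tolist())


def preprocess_continuous(
    eeg: np.ndarray,
    fs: float,
    events: pd.DataFrame,
    experiment: str,
    channels: list[str],
    meta: pd.DataFrame,
    config: PreprocessConfig,
) -> tuple[EpochSet, pd.DataFrame]:
    """Full continuous-to-epochs chain for one participant.

    Order: average re-reference (excluding configured bad channels),
    high-pass, DFT notch, epoching, baseline correction, then peak-to-peak
    artifact flagging written into ``meta['artifact_excluded']``.
    """
    x = rereference_average(eeg, channels, config.bad_channels)
    x = highpass(x, fs, config.highpass_hz)
    x = notch_dft(x, fs, config.notch_hz)
    epochs, drop_log = epoch(x, fs, events, experiment, channels, meta=meta)
    epochs = baseline_correct(epochs)
    flags = reject_artifact_trials(epochs, config.artifact_amp_threshold_uv, config.bad_channels)
    epochs.meta["artifact_excluded"] = flags
    return epochs, drop_log
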