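"""Trial-set Hilbert coherence at the tagging frequencies and its contrasts.

The central statistic: for a set of ``n`` trials, a channel and a reference
sinusoid at the tag frequency, the time-resolved magnitude-squared coherence

    coh(t) = | sum_tr Mx(t) My(t) exp(i dphi(t)) |^2
             -------------------------------------
             n * sum_tr Mx(t)^2 My(t)^2

where ``Mx``/``phi_x`` are the instantaneous magnitude and phase of the
band-passed, Hilbert-transformed EEG, ``My`` is the (constant, unit)
magnitude of the reference wave and ``dphi`` the phase difference between
them.  Coherence lies in [0, 1] (Cauchy-Schwarz), reaches 1 for perfectly
phase-locked identical trials and has expectation ~1/n under random phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from riftpipe.containers import AnalyticSignal, CoherenceTrace, EpochSet
from riftpipe.timing import timing_for

#: default half-width of the tag band-pass (Hz)
DEFAULT_HALFWIDTH = 1.9

#: coherence-spectrogram frequency grid: 56.8 .. 67.2 Hz in 0.8 Hz steps
SPECTROGRAM_FREQS = np.round(np.arange(56.8, 67.2 + 0.4, 0.8), 10)

#: row bandwidth of the spectrogram (+/- Hz).  The +/-1.9 Hz band of the tag
#: time courses is maximally flat across +/-0.8 Hz, so neighbouring grid rows
#: would capture a tag line almost unattenuated and 60/64 Hz peaks could not
#: be resolved; rows are therefore filtered at half that width, which makes
#: adjacent rows spectrally separable while the filter still settles inside
#: the epochs.
SPECTROGRAM_HALFWIDTH = 0.95


def settling_time(halfwidth: float = DEFAULT_HALFWIDTH) -> float:
    """Filter settling time (s): 3 / bandwidth, with bandwidth = 2*halfwidth."""
    return 3.0 / (2.0 * halfwidth)


def bandpass_hilbert(
    epochs: EpochSet, f0: float, halfwidth: float = DEFAULT_HALFWIDTH, order: int = 4
) -> AnalyticSignal:
    """Analytic magnitude and phase of the EEG in a narrow band around ``f0``.

    Two-pass (zero-phase) 4th-order Butterworth band-pass at ``f0 +/-
    halfwidth`` followed by a Hilbert transform, per trial and channel.
    Samples within one settling time (3/bandwidth) of either epoch edge are
    marked invalid.
    """
    if f0 + halfwidth >= epochs.fs / 2:
        raise ValueError("band edge exceeds the Nyquist frequency")
    settle = settling_time(halfwidth)
    n_t = epochs.data.shape[2]
    if n_t < 2 * settle * epochs.fs:
        raise ValueError(
            f"epoch ({n_t / epochs.fs:.2f} s) shorter than twice the filter settling "
            f"time ({settle:.2f} s)"
        )
    sos = sps.butter(
        order, [f0 - halfwidth, f0 + halfwidth], btype="bandpass", fs=epochs.fs, output="sos"
    )
    filtered = sps.sosfiltfilt(sos, np.asarray(epochs.data, dtype=float), axis=-1)
    analytic = sps.hilbert(filtered, axis=-1)
    n_settle = int(round(settle * epochs.fs))
    valid = np.zeros(n_t, dtype=bool)
    valid[n_settle : n_t - n_settle] = True
    return AnalyticSignal(
        magnitude=np.abs(analytic),
        phase=np.angle(analytic),
        times=epochs.times,
        fs=epochs.fs,
        channels=list(epochs.channels),
        center_freq=f0,
        halfwidth=halfwidth,
        valid=valid,
    )


@dataclass
class ReferenceWave:
    """Pure sinusoid at the tag frequency: unit magnitude, linear phase ramp."""

    frequency: float
    fs: float
    times: np.ndarray

    @property
    def magnitude(self) -> np.ndarray:
        return np.ones_like(self.times)

    @property
    def phase(self) -> np.ndarray:
        # phase of sin(2 pi f t) as an analytic signal: 2 pi f t - pi/2, wrapped
        return np.angle(np.exp(1j * (2.0 * np.pi * self.frequency * self.times - np.pi / 2)))


def reference_wave(frequency: float, times: np.ndarray, fs: float) -> ReferenceWave:
    return ReferenceWave(frequency=frequency, fs=fs, times=np.asarray(times, dtype=float))


def coherence_timecourse(
    analytic: AnalyticSignal,
    ref: ReferenceWave | None = None,
    trials: np.ndarray | None = None,
    condition: str = "",
) -> CoherenceTrace:
    """Trial-set magnitude-squared coherence with the reference wave.

    ``trials`` optionally selects a boolean/index subset (needs >= 2 trials).
    Where the denominator is exactly 0 (all magnitudes vanish) the coherence
    is defined as 0.
    """
    if ref is None:
        ref = reference_wave(analytic.center_freq, analytic.times, analytic.fs)
    mx = analytic.magnitude
    dphi = analytic.phase - ref.phase[None, None, :]
    my = ref.magnitude[None, None, :]
    if trials is not None:
        mx = mx[trials]
        dphi = dphi[trials]
    n = mx.shape[0]
    if n < 2:
        raise ValueError("coherence needs at least 2 trials")
    z = mx * my * np.exp(1j * dphi)
    num = np.abs(z.sum(axis=0)) ** 2
    den = n * ((mx * my) ** 2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return CoherenceTrace(
        coh=coh,
        times=analytic.times,
        fs=analytic.fs,
        channels=list(analytic.channels),
        frequency=ref.frequency,
        n_trials=n,
        condition=condition,
        valid=analytic.valid,
    )


@dataclass
class CoherenceSpectrogram:
    """Coherence as a (frequency, channel, time) map."""

    freqs: np.ndarray
    coh: np.ndarray
    times: np.ndarray
    channels: list[str]
    n_trials: int
    valid: np.ndarray

    def channel_average(self, names=None) -> np.ndarray:
        """(frequency, time) map averaged over channels."""
        if names is None:
            return self.coh.mean(axis=1)
        idx = [self.channels.index(n) for n in names]
        return self.coh[:, idx, :].mean(axis=1)

    def peak_frequency(self, interval: tuple[float, float], names=None) -> float:
        """Frequency row with the highest mean coherence in a time interval.

        Only samples inside the interval that are also clear of the filter
        settling edges contribute.
        """
        mask = (self.times >= interval[0]) & (self.times < interval[1]) & self.valid
        if not mask.any():
            raise ValueError("no valid samples in the requested interval")
        fmap = self.channel_average(names)[:, mask].mean(axis=1)
        return float(self.freqs[int(np.argmax(fmap))])


def coherence_spectrogram(
    epochs: EpochSet,
    freqs=None,
    halfwidth: float = SPECTROGRAM_HALFWIDTH,
    trials: np.ndarray | None = None,
) -> CoherenceSpectrogram:
    """Coherence time courses over a grid of reference frequencies.

    Each row band-passes the EEG at the row's center frequency (default
    row bandwidth +/- ``SPECTROGRAM_HALFWIDTH``) and evaluates the trial-set
    coherence against a reference sinusoid at that frequency.
    """
    freqs = SPECTROGRAM_FREQS if freqs is None else np.asarray(freqs, dtype=float)
    maps = []
    valid = None
    n = None
    for f in freqs:
        analytic = bandpass_hilbert(epochs, float(f), halfwidth)
        trace = coherence_timecourse(analytic, trials=trials)
        maps.append(trace.coh.astype(np.float32))
        valid = trace.valid
        n = trace.n_trials
    return CoherenceSpectrogram(
        freqs=freqs,
        coh=np.stack(maps, axis=0),
        times=epochs.times,
        channels=list(epochs.channels),
        n_trials=n,
        valid=valid,
    )


def select_top_channels(
    epochs: EpochSet,
    k: int = 6,
    freqs: tuple[float, float] = (60.0, 64.0),
    interval: tuple[float, float] | None = None,
    halfwidth: float = DEFAULT_HALFWIDTH,
) -> list[str]:
    """The ``k`` channels with the strongest tag coherence across all trials.

    Coherence is averaged over the two tag frequencies and the interval
    during which both flicker patches are on screen (the experiment's
    selection interval by default).  Ties break deterministically by channel
    list order.
    """
    if k > len(epochs.channels):
        raise ValueError("k exceeds the number of channels")
    interval = interval or timing_for(epochs.experiment).selection_interval
    sl = epochs.time_slice(*interval)
    score = np.zeros(len(epochs.channels))
    for f in freqs:
        analytic = bandpass_hilbert(epochs, f, halfwidth)
        trace = coherence_timecourse(analytic)
        score += trace.coh[:, sl].mean(axis=1)
    score /= len(freqs)
    order = np.argsort(-score, kind="stable")
    return [epochs.channels[i] for i in order[:k]]


@dataclass
class ConditionContrast:
    """Cued / uncued coherence traces and their difference, one participant."""

    cued: np.ndarray
    uncued: np.ndarray
    times: np.ndarray
    valid: np.ndarray
    channels: list[str]

    @property
    def difference(self) -> np.ndarray:
        return self.cued - self.uncued


def condition_contrast(
    epochs: EpochSet,
    top_channels: list[str],
    freqs: tuple[float, float] = (60.0, 64.0),
    halfwidth: float = DEFAULT_HALFWIDTH,
) -> ConditionContrast:
    """Cued-vs-uncued coherence contrast, averaged over channels and frequencies.

    For each tag frequency the trials on which that frequency tagged the
    *cued* location contribute to the cued trace and the others to the
    uncued trace; traces are averaged over the supplied channels and then
    over the two frequencies.
    """
    if "freq_config" not in epochs.meta.columns:
        raise ValueError("trial metadata lacks the freq_config column")
    sub = epochs.pick_channels(top_channels)
    cued_traces, uncued_traces = [], []
    valid = None
    for f in freqs:
        analytic = bandpass_hilbert(sub, f, halfwidth)
        cued_mask = (sub.meta["cued_freq"] == f).to_numpy()
        uncued_mask = (sub.meta["uncued_freq"] == f).to_numpy()
        for mask, bucket in ((cued_mask, cued_traces), (uncued_mask, uncued_traces)):
            trace = coherence_timecourse(analytic, trials=mask)
            bucket.append(trace.coh.mean(axis=0))
            valid = trace.valid
    return ConditionContrast(
        cued=np.mean(cued_traces, axis=0),
        uncued=np.mean(uncued_traces, axis=0),
        times=epochs.times,
        valid=valid,
        channels=list(top_channels),
    )


def trialwise_rift_magnitude(
    analytic: AnalyticSignal,
    interval: tuple[float, float],
    channels: list[str] | None = None,
) -> np.ndarray:
    """Hilbert magnitude averaged over an interval and channels, per trial.

    The single-trial counterpart of coherence, used as the response variable
    of the trial-wise mixed model.
    """
    i0 = int(np.searchsorted(analytic.times, interval[0]))
    i1 = int(np.searchsorted(analytic.times, interval[1]))
    if i0 >= i1:
        raise ValueError("empty interval")
    ch_idx = (
        slice(None)
        if channels is None
        else [analytic.channels.index(c) for c in channels]
    )
    return analytic.magnitude[:, ch_idx, i0:i1].mean(axis=(1, 2))
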