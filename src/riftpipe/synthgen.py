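"""Synthetic generator for frequency-tagged EEG, gaze and behaviour.

The generator emulates the statistical structure the analysis stages assume:

- 64-channel EEG epochs at 2048 Hz containing two tagged oscillations (60 and
  64 Hz, one per hemifield location) phase-locked to cue onset, projected onto
  fixed contralateral posterior channel profiles;
- an attention-dependent amplitude gain on the cued location's tag;
- lateralized 8-13.5 Hz alpha activity with contralateral attenuation after
  the cue;
- 1/f background noise, optional 50 Hz line noise and occasional large
  transients;
- binocular gaze at 500 Hz with baseline offsets, blinks (NaN runs),
  cue-directed horizontal drift and occasional fixation breaks;
- per-trial metadata with a QUEST-staircased simulated observer.

It also implements the stimulus-side computations of the task: the radial
transparency mask of the flickering patches, the tagging waveform, and the
frame-timing exclusion rule of the 480 Hz projector.

Everything is driven by `numpy` Generators seeded from
``SimulationConfig.seed``; identical config + seed reproduces the dataset
bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from riftpipe.config import ConfigurationError, SimulationConfig
from riftpipe.containers import EpochSet, GazeSet
from riftpipe.layout import ChannelLayout
from riftpipe.quest import ObserverModel, QuestState, quest_recommend, quest_update
from riftpipe.timing import ExperimentTiming, timing_for

#: projector refresh rate (Hz); frame-timing tolerance is defined against it
FRAME_RATE = 480.0

FREQ_CONFIGS = ("60L/64R", "64L/60R")
SIDES = ("left", "right")


# ---------------------------------------------------------------------------
# stimulus-side computations
# ---------------------------------------------------------------------------

def transparency_mask(x, r):
    """Radial transparency of the circular flicker patch.

    ``T(x) = 1 / (1 + exp(-6 x / r))`` for a point at distance ``x`` from the
    patch center, rising from 0.5 (semi-transparent) at the center to ~1
    (opaque) at the circumference ``x = r``.
    """
    if r <= 0:
        raise ValueError("patch radius r must be > 0")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x > r):
        raise ValueError("distances x must lie in [0, r]")
    return 1.0 / (1.0 + np.exp(-6.0 * x / r))


def tagging_waveform(freq: float, duration: float, fs: float, phase_origin: float = 0.0):
    """Unit-amplitude luminance modulation, phase 0 at ``phase_origin``.

    Returns ``sin(2 pi f (t - phase_origin))`` sampled at ``fs`` for
    ``t = 0 .. duration`` (excluded endpoint).
    """
    if freq >= fs / 2:
        raise ValueError("tag frequency must be below the Nyquist rate")
    t = np.arange(int(round(duration * fs))) / fs
    return np.sin(2.0 * np.pi * freq * (t - phase_origin))


def flag_offtime_trials(frame_times, tolerance_ms: float = 4.0, frame_rate: float = FRAME_RATE):
    """Flag trials with any display frame further than ``tolerance_ms`` off-time.

    ``frame_times`` is a sequence of per-trial arrays of frame onset times in
    seconds.  Each trial's frames are compared against the nominal
    ``1/frame_rate`` grid anchored at its first frame; a trial is flagged iff
    any |actual - nominal| exceeds the tolerance.  Empty frame lists are
    flagged as invalid.
    """
    tol = tolerance_ms / 1000.0
    flags = np.zeros(len(frame_times), dtype=bool)
    for i, ft in enumerate(frame_times):
        ft = np.asarray(ft, dtype=float)
        if ft.size == 0:
            flags[i] = True
            continue
        nominal = ft[0] + np.arange(ft.size) / frame_rate
        flags[i] = bool(np.any(np.abs(ft - nominal) > tol))
    return flags


# ---------------------------------------------------------------------------
# trial schedule and behaviour
# ---------------------------------------------------------------------------

def build_trial_schedule(config: SimulationConfig, participant: int) -> pd.DataFrame:
    """Balanced, seeded trial schedule for one participant.

    Cue side and frequency-location assignment are fully counterbalanced
    (each of the 4 cells appears ``n_trials/4`` times) and shuffled by the
    participant's schedule RNG.  Trials are grouped into consecutive blocks
    of ``config.block_size``.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, participant, 0])
    n = config.n_trials
    cells = [(side, fc) for side in SIDES for fc in FREQ_CONFIGS]
    rows = np.repeat(np.arange(4), n // 4)
    rng.shuffle(rows)
    side = [cells[i][0] for i in rows]
    fcfg = [cells[i][1] for i in rows]
    lo, hi = config.tag_freqs
    freq_left = np.where(np.asarray(fcfg) == "60L/64R", lo, hi)
    freq_right = np.where(np.asarray(fcfg) == "60L/64R", hi, lo)
    cued = np.where(np.asarray(side) == "left", freq_left, freq_right)
    uncued = np.where(np.asarray(side) == "left", freq_right, freq_left)
    meta = pd.DataFrame(
        {
            "trial_id": np.arange(n),
            "participant_id": participant,
            "experiment": config.experiment,
            "block": np.arange(n) // config.block_size,
            "cue_side": side,
            "freq_config": fcfg,
            "cued_freq": cued,
            "uncued_freq": uncued,
        }
    )
    meta["probe_offset_deg"] = np.nan
    meta["response"] = "none"
    meta["correct"] = False
    for col in ("offtime_excluded", "artifact_excluded", "gaze_excluded"):
        meta[col] = False
    return meta


def simulate_behavior(
    meta: pd.DataFrame, config: SimulationConfig, participant: int
) -> tuple[pd.DataFrame, ObserverModel]:
    """Run the QUEST staircase through a schedule, filling probe/response columns.

    The observer's true threshold is drawn per participant (log-normal around
    15 deg).  Ten practice trials warm the staircase up before the recorded
    trials, mirroring the task structure; they are not part of the returned
    schedule.  A small fraction of trials receives no response.
    """
    rng = np.random.default_rng([config.seed, participant, 1])
    observer = ObserverModel(true_threshold_deg=float(15.0 * np.exp(rng.normal(0.0, 0.25))))
    state = QuestState.create()
    for _ in range(config.n_practice):
        x = quest_recommend(state)
        state = quest_update(state, x, observer.respond(x, rng))
    meta = meta.copy()
    offsets = np.empty(len(meta))
    responses = np.empty(len(meta), dtype=object)
    correct = np.zeros(len(meta), dtype=bool)
    for i in range(len(meta)):
        x = quest_recommend(state)
        is_correct = observer.respond(x, rng)
        state = quest_update(state, x, is_correct)
        sign = 1 if rng.random() < 0.5 else -1
        offsets[i] = sign * x
        if rng.random() < 0.003:  # missed-response trials
            responses[i] = "none"
            correct[i] = False
            continue
        true_dir = "cw" if sign > 0 else "ccw"
        other = "ccw" if true_dir == "cw" else "cw"
        responses[i] = true_dir if is_correct else other
        correct[i] = is_correct
    meta["probe_offset_deg"] = offsets
    meta["response"] = responses
    meta["correct"] = correct
    return meta, observer


def simulate_frame_times(
    meta: pd.DataFrame, config: SimulationConfig, participant: int
) -> list[np.ndarray]:
    """Per-trial projector frame onsets with rare off-time glitches."""
    rng = np.random.default_rng([config.seed, participant, 4])
    timing = timing_for(config.experiment)
    n_frames = int(round((timing.tag_interval[1] - timing.tag_interval[0]) * FRAME_RATE))
    out = []
    for _ in range(len(meta)):
        ft = np.arange(n_frames) / FRAME_RATE
        ft = ft + rng.normal(0.0, 2e-4, size=n_frames)  # ~0.2 ms render jitter
        if rng.random() < config.offtime_prob:
            ft[rng.integers(1, n_frames)] += rng.uniform(0.005, 0.010)
        out.append(ft)
    return out


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------

def epoch_time_axis(window: tuple[float, float], fs: float) -> np.ndarray:
    """Half-open [start, end) sample grid, matching the epoching stage."""
    i0 = int(round(window[0] * fs))
    i1 = int(round(window[1] * fs))
    return np.arange(i0, i1) / fs


def pink_noise(n_samples: int, n_series: int, exponent: float, rng: np.random.Generator):
    """1/f^exponent noise, unit variance per series, via spectral shaping."""
    white = rng.standard_normal((n_series, n_samples))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples)
    shape = np.ones_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    shape[0] = 0.0
    out = np.fft.irfft(spec * shape, n=n_samples, axis=-1)
    sd = out.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def _ramp(t: np.ndarray, onset: float, width: float = 0.3) -> np.ndarray:
    """Smooth 0 -> 1 transition starting at ``onset`` over ``width`` seconds."""
    return 1.0 / (1.0 + np.exp(-(t - onset - width / 2) * (8.0 / width)))


def simulate_eeg_trial(
    meta_row,
    config: SimulationConfig,
    rng: np.random.Generator,
    layout: ChannelLayout | None = None,
    timing: ExperimentTiming | None = None,
) -> np.ndarray:
    """One epoch (channels x time, microvolt) for a scheduled trial.

    Sum of: two tag sinusoids at the cued/uncued frequencies projected
    through fixed contralateral posterior profiles (cued amplitude scaled by
    ``attention_gain`` after the attention onset); lateralized alpha; 1/f
    noise; optional 50 Hz line noise; a rare large transient.
    """
    if config.attention_gain < 0:
        raise ConfigurationError("attention_gain must be >= 0")
    layout = layout or ChannelLayout()
    timing = timing or timing_for(config.experiment)
    t = epoch_time_axis(timing.epoch_window, config.fs_eeg)
    n_ch, n_t = layout.n_channels, t.size
    data = np.zeros((n_ch, n_t))

    lo, hi = config.tag_freqs
    freq_at = {"left": lo, "right": hi} if meta_row.freq_config == "60L/64R" else {"left": hi, "right": lo}
    tag_on = (t >= timing.tag_interval[0]) & (t < timing.tag_interval[1])
    jitter = rng.uniform(-config.onset_jitter_ms, config.onset_jitter_ms) / 1000.0
    gain_t = 1.0 + (config.attention_gain - 1.0) * _ramp(t, timing.attention_onset)
    for side in SIDES:
        freq = freq_at[side]
        amp = config.tag_amplitude * (config.tag_high_rel_amplitude if freq == hi else 1.0)
        wave = np.sin(2.0 * np.pi * freq * (t - jitter)) * tag_on
        envelope = gain_t if side == meta_row.cue_side else np.ones_like(t)
        data += np.outer(layout.tag_profile(side), amp * envelope * wave)

    contra = "right" if meta_row.cue_side == "left" else "left"
    for hemi in SIDES:
        amp = config.alpha_amplitude * float(np.exp(rng.normal(0.0, 0.2)))
        phase = rng.uniform(0.0, 2.0 * np.pi)
        freq = config.alpha_freq + rng.normal(0.0, 0.3)
        wave = np.sin(2.0 * np.pi * freq * t + phase)
        envelope = np.ones_like(t)
        if hemi == contra:
            envelope = 1.0 - (1.0 - config.alpha_lateralization) * _ramp(t, timing.attention_onset)
        data += np.outer(layout.alpha_profile(hemi), amp * envelope * wave)

    if config.noise_scale > 0:
        data += config.noise_scale * pink_noise(n_t, n_ch, config.noise_exponent, rng)
    if config.line_noise_amplitude > 0:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        data += config.line_noise_amplitude * np.sin(2.0 * np.pi * 50.0 * t + phase)[None, :]
    if config.artifact_prob > 0 and rng.random() < config.artifact_prob:
        ch = rng.integers(0, n_ch)
        center = rng.uniform(t[0] + 0.2, t[-1] - 0.2)
        data[ch] += 300.0 * np.exp(-0.5 * ((t - center) / 0.05) ** 2)
    return data


def simulate_eeg_epochs(
    meta: pd.DataFrame,
    config: SimulationConfig,
    participant: int,
    channels: list[str] | None = None,
) -> EpochSet:
    """All epochs of one participant as a float32 :class:`EpochSet`.

    ``channels`` optionally restricts the stored channels (the simulation is
    identical; unneeded rows are simply dropped), which keeps memory modest
    for large trial counts.
    """
    layout = ChannelLayout()
    timing = timing_for(config.experiment)
    rng = np.random.default_rng([config.seed, participant, 2])
    t = epoch_time_axis(timing.epoch_window, config.fs_eeg)
    keep = list(layout.names) if channels is None else list(channels)
    keep_idx = [layout.index(c) for c in keep]
    data = np.empty((len(meta), len(keep), t.size), dtype=np.float32)
    for i, row in enumerate(meta.itertuples(index=False)):
        trial = simulate_eeg_trial(row, config, rng, layout, timing)
        data[i] = trial[keep_idx]
    return EpochSet(
        data=data,
        times=t,
        fs=config.fs_eeg,
        channels=keep,
        meta=meta.reset_index(drop=True),
        experiment=config.experiment,
    )


# ---------------------------------------------------------------------------
# gaze
# ---------------------------------------------------------------------------

def _smooth_noise(n: int, fs: float, sd: float, rng: np.random.Generator, tau: float = 0.05):
    """Low-passed Gaussian noise (moving average over ~tau seconds)."""
    w = max(1, int(round(tau * fs)))
    raw = rng.standard_normal(n + w)
    kernel = np.ones(w) / w
    sm = np.convolve(raw, kernel, mode="valid")[:n]
    s = sm.std() or 1.0
    return sd * sm / s


def simulate_gaze_trial(
    meta_row,
    config: SimulationConfig,
    rng: np.random.Generator,
    timing: ExperimentTiming | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Binocular (2, time) x/y gaze traces in dva for one trial.

    The horizontal coordinate drifts toward the cued side after the cue with
    asymptote ``gaze_drift_dva``; blinks appear as NaN runs of 40-150 ms;
    with probability ``fixation_break_prob`` the trial contains a > 2 dva
    excursion longer than 50 ms.
    """
    timing = timing or timing_for(config.experiment)
    t = epoch_time_axis(timing.gaze_window, config.fs_gaze)
    n = t.size
    sign = 1.0 if meta_row.cue_side == "right" else -1.0
    drift = np.where(
        t > timing.attention_onset,
        config.gaze_drift_dva * (1.0 - np.exp(-np.clip(t - timing.attention_onset, 0, None) / 0.3)),
        0.0,
    )
    base_x = rng.normal(0.0, 0.25)
    base_y = rng.normal(0.0, 0.25)
    x = np.empty((2, n))
    y = np.empty((2, n))
    common_x = sign * drift + _smooth_noise(n, config.fs_gaze, config.gaze_noise_dva, rng)
    common_y = _smooth_noise(n, config.fs_gaze, config.gaze_noise_dva, rng)
    if rng.random() < config.fixation_break_prob:
        start = rng.uniform(t[0] + 0.2, t[-1] - 0.4)
        dur = rng.uniform(0.08, 0.25)
        amp = rng.uniform(2.5, 5.0) * (1 if rng.random() < 0.5 else -1)
        common_x = common_x + amp * ((t >= start) & (t < start + dur))
    eye_sd = 0.4 * config.gaze_noise_dva  # residual disagreement between the eyes
    for eye in range(2):
        x[eye] = base_x + common_x + _smooth_noise(n, config.fs_gaze, eye_sd, rng)
        y[eye] = base_y + common_y + _smooth_noise(n, config.fs_gaze, eye_sd, rng)
    # blinks: Poisson count over the trial, NaN in both eyes
    duration = t[-1] - t[0]
    for _ in range(rng.poisson(config.blink_rate * duration)):
        b0 = rng.uniform(t[0], t[-1] - 0.16)
        blen = rng.uniform(0.04, 0.15)
        mask = (t >= b0) & (t < b0 + blen)
        x[:, mask] = np.nan
        y[:, mask] = np.nan
    return x, y


def simulate_gaze_set(meta: pd.DataFrame, config: SimulationConfig, participant: int) -> GazeSet:
    timing = timing_for(config.experiment)
    rng = np.random.default_rng([config.seed, participant, 3])
    t = epoch_time_axis(timing.gaze_window, config.fs_gaze)
    x = np.empty((len(meta), 2, t.size))
    y = np.empty((len(meta), 2, t.size))
    for i, row in enumerate(meta.itertuples(index=False)):
        x[i], y[i] = simulate_gaze_trial(row, config, rng, timing)
    return GazeSet(x=x, y=y, times=t, fs=config.fs_gaze, meta=meta.reset_index(drop=True))


# ---------------------------------------------------------------------------
# participant-level bundle
# ---------------------------------------------------------------------------

@dataclass
class ParticipantData:
    participant: int
    epochs: EpochSet
    gaze: GazeSet
    frame_times: list
    observer: ObserverModel

    @property
    def meta(self) -> pd.DataFrame:
        return self.epochs.meta


def simulate_participant(
    config: SimulationConfig,
    participant: int,
    channels: list[str] | None = None,
    with_gaze: bool = True,
) -> ParticipantData:
    """Full synthetic dataset (EEG, gaze, behaviour, frame times) for one participant."""
    meta = build_trial_schedule(config, participant)
    meta, observer = simulate_behavior(meta, config, participant)
    frame_times = simulate_frame_times(meta, config, participant)
    meta["offtime_excluded"] = flag_offtime_trials(frame_times)
    epochs = simulate_eeg_epochs(meta, config, participant, channels=channels)
    gaze = (
        simulate_gaze_set(meta, config, participant)
        if with_gaze
        else GazeSet(
            x=np.empty((len(meta), 2, 0)),
            y=np.empty((len(meta), 2, 0)),
            times=np.empty(0),
            fs=config.fs_gaze,
            meta=meta,
        )
    )
    return ParticipantData(
        participant=participant, epochs=epochs, gaze=gaze, frame_times=frame_times, observer=observer
    )


def continuous_from_epochs(epochs: EpochSet, margin_s: float = 0.5) -> tuple[np.ndarray, pd.DataFrame]:
    """Lay epochs out back to back into a continuous recording with markers.

    Zero-valued margins pad each epoch (they only absorb filter edges); the
    returned events table maps each trial's alignment event (epoch time 0)
    to its sample index so the epoching stage can cut the exact epochs back
    out.
    """
    fs = epochs.fs
    n_margin = int(round(margin_s * fs))
    n_t = epochs.data.shape[2]
    i0 = int(round(epochs.times[0] * fs))
    n_trials = epochs.n_trials
    total = n_trials * (n_t + n_margin) + n_margin
    cont = np.zeros((len(epochs.channels), total), dtype=np.float32)
    samples = []
    pos = n_margin
    for i in range(n_trials):
        cont[:, pos : pos + n_t] = epochs.data[i]
        samples.append(pos - i0)
        pos += n_t + n_margin
    events = pd.DataFrame(
        {"sample": samples, "label": "cue", "trial_id": epochs.meta["trial_id"].to_numpy()}
    )
    return cont, events


def simulate_continuous(
    config: SimulationConfig, participant: int, margin_s: float = 0.5
) -> tuple[np.ndarray, pd.DataFrame, float, list[str]]:
    """Continuous recording (channels x samples) with cue-onset event markers."""
    part = simulate_participant(config, participant, with_gaze=False)
    cont, events = continuous_from_epochs(part.epochs, margin_s)
    return cont, events, config.fs_eeg, list(part.epochs.channels)
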