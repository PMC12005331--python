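"""Eye-tracking cleaning, exclusion rules and the horizontal gaze-bias contrast.

Gaze is recorded binocularly at 500 Hz in degrees of visual angle (dva).
Blinks appear as runs of missing (NaN) samples and are linearly
interpolated; traces are baseline-corrected against the 800 ms before the
alignment event.  Trials are excluded when gaze leaves a 2 dva fixation
window for more than 50 ms (cumulative) or when the trial baseline deviates
more than 2 SD from the participant's mean baseline; participants failing
fixation in more than half of their trials are excluded entirely.  The
attentional readout is the difference in horizontal position between
right-cued and left-cued trials, also expressed as a percentage of the 6 dva
stimulus eccentricity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from riftpipe.containers import GazeSet

#: horizontal eccentricity of the stimulus centers (dva)
STIMULUS_ECCENTRICITY_DVA = 6.0


def blink_interpolate(trace: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    """Linearly interpolate NaN runs bounded by valid samples.

    Returns ``(filled, missing_mask, edge_dropped)``.  Runs touching the
    trace edges cannot be interpolated; their samples stay NaN and
    ``edge_dropped`` is set.  A fully missing trace raises ``ValueError``.
    """
    trace = np.asarray(trace, dtype=float)
    missing = ~np.isfinite(trace)
    if missing.all():
        raise ValueError("trace is fully missing")
    filled = trace.copy()
    idx = np.arange(trace.size)
    valid = ~missing
    interp = np.interp(idx, idx[valid], trace[valid])
    # np.interp extrapolates edges as constants; keep interior runs only
    first, last = idx[valid][0], idx[valid][-1]
    interior = missing & (idx > first) & (idx < last)
    filled[interior] = interp[interior]
    edge_dropped = bool(missing[:first].any() or missing[last + 1 :].any())
    return filled, missing, edge_dropped


def gaze_baseline(
    trace: np.ndarray, times: np.ndarray, window: tuple[float, float] = (-0.8, 0.0)
) -> tuple[np.ndarray, float]:
    """Subtract the mean position in the pre-event window.

    Returns the corrected trace and the baseline value.  Raises if the
    window is fully missing.
    """
    mask = (times >= window[0]) & (times < window[1])
    if not mask.any():
        raise ValueError("baseline window outside the trial")
    seg = trace[mask]
    if not np.isfinite(seg).any():
        raise ValueError("baseline window fully missing")
    base = float(np.nanmean(seg))
    return trace - base, base


@dataclass
class GazeCleanResult:
    gaze: GazeSet
    baselines: np.ndarray  # (trials, 2) mean x/y baseline per trial
    flags: pd.DataFrame  # per-trial exclusion flags with reasons


def clean_gaze(gaze: GazeSet, baseline_window: tuple[float, float] = (-0.8, 0.0)) -> GazeCleanResult:
    """Blink-interpolate and baseline-correct every trial of a GazeSet."""
    x = gaze.x.copy()
    y = gaze.y.copy()
    n_tr = gaze.n_trials
    fully_missing = np.zeros(n_tr, dtype=bool)
    baselines = np.zeros((n_tr, 2))
    for i in range(n_tr):
        bx = by = 0.0
        try:
            for eye in range(x.shape[1]):
                x[i, eye], _, _ = blink_interpolate(x[i, eye])
                y[i, eye], _, _ = blink_interpolate(y[i, eye])
            mean_x = np.nanmean(x[i], axis=0)
            mean_y = np.nanmean(y[i], axis=0)
            _, bx = gaze_baseline(mean_x, gaze.times, baseline_window)
            _, by = gaze_baseline(mean_y, gaze.times, baseline_window)
            x[i] -= bx
            y[i] -= by
        except ValueError:
            fully_missing[i] = True
        baselines[i] = (bx, by)
    flags = pd.DataFrame({"trial_id": gaze.meta["trial_id"].to_numpy(), "fully_missing": fully_missing})
    cleaned = replace(gaze, x=x, y=y, meta=gaze.meta.copy())
    return GazeCleanResult(gaze=cleaned, baselines=baselines, flags=flags)


def exclude_gaze_trials(
    cleaned: GazeCleanResult,
    fixation_radius_dva: float = 2.0,
    max_off_fixation_s: float = 0.050,
    baseline_sd_limit: float = 2.0,
) -> pd.DataFrame:
    """Per-trial gaze exclusion flags.

    A trial is flagged when (a) the cumulative time with gaze (binocular
    mean, baseline-corrected) further than ``fixation_radius_dva`` from
    fixation exceeds ``max_off_fixation_s``, or (b) its raw baseline lies
    more than ``baseline_sd_limit`` SDs from the participant's mean
    baseline.  Fully missing trials are always flagged.
    """
    gaze = cleaned.gaze
    dt = 1.0 / gaze.fs
    n_tr = gaze.n_trials
    off_fix = np.zeros(n_tr, dtype=bool)
    for i in range(n_tr):
        mx = np.nanmean(gaze.x[i], axis=0)
        my = np.nanmean(gaze.y[i], axis=0)
        dist = np.hypot(mx, my)
        off_time = np.count_nonzero(dist > fixation_radius_dva) * dt
        off_fix[i] = off_time > max_off_fixation_s
    base = cleaned.baselines
    mean_b = base.mean(axis=0)
    sd_b = base.std(axis=0, ddof=1)
    sd_b[sd_b == 0] = np.inf
    base_dev = np.abs(base - mean_b) / sd_b
    base_flag = (base_dev > baseline_sd_limit).any(axis=1)
    flagged = off_fix | base_flag | cleaned.flags["fully_missing"].to_numpy()
    return pd.DataFrame(
        {
            "trial_id": gaze.meta["trial_id"].to_numpy(),
            "off_fixation": off_fix,
            "baseline_outlier": base_flag,
            "fully_missing": cleaned.flags["fully_missing"].to_numpy(),
            "gaze_excluded": flagged,
        }
    )


def participant_fixation_failure(flags: pd.DataFrame, max_fraction: float = 0.5) -> bool:
    """True when more than half of the trials fail the fixation criterion."""
    return bool(flags["gaze_excluded"].mean() > max_fraction)


def smooth_uniform(trace: np.ndarray, fs: float, width_s: float = 0.010) -> np.ndarray:
    """Centered moving average of ``width_s`` (10 ms -> 5 samples at 500 Hz)."""
    w = max(1, int(round(width_s * fs)))
    kernel = np.ones(w) / w
    return np.apply_along_axis(lambda v: np.convolve(v, kernel, mode="same"), -1, trace)


@dataclass
class GazeBias:
    """Right-cued minus left-cued horizontal gaze position over time."""

    bias_dva: np.ndarray
    times: np.ndarray

    @property
    def bias_percent(self) -> np.ndarray:
        """Bias as % of the fixation-to-stimulus eccentricity (6 dva)."""
        return self.bias_dva / STIMULUS_ECCENTRICITY_DVA * 100.0


def horizontal_bias(
    cleaned: GazeCleanResult,
    flags: pd.DataFrame | None = None,
    smooth_s: float = 0.010,
) -> GazeBias:
    """Cue-direction contrast of the horizontal gaze position.

    Both eyes are averaged into one horizontal trace per trial; excluded
    trials (if ``flags`` given) are dropped; the right-cued mean minus the
    left-cued mean is smoothed with a 10 ms uniform filter.
    """
    gaze = cleaned.gaze
    keep = np.ones(gaze.n_trials, dtype=bool)
    if flags is not None:
        keep = ~flags["gaze_excluded"].to_numpy()
    sides = gaze.meta["cue_side"].to_numpy()
    mono = np.nanmean(gaze.x, axis=1)  # (trials, time)
    right = mono[keep & (sides == "right")]
    left = mono[keep & (sides == "left")]
    if len(right) == 0 or len(left) == 0:
        raise ValueError("both cue-side conditions must have surviving trials")
    bias = np.nanmean(right, axis=0) - np.nanmean(left, axis=0)
    bias = smooth_uniform(bias, gaze.fs, smooth_s)
    return GazeBias(bias_dva=bias, times=gaze.times)


def trialwise_gaze_bias(
    cleaned: GazeCleanResult, interval: tuple[float, float], smooth_s: float = 0.010
) -> np.ndarray:
    """Signed horizontal position toward the cued side, one value per trial.

    Interval-averaged binocular x position, sign-flipped on left-cued trials
    so that positive always means 'toward the cued location'.
    """
    gaze = cleaned.gaze
    sl = gaze.time_slice(*interval)
    mono = smooth_uniform(np.nanmean(gaze.x, axis=1), gaze.fs, smooth_s)
    vals = np.nanmean(mono[:, sl], axis=1)
    sides = gaze.meta["cue_side"].to_numpy()
    return np.where(sides == "right", vals, -vals)
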