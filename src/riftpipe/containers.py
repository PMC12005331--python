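"""In-memory containers shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class EpochSet:
    """Epoched EEG: ``data[trial, channel, time]`` with linked trial metadata.

    ``times`` holds the epoch time axis in seconds (0 = alignment event) and
    ``meta`` one row per trial, aligned with the first axis of ``data``.
    """

    data: np.ndarray
    times: np.ndarray
    fs: float
    channels: list[str]
    meta: pd.DataFrame
    experiment: str = ""

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("EpochSet.data must be (trials, channels, time)")
        n_tr, n_ch, n_t = self.data.shape
        if len(self.times) != n_t:
            raise ValueError("times length does not match data")
        if len(self.channels) != n_ch:
            raise ValueError("channel labels do not match data")
        if len(self.meta) != n_tr:
            raise ValueError("metadata rows do not match trial count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def time_slice(self, t_start: float, t_stop: float) -> slice:
        """Sample slice covering [t_start, t_stop) of the epoch time axis."""
        i0 = int(np.searchsorted(self.times, t_start, side="left"))
        i1 = int(np.searchsorted(self.times, t_stop, side="left"))
        if i0 >= i1:
            raise ValueError(f"window ({t_start}, {t_stop}) s is empty for this epoch")
        return slice(i0, i1)

    def pick_channels(self, names: Sequence[str]) -> "EpochSet":
        idx = [self.channels.index(n) for n in names]
        return replace(
            self,
            data=self.data[:, idx, :],
            channels=[self.channels[i] for i in idx],
            meta=self.meta.copy(),
        )

    def select_trials(self, mask) -> "EpochSet":
        mask = np.asarray(mask)
        return replace(
            self,
            data=self.data[mask],
            meta=self.meta.loc[mask].reset_index(drop=True),
        )


@dataclass
class GazeSet:
    """Binocular gaze: ``x``/``y`` of shape (trials, eyes, time) in dva.

    Blinks are NaN runs in the traces; ``times`` is relative to the same
    alignment event as the EEG epochs.
    """

    x: np.ndarray
    y: np.ndarray
    times: np.ndarray
    fs: float
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.x.shape != self.y.shape or self.x.ndim != 3:
            raise ValueError("GazeSet traces must be (trials, eyes, time)")
        if len(self.meta) != self.x.shape[0]:
            raise ValueError("metadata rows do not match trial count")

    @property
    def n_trials(self) -> int:
        return self.x.shape[0]

    def time_slice(self, t_start: float, t_stop: float) -> slice:
        i0 = int(np.searchsorted(self.times, t_start, side="left"))
        i1 = int(np.searchsorted(self.times, t_stop, side="left"))
        if i0 >= i1:
            raise ValueError(f"window ({t_start}, {t_stop}) s is empty")
        return slice(i0, i1)


@dataclass
class AnalyticSignal:
    """Per-trial analytic magnitude and phase of a narrowband signal."""

    magnitude: np.ndarray  # (trials, channels, time), >= 0
    phase: np.ndarray  # (trials, channels, time), in (-pi, pi]
    times: np.ndarray
    fs: float
    channels: list[str]
    center_freq: float
    halfwidth: float
    #: boolean mask over time; True where the zero-phase filter has settled
    valid: np.ndarray = None

    @property
    def valid_slice(self) -> slice:
        idx = np.flatnonzero(self.valid)
        if idx.size == 0:
            raise ValueError("no valid samples away from filter edges")
        return slice(int(idx[0]), int(idx[-1]) + 1)


@dataclass
class CoherenceTrace:
    """Trial-set coherence over time for one reference frequency."""

    coh: np.ndarray  # (channels, time) in [0, 1]
    times: np.ndarray
    fs: float
    channels: list[str]
    frequency: float
    n_trials: int
    condition: str = ""
    valid: np.ndarray = None


@dataclass
class Cluster:
    start_s: float
    end_s: float
    t_mass: float
    p: float
    significant: bool

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class ClusterResult:
    """Output of the cluster-based sign-flip permutation test."""

    clusters: list[Cluster]
    t_trace: np.ndarray
    p_trace: np.ndarray
    times: np.ndarray
    n_permutations: int
    percentile: float
    null_threshold: float
    min_duration_s: float

    @property
    def significant_clusters(self) -> list[Cluster]:
        return [c for c in self.clusters if c.significant]


@dataclass
class MeanDiffResult:
    """Output of the bootstrap test of the difference between two means."""

    observed: float
    ci_low: float
    ci_high: float
    p: float
    n_boot: int
    boot_mean: float
    boot_std: float

    @property
    def significant(self) -> bool:
        return self.ci_low > 0 or self.ci_high < 0
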