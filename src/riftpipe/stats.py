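"""Resampling statistics: cluster-based permutation test and bootstrap mean test.

Two procedures:

1. :func:`cluster_permutation_test` — the four-step sign-flip cluster test
   for participant-level difference traces: (i) pointwise one-sample
   t-tests, (ii) clusters of consecutively significant samples longer than
   10 ms summarized by their t-mass, (iii) a null distribution of the
   maximum |t-mass| from sign-flipped datasets, (iv) clusters accepted when
   their |t-mass| exceeds the 95th percentile of that null.

2. :func:`bootstrap_mean_difference` — bootstrap resampling of two sets of
   per-participant values; the difference of the two sample means is drawn
   repeatedly and the sets are declared different when the 95 % percentile
   interval of that distribution excludes zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sstats

from riftpipe.containers import Cluster, ClusterResult, MeanDiffResult


def _clusters_from_mask(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, stop) index pairs of True runs; stop is exclusive."""
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def _cluster_masses(t: np.ndarray, crit: float, min_samples: int) -> list[tuple[int, int, float]]:
    """Signed t-mass of every positive and negative cluster in one trace."""
    out = []
    for sign in (1.0, -1.0):
        mask = sign * t > crit
        for start, stop in _clusters_from_mask(mask):
            if stop - start >= min_samples:
                out.append((start, stop, float(t[start:stop].sum())))
    return out


def _max_masses_batch(t_batch: np.ndarray, crit: float, min_samples: int) -> np.ndarray:
    """Maximum |t-mass| per row of a (permutations, time) t matrix.

    Rows without any qualifying cluster contribute 0.  Vectorized run-length
    pass over the flattened matrix (a padding column separates rows).
    """
    n_perm, n_t = t_batch.shape
    best = np.zeros(n_perm)
    pad = np.zeros((n_perm, 1), dtype=bool)
    for sign in (1.0, -1.0):
        mask = np.hstack([sign * t_batch > crit, pad]).ravel()
        padded = np.concatenate(([False], mask))
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        starts, stops = edges[::2], edges[1::2]
        flat = np.hstack([t_batch, np.zeros((n_perm, 1))]).ravel()
        csum = np.concatenate(([0.0], np.cumsum(flat)))
        masses = csum[stops] - csum[starts]
        rows = starts // (n_t + 1)
        keep = (stops - starts) >= min_samples
        np.maximum.at(best, rows[keep], np.abs(masses[keep]))
    return best


def min_cluster_samples(fs: float, min_duration_s: float = 0.010) -> int:
    """Smallest run length whose duration strictly exceeds ``min_duration_s``."""
    k = int(np.floor(min_duration_s * fs)) + 1
    return max(k, 1)


def cluster_permutation_test(
    diff_traces: np.ndarray,
    fs: float,
    times: np.ndarray | None = None,
    alpha_point: float = 0.05,
    min_duration_s: float = 0.010,
    n_permutations: int = 10000,
    percentile: float = 95.0,
    seed: int = 0,
) -> ClusterResult:
    """Sign-flip cluster permutation test on (participants, time) difference traces.

    Pointwise two-sided one-sample t-tests at ``alpha_point`` define
    candidate clusters (consecutive significant samples spanning strictly
    more than ``min_duration_s``); the null distribution is the maximum
    |t-mass| over ``n_permutations`` random sign flips of the participant
    traces.  A cluster is significant when its |t-mass| exceeds the
    ``percentile``-th percentile of the null; its p-value is
    ``(1 + #{null >= observed}) / (n_permutations + 1)``.
    """
    X = np.asarray(diff_traces, dtype=float)
    if X.ndim != 2:
        raise ValueError("diff_traces must be (participants, time)")
    n_p, n_t = X.shape
    if n_p < 2:
        raise ValueError("need at least 2 participants")
    if times is None:
        times = np.arange(n_t) / fs
    if len(times) != n_t:
        raise ValueError("traces and time axis have unequal length")

    def _tstat(mean, sq_mean, n):
        var = (sq_mean - mean**2) * n / (n - 1)
        se = np.sqrt(np.maximum(var, 0.0) / n)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = np.where(se > 0, mean / np.where(se > 0, se, 1.0), 0.0)
        return t

    sq_mean = (X**2).mean(axis=0)
    t_obs = _tstat(X.mean(axis=0), sq_mean, n_p)
    crit = float(sstats.t.ppf(1.0 - alpha_point / 2.0, df=n_p - 1))
    p_trace = 2.0 * sstats.t.sf(np.abs(t_obs), df=n_p - 1)
    k_min = min_cluster_samples(fs, min_duration_s)
    observed = _cluster_masses(t_obs, crit, k_min)

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_permutations, n_p))
    # sign flips leave per-participant squares unchanged: only the mean moves
    perm_means = signs @ X / n_p
    t_perm = _tstat(perm_means, sq_mean[None, :], n_p)
    null_max = _max_masses_batch(t_perm, crit, k_min)
    threshold = float(np.percentile(null_max, percentile))

    clusters = []
    for start, stop, mass in observed:
        p = (1.0 + np.count_nonzero(null_max >= abs(mass))) / (n_permutations + 1.0)
        clusters.append(
            Cluster(
                start_s=float(times[start]),
                end_s=float(times[stop - 1] + 1.0 / fs),
                t_mass=mass,
                p=float(p),
                significant=bool(abs(mass) > threshold),
            )
        )
    clusters.sort(key=lambda c: c.start_s)
    return ClusterResult(
        clusters=clusters,
        t_trace=t_obs,
        p_trace=p_trace,
        times=np.asarray(times, dtype=float),
        n_permutations=n_permutations,
        percentile=percentile,
        null_threshold=threshold,
        min_duration_s=min_duration_s,
    )


def bootstrap_mean_difference(
    set_a,
    set_b,
    n_boot: int = 5000,
    seed: int = 0,
    ci: float = 95.0,
) -> MeanDiffResult:
    """Bootstrap distribution of mean(A) - mean(B) with a percentile CI.

    Each repetition resamples both sets with replacement and records the
    difference of the sample means.  Significance = the CI excludes zero;
    the two-sided p-value is twice the smaller tail of the bootstrap
    distribution relative to zero (never exactly zero).
    """
    a = np.asarray(set_a, dtype=float)
    b = np.asarray(set_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each set needs at least 2 values")
    rng = np.random.default_rng(seed)
    ia = rng.integers(0, a.size, size=(n_boot, a.size))
    ib = rng.integers(0, b.size, size=(n_boot, b.size))
    diffs = a[ia].mean(axis=1) - b[ib].mean(axis=1)
    lo = float(np.percentile(diffs, (100 - ci) / 2))
    hi = float(np.percentile(diffs, 100 - (100 - ci) / 2))
    frac_low = (1.0 + np.count_nonzero(diffs <= 0)) / (n_boot + 1.0)
    frac_high = (1.0 + np.count_nonzero(diffs >= 0)) / (n_boot + 1.0)
    p = float(min(1.0, 2.0 * min(frac_low, frac_high)))
    return MeanDiffResult(
        observed=float(a.mean() - b.mean()),
        ci_low=lo,
        ci_high=hi,
        p=p,
        n_boot=n_boot,
        boot_mean=float(diffs.mean()),
        boot_std=float(diffs.std(ddof=1)),
    )


def behavioral_summary(meta: pd.DataFrame) -> dict:
    """Accuracy over responded, non-excluded trials, per participant and group.

    Returns per-participant percent correct plus the group mean and median.
    """
    if "response" not in meta.columns:
        raise ValueError("metadata lacks a response column")
    excl_cols = [c for c in ("offtime_excluded", "artifact_excluded", "gaze_excluded") if c in meta]
    usable = meta["response"].ne("none")
    for c in excl_cols:
        usable &= ~meta[c].astype(bool)
    sub = meta.loc[usable]
    per = sub.groupby("participant_id")["correct"].mean() * 100.0
    return {
        "per_participant": per.to_dict(),
        "mean": float(per.mean()),
        "median": float(per.median()),
        "n_trials_used": int(len(sub)),
    }
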