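"""Trial-wise feature tables and linear mixed-effects models.

The three attentional readouts (trial-wise RIFT Hilbert magnitude, alpha
lateralization, gaze bias) are assembled into one table per experiment and
related by two mixed models:

    rift_response ~ 1 + cued + freq_high + gaze_bias + alpha_lat
                    + (1 + predictors | participant)
    alpha_lat     ~ 1 + rift_response + gaze_bias
                    + (1 + predictors | participant)

For the RIFT model each clean trial contributes two rows, one per tag
frequency, with ``cued`` marking whether that frequency tagged the cued
location.  Feature construction is implemented here; the REML fit is
delegated to :class:`statsmodels` MixedLM.  When the full random-slope
structure fails to converge the model is refit with random intercepts only,
and the simplification is reported in the result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


def assemble_features(
    meta: pd.DataFrame,
    rift_by_freq: dict[float, np.ndarray],
    alpha_trialwise: np.ndarray,
    gaze_trialwise: np.ndarray,
    intervals: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Long feature table: one row per clean trial and tag frequency.

    ``rift_by_freq`` maps each tag frequency to a per-trial magnitude array
    (aligned with ``meta``); ``alpha_trialwise`` / ``gaze_trialwise`` are
    per-trial.  Trials excluded upstream (off-time, artifact, gaze) are
    dropped.  ``intervals`` records which averaging windows produced the
    features and is stored in ``DataFrame.attrs`` for provenance.
    """
    n = len(meta)
    for name, arr in {"alpha": alpha_trialwise, "gaze": gaze_trialwise}.items():
        if len(arr) != n:
            raise ValueError(f"{name} feature length does not match metadata")
    excl = np.zeros(n, dtype=bool)
    for col in ("offtime_excluded", "artifact_excluded", "gaze_excluded"):
        if col in meta.columns:
            excl |= meta[col].to_numpy().astype(bool)
    rows = []
    freqs = sorted(rift_by_freq)
    for f in freqs:
        mags = np.asarray(rift_by_freq[f], dtype=float)
        if len(mags) != n:
            raise ValueError("rift feature length does not match metadata")
        part = pd.DataFrame(
            {
                "participant_id": meta["participant_id"].to_numpy(),
                "trial_id": meta["trial_id"].to_numpy(),
                "frequency": f,
                "cued": (meta["cued_freq"].to_numpy() == f).astype(int),
                "rift_response": mags,
                "alpha_lat": np.asarray(alpha_trialwise, dtype=float),
                "gaze_bias": np.asarray(gaze_trialwise, dtype=float),
            }
        )
        rows.append(part.loc[~excl])
    table = pd.concat(rows, ignore_index=True)
    table["freq_high"] = (table["frequency"] == max(freqs)).astype(int)
    table.attrs["intervals"] = dict(intervals or {})
    table.attrs["n_trials_dropped"] = int(excl.sum())
    return table


def _zscore_within_participant(table: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    out = table.copy()
    for col in columns:
        if np.isclose(out[col].std(ddof=0), 0.0):
            raise ValueError(f"predictor {col!r} has zero variance; degenerate design")
        grouped = out.groupby("participant_id")[col]
        sd = grouped.transform("std").replace(0.0, np.nan)
        out[col] = ((out[col] - grouped.transform("mean")) / sd).fillna(0.0)
    return out


@dataclass
class MixedModelResult:
    """Fixed effects of a fitted mixed model with 95 % CIs."""

    params: pd.Series
    ci: pd.DataFrame  # columns lo, hi
    converged: bool
    random_structure: str
    formula: str

    def coefficient(self, name: str) -> tuple[float, float, float]:
        """(estimate, ci_low, ci_high) for one fixed effect."""
        return float(self.params[name]), float(self.ci.loc[name, "lo"]), float(
            self.ci.loc[name, "hi"]
        )

    def to_dict(self) -> dict:
        return {
            name: {
                "estimate": float(self.params[name]),
                "ci_low": float(self.ci.loc[name, "lo"]),
                "ci_high": float(self.ci.loc[name, "hi"]),
            }
            for name in self.params.index
        }


def _fit_mixed(table: pd.DataFrame, response: str, predictors: list[str]) -> MixedModelResult:
    import statsmodels.formula.api as smf
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    if table["participant_id"].nunique() < 2:
        raise ValueError("mixed model needs at least 2 participants")
    continuous = [p for p in predictors if p not in ("cued", "freq_high")]
    data = _zscore_within_participant(table, continuous)
    for col in ("cued", "freq_high"):
        if col in predictors and data[col].nunique() < 2:
            raise ValueError(f"predictor {col!r} has zero variance; degenerate design")
    formula = f"{response} ~ {' + '.join(predictors)}"
    re_full = "1 + " + " + ".join(predictors)

    def try_fit(re_formula: str):
        model = smf.mixedlm(formula, data, groups=data["participant_id"], re_formula=re_formula)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", UserWarning)
            res = model.fit(reml=True, method="lbfgs", maxiter=200)
        return res

    def sane(res) -> bool:
        # a diverged REML run can report convergence with absurd estimates;
        # with within-participant z-scored predictors, honest fixed effects
        # are O(1)
        return (
            bool(res.converged)
            and np.all(np.isfinite(res.bse_fe))
            and np.all(np.abs(np.asarray(res.fe_params)) < 1e3)
        )

    structure = "slopes"
    try:
        res = try_fit(re_full)
        ok = sane(res)
    except (np.linalg.LinAlgError, ValueError):
        ok = False
        res = None
    if not ok:
        structure = "intercept-only"
        res = try_fit("1")
    fe_names = list(res.fe_params.index)
    ci_all = res.conf_int()
    ci = ci_all.loc[fe_names]
    ci.columns = ["lo", "hi"]
    return MixedModelResult(
        params=res.fe_params,
        ci=ci,
        converged=bool(res.converged),
        random_structure=structure,
        formula=formula,
    )


def fit_rift_model(table: pd.DataFrame) -> MixedModelResult:
    """Mixed model of the trial-wise RIFT magnitude.

    Fixed effects: cued/uncued indicator, tag frequency (high vs low), gaze
    bias and alpha lateralization; random intercept (and slopes when they
    converge) per participant.  Continuous predictors are z-scored within
    participant before fitting.
    """
    return _fit_mixed(table, "rift_response", ["cued", "freq_high", "gaze_bias", "alpha_lat"])


def fit_alpha_model(table: pd.DataFrame) -> MixedModelResult:
    """Mixed model of trial-wise alpha lateralization.

    Uses one row per trial (the RIFT response averaged over the two tag
    frequencies) with the RIFT magnitude and the gaze bias as predictors.
    """
    per_trial = (
        table.groupby(["participant_id", "trial_id"])
        .agg(
            rift_response=("rift_response", "mean"),
            alpha_lat=("alpha_lat", "first"),
            gaze_bias=("gaze_bias", "first"),
        )
        .reset_index()
    )
    return _fit_mixed(per_trial, "alpha_lat", ["rift_response", "gaze_bias"])
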