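"""Bayesian adaptive staircase (QUEST) and the simulated Weibull observer.

The staircase maintains a posterior over the log-threshold of a Weibull
psychometric function (slope ``beta`` = 3.5, lapse ``delta`` = 0.01, guess
rate ``gamma`` = 0.5 for the 2AFC orientation task) and places each trial at
the posterior-mean threshold estimate.  Following the PsychToolbox
convention, the psychometric function is shifted so that performance at the
threshold itself equals the staircase's target probability (75 % correct
here); posterior-mean placement therefore drives accuracy toward that
target.

Intensities are probe orientation offsets in degrees; internally everything
is on a log10 scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

#: probe offset range of the task, degrees
INTENSITY_MIN_DEG = 3.0
INTENSITY_MAX_DEG = 50.0


def _weibull_shift(target: float, beta: float, delta: float, gamma: float) -> float:
    """Log10 shift making p(correct at x = threshold) equal ``target``."""
    inner = (1.0 - (target - delta * gamma) / (1.0 - delta)) / (1.0 - gamma)
    if not 0.0 < inner < 1.0:
        raise ValueError("target probability out of the psychometric range")
    return math.log10(-math.log(inner))


def weibull_p_correct(
    log_intensity,
    log_threshold,
    beta: float = 3.5,
    delta: float = 0.01,
    gamma: float = 0.5,
    target: float = 0.75,
):
    """Probability of a correct response under the shifted Weibull model.

    Bounded in [gamma*delta + ...]; more precisely it rises from ``gamma``
    (far below threshold) to ``1 - delta*(1 - gamma)`` (far above), passing
    through ``target`` exactly at ``log_intensity == log_threshold``.
    """
    shift = _weibull_shift(target, beta, delta, gamma)
    expo = np.power(10.0, beta * (np.asarray(log_intensity) - log_threshold) + shift)
    return delta * gamma + (1.0 - delta) * (1.0 - (1.0 - gamma) * np.exp(-expo))


@dataclass(frozen=True)
class ObserverModel:
    """Simulated participant with a Weibull psychometric function."""

    true_threshold_deg: float = 15.0
    beta: float = 3.5
    delta: float = 0.01
    gamma: float = 0.5
    target: float = 0.75

    def p_correct(self, intensity_deg):
        return weibull_p_correct(
            np.log10(np.asarray(intensity_deg, dtype=float)),
            math.log10(self.true_threshold_deg),
            self.beta,
            self.delta,
            self.gamma,
            self.target,
        )

    def respond(self, intensity_deg: float, rng: np.random.Generator) -> bool:
        return bool(rng.random() < self.p_correct(intensity_deg))


@dataclass
class QuestState:
    """Posterior over the log10 threshold plus the trial history."""

    grid: np.ndarray  # log10 degrees
    posterior: np.ndarray  # normalized weights over grid
    beta: float = 3.5
    delta: float = 0.01
    gamma: float = 0.5
    target: float = 0.75
    history: list = field(default_factory=list)

    @classmethod
    def create(
        cls,
        grid_range_deg: tuple[float, float] = (1.0, 60.0),
        n_grid: int = 256,
        prior_mean_deg: float = 15.0,
        prior_sd_log10: float = 0.5,
        beta: float = 3.5,
        delta: float = 0.01,
        gamma: float = 0.5,
        target: float = 0.75,
    ) -> "QuestState":
        """Log-spaced grid with a Gaussian prior in log10 units.

        The default prior SD of 0.5 log10 units corresponds to 10 dB on the
        20*log10 amplitude scale.
        """
        grid = np.linspace(math.log10(grid_range_deg[0]), math.log10(grid_range_deg[1]), n_grid)
        prior = np.exp(-0.5 * ((grid - math.log10(prior_mean_deg)) / prior_sd_log10) ** 2)
        prior /= prior.sum()
        return cls(grid=grid, posterior=prior, beta=beta, delta=delta, gamma=gamma, target=target)

    @property
    def mean_log_threshold(self) -> float:
        return float(np.dot(self.posterior, self.grid))

    @property
    def threshold_estimate_deg(self) -> float:
        return float(10.0 ** self.mean_log_threshold)

    def entropy(self) -> float:
        p = self.posterior[self.posterior > 0]
        return float(-np.sum(p * np.log(p)))


def quest_update(state: QuestState, intensity_deg: float, correct: bool) -> QuestState:
    """Bayesian update of the threshold posterior after one response.

    The posterior is multiplied by the Weibull likelihood of the observed
    response at the presented intensity and renormalized.
    """
    x = math.log10(intensity_deg)
    p_corr = weibull_p_correct(x, state.grid, state.beta, state.delta, state.gamma, state.target)
    like = p_corr if correct else 1.0 - p_corr
    post = state.posterior * like
    total = post.sum()
    if not np.isfinite(total) or total <= 0.0:
        raise FloatingPointError(
            "QUEST posterior lost all mass after update; intensity far outside the grid?"
        )
    return replace(
        state,
        posterior=post / total,
        history=state.history + [(float(intensity_deg), bool(correct))],
    )


def quest_recommend(state: QuestState) -> float:
    """Next probe intensity: posterior-mean threshold, clamped to 3-50 deg."""
    return float(np.clip(state.threshold_estimate_deg, INTENSITY_MIN_DEG, INTENSITY_MAX_DEG))


@dataclass
class SessionResult:
    intensities: np.ndarray
    responses: np.ndarray
    final_state: QuestState

    @property
    def proportion_correct(self) -> float:
        return float(np.mean(self.responses))

    def late_accuracy(self, n_last: int = 300) -> float:
        return float(np.mean(self.responses[-n_last:]))


def simulate_session(
    observer: ObserverModel,
    n_trials: int = 480,
    seed: int | np.random.Generator = 0,
    state: QuestState | None = None,
) -> SessionResult:
    """Closed-loop staircase: recommend -> observer responds -> update."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if state is None:
        state = QuestState.create(
            beta=observer.beta, delta=observer.delta, gamma=observer.gamma, target=observer.target
        )
    intensities = np.empty(n_trials)
    responses = np.empty(n_trials, dtype=bool)
    for i in range(n_trials):
        x = quest_recommend(state)
        r = observer.respond(x, rng)
        state = quest_update(state, x, r)
        intensities[i] = x
        responses[i] = r
    return SessionResult(intensities=intensities, responses=responses, final_state=state)
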