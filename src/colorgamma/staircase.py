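"""QUEST Bayesian adaptive staircase targeting 85% correct.

The threshold parameter lives on a log10-contrast grid; the psychometric
family is the same 2AFC Weibull used by the simulated observer, anchored so
that performance at the threshold equals the target probability.  Trials are
placed at the posterior-mean threshold estimate (QUEST+-style mean rather
than mode).  The study's behavioral read-out is the arithmetic mean of the
last 10 presented intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import weibull_p_correct


@dataclass(frozen=True)
class QuestState:
    grid: np.ndarray  # log10 contrast support
    posterior: np.ndarray  # probability mass, sums to 1
    beta: float = 3.5
    gamma_guess: float = 0.5
    delta_lapse: float = 0.01
    target_p: float = 0.85
    history: tuple = ()  # (intensity, response) pairs

    def __post_init__(self):
        if not self.gamma_guess < self.target_p < 1.0:
            raise ValueError("target_p must lie in (guess rate, 1)")
        if not np.isclose(self.posterior.sum(), 1.0, atol=1e-9):
            raise ValueError("posterior must sum to 1")


def make_quest_state(
    grid_lo: float = -3.0,
    grid_hi: float = 0.0,
    n_grid: int = 200,
    prior_mean: float = -0.7,
    prior_sd: float = 0.5,
    beta: float = 3.5,
    delta_lapse: float = 0.01,
    target_p: float = 0.85,
) -> QuestState:
    """Fresh state: Gaussian prior in log10 contrast on a 200-point grid."""
    grid = np.linspace(grid_lo, grid_hi, n_grid)
    prior = stats.norm.pdf(grid, prior_mean, prior_sd)
    return QuestState(grid, prior / prior.sum(), beta=beta,
                      delta_lapse=delta_lapse, target_p=target_p)


def _p_correct_grid(state: QuestState, intensity: float) -> np.ndarray:
    """P(correct | intensity, threshold) across the threshold grid."""
    return weibull_p_correct(
        intensity, 10.0 ** state.grid, state.beta, state.gamma_guess,
        state.delta_lapse, state.target_p,
    )


def quest_update(state: QuestState, intensity: float, response) -> QuestState:
    """Bayes update: multiply by the response likelihood, renormalize."""
    if not isinstance(response, (bool, np.bool_)):
        raise TypeError("response must be boolean")
    if not 10.0 ** state.grid[0] <= intensity <= 10.0 ** state.grid[-1] + 1e-12:
        raise ValueError("intensity outside the grid range")
    p = _p_correct_grid(state, intensity)
    like = p if response else 1.0 - p
    post = state.posterior * like
    total = post.sum()
    if total <= 0:
        raise ValueError("degenerate posterior: zero likelihood everywhere")
    return replace(
        state,
        posterior=post / total,
        history=state.history + ((float(intensity), bool(response)),),
    )


def quest_next_intensity(state: QuestState) -> float:
    """Posterior-mean threshold estimate (in contrast units), clipped to [0, 1]."""
    mean_log = float(np.dot(state.posterior, state.grid))
    return float(np.clip(10.0 ** mean_log, 0.0, 1.0))


def staircase_threshold(history) -> float:
    """Study read-out: arithmetic mean of the final 10 presented intensities."""
    intensities = [h[0] for h in history]
    if len(intensities) < 10:
        raise ValueError("need at least 10 presentations")
    return float(np.mean(intensities[-10:]))


def run_staircase(
    observer,
    n_trials: int,
    state: QuestState | None = None,
) -> QuestState:
    """Drive the staircase against a callable observer(contrast) -> bool."""
    if state is None:
        state = make_quest_state()
    for _ in range(n_trials):
        c = quest_next_intensity(state)
        state = quest_update(state, c, bool(observer(c)))
    return state


def staircase_trace(state: QuestState) -> pd.DataFrame:
    """Trial-by-trial table: intensity, response (posterior mean is replayed)."""
    replay = make_quest_state(
        state.grid[0], state.grid[-1], len(state.grid),
        beta=state.beta, delta_lapse=state.delta_lapse, target_p=state.target_p,
    )
    rows = []
    for i, (intensity, response) in enumerate(state.history):
        replay = quest_update(replay, intensity, response)
        rows.append({
            "trial": i,
            "intensity": intensity,
            "response": response,
            "posterior_mean": quest_next_intensity(replay),
        })
    return pd.DataFrame(rows)
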