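"""QUEST Bayesian adaptive staircase on the log10 test/standard ratio.

The staircase maintains a gridded posterior over the observer's point of
subjective equality expressed as t = log10(PSE / standard).  The assumed
trial likelihood is a cumulative Gaussian in log-ratio units,

    psi(x - t) = gamma + (1 - gamma - delta) * Phi((x - t) / beta),

with guess rate gamma (0 for a two-interval "test more" response variable,
whose psychometric spans 0-1), lapse delta and spread beta.  After each
response the posterior is updated by Bayes' rule and the next test
numerosity is placed at the posterior mean plus a uniform jitter, which
spreads placements across the psychometric function so that its slope (and
hence the JND) remains estimable from the resulting data.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
from scipy.special import ndtr


def _log_normalize(log_p: np.ndarray) -> np.ndarray:
    """Renormalize log-probabilities in place-free fashion (stable)."""
    m = log_p.max()
    return log_p - (m + math.log(np.exp(log_p - m).sum()))

__all__ = [
    "QuestConfig",
    "QuestState",
    "QuestProposal",
    "quest_init",
    "quest_update",
    "quest_next",
    "quest_estimate",
    "posterior_entropy",
]


def _half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class QuestConfig:
    """Tunable staircase settings (all in log10 ratio units where relevant)."""

    grid_min: float = -0.5
    grid_max: float = 0.5
    grid_size: int = 201
    slope_beta: float = 0.15  # assumed psychometric spread
    lapse_delta: float = 0.02  # assumed lapse
    guess_gamma: float = 0.0  # lower asymptote of the "test more" function
    target_p: float = 0.5  # criterion probability (PSE tracking)
    jitter_halfwidth: float = 0.15  # uniform placement jitter
    prior_mean: float = 0.0
    prior_sd: float = 0.3


@dataclass(frozen=True)
class QuestState:
    """Immutable posterior snapshot; updates return a new state."""

    grid: np.ndarray
    log_posterior: np.ndarray
    slope_beta: float
    lapse_delta: float
    guess_gamma: float
    target_p: float
    jitter_halfwidth: float
    history: tuple[tuple[float, bool], ...] = ()

    @property
    def posterior(self) -> np.ndarray:
        return np.exp(self.log_posterior)

    def to_json(self) -> str:
        """Serializable audit snapshot of the staircase state."""
        return json.dumps(
            {
                "grid": self.grid.tolist(),
                "log_posterior": self.log_posterior.tolist(),
                "slope_beta": self.slope_beta,
                "lapse_delta": self.lapse_delta,
                "guess_gamma": self.guess_gamma,
                "target_p": self.target_p,
                "jitter_halfwidth": self.jitter_halfwidth,
                "history": [[x, bool(r)] for x, r in self.history],
            }
        )

    @classmethod
    def from_json(cls, payload: str) -> "QuestState":
        d = json.loads(payload)
        return cls(
            grid=np.asarray(d["grid"]),
            log_posterior=np.asarray(d["log_posterior"]),
            slope_beta=d["slope_beta"],
            lapse_delta=d["lapse_delta"],
            guess_gamma=d["guess_gamma"],
            target_p=d["target_p"],
            jitter_halfwidth=d["jitter_halfwidth"],
            history=tuple((x, bool(r)) for x, r in d["history"]),
        )


class QuestProposal(NamedTuple):
    test_n: int
    posterior_mean: float
    jitter: float


def quest_init(
    prior_mean: float | None = None,
    prior_sd: float | None = None,
    config: QuestConfig = QuestConfig(),
) -> QuestState:
    """Initialize the posterior to a normalized Gaussian prior over the grid."""
    mean = config.prior_mean if prior_mean is None else prior_mean
    sd = config.prior_sd if prior_sd is None else prior_sd
    if not sd > 0:
        raise ValueError("prior_sd must be > 0")
    grid = np.linspace(config.grid_min, config.grid_max, config.grid_size)
    if not np.all(np.diff(grid) > 0):
        raise ValueError("grid must be strictly increasing")
    log_post = _log_normalize(-0.5 * ((grid - mean) / sd) ** 2)
    return QuestState(
        grid=grid,
        log_posterior=log_post,
        slope_beta=config.slope_beta,
        lapse_delta=config.lapse_delta,
        guess_gamma=config.guess_gamma,
        target_p=config.target_p,
        jitter_halfwidth=config.jitter_halfwidth,
    )


def _psi(state: QuestState, x: np.ndarray) -> np.ndarray:
    core = ndtr(x / state.slope_beta)
    return state.guess_gamma + (1 - state.guess_gamma - state.lapse_delta) * core


def quest_update(state: QuestState, log_ratio: float, response: bool) -> QuestState:
    """Bayes update of the posterior with one (placement, response) pair."""
    if not math.isfinite(log_ratio):
        raise ValueError("log_ratio must be finite")
    lik = _psi(state, log_ratio - state.grid)
    if not response:
        lik = 1.0 - lik
    log_post = _log_normalize(
        state.log_posterior + np.log(np.clip(lik, 1e-300, None))
    )
    return replace(
        state,
        log_posterior=log_post,
        history=state.history + ((float(log_ratio), bool(response)),),
    )


def quest_estimate(state: QuestState) -> float:
    """Posterior mean of the log10 PSE ratio."""
    return float(np.sum(state.grid * state.posterior))


def posterior_entropy(state: QuestState) -> float:
    """Shannon entropy (nats) of the gridded posterior."""
    p = state.posterior
    return float(-np.sum(p * np.where(p > 0, np.log(np.clip(p, 1e-300, None)), 0.0)))


def quest_next(
    state: QuestState,
    standard_n: int,
    rng: np.random.Generator | None = None,
    return_details: bool = False,
) -> int | QuestProposal:
    """Recommend the next integer test numerosity.

    The recommended log-ratio is the posterior mean plus a uniform jitter in
    [-jitter_halfwidth, +jitter_halfwidth] (pass ``rng=None`` to disable the
    jitter).  The numerosity is rounded half-up, clamped to
    [max(2, round(standard_n/3)), 3*standard_n], and nudged one unit away from
    the standard (in the direction of the jitter's sign) so the comparison is
    never between identical numerosities.
    """
    if standard_n < 2:
        raise ValueError("standard_n must be >= 2")
    mean = quest_estimate(state)
    j = state.jitter_halfwidth
    jitter = float(rng.uniform(-j, j)) if (rng is not None and j > 0) else 0.0
    ratio = mean + jitter
    lo = max(2, _half_up(standard_n / 3))
    hi = 3 * standard_n
    test = min(max(_half_up(standard_n * 10.0**ratio), lo), hi)
    if test == standard_n:
        test += 1 if jitter >= 0 else -1
        if test < lo:
            test = standard_n + 1
    if return_details:
        return QuestProposal(test_n=test, posterior_mean=mean, jitter=jitter)
    return test
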