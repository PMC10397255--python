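"""Generative observer model for the two-interval numerosity comparison.

Each simulated participant forms a noisy percept of every dot array.  In
isolation, the percept of a true numerosity N is Gaussian with mean b*N and
standard deviation s*N (scalar variability: constant Weber fraction across
N).  Within a comparison trial both stimuli are judged at the noise level
set by the session's standard numerosity — the internal noise is anchored
to the magnitude range the observer is adapted to — so both percepts carry
SD s*n_std.  The decision variable (test percept minus standard percept) is
then Gaussian with SD s*sqrt(2)*n_std, and the choice function is an exact
cumulative Gaussian in the test numerosity whose midpoint sits at b*n_std:
the fitted PSE recovers the generative distortion without bias, and the
Weber fraction z_{0.75}*sqrt(2)*s is constant across standards.

The multiplicative distortion b < 1 applies only to the *symmetric
standard* array and captures the grouping-induced underestimation; random
arrays are perceived veridically on average (b = 1).  A small lapse
probability replaces the comparison by a fair coin.  A concurrent
colour-orientation conjunction judgement, performed only under attentional
load, is modelled as an independent Bernoulli success with a per-condition
accuracy.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.special import ndtr

__all__ = [
    "TASKS",
    "CONDITIONS",
    "ObserverParams",
    "TrialSpec",
    "perceived_numerosity",
    "choice_probability",
    "simulate_choice",
    "simulate_conjunction_response",
]

TASKS = ("ST", "ST_WD", "DT")  # single task, single task with distractor, dual task
CONDITIONS = ("symmetry", "random")


@dataclass(frozen=True)
class ObserverParams:
    """Generative parameters of one simulated participant.

    Parameters
    ----------
    noise
        Task -> scalar-variability coefficient s (percept SD = s * N).
    bias
        Condition -> task -> multiplicative distortion b applied to the
        symmetric standard's percept; 1.0 under the random condition.
    lapse
        Probability of replacing the comparison by a fair coin.
    conj_accuracy
        Condition -> probability of a correct conjunction-task response.
    """

    id: str
    noise: Mapping[str, float]
    bias: Mapping[str, Mapping[str, float]]
    conj_accuracy: Mapping[str, float]
    lapse: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for task, s in self.noise.items():
            if not s > 0:
                raise ValueError(f"noise coefficient must be > 0 (task {task}: {s})")
        for cond, per_task in self.bias.items():
            for task, b in per_task.items():
                if not 0 < b <= 1.5:
                    raise ValueError(f"bias multiplier out of (0, 1.5]: {cond}/{task}: {b}")
        if not 0 <= self.lapse <= 0.1:
            raise ValueError(f"lapse must lie in [0, 0.1], got {self.lapse}")
        for cond, p in self.conj_accuracy.items():
            if not 0.5 <= p <= 1:
                raise ValueError(f"conjunction accuracy out of [0.5, 1]: {cond}: {p}")

    def noise_for(self, task: str) -> float:
        return float(self.noise[task])

    def bias_for(self, condition: str, task: str) -> float:
        if condition == "random":
            return 1.0
        return float(self.bias[condition][task])


@dataclass(frozen=True)
class TrialSpec:
    """One scheduled two-interval comparison trial."""

    standard_n: int
    condition: str  # symmetry | random
    task: str  # ST | ST_WD | DT
    standard_interval: str = "first"  # bookkeeping only; no order effects modelled
    test_n: int | None = None  # filled in by the staircase at run time
    conj_is_target: bool | None = None  # None for ST (no distractor shown)
    session: int = 1
    trial_index: int = 0

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.task not in TASKS:
            raise ValueError(f"task must be one of {TASKS}")
        if self.standard_interval not in ("first", "second"):
            raise ValueError("standard_interval must be 'first' or 'second'")
        if self.test_n is not None and self.test_n < 2:
            raise ValueError("test_n must be >= 2")


def perceived_numerosity(
    n_true: int | float,
    multiplier: float,
    s: float,
    rng: np.random.Generator,
) -> float:
    """Noisy percept of a numerosity: Gaussian(b*N, s*N), floored at 0.01."""
    if n_true < 1:
        raise ValueError("n_true must be >= 1")
    percept = multiplier * n_true + rng.normal(0.0, s * n_true)
    return max(percept, 0.01)


def choice_probability(trial: TrialSpec, params: ObserverParams) -> float:
    """Closed-form P(respond "test more numerous") for a trial.

    With independent Gaussian percepts of the test (mean n_test) and the
    standard (mean b*n_std), each carrying the range-anchored noise SD
    s*n_std, the decision variable is Gaussian, giving

        P = lapse/2 + (1 - lapse) * Phi((n_test - b*n_std) / (s*sqrt(2)*n_std))

    This is the analytic oracle for :func:`simulate_choice`; the point where
    P = 0.5 (at zero lapse) sits exactly at n_test = b*n_std, anchoring the
    bias index recovered downstream.
    """
    if trial.test_n is None:
        raise ValueError("trial.test_n is not set")
    b = params.bias_for(trial.condition, trial.task)
    s = params.noise_for(trial.task)
    z = (trial.test_n - b * trial.standard_n) / (
        s * math.sqrt(2.0) * trial.standard_n
    )
    return float(params.lapse / 2 + (1 - params.lapse) * ndtr(z))


def simulate_choice(
    trial: TrialSpec, params: ObserverParams, rng: np.random.Generator
) -> bool:
    """Simulate one 2IFC response; True means "test more numerous"."""
    if trial.test_n is None:
        raise ValueError("trial.test_n is not set")
    if params.lapse > 0 and rng.random() < params.lapse:
        return bool(rng.random() < 0.5)
    b = params.bias_for(trial.condition, trial.task)
    s = params.noise_for(trial.task)
    # Both percepts at the range-anchored noise level s * n_std: the test's
    # coefficient is rescaled so its percept SD equals s * n_std too.
    s_test = s * trial.standard_n / trial.test_n
    p_test = perceived_numerosity(trial.test_n, 1.0, s_test, rng)
    p_std = perceived_numerosity(trial.standard_n, b, s, rng)
    return bool(p_test > p_std)


def simulate_conjunction_response(
    is_target: bool, p_correct: float, rng: np.random.Generator
) -> bool:
    """Bernoulli correctness of the colour-orientation conjunction response.

    Accuracy is independent of the numerosity response and of whether the
    distractor is a target; only overall correctness is modelled.
    """
    if not 0 <= p_correct <= 1:
        raise ValueError("p_correct must lie in [0, 1]")
    del is_target  # accuracy model is symmetric in target/non-target
    return bool(rng.random() < p_correct)
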