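"""Session scheduling and end-to-end simulation of a cohort.

This module is the synthetic-data generator: it builds the full
within-subject trial design (4 standard numerosities x 2 arrangement
conditions x 3 task levels, two 50-trial sessions per cell, 800 trials per
task per participant), samples a cohort of generative observer parameters
from a population model, and runs QUEST-driven two-interval trials against
those observers to emit an analysis-ready long-format trial table.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .observer import (
    CONDITIONS,
    TASKS,
    ObserverParams,
    TrialSpec,
    simulate_choice,
    simulate_conjunction_response,
)
from .quest import QuestConfig, quest_init, quest_next, quest_update
from .stimgen import (
    FieldGeometry,
    convex_hull_area,
    sample_random_array,
    sample_symmetric_array,
)

__all__ = [
    "DesignSpec",
    "PopulationParams",
    "build_schedule",
    "sample_cohort",
    "run_simulated_experiment",
    "TRIAL_COLUMNS",
]

TRIAL_COLUMNS = [
    "participant_id",
    "task",
    "condition",
    "standard_n",
    "test_n",
    "standard_interval",
    "response_test_more",
    "conj_is_target",
    "conj_correct",
    "session",
    "trial_index",
    "quest_posterior_mean",
    "quest_jitter",
]


@dataclass(frozen=True)
class DesignSpec:
    """The full within-subject design.

    Defaults reproduce the study layout: for each task, every standard
    numerosity is tested in two 50-trial sessions per arrangement condition,
    i.e. 4 x 2 x 2 x 50 = 800 trials per task per participant (400 per
    condition).
    """

    standard_numerosities: tuple[int, ...] = (8, 12, 24, 50)
    conditions: tuple[str, ...] = CONDITIONS
    tasks: tuple[str, ...] = TASKS
    sessions_per_cell: int = 2
    trials_per_session: int = 50
    n_participants: int = 26
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.standard_numerosities:
            raise ValueError("at least one standard numerosity is required")
        if any(n < 2 for n in self.standard_numerosities):
            raise ValueError("standard numerosities must be >= 2")
        unknown = set(self.conditions) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown conditions: {sorted(unknown)}")
        unknown = set(self.tasks) - set(TASKS)
        if unknown:
            raise ValueError(f"unknown tasks: {sorted(unknown)}")
        for name in ("sessions_per_cell", "trials_per_session", "n_participants"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def trials_per_task(self) -> int:
        """Trials per task per participant (800 under the default design)."""
        return (
            len(self.standard_numerosities)
            * len(self.conditions)
            * self.sessions_per_cell
            * self.trials_per_session
        )


@dataclass(frozen=True)
class PopulationParams:
    """Population (cohort-level) distribution of observer parameters.

    ``bias_mean[task]`` is the mean multiplicative distortion of the
    symmetric standard's percept under that task; ``noise_mean[task]`` the
    mean scalar-variability coefficient.  Individual differences are drawn
    as one shared susceptibility factor per subject (applied to every task's
    bias) and one shared noise factor (applied to every task's s), so a
    strongly biased observer in the single task is also relatively strongly
    biased under load — matching the correlated individual effects seen in
    dual-task data.  Conjunction accuracy is sampled for the random
    condition with a correlated symmetric-condition deficit.
    """

    bias_mean: dict[str, float] = field(
        default_factory=lambda: {"ST": 0.9213, "ST_WD": 0.936, "DT": 0.97}
    )
    bias_sd: dict[str, float] = field(
        default_factory=lambda: {"ST": 0.045, "ST_WD": 0.042, "DT": 0.025}
    )
    noise_mean: dict[str, float] = field(
        default_factory=lambda: {"ST": 0.2096, "ST_WD": 0.2096, "DT": 0.3984}
    )
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {"ST": 0.03, "ST_WD": 0.03, "DT": 0.055}
    )
    conj_accuracy_mean: float = 0.96  # random condition
    conj_accuracy_sd: float = 0.03
    conj_deficit_mean: float = 0.02  # symmetric-condition accuracy cost
    conj_deficit_sd: float = 0.015
    lapse: float = 0.02

    def __post_init__(self) -> None:
        for task in self.bias_mean:
            if not 0 < self.bias_mean[task] <= 1.5:
                raise ValueError(f"bias_mean[{task}] out of (0, 1.5]")
        for d in (self.bias_sd, self.noise_sd):
            if any(v < 0 for v in d.values()):
                raise ValueError("population SDs must be >= 0")
        for task in self.noise_mean:
            if not self.noise_mean[task] > 0:
                raise ValueError(f"noise_mean[{task}] must be > 0")
        if not 0 <= self.lapse <= 0.1:
            raise ValueError("lapse must lie in [0, 0.1]")


def build_schedule(
    design: DesignSpec, rng: np.random.Generator
) -> list[TrialSpec]:
    """Scheduled trials for one participant, all tasks, in presentation order."""
    trials: list[TrialSpec] = []
    for task in design.tasks:
        trials.extend(_schedule_task(design, task, rng))
    return trials


def _schedule_task(
    design: DesignSpec, task: str, rng: np.random.Generator
) -> list[TrialSpec]:
    trials: list[TrialSpec] = []
    for standard_n in design.standard_numerosities:
        for condition in design.conditions:
            for session in range(1, design.sessions_per_cell + 1):
                for t in range(design.trials_per_session):
                    conj = None if task == "ST" else bool(rng.random() < 0.5)
                    trials.append(
                        TrialSpec(
                            standard_n=standard_n,
                            condition=condition,
                            task=task,
                            standard_interval="first" if rng.random() < 0.5 else "second",
                            conj_is_target=conj,
                            session=session,
                            trial_index=t,
                        )
                    )
    return trials


def _truncated_normal(
    rng_draw: float, mean: float, sd: float, lo: float, hi: float
) -> float:
    return float(np.clip(mean + rng_draw * sd, lo, hi))


def sample_cohort(
    n: int,
    population: PopulationParams = PopulationParams(),
    rng: np.random.Generator | None = None,
) -> list[ObserverParams]:
    """Draw ``n`` observers from the population model (reproducible from rng)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    cohort: list[ObserverParams] = []
    for i in range(n):
        u = rng.standard_normal()  # shared symmetry-susceptibility factor
        v = rng.standard_normal()  # shared internal-noise factor
        w = rng.standard_normal()
        z = rng.standard_normal()
        bias_sym = {
            task: _truncated_normal(u, population.bias_mean[task], population.bias_sd[task], 0.01, 1.5)
            for task in population.bias_mean
        }
        noise = {
            task: _truncated_normal(v, population.noise_mean[task], population.noise_sd[task], 1e-3, 2.0)
            for task in population.noise_mean
        }
        p_rand = _truncated_normal(
            w, population.conj_accuracy_mean, population.conj_accuracy_sd, 0.5, 1.0
        )
        deficit = _truncated_normal(
            z, population.conj_deficit_mean, population.conj_deficit_sd, 0.0, 0.5
        )
        cohort.append(
            ObserverParams(
                id=f"P{i + 1:02d}",
                noise=noise,
                bias={"symmetry": bias_sym},
                conj_accuracy={"random": p_rand, "symmetry": max(0.5, p_rand - deficit)},
                lapse=population.lapse,
                seed=int(rng.integers(2**31)),
            )
        )
    return cohort


def run_simulated_experiment(
    design: DesignSpec,
    cohort: list[ObserverParams],
    geom: FieldGeometry | None = None,
    quest_config: QuestConfig = QuestConfig(),
    materialize_stimuli: bool = False,
) -> pd.DataFrame:
    """Run every scheduled trial for every observer; return the trial table.

    Each (participant x task x condition x standard numerosity x session)
    cell gets a fresh QUEST staircase.  Responses depend only on the
    numerosities under the observer model, so dot arrays are materialized
    only on request (``materialize_stimuli``), in which case per-trial convex
    hull areas are recorded for geometric audits.  The run is fully
    deterministic given ``design.seed``: a master seed sequence spawns one
    independent substream per participant x task.
    """
    if len(cohort) != design.n_participants:
        raise ValueError(
            f"cohort size {len(cohort)} != design.n_participants {design.n_participants}"
        )
    if materialize_stimuli and geom is None:
        geom = FieldGeometry()
    master = np.random.SeedSequence(design.seed)
    children = master.spawn(len(cohort) * len(design.tasks))
    rows: list[dict] = []
    for pi, obs in enumerate(cohort):
        for ti, task in enumerate(design.tasks):
            rng = np.random.default_rng(children[pi * len(design.tasks) + ti])
            schedule = _schedule_task(design, task, rng)
            states: dict[tuple, object] = {}
            for spec in schedule:
                key = (spec.condition, spec.standard_n, spec.session)
                state = states.get(key)
                if state is None:
                    state = quest_init(config=quest_config)
                proposal = quest_next(state, spec.standard_n, rng, return_details=True)
                trial = replace(spec, test_n=proposal.test_n)
                response = simulate_choice(trial, obs, rng)
                states[key] = quest_update(
                    state, math.log10(trial.test_n / trial.standard_n), response
                )
                row = {
                    "participant_id": obs.id,
                    "task": task,
                    "condition": trial.condition,
                    "standard_n": trial.standard_n,
                    "test_n": trial.test_n,
                    "standard_interval": trial.standard_interval,
                    "response_test_more": response,
                    "conj_is_target": trial.conj_is_target,
                    "conj_correct": (
                        simulate_conjunction_response(
                            trial.conj_is_target,
                            obs.conj_accuracy[trial.condition],
                            rng,
                        )
                        if trial.conj_is_target is not None
                        else None
                    ),
                    "session": trial.session,
                    "trial_index": trial.trial_index,
                    "quest_posterior_mean": proposal.posterior_mean,
                    "quest_jitter": proposal.jitter,
                }
                if materialize_stimuli:
                    standard = (
                        sample_symmetric_array(trial.standard_n, geom, rng)
                        if trial.condition == "symmetry"
                        else sample_random_array(trial.standard_n, geom, rng)
                    )
                    test = sample_random_array(trial.test_n, geom, rng)
                    row["standard_hull_area"] = convex_hull_area(standard)
                    row["test_hull_area"] = convex_hull_area(test)
                rows.append(row)
    columns = TRIAL_COLUMNS + (
        ["standard_hull_area", "test_hull_area"] if materialize_stimuli else []
    )
    return pd.DataFrame(rows, columns=columns)
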