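"""Shared fixtures and helpers for the test suite."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from symnum.experiment import (
    DesignSpec,
    PopulationParams,
    run_simulated_experiment,
    sample_cohort,
)
from symnum.psychometrics import aggregate_cells

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def homogeneous_population(
    tasks: tuple[str, ...],
    bias: float | dict = 1.0,
    noise: float | dict = 0.2096,
    bias_sd: float = 0.0,
    noise_sd: float = 0.0,
    lapse: float = 0.02,
) -> PopulationParams:
    """Population with identical task-level means (optionally zero spread)."""
    if not isinstance(bias, dict):
        bias = {t: bias for t in tasks}
    if not isinstance(noise, dict):
        noise = {t: noise for t in tasks}
    return PopulationParams(
        bias_mean=bias,
        bias_sd={t: bias_sd for t in tasks},
        noise_mean=noise,
        noise_sd={t: noise_sd for t in tasks},
        lapse=lapse,
    )


def simulate_cells(
    *,
    tasks: tuple[str, ...] = ("ST",),
    bias: float | dict = 1.0,
    noise: float | dict = 0.2096,
    bias_sd: float = 0.0,
    noise_sd: float = 0.0,
    lapse: float = 0.02,
    n_participants: int = 26,
    sessions: int = 2,
    trials_per_session: int = 50,
    standards: tuple[int, ...] = (8, 12, 24, 50),
    seed: int = 0,
    fit_lapse: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort and fit all cells; returns (trials, cells)."""
    design = DesignSpec(
        standard_numerosities=standards,
        tasks=tasks,
        sessions_per_cell=sessions,
        trials_per_session=trials_per_session,
        n_participants=n_participants,
        seed=seed,
    )
    pop = homogeneous_population(
        tasks, bias=bias, noise=noise, bias_sd=bias_sd, noise_sd=noise_sd, lapse=lapse
    )
    cohort = sample_cohort(n_participants, pop, np.random.default_rng(seed + 1))
    trials = run_simulated_experiment(design, cohort)
    cells = aggregate_cells(trials, lapse=fit_lapse)
    return trials, cells


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
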