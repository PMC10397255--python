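"""Psychometric-function fitting and the accuracy/precision indices.

For each analysis cell (participant x task x condition x standard
numerosity) the proportion of "test more numerous" responses as a function
of the test numerosity x is fitted with a cumulative Gaussian

    P(test more | x) = lapse/2 + (1 - lapse) * Phi((x - mu) / sigma)

by binomial maximum likelihood (lapse fixed, 0 by default).  The fitted
midpoint mu is the point of subjective equality (PSE).  Two indices derive
from the fit:

* Bias  = (PSE / N - 1) * 100        (percent; negative = the standard,
  here the symmetric array, is perceived as less numerous),
* Wf    = JND / N with JND the numerosity span between the 50% and 75%
  points of the lapse-free function, i.e. JND = z_{0.75} * sigma.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import fmin_l_bfgs_b
from scipy.special import ndtr
from scipy.stats import norm

__all__ = [
    "DegenerateDataError",
    "PsychometricModel",
    "PsychometricFit",
    "fit_psychometric",
    "jnd",
    "bias_index",
    "weber_fraction",
    "aggregate_cells",
]

Z75 = float(norm.ppf(0.75))  # 0.6744897501960817

MIN_TRIALS = 20
MIN_LEVELS = 3


class DegenerateDataError(ValueError):
    """Raised when a cell's data cannot identify a psychometric function."""


@dataclass(frozen=True)
class PsychometricFit:
    """Fitted cumulative-Gaussian parameters for one analysis cell."""

    mu: float  # PSE, numerosity units
    sigma: float  # spread, numerosity units
    lapse: float
    loglik: float
    n_trials: int
    converged: bool
    cell: tuple = ()

    @property
    def pse(self) -> float:
        return self.mu

    @property
    def jnd(self) -> float:
        return Z75 * self.sigma

    def predict(self, x: np.ndarray) -> np.ndarray:
        """P(test more numerous) at test numerosities x."""
        x = np.asarray(x, dtype=float)
        return self.lapse / 2 + (1 - self.lapse) * ndtr((x - self.mu) / self.sigma)

    def summary(self) -> str:
        lines = [
            "Cumulative-Gaussian psychometric fit (binomial ML)",
            "-" * 50,
            f"{'n trials':<22}{self.n_trials}",
            f"{'PSE (mu)':<22}{self.mu:.4f}",
            f"{'sigma':<22}{self.sigma:.4f}",
            f"{'JND (50%->75%)':<22}{self.jnd:.4f}",
            f"{'lapse (fixed)':<22}{self.lapse:.4f}",
            f"{'log-likelihood':<22}{self.loglik:.3f}",
            f"{'converged':<22}{self.converged}",
        ]
        return "\n".join(lines)


class PsychometricModel:
    """Binomial model of 2IFC responses versus test numerosity.

    Parameters
    ----------
    test_n
        Test numerosity of each trial.
    response
        Whether the test was judged more numerous on each trial.
    """

    def __init__(self, test_n: Sequence[float], response: Sequence[bool], cell: tuple = ()):
        x = np.asarray(test_n, dtype=float)
        r = np.asarray(response, dtype=bool)
        if x.shape != r.shape or x.ndim != 1:
            raise ValueError("test_n and response must be 1-D of equal length")
        self.cell = cell
        # Aggregate to unique stimulus levels: (x_j, successes k_j, trials m_j)
        self.levels, inverse = np.unique(x, return_inverse=True)
        self.m = np.bincount(inverse).astype(float)
        self.k = np.bincount(inverse, weights=r.astype(float))
        self.n_trials = int(x.size)
        self._check_identifiable()

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        x_col: str = "test_n",
        response_col: str = "response_test_more",
        cell: tuple = (),
    ) -> "PsychometricModel":
        return cls(data[x_col].to_numpy(), data[response_col].to_numpy(), cell=cell)

    def _check_identifiable(self) -> None:
        if self.n_trials < MIN_TRIALS:
            raise DegenerateDataError(
                f"need >= {MIN_TRIALS} trials, got {self.n_trials}"
            )
        if self.levels.size < MIN_LEVELS:
            raise DegenerateDataError(
                f"need >= {MIN_LEVELS} distinct test levels, got {self.levels.size}"
            )
        total_k = self.k.sum()
        if total_k == 0 or total_k == self.m.sum():
            raise DegenerateDataError("responses are constant; PSE is unidentified")

    def _probit_start(self) -> np.ndarray | None:
        """Weighted probit-regression initializer.

        A linear fit of Phi^{-1}(k/m) on the test level gives closed-form
        slope/intercept estimates of (mu, sigma); this extra start rescues
        the optimizer from flat likelihood plateaus when the response
        transition is far from the weighted median level.
        """
        p_obs = np.clip(self.k / self.m, 0.02, 0.98)
        z = norm.ppf(p_obs)
        w = self.m
        xb = np.average(self.levels, weights=w)
        zb = np.average(z, weights=w)
        sxx = np.sum(w * (self.levels - xb) ** 2)
        if sxx <= 0:
            return None
        slope = np.sum(w * (self.levels - xb) * (z - zb)) / sxx
        if slope <= 1e-6:
            return None
        sigma0 = 1.0 / slope
        mu0 = xb - zb * sigma0
        if not (np.isfinite(mu0) and mu0 > 0):
            return None
        return np.array([float(mu0), math.log(float(max(min(sigma0, 1e3), 1e-3)))])

    # -- likelihood ---------------------------------------------------------
    def _nll_grad(self, theta: np.ndarray, lapse: float) -> tuple[float, np.ndarray]:
        mu, log_sigma = theta
        sigma = math.exp(log_sigma)
        z = (self.levels - mu) / sigma
        p = lapse / 2 + (1 - lapse) * ndtr(z)
        p = np.clip(p, 1e-12, 1 - 1e-12)
        nll = -np.sum(self.k * np.log(p) + (self.m - self.k) * np.log1p(-p))
        # dp/dmu = -(1-lapse) phi(z) / sigma ; dp/dlog_sigma = -(1-lapse) phi(z) z
        phi = np.exp(-0.5 * z * z) / math.sqrt(2 * math.pi)
        w = self.k / p - (self.m - self.k) / (1 - p)
        grad_mu = np.sum(w * (1 - lapse) * phi / sigma)
        grad_ls = np.sum(w * (1 - lapse) * phi * z)
        return float(nll), np.array([grad_mu, grad_ls])

    def fit(self, lapse: float = 0.0) -> PsychometricFit:
        """Maximum-likelihood fit of (mu, sigma) with the lapse held fixed.

        Deterministic multi-start L-BFGS-B: mu starts at the trial-weighted
        median test level, sigma at {0.1, 0.2, 0.4} times that value.
        """
        if not 0 <= lapse <= 0.1:
            raise ValueError("lapse must lie in [0, 0.1]")
        order = np.argsort(self.levels)
        cum = np.cumsum(self.m[order])
        mu0 = float(self.levels[order][np.searchsorted(cum, cum[-1] / 2)])
        span = float(self.levels.max() - self.levels.min())
        starts = [
            np.array([mu0, math.log(max(frac * mu0, 1e-3))]) for frac in (0.1, 0.2, 0.4)
        ]
        # edge anchors rescue cells whose transition falls outside the
        # sampled levels, plus a closed-form probit-regression start
        for mu_edge in (float(self.levels.min()), float(self.levels.max())):
            starts.append(np.array([mu_edge, math.log(max(0.2 * mu_edge, 1e-3))]))
        probit = self._probit_start()
        if probit is not None:
            starts.append(probit)
        bounds = [
            (1e-6, 10 * self.levels.max()),
            (math.log(1e-3), math.log(max(10 * span, 10 * mu0, 1.0))),
        ]
        starts = [
            np.array(
                [
                    np.clip(x0[0], bounds[0][0], bounds[0][1]),
                    np.clip(x0[1], bounds[1][0], bounds[1][1]),
                ]
            )
            for x0 in starts
        ]
        # rank the deterministic starts by their initial likelihood and
        # polish only the three most promising (keeps fitting fast over
        # hundreds of cells without sacrificing the multi-start safety net)
        starts.sort(key=lambda x0: self._nll_grad(x0, lapse)[0])
        best_x, best_f, best_ok = None, np.inf, False
        for x0 in starts[:3]:
            x_opt, f_opt, info = fmin_l_bfgs_b(
                self._nll_grad,
                x0,
                args=(lapse,),
                bounds=bounds,
                maxiter=500,
                factr=1e-8 / np.finfo(float).eps,  # ftol 1e-8
                pgtol=1e-8,
            )
            if f_opt < best_f - 1e-12:
                best_x, best_f = x_opt, f_opt
                best_ok = info["warnflag"] == 0
        mu, log_sigma = best_x
        if not np.isfinite(best_f):  # pragma: no cover - defensive
            raise DegenerateDataError("likelihood is not finite at the optimum")
        return PsychometricFit(
            mu=float(mu),
            sigma=float(math.exp(log_sigma)),
            lapse=float(lapse),
            loglik=float(-best_f),
            n_trials=self.n_trials,
            converged=bool(best_ok),
            cell=self.cell,
        )


def fit_psychometric(
    cell_trials: Iterable[tuple[float, bool]] | pd.DataFrame,
    lapse: float = 0.0,
) -> PsychometricFit:
    """Fit one cell from (test_n, response) pairs or a trial DataFrame."""
    if isinstance(cell_trials, pd.DataFrame):
        model = PsychometricModel.from_dataframe(cell_trials)
    else:
        pairs = list(cell_trials)
        model = PsychometricModel([p[0] for p in pairs], [p[1] for p in pairs])
    return model.fit(lapse=lapse)


def jnd(fit: PsychometricFit) -> float:
    """Numerosity span between the 50% and 75% points: z_{0.75} * sigma.

    Computed from the lapse-free core function so the definition stays
    well-posed when a nonzero lapse is assumed.
    """
    return Z75 * fit.sigma


def bias_index(pse: float, standard_n: int) -> float:
    """Percent deviation of the PSE from the standard: (PSE/N - 1) * 100."""
    if standard_n < 1:
        raise ValueError("standard_n must be >= 1")
    if not pse > 0:
        raise ValueError("pse must be > 0")
    return (pse / standard_n - 1.0) * 100.0


def weber_fraction(jnd_value: float, standard_n: int) -> float:
    """Dimensionless precision index: JND / N."""
    if standard_n < 1:
        raise ValueError("standard_n must be >= 1")
    if not jnd_value > 0:
        raise ValueError("jnd must be > 0")
    return jnd_value / standard_n


CELL_KEYS = ["participant_id", "task", "condition", "standard_n"]


def aggregate_cells(trials: pd.DataFrame, lapse: float = 0.0) -> pd.DataFrame:
    """Fit every (participant x task x condition x standard_n) cell.

    Returns one row per cell with pse, sigma, jnd, bias_pct, wf, n_trials
    and a converged flag.  Cells whose data are degenerate (one-sided
    responses, too few trials or levels) are flagged ``excluded`` with the
    failure reason and carry NaN estimates; they are reported, never
    imputed, and a warning summarises how many were dropped.
    """
    rows = []
    n_excluded = 0
    for cell, sub in trials.groupby(CELL_KEYS, sort=True):
        participant_id, task, condition, standard_n = cell
        record = {
            "participant_id": participant_id,
            "task": task,
            "condition": condition,
            "standard_n": standard_n,
        }
        try:
            fit = PsychometricModel.from_dataframe(sub, cell=cell).fit(lapse=lapse)
            record.update(
                pse=fit.mu,
                sigma=fit.sigma,
                jnd=fit.jnd,
                bias_pct=bias_index(fit.mu, standard_n),
                wf=weber_fraction(fit.jnd, standard_n),
                n_trials=fit.n_trials,
                converged=fit.converged,
                excluded=False,
                exclusion_reason="",
            )
        except DegenerateDataError as err:
            n_excluded += 1
            record.update(
                pse=np.nan,
                sigma=np.nan,
                jnd=np.nan,
                bias_pct=np.nan,
                wf=np.nan,
                n_trials=len(sub),
                converged=False,
                excluded=True,
                exclusion_reason=str(err),
            )
        rows.append(record)
    if n_excluded:
        warnings.warn(
            f"{n_excluded} cell(s) excluded as degenerate", RuntimeWarning, stacklevel=2
        )
    return pd.DataFrame(rows)
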