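"""Within-subject inference: RM ANOVA, post-hoc tests, and power analysis.

Implements the full statistical battery applied to the bias and Weber
fraction tables: fully-factorial repeated-measures ANOVA with classical
eta-squared (SS_effect / SS_total) and Greenhouse-Geisser sphericity
correction, Bonferroni-corrected paired t-tests with Cohen's d, an exact
small-sample Wilcoxon signed-rank test, and paired-t power / sample-size
calculations based on the noncentral t distribution.

The ANOVA decomposition is computed from definitional marginal-mean
(inclusion-exclusion) formulas on the subject x cells array; every effect
is tested against its own subject-interaction error term, as is standard
for fully within-subject designs with one observation per subject per cell.
"""
from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import helmert
from scipy.special import ndtr
from scipy.stats import f as f_dist
from scipy.stats import nct, rankdata
from scipy.stats import t as t_dist

__all__ = [
    "AnovaResult",
    "UnbalancedDesignError",
    "MissingCellError",
    "ZeroVarianceError",
    "AllZeroDifferencesError",
    "rm_anova",
    "gg_epsilon",
    "paired_t",
    "bonferroni",
    "wilcoxon_signed_rank",
    "power_paired_t",
    "required_sample_size_paired_t",
]


class UnbalancedDesignError(ValueError):
    """A subject is missing some factor-level combination."""


class MissingCellError(ValueError):
    """A factor-level combination has no observations at all."""


class ZeroVarianceError(ValueError):
    """Paired differences are all identical; t is undefined."""


class AllZeroDifferencesError(ValueError):
    """Every paired difference is zero; the signed-rank test is undefined."""


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA
# ---------------------------------------------------------------------------


@dataclass
class AnovaResult:
    """Per-effect decomposition of a fully within-subject design.

    ``table`` has one row per effect with columns: effect, ss, df, ms, F, p,
    eta_sq, gg_epsilon, p_gg, err_ss, err_df, err_ms.  ``ss_subject`` and
    ``ss_total`` complete the decomposition:
    ss_total = ss_subject + sum(ss + err_ss over effects).
    """

    table: pd.DataFrame
    ss_subject: float
    ss_total: float
    n_subjects: int

    def effect(self, name: str) -> pd.Series:
        match = self.table[self.table["effect"] == name]
        if match.empty:
            raise KeyError(f"no effect named {name!r}; have {list(self.table['effect'])}")
        return match.iloc[0]

    def summary(self) -> str:
        lines = [
            f"Repeated-measures ANOVA ({self.n_subjects} subjects)",
            "=" * 78,
            f"{'effect':<24}{'df':>8}{'F':>10}{'p':>10}{'eta^2':>8}{'GG eps':>8}{'p[GG]':>10}",
            "-" * 78,
        ]
        for _, row in self.table.iterrows():
            lines.append(
                f"{row['effect']:<24}"
                f"{f'{row.df:.0f}, {row.err_df:.0f}':>8}"
                f"{row.F:>10.3f}{row.p:>10.4f}{row.eta_sq:>8.3f}"
                f"{row.gg_epsilon:>8.3f}{row.p_gg:>10.4f}"
            )
        lines.append("-" * 78)
        lines.append(
            f"SS subject = {self.ss_subject:.4f}; SS total = {self.ss_total:.4f}"
        )
        return "\n".join(lines)

    def to_records(self) -> list[dict]:
        return self.table.to_dict(orient="records")


def _effect_ss(Y: np.ndarray, axes: tuple[int, ...]) -> float:
    """SS attributable to the interaction of ``axes`` via inclusion-exclusion.

    ``Y`` has the subject axis first and one axis per factor.  The effect
    array at a subset A of axes is sum over B subseteq A of (-1)^{|A|-|B|}
    times the data averaged over all axes outside B; its squared sum, scaled
    by the number of observations per A-cell, is the effect SS.
    """
    all_axes = tuple(range(Y.ndim))
    e = np.zeros([Y.shape[a] if a in axes else 1 for a in all_axes])
    for r in range(len(axes) + 1):
        for B in itertools.combinations(axes, r):
            sign = (-1) ** (len(axes) - len(B))
            collapse = tuple(a for a in all_axes if a not in B)
            e = e + sign * Y.mean(axis=collapse, keepdims=True)
    n_per_cell = int(np.prod([Y.shape[a] for a in all_axes if a not in axes]))
    return float(n_per_cell * np.sum(e**2))


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k, k-1) orthonormal contrast matrix with columns orthogonal to ones."""
    return helmert(k, full=False).T


def gg_epsilon(cell_data: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon-hat from a subjects x levels matrix.

    Computed from the sample covariance of the level columns projected onto
    an orthonormal contrast basis (Box's epsilon).  Bounded to
    [1/(k-1), 1]; exactly 1 for a 2-level factor.
    """
    Z = np.asarray(cell_data, dtype=float)
    if Z.ndim != 2 or Z.shape[1] < 2:
        raise ValueError("cell_data must be a subjects x levels matrix, >= 2 levels")
    n, k = Z.shape
    if n < k:
        warnings.warn(
            "fewer subjects than levels: covariance is singular, epsilon unstable",
            RuntimeWarning,
            stacklevel=2,
        )
    return _epsilon_from_cov(np.cov(Z, rowvar=False), _orthonormal_contrasts(k))


def _epsilon_from_cov(cov: np.ndarray, C: np.ndarray) -> float:
    M = C.T @ np.atleast_2d(cov) @ C
    d = M.shape[0]
    tr = float(np.trace(M))
    tr2 = float(np.trace(M @ M))
    if tr2 <= 0:
        return 1.0
    eps = tr**2 / (d * tr2)
    return float(min(1.0, max(1.0 / d, eps)))


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    within: Sequence[str],
    subject: str,
) -> AnovaResult:
    """Fully-factorial repeated-measures ANOVA.

    Requires a complete, balanced design with one observation per subject
    per cell (replicates are first reduced to cell means).  Every effect is
    tested against its interaction with subjects; eta-squared uses the total
    SS denominator, and the Greenhouse-Geisser corrected p-value scales both
    degrees of freedom by the effect's epsilon-hat.
    """
    within = list(within)
    if not within:
        raise ValueError("at least one within factor is required")
    df = data[[subject, *within, dv]].copy()
    if df[dv].isna().any():
        raise ValueError("dv contains missing values")
    # cell means if replicates exist
    df = df.groupby([subject, *within], sort=True, observed=True)[dv].mean().reset_index()

    levels = [np.unique(df[f].to_numpy()) for f in within]
    subjects = np.unique(df[subject].to_numpy())
    n = len(subjects)
    n_cells = int(np.prod([len(l) for l in levels]))
    expected = n * n_cells
    for f, lev in zip(within, levels):
        if len(lev) < 2:
            raise MissingCellError(f"factor {f!r} has fewer than 2 levels")
    if len(df) != expected:
        counts = df.groupby(subject, observed=True).size()
        bad = counts[counts != n_cells]
        if not bad.empty:
            raise UnbalancedDesignError(
                f"subjects with incomplete cells: {list(bad.index)}"
            )
        raise MissingCellError("design has missing factor-level combinations")

    pivot = df.set_index([subject, *within])[dv].unstack(within)
    if pivot.isna().any().any():
        raise UnbalancedDesignError("some subject x cell combinations are missing")
    # reorder columns to the sorted factorial layout, then reshape
    full_index = pd.MultiIndex.from_product(levels, names=within) if len(within) > 1 else pd.Index(levels[0], name=within[0])
    pivot = pivot.reindex(columns=full_index)
    Y = pivot.to_numpy().reshape(n, *[len(l) for l in levels])

    grand = Y.mean()
    ss_total = float(np.sum((Y - grand) ** 2))
    ss_subject = _effect_ss(Y, axes=(0,))

    rows = []
    factor_axes = {f: i + 1 for i, f in enumerate(within)}
    for r in range(1, len(within) + 1):
        for combo in itertools.combinations(within, r):
            axes = tuple(factor_axes[f] for f in combo)
            ss = _effect_ss(Y, axes)
            df_eff = int(np.prod([Y.shape[a] - 1 for a in axes]))
            ss_err = _effect_ss(Y, (0, *axes))
            df_err = (n - 1) * df_eff
            ms, ms_err = ss / df_eff, ss_err / df_err
            F = ms / ms_err if ms_err > 0 else 0.0
            p = float(f_dist.sf(F, df_eff, df_err)) if ms_err > 0 else 1.0
            eps = _gg_epsilon_for_effect(Y, axes)
            p_gg = (
                float(f_dist.sf(F, df_eff * eps, df_err * eps)) if ms_err > 0 else 1.0
            )
            rows.append(
                {
                    "effect": ":".join(combo),
                    "ss": ss,
                    "df": df_eff,
                    "ms": ms,
                    "F": F,
                    "p": p,
                    "eta_sq": ss / ss_total if ss_total > 0 else 0.0,
                    "gg_epsilon": eps,
                    "p_gg": p_gg,
                    "err_ss": ss_err,
                    "err_df": df_err,
                    "err_ms": ms_err,
                }
            )
    return AnovaResult(
        table=pd.DataFrame(rows),
        ss_subject=ss_subject,
        ss_total=ss_total,
        n_subjects=n,
    )


def _gg_epsilon_for_effect(Y: np.ndarray, axes: tuple[int, ...]) -> float:
    """Epsilon-hat for one effect: contrast-projected covariance of the
    subject data collapsed over the uninvolved factors."""
    all_axes = tuple(range(Y.ndim))
    collapse = tuple(a for a in all_axes if a != 0 and a not in axes)
    Z = Y.mean(axis=collapse) if collapse else Y
    n = Z.shape[0]
    K = int(np.prod(Z.shape[1:]))
    Z = Z.reshape(n, K)
    C = _orthonormal_contrasts(Y.shape[axes[0]])
    for a in axes[1:]:
        C = np.kron(C, _orthonormal_contrasts(Y.shape[a]))
    if n <= C.shape[1]:
        warnings.warn(
            "few subjects relative to effect df: epsilon estimate unstable",
            RuntimeWarning,
            stacklevel=3,
        )
    return _epsilon_from_cov(np.cov(Z, rowvar=False), C)


# ---------------------------------------------------------------------------
# Paired comparisons
# ---------------------------------------------------------------------------


class PairedTResult(NamedTuple):
    t: float
    df: int
    p: float
    cohen_d: float


def paired_t(x: Sequence[float], y: Sequence[float]) -> PairedTResult:
    """Two-sided paired t-test with Cohen's d = mean(diff)/SD(diff)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length vectors of length >= 2")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise ZeroVarianceError("all paired differences are identical")
    n = d.size
    t = d.mean() / (sd / math.sqrt(n))
    p = 2 * float(t_dist.sf(abs(t), n - 1))
    return PairedTResult(t=float(t), df=n - 1, p=p, cohen_d=float(d.mean() / sd))


def bonferroni(p_values: Sequence[float], m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, m * p) elementwise."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size if m is None else m
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.minimum(1.0, m * p)


class WilcoxonResult(NamedTuple):
    W: float
    p: float
    n: int
    method: str


def _signed_rank_distribution(int_ranks: np.ndarray) -> np.ndarray:
    """Null pmf of the positive-rank sum over all 2^n sign assignments.

    Dynamic programming over the (integer) rank values; equivalent to the
    full enumeration but polynomial in the total rank sum, and valid with
    midranks (ties) once ranks are doubled to integers.
    """
    total = int(int_ranks.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in int_ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r] if r > 0 else counts
        counts = counts + shifted
    return counts / counts.sum()


def wilcoxon_signed_rank(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 25
) -> WilcoxonResult:
    """Wilcoxon signed-rank test for paired samples.

    Zero differences are removed.  W is the smaller of the positive- and
    negative-rank sums.  The two-sided p-value is exact (full sign-flip
    null, computed by dynamic programming and valid under ties) for
    n <= ``exact_max_n`` after zero removal, and otherwise uses the normal
    approximation with the midrank tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        raise AllZeroDifferencesError("all paired differences are zero")
    n = d.size
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    total = n * (n + 1) / 2
    W = min(w_plus, total - w_plus)
    if n <= exact_max_n:
        int_ranks = np.rint(2 * ranks).astype(int)  # doubling makes midranks integral
        pmf = _signed_rank_distribution(int_ranks)
        k = int(round(2 * w_plus))
        cdf = float(pmf[: k + 1].sum())
        sf = float(pmf[k:].sum())
        p = min(1.0, 2 * min(cdf, sf))
        method = "exact"
    else:
        mean = total / 2
        tie_counts = np.unique(np.abs(d), return_counts=True)[1]
        var = n * (n + 1) * (2 * n + 1) / 24 - np.sum(tie_counts**3 - tie_counts) / 48
        z = (w_plus - mean) / math.sqrt(var)
        p = 2 * float(ndtr(-abs(z)))
        method = "normal"
    return WilcoxonResult(W=float(W), p=float(p), n=n, method=method)


# ---------------------------------------------------------------------------
# Power analysis (paired t, noncentral t)
# ---------------------------------------------------------------------------


def power_paired_t(n: int, d: float, alpha: float = 0.05, tails: int = 2) -> float:
    """Exact power of a paired t-test with n pairs at effect size d.

    Uses the noncentral t distribution with df = n - 1 and noncentrality
    |d| * sqrt(n).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    df = n - 1
    delta = abs(d) * math.sqrt(n)
    if tails == 2:
        tc = t_dist.ppf(1 - alpha / 2, df)
        return float(nct.sf(tc, df, delta) + nct.cdf(-tc, df, delta))
    tc = t_dist.ppf(1 - alpha, df)
    return float(nct.sf(tc, df, delta))


def required_sample_size_paired_t(
    d: float,
    alpha: float = 0.05,
    power: float = 0.95,
    tails: int = 2,
    n_max: int = 1_000_000,
) -> int:
    """Smallest n >= 2 whose exact noncentral-t power reaches the target."""
    if d == 0:
        raise ValueError("d must be nonzero")
    if not 0 < power < 1:
        raise ValueError("power must lie in (0, 1)")
    for n in range(2, n_max + 1):
        if power_paired_t(n, d, alpha=alpha, tails=tails) >= power:
            return n
    raise RuntimeError(f"no n <= {n_max} reaches the requested power")
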