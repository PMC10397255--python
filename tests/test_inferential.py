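"""RM ANOVA decomposition, epsilon, paired tests, Wilcoxon, power."""
from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import rankdata
from scipy.stats import t as t_dist
from scipy.stats import wilcoxon as scipy_wilcoxon

from symnum.inferential import (
    AllZeroDifferencesError,
    MissingCellError,
    UnbalancedDesignError,
    ZeroVarianceError,
    bonferroni,
    gg_epsilon,
    paired_t,
    power_paired_t,
    required_sample_size_paired_t,
    rm_anova,
    wilcoxon_signed_rank,
)
from symnum.inferential import _epsilon_from_cov, _orthonormal_contrasts


def long_table(Y, factors):
    """subjects x levels... array to a long-format frame."""
    rows = []
    shape = Y.shape[1:]
    for s in range(Y.shape[0]):
        for idx in itertools.product(*(range(k) for k in shape)):
            row = {"subject": f"S{s}", "y": Y[(s, *idx)]}
            for name, lev in zip(factors, idx):
                row[name] = f"{name}{lev}"
            rows.append(row)
    return pd.DataFrame(rows)


def definitional_two_way_ss(Y):
    """Textbook cell-means/marginal-means sums of squares for a 2-factor
    within-subject design, written with explicit loops (independent of the
    package's inclusion-exclusion implementation)."""
    n, a, b = Y.shape
    grand = Y.mean()
    ss = {}
    ss["A"] = n * b * sum((Y[:, i, :].mean() - grand) ** 2 for i in range(a))
    ss["B"] = n * a * sum((Y[:, :, j].mean() - grand) ** 2 for j in range(b))
    ss["A:B"] = n * sum(
        (Y[:, i, j].mean() - Y[:, i, :].mean() - Y[:, :, j].mean() + grand) ** 2
        for i in range(a)
        for j in range(b)
    )
    ss["subject"] = a * b * sum((Y[s].mean() - grand) ** 2 for s in range(n))
    ss["err_A"] = b * sum(
        (Y[s, i, :].mean() - Y[s].mean() - Y[:, i, :].mean() + grand) ** 2
        for s in range(n)
        for i in range(a)
    )
    ss["err_B"] = a * sum(
        (Y[s, :, j].mean() - Y[s].mean() - Y[:, :, j].mean() + grand) ** 2
        for s in range(n)
        for j in range(b)
    )
    ss["total"] = ((Y - grand) ** 2).sum()
    ss["err_AB"] = (
        ss["total"] - ss["subject"] - ss["A"] - ss["B"] - ss["A:B"] - ss["err_A"] - ss["err_B"]
    )
    return ss


def test_constant_dv_gives_zero_effect():
    Y = np.ones((6, 2, 3)) + np.arange(6)[:, None, None]  # subject offsets only
    res = rm_anova(long_table(Y, ["A", "B"]), "y", ["A", "B"], "subject")
    for name in ("A", "B", "A:B"):
        eff = res.effect(name)
        assert eff.ss == pytest.approx(0.0, abs=1e-18)
        assert eff.F == pytest.approx(0.0, abs=1e-12)


def test_two_level_factor_F_equals_squared_paired_t():
    rng = np.random.default_rng(1)
    x, y = rng.normal(0, 1, 12), rng.normal(0.4, 1, 12)
    df = long_table(np.stack([x, y], axis=1), ["A"])
    res = rm_anova(df, "y", ["A"], "subject")
    t = paired_t(x, y)
    assert res.effect("A").F == pytest.approx(t.t**2, rel=1e-12)
    assert res.effect("A").p == pytest.approx(t.p, rel=1e-12)
    assert res.effect("A").gg_epsilon == 1.0


def test_ss_decomposition_matches_definitional_oracle():
    rng = np.random.default_rng(2)
    Y = rng.normal(0, 1, (6, 2, 3)) + rng.normal(0, 1, (6, 1, 1))
    res = rm_anova(long_table(Y, ["A", "B"]), "y", ["A", "B"], "subject")
    oracle = definitional_two_way_ss(Y)
    assert res.effect("A").ss == pytest.approx(oracle["A"], rel=1e-10)
    assert res.effect("B").ss == pytest.approx(oracle["B"], rel=1e-10)
    assert res.effect("A:B").ss == pytest.approx(oracle["A:B"], rel=1e-10)
    assert res.effect("A").err_ss == pytest.approx(oracle["err_A"], rel=1e-10)
    assert res.effect("B").err_ss == pytest.approx(oracle["err_B"], rel=1e-10)
    assert res.effect("A:B").err_ss == pytest.approx(oracle["err_AB"], rel=1e-10)
    assert res.ss_subject == pytest.approx(oracle["subject"], rel=1e-10)
    assert res.ss_total == pytest.approx(oracle["total"], rel=1e-10)


def test_total_ss_is_conserved_in_three_factor_design():
    rng = np.random.default_rng(3)
    Y = rng.normal(0, 1, (8, 4, 2, 3))
    res = rm_anova(long_table(Y, ["A", "B", "C"]), "y", ["A", "B", "C"], "subject")
    assert len(res.table) == 7  # 3 mains + 3 two-way + 1 three-way
    parts = res.ss_subject + (res.table.ss + res.table.err_ss).sum()
    assert parts == pytest.approx(res.ss_total, rel=1e-12)
    # eta^2 uses the total denominator and therefore sums below 1
    assert res.table.eta_sq.between(0, 1).all()
    assert res.table.eta_sq.sum() < 1


def test_f_values_match_statsmodels_anova_rm():
    from statsmodels.stats.anova import AnovaRM

    rng = np.random.default_rng(4)
    Y = rng.normal(0, 1, (10, 2, 2, 4)) + rng.normal(0, 0.5, (10, 1, 1, 1))
    df = long_table(Y, ["A", "B", "D"])
    ours = rm_anova(df, "y", ["A", "B", "D"], "subject")
    theirs = AnovaRM(df, "y", "subject", within=["A", "B", "D"]).fit().anova_table
    for effect in ("A", "B", "D", "A:B", "A:D", "B:D", "A:B:D"):
        assert ours.effect(effect).F == pytest.approx(
            theirs.loc[effect, "F Value"], rel=1e-8
        )
        assert ours.effect(effect).p == pytest.approx(
            theirs.loc[effect, "Pr > F"], abs=1e-10
        )


def test_one_way_matches_pingouin_including_epsilon():
    import pingouin as pg

    rng = np.random.default_rng(5)
    Y = rng.normal(0, 1, (12, 4)) + rng.normal(0, 0.8, (12, 1))
    df = long_table(Y, ["A"])
    ours = rm_anova(df, "y", ["A"], "subject")
    theirs = pg.rm_anova(data=df, dv="y", within="A", subject="subject", correction=True)
    assert ours.effect("A").F == pytest.approx(theirs.loc[0, "F"], rel=1e-8)
    assert ours.effect("A").p == pytest.approx(theirs.loc[0, "p_unc"], abs=1e-10)
    assert ours.effect("A").gg_epsilon == pytest.approx(theirs.loc[0, "eps"], rel=1e-6)
    assert gg_epsilon(Y) == pytest.approx(theirs.loc[0, "eps"], rel=1e-6)


def test_unbalanced_and_missing_designs_rejected():
    rng = np.random.default_rng(6)
    Y = rng.normal(0, 1, (5, 2, 2))
    df = long_table(Y, ["A", "B"])
    with pytest.raises(UnbalancedDesignError):
        rm_anova(df.drop(index=0), "y", ["A", "B"], "subject")
    with pytest.raises(MissingCellError):
        rm_anova(df[df.A == "A0"], "y", ["A", "B"], "subject")


def test_gg_epsilon_bounds_and_special_cases():
    rng = np.random.default_rng(7)
    assert gg_epsilon(rng.normal(0, 1, (10, 2))) == 1.0
    # exact compound symmetry (identity + constant): sphericity holds
    k = 4
    cs = np.eye(k) + 0.5 * np.ones((k, k))
    assert _epsilon_from_cov(cs, _orthonormal_contrasts(k)) == pytest.approx(1.0, abs=1e-9)
    for seed in range(20):
        Z = np.random.default_rng(seed).normal(0, 1, (15, 4)) * [1, 2, 3, 4]
        assert 1 / 3 - 1e-12 <= gg_epsilon(Z) <= 1.0
    with pytest.warns(RuntimeWarning):
        gg_epsilon(rng.normal(0, 1, (3, 4)))


def test_paired_t_hand_example_and_errors():
    res = paired_t([2, 4, 6], [1, 2, 3])  # differences 1, 2, 3
    assert res.cohen_d == pytest.approx(2.0)
    assert res.t == pytest.approx(2 * np.sqrt(3), rel=1e-12)
    assert res.df == 2
    with pytest.raises(ZeroVarianceError):
        paired_t([1, 2, 3], [0, 1, 2])


def test_paired_t_p_close_to_sign_flip_null():
    # Exact sign-flip (randomization) null of the t statistic; for normal
    # samples of this size its p-value tracks the parametric one closely.
    rng = np.random.default_rng(8)
    for _ in range(5):
        d = rng.normal(0.5, 1, 15)
        res = paired_t(d, np.zeros_like(d))
        signs = np.array(list(itertools.product([-1.0, 1.0], repeat=15)))
        flipped = signs * d
        t_null = flipped.mean(axis=1) / (flipped.std(axis=1, ddof=1) / np.sqrt(15))
        p_perm = np.mean(np.abs(t_null) >= abs(res.t) - 1e-12)
        assert abs(res.p - p_perm) < 0.02


def test_bonferroni_examples():
    np.testing.assert_allclose(bonferroni([0.002], m=4), [0.008])
    np.testing.assert_allclose(bonferroni([0.5], m=4), [1.0])
    np.testing.assert_allclose(bonferroni([0.2, 0.04], m=1), [0.2, 0.04])


@given(st.lists(st.floats(0, 1), min_size=1, max_size=10))
def test_bonferroni_never_decreases_p(ps):
    adj = bonferroni(ps)
    assert np.all(adj >= np.asarray(ps) - 1e-15)
    assert np.all(adj <= 1.0)


def test_wilcoxon_all_positive_differences():
    res = wilcoxon_signed_rank([2, 3, 4, 5, 6], [1, 2, 3, 4, 5])
    assert res.W == 0.0
    assert res.p == pytest.approx(2 * (1 / 32))  # two-sided doubling of 1/2^5


def test_wilcoxon_antisymmetry():
    rng = np.random.default_rng(9)
    x, y = rng.normal(0.4, 1, 14), rng.normal(0, 1, 14)
    a = wilcoxon_signed_rank(x, y)
    b = wilcoxon_signed_rank(y, x)
    assert a.W == b.W and a.p == b.p


def test_wilcoxon_matches_full_enumeration_oracle():
    rng = np.random.default_rng(10)
    for rep in range(8):
        n = int(rng.integers(6, 13))
        d = np.round(rng.normal(0.4, 1, n), 1)  # rounding creates ties
        d = d[d != 0]
        if d.size < 2:
            continue
        res = wilcoxon_signed_rank(d, np.zeros_like(d))
        ranks = rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        total = ranks.sum()
        null = []
        for signs in itertools.product([0, 1], repeat=d.size):
            null.append(np.dot(signs, ranks))
        null = np.asarray(null)
        cdf = np.mean(null <= w_obs + 1e-9)
        sf = np.mean(null >= w_obs - 1e-9)
        p_exact = min(1.0, 2 * min(cdf, sf))
        assert res.p == pytest.approx(p_exact, abs=1e-12)
        assert res.W == pytest.approx(min(w_obs, total - w_obs))


def test_wilcoxon_matches_scipy_without_ties():
    rng = np.random.default_rng(11)
    d = rng.normal(0.3, 1, 18)
    res = wilcoxon_signed_rank(d, np.zeros_like(d))
    ref = scipy_wilcoxon(d, mode="exact") if hasattr(scipy_wilcoxon, "mode") else scipy_wilcoxon(d, method="exact")
    assert res.p == pytest.approx(ref.pvalue, abs=1e-12)


def test_wilcoxon_exact_and_normal_branches_agree_at_boundary():
    rng = np.random.default_rng(12)
    d = rng.normal(0.3, 1, 25)
    exact = wilcoxon_signed_rank(d, np.zeros_like(d), exact_max_n=25)
    approx = wilcoxon_signed_rank(d, np.zeros_like(d), exact_max_n=10)
    assert exact.method == "exact" and approx.method == "normal"
    assert abs(exact.p - approx.p) < 0.01


def test_wilcoxon_rejects_all_zero_differences():
    with pytest.raises(AllZeroDifferencesError):
        wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])


def test_required_sample_size_for_study_effect():
    assert required_sample_size_paired_t(0.75, 0.05, 0.95, tails=2) == 26
    # independent cross-check via statsmodels' power solver
    from statsmodels.stats.power import TTestPower

    n_sm = TTestPower().solve_power(effect_size=0.75, alpha=0.05, power=0.95)
    assert int(np.ceil(n_sm)) == 26


def test_sample_size_monotone_in_effect_size():
    ns = [required_sample_size_paired_t(d, 0.05, 0.95) for d in (0.3, 0.5, 0.75, 1.0, 1.5)]
    assert all(a >= b for a, b in zip(ns, ns[1:]))


def test_one_tailed_needs_fewer_subjects():
    n2 = required_sample_size_paired_t(0.75, 0.05, 0.95, tails=2)
    n1 = required_sample_size_paired_t(0.75, 0.05, 0.95, tails=1)
    assert n1 < n2


def test_power_null_and_monotonicity():
    assert power_paired_t(26, 0.0) == pytest.approx(0.05, abs=1e-6)
    powers = [power_paired_t(n, 0.5) for n in range(5, 60, 5)]
    assert all(a < b for a, b in zip(powers, powers[1:]))


def test_condition_effect_detected_in_nearly_all_replicate_cohorts():
    """Power sanity: with the single-task symmetric-standard multiplier
    0.9213, the condition main effect of the bias ANOVA reaches p < .001 in
    at least 95% of replicate cohorts (26 subjects, one 50-trial session
    per cell)."""
    from tests.conftest import simulate_cells

    hits = 0
    n_rep = 100
    for rep in range(n_rep):
        _, cells = simulate_cells(
            tasks=("ST",), bias=0.9213, noise=0.2096, bias_sd=0.045, noise_sd=0.03,
            n_participants=26, sessions=1, trials_per_session=50, seed=4000 + rep,
        )
        ok = cells[~cells.excluded]
        complete = ok.groupby("participant_id").size() == 8
        ok = ok[ok.participant_id.isin(complete[complete].index)]
        res = rm_anova(
            ok.rename(columns={"bias_pct": "value"}),
            "value",
            ["standard_n", "condition"],
            "participant_id",
        )
        if res.effect("condition").p < 0.001:
            hits += 1
    assert hits / n_rep >= 0.95, hits


def test_power_matches_monte_carlo_oracle():
    rng = np.random.default_rng(13)
    n, d = 26, 0.75
    sims = 100_000
    x = rng.normal(d, 1.0, size=(sims, n))
    t = x.mean(axis=1) / (x.std(axis=1, ddof=1) / np.sqrt(n))
    crit = t_dist.ppf(0.975, n - 1)
    mc = np.mean(np.abs(t) > crit)
    exact = power_paired_t(n, d)
    se = np.sqrt(exact * (1 - exact) / sims)
    assert abs(mc - exact) < 3 * se
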