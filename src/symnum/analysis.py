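"""The study's analysis battery applied to a simulated trial table.

Mirrors the original analysis plan: per-cell psychometric fits feed bias
and Weber-fraction tables; biases enter two repeated-measures ANOVAs
(single task without vs with distractor, then single-with-distractor vs
dual task), Weber fractions enter a three-task ANOVA; Bonferroni-corrected
paired t-tests probe the condition contrasts; and conjunction-task accuracy
under the dual task is compared between conditions with a Wilcoxon
signed-rank test.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inferential import (
    AnovaResult,
    bonferroni,
    paired_t,
    rm_anova,
    wilcoxon_signed_rank,
)
from .psychometrics import aggregate_cells

__all__ = [
    "AnalysisReport",
    "summarize_cells",
    "bias_anova",
    "wf_anova",
    "condition_posthocs",
    "task_posthocs_wf",
    "conjunction_accuracy",
    "run_standard_battery",
]


def _participant_table(cells: pd.DataFrame, value: str, tasks: list[str]) -> pd.DataFrame:
    sub = cells[cells["task"].isin(tasks) & ~cells["excluded"]]
    return sub[["participant_id", "task", "condition", "standard_n", value]].rename(
        columns={value: "value"}
    )


def bias_anova(cells: pd.DataFrame, tasks: list[str]) -> AnovaResult:
    """RM ANOVA on the bias index with numerosity, condition (and task)."""
    data = _participant_table(cells, "bias_pct", tasks)
    within = ["standard_n", "condition"] + (["task"] if len(tasks) > 1 else [])
    return rm_anova(data, "value", within, "participant_id")


def wf_anova(cells: pd.DataFrame, tasks: list[str]) -> AnovaResult:
    """RM ANOVA on Weber fractions with numerosity, condition (and task)."""
    data = _participant_table(cells, "wf", tasks)
    within = ["standard_n", "condition"] + (["task"] if len(tasks) > 1 else [])
    return rm_anova(data, "value", within, "participant_id")


def _participant_means(
    cells: pd.DataFrame, value: str, by: list[str]
) -> pd.DataFrame:
    ok = cells[~cells["excluded"]]
    return (
        ok.groupby(["participant_id", *by], sort=True)[value].mean().reset_index()
    )


def condition_posthocs(cells: pd.DataFrame, task: str) -> pd.DataFrame:
    """Symmetric vs random bias at each standard numerosity (one family).

    Bonferroni-corrected over the four numerosities, as in the study's
    post-hoc comparisons.
    """
    sub = cells[(cells["task"] == task) & ~cells["excluded"]]
    rows = []
    for n, grp in sub.groupby("standard_n"):
        wide = grp.pivot(index="participant_id", columns="condition", values="bias_pct")
        res = paired_t(wide["symmetry"].to_numpy(), wide["random"].to_numpy())
        rows.append(
            {
                "family": f"bias_{task}_sym_vs_rand",
                "comparison": f"N={n}",
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "cohen_d": res.cohen_d,
            }
        )
    out = pd.DataFrame(rows)
    out["m"] = len(out)
    out["p_bonf"] = bonferroni(out["p"].to_numpy())
    return out


def task_posthocs_wf(cells: pd.DataFrame, tasks: list[str]) -> pd.DataFrame:
    """Pairwise task comparisons of participant-mean Weber fractions."""
    means = _participant_means(cells[cells["task"].isin(tasks)], "wf", ["task"])
    wide = means.pivot(index="participant_id", columns="task", values="wf")
    rows = []
    pairs = [(a, b) for i, a in enumerate(tasks) for b in tasks[i + 1 :]]
    for a, b in pairs:
        res = paired_t(wide[a].to_numpy(), wide[b].to_numpy())
        rows.append(
            {
                "family": "wf_task",
                "comparison": f"{a} vs {b}",
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "cohen_d": res.cohen_d,
            }
        )
    out = pd.DataFrame(rows)
    out["m"] = len(out)
    out["p_bonf"] = bonferroni(out["p"].to_numpy())
    return out


def dual_task_bias_posthocs(cells: pd.DataFrame) -> pd.DataFrame:
    """The attentional-modulation contrasts (one 3-comparison family):
    symmetric bias dual vs single-with-distractor, random bias dual vs
    single-with-distractor, and symmetric vs random within the dual task."""
    means = _participant_means(
        cells[cells["task"].isin(["ST_WD", "DT"])], "bias_pct", ["task", "condition"]
    )
    wide = means.pivot(
        index="participant_id", columns=["task", "condition"], values="bias_pct"
    )
    comparisons = [
        ("sym DT vs ST_WD", ("DT", "symmetry"), ("ST_WD", "symmetry")),
        ("rand DT vs ST_WD", ("DT", "random"), ("ST_WD", "random")),
        ("DT sym vs rand", ("DT", "symmetry"), ("DT", "random")),
    ]
    rows = []
    for label, a, b in comparisons:
        res = paired_t(wide[a].to_numpy(), wide[b].to_numpy())
        rows.append(
            {
                "family": "bias_dual_task",
                "comparison": label,
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "cohen_d": res.cohen_d,
            }
        )
    out = pd.DataFrame(rows)
    out["m"] = len(out)
    out["p_bonf"] = bonferroni(out["p"].to_numpy())
    return out


def conjunction_accuracy(trials: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Dual-task conjunction accuracy per participant and condition,
    compared between conditions with the Wilcoxon signed-rank test."""
    dt = trials[(trials["task"] == "DT") & trials["conj_correct"].notna()]
    if dt.empty:
        return pd.DataFrame(), {}
    acc = (
        dt.groupby(["participant_id", "condition"])["conj_correct"]
        .mean()
        .reset_index(name="prop_correct")
    )
    wide = acc.pivot(index="participant_id", columns="condition", values="prop_correct")
    res = wilcoxon_signed_rank(wide["random"].to_numpy(), wide["symmetry"].to_numpy())
    stats = {
        "mean_random": float(wide["random"].mean()),
        "std_random": float(wide["random"].std(ddof=1)),
        "mean_symmetry": float(wide["symmetry"].mean()),
        "std_symmetry": float(wide["symmetry"].std(ddof=1)),
        "W": res.W,
        "p": res.p,
        "n": res.n,
        "method": res.method,
    }
    return acc, stats


def summarize_cells(
    cells: pd.DataFrame,
    n_boot: int = 2000,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Cohort-mean bias and Wf per task x condition x standard numerosity,
    with bootstrap-over-participants 95% confidence intervals."""
    rng = np.random.default_rng(0) if rng is None else rng
    ok = cells[~cells["excluded"]]
    rows = []
    for (task, condition, n), grp in ok.groupby(["task", "condition", "standard_n"]):
        for value in ("bias_pct", "wf"):
            vals = grp[value].to_numpy()
            boots = np.array(
                [vals[rng.integers(0, len(vals), len(vals))].mean() for _ in range(n_boot)]
            )
            lo, hi = np.percentile(boots, [2.5, 97.5])
            rows.append(
                {
                    "task": task,
                    "condition": condition,
                    "standard_n": n,
                    "measure": value,
                    "mean": float(vals.mean()),
                    "ci_lo": float(lo),
                    "ci_hi": float(hi),
                    "n_participants": len(vals),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class AnalysisReport:
    """All outputs of the standard battery for one trial table."""

    cells: pd.DataFrame
    summary: pd.DataFrame
    anovas: dict[str, AnovaResult] = field(default_factory=dict)
    posthocs: pd.DataFrame = field(default_factory=pd.DataFrame)
    conjunction: dict = field(default_factory=dict)
    conjunction_acc: pd.DataFrame = field(default_factory=pd.DataFrame)

    def anova_records(self) -> dict[str, list[dict]]:
        return {name: res.to_records() for name, res in self.anovas.items()}

    def to_markdown(self) -> str:
        lines = ["# Simulated-cohort analysis summary", ""]
        lines.append("## Cohort-mean bias and Weber fraction (bootstrap 95% CI)")
        lines.append("")
        lines.append("| task | condition | N | measure | mean | 95% CI |")
        lines.append("|---|---|---|---|---|---|")
        for _, r in self.summary.iterrows():
            lines.append(
                f"| {r['task']} | {r['condition']} | {r['standard_n']} | "
                f"{r['measure']} | {r['mean']:.3f} | "
                f"[{r['ci_lo']:.3f}, {r['ci_hi']:.3f}] |"
            )
        for name, res in self.anovas.items():
            lines += ["", f"## RM ANOVA: {name}", "", "```", res.summary(), "```"]
        if not self.posthocs.empty:
            lines += ["", "## Post-hoc paired t-tests (Bonferroni within family)", ""]
            lines.append("| family | comparison | t | df | p | p_bonf | d |")
            lines.append("|---|---|---|---|---|---|---|")
            for _, r in self.posthocs.iterrows():
                lines.append(
                    f"| {r['family']} | {r['comparison']} | {r['t']:.3f} | "
                    f"{r['df']} | {r['p']:.4f} | {r['p_bonf']:.4f} | {r['cohen_d']:.3f} |"
                )
        if self.conjunction:
            c = self.conjunction
            lines += [
                "",
                "## Conjunction-task accuracy (dual task)",
                "",
                f"random: mean {c['mean_random']:.3f} (sd {c['std_random']:.3f}); "
                f"symmetry: mean {c['mean_symmetry']:.3f} (sd {c['std_symmetry']:.3f})",
                f"Wilcoxon signed-rank: W = {c['W']:.1f}, p = {c['p']:.4f} "
                f"({c['method']}, n = {c['n']})",
            ]
        return "\n".join(lines) + "\n"


def run_standard_battery(
    trials: pd.DataFrame,
    cells: pd.DataFrame | None = None,
    lapse: float = 0.0,
    seed: int = 0,
) -> AnalysisReport:
    """Fit all cells and run every applicable piece of the battery.

    ANOVAs and post-hoc families are included only when the trial table
    contains the tasks they need, so reduced designs analyse cleanly.
    """
    if cells is None:
        cells = aggregate_cells(trials, lapse=lapse)
    tasks = [t for t in ("ST", "ST_WD", "DT") if t in set(trials["task"])]
    report = AnalysisReport(
        cells=cells,
        summary=summarize_cells(cells, rng=np.random.default_rng(seed)),
    )
    posthoc_frames = []
    if {"ST", "ST_WD"} <= set(tasks):
        report.anovas["bias: ST vs ST_WD"] = bias_anova(cells, ["ST", "ST_WD"])
    if {"ST_WD", "DT"} <= set(tasks):
        report.anovas["bias: ST_WD vs DT"] = bias_anova(cells, ["ST_WD", "DT"])
        posthoc_frames.append(dual_task_bias_posthocs(cells))
    if len(tasks) == 1:
        report.anovas[f"bias: {tasks[0]}"] = bias_anova(cells, tasks)
    report.anovas["wf: " + " vs ".join(tasks)] = wf_anova(cells, tasks)
    for task in tasks:
        posthoc_frames.append(condition_posthocs(cells, task))
    if len(tasks) > 1:
        posthoc_frames.append(task_posthocs_wf(cells, tasks))
    report.posthocs = pd.concat(posthoc_frames, ignore_index=True)
    report.conjunction_acc, report.conjunction = conjunction_accuracy(trials)
    return report
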