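# symnum

Simulation and analysis of the **symmetry-induced numerosity underestimation
effect** and its modulation by visual attention.

When people compare the numerosity of two dot arrays, mirror-symmetric
arrays are judged less numerous than random ones — a Gestalt-grouping
illusion of roughly 6–8% with full attention, which shrinks by about half
when attention is consumed by a concurrent colour–orientation conjunction
task.  `symnum` provides a complete, testable *in silico* version of such a
dual-task experiment for psychophysicists who want to validate analysis
pipelines, run power analyses, or explore how design choices propagate into
the recovered indices:

- **stimuli** — random and vertically mirror-symmetric dot arrays under the
  standard geometric constraints (10° field, 0.3° dots, 0.3° separation,
  central 1.6°×1.6° exclusion), with convex-hull audits;
- **observers** — generative participants with scalar internal noise
  (SD = s·N), a multiplicative underestimation b of the symmetric standard,
  lapses, and conjunction-task accuracy;
- **QUEST** — a Bayesian adaptive staircase on log₁₀(test/standard) placing
  each trial near the point of subjective equality (PSE), with placement
  jitter so the slope stays estimable;
- **psychometrics** — per-cell binomial maximum-likelihood fits of the
  cumulative Gaussian P(test more | x) = λ/2 + (1−λ)Φ((x−μ)/σ), and the
  two standard indices

  `Bias = (PSE_N / N − 1) × 100`  and  `Wf = JND / N`, `JND = z₀.₇₅·σ`;

- **inference** — fully-factorial repeated-measures ANOVA (classical η²,
  Greenhouse–Geisser correction), Bonferroni-corrected paired t-tests with
  Cohen's d, exact small-sample Wilcoxon signed-rank, and noncentral-t
  power / sample-size analysis.

The default synthetic cohort reproduces the published study conditions:
26 participants, standards {8, 12, 24, 50}, 800 QUEST-driven trials per
task (400 symmetric + 400 random), generative biases of −7.87% (single
task), −6.4% (single task with ignored distractor) and −3% (dual task), and
Weber fractions of 0.20 (single) and 0.38 (dual).

## Worked example

Simulate a 26-participant cohort for the single-task-with-distractor and
dual-task conditions, fit every cell, and run the analysis battery:

```python
import numpy as np
from symnum import (DesignSpec, PopulationParams, sample_cohort,
                    run_simulated_experiment, run_standard_battery)

design = DesignSpec(tasks=("ST_WD", "DT"), n_participants=26, seed=7)
cohort = sample_cohort(26, PopulationParams(), np.random.default_rng(1))
trials = run_simulated_experiment(design, cohort)   # 41,600 trials, ~3 s
report = run_standard_battery(trials)

cells = report.cells
print(cells[~cells.excluded].groupby(["task", "condition"])
      [["bias_pct", "wf"]].mean().round(2))
print(report.anovas["bias: ST_WD vs DT"].summary())
```

prints

```
                 bias_pct    wf
task  condition
DT    random         0.41  0.37
      symmetry      -2.22  0.37
ST_WD random        -0.18  0.20
      symmetry      -6.45  0.19

Repeated-measures ANOVA (26 subjects)
==============================================================================
effect                        df         F         p   eta^2  GG eps     p[GG]
------------------------------------------------------------------------------
standard_n                 3, 75     1.073    0.3659   0.007   0.855    0.3603
condition                  1, 25    35.740    0.0000   0.096   1.000    0.0000
task                       1, 25    14.271    0.0009   0.028   1.000    0.0009
standard_n:condition       3, 75     1.870    0.1418   0.012   0.931    0.1464
standard_n:task            3, 75     0.208    0.8903   0.001   0.874    0.8665
condition:task             1, 25    12.598    0.0016   0.016   1.000    0.0016
standard_n:condition:task   3, 75     1.601    0.1962   0.008   0.835    0.2042
------------------------------------------------------------------------------
```

Reading the output: random-condition biases sit at zero while symmetric
arrays are underestimated, much more in the single task (−6.45%) than under
attentional load (−2.22%); the significant `condition:task` interaction
(F(1,25) = 12.6, p = .002) is the attentional modulation of the illusion.
Weber fractions double under load (0.20 → 0.37) but do not differ between
arrangements.  The Bonferroni post-hocs in `report.posthocs` confirm the
dual-task symmetric bias is reduced but still negative
(`DT sym vs rand: t = −3.16, p_bonf = .012, d = −0.62`), and the
conjunction task is slightly less accurate alongside symmetric arrays
(0.940 vs 0.959, Wilcoxon W = 23).

The same pipeline is available from the shell:

```bash
symnum simulate --out run/                # bundled default config
symnum analyze  --trials run/trials.csv --out run/
symnum power    --d 0.75                  # -> required n = 26 (power 0.9567)
symnum report   --cells run/cells.csv --out run/
```

`simulate` writes `trials.csv`, `cohort.json` and a validated config echo;
`analyze` writes `cells.csv`, `anova.json`, `posthoc.csv` and `summary.md`
with bootstrap confidence intervals.

## Layout

```
src/symnum/
  stimgen.py        dot-array generation and validation
  observer.py       generative observer model
  quest.py          Bayesian adaptive staircase
  experiment.py     design schedule, population model, cohort simulation
  psychometrics.py  cumulative-Gaussian MLE, Bias / JND / Wf
  inferential.py    RM ANOVA, GG epsilon, t / Wilcoxon / power
  analysis.py       the full analysis battery
  config.py         validated JSON run configuration
  cli.py            simulate / analyze / power / report commands
docs/methods.md     model, parameters, design decisions, limitations
```
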