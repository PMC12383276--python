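# nutflex

**Macronutrient regulation and metabolic flexibility in wild primates.**

Field studies of frugivorous primates pair full-day feeding follows (daily
kcal of protein, nonstructural carbohydrates, fiber and lipid) with
next-morning urine samples carrying biomarkers of metabolic state
(C-peptide of insulin, urea, δ15N, ketone bodies) and a habitat-level
fruit availability index (FAI, the monthly percentage of monitored trees
in fruit).  `nutflex` is a toolkit for the statistical chain such studies
need:

* **Intake accounting** — FAI computation, median-split low/high fruit
  periods, daily macronutrient kcal, non-protein energy (NPe) and
  macronutrient ratios.
* **Protein-leverage power law** — a hierarchical Bayesian fit of
  log %P = c + a_j + L·log E: the exponent *L* measures protein
  prioritization (*L* = −1 constant absolute protein, *L* = 0 constant
  proportion), with Bayesian R² and per-individual random intercepts
  integrated out analytically.
* **Robust correlation** — multivariate Student-t correlation with an
  LKJ vine prior and per-individual random intercepts, used to screen
  intake variables for concurvity before smooth regression.
* **Bayesian penalized-spline GAMMs** — each biomarker or intake response
  on one predictor through a low-rank thin-plate smooth, with Gaussian /
  log-normal / gamma / Bernoulli likelihoods and maximal random effects.
* **Posterior derivative inference** — finite-difference first
  derivatives of fitted smooths per posterior draw, flagging regions
  where the response is credibly rising or falling.
* **Biomarker preparation** — specific-gravity dilution correction
  (reference SG 1.023), exclusion of overly dilute samples (SG < 1.002),
  assay-CV filtering (>15%), ketone presence coding, and matching of each
  urine sample to the previous day's full feeding follow.
* **Synthetic-data generator** — phenology, follow and urine tables with
  known ground truth (scenario-controlled prioritization exponent,
  saturating NPe(FAI) link, biomarker links, SG dilution), so the whole
  pipeline is testable without field data.

Models follow the statsmodels idiom: build a model object from a
DataFrame, call `.fit()`, get a results object with draws, `summary()`,
diagnostics and plotting hooks.

## Worked example

```python
import numpy as np
from nutflex import (
    SimConfig, make_truth, simulate_phenology, simulate_follows,
    ProteinLeverageModel,
)

cfg = SimConfig()                                    # 40 individuals x 40 days
truth = make_truth("partial_prioritization", seed=7) # generating exponent -0.73
phen = simulate_phenology(cfg, truth)
follows = simulate_follows(cfg, truth, phen)

res = ProteinLeverageModel(follows[follows.full_day]).fit(profile="test", seed=2)
print(f"L = {res.L.mean():.3f}  95% CI "
      f"[{np.quantile(res.L, 0.025):.3f}, {np.quantile(res.L, 0.975):.3f}]")
r2 = res.bayes_r2()
print(f"Bayesian R^2 = {r2['mean']:.3f} ({r2['ci_low']:.3f} to {r2['ci_high']:.3f})")
print(res.interpret()["label"])
```

prints

```
L = -0.744  95% CI [-0.772, -0.715]
Bayesian R^2 = 0.664 (0.641 to 0.685)
strong but not complete
```

The credible interval covers the generating exponent −0.73; the label
reads the posterior against the two benchmarks (−1 complete, 0 none) and
reports a strong-but-incomplete prioritizer, the pattern typical of
frugivorous primates.  An end-to-end run — simulate → clean → match →
fit → detect regions → report — is one call:

```bash
nutflex run-all out/ --scenario partial_prioritization --seed 1 \
    --analyses power,correlation
```

which writes every intermediate table, fit summaries, region tables, a
`report.md` and a manifest with artifact hashes (reruns with the same
configuration are bit-identical).

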