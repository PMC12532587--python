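# attrecho

Statistical toolkit for echocardiographic endpoints in longitudinal
placebo-controlled trials of transthyretin amyloidosis with cardiomyopathy
(ATTR-CM), written for trial statisticians and methodologists. It covers
the full analysis chain for a 30-month trial with assessments at baseline
and months 12/18/24/30:

* **Echo parameter derivation** — mean LV wall thickness, relative wall
  thickness, Devereux LV mass indexed to body surface area, biplane
  Simpson volumes and LVEF, LVOT stroke volume, E/A and E/e′ ratios — with
  a parameter registry carrying units and each parameter's clinically
  "worse" direction of change.
* **Primary analysis** — a mixed model for repeated measures (MMRM) of
  change from baseline with a 4×4 unstructured within-subject covariance,
  fit by REML over a log-Cholesky parameterization with analytic
  gradients. Fixed effects: treatment-by-visit cell means, baseline value,
  ATTR genotype, age group, and (in the overall population) baseline
  tafamidis use and its interaction with treatment. Output: LS means per
  arm and the placebo-corrected difference at each visit with
  Satterthwaite-df CIs and p-values.
* **Sensitivity analysis** — a four-pattern pattern-mixture multiple
  imputation: worst-decile sampling after death, MAR MI by
  multivariate-normal MCMC data augmentation for on-treatment gaps,
  retrieved-dropout regression or copy-reference imputation for
  off-treatment gaps (126-day window = 1.5 × the 84-day dosing interval,
  ≥10 retrieved dropouts for sufficiency), every imputed change capped at
  0 − baseline; then an ANCOVA per completed dataset pooled by Rubin's
  rules with Barnard–Rubin degrees of freedom.
* **Synthetic trial generator** — seeded, with known ground-truth effects,
  configurable MCAR/MAR/MNAR missingness, deaths and discontinuations, so
  every estimator is testable without access-restricted trial data.

The model, in brief: for patient *i* at post-baseline visit *t*,

    y_it = x_it' β + e_i,    e_i ~ N(0, Σ_{obs(i)})

where y is the change from baseline, Σ is unstructured over the four
visits and each patient contributes the submatrix matching their observed
visits. Rubin pooling uses q̄ = m⁻¹Σq_i, T = ū + (1+1/m)b.

## Worked example

```python
from attrecho import (TrialConfig, simulate_trial, apply_missingness,
                      ModelSpec, analyze)
from attrecho.imputation import run_pattern_mixture
from attrecho.pooling import sensitivity_report

cfg = TrialConfig(seed=3)             # stroke-volume scale, true effect +4.1 ml
ds = apply_missingness(simulate_trial(cfg), cfg)

fit, contrasts = analyze(ds, ModelSpec(population="overall"))
c30 = contrasts[-1]
print(f"MMRM month-30 difference {c30.difference:.2f} ml "
      f"(95% CI {c30.ci_low:.2f}, {c30.ci_high:.2f}; p={c30.p_value:.4f})")

run = run_pattern_mixture(ds, m=100, seed=3)
pooled, _ = sensitivity_report(run, ModelSpec(population="overall"))
print(f"pattern-mixture pooled difference {pooled.q_bar:.2f} ml "
      f"(95% CI {pooled.ci_low:.2f}, {pooled.ci_high:.2f}; p={pooled.p_value:.4f})")
```

prints (seed 3):

```
MMRM month-30 difference 2.85 ml (95% CI 0.41, 5.30; p=0.0223)
pattern-mixture pooled difference 3.45 ml (95% CI 0.91, 5.99; p=0.0080)
```

The simulated truth is a +4.1 ml month-30 treatment effect; both the
primary MMRM and the pattern-mixture sensitivity estimate recover it
within sampling error for this single replicate, and the two agree with
each other — the robustness property the sensitivity analysis probes.

The same pipeline is available from the shell:

```bash
attrecho simulate --out trial.csv --seed 3
attrecho report --data trial.csv
attrecho analyze --data trial.csv --population overall
attrecho sensitivity --data trial.csv --m 100 --seed 3
```

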