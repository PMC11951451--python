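# smoketrends

Bayesian calibration of a compartmental life-course model of smoking
behaviour, exercised end to end on synthetic cross-sectional surveys with
known ground truth.

## The problem

Simulation models of population smoking behaviour feed burden-of-disease
estimates and tobacco-policy forecasts, but most are calibrated without a
coherent account of parameter uncertainty. This package implements a full
Bayesian calibration pipeline for such a model: a birth cohort of one sex
starts at age 20 split between never-smokers and initiators (proportion
P_I, of whom a fraction P_F already quit), current smokers quit permanently
at a rate λ_Q(age, year), quitters pass through a two-year recently-quit
state into a formerly-smoked state classified by age at quitting (<30,
30–39, ≥40), and long-term former smokers may switch to *reporting* that
they never smoked at a group-specific rate λ_R. Everyone is exposed to
status-specific mortality tied to the observed population rate μ through
the mixture identity

    μ = μ_N·ρ_N + HR_C·μ_N·ρ_C + HR_F·μ_N·ρ_F

where ρ_N, ρ_C, ρ_F are the alive-conditional never/current/former
proportions and HR_C, HR_F the hazard ratios of death for current and
former smokers; the identity is inverted at every integration substep to
recover the never-smoker baseline μ_N.

P_I is a logit-linked natural cubic spline in birth year, log λ_Q the sum
of natural cubic splines in age and calendar year, and λ_R is constant per
age-at-quit group. Cross-sectional survey cross-tabs (by survey, sex and
age) enter a Dirichlet likelihood with concentration set by the weighted
category proportions and the Kish effective sample size of each cell;
survey weights are raked to population margins by iterative proportional
fitting. The posterior over the full parameter block — including the
log hazard ratios, which carry an informative prior from an external
cohort-study summary — is sampled by blockwise adaptive random-walk
Metropolis (Metropolis-within-Gibbs), with MAP estimation, profile-
posterior identifiability diagnostics, prior/posterior overlap statistics,
DIC model selection across a nested ladder of eight variants, and
posterior-predictive checks.

Because the real inputs (26 national surveys, population mortality, the
cohort-study hazard ratios) are not redistributable, the package ships a
synthetic-data module that generates all three inputs from a known truth —
including selection bias with design weights, missing age-at-quit, optional
overdispersion, and a two-category early-poll dialect — so that every
pipeline stage is testable and the acceptance surface is recovery of that
truth.

## Worked example

```python
import numpy as np
from smoketrends import (Scenario, make_truth, make_mortality,
                         make_hr_study, make_surveys, fit_variant,
                         variant_ladder)
from smoketrends.surveys import add_age_bands, build_cells, rake_weights, CellConfig
from smoketrends.inference import McmcConfig
from smoketrends.params import report_rate

sc = Scenario.small()                      # 6 surveys x 2000 respondents
truth = make_truth(sc)
mort = make_mortality(truth)
hr_prior = make_hr_study(truth)
table, margins = make_surveys(truth, mort)

banded = add_age_bands(table)
w = np.empty(len(banded))
for _, g in banded.groupby("survey_id", sort=False):
    w[g.index] = rake_weights(g, margins)
cells = build_cells(table, w, CellConfig(age_group_width=5))

fit = fit_variant(cells, mort, hr_prior, variant_ladder()[5], seed=20260929,
                  mcmc=McmcConfig(burn_in=400, max_sweeps=2000), n_chains=2)
med = fit.evaluator.as_theta(np.median(fit.sample.draws, axis=0))
lam = 100 * report_rate(0, "F", med, fit.variant)
print(f"reporting-as-never (<30, women): {lam:.2f} per 100 person-years")
```

prints (a few minutes of sampling later):

```
reporting-as-never (<30, women): 1.50 per 100 person-years
```

against a generating truth of 2.05 per 100 person-years — within the
posterior's 90% interval for this data realisation; the direction and
magnitude of such offsets along the weakly identified reporting-as-never /
initiation ridge are discussed in `docs/methods.md`.

The `analysis/` directory holds the same pipeline as numbered drivers
(`01_simulate.py` … `06_summarise.py`), each writing delimited-text tables
under `results/`.

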