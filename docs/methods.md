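# Methods

## Model

One birth cohort of one sex is followed from age 20 in thirteen
compartments: never-smoked; currently-smoking; a recently-quit conveyor of
two one-year slots per age-at-quit group (<30, 30–39, ≥40); formerly-smoked
per group; reporting-as-never; and cumulative dead. Transitions are:
current → recently-quit at the quit rate λ_Q(age, year, sex) (a permanent
quit event — no relapse is modelled, so λ_Q is a *permanent* cessation
rate); the conveyor advances deterministically once per year, so quitters
reach the formerly-smoked state after exactly two years; former →
reporting-as-never at λ_R(group, sex). The age-at-quit group is the group
of the age at which the quit event occurs.

Mortality is status-specific: never-smokers and reporting-as-never die at
μ_N, current and recently-quit smokers at HR_C·μ_N, former smokers at
HR_F·μ_N, with the hazard ratios piece-wise constant over age strata.  μ_N
is not an input: it is recovered from the all-cause population rate
μ(age, sex, year) through the mixture identity
μ = μ_N(ρ_N + HR_C ρ_C + HR_F ρ_F), where the ρ are the cohort's own
alive-conditional pooled proportions. Each (age, calendar-year) pair maps
to exactly one cohort, so the identity is solvable within the cohort.

The age-20 initial state is: never = 1−P_I; current = P_I(1−P_F); the quit
mass P_I·P_F all in the <30 group, a fraction `recent_fraction` (default
0.5) of it still in the conveyor — split evenly over the two slots, since
nothing identifies the within-conveyor allocation — and the rest in
formerly-smoked.

## Parameterisation

logit P_I is an intercept plus a natural cubic spline in birth year
(domain 1910–1996); log λ_Q is an intercept plus separable natural cubic
splines in age (20–99) and calendar year (1930–2016, or birth cohort under
a sensitivity toggle); λ_R is constant per group and sex. Splines use the
truncated-power natural basis with boundary knots at the domain ends and
equally spaced interior knots; `df = 1` degenerates to a centred linear
term. All behavioural blocks are sex-specific.

Eight nested variants A–H grow from an intercepts-only null (A) by adding
time df, then age df, then birth df, then reporting-as-never groups (<30,
then 30–39), with G adding the ≥40 group and H one further birth df. The
selected rung F has three birth-year df, two age df, two year df and
reporting-as-never for quitters under 40.

## Priors

Informative Gaussian priors on the log hazard ratios (mean/SE from an
external cohort-study summary) — this is what resolves the structural
non-identifiability of the quartet (λ_Q, λ_R, μ_C, μ_F): the observed
proportions identify any three given the fourth. P_F is uniform on
[0, 0.5]. Spline coefficients get zero-mean Gaussians: intercepts with SD
10 on the link scale; non-intercept coefficients of bases standardised to
unit sample variance over the observed covariate values (this is the data
dependence) with scale τ, one nuisance scale each for initiation and
cessation, each with a half-Cauchy(0, 2.5) hyperprior. λ_R carries the
improper scale prior 1/λ_R (flat on log λ_R; proper truncation bounds are
used only when *sampling* from the prior). MAP and MCMC operate on an
unconstrained working scale (logit for P_F rescaled to [0, 0.5], log for
rates and scales) with the change-of-variable Jacobians included.

## Likelihood

Each survey × sex × age cell contributes a Dirichlet log-density evaluated
at the model's observation-category probabilities with concentration
α_k = eff_n·p̂_k + ε, where p̂ are the weighted category proportions and
eff_n the Kish effective sample size (Σw)²/Σw² of the cell. Observation
categories pool the model states: current = currently-smoking +
recently-quit; never = never + reporting-as-never; former per age-at-quit
group. Two-category early-poll dialects use (current, not-current). In
surveys where a fraction of former smokers lack age-at-quit, the
survey-level observed masked share m̂ splits the former probabilities into
(1−m̂)·former_g per group plus m̂·Σ_g former_g for the aggregate
`former_unknown` category, keeping each dialect's probabilities on the
simplex (a missing-at-random treatment).

ε defaults to 1.0: with that choice the density's mode over the model
probabilities, (α−1)/Σ(α−1), sits exactly at the observed proportions.
Smaller ε (e.g. 0.5) leaves α < 1 corners for rare categories and
measurably repels the fit from them — on synthetic data this produced a
systematic ~3–4 percentage-point downward bias in recovered initiation
proportions, which ε = 1 removes. Model probabilities are floored at 1e−12
before logs.

Weights are raked to one-way population margins (age band, sex, region,
capital-city flag) by iterative proportional fitting, multiplying — never
replacing — the design weights. Cells default to single-year age;
analyses here use 5-year bands (labelled by band centre) for speed, which
was verified on synthetic data to leave recovery errors unchanged
relative to single-year cells.

## Numerics

Within one integration substep all rates are frozen, making the system a
feed-forward chain of competing exponentials with exact closed-form
solutions; no matrix exponential is needed. The substep count (default 12
per year) therefore only controls how often μ_N is refreshed from the
mixture identity. The refresh uses a midpoint predictor (half-step under
the start-of-substep μ_N, identity re-solved at the predicted mix), making
the state-dependence error second order: the default integration matches a
52-substep oracle to ~1e−8 per component (1e−6 is the acceptance bound;
without the midpoint refresh the difference is ~5e−6). Rate surfaces are
sampled once per integer (age, year) and held constant within the year.
Calendar years outside the mortality table are clamped to the nearest
covered year; covariates outside spline domains are clamped to the domain
ends. The hazard-ratio strata cover ages 45+; below 45 the lowest stratum
extends down (configurable to HR = 1). The integrator is numba-compiled
with a pure-Python fallback.

## Inference

MAP: L-BFGS on the working scale with the HRs fixed at their prior mode
(the identifiability-step convention); Hessian of the negative log
posterior by central finite differences. Practical identifiability:
profile posteriors over ±7.1 asymptotic SDs by a predictor–corrector march
(warm starts linearly extrapolated from the previous two conditional
optima, plus a jittered restart to escape saddle points of curved
posteriors); the highest confidence level whose profile interval stays
inside the neighbourhood flags components below 0.95 as questionable. The
prior/posterior overlap statistic is the integrated minimum of two kernel
density estimates; the conventional reading treats values ≤ 0.35 as weak
updating, and both the value and the flag are reported because the
literature uses the threshold in both directions.

Sampling: blockwise Gaussian random-walk Metropolis over lockstep chains.
Default blocks: hazard ratios; the behavioural block per sex (P_F,
initiation and quit-rate coefficients, *and* that sex's reporting-as-never
rates); nuisance scales. The reporting rates deliberately stay inside
their sex's block: λ_R and the initiation coefficients share a long,
weakly identified posterior ridge, and the block proposal — shaped by the
Cholesky factor of the inverse MAP-Hessian block — can only travel along
that ridge if both ends are updated jointly. Per-block scalar step sizes
start at 2.38/√d and adapt toward ~28% acceptance during burn-in only.
Starts are over-dispersed: MAP ± 2 asymptotic SDs for behavioural blocks,
prior draws inflated twofold for the HRs. After burn-in (protocol default
1600 sweeps; scaled-down runs use 400) sampling continues in chunks until
the smallest multi-chain effective sample size — the variogram/
autocorrelation estimator over chains — reaches 50, capped by a sweep
budget with a warning. Each chain is culled to 40 evenly-spaced retained
draws (200 retained under the 5-chain protocol). The potential-scale-
reduction factor is reported with a warning threshold of 1.11, not used as
a stop rule.

## Evaluation

DIC uses the Dirichlet cell likelihood only (prior excluded), with the
posterior mean taken on the working scale; p_D = D̄ − D(θ̄). Discrepancy
summaries report the posterior-averaged mean (bias) and SD (unexplained
variation) of cell-level log-odds gaps for three outcomes: proportion
currently smoking; never-smoked among the not-currently-smoking; and
quit-before-30 among formers with known age-at-quit. Observed and model
proportions are both smoothed by 0.5/eff_n before the logit so empty
categories stay finite and a perfect model scores exactly zero.
Posterior-predictive draws are Dirichlet-multinomial (size raw_n,
concentration eff_n × model probabilities) with mid-rank two-tailed
p-values 2·min(q, 1−q) and 90% equal-tailed coverage flags. Trend outputs
(initiation by birth year, quit rate per 100 person-years on an age × year
grid, reporting-as-never per group, and annual growth rates 100·Δlog)
summarise the retained draws by median and 5th/95th percentiles;
sex-comparison p-values pair the two sexes within each posterior draw, and
pooled "persons" outputs weight the sexes 50:50 (configurable).

## Synthetic studies

The generator defines the study conditions. The default truth follows the
selected variant F with surfaces solved exactly through anchor points:
initiation peaking mid-century (women ~55% for the 1962 cohort, men
declining from ~87% for 1910), quit rates rising from ~0.4–0.5 to ~4–6 per
100 person-years between 1940 and 2016, reporting-as-never 2.05 (<30) and
0.29 (30–39) per 100 person-years, P_F ≈ 8%, HR_C = 2.2, HR_F = 1.45. The
mortality table is emitted as μ = μ_N × mixture-factor from a Gompertz
baseline and the truth's own mixes, so the identity inverts exactly. The
HR "study" reports Normal(log-HR truth, SE) estimates with two-arm SEs
√(1/e₁ + 1/e₂). Surveys draw respondents from a uniform-age population
with fixed region/capital shares through a logistic selection tilt in age,
sex and region (design weight = inverse selection probability), draw
categories from the truth's observation probabilities, optionally
overdispersed by a Dirichlet, and mask age-at-quit for a set fraction of
former smokers. Margins for raking come from the known population.

Presets: "small" — 6 surveys × 2000 respondents spanning 1966–2016, ages
20–80, selection tilt 0.4, 10% missing age-at-quit, no overdispersion (so
the likelihood is well-specified in recovery tests); "paper-like" — 26
surveys 1962–2016, n 1000–20000, ages 20–99, early surveys in the
two-category dialect. What the generator does *not* emulate: between-survey
questionnaire effects, non-response correlated with smoking status within
(age, sex) cells, age heaping, or relapse — so passing recovery tests
demonstrates estimator correctness under the stated sampling model, not
robustness to those real-data features.

## Problem sizes and what the checks show

End-to-end checks run the small scenario with 2 chains, 400 burn-in sweeps
and a 2000-sweep sampling cap (~3 minutes); interval-calibration uses 12
seed-replicates and model selection 6 replicates at 4 substeps/year and
shorter chains. Recovery is assessed at fixed reference points (quit rate
at ages 30/50/70 for years 1990–2016, initiation at decades 1920–1980,
reporting-as-never <30), echoing the grids such models report on.

Known limitations: the men's 30–39 reporting-as-never rate is only weakly
practically identified (profile levels well under 0.95; near-flat
posterior ridge with the initiation level) — an inherent feature of this
model class rather than a defect of the sampler, and the reason recovery
of the <30 rate is assessed with a generous 30% band while the 30–39 rate
is not assessed at all. At the default small-study size, posterior-median
initiation errors at single reference years can reach ~2 percentage
points along that ridge for unlucky data realisations (they shrink as
1/√n in the survey size). No age × year interaction in λ_Q; no migration;
no relapse compartment; pooled-sex outputs assume equal sex shares.
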