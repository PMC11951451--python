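"""Synthetic study generator with known ground truth.

Because the real inputs (26 national surveys, population mortality, a
prospective cohort study for mortality hazard ratios) are not
redistributable, every pipeline stage is exercised on data generated here:

* a ground-truth parameter vector whose behavioural surfaces pass through
  scenario anchor points (initiation peaking mid-century; quit rates of
  order 1-5 per 100 person-years rising over calendar time;
  reporting-as-never of order 2 per 100 person-years for early quitters);
* a population mortality table emitted as mu = mu_N * (rho_N + HR_C rho_C +
  HR_F rho_F) from a Gompertz never-smoker baseline and the truth's own
  mixes, so the mixture-identity inversion is exact by construction;
* a hazard-ratio study summary with asymptotic Cox-like SEs around truth;
* respondent-level cross-sectional surveys with age/sex/region selection
  bias (design weights = inverse selection probability), optional Dirichlet
  overdispersion of the cell category probabilities, and a controllable
  fraction of former smokers with missing age-at-quit; plus the population
  margin tables used for raking.

Everything is deterministic given the scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from ._kernel import integrate_cohorts
from .cohort import initial_state
from .likelihood import category_probabilities
from .mortality import SEXES, MortalityTable
from .params import (
    ParameterLayout,
    ParameterVector,
    initiation_proportion,
    make_spline_specs,
    quit_rate_surface,
)
from .priors import HRPriorSpec
from .splines import natural_cubic_basis
from .states import IDX_DEAD, quit_group_of_age
from .surveys import CATEGORIES
from .variants import ModelVariant, variant_ladder

__all__ = ["Scenario", "Truth", "make_truth", "make_mortality",
           "make_hr_study", "make_surveys", "observation_probabilities"]


@dataclass(frozen=True)
class Scenario:
    """Study-design settings for one synthetic data set."""

    name: str
    survey_years: tuple[int, ...]
    survey_sizes: tuple[int, ...]
    gallup: tuple[bool, ...] = ()        # per-survey 2-category dialect flag
    age_range: tuple[int, int] = (20, 80)
    mortality_years: tuple[int, int] = (1930, 2016)
    selection_bias: float = 0.4          # logistic tilt strength
    overdispersion: float = 0.0          # Dirichlet concentration; 0 = off
    missing_aaq_frac: float = 0.1        # former smokers with masked age-at-quit
    # truth anchors ------------------------------------------------------
    pf: dict = field(default_factory=lambda: {"F": 0.080, "M": 0.086})
    init_anchors: dict = field(default_factory=lambda: {
        "F": [(1910, 0.44), (1940, 0.46), (1962, 0.55), (1996, 0.16)],
        "M": [(1910, 0.87), (1940, 0.71), (1962, 0.60), (1996, 0.22)],
    })
    quit_anchors: dict = field(default_factory=lambda: {
        "F": [(30, 1940, 0.004), (50, 1970, 0.016), (30, 2016, 0.055),
              (70, 2016, 0.059), (50, 2016, 0.051)],
        "M": [(30, 1940, 0.005), (50, 1970, 0.024), (30, 2016, 0.037),
              (70, 2016, 0.048), (50, 2016, 0.047)],
    })
    lambda_r: dict = field(default_factory=lambda: {0: 0.0205, 1: 0.0029})
    hr_current: float = 2.2
    hr_former: float = 1.45
    hr_strata: tuple = ((45, 70), (70, 100))
    hr_events: float = 2000.0            # events per arm per stratum
    recent_fraction: float = 0.5
    substeps: int = 12
    seed: int = 20260901

    def __post_init__(self) -> None:
        if len(self.survey_years) != len(self.survey_sizes):
            raise ValueError("one size per survey year required")
        if any(n <= 0 for n in self.survey_sizes):
            raise ValueError("survey sizes must be positive")
        if not 0.0 <= self.missing_aaq_frac <= 1.0:
            raise ValueError("missing_aaq_frac must be in [0, 1]")
        g = self.gallup or (False,) * len(self.survey_years)
        object.__setattr__(self, "gallup", tuple(g))

    @classmethod
    def small(cls, **overrides) -> "Scenario":
        """Desk-scale preset: 6 surveys of n = 2000 spanning 50 years."""
        return cls(name="small",
                   survey_years=(1966, 1976, 1986, 1996, 2006, 2016),
                   survey_sizes=(2000,) * 6, **overrides)

    @classmethod
    def paper_like(cls, **overrides) -> "Scenario":
        """Realistic stressor: 26 surveys 1962-2016, n 1000-20000."""
        years = tuple(int(y) for y in np.linspace(1962, 2016, 26).round())
        rng = np.random.default_rng(7)
        sizes = tuple(int(s) for s in
                      np.exp(rng.uniform(np.log(1000), np.log(20000), 26)))
        gallup = tuple(y < 1970 for y in years)
        return cls(name="paper_like", survey_years=years, survey_sizes=sizes,
                   gallup=gallup, age_range=(20, 99), hr_events=4000.0,
                   hr_strata=tuple((a, a + 5) for a in range(45, 95, 5))
                   + ((95, 100),), **overrides)


@dataclass
class Truth:
    """Ground-truth parameters plus the specs they are expressed in."""

    theta: ParameterVector
    variant: ModelVariant
    specs: dict
    scenario: Scenario

    def initiation(self, birth_year, sex):
        return initiation_proportion(birth_year, sex, self.theta, self.specs)

    def quit_rate(self, age, year, sex):
        return quit_rate_surface(age, year, sex, self.theta, self.specs,
                                 self.variant)

    def to_frame(self) -> pd.DataFrame:
        names = self.theta.layout.names()
        return pd.DataFrame({"parameter": names, "value": self.theta.values})


def make_truth(scenario: Scenario) -> Truth:
    """Construct the ground-truth parameter vector for the selected variant.

    Spline coefficient blocks are solved exactly so the implied surfaces pass
    through the scenario anchors (the linear systems are square by design).
    """
    variant = variant_ladder()[5]        # selected rung F
    specs = make_spline_specs(variant)
    # standardise over a regular grid so truth construction is self-contained
    specs = {
        "birth": specs["birth"].standardised_over(
            np.arange(*specs["birth"].domain)),
        "age": specs["age"].standardised_over(np.arange(*specs["age"].domain)),
        "time": specs["time"].standardised_over(
            np.arange(*specs["time"].domain)),
    }
    layout = ParameterLayout(variant=variant, n_strata=len(scenario.hr_strata))
    theta = ParameterVector.zeros(layout)
    for sex in SEXES:
        theta.set_block(f"log_hr_current_{sex}",
                        np.log(scenario.hr_current))
        theta.set_block(f"log_hr_former_{sex}", np.log(scenario.hr_former))
        p = scenario.pf[sex] / 0.5
        theta.set_block(f"z_pf_{sex}", logit(p))
        # initiation: solve intercept + birth spline through the anchors
        anchors = scenario.init_anchors[sex]
        if len(anchors) != 1 + variant.df_birth:
            raise ValueError("need exactly 1 + df_birth initiation anchors")
        years = np.array([a[0] for a in anchors], dtype=float)
        vals = np.array([a[1] for a in anchors], dtype=float)
        if np.any(years < specs["birth"].domain[0]) or \
                np.any(years > specs["birth"].domain[1]):
            raise ValueError("initiation anchor outside spline domain")
        X = np.column_stack([np.ones(years.size),
                             natural_cubic_basis(years, specs["birth"])])
        theta.set_block(f"beta_init_{sex}", np.linalg.solve(X, logit(vals)))
        # quit rate: intercept + age spline + time spline through the anchors
        qa = scenario.quit_anchors[sex]
        n_coef = 1 + variant.df_age + variant.df_year
        if len(qa) != n_coef:
            raise ValueError("need exactly 1 + df_age + df_year quit anchors")
        ages = np.array([a[0] for a in qa], dtype=float)
        yrs = np.array([a[1] for a in qa], dtype=float)
        rates = np.array([a[2] for a in qa], dtype=float)
        for arr, spec in ((ages, specs["age"]), (yrs, specs["time"])):
            if np.any(arr < spec.domain[0]) or np.any(arr > spec.domain[1]):
                raise ValueError("quit anchor outside spline domain")
        Xq = np.column_stack([np.ones(len(qa)),
                              natural_cubic_basis(ages, specs["age"]),
                              natural_cubic_basis(yrs, specs["time"])])
        theta.set_block(f"beta_quit_{sex}", np.linalg.solve(Xq, np.log(rates)))
        # reporting-as-never truth
        lr = [np.log(scenario.lambda_r[int(g)]) for g in variant.report_groups]
        theta.set_block(f"log_report_{sex}", lr)
    theta.set_block("log_tau_init", 0.0)
    theta.set_block("log_tau_quit", 0.0)
    return Truth(theta=theta, variant=variant, specs=specs, scenario=scenario)


# ----------------------------------------------------------------------
# forward runs under truth
# ----------------------------------------------------------------------
def _truth_trajectories(truth: Truth, sex: str, cohorts: np.ndarray,
                        end_age: int, mu: np.ndarray,
                        mu_is_baseline: bool) -> np.ndarray:
    """(n_cohorts, n_ages, 13) trajectories from age 20 under the truth."""
    sc = truth.scenario
    ages = np.arange(20, end_age)
    lam_q = np.vstack([
        truth.quit_rate(ages.astype(float),
                        np.clip(b + ages, *truth.specs["time"].domain), sex)
        for b in cohorts])
    lam_r = np.zeros(3)
    for i, g in enumerate(truth.variant.report_groups):
        lam_r[int(g)] = np.exp(truth.theta.block(f"log_report_{sex}")[i])
    edges = np.array([s[0] for s in sc.hr_strata])
    sidx = np.clip(np.searchsorted(edges, ages, side="right") - 1, 0,
                   len(sc.hr_strata) - 1)
    hr_c = np.exp(truth.theta.block(f"log_hr_current_{sex}"))[sidx]
    hr_f = np.exp(truth.theta.block(f"log_hr_former_{sex}"))[sidx]
    qg = np.array([int(quit_group_of_age(a)) for a in ages], dtype=np.int64)
    p_i = truth.initiation(np.clip(cohorts.astype(float),
                                   *truth.specs["birth"].domain), sex)
    init = np.vstack([initial_state(float(p), truth.theta.pf(sex),
                                    sc.recent_fraction).values for p in p_i])
    return integrate_cohorts(init, lam_q, lam_r, mu, hr_c, hr_f, qg,
                             sc.substeps, mu_is_baseline, True)


def _gompertz_baseline(ages: np.ndarray, years: np.ndarray, sex: str
                       ) -> np.ndarray:
    """Never-smoker mortality: Gompertz in age with a mild secular decline."""
    a0 = 3.0e-4 * (1.35 if sex == "M" else 1.0)
    b = 0.085
    c = 0.004
    A, Y = np.meshgrid(ages, years, indexing="ij")
    return a0 * np.exp(b * (A - 20)) * np.exp(-c * (Y - 1970))


def make_mortality(truth: Truth) -> MortalityTable:
    """Population mortality table consistent with the truth by construction.

    mu(age, sex, year) = mu_N(age, sex, year) * (rho_N + HR_C rho_C +
    HR_F rho_F), with the mixes taken from the forward model run under the
    Gompertz baseline itself, so inverting the identity recovers mu_N
    exactly.
    """
    sc = truth.scenario
    y0, y1 = sc.mortality_years
    years = np.arange(y0, y1 + 1)
    ages = np.arange(20, 100)
    rates = {}
    for sex in SEXES:
        mu_n = _gompertz_baseline(ages, years, sex)
        cohorts = np.arange(y0 - 99, y1 - 20 + 1)
        # baseline rates along each cohort diagonal (year clamped at the edges)
        mu_diag = np.empty((cohorts.size, ages.size - 1))
        for i, b in enumerate(cohorts):
            yy = np.clip(b + ages[:-1], y0, y1)
            mu_diag[i] = mu_n[np.arange(ages.size - 1), yy - y0]
        traj = _truth_trajectories(truth, sex, cohorts, 99, mu_diag, True)
        edges = np.array([s[0] for s in sc.hr_strata])
        sidx = np.clip(np.searchsorted(edges, ages, side="right") - 1, 0,
                       len(sc.hr_strata) - 1)
        hr_c = np.exp(truth.theta.block(f"log_hr_current_{sex}"))[sidx]
        hr_f = np.exp(truth.theta.block(f"log_hr_former_{sex}"))[sidx]
        mu = mu_n.copy()
        for j, year in enumerate(years):
            b_needed = year - ages
            ci = b_needed - cohorts[0]
            ai = ages - 20
            states = traj[ci, ai]
            alive = states[:, :IDX_DEAD].sum(axis=1)
            mix = states[:, :IDX_DEAD] / alive[:, None]
            rho_n = mix[:, 0] + mix[:, 11]
            rho_c = mix[:, 1] + mix[:, 2:8].sum(axis=1)
            rho_f = mix[:, 8:11].sum(axis=1)
            mu[:, j] = mu_n[:, j] * (rho_n + hr_c * rho_c + hr_f * rho_f)
        rates[sex] = mu
    return MortalityTable(ages=ages, years=years, rates=rates)


def make_hr_study(truth: Truth, events: float | None = None,
                  seed: int | None = None) -> HRPriorSpec:
    """Cox-like hazard-ratio summary around truth.

    log-HR estimates are Normal(true log HR, SE) with the asymptotic
    two-arm SE sqrt(1/events_exposed + 1/events_reference).
    """
    sc = truth.scenario
    events = sc.hr_events if events is None else float(events)
    if events <= 0:
        raise ValueError("events must be positive")
    rng = np.random.default_rng(sc.seed + 1 if seed is None else seed)
    se_val = np.sqrt(2.0 / events)
    strata = [tuple(s) for s in sc.hr_strata]
    mean = {st: {} for st in ("current", "former")}
    se = {st: {} for st in ("current", "former")}
    for sex in SEXES:
        for st, key in (("current", f"log_hr_current_{sex}"),
                        ("former", f"log_hr_former_{sex}")):
            true = truth.theta.block(key)
            mean[st][sex] = rng.normal(true, se_val)
            se[st][sex] = np.full(len(strata), se_val)
    return HRPriorSpec(strata=strata, mean=mean, se=se)


def observation_probabilities(truth: Truth, mort: MortalityTable, year: int,
                              ages: np.ndarray, sex: str) -> np.ndarray:
    """Full-dialect category probabilities at one survey year, (n_ages, 6).

    Columns follow :data:`smoketrends.surveys.CATEGORIES`, with the masked
    share folded in by the caller (here mask_frac = 0; masking happens at
    the respondent level).
    """
    ages = np.asarray(ages, dtype=int)
    cohorts = year - ages[::-1]          # increasing birth year
    mu = np.vstack([mort.gather_cohort(int(b), sex, np.arange(20, ages.max()))
                    for b in cohorts])
    traj = _truth_trajectories(truth, sex, cohorts, int(ages.max()), mu, False)
    out = np.empty((ages.size, len(CATEGORIES)))
    for i, age in enumerate(ages):
        ci = int(np.searchsorted(cohorts, year - age))
        state = traj[ci, age - 20]
        mix = state[:IDX_DEAD] / state[:IDX_DEAD].sum()
        out[i] = category_probabilities(mix, CATEGORIES, mask_frac=0.0)
    return out


def make_surveys(truth: Truth, mort: MortalityTable,
                 seed: int | None = None
                 ) -> tuple[pd.DataFrame, dict[str, pd.Series]]:
    """Respondent-level survey tables plus population raking margins.

    Respondents are drawn from a population uniform in age with fixed
    region/capital shares, tilted by a logistic selection model in age, sex
    and region (design weight = inverse selection probability).  Categories
    are drawn from the truth's observation probabilities at (sex, age,
    year), optionally overdispersed with a Dirichlet of concentration
    ``scenario.overdispersion``; a fraction of former smokers have their
    age-at-quit masked.
    """
    sc = truth.scenario
    rng = np.random.default_rng(sc.seed + 2 if seed is None else seed)
    lo, hi = sc.age_range
    ages = np.arange(lo, hi + 1)
    regions = np.array(["R1", "R2"])
    region_share = np.array([0.6, 0.4])
    capital = np.array(["1", "0"])
    capital_share = np.array([0.65, 0.35])
    sex_share = np.array([0.5, 0.5])

    frames = []
    for k, (year, n, is_gallup) in enumerate(
            zip(sc.survey_years, sc.survey_sizes, sc.gallup)):
        sid = f"SYN{year}_{k}"
        # stratum enumeration: sex x age x region x capital
        grid = pd.MultiIndex.from_product(
            [list(SEXES), ages, regions, capital],
            names=["sex", "age", "region", "capital_city"]).to_frame(False)
        sex_p = grid["sex"].map(dict(zip(SEXES, sex_share))).to_numpy()
        reg_p = grid["region"].map(dict(zip(regions, region_share))).to_numpy()
        cap_p = grid["capital_city"].map(
            dict(zip(capital, capital_share))).to_numpy()
        pop_p = sex_p * reg_p * cap_p / ages.size
        b = sc.selection_bias
        tilt = expit(b * (grid["age"].to_numpy() - 50.0) / 30.0
                     - 0.5 * b * (grid["sex"] == "M").to_numpy()
                     + 0.3 * b * (grid["region"] == "R1").to_numpy())
        sel_p = pop_p * tilt
        sel_p /= sel_p.sum()
        counts = rng.multinomial(n, sel_p)
        rows = grid.loc[grid.index.repeat(counts)].reset_index(drop=True)
        rows["weight"] = np.repeat(1.0 / tilt, counts)
        rows["survey_id"] = sid
        rows["year"] = year
        # categories from the truth's observation probabilities
        cat = np.empty(len(rows), dtype=object)
        for sex in SEXES:
            probs = observation_probabilities(truth, mort, year, ages, sex)
            for i, age in enumerate(ages):
                m = (rows["sex"] == sex).to_numpy() & \
                    (rows["age"] == age).to_numpy()
                cnt = int(m.sum())
                if cnt == 0:
                    continue
                p = probs[i].copy()
                if sc.overdispersion > 0:
                    p = rng.dirichlet(np.maximum(p, 1e-9) *
                                      sc.overdispersion)
                p = np.maximum(p, 0)
                p /= p.sum()
                cat[m] = rng.choice(CATEGORIES, size=cnt, p=p)
        rows["category"] = cat
        # mask age-at-quit for a fraction of former smokers
        former = rows["category"].str.startswith("former_").to_numpy()
        masked = former & (rng.random(len(rows)) < sc.missing_aaq_frac)
        rows.loc[masked, "category"] = "former_unknown"
        if is_gallup:
            rows["category"] = np.where(rows["category"] == "current",
                                        "current", "not_current")
        frames.append(rows)
    table = pd.concat(frames, ignore_index=True)[
        ["survey_id", "year", "sex", "age", "category", "weight",
         "region", "capital_city"]]

    n_total = float(len(table))
    margins = {
        "sex": pd.Series(sex_share * n_total, index=list(SEXES)),
        "region": pd.Series(region_share * n_total, index=list(regions)),
        "capital_city": pd.Series(capital_share * n_total,
                                  index=list(capital)),
        "age_band": pd.Series(
            {str(b): n_total * np.sum((ages - lo) // 10 == b) / ages.size
             for b in np.unique((ages - lo) // 10)}),
    }
    return table, margins
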