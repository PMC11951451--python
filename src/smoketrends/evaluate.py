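"""Model selection and posterior outputs.

DIC compares the rungs of the variant ladder; Kennedy-O'Hagan-style
discrepancy summaries (mean = bias, SD = unexplained variation, on a
log-odds scale) describe where a model misses; posterior-predictive
Dirichlet-multinomial draws give cell-level coverage and two-tailed
p-values; and the trend tables summarise the behavioural surfaces
(initiation by birth year, quit rate by age x year, reporting-as-never by
quit group) as the median and 90% equal-tailed interval over the retained
posterior draws, with paired-draw sex-comparison p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logit

from .inference import PosteriorSample
from .likelihood import LikelihoodEvaluator, _COL
from .mortality import SEXES
from .params import (
    ParameterVector,
    initiation_proportion,
    quit_rate_surface,
    report_rate,
)

__all__ = ["DicResult", "dic", "DiscrepancySummary", "discrepancy_summary",
           "posterior_predictive_cells", "trend_outputs"]


# ----------------------------------------------------------------------
# DIC
# ----------------------------------------------------------------------
@dataclass
class DicResult:
    dbar: float        # posterior mean deviance
    d_at_mean: float   # deviance at the posterior mean parameters
    p_d: float         # effective number of parameters = dbar - d_at_mean
    dic: float         # dbar + p_d


def dic(sample: PosteriorSample, loglik_fn) -> DicResult:
    """Deviance information criterion from the retained sample.

    Deviance is -2 x the Dirichlet cell log likelihood (prior excluded).
    The posterior mean is taken on the unconstrained working scale, where
    every component is free of boundary effects, then scored once.
    """
    if sample.draws.shape[0] < 2:
        raise ValueError("need at least 2 draws for DIC")
    dbar = float(np.mean(-2.0 * sample.log_lik))
    theta_bar = sample.draws.mean(axis=0)
    d_at_mean = -2.0 * float(loglik_fn(theta_bar))
    p_d = dbar - d_at_mean
    return DicResult(dbar=dbar, d_at_mean=d_at_mean, p_d=p_d, dic=dbar + p_d)


# ----------------------------------------------------------------------
# Discrepancy summaries
# ----------------------------------------------------------------------
#: The three discrepancy outcomes: observed vs model-expected proportion of
#: current smokers; of never-smokers among the not-currently-smoking; and of
#: quit-before-30 among the formerly smoked (known age-at-quit).
OUTCOMES = ("current", "never_given_not_current", "quit_lt30_given_former")


@dataclass
class DiscrepancySummary:
    mean: dict[str, float]   # posterior-averaged cell-mean log-odds gap
    sd: dict[str, float]     # posterior-averaged cell-SD of the gap
    n_cells: dict[str, int]


def _outcome_pair(cells: pd.DataFrame, probs: np.ndarray, outcome: str):
    """(observed proportion, model probability, eff_n) arrays for the cells
    where the outcome is defined."""
    p = probs
    c = _COL
    if outcome == "current":
        obs = cells["p_current"].to_numpy(float)
        mod = p[:, c["current"]]
        ok = np.isfinite(obs)
    elif outcome == "never_given_not_current":
        obs_n = cells["p_never"].to_numpy(float)
        obs_c = cells["p_current"].to_numpy(float)
        obs = obs_n / np.clip(1.0 - obs_c, 1e-12, None)
        mod = p[:, c["never"]] / np.clip(1.0 - p[:, c["current"]], 1e-12, None)
        ok = np.isfinite(obs_n) & np.isfinite(obs_c) & (obs_c < 1)
    elif outcome == "quit_lt30_given_former":
        f1 = cells["p_former_lt30"].to_numpy(float)
        f2 = cells["p_former_3039"].to_numpy(float)
        f3 = cells["p_former_ge40"].to_numpy(float)
        tot = f1 + f2 + f3
        obs = f1 / np.where(tot > 0, tot, np.nan)
        m1 = p[:, c["former_lt30"]]
        mtot = m1 + p[:, c["former_3039"]] + p[:, c["former_ge40"]]
        mod = m1 / np.clip(mtot, 1e-12, None)
        ok = np.isfinite(obs)
    else:
        raise KeyError(outcome)
    eff_n = cells["eff_n"].to_numpy(float)
    return obs[ok], mod[ok], eff_n[ok]


def discrepancy_summary(sample: PosteriorSample,
                        evaluator: LikelihoodEvaluator) -> DiscrepancySummary:
    """Posterior-expected mean and SD of the cell-level log-odds gaps.

    Observed proportions are smoothed by 0.5/eff_n before the logit so empty
    categories stay finite; cells lacking an outcome's categories are
    skipped for that outcome.
    """
    cells = evaluator.cells
    means = {o: [] for o in OUTCOMES}
    sds = {o: [] for o in OUTCOMES}
    n_cells = {}
    for k in range(sample.draws.shape[0]):
        probs = evaluator.cell_probs(evaluator.as_theta(sample.draws[k]))
        for outcome in OUTCOMES:
            obs, mod, eff_n = _outcome_pair(cells, probs, outcome)
            n_cells[outcome] = obs.size
            if obs.size == 0:
                continue
            smooth = 0.5 / eff_n
            obs_s = np.clip(obs, smooth, 1.0 - smooth)
            mod_s = np.clip(mod, smooth, 1.0 - smooth)  # same rule both sides
            gap = logit(obs_s) - logit(mod_s)
            means[outcome].append(gap.mean())
            sds[outcome].append(gap.std(ddof=0))
    for o in OUTCOMES:
        if n_cells.get(o, 0) == 0:
            raise ValueError(f"no eligible cells for outcome {o!r}")
    return DiscrepancySummary(
        mean={o: float(np.mean(means[o])) for o in OUTCOMES},
        sd={o: float(np.mean(sds[o])) for o in OUTCOMES},
        n_cells=n_cells,
    )


# ----------------------------------------------------------------------
# Posterior predictive checks
# ----------------------------------------------------------------------
def posterior_predictive_cells(sample: PosteriorSample,
                               evaluator: LikelihoodEvaluator,
                               seed: int = 0) -> pd.DataFrame:
    """Dirichlet-multinomial predictive draws and cell-level diagnostics.

    Per retained draw and cell: category probabilities ~ Dirichlet with
    concentration eff_n x model probabilities, then counts ~ Multinomial of
    size raw_n.  Returns one row per (cell, category) with the observed
    proportion, the predictive 90% equal-tailed interval and coverage flag,
    and the two-tailed statistic p = 2 min(q, 1-q) where q is the mid-rank
    predictive quantile of the observed value.
    """
    rng = np.random.default_rng(seed)
    cells = evaluator.cells
    n_draws = sample.draws.shape[0]
    all_probs = np.stack([
        evaluator.cell_probs(evaluator.as_theta(sample.draws[k]))
        for k in range(n_draws)])      # (n_draws, n_cells, n_cols)
    rows = []
    for r, row in cells.iterrows():
        dialect = evaluator._cell_dialects[r]
        cols = [_COL[c] for c in dialect]
        conc = np.clip(all_probs[:, r, cols], 1e-9, None) * row["eff_n"]
        # vectorised Dirichlet draws via normalised gammas
        g = rng.gamma(conc)
        p_pred = g / g.sum(axis=1, keepdims=True)
        counts = np.stack([rng.multinomial(int(row["raw_n"]), p)
                           for p in p_pred])
        prop_pred = counts / float(row["raw_n"])
        for j, cat in enumerate(dialect):
            obs = row[f"p_{cat}"]
            pred = prop_pred[:, j]
            less = float(np.mean(pred < obs))
            equal = float(np.mean(pred == obs))
            q = less + 0.5 * equal
            lo, hi = np.percentile(pred, [5.0, 95.0])
            rows.append({
                "survey_id": row["survey_id"], "year": row["year"],
                "sex": row["sex"], "age": row["age"], "category": cat,
                "observed": obs, "pred_lo": lo, "pred_hi": hi,
                "covered90": bool(lo <= obs <= hi),
                "q": q, "p_two_tailed": 2.0 * min(q, 1.0 - q),
            })
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# Trend outputs
# ----------------------------------------------------------------------
def _summary(draws_by_sex: dict[str, np.ndarray], meta: pd.DataFrame,
             output: str, pooled_weights=(0.5, 0.5)) -> pd.DataFrame:
    """Median / 5th / 95th percentiles per sex plus pooled, with paired-draw
    sex-comparison p-values."""
    w_f, w_m = pooled_weights
    rows = []
    f, m = draws_by_sex["F"], draws_by_sex["M"]
    pooled = w_f * f + w_m * m
    gt = np.mean(m > f, axis=0)
    lt = np.mean(m < f, axis=0)
    p_sex = np.minimum(1.0, 2.0 * np.minimum(gt, lt) + np.mean(m == f, axis=0))
    for i in range(meta.shape[0]):
        base = meta.iloc[i].to_dict()
        base["output"] = output
        for label, arr in (("F", f), ("M", m), ("persons", pooled)):
            lo, med, hi = np.percentile(arr[:, i], [5.0, 50.0, 95.0])
            rows.append({**base, "sex": label, "median": med,
                         "q5": lo, "q95": hi,
                         "p_sex": float(p_sex[i])})
    return pd.DataFrame(rows)


def trend_outputs(sample: PosteriorSample, evaluator: LikelihoodEvaluator,
                  birth_years=None, quit_ages=(30, 50, 70), quit_years=None,
                  pooled_weights=(0.5, 0.5)) -> pd.DataFrame:
    """Posterior trend tables over the retained draws.

    Outputs: initiation proportion by birth year (with annual growth,
    100 * d log P_I / d year), quit rate per 100 person-years by (age, year)
    (with annual growth in year), and the reporting-as-never rates per 100
    person-years by age-at-quit group.  ETIs are the 5th/95th percentiles;
    the sex p-value is the paired-draw two-tailed comparison.
    """
    specs = evaluator.specs
    variant = evaluator.variant
    layout = evaluator.layout
    if birth_years is None:
        lo, hi = specs["birth"].domain if specs["birth"] is not None else (1920, 1990)
        birth_years = np.arange(int(lo), int(hi) + 1, 10)
    birth_years = np.asarray(birth_years, dtype=float)
    if quit_years is None:
        lo, hi = specs["time"].domain if specs["time"] is not None else (1940, 2016)
        quit_years = np.arange(int(lo) + 10, int(hi) + 1, 10)
    quit_years = np.asarray(quit_years, dtype=float)
    n = sample.draws.shape[0]

    thetas = [ParameterVector(layout, sample.draws[k]) for k in range(n)]

    frames = []
    # initiation level and growth
    pi = {s: np.stack([initiation_proportion(birth_years, s, th, specs)
                       for th in thetas]) for s in SEXES}
    meta = pd.DataFrame({"birth_year": birth_years.astype(int)})
    frames.append(_summary({s: 100 * pi[s] for s in SEXES}, meta,
                           "initiation_pct", pooled_weights))
    growth = {s: 100 * (np.log(np.stack(
        [initiation_proportion(birth_years + 1, s, th, specs) for th in thetas]))
        - np.log(pi[s])) for s in SEXES}
    frames.append(_summary(growth, meta, "initiation_growth_pct", pooled_weights))

    # quit rate level and growth on the (age, year) grid
    ages_g, years_g = np.meshgrid(quit_ages, quit_years, indexing="ij")
    meta_q = pd.DataFrame({"age": ages_g.ravel().astype(int),
                           "year": years_g.ravel().astype(int)})
    lam = {s: np.stack([
        100 * quit_rate_surface(ages_g.ravel(), years_g.ravel(), s, th,
                                specs, variant) for th in thetas])
        for s in SEXES}
    frames.append(_summary(lam, meta_q, "quit_rate_per100py", pooled_weights))
    lam_next = {s: np.stack([
        100 * quit_rate_surface(ages_g.ravel(), years_g.ravel() + 1, s, th,
                                specs, variant) for th in thetas])
        for s in SEXES}
    growth_q = {s: 100 * (np.log(lam_next[s]) - np.log(lam[s])) for s in SEXES}
    frames.append(_summary(growth_q, meta_q, "quit_growth_pct", pooled_weights))

    # reporting-as-never rates
    if variant.report_groups:
        labels = {0: "lt30", 1: "q30_39", 2: "ge40"}
        meta_r = pd.DataFrame({"quit_group": [labels[int(g)]
                                              for g in variant.report_groups]})
        rep = {s: np.stack([
            np.array([100 * report_rate(int(g), s, th, variant)
                      for g in variant.report_groups]) for th in thetas])
            for s in SEXES}
        frames.append(_summary(rep, meta_r, "report_never_per100py",
                               pooled_weights))

    out = pd.concat(frames, ignore_index=True)
    bad = out["q5"] > out["median"]
    if bad.any() or (out["median"] > out["q95"]).any():
        raise AssertionError("ETI ordering violated")
    return out
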