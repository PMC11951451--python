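"""Dirichlet survey likelihood over model cross-sections.

Each survey cell (survey x sex x age) contributes a Dirichlet log-density
evaluated at the model's observation-category probabilities, with
concentration alpha_k = eff_n * p_hat_k + eps determined by the observed
weighted proportions and the Kish effective sample size.  The model
probabilities come from the alive-conditional cross-section of the forward
model: 'current' pools currently-smoking with recently-quit, 'never' pools
never-smoked with reporting-as-never, and the former categories map to the
age-at-quit groups (scaled by the survey's observed missing-age-at-quit
share when some quitters could not be classified).

:class:`LikelihoodEvaluator` precomputes everything theta-independent
(design matrices along each cohort diagonal, gathered mortality, Dirichlet
constants, cell index maps) so one likelihood evaluation is a single
vectorised forward integration plus a gather — cheap enough to sit inside
an MCMC loop.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln

from ._kernel import integrate_cohorts
from .cohort import initial_state
from .mortality import SEXES, MortalityTable
from .priors import HRPriorSpec, PriorConfig, log_prior_working
from .params import ParameterLayout, ParameterVector, make_spline_specs
from .splines import natural_cubic_basis
from .states import (
    IDX_CURRENT,
    IDX_DEAD,
    IDX_NEVER,
    IDX_REPORT_NEVER,
    quit_group_of_age,
)
from .surveys import CATEGORIES
from .variants import ModelVariant

__all__ = ["LikelihoodConfig", "category_probabilities", "cell_loglik",
           "LikelihoodEvaluator", "total_log_posterior"]

#: Column order of model observation probabilities.
PROB_COLUMNS = CATEGORIES + ["not_current"]
_COL = {c: i for i, c in enumerate(PROB_COLUMNS)}


@dataclass(frozen=True)
class LikelihoodConfig:
    """Numerical and structural options of the likelihood."""

    eps: float = 1.0            # smoothing added to each alpha; at 1.0 the
                                # cell density's mode over the model
                                # probabilities sits exactly at the observed
                                # proportions (mode (alpha-1)/sum(alpha-1))
    floor: float = 1e-12        # model probabilities floored before logs
    substeps: int = 12
    midpoint_refresh: bool = True
    recent_fraction: float = 0.5
    extend_hr_down: bool = True  # lowest HR stratum extended below its lo age
    prior: PriorConfig = PriorConfig()


def category_probabilities(mix: np.ndarray, dialect: list[str],
                           mask_frac: float = 0.0) -> np.ndarray:
    """Observation-category probabilities for one alive-conditional mix.

    ``mix`` is the length-12 alive-conditional live-state vector.  Former
    probabilities are split between the per-group categories (share
    ``1 - mask_frac``) and ``former_unknown`` (share ``mask_frac``).
    """
    mix = np.asarray(mix, dtype=float)
    current = mix[IDX_CURRENT] + mix[2:8].sum()
    formers = mix[8:11]
    never = mix[IDX_NEVER] + mix[IDX_REPORT_NEVER]
    full = {
        "current": current,
        "former_lt30": (1.0 - mask_frac) * formers[0],
        "former_3039": (1.0 - mask_frac) * formers[1],
        "former_ge40": (1.0 - mask_frac) * formers[2],
        "former_unknown": mask_frac * formers.sum(),
        "never": never,
        "not_current": 1.0 - current,
    }
    return np.array([full[c] for c in dialect])


def cell_loglik(p_hat: np.ndarray, eff_n: float, probs: np.ndarray,
                eps: float = 1.0, floor: float = 1e-12) -> float:
    """Dirichlet log-density at the model probabilities.

    alpha_k = eff_n * p_hat_k + eps; evaluated via log-gamma.  With K = 2
    this is the Beta log-density at (pi, 1 - pi).
    """
    alpha = np.asarray(p_hat, dtype=float) * eff_n + eps
    p = np.maximum(np.asarray(probs, dtype=float), floor)
    val = (lgamma(float(alpha.sum())) - float(gammaln(alpha).sum())
           + float(((alpha - 1.0) * np.log(p)).sum()))
    if not np.isfinite(val):
        raise FloatingPointError("degenerate cell: non-finite Dirichlet density")
    return val


class LikelihoodEvaluator:
    """Precompiled map theta -> (cell probabilities, log likelihood).

    Parameters
    ----------
    cells
        Cell table from :func:`smoketrends.surveys.build_cells`.
    mort
        Population mortality table.
    hr_prior
        HR prior summary; its age strata define the HR parameter blocks.
    variant
        Model variant (spline dimensions, report groups, toggles).
    config
        Numerical options.
    specs
        Optional pre-built spline specs; by default equally-spaced-knot specs
        standardised over the observed covariate values in ``cells``.
    """

    def __init__(self, cells: pd.DataFrame, mort: MortalityTable,
                 hr_prior: HRPriorSpec, variant: ModelVariant,
                 config: LikelihoodConfig = LikelihoodConfig(),
                 specs: dict | None = None,
                 domains: dict | None = None):
        self.variant = variant
        self.config = config
        self.hr_prior = hr_prior
        self.layout = ParameterLayout(variant=variant,
                                      n_strata=hr_prior.n_strata)
        cells = cells[cells["age"] >= variant.init_complete_age].reset_index(
            drop=True)
        if cells.empty:
            raise ValueError("no cells at or above the initiation-complete age")
        self.cells = cells
        if specs is None:
            specs = make_spline_specs(variant, domains)
            obs = {
                "birth": cells["birth_year"].to_numpy(float),
                "age": cells["age"].to_numpy(float),
                "time": (cells["year"].to_numpy(float)
                         if variant.quit_time_axis == "calendar_year"
                         else cells["birth_year"].to_numpy(float)),
            }
            specs = {k: (sp.standardised_over(np.clip(obs[k], *sp.domain))
                         if sp is not None else None)
                     for k, sp in specs.items()}
        self.specs = specs
        self._build(mort)

    # ------------------------------------------------------------------
    def _build(self, mort: MortalityTable) -> None:
        v = self.variant
        start_age = v.init_complete_age
        self._start_age = start_age
        self._per_sex = {}
        flat_cell, flat_col, flat_alpha = [], [], []
        const = 0.0
        self._cell_dialects: list[list[str]] = [None] * len(self.cells)
        row_offset = {}
        n_running = 0
        for sex in SEXES:
            sub = self.cells[self.cells["sex"] == sex]
            if sub.empty:
                self._per_sex[sex] = None
                continue
            cohorts = np.sort(sub["birth_year"].unique())
            coh_idx = {int(b): i for i, b in enumerate(cohorts)}
            max_age = int(sub["age"].max())
            ages = np.arange(start_age, max_age)          # stepped years
            n_steps = ages.size
            # quit-rate design tensor (n_coh, n_steps, 1 + df_age + df_year)
            n_coef = 1 + v.df_age + v.df_year
            Xq = np.zeros((cohorts.size, n_steps, n_coef))
            Xq[:, :, 0] = 1.0
            pos = 1
            if self.specs["age"] is not None:
                Ba = natural_cubic_basis(
                    np.clip(ages, *self.specs["age"].domain), self.specs["age"])
                Xq[:, :, pos:pos + v.df_age] = Ba[None, :, :]
                pos += v.df_age
            if self.specs["time"] is not None:
                spec_t = self.specs["time"]
                for i, b in enumerate(cohorts):
                    t = (b + ages if v.quit_time_axis == "calendar_year"
                         else np.full(n_steps, float(b)))
                    Xq[i, :, pos:pos + v.df_year] = natural_cubic_basis(
                        np.clip(t, *spec_t.domain), spec_t)
            # initiation design (n_coh, 1 + df_birth)
            Bi = np.ones((cohorts.size, 1 + v.df_birth))
            if self.specs["birth"] is not None:
                Bi[:, 1:] = natural_cubic_basis(
                    np.clip(cohorts.astype(float), *self.specs["birth"].domain),
                    self.specs["birth"])
            mu = np.vstack([mort.gather_cohort(int(b), sex, ages)
                            for b in cohorts])
            strat_idx = np.clip(
                np.searchsorted([s[0] for s in self.hr_prior.strata],
                                ages, side="right") - 1,
                0, self.hr_prior.n_strata - 1)
            below = (ages < self.hr_prior.strata[0][0])
            quit_group = np.array([int(quit_group_of_age(a)) for a in ages],
                                  dtype=np.int64)
            cell_ci = sub["birth_year"].map(lambda b: coh_idx[int(b)]).to_numpy()
            cell_ai = (sub["age"] - start_age).to_numpy(dtype=int)
            self._per_sex[sex] = dict(
                cohorts=cohorts, ages=ages, Xq=Xq, Bi=Bi, mu=mu,
                strat_idx=strat_idx, below=below, quit_group=quit_group,
                cell_rows=sub.index.to_numpy(), cell_ci=cell_ci,
                cell_ai=cell_ai)
        # Dirichlet constants and flat index maps
        eps = self.config.eps
        for r, row in self.cells.iterrows():
            if row["dialect"] == "gallup":
                dialect = ["current", "not_current"]
            else:
                dialect = [c for c in CATEGORIES + ["not_current"]
                           if np.isfinite(row[f"p_{c}"])]
            self._cell_dialects[r] = dialect
            p_hat = np.array([row[f"p_{c}"] for c in dialect])
            alpha = p_hat * row["eff_n"] + eps
            const += lgamma(float(alpha.sum())) - float(gammaln(alpha).sum())
            for c, a in zip(dialect, alpha):
                flat_cell.append(r)
                flat_col.append(_COL[c])
                flat_alpha.append(a)
        self._flat_cell = np.array(flat_cell, dtype=int)
        self._flat_col = np.array(flat_col, dtype=int)
        self._flat_alpha_m1 = np.array(flat_alpha) - 1.0
        self._dirichlet_const = const
        self._mask_frac = self.cells["mask_frac"].to_numpy(dtype=float)

    # ------------------------------------------------------------------
    def _check(self, theta: ParameterVector) -> None:
        if theta.layout.size != self.layout.size:
            raise ValueError("theta dimension does not match variant layout")

    def cell_probs(self, theta: ParameterVector) -> np.ndarray:
        """Model observation probabilities, (n_cells, len(PROB_COLUMNS))."""
        self._check(theta)
        cfg = self.config
        out = np.empty((len(self.cells), len(PROB_COLUMNS)))
        for sex in SEXES:
            d = self._per_sex[sex]
            if d is None:
                continue
            # rate capped at e^6 ~ 400/yr (instant quitting) to avoid overflow
            lam_q = np.exp(np.clip(
                np.einsum("ctk,k->ct", d["Xq"],
                          theta.block(f"beta_quit_{sex}")), -np.inf, 6.0))
            p_i = expit(d["Bi"] @ theta.block(f"beta_init_{sex}"))
            pf = theta.pf(sex)
            lam_r = np.zeros(3)
            for i, g in enumerate(self.variant.report_groups):
                lam_r[int(g)] = np.exp(theta.block(f"log_report_{sex}")[i])
            hr_c_strat = np.exp(theta.block(f"log_hr_current_{sex}"))
            hr_f_strat = np.exp(theta.block(f"log_hr_former_{sex}"))
            hr_c = hr_c_strat[d["strat_idx"]].copy()
            hr_f = hr_f_strat[d["strat_idx"]].copy()
            if not cfg.extend_hr_down:
                hr_c[d["below"]] = 1.0
                hr_f[d["below"]] = 1.0
            init = np.vstack([
                initial_state(float(p), pf, cfg.recent_fraction).values
                for p in p_i])
            traj = integrate_cohorts(
                init, lam_q, lam_r, d["mu"], hr_c, hr_f, d["quit_group"],
                cfg.substeps, False, cfg.midpoint_refresh)
            states = traj[d["cell_ci"], d["cell_ai"]]
            alive = states[:, :IDX_DEAD].sum(axis=1)
            mix = states[:, :IDX_DEAD] / alive[:, None]
            rows = d["cell_rows"]
            m = self._mask_frac[rows]
            current = mix[:, IDX_CURRENT] + mix[:, 2:8].sum(axis=1)
            formers = mix[:, 8:11]
            never = mix[:, IDX_NEVER] + mix[:, IDX_REPORT_NEVER]
            out[rows, _COL["current"]] = current
            out[rows, _COL["former_lt30"]] = (1 - m) * formers[:, 0]
            out[rows, _COL["former_3039"]] = (1 - m) * formers[:, 1]
            out[rows, _COL["former_ge40"]] = (1 - m) * formers[:, 2]
            out[rows, _COL["former_unknown"]] = m * formers.sum(axis=1)
            out[rows, _COL["never"]] = never
            out[rows, _COL["not_current"]] = 1.0 - current
        return out

    def log_likelihood(self, theta: ParameterVector) -> float:
        probs = self.cell_probs(theta)
        p = np.maximum(probs[self._flat_cell, self._flat_col], self.config.floor)
        return self._dirichlet_const + float(self._flat_alpha_m1 @ np.log(p))

    def log_posterior(self, theta: ParameterVector) -> tuple[float, float]:
        """(log posterior, log likelihood) on the working scale."""
        lp = log_prior_working(theta, self.hr_prior, self.config.prior)
        if not np.isfinite(lp):
            return -np.inf, np.nan
        ll = self.log_likelihood(theta)
        return lp + ll, ll

    def as_theta(self, values: np.ndarray) -> ParameterVector:
        return ParameterVector(self.layout, np.asarray(values, dtype=float))

    def log_posterior_flat(self, values: np.ndarray) -> tuple[float, float]:
        return self.log_posterior(self.as_theta(values))


def total_log_posterior(theta: ParameterVector, cells: pd.DataFrame,
                        mort: MortalityTable, hr_prior: HRPriorSpec,
                        variant: ModelVariant,
                        config: LikelihoodConfig = LikelihoodConfig()) -> float:
    """Working-scale log posterior (prior + Dirichlet cell likelihood)."""
    if cells.empty:
        return log_prior_working(theta, hr_prior, config.prior)
    ev = LikelihoodEvaluator(cells, mort, hr_prior, variant, config)
    return ev.log_posterior(theta)[0]
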