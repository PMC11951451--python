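"""Prior distribution of the full parameter block.

The prior factorises over blocks:

* log hazard ratios — informative Gaussian, mean/SE from an external cohort
  study summary (this is what resolves the structural non-identifiability of
  the quartet lambda_Q, lambda_R, mu_C, mu_F);
* P_F — uniform on [0, 0.5];
* spline coefficients — zero-mean Gaussians: intercepts get a fixed wide SD,
  non-intercept coefficients of the standardised bases get SD tau (one
  nuisance scale for initiation, one for the quit rate);
* lambda_R — the improper scale prior 1/lambda_R (flat on log lambda_R);
* tau — half-Cauchy(0, 2.5).

``log_prior`` evaluates the natural-scale density; the working-scale variant
adds the change-of-variable Jacobians and is what MAP and MCMC consume.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import log_expit

from .mortality import SEXES
from .params import ParameterLayout, ParameterVector

__all__ = ["HRPriorSpec", "PriorConfig", "log_prior", "log_prior_working",
           "prior_sample"]

_LOG_2_OVER_PI = np.log(2.0 / np.pi)


@dataclass
class HRPriorSpec:
    """Mean/SE of log hazard ratios by sex, status and 5-year age stratum."""

    strata: list[tuple[int, int]]
    mean: dict[str, dict[str, np.ndarray]]  # mean[status][sex] -> (n_strata,)
    se: dict[str, dict[str, np.ndarray]]

    def __post_init__(self) -> None:
        n = len(self.strata)
        for status in ("current", "former"):
            for sex in SEXES:
                for d in (self.mean, self.se):
                    d[status][sex] = np.asarray(d[status][sex], dtype=float)
                    if d[status][sex].shape != (n,):
                        raise ValueError("prior block shape mismatch")
                if np.any(self.se[status][sex] <= 0):
                    raise ValueError("prior SEs must be > 0")

    @property
    def n_strata(self) -> int:
        return len(self.strata)

    def block(self, status: str, sex: str) -> tuple[np.ndarray, np.ndarray]:
        return self.mean[status][sex], self.se[status][sex]

    # -- delimited-text round trip ----------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for status in ("current", "former"):
            for sex in SEXES:
                for k, (lo, hi) in enumerate(self.strata):
                    rows.append((sex, status, lo, hi,
                                 self.mean[status][sex][k],
                                 self.se[status][sex][k]))
        return pd.DataFrame(rows, columns=["sex", "status", "age_lo", "age_hi",
                                           "log_hr_mean", "log_hr_se"])

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "HRPriorSpec":
        strata = sorted({(int(r.age_lo), int(r.age_hi))
                         for r in df.itertuples()})
        idx = {s: k for k, s in enumerate(strata)}
        mean = {st: {s: np.full(len(strata), np.nan) for s in SEXES}
                for st in ("current", "former")}
        se = {st: {s: np.full(len(strata), np.nan) for s in SEXES}
              for st in ("current", "former")}
        for r in df.itertuples():
            k = idx[(int(r.age_lo), int(r.age_hi))]
            mean[r.status][r.sex][k] = r.log_hr_mean
            se[r.status][r.sex][k] = r.log_hr_se
        for st in ("current", "former"):
            for s in SEXES:
                if np.any(np.isnan(mean[st][s])) or np.any(np.isnan(se[st][s])):
                    raise ValueError("incomplete HR prior table")
        return cls(strata=strata, mean=mean, se=se)

    @classmethod
    def read(cls, path: str | Path) -> "HRPriorSpec":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


@dataclass(frozen=True)
class PriorConfig:
    """Fixed hyperparameters of the prior."""

    pf_upper: float = 0.5
    intercept_sd: float = 10.0
    tau_scale: float = 2.5          # half-Cauchy scale for the nuisance SDs
    # proper truncations for sampling from the improper components
    log_report_bounds: tuple[float, float] = (-12.0, 2.0)
    log_tau_bounds: tuple[float, float] = (-6.0, 3.0)


def _gauss(x, mean, sd):
    z = (np.asarray(x) - mean) / sd
    return float(np.sum(-0.5 * z * z - np.log(sd)))


def _half_cauchy_logpdf(x, scale):
    if x <= 0:
        return -np.inf
    return _LOG_2_OVER_PI - np.log(scale) - np.log1p((x / scale) ** 2)


def log_prior(theta: ParameterVector, hr_prior: HRPriorSpec,
              config: PriorConfig = PriorConfig()) -> float:
    """Natural-scale log prior density of theta (up to an additive constant)."""
    if hr_prior.n_strata != theta.layout.n_strata:
        raise ValueError("HR prior strata do not match parameter layout")
    lp = 0.0
    for status in ("current", "former"):
        for sex in SEXES:
            m, s = hr_prior.block(status, sex)
            lp += _gauss(theta.block(f"log_hr_{status}_{sex}"), m, s)
    for sex in SEXES:
        pf = theta.pf(sex)
        if not 0.0 <= pf <= config.pf_upper:
            return -np.inf
    tau_init, tau_quit = theta.tau("init"), theta.tau("quit")
    for sex in SEXES:
        bi = theta.block(f"beta_init_{sex}")
        bq = theta.block(f"beta_quit_{sex}")
        lp += _gauss(bi[:1], 0.0, config.intercept_sd)
        lp += _gauss(bq[:1], 0.0, config.intercept_sd)
        if bi.size > 1:
            lp += _gauss(bi[1:], 0.0, tau_init)
        if bq.size > 1:
            lp += _gauss(bq[1:], 0.0, tau_quit)
        # 1/lambda prior: log density = -log lambda = -log_report
        lp -= float(np.sum(theta.block(f"log_report_{sex}")))
    lp += _half_cauchy_logpdf(tau_init, config.tau_scale)
    lp += _half_cauchy_logpdf(tau_quit, config.tau_scale)
    return lp


def log_prior_working(theta: ParameterVector, hr_prior: HRPriorSpec,
                      config: PriorConfig = PriorConfig()) -> float:
    """Log prior density on the unconstrained working scale.

    Adds the Jacobians of P_F = pf_upper * expit(z) (per sex),
    lambda_R = exp(u) (which exactly cancels the 1/lambda density) and
    tau = exp(u).
    """
    lp = log_prior(theta, hr_prior, config)
    if not np.isfinite(lp):
        return lp
    for sex in SEXES:
        z = float(theta.block(f"z_pf_{sex}")[0])
        lp += float(log_expit(z) + log_expit(-z))  # log d(P_F)/dz + const
    for sex in SEXES:
        lp += float(np.sum(theta.block(f"log_report_{sex}")))  # exp Jacobian
    lp += float(theta.block("log_tau_init")[0] + theta.block("log_tau_quit")[0])
    return lp


def prior_sample(hr_prior: HRPriorSpec, layout: ParameterLayout,
                 config: PriorConfig = PriorConfig(),
                 seed: int | np.random.Generator = 0) -> ParameterVector:
    """Independent draw per block, with proper truncations for the improper
    components (lambda_R and tau bounds from the config)."""
    rng = np.random.default_rng(seed)
    theta = ParameterVector.zeros(layout)
    for status in ("current", "former"):
        for sex in SEXES:
            m, s = hr_prior.block(status, sex)
            theta.set_block(f"log_hr_{status}_{sex}", rng.normal(m, s))
    lo_r, hi_r = config.log_report_bounds
    lo_t, hi_t = config.log_tau_bounds
    theta.set_block("log_tau_init", rng.uniform(lo_t, hi_t))
    theta.set_block("log_tau_quit", rng.uniform(lo_t, hi_t))
    tau_i, tau_q = theta.tau("init"), theta.tau("quit")
    for sex in SEXES:
        pf = rng.uniform(0.0, config.pf_upper)
        # z = logit(pf / pf_upper)
        p = pf / config.pf_upper
        theta.set_block(f"z_pf_{sex}", np.log(p) - np.log1p(-p))
        bi = theta.block(f"beta_init_{sex}")
        bq = theta.block(f"beta_quit_{sex}")
        vi = rng.normal(0.0, config.intercept_sd, 1)
        vq = rng.normal(0.0, config.intercept_sd, 1)
        theta.set_block(f"beta_init_{sex}",
                        np.concatenate([vi, rng.normal(0, tau_i, bi.size - 1)]))
        theta.set_block(f"beta_quit_{sex}",
                        np.concatenate([vq, rng.normal(0, tau_q, bq.size - 1)]))
        n_rep = theta.block(f"log_report_{sex}").size
        theta.set_block(f"log_report_{sex}", rng.uniform(lo_r, hi_r, n_rep))
    return theta
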