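"""End-to-end calibration of one model variant.

Mirrors the calibration protocol: maximise the posterior with the hazard
ratios fixed at their prior mode, start the chains over-dispersed (MAP plus
twice the asymptotic SD for the behavioural blocks; HR prior draws inflated
twofold), run blockwise Metropolis-within-Gibbs until the multi-chain
effective sample size target is met, and cull each chain to evenly-spaced
retained draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import (
    ChainSet,
    MapResult,
    McmcConfig,
    PosteriorSample,
    block_cholesky,
    find_map,
    metropolis_within_gibbs,
    thin_to_sample,
)
from .likelihood import LikelihoodConfig, LikelihoodEvaluator
from .mortality import SEXES, MortalityTable
from .params import ParameterLayout, ParameterVector
from .priors import HRPriorSpec
from .variants import ModelVariant

__all__ = ["CalibrationResult", "default_blocks", "initial_theta",
           "overdispersed_starts", "fit_variant"]


def default_blocks(layout: ParameterLayout) -> list[np.ndarray]:
    """Gibbs blocks: HRs; behavioural model per sex; reporting rates;
    nuisance scales.

    The behavioural block is split by sex (the two sexes' cells are scored
    independently given the HRs, so the split is nearly free and halves the
    block dimension).  The reporting-as-never rates stay inside their sex's
    block: they ride a long, weakly identified ridge with the initiation
    coefficients, and the inverse-Hessian proposal can only follow that
    ridge if both ends live in the same block.
    """
    hr, model_f, model_m, nuisance = [], [], [], []
    for name, sl in layout.slices.items():
        idx = list(range(sl.start, sl.stop))
        if name.startswith("log_hr"):
            hr.extend(idx)
        elif name.startswith("log_tau"):
            nuisance.extend(idx)
        elif name.endswith("_M"):
            model_m.extend(idx)
        else:
            model_f.extend(idx)
    blocks = [hr, model_f, model_m, nuisance]
    return [np.array(b) for b in blocks if b]


def initial_theta(layout: ParameterLayout, hr_prior: HRPriorSpec
                  ) -> ParameterVector:
    """Neutral starting point: HRs at the prior mode, modest smoking levels."""
    theta = ParameterVector.zeros(layout)
    for status in ("current", "former"):
        for sex in SEXES:
            m, _ = hr_prior.block(status, sex)
            theta.set_block(f"log_hr_{status}_{sex}", m)
    for sex in SEXES:
        theta.set_block(f"z_pf_{sex}", -1.0)           # P_F ~ 0.13
        bi = np.zeros(theta.block(f"beta_init_{sex}").size)
        theta.set_block(f"beta_init_{sex}", bi)        # P_I = 0.5
        bq = np.zeros(theta.block(f"beta_quit_{sex}").size)
        bq[0] = np.log(0.03)
        theta.set_block(f"beta_quit_{sex}", bq)
        n_rep = theta.block(f"log_report_{sex}").size
        theta.set_block(f"log_report_{sex}", np.full(n_rep, np.log(0.01)))
    return theta


def overdispersed_starts(map_result: MapResult, layout: ParameterLayout,
                         hr_prior: HRPriorSpec, n_chains: int,
                         rng: np.random.Generator,
                         inflation: float = 2.0) -> np.ndarray:
    """Chain starts over-dispersed w.r.t. the asymptotic distribution."""
    sd = map_result.asymptotic_sd()
    sd[~np.isfinite(sd)] = 0.1
    sd = np.minimum(sd, 1.0)  # guard against a rough Hessian direction
    starts = np.empty((n_chains, layout.size))
    hr_idx = default_blocks(layout)[0]
    for c in range(n_chains):
        x = map_result.theta_hat + inflation * sd * \
            rng.standard_normal(layout.size)
        # HR block: inflated prior draws instead of MAP jitter
        hr_vals = []
        for sex in SEXES:
            for status in ("current", "former"):
                m, s = hr_prior.block(status, sex)
                hr_vals.append(rng.normal(m, inflation * s))
        x[hr_idx] = np.concatenate(hr_vals)
        starts[c] = x
    return starts


@dataclass
class CalibrationResult:
    variant: ModelVariant
    evaluator: LikelihoodEvaluator
    map_result: MapResult
    chains: ChainSet
    sample: PosteriorSample

    def summary(self) -> pd.DataFrame:
        names = self.evaluator.layout.names()
        q5, med, q95 = np.percentile(self.sample.draws, [5, 50, 95], axis=0)
        return pd.DataFrame({"parameter": names, "map": self.map_result.theta_hat,
                             "q5": q5, "median": med, "q95": q95})


def fit_variant(cells: pd.DataFrame, mort: MortalityTable,
                hr_prior: HRPriorSpec, variant: ModelVariant, seed: int,
                lik_config: LikelihoodConfig = LikelihoodConfig(),
                mcmc: McmcConfig = McmcConfig(), n_chains: int = 5,
                per_chain: int = 40, map_maxiter: int = 400,
                ) -> CalibrationResult:
    """Calibrate one variant end to end on a cell table."""
    if not variant.use_weights:
        raise ValueError("unweighted sensitivity is applied when building "
                         "cells (CellConfig.use_weights), not here")
    ev = LikelihoodEvaluator(cells, mort, hr_prior, variant, lik_config)
    rng = np.random.default_rng(seed)
    theta0 = initial_theta(ev.layout, hr_prior)
    hr_mask = np.zeros(ev.layout.size, dtype=bool)
    hr_mask[default_blocks(ev.layout)[0]] = True
    map_result = find_map(ev.log_posterior_flat, theta0.values, fix=hr_mask,
                          maxiter=map_maxiter)
    starts = overdispersed_starts(map_result, ev.layout, hr_prior, n_chains,
                                  rng)
    # proposals: prior SEs for the HR block, inverse-Hessian Cholesky factors
    # for the behavioural and nuisance blocks (captures correlation)
    blocks = default_blocks(ev.layout)
    se_vals = []
    for sex in SEXES:
        for status in ("current", "former"):
            se_vals.append(hr_prior.block(status, sex)[1])
    chol_hr = np.diag(np.concatenate(se_vals))
    chols = [chol_hr] + [block_cholesky(map_result.hessian, b)
                         for b in blocks[1:]]
    chains = metropolis_within_gibbs(
        ev.log_posterior_flat, blocks, starts, mcmc,
        seed=int(rng.integers(2 ** 31 - 1)), proposal_chol=chols)
    sample = thin_to_sample(chains, per_chain=per_chain)
    return CalibrationResult(variant=variant, evaluator=ev,
                             map_result=map_result, chains=chains,
                             sample=sample)
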