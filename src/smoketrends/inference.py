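"""MAP estimation, identifiability diagnostics, and posterior sampling.

Everything here operates on flat working-scale parameter vectors through a
log-posterior callable, so the same machinery runs on toy targets in tests
and on the full survey posterior.  The callable may return either the log
posterior alone or a ``(log_posterior, log_likelihood)`` pair (the latter is
tracked per draw for DIC).

The sampler is blockwise random-walk Metropolis (Metropolis-within-Gibbs):
each sweep updates every parameter block with a Gaussian proposal whose
scale is adapted during burn-in only, then frozen.  Chains run in lockstep;
after burn-in, sampling continues in chunks until the smallest multi-chain
effective sample size across components reaches the target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.interpolate import CubicSpline

__all__ = [
    "MapResult",
    "find_map",
    "ProfileResult",
    "profile_posterior",
    "overlap_statistic",
    "McmcConfig",
    "ChainSet",
    "metropolis_within_gibbs",
    "PosteriorSample",
    "thin_to_sample",
    "ess_multichain",
    "rhat",
]


def _as_pair(fn):
    """Wrap a log-posterior callable so it always returns (lp, ll)."""
    def wrapped(x):
        out = fn(x)
        if isinstance(out, tuple):
            return float(out[0]), float(out[1])
        return float(out), float(out)
    return wrapped


# ----------------------------------------------------------------------
# MAP
# ----------------------------------------------------------------------
@dataclass
class MapResult:
    theta_hat: np.ndarray
    log_post: float
    hessian: np.ndarray          # of the NEGATIVE log posterior
    converged: bool
    hessian_pd: bool = field(init=False)
    free: np.ndarray | None = None   # mask of optimised components

    def __post_init__(self) -> None:
        h = 0.5 * (self.hessian + self.hessian.T)
        self.hessian = h
        try:
            np.linalg.cholesky(h + 0.0 * np.eye(h.shape[0]))
            self.hessian_pd = True
        except np.linalg.LinAlgError:
            self.hessian_pd = False

    def asymptotic_sd(self) -> np.ndarray:
        """Per-component SD from the inverse Hessian (regularised if needed)."""
        h = self.hessian
        try:
            cov = np.linalg.inv(h)
            sd = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            sd = np.full(h.shape[0], np.nan)
        # fall back to 1/sqrt(diag) wherever the inverse is unusable
        dg = np.sqrt(1.0 / np.clip(np.diag(h), 1e-12, None))
        bad = ~np.isfinite(sd) | (sd <= 0)
        sd[bad] = dg[bad]
        return sd


def _finite_diff_hessian(f, x, step=1e-4):
    d = x.size
    h = np.maximum(step, step * np.abs(x))
    H = np.empty((d, d))
    f0 = f(x)
    fp = np.empty(d)
    fm = np.empty(d)
    for i in range(d):
        e = np.zeros(d); e[i] = h[i]
        fp[i] = f(x + e)
        fm[i] = f(x - e)
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h[i] ** 2
    for i in range(d):
        for j in range(i + 1, d):
            ei = np.zeros(d); ei[i] = h[i]
            ej = np.zeros(d); ej[j] = h[j]
            fpp = f(x + ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (
                fpp - fp[i] - fp[j] + 2 * f0 - fm[i] - fm[j] + fmm
            ) / (2 * h[i] * h[j])
    return H


def find_map(log_post, theta0: np.ndarray, fix: np.ndarray | None = None,
             maxiter: int = 3000, hess_step: float = 1e-4) -> MapResult:
    """Quasi-Newton maximisation of the log posterior on the working scale.

    ``fix`` is an optional boolean mask of components held at their
    ``theta0`` values (used to fix the HRs at their prior mode during the
    identifiability step).  The Hessian of the negative log posterior is
    computed by central finite differences over the free components.
    """
    pair = _as_pair(log_post)
    theta0 = np.asarray(theta0, dtype=float)
    d = theta0.size
    free = np.ones(d, dtype=bool) if fix is None else ~np.asarray(fix, bool)

    def neg(xfree):
        x = theta0.copy()
        x[free] = xfree
        lp, _ = pair(x)
        return -lp if np.isfinite(lp) else 1e12

    res = optimize.minimize(neg, theta0[free], method="L-BFGS-B",
                            options={"maxiter": maxiter, "maxfun": 20 * maxiter})
    x_hat = theta0.copy()
    x_hat[free] = res.x
    Hfree = _finite_diff_hessian(neg, res.x, step=hess_step)
    H = np.eye(d)
    H[np.ix_(free, free)] = Hfree
    return MapResult(theta_hat=x_hat, log_post=-float(res.fun), hessian=H,
                     converged=bool(res.success), free=free)


# ----------------------------------------------------------------------
# Profile posteriors
# ----------------------------------------------------------------------
@dataclass
class ProfileResult:
    component: int
    grid: np.ndarray
    profile: np.ndarray          # profiled log posterior at each grid value
    map_value: float
    map_log_post: float
    sd: float
    highest_contained_level: float
    inner_failures: int = 0

    @property
    def questionable(self) -> bool:
        """Practical identifiability flag: CI at the 95% level escapes the
        +-7.1 SD neighbourhood."""
        return self.highest_contained_level < 0.95

    def _drop(self):
        return self.map_log_post - self.profile

    def interval(self, level: float) -> tuple[float, float]:
        """Profile-based CI endpoints by inverse interpolation of the drop
        curve; +-inf where the drop never reaches the cutoff."""
        cutoff = stats.chi2.ppf(level, 1) / 2.0
        drop = self._drop()
        centre = int(np.argmin(drop))
        lo, hi = -np.inf, np.inf
        left = slice(0, centre + 1)
        if drop[left].max() >= cutoff:
            cs = CubicSpline(self.grid[left], drop[left] - cutoff)
            roots = [r for r in cs.roots(extrapolate=False)
                     if r <= self.grid[centre]]
            if roots:
                lo = float(max(roots))
        right = slice(centre, None)
        if drop[right].max() >= cutoff:
            cs = CubicSpline(self.grid[right], drop[right] - cutoff)
            roots = [r for r in cs.roots(extrapolate=False)
                     if r >= self.grid[centre]]
            if roots:
                hi = float(min(roots))
        return lo, hi


def profile_posterior(map_result: MapResult, component: int, log_post,
                      sd_multiple: float = 7.1, n_grid: int = 21,
                      maxiter: int = 200) -> ProfileResult:
    """Profile log posterior of one component over +- ``sd_multiple`` SD.

    Marches outward from the MAP re-optimising the remaining components at
    each grid value, warm-started by linear extrapolation of the previous
    two conditional optima (predictor) before the inner optimisation
    (corrector).  The highest contained confidence level is the largest
    level whose profile CI lies inside the neighbourhood; below 0.95 flags
    questionable practical identifiability.
    """
    pair = _as_pair(log_post)
    theta_hat = map_result.theta_hat
    d = theta_hat.size
    sd = map_result.asymptotic_sd()[component]
    if not np.isfinite(sd) or sd <= 0:
        sd = 1.0
    grid = theta_hat[component] + sd_multiple * sd * np.linspace(-1, 1, n_grid)
    centre = n_grid // 2
    grid[centre] = theta_hat[component]
    others = np.arange(d) != component
    failures = 0

    def profiled(value, start):
        def neg(xo):
            x = np.empty(d)
            x[others] = xo
            x[component] = value
            lp, _ = pair(x)
            return -lp if np.isfinite(lp) else 1e12
        if d == 1:
            x = np.array([value], dtype=float)
            return pair(x)[0], np.empty(0), True
        res = optimize.minimize(neg, start, method="L-BFGS-B",
                                options={"maxiter": maxiter})
        # retry from a deterministically jittered start: the predictor can
        # land exactly on a saddle (zero gradient) of a curved posterior
        jitter = start + 1e-3 * (1.0 + np.abs(start))
        res2 = optimize.minimize(neg, jitter, method="L-BFGS-B",
                                 options={"maxiter": maxiter})
        if res2.fun < res.fun:
            res = res2
        return -float(res.fun), res.x, bool(res.success)

    profile = np.empty(n_grid)
    profile[centre] = map_result.log_post
    for direction in (1, -1):
        prev = [(theta_hat[component], theta_hat[others].copy())]
        idx = range(centre + 1, n_grid) if direction == 1 else \
            range(centre - 1, -1, -1)
        for i in idx:
            value = grid[i]
            start = prev[-1][1]
            if len(prev) >= 2 and prev[-1][0] != prev[-2][0]:
                slope = (prev[-1][1] - prev[-2][1]) / (prev[-1][0] - prev[-2][0])
                start = prev[-1][1] + slope * (value - prev[-1][0])
            val, xo, ok = profiled(value, start)
            if not ok:
                failures += 1
            profile[i] = val
            prev.append((value, xo))

    drop_left = map_result.log_post - profile[0]
    drop_right = map_result.log_post - profile[-1]
    level = float(stats.chi2.cdf(2.0 * max(0.0, min(drop_left, drop_right)), 1))
    return ProfileResult(component=component, grid=grid, profile=profile,
                         map_value=float(theta_hat[component]),
                         map_log_post=map_result.log_post, sd=float(sd),
                         highest_contained_level=level,
                         inner_failures=failures)


# ----------------------------------------------------------------------
# Prior/posterior overlap
# ----------------------------------------------------------------------
def overlap_statistic(draws_a, draws_b, n_grid: int = 1024) -> float:
    """Integrated min of two kernel density estimates, in [0, 1].

    Symmetric in its arguments; ~1 for identical distributions, ~0 for
    disjoint ones.  Values at or below 0.35 are conventionally read as weak
    updating of the prior by the data (both readings of the threshold are
    reported by downstream summaries).
    """
    a = np.asarray(draws_a, dtype=float)
    b = np.asarray(draws_b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("degenerate (zero-variance) sample")
    ka, kb = stats.gaussian_kde(a), stats.gaussian_kde(b)
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    pad = 0.1 * (hi - lo)
    grid = np.linspace(lo - pad, hi + pad, n_grid)
    return float(np.trapezoid(np.minimum(ka(grid), kb(grid)), grid))


# ----------------------------------------------------------------------
# Effective sample size and R-hat (multi-chain)
# ----------------------------------------------------------------------
def _var_components(x: np.ndarray):
    m, n = x.shape
    means = x.mean(axis=1)
    W = float(x.var(axis=1, ddof=1).mean())
    B = n * float(means.var(ddof=1)) if m > 1 else 0.0
    var_plus = (n - 1) / n * W + B / n
    return W, B, var_plus


def ess_multichain(x: np.ndarray) -> float:
    """Multi-chain effective sample size from variogram autocorrelations.

    ``x`` has shape (n_chains, n_draws).  rho_t = 1 - V_t / (2 var+), with
    V_t the lag-t variogram pooled over chains and var+ the multi-chain
    marginal variance; lags are summed while successive pairs of
    autocorrelations remain positive.
    """
    x = np.asarray(x, dtype=float)
    m, n = x.shape
    _, _, var_plus = _var_components(x)
    if var_plus <= 0:
        return float(m * n)
    rho_sum = 0.0
    t = 1
    prev_pair = None
    while t < n - 1:
        rho = np.empty(2)
        for k in range(2):
            lag = t + k
            diffs = x[:, lag:] - x[:, :-lag]
            V = float((diffs ** 2).mean())
            rho[k] = 1.0 - V / (2.0 * var_plus)
        pair = rho.sum()
        if pair < 0:
            break
        if prev_pair is not None and pair > prev_pair:
            pair = prev_pair  # enforce monotone decrease (initial monotone seq)
        rho_sum += pair
        prev_pair = pair
        t += 2
    return float(m * n / (1.0 + 2.0 * rho_sum))


def rhat(x: np.ndarray) -> float:
    """Potential scale reduction factor over chains (shape (m, n))."""
    x = np.asarray(x, dtype=float)
    W, _, var_plus = _var_components(x)
    if W <= 0:
        return 1.0
    return float(np.sqrt(var_plus / W))


# ----------------------------------------------------------------------
# Metropolis-within-Gibbs
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class McmcConfig:
    burn_in: int = 1600
    target_ess: float = 50.0
    check_every: int = 200
    max_sweeps: int = 20000      # post-burn-in cap
    adapt_target: float = 0.28   # acceptance rate aimed for during burn-in
    adapt_batch: int = 25
    rhat_warn: float = 1.11


@dataclass
class ChainSet:
    draws: np.ndarray            # (n_chains, n_draws, d), post burn-in
    log_post: np.ndarray         # (n_chains, n_draws)
    log_lik: np.ndarray
    burn_in: int
    acceptance: np.ndarray       # (n_chains, n_blocks)
    blocks: list[np.ndarray]
    min_ess: float
    max_rhat: float
    converged: bool

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]


def block_cholesky(hessian: np.ndarray, block: np.ndarray,
                   ridge: float = 1e-8) -> np.ndarray:
    """Proposal Cholesky factor for one block: chol of the inverse of the
    block submatrix of the negative-log-posterior Hessian, with eigenvalue
    clipping so a rough Hessian still yields a usable proposal."""
    sub = hessian[np.ix_(block, block)]
    sub = 0.5 * (sub + sub.T)
    w, V = np.linalg.eigh(sub)
    w = np.clip(w, ridge, None)
    cov = (V / w) @ V.T
    w2, V2 = np.linalg.eigh(0.5 * (cov + cov.T))
    w2 = np.clip(w2, ridge, None)
    return V2 * np.sqrt(w2)


def metropolis_within_gibbs(log_post, blocks, starts, config: McmcConfig,
                            seed: int, proposal_scales=None,
                            proposal_chol=None) -> ChainSet:
    """Blockwise Gaussian random-walk Metropolis over lockstep chains.

    ``blocks`` partition the component indices; ``starts`` has one row per
    chain (over-dispersed).  The proposal for a block is a Gaussian shaped
    either by ``proposal_chol`` (a per-block Cholesky factor, e.g. from the
    inverse MAP Hessian — captures within-block correlation) or by the
    per-component SDs in ``proposal_scales``; either is multiplied by an
    adaptive scalar initialised at 2.38/sqrt(d_block) and tuned to the
    target acceptance rate during burn-in only, frozen afterwards.
    Reproducible for a fixed seed.
    """
    pair = _as_pair(log_post)
    starts = np.atleast_2d(np.asarray(starts, dtype=float))
    m, d = starts.shape
    blocks = [np.asarray(b, dtype=int) for b in blocks]
    covered = np.sort(np.concatenate(blocks))
    if not np.array_equal(covered, np.arange(d)):
        raise ValueError("blocks must partition the parameter indices")
    base_sd = (np.ones(d) if proposal_scales is None
               else np.asarray(proposal_scales, dtype=float).copy())
    base_sd[~np.isfinite(base_sd) | (base_sd <= 0)] = 1.0
    chols: list[np.ndarray | None] = (
        [None] * len(blocks) if proposal_chol is None else list(proposal_chol))
    rng = np.random.default_rng(seed)

    scales = np.array([[2.38 / np.sqrt(len(b)) for b in blocks]
                       for _ in range(m)])
    x = starts.copy()
    lp = np.empty(m)
    ll = np.empty(m)
    for c in range(m):
        lp[c], ll[c] = pair(x[c])
        if not np.isfinite(lp[c]):
            raise ValueError(f"chain {c} start has zero posterior density")

    acc = np.zeros((m, len(blocks)))
    trials = np.zeros((m, len(blocks)))

    def sweep(adapting):
        for c in range(m):
            for bi, b in enumerate(blocks):
                prop = x[c].copy()
                z = rng.standard_normal(b.size)
                if chols[bi] is not None:
                    prop[b] += scales[c, bi] * (chols[bi] @ z)
                else:
                    prop[b] += scales[c, bi] * base_sd[b] * z
                lp_new, ll_new = pair(prop)
                if np.log(rng.random()) < lp_new - lp[c]:
                    x[c] = prop
                    lp[c], ll[c] = lp_new, ll_new
                    acc[c, bi] += 1
                trials[c, bi] += 1

    # burn-in with adaptation
    for s in range(config.burn_in):
        sweep(True)
        if (s + 1) % config.adapt_batch == 0:
            rate = acc / np.maximum(trials, 1)
            scales *= np.exp(0.66 * (rate - config.adapt_target))
            acc[:] = 0.0
            trials[:] = 0.0

    # sampling: frozen proposals, run until min multi-chain ESS >= target
    acc[:] = 0.0
    trials[:] = 0.0
    draws, lps, lls = [], [], []
    n_done = 0
    converged = False
    min_ess = 0.0
    while n_done < config.max_sweeps:
        chunk = min(config.check_every, config.max_sweeps - n_done)
        block_draws = np.empty((m, chunk, d))
        block_lp = np.empty((m, chunk))
        block_ll = np.empty((m, chunk))
        for s in range(chunk):
            sweep(False)
            block_draws[:, s] = x
            block_lp[:, s] = lp
            block_ll[:, s] = ll
        draws.append(block_draws)
        lps.append(block_lp)
        lls.append(block_ll)
        n_done += chunk
        all_draws = np.concatenate(draws, axis=1)
        min_ess = min(ess_multichain(all_draws[:, :, j]) for j in range(d))
        if min_ess >= config.target_ess:
            converged = True
            break
    if not converged:
        warnings.warn(f"ESS target {config.target_ess} not reached within "
                      f"{config.max_sweeps} sweeps (min ESS {min_ess:.1f})")
    all_draws = np.concatenate(draws, axis=1)
    all_lp = np.concatenate(lps, axis=1)
    all_ll = np.concatenate(lls, axis=1)
    max_rhat = max(rhat(all_draws[:, :, j]) for j in range(d)) if m > 1 else 1.0
    if max_rhat > config.rhat_warn:
        warnings.warn(f"max R-hat {max_rhat:.3f} exceeds {config.rhat_warn}")
    return ChainSet(draws=all_draws, log_post=all_lp, log_lik=all_ll,
                    burn_in=config.burn_in,
                    acceptance=acc / np.maximum(trials, 1), blocks=blocks,
                    min_ess=float(min_ess), max_rhat=float(max_rhat),
                    converged=converged)


# ----------------------------------------------------------------------
# Culling to the retained posterior sample
# ----------------------------------------------------------------------
@dataclass
class PosteriorSample:
    draws: np.ndarray            # (n_chains * per_chain, d)
    log_lik: np.ndarray
    chain_id: np.ndarray
    per_chain: int


def thin_to_sample(chains: ChainSet, per_chain: int = 40) -> PosteriorSample:
    """Retain ``per_chain`` evenly-spaced post-burn-in draws per chain
    (first and last included)."""
    m, n, d = chains.draws.shape
    if n < per_chain:
        raise ValueError(f"chains of length {n} cannot yield {per_chain} draws")
    idx = np.round(np.linspace(0, n - 1, per_chain)).astype(int)
    if np.unique(idx).size != per_chain:
        raise RuntimeError("thinning indices not distinct")
    draws = chains.draws[:, idx, :].reshape(m * per_chain, d)
    ll = chains.log_lik[:, idx].reshape(m * per_chain)
    chain_id = np.repeat(np.arange(m), per_chain)
    return PosteriorSample(draws=draws, log_lik=ll, chain_id=chain_id,
                           per_chain=per_chain)
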