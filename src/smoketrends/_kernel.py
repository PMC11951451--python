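"""Inner integration kernel for the cohort forward model.

Within one substep all transition rates are frozen, which makes the
compartment system a feed-forward chain of competing exponentials with exact
closed-form solutions (no matrix exponential needed):

* ``current`` decays at lambda_Q + mu_C, spilling lambda_Q-mass into the
  recently-quit conveyor slot 0 of the current age-at-quit group;
* conveyor slots decay at mu_C and advance deterministically once per year
  (slot 1 empties into ``former`` — the fixed two-year sojourn);
* ``former[g]`` decays at lambda_R[g] + mu_F, spilling lambda_R-mass into
  ``report_never``;
* ``never`` and ``report_never`` decay at mu_N.

The substep count therefore only controls how often mu_N is refreshed from
the mortality mixture identity, which depends on the evolving state.  The
refresh uses a midpoint predictor (half-step under the start-of-substep
mu_N, then re-solve the identity at the predicted mix) so the discretisation
error in the mix-dependence is second order in the substep length.

The kernel is JIT-compiled with numba when available; a pure-Python fallback
keeps the package importable without it.
"""

from __future__ import annotations

import numpy as np

NSTATE = 13
_I_NEVER = 0
_I_CURRENT = 1
_I_RQ0 = 2
_I_FORMER0 = 8
_I_RN = 11
_I_DEAD = 12


def _mixture(y):
    """Alive-conditional (rho_N, rho_C, rho_F) of one flat state row."""
    alive = 0.0
    for k in range(_I_DEAD):
        alive += y[k]
    if alive <= 0.0:
        return 1.0, 0.0, 0.0
    rho_n = (y[_I_NEVER] + y[_I_RN]) / alive
    rho_c = y[_I_CURRENT]
    for k in range(_I_RQ0, _I_FORMER0):
        rho_c += y[k]
    rho_c /= alive
    rho_f = (y[_I_FORMER0] + y[_I_FORMER0 + 1] + y[_I_FORMER0 + 2]) / alive
    return rho_n, rho_c, rho_f


def _apply_substep(y, h, lam_q, gq, lam_r, mu_n, hr_c, hr_f, out):
    """Exact one-substep update with frozen rates; writes into ``out``."""
    mu_c = hr_c * mu_n
    mu_f = hr_f * mu_n
    e_n = np.exp(-mu_n * h)
    e_cq = np.exp(-(lam_q + mu_c) * h)
    s_c = np.exp(-mu_c * h)

    out[_I_NEVER] = y[_I_NEVER] * e_n
    out[_I_CURRENT] = y[_I_CURRENT] * e_cq
    # quit-flow into conveyor slot 0 of the current age's quit group
    rq_in = y[_I_CURRENT] * s_c * (1.0 - np.exp(-lam_q * h))
    for g in range(3):
        for s in range(2):
            k = _I_RQ0 + 2 * g + s
            out[k] = y[k] * s_c
    out[_I_RQ0 + 2 * gq] += rq_in

    rn = y[_I_RN] * e_n
    for g in range(3):
        kf = _I_FORMER0 + g
        b = lam_r[g] + mu_f
        out[kf] = y[kf] * np.exp(-b * h)
        # inflow former -> report_never, convolved with report_never decay
        if lam_r[g] > 0.0:
            d = b - mu_n
            if abs(d) > 1e-12:
                rn += lam_r[g] * y[kf] * (e_n - np.exp(-b * h)) / d
            else:
                rn += lam_r[g] * y[kf] * h * e_n
    out[_I_RN] = rn

    alive_before = 0.0
    alive_after = 0.0
    for k in range(_I_DEAD):
        alive_before += y[k]
        alive_after += out[k]
    out[_I_DEAD] = y[_I_DEAD] + (alive_before - alive_after)


def _integrate_cohorts_impl(
    states0,       # (n_coh, 13) at the starting age
    lam_q,         # (n_coh, n_steps) quit rate per year of age
    lam_r,         # (3,) reporting-as-never rate per quit group
    mu,            # (n_coh, n_steps) population mortality (or mu_N itself)
    hr_c,          # (n_steps,) hazard ratio current vs never, per age
    hr_f,          # (n_steps,)
    quit_group,    # (n_steps,) int age-at-quit group of each age-year
    substeps,      # int
    mu_is_baseline,  # bool: mu already is the never-smoker rate
    midpoint_refresh,  # bool: second-order mu_N refresh
):
    n_coh = states0.shape[0]
    n_steps = lam_q.shape[1]
    traj = np.empty((n_coh, n_steps + 1, NSTATE))
    h = 1.0 / substeps
    tmp = np.empty(NSTATE)
    half = np.empty(NSTATE)
    for i in range(n_coh):
        y = states0[i].copy()
        traj[i, 0] = y
        for t in range(n_steps):
            lq = lam_q[i, t]
            m = mu[i, t]
            hc = hr_c[t]
            hf = hr_f[t]
            gq = quit_group[t]
            for _ in range(substeps):
                if mu_is_baseline:
                    mu_n = m
                else:
                    rho_n, rho_c, rho_f = _mixture(y)
                    mu_n = m / (rho_n + hc * rho_c + hf * rho_f)
                    if midpoint_refresh:
                        _apply_substep(y, 0.5 * h, lq, gq, lam_r, mu_n, hc, hf, half)
                        rho_n, rho_c, rho_f = _mixture(half)
                        mu_n = m / (rho_n + hc * rho_c + hf * rho_f)
                _apply_substep(y, h, lq, gq, lam_r, mu_n, hc, hf, tmp)
                for k in range(NSTATE):
                    y[k] = tmp[k]
            # annual conveyor advance: slot 1 empties into former, slot 0 shifts
            for g in range(3):
                k0 = _I_RQ0 + 2 * g
                traj_former = y[_I_FORMER0 + g] + y[k0 + 1]
                y[_I_FORMER0 + g] = traj_former
                y[k0 + 1] = y[k0]
                y[k0] = 0.0
            traj[i, t + 1] = y
    return traj


try:  # pragma: no cover - exercised implicitly everywhere
    import numba

    _mixture = numba.njit(cache=True, fastmath=False)(_mixture)
    _apply_substep = numba.njit(cache=True, fastmath=False)(_apply_substep)
    integrate_cohorts = numba.njit(cache=True, fastmath=False)(
        _integrate_cohorts_impl
    )
    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    integrate_cohorts = _integrate_cohorts_impl
    HAVE_NUMBA = False
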