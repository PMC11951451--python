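"""Forward simulation of a birth cohort's smoking life-course from age 20.

The cohort starts at age 20 split between never-smokers and initiators (a
fraction P_I initiated; of those, P_F already quit).  Each subsequent year the
currently-smoking compartment loses mass to the recently-quit conveyor at the
quit rate lambda_Q, the conveyor advances (two-year sojourn) into the
formerly-smoked compartments, which in turn leak into reporting-as-never at
lambda_R, and every live compartment is exposed to status-specific mortality
derived from the population rate via the mixture identity
(:func:`smoketrends.mortality.baseline_mortality`).
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from ._kernel import integrate_cohorts
from .mortality import SEXES, HazardRatioSet, MortalityTable
from .states import (
    IDX_CURRENT,
    IDX_DEAD,
    IDX_NEVER,
    NSTATE,
    AgeAtQuitGroup,
    CohortTrajectory,
    StateVector,
    idx_former,
    idx_recent_quit,
    quit_group_of_age,
)

__all__ = [
    "START_AGE",
    "END_AGE",
    "DEFAULT_SUBSTEPS",
    "initial_state",
    "step_cohort",
    "solve_cohort",
    "cross_section",
]

START_AGE = 20
END_AGE = 99
DEFAULT_SUBSTEPS = 12


def initial_state(p_init: float, p_former: float,
                  recent_fraction: float = 0.5) -> StateVector:
    """State at the starting age (20 years).

    ``p_init`` is the proportion that initiated smoking (P_I); ``p_former``
    the proportion of initiators who already quit (P_F).  Quitters at age 20
    belong to age-at-quit group <30 by construction; ``recent_fraction`` of
    them are still in the recently-quit conveyor (split evenly over its two
    slots), the rest are in the formerly-smoked compartment.
    """
    for name, v in (("p_init", p_init), ("p_former", p_former),
                    ("recent_fraction", recent_fraction)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    y = np.zeros(NSTATE)
    y[IDX_NEVER] = 1.0 - p_init
    y[IDX_CURRENT] = p_init * (1.0 - p_former)
    quit_mass = p_init * p_former
    recent = quit_mass * recent_fraction
    y[idx_recent_quit(AgeAtQuitGroup.LT30, 0)] = recent / 2.0
    y[idx_recent_quit(AgeAtQuitGroup.LT30, 1)] = recent / 2.0
    y[idx_former(AgeAtQuitGroup.LT30)] = quit_mass - recent
    return StateVector(y)


def _lam_r_array(rates, sex: str) -> np.ndarray:
    return np.array([rates.report_never_rate(g, sex) for g in range(3)])


class RateFunctions:
    """Bundle of behavioural rate surfaces used by the stepper.

    ``quit_rate(age, year, sex)`` gives lambda_Q per person-year;
    ``report_never_rate(group, sex)`` gives lambda_R per person-year.
    """

    def __init__(self, quit_rate: Callable[[int, int, str], float],
                 report_never_rate: Callable[[int, str], float]):
        self.quit_rate = quit_rate
        self.report_never_rate = report_never_rate


def step_cohort(state: StateVector, age: int, year: int, rates: RateFunctions,
                mort: MortalityTable, hrs: HazardRatioSet, sex: str = "F",
                substeps: int = DEFAULT_SUBSTEPS,
                midpoint_refresh: bool = True) -> StateVector:
    """Advance one cohort-state by one year of age.

    Rate surfaces are sampled once at the integer (age, year) and held
    constant over the year; the substep count controls the refresh frequency
    of the never-smoker baseline rate mu_N (state-dependent via the mixture
    identity).  The recently-quit conveyor advances at the year boundary.
    """
    state.validate()
    lam_q = float(rates.quit_rate(age, year, sex))
    lam_r = _lam_r_array(rates, sex)
    if lam_q < 0 or np.any(lam_r < 0):
        raise ValueError("rates must be non-negative")
    mu = np.array([[mort.lookup(age, sex, year)]])
    traj = integrate_cohorts(
        state.values[None, :].copy(),
        np.array([[lam_q]]),
        lam_r,
        mu,
        np.asarray([float(hrs.current(age, sex))]),
        np.asarray([float(hrs.former(age, sex))]),
        np.array([int(quit_group_of_age(age))], dtype=np.int64),
        substeps,
        False,
        midpoint_refresh,
    )
    out = StateVector(traj[0, 1].copy())
    out.validate()
    return out


def solve_cohort(birth_year: int, sex: str, rates: RateFunctions,
                 p_init: float, p_former: float, mort: MortalityTable,
                 hrs: HazardRatioSet, recent_fraction: float = 0.5,
                 end_age: int = END_AGE, substeps: int = DEFAULT_SUBSTEPS,
                 midpoint_refresh: bool = True,
                 clamp_years: bool = True) -> CohortTrajectory:
    """Deterministic trajectory from age 20 to ``end_age``.

    Calendar years outside the mortality table span are clamped to the
    nearest covered year (boundary-cohort policy).
    """
    ages = np.arange(START_AGE, end_age)  # stepped years [age, age+1)
    lam_q = np.array([[float(rates.quit_rate(a, birth_year + a, sex))
                       for a in ages]])
    lam_r = _lam_r_array(rates, sex)
    mu = mort.gather_cohort(birth_year, sex, ages, clamp_years=clamp_years)[None, :]
    traj = integrate_cohorts(
        initial_state(p_init, p_former, recent_fraction).values[None, :],
        lam_q,
        lam_r,
        mu,
        np.asarray(hrs.current(ages, sex), dtype=float),
        np.asarray(hrs.former(ages, sex), dtype=float),
        np.array([int(quit_group_of_age(a)) for a in ages], dtype=np.int64),
        substeps,
        False,
        midpoint_refresh,
    )
    return CohortTrajectory(birth_year=birth_year, sex=sex,
                            start_age=START_AGE, states=traj[0])


def cross_section(trajectories: dict[tuple[int, str], CohortTrajectory],
                  year: int, ages: np.ndarray) -> dict[str, np.ndarray]:
    """Alive-conditional live-compartment proportions at one calendar year.

    For each sex and requested age, looks up the cohort with
    ``birth_year = year - age`` and returns its alive-conditional state
    (shape (n_ages, 12); rows sum to 1).  Missing cohorts raise ``KeyError``.
    """
    ages = np.asarray(ages, dtype=int)
    out = {}
    for sex in SEXES:
        rows = np.empty((ages.size, IDX_DEAD))
        for i, age in enumerate(ages):
            key = (year - int(age), sex)
            if key not in trajectories:
                raise KeyError(f"no trajectory for cohort {key}")
            rows[i] = trajectories[key].at_age(int(age)).alive_conditional()
        out[sex] = rows
    return out
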