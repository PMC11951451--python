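"""Compartmental state layout for the smoking life-course model.

One live individual (or unit cohort mass) occupies exactly one of the
compartments below.  The model follows a birth cohort of one sex from age 20:

* ``never``            — never initiated regular smoking;
* ``current``          — currently smokes;
* ``recent_quit[g][s]``— quit within the last two years (age-at-quit group
  ``g``, conveyor slot ``s`` counting completed years since the quit event);
* ``former[g]``        — quit more than two years ago, age-at-quit group ``g``;
* ``report_never``     — formerly smoked but now reports never having smoked;
* ``cumulative_dead``  — absorbing.

Age-at-quit groups split quitters at ages 30 and 40 (<30, 30-39, >=40), which
lets short-duration smokers switch to reporting-as-never at their own rate.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AgeAtQuitGroup",
    "StateVector",
    "CohortTrajectory",
    "NSTATE",
    "IDX_NEVER",
    "IDX_CURRENT",
    "IDX_REPORT_NEVER",
    "IDX_DEAD",
    "idx_recent_quit",
    "idx_former",
    "quit_group_of_age",
]

NSTATE = 13
IDX_NEVER = 0
IDX_CURRENT = 1
_IDX_RQ0 = 2  # recent_quit[g][s] at 2 + 2*g + s
_IDX_FORMER0 = 8  # former[g] at 8 + g
IDX_REPORT_NEVER = 11
IDX_DEAD = 12


class AgeAtQuitGroup(enum.IntEnum):
    """Age-at-quit classification with boundaries at ages 30 and 40."""

    LT30 = 0
    Q30_39 = 1
    GE40 = 2


def idx_recent_quit(group: int, slot: int) -> int:
    """Flat index of the recently-quit conveyor compartment."""
    if not (0 <= group < 3 and 0 <= slot < 2):
        raise IndexError(f"recent_quit[{group}][{slot}] out of range")
    return _IDX_RQ0 + 2 * group + slot


def idx_former(group: int) -> int:
    """Flat index of the formerly-smoked compartment for a quit group."""
    if not 0 <= group < 3:
        raise IndexError(f"former[{group}] out of range")
    return _IDX_FORMER0 + group


def quit_group_of_age(age: float) -> AgeAtQuitGroup:
    """Age-at-quit group for a quit event occurring at ``age``."""
    if age < 30:
        return AgeAtQuitGroup.LT30
    if age < 40:
        return AgeAtQuitGroup.Q30_39
    return AgeAtQuitGroup.GE40


_MASS_TOL = 1e-10


@dataclass
class StateVector:
    """Occupancy of one birth-cohort x sex at a single age.

    Wraps a flat length-13 array; live compartments plus ``cumulative_dead``
    sum to 1.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (NSTATE,):
            raise ValueError(f"expected shape ({NSTATE},), got {self.values.shape}")

    # -- named accessors ---------------------------------------------------
    @property
    def never(self) -> float:
        return float(self.values[IDX_NEVER])

    @property
    def current(self) -> float:
        return float(self.values[IDX_CURRENT])

    def recent_quit(self, group: int, slot: int) -> float:
        return float(self.values[idx_recent_quit(group, slot)])

    def former(self, group: int) -> float:
        return float(self.values[idx_former(group)])

    @property
    def report_never(self) -> float:
        return float(self.values[IDX_REPORT_NEVER])

    @property
    def cumulative_dead(self) -> float:
        return float(self.values[IDX_DEAD])

    # -- derived quantities ------------------------------------------------
    @property
    def alive(self) -> float:
        return float(self.values[:IDX_DEAD].sum())

    def alive_conditional(self) -> np.ndarray:
        """Live compartment proportions conditional on being alive."""
        alive = self.alive
        if alive <= 0:
            raise ValueError("no mass alive")
        return self.values[:IDX_DEAD] / alive

    def mixture_proportions(self) -> tuple[float, float, float]:
        """Alive-conditional (rho_N, rho_C, rho_F) for the mortality mixture.

        rho_N pools never and reporting-as-never, rho_C pools current and
        recently quit, rho_F pools the formerly-smoked groups.
        """
        cond = self.alive_conditional()
        rho_n = cond[IDX_NEVER] + cond[IDX_REPORT_NEVER]
        rho_c = cond[IDX_CURRENT] + cond[_IDX_RQ0:_IDX_FORMER0].sum()
        rho_f = cond[_IDX_FORMER0:IDX_REPORT_NEVER].sum()
        return float(rho_n), float(rho_c), float(rho_f)

    def validate(self) -> None:
        v = self.values
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite state")
        if np.any(v < -_MASS_TOL):
            raise ValueError("negative occupancy beyond tolerance")
        if abs(v.sum() - 1.0) > _MASS_TOL:
            raise ValueError(f"mass not conserved: sum={v.sum()!r}")


@dataclass
class CohortTrajectory:
    """States of one birth-cohort x sex at integer ages ``start_age``..end."""

    birth_year: int
    sex: str
    start_age: int
    states: np.ndarray  # (n_ages, NSTATE)
    ages: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=float)
        if self.states.ndim != 2 or self.states.shape[1] != NSTATE:
            raise ValueError("states must be (n_ages, 13)")
        self.ages = self.start_age + np.arange(self.states.shape[0])

    def at_age(self, age: int) -> StateVector:
        i = age - self.start_age
        if not 0 <= i < self.states.shape[0]:
            raise KeyError(f"age {age} outside trajectory")
        return StateVector(self.states[i])

    def validate(self) -> None:
        for row in self.states:
            StateVector(row.copy()).validate()
        dead = self.states[:, IDX_DEAD]
        if np.any(np.diff(dead) < -_MASS_TOL):
            raise ValueError("cumulative_dead not non-decreasing")
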