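"""Population mortality and smoking-status hazard ratios.

Status-specific mortality is tied to the all-cause population rate through a
mixture identity: if rho_N, rho_C, rho_F are the alive-conditional proportions
pooled as never/current/former (see :meth:`StateVector.mixture_proportions`)
and HR_C, HR_F the hazard ratios of death for current and former smokers
relative to never smokers, then

    mu = mu_N * (rho_N + HR_C * rho_C + HR_F * rho_F)

which is inverted at every integration substep to recover the never-smoker
baseline mu_N from the observed population rate mu.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SEXES = ("F", "M")

__all__ = ["SEXES", "MortalityTable", "HazardRatioSet", "baseline_mortality"]


def baseline_mortality(
    mu: float,
    rho_n: float,
    rho_c: float,
    rho_f: float,
    hr_c: float,
    hr_f: float,
) -> float:
    """Never-smoker mortality rate implied by the mixture identity.

    Parameters
    ----------
    mu
        All-cause population mortality rate (per person-year).
    rho_n, rho_c, rho_f
        Alive-conditional proportions never/current/former (pooled as in the
        model); must be non-negative and sum to 1.
    hr_c, hr_f
        Hazard ratios of death for current and former smokers vs never.
    """
    vals = np.array([mu, rho_n, rho_c, rho_f, hr_c, hr_f], dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite input")
    if mu < 0 or min(rho_n, rho_c, rho_f) < 0:
        raise ValueError("negative input")
    if hr_c <= 0 or hr_f <= 0:
        raise ValueError("hazard ratios must be positive")
    if abs(rho_n + rho_c + rho_f - 1.0) > 1e-8:
        raise ValueError("proportions must sum to 1")
    denom = rho_n + hr_c * rho_c + hr_f * rho_f
    if denom <= 0:
        raise ZeroDivisionError("zero mixture denominator")
    return mu / denom


@dataclass
class MortalityTable:
    """All-cause mortality mu(age, sex, year) on a complete rectangular grid.

    ``rates[sex]`` is an (n_ages, n_years) array over integer ages and
    calendar years.  Lookups outside the grid raise ``KeyError``; cohorts that
    genuinely extend past the year span are handled upstream by clamping.
    """

    ages: np.ndarray
    years: np.ndarray
    rates: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=int)
        self.years = np.asarray(self.years, dtype=int)
        for sex in SEXES:
            r = np.asarray(self.rates[sex], dtype=float)
            if r.shape != (self.ages.size, self.years.size):
                raise ValueError(f"rates[{sex}] shape {r.shape} != grid")
            if np.any(r <= 0) or not np.all(np.isfinite(r)):
                raise ValueError("all mortality rates must be finite and > 0")
            self.rates[sex] = r

    @property
    def year_span(self) -> tuple[int, int]:
        return int(self.years[0]), int(self.years[-1])

    def lookup(self, age: int, sex: str, year: int) -> float:
        ai = age - int(self.ages[0])
        yi = year - int(self.years[0])
        if not (0 <= ai < self.ages.size and 0 <= yi < self.years.size):
            raise KeyError(f"(age={age}, year={year}) outside mortality table")
        return float(self.rates[sex][ai, yi])

    def gather_cohort(self, birth_year: int, sex: str, ages: np.ndarray,
                      clamp_years: bool = True) -> np.ndarray:
        """Rates along a cohort diagonal (year = birth_year + age).

        Years outside the table span are clamped to the nearest covered year
        when ``clamp_years`` (the boundary-cohort policy); otherwise raises.
        """
        ages = np.asarray(ages, dtype=int)
        yrs = birth_year + ages
        if clamp_years:
            yrs = np.clip(yrs, self.years[0], self.years[-1])
        ai = ages - int(self.ages[0])
        yi = yrs - int(self.years[0])
        if np.any(ai < 0) or np.any(ai >= self.ages.size):
            raise KeyError("age outside mortality table")
        if np.any(yi < 0) or np.any(yi >= self.years.size):
            raise KeyError("year outside mortality table")
        return self.rates[sex][ai, yi]

    # -- delimited-text round trip ----------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sex in SEXES:
            r = self.rates[sex]
            for j, year in enumerate(self.years):
                for i, age in enumerate(self.ages):
                    rows.append((int(year), sex, int(age), r[i, j]))
        return pd.DataFrame(rows, columns=["year", "sex", "age", "mx"])

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MortalityTable":
        ages = np.sort(df["age"].unique())
        years = np.sort(df["year"].unique())
        rates = {}
        for sex in SEXES:
            sub = df[df["sex"] == sex]
            piv = sub.pivot(index="age", columns="year", values="mx")
            piv = piv.reindex(index=ages, columns=years)
            if piv.isna().any().any():
                raise ValueError(f"incomplete mortality grid for sex {sex}")
            rates[sex] = piv.to_numpy(dtype=float)
        return cls(ages=ages, years=years, rates=rates)

    @classmethod
    def read(cls, path: str | Path) -> "MortalityTable":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


@dataclass
class HazardRatioSet:
    """Piece-wise constant (by age stratum) mortality hazard ratios, per sex.

    ``strata`` is a list of [lo, hi) age bands partitioning the covered range;
    ``hr_current[sex]`` / ``hr_former[sex]`` give one ratio per stratum.  Ages
    below the first stratum use the first stratum's ratio by default (the HR
    source covers ages 45+ only), or HR = 1 when ``extend_down`` is False.
    """

    strata: list[tuple[int, int]]
    hr_current: dict[str, np.ndarray]
    hr_former: dict[str, np.ndarray]
    extend_down: bool = True
    _edges: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        for lo, hi in self.strata:
            if hi <= lo:
                raise ValueError("empty age stratum")
        los = [s[0] for s in self.strata]
        his = [s[1] for s in self.strata]
        if los != sorted(los) or any(h != l for h, l in zip(his[:-1], los[1:])):
            raise ValueError("strata must partition the covered age range")
        for sex in SEXES:
            for d in (self.hr_current, self.hr_former):
                arr = np.asarray(d[sex], dtype=float)
                if arr.shape != (len(self.strata),):
                    raise ValueError("one ratio per stratum required")
                if np.any(arr <= 0):
                    raise ValueError("hazard ratios must be > 0")
                d[sex] = arr
        self._edges = np.array([s[0] for s in self.strata], dtype=float)

    def stratum_index(self, age) -> np.ndarray:
        return np.clip(np.searchsorted(self._edges, age, side="right") - 1, 0,
                       len(self.strata) - 1)

    def _lookup(self, table: dict[str, np.ndarray], age, sex: str) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        out = table[sex][self.stratum_index(age)]
        if not self.extend_down:
            out = np.where(age < self.strata[0][0], 1.0, out)
        return out

    def current(self, age, sex: str):
        return self._lookup(self.hr_current, age, sex)

    def former(self, age, sex: str):
        return self._lookup(self.hr_former, age, sex)
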