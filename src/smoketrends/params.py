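"""Free-parameter vector layout and the parameter -> surface maps.

The full parameter block theta holds, in order: log hazard ratios (sex x
status x age stratum), the logit-type transform of P_F per sex, initiation
spline coefficients per sex (intercept first), quit-rate spline coefficients
per sex (intercept, age block, time block), log reporting-as-never rates per
sex for the variant's report groups, and the two log nuisance scales.

All components live on an unconstrained working scale:

* P_F in [0, 0.5] via ``P_F = 0.5 * expit(z)``;
* rates and scales via log;
* spline coefficients and log-HRs are already unconstrained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .mortality import SEXES, HazardRatioSet
from .splines import SplineSpec, natural_cubic_basis
from .variants import DEFAULT_DOMAINS, ModelVariant

__all__ = [
    "ParameterLayout",
    "ParameterVector",
    "make_spline_specs",
    "initiation_proportion",
    "quit_rate_surface",
    "report_rate",
]


def make_spline_specs(variant: ModelVariant,
                      domains: dict[str, tuple[float, float]] | None = None,
                      ) -> dict[str, SplineSpec | None]:
    """Equally-spaced-knot spline specs implied by a variant.

    The quit-rate time axis uses the calendar-year domain, or the birth-year
    domain when the variant's time axis is the birth cohort.
    """
    dom = dict(DEFAULT_DOMAINS)
    if domains:
        dom.update(domains)
    time_dom = dom["year"] if variant.quit_time_axis == "calendar_year" else dom["birth"]
    return {
        "birth": (SplineSpec.equally_spaced(*dom["birth"], variant.df_birth)
                  if variant.df_birth else None),
        "age": (SplineSpec.equally_spaced(*dom["age"], variant.df_age)
                if variant.df_age else None),
        "time": (SplineSpec.equally_spaced(*time_dom, variant.df_year)
                 if variant.df_year else None),
    }


@dataclass(frozen=True)
class ParameterLayout:
    """Index map from named blocks into the flat working-scale vector."""

    variant: ModelVariant
    n_strata: int
    slices: dict[str, slice] = field(default_factory=dict)
    size: int = 0

    def __post_init__(self) -> None:
        v = self.variant
        order: list[tuple[str, int]] = []
        for sex in SEXES:
            order.append((f"log_hr_current_{sex}", self.n_strata))
            order.append((f"log_hr_former_{sex}", self.n_strata))
        for sex in SEXES:
            order.append((f"z_pf_{sex}", 1))
        for sex in SEXES:
            order.append((f"beta_init_{sex}", 1 + v.df_birth))
        for sex in SEXES:
            order.append((f"beta_quit_{sex}", 1 + v.df_age + v.df_year))
        for sex in SEXES:
            order.append((f"log_report_{sex}", len(v.report_groups)))
        order.append(("log_tau_init", 1))
        order.append(("log_tau_quit", 1))
        slices, pos = {}, 0
        for name, n in order:
            slices[name] = slice(pos, pos + n)
            pos += n
        object.__setattr__(self, "slices", slices)
        object.__setattr__(self, "size", pos)

    def names(self) -> list[str]:
        """One label per scalar component, for chain stores and summaries."""
        out = []
        for name, sl in self.slices.items():
            n = sl.stop - sl.start
            out.extend([name] if n == 1 else [f"{name}[{i}]" for i in range(n)])
        return out


@dataclass
class ParameterVector:
    """Flat working-scale parameter vector plus its layout."""

    layout: ParameterLayout
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.layout.size,):
            raise ValueError(
                f"theta length {self.values.size} != layout size {self.layout.size}")

    @classmethod
    def zeros(cls, layout: ParameterLayout) -> "ParameterVector":
        return cls(layout, np.zeros(layout.size))

    def block(self, name: str) -> np.ndarray:
        return self.values[self.layout.slices[name]]

    def set_block(self, name: str, vals) -> None:
        self.values[self.layout.slices[name]] = vals

    def copy(self) -> "ParameterVector":
        return ParameterVector(self.layout, self.values.copy())

    # -- natural-scale accessors -------------------------------------------
    def pf(self, sex: str) -> float:
        return 0.5 * float(expit(self.block(f"z_pf_{sex}")[0]))

    def tau(self, which: str) -> float:
        return float(np.exp(self.block(f"log_tau_{which}")[0]))

    def hazard_ratios(self, strata: list[tuple[int, int]],
                      extend_down: bool = True) -> HazardRatioSet:
        return HazardRatioSet(
            strata=strata,
            hr_current={s: np.exp(self.block(f"log_hr_current_{s}")) for s in SEXES},
            hr_former={s: np.exp(self.block(f"log_hr_former_{s}")) for s in SEXES},
            extend_down=extend_down,
        )


def _clamp(x, domain):
    return np.clip(np.asarray(x, dtype=float), domain[0], domain[1])


def initiation_proportion(birth_year, sex: str, theta: ParameterVector,
                          specs: dict[str, SplineSpec | None]) -> np.ndarray:
    """P_I(birth year): inverse-logit of intercept + birth-year spline."""
    beta = theta.block(f"beta_init_{sex}")
    eta = np.full(np.atleast_1d(np.asarray(birth_year)).shape, beta[0])
    spec = specs["birth"]
    if spec is not None:
        eta = eta + natural_cubic_basis(_clamp(birth_year, spec.domain), spec) @ beta[1:]
    return expit(eta)


def quit_rate_surface(age, year, sex: str, theta: ParameterVector,
                      specs: dict[str, SplineSpec | None],
                      variant: ModelVariant) -> np.ndarray:
    """lambda_Q(age, time): exp of intercept + age spline + time spline.

    Additive on the log scale, hence multiplicatively separable in age and
    time.  The time axis is the calendar year, or birth cohort (year - age)
    under the cohort-axis sensitivity variant.
    """
    age = np.atleast_1d(np.asarray(age, dtype=float))
    year = np.atleast_1d(np.asarray(year, dtype=float))
    age, year = np.broadcast_arrays(age, year)
    beta = theta.block(f"beta_quit_{sex}")
    eta = np.full(age.shape, beta[0])
    pos = 1
    spec_a = specs["age"]
    if spec_a is not None:
        eta = eta + natural_cubic_basis(_clamp(age, spec_a.domain), spec_a) \
            @ beta[pos:pos + variant.df_age]
        pos += variant.df_age
    spec_t = specs["time"]
    if spec_t is not None:
        t = year if variant.quit_time_axis == "calendar_year" else year - age
        eta = eta + natural_cubic_basis(_clamp(t, spec_t.domain), spec_t) \
            @ beta[pos:pos + variant.df_year]
    return np.exp(eta)


def report_rate(group, sex: str, theta: ParameterVector,
                variant: ModelVariant) -> float:
    """lambda_R for one age-at-quit group (0 outside the report groups)."""
    groups = variant.report_groups
    for i, g in enumerate(groups):
        if int(g) == int(group):
            return float(np.exp(theta.block(f"log_report_{sex}")[i]))
    return 0.0
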