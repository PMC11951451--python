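"""Model variant ladder.

Eight nested variants A..H grow from a null model (intercept-only initiation
and quit rate, no reporting-as-never) by sequentially adding spline degrees
of freedom and reporting-as-never pathways.  The default ladder places the
selected model at position F: three birth-year df for initiation, two df
each for age and calendar year in the quit rate, and reporting-as-never for
quitters under age 40 (<30 and 30-39 groups).
"""

from __future__ import annotations

from dataclasses import dataclass

from .states import AgeAtQuitGroup

__all__ = ["ModelVariant", "variant_ladder", "DEFAULT_DOMAINS"]

#: Covariate domains: birth year for initiation, age and calendar year for
#: the quit rate.
DEFAULT_DOMAINS = {
    "birth": (1910.0, 1996.0),
    "age": (20.0, 99.0),
    "year": (1930.0, 2016.0),
}


@dataclass(frozen=True)
class ModelVariant:
    """One rung of the model ladder."""

    id: str
    df_birth: int   # spline df for initiation (0 = intercept only)
    df_age: int     # spline df for quit rate, age axis
    df_year: int    # spline df for quit rate, time axis
    report_groups: tuple[AgeAtQuitGroup, ...] = ()
    quit_time_axis: str = "calendar_year"   # or "birth_cohort"
    init_complete_age: int = 20
    use_weights: bool = True

    def __post_init__(self) -> None:
        if min(self.df_birth, self.df_age, self.df_year) < 0:
            raise ValueError("spline df must be >= 0")
        if self.quit_time_axis not in ("calendar_year", "birth_cohort"):
            raise ValueError(f"unknown quit_time_axis {self.quit_time_axis!r}")
        groups = tuple(AgeAtQuitGroup(g) for g in self.report_groups)
        if len(set(groups)) != len(groups):
            raise ValueError("duplicate report groups")
        object.__setattr__(self, "report_groups", groups)

    @property
    def is_null(self) -> bool:
        return (self.df_birth == self.df_age == self.df_year == 0
                and not self.report_groups)

    def n_free_parameters(self, n_strata: int, n_sexes: int = 2) -> int:
        """Length of the full free-parameter vector under this variant."""
        per_sex = (
            1                       # logit P_F
            + 1 + self.df_birth     # initiation intercept + spline
            + 1 + self.df_age + self.df_year  # quit intercept + splines
            + len(self.report_groups)         # log lambda_R
        )
        hr = n_sexes * 2 * n_strata  # current & former log-HR per stratum
        return hr + n_sexes * per_sex + 2  # + tau_init, tau_quit


_G = AgeAtQuitGroup


def variant_ladder(selected_dfs: tuple[int, int, int] = (3, 2, 2),
                   **overrides) -> list[ModelVariant]:
    """The default eight-variant ladder A..H.

    Growth order: time df, then age df, then birth df, then reporting-as-never
    groups (<30, then 30-39); G adds the >=40 group and H one extra birth df.
    ``selected_dfs`` = (df_birth, df_age, df_year) of the selected rung F.
    ``overrides`` (e.g. ``quit_time_axis``, ``init_complete_age``,
    ``use_weights``) apply to every rung — the sensitivity toggles.
    """
    db, da, dy = selected_dfs
    rungs = [
        ("A", 0, 0, 0, ()),
        ("B", 0, 0, dy, ()),
        ("C", 0, da, dy, ()),
        ("D", db, da, dy, ()),
        ("E", db, da, dy, (_G.LT30,)),
        ("F", db, da, dy, (_G.LT30, _G.Q30_39)),
        ("G", db, da, dy, (_G.LT30, _G.Q30_39, _G.GE40)),
        ("H", db + 1, da, dy, (_G.LT30, _G.Q30_39, _G.GE40)),
    ]
    ladder = [ModelVariant(id=i, df_birth=b, df_age=a, df_year=y,
                           report_groups=g, **overrides)
              for i, b, a, y, g in rungs]
    if not ladder[0].is_null:
        raise ValueError("first rung must be the null variant")
    for prev, cur in zip(ladder, ladder[1:]):
        if cur.n_free_parameters(1) <= prev.n_free_parameters(1):
            raise ValueError("ladder must be strictly nested")
    return ladder
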