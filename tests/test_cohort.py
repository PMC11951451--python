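import numpy as np
import pytest
from hypothesis import given, settings, strategies as st_h

from smoketrends.cohort import (
    RateFunctions,
    cross_section,
    initial_state,
    solve_cohort,
    step_cohort,
)
from smoketrends.mortality import HazardRatioSet, MortalityTable
from smoketrends.states import IDX_DEAD, IDX_NEVER, IDX_REPORT_NEVER


def flat_mortality(value=1e-9, years=(1900, 2100)):
    ages = np.arange(20, 100)
    yrs = np.arange(*years)
    return MortalityTable(ages=ages, years=yrs,
                          rates={s: np.full((ages.size, yrs.size), value)
                                 for s in ("F", "M")})


def unit_hrs():
    return HazardRatioSet(strata=[(45, 100)],
                          hr_current={"F": np.array([1.0]), "M": np.array([1.0])},
                          hr_former={"F": np.array([1.0]), "M": np.array([1.0])})


def make_rates(lam_q=0.0, lam_r=(0.0, 0.0, 0.0)):
    return RateFunctions(quit_rate=lambda a, y, s: lam_q,
                         report_never_rate=lambda g, s: lam_r[g])


class TestInitialState:
    def test_no_initiation(self):
        s = initial_state(0.0, 0.3)
        assert s.never == 1.0 and s.alive == 1.0
        assert s.values[1:].sum() == 0.0

    def test_no_quitters(self):
        s = initial_state(0.5, 0.0)
        assert s.current == 0.5 and s.never == 0.5

    def test_quit_split(self):
        s = initial_state(0.5, 0.2, recent_fraction=0.5)
        assert s.current == pytest.approx(0.4)
        recent = s.recent_quit(0, 0) + s.recent_quit(0, 1)
        assert recent == pytest.approx(0.05)
        assert s.former(0) == pytest.approx(0.05)
        assert s.cumulative_dead == 0.0

    def test_bounds(self):
        with pytest.raises(ValueError):
            initial_state(1.2, 0.0)
        with pytest.raises(ValueError):
            initial_state(0.5, -0.1)


class TestStepCohort:
    def test_no_rates_no_mortality_is_identity(self):
        s0 = initial_state(0.5, 0.2)
        # move conveyor mass to former first so the annual advance is a no-op
        s0.values[8] += s0.values[2] + s0.values[3]
        s0.values[2] = s0.values[3] = 0.0
        # (the mortality table demands mu > 0, hence the 1e-9 floor)
        s1 = step_cohort(s0, 35, 1970, make_rates(), flat_mortality(), unit_hrs())
        np.testing.assert_allclose(s1.values, s0.values, atol=1e-8)

    def test_pure_quit_decay_closed_form(self):
        lam = 0.3
        s0 = initial_state(0.6, 0.0)
        s1 = step_cohort(s0, 45, 1970, make_rates(lam_q=lam),
                         flat_mortality(), unit_hrs())
        assert s1.current == pytest.approx(0.6 * np.exp(-lam), rel=1e-8)

    def test_conveyor_two_year_sojourn(self):
        # quitters entering the conveyor reach 'former' after exactly 2 years
        s = initial_state(1.0, 0.0)
        rates_on = make_rates(lam_q=5.0)
        s = step_cohort(s, 25, 1970, rates_on, flat_mortality(), unit_hrs())
        in_conveyor = s.recent_quit(0, 1)
        assert in_conveyor > 0.99 and s.former(0) == 0.0
        s = step_cohort(s, 26, 1971, make_rates(), flat_mortality(), unit_hrs())
        assert s.recent_quit(0, 1) == 0.0
        assert s.former(0) == pytest.approx(in_conveyor)

    def test_quit_age_group_assignment(self):
        for age, group in ((25, 0), (35, 1), (45, 2)):
            s = step_cohort(initial_state(1.0, 0.0), age, 1970,
                            make_rates(lam_q=1.0), flat_mortality(), unit_hrs())
            assert s.recent_quit(group, 1) > 0.5

    @given(lam_q=st_h.floats(0, 0.5), lam_r=st_h.floats(0, 0.1),
           mu=st_h.floats(1e-6, 0.1), hr=st_h.floats(1.0, 4.0))
    @settings(max_examples=25, deadline=None)
    def test_mass_conserved_property(self, lam_q, lam_r, mu, hr):
        hrs = HazardRatioSet(strata=[(45, 100)],
                             hr_current={"F": np.array([hr]),
                                         "M": np.array([hr])},
                             hr_former={"F": np.array([max(1.0, hr / 2)]),
                                        "M": np.array([max(1.0, hr / 2)])})
        s = initial_state(0.6, 0.1)
        for age in range(20, 40):
            s = step_cohort(s, age, 1950 + (age - 20),
                            make_rates(lam_q, (lam_r,) * 3),
                            flat_mortality(mu), hrs)
        s.validate()  # includes live + dead = 1 to 1e-10
        assert s.values[IDX_DEAD] >= 0


def _generic_setup(hr_c=2.0, hr_f=1.5):
    hrs = HazardRatioSet(strata=[(45, 70), (70, 100)],
                         hr_current={"F": np.full(2, hr_c),
                                     "M": np.full(2, hr_c)},
                         hr_former={"F": np.full(2, hr_f),
                                    "M": np.full(2, hr_f)})
    ages = np.arange(20, 100)
    yrs = np.arange(1900, 2100)
    rates = {s: 2e-4 * np.exp(0.08 * (ages[:, None] - 20))
             * np.exp(-0.002 * (yrs[None, :] - 2000)) for s in ("F", "M")}
    mort = MortalityTable(ages=ages, years=yrs, rates=rates)
    rf = RateFunctions(
        quit_rate=lambda a, y, s: 0.01 * np.exp(0.02 * (y - 1950)),
        report_never_rate=lambda g, s: (0.02, 0.004, 0.0)[g])
    return rf, mort, hrs


class TestSolveCohort:
    def test_everyone_smokes_forever(self):
        _, mort, hrs = _generic_setup()
        tr = solve_cohort(1950, "F", make_rates(), 1.0, 0.0, mort, hrs)
        cond = np.array([tr.at_age(a).alive_conditional()[1]
                         for a in range(20, 100)])
        np.testing.assert_allclose(cond, 1.0, atol=1e-12)

    def test_equal_hazards_cancel_under_conditioning(self):
        rf, mort_a, _ = _generic_setup()
        mort_b = flat_mortality(0.02)
        hrs = unit_hrs()
        ta = solve_cohort(1950, "M", rf, 0.6, 0.1, mort_a, hrs)
        tb = solve_cohort(1950, "M", rf, 0.6, 0.1, mort_b, hrs)
        conda = ta.states[:, :IDX_DEAD] / ta.states[:, :IDX_DEAD].sum(1, keepdims=True)
        condb = tb.states[:, :IDX_DEAD] / tb.states[:, :IDX_DEAD].sum(1, keepdims=True)
        np.testing.assert_allclose(conda, condb, atol=1e-8)

    def test_monotone_trends(self):
        rf, mort, hrs = _generic_setup()
        tr = solve_cohort(1940, "F", rf, 0.7, 0.1, mort, hrs)
        tr.validate()
        never = tr.states[:, IDX_NEVER]
        alive = tr.states[:, :IDX_DEAD].sum(axis=1)
        rn_cond = tr.states[:, IDX_REPORT_NEVER] / alive
        dead = tr.states[:, IDX_DEAD]
        assert np.all(np.diff(never) <= 1e-12)
        # reporting-as-never only gains members among the living
        assert np.all(np.diff(rn_cond) >= -1e-12)
        assert np.all(np.diff(dead) >= -1e-12)

    def test_dense_substep_oracle(self):
        rf, mort, hrs = _generic_setup()
        t_default = solve_cohort(1945, "F", rf, 0.65, 0.12, mort, hrs)
        t_oracle = solve_cohort(1945, "F", rf, 0.65, 0.12, mort, hrs,
                                substeps=52)
        assert np.abs(t_default.states - t_oracle.states).max() < 1e-6


class TestCrossSection:
    def test_single_cohort_and_sum(self):
        rf, mort, hrs = _generic_setup()
        trajs = {(1950, s): solve_cohort(1950, s, rf, 0.6, 0.1, mort, hrs)
                 for s in ("F", "M")}
        out = cross_section(trajs, 1990, np.array([40]))
        for s in ("F", "M"):
            np.testing.assert_allclose(
                out[s][0], trajs[(1950, s)].at_age(40).alive_conditional())
            assert out[s].sum() == pytest.approx(1.0)

    def test_time_invariant_rates_shift_by_cohort(self):
        # with rates independent of calendar year, the cross-section at y+1
        # equals the cross-section at y relabelled by birth cohort
        _, mort, hrs = _generic_setup()
        mort_flat = flat_mortality(0.01)
        rf = make_rates(lam_q=0.05, lam_r=(0.01, 0.0, 0.0))
        trajs = {(b, s): solve_cohort(b, s, rf, 0.6, 0.1, mort_flat, hrs)
                 for b in (1948, 1949, 1950, 1951) for s in ("F", "M")}
        a = cross_section(trajs, 1990, np.array([40, 41]))
        b = cross_section(trajs, 1991, np.array([40, 41]))
        np.testing.assert_allclose(a["F"], b["F"], atol=1e-12)

    def test_missing_cohort_raises(self):
        rf, mort, hrs = _generic_setup()
        trajs = {(1950, "F"): solve_cohort(1950, "F", rf, 0.6, 0.1, mort, hrs)}
        with pytest.raises(KeyError):
            cross_section(trajs, 1990, np.array([41]))
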