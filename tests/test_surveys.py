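import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st_h

from smoketrends.surveys import (
    CellConfig,
    add_age_bands,
    build_cells,
    effective_sample_size,
    rake_weights,
    read_margins,
    read_survey_table,
    write_margins,
    write_survey_table,
)


def respondent_table(rows):
    df = pd.DataFrame(rows, columns=["survey_id", "year", "sex", "age",
                                     "category", "weight", "region",
                                     "capital_city"])
    df["capital_city"] = df["capital_city"].astype(str)
    return df


class TestEffectiveSampleSize:
    def test_equal_weights(self):
        assert effective_sample_size(np.ones(100)) == pytest.approx(100.0)

    def test_hand_computed(self):
        assert effective_sample_size([1, 1, 2]) == pytest.approx(16 / 6)

    def test_scale_invariant(self):
        w = np.array([0.5, 2.0, 3.0, 1.0])
        assert effective_sample_size(7 * w) == \
            pytest.approx(effective_sample_size(w), rel=1e-14)

    @given(st_h.lists(st_h.floats(0.01, 100), min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_bounded_by_n(self, weights):
        ess = effective_sample_size(weights)
        assert 0 < ess <= len(weights) + 1e-9

    def test_errors(self):
        with pytest.raises(ValueError):
            effective_sample_size([])
        with pytest.raises(ValueError):
            effective_sample_size([1.0, 0.0])


def simple_table():
    rows = []
    for sex, n in (("F", 6), ("M", 4)):
        for i in range(n):
            rows.append(("S1", 2000, sex, 30 + i, "never", 1.0,
                         "R1" if i % 2 else "R2", "1"))
    return respondent_table(rows)


class TestRaking:
    def test_already_matching_unchanged(self):
        t = simple_table()
        margins = {"sex": pd.Series({"F": 6.0, "M": 4.0})}
        w = rake_weights(t, margins)
        np.testing.assert_allclose(w, 1.0, atol=1e-14)

    def test_single_dimension_closed_form(self):
        t = simple_table()
        margins = {"sex": pd.Series({"F": 8.0, "M": 2.0})}
        w = rake_weights(t, margins)
        np.testing.assert_allclose(w[t["sex"] == "F"], 8 / 6, rtol=1e-12)
        np.testing.assert_allclose(w[t["sex"] == "M"], 2 / 4, rtol=1e-12)

    def test_two_by_two_matches_ipf_oracle(self):
        # 2x2 table from a uniform start; margins rows (60, 40), cols (50, 50)
        rows = [("S1", 2000, sex, 30, "never", 1.0, "R1", cap)
                for sex in ("F", "M") for cap in ("1", "0")]
        t = respondent_table(rows)
        margins = {"sex": pd.Series({"F": 60.0, "M": 40.0}),
                   "capital_city": pd.Series({"1": 50.0, "0": 50.0})}
        w = rake_weights(t, margins, tol=1e-12)
        # oracle: direct alternating scaling of the 2x2 count matrix
        M = np.ones((2, 2))
        for _ in range(200):
            M *= (np.array([60.0, 40.0]) / M.sum(1))[:, None]
            M *= np.array([50.0, 50.0]) / M.sum(0)
        got = np.array([[w[(t.sex == s) & (t.capital_city == c)].sum()
                         for c in ("1", "0")] for s in ("F", "M")])
        np.testing.assert_allclose(got, M, rtol=1e-10)

    def test_margins_matched_multiway(self, survey_data, raked_weights):
        # four raking dimensions on the synthetic surveys, matched per survey
        table, margins = survey_data
        banded = add_age_bands(table)
        banded["w"] = raked_weights
        for _, sv in banded.groupby("survey_id"):
            for dim, target in margins.items():
                got = sv.groupby(sv[dim].astype(str))["w"].sum()
                for level, t in target.items():
                    assert got[str(level)] == pytest.approx(t, rel=1e-7)

    def test_grand_total_preserved(self, survey_data, raked_weights):
        # every margin shares one grand total (the population size), so each
        # survey's raked weights sum to it
        table, margins = survey_data
        grand = margins["sex"].sum()
        for dim in margins:
            assert margins[dim].sum() == pytest.approx(grand, rel=1e-12)
        banded = add_age_bands(table)
        banded["w"] = raked_weights
        per_survey = banded.groupby("survey_id")["w"].sum()
        np.testing.assert_allclose(per_survey, grand, rtol=1e-8)

    def test_positive_weights(self, raked_weights):
        assert np.all(raked_weights > 0)

    def test_empty_level_with_target_raises(self):
        t = simple_table()
        margins = {"region": pd.Series({"R1": 5.0, "R2": 4.0, "R9": 1.0})}
        with pytest.raises(ValueError):
            rake_weights(t, margins)


class TestBuildCells:
    def test_four_respondent_example(self):
        rows = [("S1", 2000, "F", 40, c, 1.0, "R1", "1")
                for c in ("current", "current", "never", "former_lt30")]
        cells = build_cells(respondent_table(rows))
        assert len(cells) == 1
        cell = cells.iloc[0]
        assert cell["p_current"] == pytest.approx(0.5)
        assert cell["p_never"] == pytest.approx(0.25)
        assert cell["p_former_lt30"] == pytest.approx(0.25)
        assert cell["raw_n"] == 4 and cell["eff_n"] == pytest.approx(4.0)
        assert cell["birth_year"] == 1960

    def test_gallup_dialect_two_categories(self):
        rows = [("G1", 1964, "M", 50, c, 1.0, "R1", "1")
                for c in ("current", "not_current", "not_current")]
        cells = build_cells(respondent_table(rows))
        cell = cells.iloc[0]
        assert cell["dialect"] == "gallup"
        assert cell["p_current"] == pytest.approx(1 / 3)
        assert cell["p_not_current"] == pytest.approx(2 / 3)
        assert np.isnan(cell["p_never"])

    def test_weighted_equals_unweighted_for_constant_weights(self):
        rows = [("S1", 2000, "F", 40, c, 3.7, "R1", "1")
                for c in ("current", "never", "never", "former_ge40")]
        a = build_cells(respondent_table(rows))
        rows2 = [(r[0], r[1], r[2], r[3], r[4], 1.0, r[6], r[7]) for r in rows]
        b = build_cells(respondent_table(rows2))
        for c in ("p_current", "p_never", "p_former_ge40"):
            assert a.iloc[0][c] == pytest.approx(b.iloc[0][c])
        assert a.iloc[0]["eff_n"] == pytest.approx(4.0)

    def test_proportions_sum_to_one(self, cells):
        pcols = [c for c in cells.columns if c.startswith("p_")]
        sums = cells[pcols].sum(axis=1, skipna=True) - \
            cells["p_not_current"].fillna(0)
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)

    def test_eff_n_bounded_by_raw_n(self, cells):
        assert (cells["eff_n"] <= cells["raw_n"] + 1e-9).all()
        assert (cells["eff_n"] >= 1.0).all()

    def test_unweighted_sensitivity_flattens_weights(self):
        rows = [("S1", 2000, "F", 40, "current", 5.0, "R1", "1"),
                ("S1", 2000, "F", 40, "never", 1.0, "R1", "1")]
        weighted = build_cells(respondent_table(rows))
        flat = build_cells(respondent_table(rows),
                           config=CellConfig(use_weights=False))
        assert weighted.iloc[0]["p_current"] == pytest.approx(5 / 6)
        assert flat.iloc[0]["p_current"] == pytest.approx(0.5)
        assert flat.iloc[0]["eff_n"] == pytest.approx(2.0)

    def test_mask_frac_survey_level(self):
        rows = [("S1", 2000, "F", 40, "former_lt30", 1.0, "R1", "1"),
                ("S1", 2000, "F", 45, "former_unknown", 1.0, "R1", "1"),
                ("S1", 2000, "F", 45, "never", 1.0, "R1", "1")]
        cells = build_cells(respondent_table(rows))
        np.testing.assert_allclose(cells["mask_frac"], 0.5)


def test_survey_table_round_trip(tmp_path, survey_data):
    table, margins = survey_data
    p1 = tmp_path / "survey.tsv"
    write_survey_table(table, p1)
    back = read_survey_table(p1)
    pd.testing.assert_frame_equal(
        back, table.reset_index(drop=True), check_dtype=False)
    p2 = tmp_path / "margins.tsv"
    write_margins(margins, p2)
    margins2 = read_margins(p2)
    assert set(margins2) == set(margins)
    for dim in margins:
        got = margins2[dim]
        for level, t in margins[dim].items():
            assert got[str(level)] == pytest.approx(t)
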