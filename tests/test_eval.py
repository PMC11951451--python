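import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit, logit

from smoketrends.evaluate import (
    dic,
    discrepancy_summary,
    posterior_predictive_cells,
    trend_outputs,
)
from smoketrends.inference import PosteriorSample
from smoketrends.likelihood import LikelihoodEvaluator


def make_sample(draws, loglik):
    draws = np.asarray(draws, dtype=float)
    return PosteriorSample(draws=draws, log_lik=np.asarray(loglik, float),
                           chain_id=np.zeros(draws.shape[0], dtype=int),
                           per_chain=draws.shape[0])


class TestDic:
    def test_identical_draws_give_zero_pd(self):
        theta = np.array([1.0, 2.0])
        ll = -12.5
        sample = make_sample(np.tile(theta, (50, 1)), np.full(50, ll))
        res = dic(sample, lambda th: ll)
        assert res.p_d == pytest.approx(0.0, abs=1e-12)
        assert res.dic == pytest.approx(res.dbar)
        assert res.dbar == pytest.approx(-2 * ll)

    def test_identities_hold(self):
        rng = np.random.default_rng(0)
        draws = rng.normal(size=(100, 3))
        ll = rng.normal(-50, 2, size=100)
        res = dic(make_sample(draws, ll), lambda th: -49.0)
        assert res.p_d == pytest.approx(res.dbar - res.d_at_mean)
        assert res.dic == pytest.approx(res.dbar + res.p_d)

    def test_effective_parameters_match_gaussian_count(self):
        """Classical calibration: k independent Gaussian means, conjugate
        posterior => p_d ~ k."""
        rng = np.random.default_rng(4)
        k, n = 6, 200
        y = rng.normal(0.0, 1.0, size=(k, n))
        ybar = y.mean(axis=1)

        def loglik(theta):
            return float(np.sum(stats.norm.logpdf(y, theta[:, None], 1.0)))

        post_sd = 1 / np.sqrt(n)
        draws = ybar + post_sd * rng.standard_normal((800, k))
        ll = np.array([loglik(d) for d in draws])
        res = dic(make_sample(draws, ll), loglik)
        assert res.p_d == pytest.approx(k, rel=0.15)

    def test_needs_two_draws(self):
        with pytest.raises(ValueError):
            dic(make_sample(np.zeros((1, 2)), [-1.0]), lambda th: -1.0)


@pytest.fixture(scope="module")
def tiny_eval(cells, mort, hr_prior, selected_variant):
    # a few cells from every survey, so all covariate axes have spread
    sub = (cells[cells["dialect"] == "full"]
           .groupby("survey_id", sort=False).head(4).reset_index(drop=True))
    return LikelihoodEvaluator(sub, mort, hr_prior, selected_variant)


@pytest.fixture(scope="module")
def tiny_sample(tiny_eval, hr_prior):
    from smoketrends.calibrate import initial_theta
    rng = np.random.default_rng(6)
    base = initial_theta(tiny_eval.layout, hr_prior).values
    draws = base + 0.05 * rng.standard_normal((24, base.size))
    ll = np.array([tiny_eval.log_likelihood(tiny_eval.as_theta(d))
                   for d in draws])
    return make_sample(draws, ll)


class TestDiscrepancy:
    def test_perfect_model_zero_discrepancy(self, tiny_eval, truth):
        """If the observed proportions are replaced by the model's own
        probabilities, every outcome's mean and SD vanish."""
        from smoketrends.likelihood import _COL
        ev = tiny_eval
        theta = ev.as_theta(truth.theta.values)
        probs = ev.cell_probs(theta)
        cells2 = ev.cells.copy()
        for c in ("current", "former_lt30", "former_3039", "former_ge40",
                  "former_unknown", "never"):
            col = f"p_{c}"
            mask = np.isfinite(cells2[col].to_numpy(float))
            cells2.loc[mask, col] = probs[mask, _COL[c]]
        cells2["eff_n"] = 1e9   # neutralise the logit smoothing
        old = ev.cells
        ev.cells = cells2
        try:
            sample = make_sample(np.tile(theta.values, (3, 1)), np.zeros(3))
            summ = discrepancy_summary(sample, ev)
        finally:
            ev.cells = old
        for o in summ.mean:
            assert abs(summ.mean[o]) < 1e-6
            assert summ.sd[o] < 1e-6

    def test_constant_offset_recovered(self, tiny_eval, truth):
        from smoketrends.likelihood import _COL
        ev = tiny_eval
        theta = ev.as_theta(truth.theta.values)
        probs = ev.cell_probs(theta)
        cells2 = ev.cells.copy()
        delta = 0.3
        # inject a log-odds offset into the observed 'current' proportions
        cur = probs[:, _COL["current"]]
        cells2["p_current"] = expit(logit(cur) + delta)
        cells2["eff_n"] = 1e9
        old = ev.cells
        ev.cells = cells2
        try:
            sample = make_sample(np.tile(theta.values, (2, 1)), np.zeros(2))
            summ = discrepancy_summary(sample, ev)
        finally:
            ev.cells = old
        assert summ.mean["current"] == pytest.approx(delta, abs=1e-6)
        assert summ.sd["current"] == pytest.approx(0.0, abs=1e-6)


class TestPosteriorPredictive:
    def test_two_tailed_statistic_and_coverage_flags(self, tiny_eval,
                                                     tiny_sample):
        out = posterior_predictive_cells(tiny_sample, tiny_eval, seed=3)
        assert len(out) > 0
        np.testing.assert_allclose(out["p_two_tailed"],
                                   2 * np.minimum(out["q"], 1 - out["q"]),
                                   atol=1e-12)
        assert out["p_two_tailed"].between(0, 1).all()
        flag = (out["pred_lo"] <= out["observed"]) & \
            (out["observed"] <= out["pred_hi"])
        assert (out["covered90"] == flag).all()

    def test_reproducible_by_seed(self, tiny_eval, tiny_sample):
        a = posterior_predictive_cells(tiny_sample, tiny_eval, seed=3)
        b = posterior_predictive_cells(tiny_sample, tiny_eval, seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestTrendOutputs:
    def test_structure_and_eti_ordering(self, tiny_eval, tiny_sample):
        out = trend_outputs(tiny_sample, tiny_eval,
                            birth_years=(1930, 1960, 1990),
                            quit_years=(1970, 2000))
        assert (out["q5"] <= out["median"] + 1e-12).all()
        assert (out["median"] <= out["q95"] + 1e-12).all()
        assert set(out["output"]) >= {"initiation_pct", "initiation_growth_pct",
                                      "quit_rate_per100py", "quit_growth_pct",
                                      "report_never_per100py"}
        assert out["p_sex"].between(0, 1).all()

    def test_constant_rate_zero_growth(self, tiny_eval):
        theta = np.zeros(tiny_eval.layout.size)
        for sex in ("F", "M"):
            sl = tiny_eval.layout.slices[f"beta_quit_{sex}"]
            theta[sl.start] = np.log(0.03)          # intercept only
            theta[tiny_eval.layout.slices[f"log_report_{sex}"]] = -4.0
        sample = make_sample(np.tile(theta, (3, 1)), np.zeros(3))
        out = trend_outputs(sample, tiny_eval, birth_years=(1950,),
                            quit_years=(1980, 2000))
        growth = out[out["output"] == "quit_growth_pct"]
        np.testing.assert_allclose(growth["median"], 0.0, atol=1e-10)

    def test_identical_sexes_give_p_one(self, tiny_eval):
        theta = np.zeros(tiny_eval.layout.size)
        lay = tiny_eval.layout
        theta[lay.slices["beta_quit_F"].start] = np.log(0.02)
        theta[lay.slices["beta_quit_M"].start] = np.log(0.02)
        theta[lay.slices["log_report_F"]] = -4.0
        theta[lay.slices["log_report_M"]] = -4.0
        sample = make_sample(np.tile(theta, (4, 1)), np.zeros(4))
        out = trend_outputs(sample, tiny_eval, birth_years=(1950,),
                            quit_years=(1990,))
        np.testing.assert_allclose(out["p_sex"], 1.0)

    def test_constructed_exponential_growth(self, tiny_eval):
        """Initiation built to grow at ~1%/year at the domain centre."""
        spec = tiny_eval.specs["birth"]
        lo, hi = spec.domain
        t0 = 0.5 * (lo + hi)
        theta = np.zeros(tiny_eval.layout.size)
        lay = tiny_eval.layout
        # logit-linear slope s gives d log P/dt = s * (1 - P); choose s so
        # the growth at P = 0.2 is 1%/year
        s = 0.01 / 0.8
        from smoketrends.splines import natural_cubic_basis
        b0 = natural_cubic_basis(np.array([t0, t0 + 1.0]), spec)
        slope_std = b0[1] - b0[0]          # per-year change of basis columns
        coef = np.zeros(spec.df)
        coef[0] = s / slope_std[0]
        for sex in ("F", "M"):
            sl = lay.slices[f"beta_init_{sex}"]
            theta[sl.start] = logit(0.2) - float(b0[0] @ coef)
            theta[sl.start + 1:sl.stop] = coef
            theta[lay.slices[f"beta_quit_{sex}"].start] = np.log(0.02)
            theta[lay.slices[f"log_report_{sex}"]] = -4.0
        sample = make_sample(np.tile(theta, (3, 1)), np.zeros(3))
        out = trend_outputs(sample, tiny_eval, birth_years=(int(t0),),
                            quit_years=(1990,))
        growth = out[(out["output"] == "initiation_growth_pct")
                     & (out["sex"] == "F")]
        assert growth["median"].iloc[0] == pytest.approx(1.0, abs=0.05)
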