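"""Design-based estimators against brute-force and reduction oracles."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from somnoscope import survey
from somnoscope.survey import (SurveyDesign, SurveyOrdinalLogit,
                               SurveyPolynomialTrend, four_year_weights,
                               weighted_mean_se, weighted_quantiles)


def _demo(weights=(20000.0, 15000.0), cycles=("A", "B")):
    n = len(weights)
    return pd.DataFrame({
        "subject_id": range(1, n + 1),
        "age_years": 30, "sex": "male", "race": "NH White",
        "weight_2yr": weights, "stratum": 1,
        "psu": (np.arange(n) % 2) + 1,
        "cycle": [cycles[i % len(cycles)] for i in range(n)],
    })


class TestFourYearWeights:
    def test_halving_and_total(self):
        d = four_year_weights(_demo())
        assert d["weight_4yr"].tolist() == [10000.0, 7500.0]
        assert d["weight_4yr"].sum() == 0.5 * d["weight_2yr"].sum()

    def test_single_cycle_needs_flag(self):
        demo = _demo(cycles=("A",))
        with pytest.raises(ValueError, match="single_cycle"):
            four_year_weights(demo)
        with pytest.warns(UserWarning, match="unhalved"):
            d = four_year_weights(demo, allow_single_cycle=True)
        assert d["weight_4yr"].tolist() == [20000.0, 15000.0]


def _design(n, n_strata=5, seed=0, weights=None):
    rng = np.random.default_rng(seed)
    return SurveyDesign(
        stratum=rng.integers(1, n_strata + 1, n),
        psu=rng.integers(1, 3, n),
        weight=weights if weights is not None
        else rng.uniform(0.5, 3.0, n))


class TestWeightedMean:
    def test_two_point_mean(self):
        d = SurveyDesign(stratum=[1, 1], psu=[1, 2], weight=[1.0, 3.0])
        m, se = weighted_mean_se([1.0, 3.0], d)
        assert m == 2.5

    def test_weight_rescaling_invariance(self):
        rng = np.random.default_rng(2)
        y = rng.normal(5, 2, 200)
        d = _design(200, seed=3)
        d2 = SurveyDesign(d.stratum, d.psu, 2.0 * d.weight)
        m1, se1 = weighted_mean_se(y, d)
        m2, se2 = weighted_mean_se(y, d2)
        assert m1 == pytest.approx(m2, abs=1e-12)
        assert se1 == pytest.approx(se2, abs=1e-12)

    def test_equal_weight_se_near_srs(self):
        """Many PSUs, equal weights: the linearized SE is close to the
        simple-random-sampling SE."""
        rng = np.random.default_rng(7)
        n = 4000
        y = rng.normal(0, 1, n)
        d = SurveyDesign(stratum=np.arange(n) % 40,
                         psu=rng.integers(1, 6, n),
                         weight=np.ones(n))
        _, se = weighted_mean_se(y, d)
        srs = y.std(ddof=1) / np.sqrt(n)
        assert abs(se - srs) / srs < 0.10

    def test_lonely_psu_warns(self):
        d = SurveyDesign(stratum=[1, 1, 2], psu=[1, 2, 1],
                         weight=[1.0, 1.0, 1.0])
        with pytest.warns(survey.LonelyPSUWarning):
            weighted_mean_se([1.0, 2.0, 3.0], d)


class TestWeightedQuantiles:
    def test_equal_weight_median(self):
        q = weighted_quantiles([1, 2, 3], [1, 1, 1], (0.5,))
        assert q[0] == 2

    def test_mass_dominance(self):
        q = weighted_quantiles([1, 2, 3], [1, 1, 100], (0.5,))
        assert q[0] == 3

    def test_against_bruteforce_cdf_inversion(self):
        rng = np.random.default_rng(11)
        y = rng.normal(0, 1, 1000)
        w = rng.uniform(0.1, 5, 1000)
        probs = (0.05, 0.1, 0.25, 0.5, 0.75, 0.9)
        qs = weighted_quantiles(y, w, probs)
        order = np.argsort(y)
        ys, ws = y[order], w[order]
        cdf = np.cumsum(ws) / ws.sum()
        for p, q in zip(probs, qs):
            expect = ys[np.argmax(cdf >= p)]     # brute-force inversion
            assert q == expect

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            weighted_quantiles([], [], (0.5,))


def synth_subjects(n, seed, beta_sex=0.2, interactions=False,
                   n_strata=12, resid_sd=0.8):
    """Subject-level outcomes from a known quartic-age + sex + race model."""
    rng = np.random.default_rng(seed)
    age = rng.integers(6, 86, n)
    sex = np.where(rng.random(n) < 0.5, "female", "male")
    race = rng.choice(survey.RACE_LEVELS, n, p=[0.64, 0.12, 0.10, 0.14])
    a = (age - survey.AGE_CENTER) / survey.AGE_SCALE
    coef = np.array([22.8, 0.5, -0.3, 0.1, -0.05])
    y = (coef[0] + coef[1] * a + coef[2] * a ** 2 + coef[3] * a ** 3
         + coef[4] * a ** 4 + beta_sex * (sex == "female"))
    if interactions:
        y = y + 0.3 * (sex == "female") * a
    y = y + rng.normal(0, resid_sd, n)
    return pd.DataFrame({
        "age_years": age, "sex": sex, "race": race, "outcome": y,
        "stratum": rng.integers(1, n_strata + 1, n),
        "psu": rng.integers(1, 3, n),
        "weight_4yr": rng.uniform(0.5, 4.0, n),
    }), coef


class TestPolynomialTrend:
    def test_equal_weights_reduce_to_ols(self):
        data, _ = synth_subjects(400, seed=5)
        data["weight_4yr"] = 1.0
        m = SurveyPolynomialTrend("outcome").fit(data)
        X, names = survey.build_design_matrix(data)
        ols = sm.OLS(data["outcome"], X).fit()
        assert np.allclose(m.params_.to_numpy(), ols.params, atol=1e-10)

    def test_row_permutation_invariance(self):
        data, _ = synth_subjects(300, seed=6)
        m1 = SurveyPolynomialTrend("outcome").fit(data)
        perm = data.sample(frac=1, random_state=1)
        m2 = SurveyPolynomialTrend("outcome").fit(perm)
        assert np.allclose(m1.params_, m2.params_, atol=1e-10)
        assert np.allclose(m1.se_, m2.se_, atol=1e-10)

    def test_recovers_generating_coefficients(self):
        data, coef = synth_subjects(2000, seed=8)
        m = SurveyPolynomialTrend("outcome").fit(data)
        est = m.params_[["intercept", "age1", "age2", "age3", "age4"]]
        se = m.se_[["intercept", "age1", "age2", "age3", "age4"]]
        assert (np.abs(est.to_numpy() - coef) < 3 * se.to_numpy()).all()
        assert m.wald_["sex"]["p"] < 0.05      # true sex effect present

    def test_interaction_wald_detects_true_interaction(self):
        data, _ = synth_subjects(2000, seed=9, interactions=True)
        m = SurveyPolynomialTrend("outcome", ("sex",)).fit(data)
        assert m.wald_["sex_x_age"]["p"] < 0.01

    def test_curve_grid_shape(self):
        data, _ = synth_subjects(500, seed=10)
        m = SurveyPolynomialTrend("outcome").fit(data)
        grid = m.curve_grid()
        assert len(grid) == 80 * 2 * 4
        assert grid["fitted"].notna().all()


class TestOrdinal:
    def test_binary_collapse_matches_weighted_logit(self):
        data, _ = synth_subjects(800, seed=12)
        med = weighted_quantiles(data["outcome"], data["weight_4yr"], (0.5,))[0]
        cats = (data["outcome"] > med).astype(int)
        m = SurveyOrdinalLogit().fit(data, cats)
        X, names = survey.build_design_matrix(data)
        w = data["weight_4yr"] / data["weight_4yr"].mean()
        glm = sm.GLM(cats, X, family=sm.families.Binomial(),
                     freq_weights=w).fit()
        # OrderedModel: P(y<=0) = F(thr - xb); Logit intercept = -thr
        assert np.allclose(m.params_.to_numpy(), glm.params[1:], atol=1e-3)

    def test_reversed_categories_flip_signs(self):
        data, _ = synth_subjects(600, seed=13)
        cuts = weighted_quantiles(data["outcome"], data["weight_4yr"],
                                  (0.25, 0.5, 0.75))
        cats = np.searchsorted(cuts, data["outcome"].to_numpy())
        m1 = SurveyOrdinalLogit().fit(data, cats)
        m2 = SurveyOrdinalLogit().fit(data, 3 - cats)
        assert np.allclose(m1.params_, -m2.params_, atol=1e-3)

    def test_efficiency_quartile_wrapper(self):
        data, _ = synth_subjects(600, seed=14)
        data["mean_efficiency"] = 1 / (1 + np.exp(-data["outcome"] + 22.8))
        m = survey.efficiency_quartile_ordinal(data)
        assert len(m.cutpoints_) == 3
        assert m.wald_["sex"]["p"] < 0.05   # sex effect carries through


def test_population_summary_totals():
    rng = np.random.default_rng(15)
    n = 300
    data = pd.DataFrame({
        "age_years": rng.integers(6, 86, n),
        "sex": np.where(rng.random(n) < 0.5, "female", "male"),
        "race": rng.choice(survey.RACE_LEVELS, n),
        "stratum": rng.integers(1, 9, n), "psu": rng.integers(1, 3, n),
        "weight_4yr": rng.uniform(1000, 9000, n),
        "mean_duration_h": rng.normal(8, 1, n),
        "mean_onset_clock": rng.normal(23, 1, n),
        "mean_efficiency": rng.uniform(0.9, 1.0, n),
    })
    out = survey.population_summary(data).set_index("variable")
    assert out.loc["weighted_population", "value"] == pytest.approx(
        data["weight_4yr"].sum())
    assert out.loc["n_subjects", "value"] == n
    race_pct = out.loc[[f"race_{r.replace(' ', '_')}_pct"
                        for r in survey.RACE_LEVELS], "value"]
    assert race_pct.sum() == pytest.approx(100.0)
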