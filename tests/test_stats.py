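"""t-tests and the Bayesian GLM layer."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from callspace.errors import DegenerateDataError, InsufficientDataError, ValidationError
from callspace.glm import (
    SamplerConfig,
    VocalLearningGLM,
    pooled_ttest,
    summarize_results,
    ttest_from_summary,
)

QUICK = SamplerConfig(walkers=24, warmup=800, iterations=800, seed=0, ess_min=300)


# ---------------------------------------------------------------------------
# t-tests


def test_pooled_ttest_hand_formula_example():
    """x = {1,2,3} vs y = {2,3,4}: pooled-variance t = -sqrt(3/2), df = 4."""
    res = pooled_ttest([1, 2, 3], [2, 3, 4])
    assert res.t == pytest.approx(-1.2247, abs=5e-5)
    assert res.df == 4


def test_pooled_ttest_identical_samples():
    res = pooled_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.t == 0.0
    assert res.p == pytest.approx(1.0)


def test_pooled_ttest_df_for_twelve_per_group():
    rng = np.random.default_rng(0)
    res = pooled_ttest(rng.normal(size=12), rng.normal(size=12))
    assert res.df == 22


def test_pooled_ttest_errors():
    with pytest.raises(InsufficientDataError):
        pooled_ttest([1.0], [1.0, 2.0])
    with pytest.raises(DegenerateDataError):
        pooled_ttest([1.0, 1.0], [2.0, 2.0])


def test_summary_ttest_reproduces_published_ratio_comparison():
    """Group summaries 0.744 +/- 0.049 vs 0.811 +/- 0.061 (n = 12 each)."""
    res = ttest_from_summary(0.744, 0.049, 12, 0.811, 0.061, 12)
    assert round(res.t, 2) == -0.86
    assert res.df == 22
    assert res.p > 0.05


def test_summary_ttest_vsp_comparison():
    res = ttest_from_summary(0.441, 0.024, 12, 0.480, 0.034, 12)
    assert res.t == pytest.approx(-0.94, abs=0.005)


def test_summary_ttest_zero_difference_and_validation():
    assert ttest_from_summary(0.5, 0.1, 5, 0.5, 0.1, 5).t == 0.0
    with pytest.raises(ValidationError):
        ttest_from_summary(0.5, 0.0, 5, 0.5, 0.1, 5)


def test_pooled_and_summary_tests_agree_on_raw_samples():
    rng = np.random.default_rng(1)
    x, y = rng.normal(0, 1, 15), rng.normal(0.4, 1, 15)
    raw = pooled_ttest(x, y)
    summ = ttest_from_summary(raw.mean1, raw.se1, 15, raw.mean2, raw.se2, 15)
    assert summ.t == pytest.approx(raw.t, abs=1e-12)
    assert summ.p == pytest.approx(raw.p, abs=1e-12)


def test_ttest_antisymmetric_under_group_swap():
    rng = np.random.default_rng(2)
    x, y = rng.normal(0, 1, 10), rng.normal(1, 1, 12)
    a, b = pooled_ttest(x, y), pooled_ttest(y, x)
    assert a.t == pytest.approx(-b.t)
    assert a.p == pytest.approx(b.p)


# ---------------------------------------------------------------------------
# Bayesian GLM


def _design(n, seed=0):
    rng = np.random.default_rng(seed)
    age = (np.arange(n) % 2).astype(float)
    fox = rng.normal(0, 0.2, n)
    return np.column_stack([np.ones(n), fox, age, fox * age]), age, fox


def test_normal_family_recovers_linear_truth():
    """y = 2 - age + noise: the age posterior matches and foxp2's HPD covers 0."""
    X, age, _fox = _design(200, seed=3)
    rng = np.random.default_rng(4)
    y = 2.0 - 1.0 * age + rng.normal(0, 0.5, len(age))
    res = VocalLearningGLM(y, X, family="normal", names=["intercept", "foxp2", "age", "foxp2_x_age"]).fit(QUICK)
    assert res.medians["age"] == pytest.approx(-1.0, abs=0.25)
    lo, hi = res.hpd["foxp2"]
    assert lo < 0 < hi


def test_normal_posterior_approaches_least_squares():
    X, age, fox = _design(500, seed=5)
    rng = np.random.default_rng(6)
    y = 1.0 + 0.8 * fox - 0.5 * age + rng.normal(0, 0.4, 500)
    ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    res = VocalLearningGLM(y, X, family="normal").fit(QUICK)
    for i, name in enumerate(res.model.names):
        assert res.medians[name] == pytest.approx(ols[i], abs=max(0.05 * abs(ols[i]), 0.05))


def test_beta_family_detects_logit_age_effect():
    X, age, _ = _design(200, seed=7)
    rng = np.random.default_rng(8)
    mu = expit(0.5 - 0.7 * age)
    y = rng.beta(mu * 30, (1 - mu) * 30)
    res = VocalLearningGLM(y, X, family="beta").fit(QUICK)
    lo, hi = res.hpd[res.model.names[2]]
    assert hi < 0  # the negative age effect is resolved
    assert lo <= res.medians[res.model.names[2]] <= hi


def test_beta_boundary_compression_is_monotone_and_open():
    y = np.array([0.0, 0.2, 0.5, 0.8, 1.0])
    X = np.column_stack([np.ones(5), np.arange(5.0)])
    model = VocalLearningGLM(np.repeat(y, 2)[:6], np.ones((6, 1)), family="beta")
    z = model._y
    assert (z > 0).all() and (z < 1).all()
    assert (np.diff(np.sort(z)) >= 0).all()
    with pytest.raises(ValidationError):
        VocalLearningGLM(np.array([0.5, 1.2, 0.3, 0.4, 0.5, 0.6]), np.ones((6, 1)), family="beta")


def test_fit_is_seed_deterministic():
    X, age, _ = _design(60, seed=9)
    rng = np.random.default_rng(10)
    y = 1.0 + 0.3 * age + rng.normal(0, 0.3, 60)
    cfg = SamplerConfig(walkers=16, warmup=200, iterations=200, seed=5)
    a = VocalLearningGLM(y, X, family="normal").fit(cfg)
    b = VocalLearningGLM(y, X, family="normal").fit(cfg)
    np.testing.assert_array_equal(a.chain, b.chain)


def test_results_invariants_and_summary_flags():
    X, age, _ = _design(120, seed=11)
    rng = np.random.default_rng(12)
    y = 2.0 - 1.5 * age + rng.normal(0, 0.3, 120)
    res = VocalLearningGLM(y, X, family="normal").fit(QUICK)
    table = res.summary()
    for _, row in table.iterrows():
        assert row["hpd_lower"] <= row["estimate"] <= row["hpd_upper"]
        assert row["significant"] == (row["hpd_lower"] > 0 or row["hpd_upper"] < 0)


def test_from_measures_builds_centered_design():
    measures = pd.DataFrame(
        {
            "bird_id": [f"b{i}" for i in range(8)],
            "age_class": ["young"] * 4 + ["older"] * 4,
            "included": True,
            "vocal_convergence": np.linspace(0.2, 0.8, 8),
            "foxp2_ratio": np.linspace(0.6, 1.1, 8),
        }
    )
    model = VocalLearningGLM.from_measures(measures, "vocal_convergence")
    assert model.family == "beta"
    assert model.exog[:, 1].mean() == pytest.approx(0.0, abs=1e-12)  # centered ratio
    np.testing.assert_array_equal(model.exog[:, 2], [0, 0, 0, 0, 1, 1, 1, 1])
    np.testing.assert_allclose(model.exog[:, 3], model.exog[:, 1] * model.exog[:, 2])


def test_insufficient_rows_rejected():
    with pytest.raises(InsufficientDataError):
        VocalLearningGLM(np.ones(4), np.ones((4, 1)), family="normal")


def test_summarize_results_flags_hpd_excluding_zero():
    X, age, _ = _design(120, seed=13)
    rng = np.random.default_rng(14)
    y = 2.0 - 1.5 * age + rng.normal(0, 0.3, 120)
    model = VocalLearningGLM(y, X, family="normal", names=["intercept", "foxp2", "age", "foxp2_x_age"])
    model.response = "vocal_diversity"
    res = model.fit(QUICK)
    report = summarize_results(
        ttests={"ratio": pooled_ttest([1, 2, 3], [2, 3, 4])},
        fits={"vocal_diversity": res},
    )
    age_coef = report["glm"]["vocal_diversity"]["coefficients"]["age"]
    assert age_coef["significant"] is (age_coef["hpd_upper"] < 0 or age_coef["hpd_lower"] > 0)
    assert report["t_tests"]["ratio"]["df"] == 4
    assert summarize_results() == {"t_tests": {}, "glm": {}}
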