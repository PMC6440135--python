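import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

import edtransit as e
from edtransit.model import DepartureModel, RankDeficiencyError, combined_or, lr_interaction_test

from _oracles import brute_force_fit_2d


def _design(d, n, **covs):
    return pd.DataFrame({"D": d, "n": n, **covs})


def test_intercept_only_fit_is_pooled_proportion():
    design = _design([3, 1, 4], [5, 6, 7])
    res = DepartureModel(design).fit()
    p_hat = expit(res.params["intercept"])
    assert p_hat == pytest.approx(8 / 18, abs=1e-10)
    assert res.converged


def test_fit_matches_brute_force_likelihood_search():
    rng = np.random.default_rng(11)
    x1 = rng.normal(size=30)
    n = rng.integers(1, 12, size=30)
    p = expit(-0.4 + 0.8 * x1)
    d = rng.binomial(n, p)
    design = _design(d, n, x1=x1)
    res = DepartureModel(design).fit()
    exog = np.column_stack([np.ones(30), x1])
    oracle = brute_force_fit_2d(d.astype(float), n.astype(float), exog)
    assert res.params.to_numpy() == pytest.approx(oracle, abs=1e-4)


def test_fit_matches_statsmodels_glm(sim_month_design, sim_month_fit):
    sm = pytest.importorskip("statsmodels.api")
    cols = sim_month_fit.model.covariate_names
    exog = sm.add_constant(sim_month_design[cols].to_numpy(float))
    endog = np.column_stack(
        [sim_month_design["D"], sim_month_design["n"] - sim_month_design["D"]]
    )
    ref = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
    assert sim_month_fit.params.to_numpy() == pytest.approx(ref.params, abs=1e-6)
    assert sim_month_fit.bse.to_numpy() == pytest.approx(ref.bse, rel=1e-4)
    assert sim_month_fit.residual_deviance == pytest.approx(ref.deviance, rel=1e-8)
    assert sim_month_fit.null_deviance == pytest.approx(ref.null_deviance, rel=1e-8)


def test_score_is_zero_at_optimum(sim_month_design, sim_month_fit):
    p = sim_month_fit.predict()
    resid = sim_month_design["D"].to_numpy() - sim_month_design["n"].to_numpy() * p
    score = sim_month_fit.model.exog.T @ resid
    assert np.abs(score).max() < 1e-6


def test_fitted_margins_reproduce_observed_totals(sim_month_design, sim_month_fit):
    p = sim_month_fit.predict()
    assert (sim_month_design["n"] * p).sum() == pytest.approx(
        sim_month_design["D"].sum(), abs=1e-6
    )


def test_deviance_decreases_monotonically(sim_month_fit):
    path = np.asarray(sim_month_fit.deviance_path)
    assert (np.diff(path) <= 1e-8).all()
    assert sim_month_fit.residual_deviance <= sim_month_fit.null_deviance


def test_covariance_positive_semidefinite(sim_month_fit):
    eigvals = np.linalg.eigvalsh(sim_month_fit.cov_params.to_numpy())
    assert eigvals.min() > -1e-12


def test_rank_deficiency_error_names_collinear_column():
    rng = np.random.default_rng(3)
    x1 = rng.normal(size=20)
    design = _design(
        rng.integers(0, 3, 20), np.full(20, 4), x1=x1, x1_copy=2.0 * x1
    )
    with pytest.raises(RankDeficiencyError, match="x1"):
        DepartureModel(design)


def test_odds_ratio_table_matches_coefficients(sim_month_fit):
    table = sim_month_fit.odds_ratio_table().set_index("term")
    for term in sim_month_fit.model.covariate_names:
        coef = sim_month_fit.params[term]
        se = sim_month_fit.bse[term]
        row = table.loc[term]
        assert row["or"] == pytest.approx(np.exp(coef), rel=1e-12)
        assert row["ci_low"] == pytest.approx(np.exp(coef - 1.96 * se), rel=1e-12)
        assert row["ci_high"] == pytest.approx(np.exp(coef + 1.96 * se), rel=1e-12)
        assert row["wt_change_pct"] == round(100 / np.exp(coef))
        assert 0 <= row["p_value"] <= 1


@pytest.mark.parametrize(
    "or_value,pct",
    [(0.942, 106), (1.0, 100), (1.145, 87), (0.978, 102), (1.103, 91)],
)
def test_waiting_time_percent_column_from_known_odds_ratios(or_value, pct):
    design = _design([1, 3, 2, 4], [4, 5, 6, 7], x=[0.0, 1.0, 0.0, 1.0])
    res = DepartureModel(design).fit()
    res.params["x"] = np.log(or_value)  # evaluate display maths at a known coefficient
    table = res.odds_ratio_table().set_index("term")
    assert table.loc["x", "or"] == pytest.approx(or_value, rel=1e-12)
    assert table.loc["x", "wt_change_pct"] == pct


def test_combined_or_reference_cell_is_one():
    coefs = pd.Series(
        {
            "shift_evening": np.log(1.103),
            "shift_night": np.log(1.145),
            "weekend": np.log(1.002),
            "evening_weekend": np.log(1.152),
            "night_weekend": np.log(0.943),
        }
    )
    ratio, pct = combined_or(coefs, "day", weekend=False)
    assert ratio == 1.0 and pct == 100


def test_combined_or_reproduces_weekend_cells():
    coefs = pd.Series(
        {
            "shift_evening": np.log(1.103),
            "shift_night": np.log(1.145),
            "weekend": np.log(1.002),
            "evening_weekend": np.log(1.152),
            "night_weekend": np.log(0.943),
        }
    )
    ev_ratio, ev_pct = combined_or(coefs, "evening", weekend=True)
    assert ev_ratio == pytest.approx(1.273, abs=5e-4)
    assert ev_pct == 79
    ni_ratio, ni_pct = combined_or(coefs, "night", weekend=True)
    assert ni_ratio == pytest.approx(1.082, abs=5e-4)
    assert ni_pct == 92
    # weekday cells are the main effects alone
    assert combined_or(coefs, "evening", weekend=False)[0] == pytest.approx(1.103)
    assert combined_or(coefs, "night", weekend=False)[1] == 87


def test_combined_or_unknown_shift_errors():
    with pytest.raises(ValueError, match="unknown shift"):
        combined_or(pd.Series(dtype=float), "dawn", weekend=False)


def test_lr_test_of_identical_models_is_null():
    design = _design([1, 3, 2], [4, 5, 6], x=[0.0, 1.0, 2.0])
    a = DepartureModel(design).fit()
    b = DepartureModel(design).fit()
    chi2, df, p = lr_interaction_test(a, b)
    assert chi2 == pytest.approx(0.0, abs=1e-10)
    assert df == 0 and p == 1.0


def test_lr_test_rejects_non_nested_inputs():
    d1 = _design([1, 3, 2], [4, 5, 6], x=[0.0, 1.0, 2.0])
    d2 = _design([1, 3], [4, 5], x=[0.0, 1.0])
    with pytest.raises(ValueError, match="same design rows"):
        lr_interaction_test(DepartureModel(d1).fit(), DepartureModel(d2).fit())


def test_lr_interaction_chi2_against_deviance_difference(sim_month_design):
    full = DepartureModel(sim_month_design).fit()
    reduced_cols = [
        c
        for c in full.model.covariate_names
        if c not in ("evening_weekend", "night_weekend")
    ]
    reduced = DepartureModel(sim_month_design, covariates=reduced_cols).fit()
    chi2, df, p = lr_interaction_test(full, reduced)
    assert df == 2
    assert chi2 == pytest.approx(
        reduced.residual_deviance - full.residual_deviance, abs=1e-9
    )
    assert 0 <= p <= 1


def test_dropping_lag_terms_barely_moves_other_coefficients(sim_month_design):
    """With weak serial-correlation truth the pre-specified predictors are
    nearly unchanged when the departure-lag terms are removed."""
    full = DepartureModel(sim_month_design).fit()
    kept = [c for c in full.model.covariate_names if not c.startswith("dep_lag")]
    reduced = DepartureModel(sim_month_design, covariates=kept).fit()
    shift = (full.params[["intercept", *kept]] - reduced.params).abs()
    assert (shift < 3 * full.bse[["intercept", *kept]]).all()


def test_summary_mentions_convergence_and_deviances(sim_month_fit):
    text = sim_month_fit.summary()
    assert "converged: True" in text
    assert "residual deviance" in text
    assert "arrivals" in text
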