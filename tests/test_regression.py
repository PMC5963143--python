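import numpy as np
import pandas as pd
import pytest

from conftest import make_calls, make_traits
from hpapredict.datatypes import MatingDesign, TraitTable, ValidationError
from hpapredict.regression import (
    FitError,
    HybridPerformanceRegressor,
    cross_validate,
    fit_mlr,
    fit_simple,
    summarize_cv,
)
from hpapredict.simulate import SimulationConfig, simulate_dataset
from hpapredict.differential import call_differential


def test_simple_ols_matches_closed_form():
    rng = np.random.default_rng(0)
    x = rng.uniform(0, 1, 20)
    y = rng.normal(size=20)
    model = fit_simple(x, y)
    X = np.column_stack([np.ones(20), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    assert model.intercept == pytest.approx(beta[0])
    assert model.coefficients[0] == pytest.approx(beta[1])


def test_simple_exact_line_and_two_points():
    x = np.array([0.1, 0.4, 0.9])
    model = fit_simple(x, 2.0 + 3.0 * x)
    assert model.intercept == pytest.approx(2.0)
    assert model.coefficients[0] == pytest.approx(3.0)
    assert model.r_squared == pytest.approx(1.0)
    with pytest.raises(FitError):
        fit_simple([0.5, 0.5, 0.5], [1, 2, 3])
    with pytest.raises(FitError):
        fit_simple([0.1, 0.9], [1, 2])  # < 3 hybrids


def test_mlr_exact_recovery_and_constant_column():
    rng = np.random.default_rng(1)
    n = 30
    table = pd.DataFrame(
        {
            "D_b_pos": rng.uniform(0, 1, n),
            "D_b_neg": rng.uniform(0, 1, n),
            "m_f": rng.uniform(0, 1, n),
            "m_d": rng.normal(size=n),
        }
    )
    beta = np.array([1.5, -2.0, 0.7, 0.3])
    y = 4.0 + table.to_numpy() @ beta
    model = fit_mlr(table, y)
    assert model.intercept == pytest.approx(4.0, abs=1e-8)
    np.testing.assert_allclose(model.coefficients, beta, atol=1e-8)

    table2 = table.copy()
    table2["D_b_neg"] = 0.5
    with pytest.warns(UserWarning, match="constant"):
        reduced = fit_mlr(table2, y)
    assert reduced.predictor_names == ["D_b_pos", "m_f", "m_d"]


def test_mlr_requires_enough_rows():
    table = pd.DataFrame({"D_b_pos": [0.1, 0.2], "D_b_neg": [0.3, 0.4],
                          "m_f": [0.5, 0.6], "m_d": [0.7, 0.8]})
    with pytest.raises(FitError):
        fit_mlr(table, [1.0, 2.0])


def _planted_calls(n_hybrids=24, n_markers=40, seed=2):
    """Marker 0 drives the trait up; marker 1 (its near-complement) drives it down."""
    rng = np.random.default_rng(seed)
    hybrids = [("F1", f"D{i:02d}") for i in range(n_hybrids)]
    arr = rng.random((n_hybrids, n_markers)) < 0.5
    arr[:, 0] = np.arange(n_hybrids) % 2 == 0  # balanced positive factor
    arr[:, 1] = ~arr[:, 0]
    arr[7, 1] = arr[21, 1] = False  # not exactly collinear with marker 0
    y = 10 + 2.0 * arr[:, 0] - 2.0 * arr[:, 1] + rng.normal(0, 0.05, n_hybrids)
    return make_calls(arr, hybrids), make_traits(y, hybrids), hybrids


def test_regressor_fit_predict_insample():
    calls, traits, hybrids = _planted_calls()
    y = traits.values.to_numpy()
    est = HybridPerformanceRegressor(predictor="MLR", fdr_level=0.2)
    est.fit(calls, y)
    pred = est.predict(calls)
    assert np.corrcoef(pred, y)[0, 1] > 0.9
    assert "m0" in est.positive_markers_ and "m1" in est.negative_markers_
    params = est.get_params()
    assert params["predictor"] == "MLR"
    est2 = HybridPerformanceRegressor(**params).fit(calls, y)
    np.testing.assert_allclose(est2.predict(calls), pred)


def test_regressor_requires_direction():
    rng = np.random.default_rng(5)
    hybrids = [("F1", f"D{i:02d}") for i in range(20)]
    arr = rng.random((20, 30)) < 0.5
    arr[:, 0] = np.arange(20) % 2 == 0  # balanced positive factor
    y = 10 + 2.0 * arr[:, 0] + rng.normal(0, 0.05, 20)  # positive signal only
    calls = make_calls(arr, hybrids)
    est = HybridPerformanceRegressor(predictor="D_b_neg", fdr_level=0.05)
    with pytest.raises(FitError, match="negatively"):
        est.fit(calls, y)
    # the positive-direction predictor fits fine on the same data
    HybridPerformanceRegressor(predictor="D_b_pos", fdr_level=0.05).fit(calls, y)


def test_cross_validate_deterministic(default_dataset):
    d = default_dataset
    kw = dict(scheme="type2", predictor_sets=("D_b_com",), n_runs=3, seed=123)
    r1 = cross_validate(d["calls"], d["design"], d["traits"], **kw)
    r2 = cross_validate(d["calls"], d["design"], d["traits"], **kw)
    assert [r.accuracy for r in r1] == [r.accuracy for r in r2]
    assert [r.estimation_flint for r in r1] == [r.estimation_flint for r in r2]


def test_cross_validate_training_sets_by_scheme(default_dataset):
    d = default_dataset
    for scheme, expected_train in (("type2", 62), ("type0", 15)):
        runs = cross_validate(d["calls"], d["design"], d["traits"], scheme=scheme,
                              predictor_sets=("D_b_com",), n_runs=2, seed=1)
        for r in runs:
            assert r.n_validation == 36
            assert r.n_training == expected_train
    runs = cross_validate(d["calls"], d["design"], d["traits"], scheme="type1",
                          predictor_sets=("D_b_com",), n_runs=4, seed=1)
    for r in runs:
        assert r.n_training == (35 if r.tested_group == "Flint" else 42)


def test_validation_traits_do_not_leak(default_dataset):
    """Permuting validation-hybrid traits must not change the predictions."""
    d = default_dataset
    calls, design, traits = d["calls"], d["design"], d["traits"]
    runs = cross_validate(calls, design, traits, scheme="type2",
                          predictor_sets=("D_b_com",), n_runs=1, seed=99)
    run = runs[0]
    est_f, est_d = set(run.estimation_flint), set(run.estimation_dent)
    validation = [(f, dd) for f, dd in design.hybrids
                  if f not in est_f and dd not in est_d]
    perturbed = traits.values.copy()
    rng = np.random.default_rng(0)
    vidx = pd.MultiIndex.from_tuples(validation)
    perturbed.loc[vidx] = rng.permutation(perturbed.loc[vidx].to_numpy())
    runs2 = cross_validate(calls, design, TraitTable("GY", perturbed),
                           scheme="type2", predictor_sets=("D_b_com",),
                           n_runs=1, seed=99)
    # same markers selected, same model: only the accuracy changes
    assert runs2[0].n_positive == run.n_positive
    assert runs2[0].n_negative == run.n_negative


def test_cv_on_null_dataset_mostly_fails():
    cfg = SimulationConfig(seed=4, n_pos_planted=0, n_neg_planted=0,
                           n_snp=50, n_mrna=50, n_srna=800)
    mats, design, traits, _ = simulate_dataset(cfg)
    calls = call_differential(mats["sRNA"], design)
    runs = cross_validate(calls, design, traits, scheme="type2",
                          predictor_sets=("D_b_com",), n_runs=10, seed=0)
    summary = summarize_cv(runs)
    assert summary.loc["D_b_com", "n_success"] <= 1


def test_unknown_scheme_rejected(default_dataset):
    d = default_dataset
    with pytest.raises(ValidationError):
        cross_validate(d["calls"], d["design"], d["traits"], scheme="type3")
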