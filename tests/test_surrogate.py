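import numpy as np
import pandas as pd
import pytest
from synthetic_tables import monotone_response_table

from amsriver import SneakerSuccessBRT, SurrogateConfig
from amsriver.sensitivity import PARAM_NAMES
from amsriver.surrogate import (
    backward_eliminate,
    importance_and_partial_dependence,
    split_train_test,
    tune_and_fit,
    validate,
)

FAST = SurrogateConfig(n_bootstrap=25, max_trees=150, cv_folds=3, seed=0)


@pytest.fixture(scope="module")
def table():
    return monotone_response_table(n=100, seed=7)


@pytest.fixture(scope="module")
def tuned(table):
    train, test = split_train_test(table, 0.7, seed=0)
    model, hyper, grid = tune_and_fit(train, FAST, PARAM_NAMES)
    return train, test, model, hyper, grid


# -- split --------------------------------------------------------------------

def test_split_70_30(table):
    train, test = split_train_test(table, 0.7, seed=1)
    assert len(train) == 70 and len(test) == 30
    assert set(train.index).isdisjoint(test.index)
    assert len(set(train.index) | set(test.index)) == 100


def test_split_reproducible_and_validated(table):
    a, _ = split_train_test(table, 0.7, seed=2)
    b, _ = split_train_test(table, 0.7, seed=2)
    assert a.index.tolist() == b.index.tolist()
    with pytest.raises(ValueError):
        split_train_test(table, 1.0, seed=0)
    with pytest.raises(ValueError):
        split_train_test(table.head(5), 0.7, seed=0)


# -- tuning -------------------------------------------------------------------

def test_grid_enumerates_36_cells(tuned):
    *_, grid = tuned
    assert len(grid) == 36
    assert set(grid["bag_fraction"]) == {0.5, 0.6, 0.7}
    assert set(grid["tree_complexity"]) == {2, 3, 4}
    assert set(grid["learning_rate"]) == {0.01, 0.005, 0.001, 0.0005}


def test_selected_model_beats_variance_baseline(tuned):
    train, test, model, hyper, _ = tuned
    pred = model.predict(test[PARAM_NAMES].to_numpy())
    mae = np.abs(pred - test["score"].to_numpy()).mean()
    assert mae < test["score"].std()  # better than predicting the mean
    assert hyper["cv_mae"] < train["score"].std()


def test_constant_response_flagged(table):
    flat = table.copy()
    flat["score"] = 0.4
    model, hyper, _ = tune_and_fit(flat, FAST, PARAM_NAMES)
    assert hyper["degenerate"]
    assert np.allclose(model.predict(flat[PARAM_NAMES].to_numpy()), 0.4)


# -- backward elimination -----------------------------------------------------

def test_noise_predictor_eliminated(table):
    predictors = PARAM_NAMES + ["noise"]
    train, _ = split_train_test(table, 0.7, seed=3)
    model, hyper, _ = tune_and_fit(train, FAST, predictors)
    retained, refit = backward_eliminate(model, train, FAST, predictors)
    assert "noise" not in retained
    assert len(retained) >= 1
    assert refit.n_features_in_ == len(retained)


def test_single_predictor_always_retained(table):
    train, _ = split_train_test(table, 0.7, seed=4)
    model, _, _ = tune_and_fit(train, FAST, ["assortative_c"])
    retained, _ = backward_eliminate(model, train, FAST, ["assortative_c"])
    assert retained == ["assortative_c"]


# -- importance and partial dependence ---------------------------------------

def test_importances_sum_to_100_and_pd_signs(tuned):
    train, _, model, _, _ = tuned
    imp, pdp = importance_and_partial_dependence(model, train, FAST, PARAM_NAMES)
    assert imp.sum() == pytest.approx(100.0)
    assert (imp >= 0).all()

    def slope(name):
        c = pdp[name]
        return np.polyfit(c["value"], c["mean"], 1)[0]

    lo, hi = 1.0, 3.0
    assert slope("assortative_c") < 0
    assert slope("sneaker_additive_mortality") < 0
    assert slope("sneaker_male_proportion") > 0
    # envelopes bracket the mean
    for c in pdp.values():
        assert (c["lo"] <= c["mean"] + 1e-9).all()
        assert (c["hi"] >= c["mean"] - 1e-9).all()


def test_irrelevant_predictor_has_flat_pd_and_low_importance(table):
    predictors = PARAM_NAMES + ["noise"]
    train, _ = split_train_test(table, 0.7, seed=5)
    model, _, _ = tune_and_fit(train, FAST, predictors)
    imp, pdp = importance_and_partial_dependence(model, train, FAST, predictors)
    # the noise column explains less than any real driver of the response
    for real in ("assortative_c", "sneaker_male_proportion",
                 "sneaker_additive_mortality"):
        assert imp["noise"] < imp[real]
    span = pdp["noise"]["mean"].max() - pdp["noise"]["mean"].min()
    span_c = pdp["assortative_c"]["mean"].max() - pdp["assortative_c"]["mean"].min()
    assert span < span_c / 2


def test_permutation_consistency(table):
    """Destroying a predictor's association with the response reduces its
    fitted importance."""
    train, _ = split_train_test(table, 0.7, seed=6)
    model, _, _ = tune_and_fit(train, FAST, PARAM_NAMES)
    imp_before = pd.Series(model.feature_importances_, index=PARAM_NAMES)
    shuffled = train.copy()
    shuffled["assortative_c"] = (
        np.random.default_rng(0).permutation(shuffled["assortative_c"].to_numpy())
    )
    model2, _, _ = tune_and_fit(shuffled, FAST, PARAM_NAMES)
    imp_after = pd.Series(model2.feature_importances_, index=PARAM_NAMES)
    assert imp_after["assortative_c"] < imp_before["assortative_c"]


# -- validation ---------------------------------------------------------------

class _Echo:
    def __init__(self, values):
        self.values = np.asarray(values, dtype=float)

    def predict(self, X):
        return self.values


def test_validate_perfect_and_reversed(table):
    test = table.head(10)
    y = test["score"].to_numpy()
    perfect = validate(_Echo(y), test, PARAM_NAMES)
    assert perfect["spearman"] == pytest.approx(1.0)
    assert perfect["mae"] == pytest.approx(0.0)
    reversed_ = validate(_Echo(np.sort(y)[::-1][np.argsort(np.argsort(y))]),
                         test, PARAM_NAMES)
    assert reversed_["spearman"] == pytest.approx(-1.0)


def test_validate_requires_three_rows(table):
    with pytest.raises(ValueError):
        validate(_Echo([1, 2]), table.head(2), PARAM_NAMES)


# -- model/results interface --------------------------------------------------

def test_model_results_workflow(table):
    res = SneakerSuccessBRT(table, config=FAST).fit()
    assert res.relative_importance.sum() == pytest.approx(100.0)
    assert res.validation["spearman"] > 0.5  # strong synthetic signal
    assert set(res.retained_predictors) <= set(PARAM_NAMES)
    text = res.summary()
    assert "importance" in text and "Spearman" in text
    payload = res.to_json()
    assert "relative_importance" in payload


def test_model_rejects_missing_columns(table):
    with pytest.raises(ValueError, match="missing"):
        SneakerSuccessBRT(table.drop(columns=["score"]))
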