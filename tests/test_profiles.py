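"""Latent-profile model, simplified tree and evaluation metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from nutriprofile import (evaluate_classifier, fit_latent_profiles,
                          assign_profiles, feature_importance, canonical_tree,
                          train_simplified_tree, CANONICAL_ITEM_SUBSET)
from nutriprofile.cohort import liking_columns
from nutriprofile.profiles import FitError


# --- latent profile fitting -------------------------------------------------

def test_empty_input_raises():
    with pytest.raises(FitError):
        fit_latent_profiles(pd.DataFrame(columns=["a", "b"]), k_range=[2])


def test_two_planted_clusters_recovered_with_high_ari():
    rng = np.random.default_rng(0)
    a = rng.normal(0, 1, size=(150, 4))
    b = rng.normal(6, 1, size=(150, 4))
    X = pd.DataFrame(np.vstack([a, b]), columns=list("wxyz"))
    truth = np.array([0] * 150 + [1] * 150)
    fit = fit_latent_profiles(X, k_range=[2], seed=1)
    comp = fit.posterior.argmax(axis=1)
    assert adjusted_rand_score(truth, comp) >= 0.95


def test_bic_prefers_smallest_k_on_homogeneous_cloud():
    rng = np.random.default_rng(3)
    X = pd.DataFrame(rng.normal(5, 1, size=(400, 3)), columns=list("abc"))
    fit = fit_latent_profiles(X, k_range=[2, 3], seed=1)
    admissible = [c for c in fit.candidates if c["admissible"]]
    assert fit.k == min(c["k"] for c in admissible)


def test_posterior_rows_sum_to_one(liking_matrix):
    fit = fit_latent_profiles(liking_matrix, k_range=[3], seed=1)
    np.testing.assert_allclose(fit.posterior.sum(axis=1), 1.0, atol=1e-9)


def test_assignment_recovers_planted_profiles(small_cohort, liking_matrix):
    fit = fit_latent_profiles(liking_matrix, k_range=[3], seed=1)
    labels = assign_profiles(fit, liking_matrix)
    acc = (labels.values == small_cohort.true_profile.values).mean()
    assert acc >= 0.9


def test_assignment_invariant_to_record_order(liking_matrix):
    fit = fit_latent_profiles(liking_matrix, k_range=[3], seed=1)
    labels = assign_profiles(fit, liking_matrix)
    perm = np.random.default_rng(0).permutation(len(liking_matrix))
    shuffled = liking_matrix.iloc[perm]
    labels2 = assign_profiles(fit, shuffled)
    assert (labels2.values == labels.values[perm]).all()


def test_fit_handles_missing_values(missing_cohort):
    liking = missing_cohort.data[liking_columns()]
    fit = fit_latent_profiles(liking, k_range=[3], seed=1)
    labels = assign_profiles(fit, liking)
    acc = (labels.values == missing_cohort.true_profile.values).mean()
    assert acc >= 0.85


# --- canonical simplified tree ---------------------------------------------

def test_canonical_tree_item_subset_is_the_14_questionnaire_items():
    tree = canonical_tree()
    assert len(tree.item_subset) == 14
    assert set(tree.item_subset) == set(CANONICAL_ITEM_SUBSET)


@pytest.mark.parametrize("liking,expected", [
    ({"tea_with_sugar": 2, "vegetables": 9}, "health_conscious"),
    ({"tea_with_sugar": 5, "roast_chicken": 8}, "omnivore"),
    ({"tea_with_sugar": 5, "roast_chicken": 5}, "sweet_tooth"),
    # threshold directions are exact: <3 strict, >=8 and >=7 inclusive
    ({"tea_with_sugar": 3, "roast_chicken": 7}, "omnivore"),
    ({"tea_with_sugar": 2, "vegetables": 8}, "health_conscious"),
    ({"tea_with_sugar": 2, "vegetables": 7}, "omnivore"),
])
def test_canonical_tree_narrated_splits(liking, expected):
    assert canonical_tree().classify(liking) == expected


def test_canonical_tree_requires_split_items():
    with pytest.raises(ValueError, match="tea_with_sugar"):
        canonical_tree().classify({"vegetables": 9})


@settings(max_examples=200, deadline=None)
@given(tea=st.integers(1, 9), veg=st.integers(1, 9), chicken=st.integers(1, 9))
def test_canonical_tree_is_total_and_deterministic(tea, veg, chicken):
    """Every liking vector with the three split items present maps to
    exactly one of the three profiles, reproducibly."""
    tree = canonical_tree()
    scores = {"tea_with_sugar": tea, "vegetables": veg, "roast_chicken": chicken}
    label = tree.classify(scores)
    assert label in ("health_conscious", "omnivore", "sweet_tooth")
    assert tree.classify(scores) == label
    if tea < 3 and veg >= 8:
        assert label == "health_conscious"
    if tea >= 3:
        assert label == ("omnivore" if chicken >= 7 else "sweet_tooth")


def test_tree_json_roundtrip(tmp_path):
    import json

    from nutriprofile.profiles import SimplifiedTree
    tree = canonical_tree()
    blob = json.dumps(tree.to_json())
    back = SimplifiedTree.from_json(json.loads(blob))
    assert back.classify({"tea_with_sugar": 5, "roast_chicken": 9}) == "omnivore"


# --- trained simplified tree -------------------------------------------------

def _separable_toy():
    rows = [(1, 9, "a")] * 10 + [(9, 1, "b")] * 10
    X = pd.DataFrame([(r[0], r[1]) for r in rows], columns=["f1", "f2"])
    y = pd.Series([r[2] for r in rows])
    return X, y


def test_separable_toy_reaches_training_accuracy_one():
    X, y = _separable_toy()
    tree = train_simplified_tree(X, y, max_items=2)
    pred = tree.classify_frame(X)
    assert (pred.values == y.values).all()


def test_max_items_one_uses_single_split_variable():
    X, y = _separable_toy()
    tree = train_simplified_tree(X, y, max_items=1)
    assert len(tree.item_subset) == 1


def test_single_class_input_gives_one_leaf_with_warning():
    X = pd.DataFrame({"f": [1, 2, 3]})
    y = pd.Series(["a", "a", "a"])
    with pytest.warns(UserWarning):
        tree = train_simplified_tree(X, y)
    assert len(tree.nodes) == 1
    assert tree.classify({"f": 5}) == "a"


def test_trained_tree_beats_majority_baseline(small_cohort, liking_matrix):
    truth = small_cohort.true_profile
    n = len(truth)
    tr = np.arange(n) < int(0.7 * n)
    tree = train_simplified_tree(liking_matrix.iloc[tr], truth.iloc[tr],
                                 max_items=14)
    assert len(set(tree.item_subset)) <= 14
    pred = tree.classify_frame(liking_matrix.iloc[~tr])
    acc = (pred.values == truth.iloc[~tr].values).mean()
    baseline = truth.iloc[~tr].value_counts(normalize=True).max()
    assert acc > baseline
    metrics = evaluate_classifier(truth.iloc[~tr], pred)
    for cls in metrics.per_class:
        assert metrics[cls]["f1"] > 0.5


# --- evaluation metrics -------------------------------------------------------

def test_perfect_prediction_scores_one_everywhere():
    y = ["a", "b", "c", "a", "b"]
    m = evaluate_classifier(y, list(y))
    for cls in "abc":
        assert m[cls] == {"sensitivity": 1.0, "specificity": 1.0, "f1": 1.0}


def test_hand_computed_confusion_metrics():
    # class "x": TP=3 FP=1 FN=1 TN=5
    true = ["x"] * 4 + ["y"] * 6
    pred = ["x", "x", "x", "y", "x", "y", "y", "y", "y", "y"]
    m = evaluate_classifier(true, pred)
    assert m["x"]["sensitivity"] == pytest.approx(0.75)
    assert m["x"]["specificity"] == pytest.approx(5 / 6)
    assert m["x"]["f1"] == pytest.approx(0.75)


def test_complement_prediction_has_zero_sensitivity():
    true = ["a", "a", "b", "b"]
    pred = ["b", "b", "a", "a"]
    m = evaluate_classifier(true, pred)
    assert m["a"]["sensitivity"] == 0.0


def test_absent_class_reported_undefined_not_zero():
    m = evaluate_classifier(["a", "a"], ["a", "b"], classes=["a", "b"])
    assert "b" in m.undefined
    assert np.isnan(m["b"]["sensitivity"])


# --- feature importance -------------------------------------------------------

def test_fully_determining_item_ranked_first_by_all_methods():
    rng = np.random.default_rng(4)
    n = 300
    y = rng.integers(0, 2, n)
    X = pd.DataFrame({
        "signal": y * 6.0 + rng.normal(0, 0.3, n),
        "noise1": rng.normal(5, 1, n),
        "noise2": rng.normal(5, 1, n),
    })
    imp = feature_importance(X, pd.Series(y.astype(str)), seed=0)
    for method in ("rf", "lasso", "shapley"):
        assert imp[method].idxmax() == "signal"
    assert imp.index[0] == "signal"


def test_pure_noise_items_have_near_zero_importance():
    rng = np.random.default_rng(5)
    n = 300
    y = rng.integers(0, 2, n)
    X = pd.DataFrame({
        "signal": y * 6.0 + rng.normal(0, 0.3, n),
        "noise": rng.normal(0, 1, n),
    })
    imp = feature_importance(X, pd.Series(y.astype(str)), seed=0)
    assert imp.loc["noise", "rf"] < 0.1 * imp.loc["signal", "rf"]
    assert imp.loc["noise", "shapley"] < 0.2 * imp.loc["signal", "shapley"]


def test_single_feature_gives_ranking_of_length_one():
    rng = np.random.default_rng(6)
    y = rng.integers(0, 2, 60)
    X = pd.DataFrame({"only": y + rng.normal(0, 0.2, 60)})
    imp = feature_importance(X, pd.Series(y.astype(str)), seed=0)
    assert len(imp) == 1
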