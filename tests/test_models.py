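"""Classifier-family contracts: losses, pooling, invariance, recovery."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from cariescolor.models import (TrainingPolicy, attention_pool,
                                collapse_to_binary, default_policies,
                                focal_loss, inverse_frequency_weights,
                                predict_tooth, train_model, _site_blocks)


# ---------------------------------------------------------------------------
# class weights and focal loss

def test_inverse_frequency_weights_table_counts():
    w = inverse_frequency_weights((40, 181, 79))
    assert w[0] == pytest.approx(300 / (3 * 40))  # sound weight 2.5
    assert w[0] == pytest.approx(2.5)
    # count-weighted mean is 1
    counts = np.array([40, 181, 79])
    assert (w * counts).sum() / counts.sum() == pytest.approx(1.0)


def test_inverse_frequency_weights_balanced_and_invalid():
    assert inverse_frequency_weights((10, 10, 10)) == pytest.approx([1, 1, 1])
    with pytest.raises(ValueError):
        inverse_frequency_weights((0, 5, 5))


@pytest.mark.parametrize(
    "probs,y,gamma,expected",
    [
        ((1.0, 0.0, 0.0), 0, 2.0, 0.0),
        ((0.5, 0.3, 0.2), 0, 0.0, math.log(2)),
        ((0.5, 0.3, 0.2), 0, 2.0, 0.25 * math.log(2)),
    ],
)
def test_focal_loss_oracle(probs, y, gamma, expected):
    assert focal_loss(probs, y, gamma) == pytest.approx(expected, abs=1e-12)


def test_focal_loss_properties(rng):
    # non-negative; decreasing in p_y; gamma shrinks well-classified loss
    for _ in range(50):
        p = rng.dirichlet(np.ones(3))
        y = int(rng.integers(3))
        g = float(rng.uniform(0, 4))
        assert focal_loss(p, y, g) >= 0
    grid = np.linspace(0.05, 0.95, 19)
    losses = [focal_loss((py, (1 - py) / 2, (1 - py) / 2), 0, 2.0)
              for py in grid]
    assert all(a > b for a, b in zip(losses, losses[1:]))
    well = (0.8, 0.1, 0.1)
    assert focal_loss(well, 0, 2.0) < focal_loss(well, 0, 0.0)


def test_focal_loss_zero_probability_floored():
    loss = focal_loss((0.0, 1.0, 0.0), 0, 2.0)
    assert np.isfinite(loss) and loss > 0


# ---------------------------------------------------------------------------
# attention pooling

def test_attention_pool_shared_embedding_is_identity(rng):
    e = rng.normal(size=4)
    H = np.tile(e, (5, 1))
    out = attention_pool(H, score_vector=rng.normal(size=4))
    assert out == pytest.approx(e)


def test_attention_pool_zero_scores_is_mean(rng):
    H = rng.normal(size=(2, 3))
    assert attention_pool(H) == pytest.approx(H.mean(axis=0))


def test_attention_pool_permutation_invariant(rng):
    H = rng.normal(size=(5, 6))
    v = rng.normal(size=6)
    base = attention_pool(H, v, 0.3)
    for perm in itertools.permutations(range(5)):
        assert attention_pool(H[list(perm)], v, 0.3) == pytest.approx(base)


def test_attention_pool_empty_rejected():
    with pytest.raises(ValueError):
        attention_pool(np.empty((0, 3)))


# ---------------------------------------------------------------------------
# binary collapse

def test_collapse_to_binary_components():
    p = (0.2, 0.5, 0.3)
    assert collapse_to_binary(p, "operative") == pytest.approx(0.3)
    assert collapse_to_binary(p, "early") == pytest.approx(0.8)
    assert collapse_to_binary(p, "early") + p[0] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        collapse_to_binary(p, "bogus")


def test_collapse_to_binary_dataframe(default_run):
    P = default_run.test_predictions["mlp"]
    early = collapse_to_binary(P, "early")
    assert np.allclose(early, 1.0 - P["sound"])


# ---------------------------------------------------------------------------
# training contracts

def test_policy_validation():
    with pytest.raises(ValueError):
        TrainingPolicy(model_family="svm")
    with pytest.raises(ValueError):
        TrainingPolicy(model_family="mlp", focal_gamma=-1)
    with pytest.raises(ValueError):
        TrainingPolicy(model_family="deep_sets", input_mode="site")


def test_all_predictions_are_simplexes(separable_run):
    for P in separable_run.test_predictions.values():
        arr = P.to_numpy()
        assert (arr >= 0).all()
        assert np.allclose(arr.sum(axis=1), 1.0, atol=1e-6)


def test_training_ba_is_perfect_on_separable_cohort(separable_run):
    from cariescolor.evaluation import balanced_accuracy, confusion_matrix

    train_ids = separable_run.split.train_ids
    y = separable_run.labels.loc[train_ids].to_numpy()
    for fam, model in separable_run.models.items():
        P = predict_tooth(model, separable_run.features.loc[train_ids])
        ba = balanced_accuracy(confusion_matrix(y, P.to_numpy().argmax(1), 3))
        assert ba == pytest.approx(1.0), fam


def test_determinism_same_seed_same_predictions(separable_run):
    policies = default_policies(seed=42)
    for fam in ("random_forest", "xgboost", "lightgbm", "mlp", "deep_sets"):
        again = train_model(
            separable_run.features, separable_run.labels,
            separable_run.split, policies[fam],
        )
        P1 = separable_run.test_predictions[fam].to_numpy()
        P2 = predict_tooth(
            again, separable_run.features.loc[separable_run.split.test_ids]
        ).to_numpy()
        assert np.array_equal(P1, P2), fam


def test_deep_sets_site_permutation_invariance(default_run):
    """Deep Sets logits identical under every one of the 120 orderings of
    a tooth's five site blocks."""
    model = default_run.models["deep_sets"]
    features = default_run.features.loc[default_run.split.test_ids[:1]]
    X = model.scaler.transform(_site_blocks(features))
    base = model.estimator.predict_logits(X)
    for perm in itertools.permutations(range(5)):
        out = model.estimator.predict_logits(X[:, list(perm), :])
        assert np.max(np.abs(out - base)) < 1e-6


def test_duplicated_tooth_rows_get_identical_outputs(default_run):
    F = default_run.features.loc[default_run.split.test_ids[:3]]
    doubled = pd.concat([F, F])
    for fam, model in default_run.models.items():
        P = predict_tooth(model, doubled).to_numpy()
        # batched BLAS kernels may differ in the last ulp between batch sizes
        assert np.allclose(P[:3], P[3:], rtol=0, atol=1e-12), fam


def test_unseen_feature_schema_rejected(default_run):
    F = default_run.features.iloc[:5, :10]
    with pytest.raises(ValueError, match="schema"):
        predict_tooth(default_run.models["mlp"], F)


def test_labels_missing_test_teeth_train_identically(default_run):
    """The leakage audit: training reads only train/validation labels, so
    removing the test labels changes nothing."""
    split = default_run.split
    censored = default_run.labels.drop(index=split.test_ids)
    policy = default_policies(seed=42)["deep_sets"]
    model = train_model(default_run.features, censored, split, policy)
    P1 = default_run.test_predictions["deep_sets"].to_numpy()
    P2 = predict_tooth(
        model, default_run.features.loc[split.test_ids]
    ).to_numpy()
    assert np.array_equal(P1, P2)


def test_test_tooth_in_training_input_is_rejected(default_run):
    from cariescolor.models import _leakage_guard

    split = default_run.split
    with pytest.raises(ValueError, match="leakage"):
        _leakage_guard(split, [split.test_ids[0]])
    _leakage_guard(split, split.train_ids)  # clean input passes


def test_site_input_mode_trains_and_averages(default_run):
    policy = TrainingPolicy(model_family="random_forest", input_mode="site",
                            n_estimators=100, seed=42)
    model = train_model(default_run.features, default_run.labels,
                        default_run.split, policy)
    P = predict_tooth(
        model, default_run.features.loc[default_run.split.test_ids]
    )
    arr = P.to_numpy()
    assert arr.shape == (30, 3)
    assert np.allclose(arr.sum(axis=1), 1.0, atol=1e-6)
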