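"""Evaluation metrics against enumeration and simulation oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cariescolor.evaluation import (BootstrapCI, balanced_accuracy,
                                    clustered_bootstrap_ci, confusion_matrix,
                                    delong_test, evaluate, holm_adjust,
                                    macro_f1, mcnemar_test, roc_auc,
                                    sens_spec_per_class,
                                    wilcoxon_signed_rank, add_delta_auc)
from cariescolor.records import CATEGORIES


# ---------------------------------------------------------------------------
# confusion matrix and derived metrics

def test_confusion_matrix_hand_count():
    cm = confusion_matrix([0, 0, 1, 2], [0, 1, 1, 2], 3)
    expected = np.array([[1, 1, 0], [0, 1, 0], [0, 0, 1]])
    assert np.array_equal(cm, expected)
    assert cm.sum() == 4


def test_confusion_matrix_rejects_out_of_range():
    with pytest.raises(ValueError):
        confusion_matrix([0, 3], [0, 1], 3)


def test_balanced_accuracy_oracles():
    assert balanced_accuracy(np.diag([5, 2, 9])) == 1.0
    # all predictions to one class over balanced truths
    cm = np.array([[4, 0, 0], [4, 0, 0], [4, 0, 0]])
    assert balanced_accuracy(cm) == pytest.approx(1 / 3)
    # recalls (1.0, 0.5, 0.75)
    cm = np.array([[4, 0, 0], [1, 2, 1], [0, 1, 3]])
    assert balanced_accuracy(cm) == pytest.approx(0.75)
    with pytest.raises(ValueError):
        balanced_accuracy(np.array([[2, 0], [0, 0]]))


def test_macro_f1_oracles():
    assert macro_f1(np.diag([3, 3, 3])) == 1.0
    cm = np.array([[8, 2], [1, 9]])
    assert macro_f1(cm) == pytest.approx((16 / 19 + 18 / 21) / 2)
    # a class never predicted drags the mean through F1 = 0
    cm = np.array([[5, 0], [5, 0]])
    assert macro_f1(cm) == pytest.approx(0.5 * (10 / 15))


def test_metrics_agree_with_sklearn(rng):
    from sklearn.metrics import balanced_accuracy_score, f1_score

    for _ in range(20):
        y_true = rng.integers(0, 3, size=60)
        y_pred = rng.integers(0, 3, size=60)
        if len(np.unique(y_true)) < 3:
            continue
        cm = confusion_matrix(y_true, y_pred, 3)
        assert balanced_accuracy(cm) == pytest.approx(
            balanced_accuracy_score(y_true, y_pred)
        )
        assert macro_f1(cm) == pytest.approx(
            f1_score(y_true, y_pred, average="macro", zero_division=0)
        )


def test_sens_spec_oracles():
    cm = np.diag([4, 4])
    assert sens_spec_per_class(cm, 0) == pytest.approx((1.0, 1.0))
    cm = np.array([[3, 1], [2, 4]])
    assert sens_spec_per_class(cm, 0) == pytest.approx((0.75, 2 / 3))
    cm = np.array([[0, 4], [0, 6]])  # class 0 never predicted
    assert sens_spec_per_class(cm, 0)[0] == 0.0


# ---------------------------------------------------------------------------
# ROC AUC vs brute-force pair counting

def _auc_bruteforce(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_roc_auc_oracles():
    assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
    assert roc_auc([0.5] * 6, [0, 0, 0, 1, 1, 1]) == 0.5
    assert roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)
    with pytest.raises(ValueError):
        roc_auc([0.1, 0.2], [1, 1])


def test_roc_auc_equals_pair_counting_on_random_inputs(rng):
    """Midrank AUC equals the fraction of correctly ordered pairs
    (ties counting one half) on inputs up to 50 teeth."""
    for _ in range(100):
        n = int(rng.integers(4, 51))
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            continue
        # discretized scores force ties
        scores = np.round(rng.random(n), 1)
        assert roc_auc(scores, labels) == pytest.approx(
            _auc_bruteforce(scores, labels), abs=1e-12
        )


# ---------------------------------------------------------------------------
# clustered bootstrap

def test_bootstrap_constant_metric_zero_width():
    frame = pd.DataFrame({"x": np.arange(10)})
    ci = clustered_bootstrap_ci(lambda f: 1.0, frame, B=100, seed=0)
    assert ci.lower == ci.upper == ci.point == 1.0


def test_bootstrap_seed_reproducibility(rng):
    frame = pd.DataFrame({"x": rng.normal(size=25)})
    fn = lambda f: float(f["x"].mean())
    a = clustered_bootstrap_ci(fn, frame, B=200, seed=5)
    b = clustered_bootstrap_ci(fn, frame, B=200, seed=5)
    assert (a.lower, a.upper) == (b.lower, b.upper)


def test_bootstrap_skips_undefined_resamples():
    frame = pd.DataFrame({"x": [0.0] * 19 + [1.0]})

    def fragile(f):
        if f["x"].max() == 0:
            raise ValueError("class absent")
        return float(f["x"].mean())

    ci = clustered_bootstrap_ci(fragile, frame, B=300, seed=2)
    assert ci.n_skipped > 0
    assert ci.lower <= ci.upper


def test_bootstrap_unstable_metric_fails():
    frame = pd.DataFrame({"x": np.arange(6)})

    def needs_every_cluster(f):
        # defined on the full frame, almost never on a resample
        if f["x"].nunique() < 6:
            raise ValueError("cluster missing")
        return float(f["x"].mean())

    with pytest.raises(ValueError, match="unstable"):
        clustered_bootstrap_ci(needs_every_cluster, frame, B=50, seed=0)


def test_bootstrap_ci_invariants():
    with pytest.raises(ValueError):
        BootstrapCI(point=0.5, lower=0.6, upper=0.4, n_iterations=10)
    with pytest.raises(ValueError):
        BootstrapCI(point=0.5, lower=0.4, upper=0.6, n_iterations=0)


# ---------------------------------------------------------------------------
# paired tests vs enumeration oracles

def test_mcnemar_oracles():
    a = np.array([True, False, True, True])
    assert mcnemar_test(a, a) == 1.0
    # discordant (10, 2): exact binomial two-sided at n = 12
    correct_a = np.concatenate([np.ones(10, bool), np.zeros(2, bool),
                                np.ones(20, bool)])
    correct_b = np.concatenate([np.zeros(10, bool), np.ones(2, bool),
                                np.ones(20, bool)])
    expected = 2 * sum(
        stats.binom.pmf(k, 12, 0.5) for k in range(3)
    )
    assert mcnemar_test(correct_a, correct_b) == pytest.approx(expected)
    assert mcnemar_test(correct_a, correct_b) == pytest.approx(0.0386, abs=5e-4)


def test_mcnemar_bounds(rng):
    for _ in range(20):
        a = rng.integers(0, 2, 30).astype(bool)
        b = rng.integers(0, 2, 30).astype(bool)
        p = mcnemar_test(a, b)
        assert 0.0 < p <= 1.0


def test_wilcoxon_exact_enumeration():
    a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    b = a - np.array([0.5, 0.4, 0.3, 0.2, 0.1])  # all positive diffs
    assert wilcoxon_signed_rank(a, b) == pytest.approx(2 / 2**5)
    # antisymmetry
    assert wilcoxon_signed_rank(b, a) == pytest.approx(
        wilcoxon_signed_rank(a, b)
    )
    with pytest.raises(ValueError):
        wilcoxon_signed_rank(a, a)


def test_wilcoxon_large_sample_normal_approximation(rng):
    a = rng.normal(0.3, 1.0, size=60)
    b = rng.normal(0.0, 1.0, size=60)
    p = wilcoxon_signed_rank(a, b)
    ref = stats.wilcoxon(a - b, method="approx", correction=True).pvalue
    assert p == pytest.approx(ref)
    assert 0.0 < p <= 1.0


def test_holm_oracles():
    assert holm_adjust([0.04]) == pytest.approx([0.04])
    adj = holm_adjust([0.01, 0.04, 0.03])
    assert adj == pytest.approx([0.03, 0.06, 0.06])
    raw = np.array([0.2, 0.01, 0.6, 0.04])
    assert np.all(holm_adjust(raw) >= raw)


def test_delong_identical_scores():
    y = np.array([0, 1] * 10)
    s = np.linspace(0, 1, 20)
    delta, p = delong_test(s, s, y)
    assert delta == 0.0
    assert p == 1.0


def test_delong_auc_matches_roc_auc(rng):
    y = rng.integers(0, 2, size=40)
    y[:2] = [0, 1]
    sa, sb = rng.random(40), rng.random(40)
    delta, _ = delong_test(sa, sb, y)
    assert delta == pytest.approx(roc_auc(sa, y) - roc_auc(sb, y), abs=1e-12)


def test_delong_matches_independent_reference_values():
    """Frozen oracle: DeLong p for this fixture computed independently
    with R's pROC (roc.test, method='delong', paired)."""
    rng = np.random.default_rng(23)
    n = 40
    y = np.array([0] * 22 + [1] * 18)
    latent = rng.normal(size=n) + 1.1 * y
    sa = latent + rng.normal(0, 0.5, n)
    sb = latent + rng.normal(0, 2.0, n)
    delta, p = delong_test(sa, sb, y)
    assert delta == pytest.approx(0.06060606, abs=1e-8)
    assert p == pytest.approx(0.3097576, abs=1e-6)


def test_delong_agrees_with_permutation_oracle():
    """DeLong p within 0.02 of a 2000-rep paired-permutation p on a
    40-tooth fixture."""
    rng = np.random.default_rng(11)
    n = 40
    y = np.array([0] * 22 + [1] * 18)
    sa = 1.6 * y + rng.normal(0, 1.0, n)
    sb = 0.3 * sa + rng.normal(0, 1.0, n)
    delta_obs, p_delong = delong_test(sa, sb, y)
    reps = 2000
    count = 0
    for _ in range(reps):
        swap = rng.integers(0, 2, size=n).astype(bool)
        pa = np.where(swap, sb, sa)
        pb = np.where(swap, sa, sb)
        d, _ = delong_test(pa, pb, y)
        count += abs(d) >= abs(delta_obs) - 1e-12
    p_perm = count / reps
    assert p_delong == pytest.approx(p_perm, abs=0.02)


# ---------------------------------------------------------------------------
# full report

def _perfect_frame():
    y = np.array([0] * 2 + [1] * 3 + [2] * 2)
    P = np.full((len(y), 3), 0.05)
    P[np.arange(len(y)), y] = 0.9
    probs = pd.DataFrame(P, columns=list(CATEGORIES),
                         index=[f"T{i}" for i in range(len(y))])
    labels = pd.Series(y, index=probs.index)
    return probs, labels


def test_evaluate_perfect_predictions():
    probs, labels = _perfect_frame()
    report = evaluate(probs, labels, B=50, seed=0)
    assert report.multiclass["accuracy"].point == 1.0
    assert report.multiclass["balanced_accuracy"].point == 1.0
    assert report.multiclass["macro_f1"].point == 1.0
    for cat in CATEGORIES:
        assert report.auc_ovr[cat].point == 1.0
    for contrast in ("early", "operative"):
        assert report.contrasts[contrast]["auc"].point == 1.0


def test_evaluate_six_tooth_hand_fixture():
    """Hand-computed metrics on a printed 6-tooth fixture."""
    probs = pd.DataFrame(
        [
            [0.7, 0.2, 0.1],   # true 0, pred 0
            [0.2, 0.6, 0.2],   # true 0, pred 1  (FP for early)
            [0.1, 0.8, 0.1],   # true 1, pred 1
            [0.5, 0.3, 0.2],   # true 1, pred 0
            [0.1, 0.3, 0.6],   # true 2, pred 2
            [0.2, 0.5, 0.3],   # true 2, pred 1
        ],
        columns=list(CATEGORIES),
        index=[f"T{i}" for i in range(6)],
    )
    labels = pd.Series([0, 0, 1, 1, 2, 2], index=probs.index)
    report = evaluate(probs, labels, B=20, seed=0)
    # accuracy 3/6; recalls all 1/2 -> BA 1/2
    assert report.multiclass["accuracy"].point == pytest.approx(0.5)
    assert report.multiclass["balanced_accuracy"].point == pytest.approx(0.5)
    # per-class F1: all 0.5 here (each class: TP1 FN1, FP1 except cls2 FP... )
    cm = confusion_matrix(labels, probs.to_numpy().argmax(1), 3)
    assert np.array_equal(cm, np.array([[1, 1, 0], [1, 1, 0], [0, 1, 1]]))
    f1_0 = 2 * 1 / (2 * 1 + 1 + 1)
    f1_1 = 2 * 1 / (2 * 1 + 2 + 1)
    f1_2 = 2 * 1 / (2 * 1 + 0 + 1)
    assert report.multiclass["macro_f1"].point == pytest.approx(
        (f1_0 + f1_1 + f1_2) / 3
    )
    # early contrast at 0.5: scores 1-p(sound)
    early_scores = 1 - probs["sound"].to_numpy()
    y_early = np.array([0, 0, 1, 1, 1, 1])
    se = np.mean((early_scores > 0.5)[y_early == 1])
    sp = np.mean(~(early_scores > 0.5)[y_early == 0])
    assert report.contrasts["early"]["sensitivity"].point == pytest.approx(se)
    assert report.contrasts["early"]["specificity"].point == pytest.approx(sp)
    assert report.contrasts["early"]["auc"].point == pytest.approx(
        _auc_bruteforce(early_scores, y_early)
    )


def test_binary_se_consistent_with_collapsed_confusion_matrix(default_run):
    """Early-contrast SE from collapsed probabilities equals SE from a
    direct 2-class confusion matrix of the collapsed labels."""
    from cariescolor.models import collapse_labels, collapse_to_binary

    P = default_run.test_predictions["deep_sets"]
    y = default_run.test_labels()
    report = evaluate(P, default_run.labels, split=default_run.split,
                      B=20, seed=0)
    score = collapse_to_binary(P.to_numpy(), "early")
    y_bin = collapse_labels(y, "early")
    pred = (score > 0.5).astype(int)
    cm2 = confusion_matrix(y_bin, pred, 2)
    se_direct, _ = sens_spec_per_class(cm2, 1)
    assert report.contrasts["early"]["sensitivity"].point == \
        pytest.approx(se_direct)


def test_evaluate_rejects_non_test_teeth(default_run):
    F = default_run.features.loc[default_run.split.train_ids[:5]]
    P = default_run.models["mlp"].predict_proba(F)
    with pytest.raises(ValueError, match="leakage"):
        evaluate(P, default_run.labels, split=default_run.split, B=10)


def test_report_invariant_to_tooth_ordering():
    probs, labels = _perfect_frame()
    shuffled = probs.sample(frac=1.0, random_state=3)
    r1 = evaluate(probs, labels, B=50, seed=1)
    r2 = evaluate(shuffled, labels, B=50, seed=1)
    assert r1.multiclass["accuracy"].point == r2.multiclass["accuracy"].point
    assert r1.macro_auc.point == pytest.approx(r2.macro_auc.point)


def test_delta_auc_vs_best():
    probs, labels = _perfect_frame()
    good = evaluate(probs, labels, B=20, seed=0)
    noisy = probs.copy()
    noisy.iloc[0] = [0.1, 0.6, 0.3]  # degrade one sound tooth
    worse = evaluate(noisy, labels, B=20, seed=0)
    reports = add_delta_auc({"good": good, "worse": worse})
    for contrast in ("early", "operative"):
        assert reports["good"].delta_auc[contrast] == 0.0
        assert reports["worse"].delta_auc[contrast] <= 0.0


def test_balanced_accuracy_equals_accuracy_when_balanced_and_symmetric():
    # balanced truths, class-symmetric confusion
    cm = np.array([[6, 1, 1], [1, 6, 1], [1, 1, 6]])
    assert balanced_accuracy(cm) == pytest.approx(6 / 8)
    assert balanced_accuracy(cm) == pytest.approx(np.trace(cm) / cm.sum())
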