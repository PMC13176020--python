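"""Tooth-level evaluation: metrics, clustered bootstrap, paired tests.

The tooth is the unit of analysis throughout — its five site readings
are repeated measurements, so confidence intervals come from a
clustered bootstrap that resamples whole teeth with replacement.
Reported metrics are multiclass accuracy, balanced accuracy (the
primary metric under class imbalance), macro-F1, per-class
sensitivity/specificity, one-vs-rest AUCs, and the two clinical binary
contrasts (early: ICDAS 1-4 vs 0; operative: ICDAS 3-4 vs 0-2) with
sensitivity/specificity at a 0.5 operating point plus threshold-free
AUC.  Paired model comparisons use McNemar's exact test (accuracy),
DeLong's test with Holm correction (AUC), and the Wilcoxon signed-rank
test (paired metrics).

Percentile (not BCa) bootstrap intervals are used; under heavy class
imbalance a percentile CI can exclude the point estimate, which is
expected behaviour and not asserted against.  Resamples on which a
metric is undefined (e.g. a class absent after resampling) are skipped
and counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as _skm
from statsmodels.stats.multitest import multipletests

from .models import collapse_labels, collapse_to_binary
from .records import CATEGORIES, CONTRASTS
from .splitting import SplitAssignment

__all__ = [
    "BootstrapCI",
    "MetricReport",
    "confusion_matrix",
    "balanced_accuracy",
    "macro_f1",
    "sens_spec_per_class",
    "roc_auc",
    "clustered_bootstrap_ci",
    "mcnemar_test",
    "delong_test",
    "holm_adjust",
    "wilcoxon_signed_rank",
    "evaluate",
    "add_delta_auc",
]


# ---------------------------------------------------------------------------
# point metrics

def confusion_matrix(y_true, y_pred, n_classes: int) -> np.ndarray:
    """K x K counts: entry (i, j) = number of true i predicted j."""
    yt = np.asarray(y_true, dtype=int)
    yp = np.asarray(y_pred, dtype=int)
    if yt.shape != yp.shape:
        raise ValueError("y_true and y_pred must be aligned")
    for name, y in (("y_true", yt), ("y_pred", yp)):
        if y.size and (y.min() < 0 or y.max() >= n_classes):
            raise ValueError(f"{name} contains labels outside [0, {n_classes})")
    return _skm.confusion_matrix(yt, yp, labels=range(n_classes))


def balanced_accuracy(cm: np.ndarray) -> float:
    """Unweighted mean of per-class recall, from a confusion matrix."""
    cm = np.asarray(cm, dtype=float)
    support = cm.sum(axis=1)
    if np.any(support == 0):
        raise ValueError("balanced accuracy undefined: a true class is empty")
    return float(np.mean(np.diag(cm) / support))


def macro_f1(cm: np.ndarray) -> float:
    """Unweighted mean of per-class F1.

    A class with zero predicted and zero true positives contributes
    F1 = 0 (the conventional pessimistic treatment).
    """
    cm = np.asarray(cm, dtype=float)
    support = cm.sum(axis=1)
    if np.any(support == 0):
        raise ValueError("macro F1 undefined: a true class is empty")
    tp = np.diag(cm)
    fp = cm.sum(axis=0) - tp
    fn = support - tp
    denom = 2 * tp + fp + fn
    f1 = np.where(denom > 0, 2 * tp / np.where(denom > 0, denom, 1.0), 0.0)
    return float(f1.mean())


def accuracy(cm: np.ndarray) -> float:
    cm = np.asarray(cm, dtype=float)
    return float(np.trace(cm) / cm.sum())


def sens_spec_per_class(cm: np.ndarray, cls: int) -> tuple[float, float]:
    """One-vs-rest (sensitivity, specificity) for one class."""
    cm = np.asarray(cm, dtype=float)
    tp = cm[cls, cls]
    fn = cm[cls].sum() - tp
    fp = cm[:, cls].sum() - tp
    tn = cm.sum() - tp - fn - fp
    se = tp / (tp + fn) if tp + fn > 0 else np.nan
    sp = tn / (tn + fp) if tn + fp > 0 else np.nan
    return float(se), float(sp)


def roc_auc(scores, binary_labels) -> float:
    """Trapezoidal AUC with midrank tie handling (= normalized
    Mann-Whitney U)."""
    y = np.asarray(binary_labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("roc_auc undefined: both classes must be present")
    return float(_skm.roc_auc_score(y, np.asarray(scores, dtype=float)))


# ---------------------------------------------------------------------------
# clustered bootstrap

@dataclass(frozen=True)
class BootstrapCI:
    """Percentile bootstrap CI from tooth-level (cluster) resampling."""

    point: float
    lower: float
    upper: float
    n_iterations: int
    n_skipped: int = 0
    resampling_unit: str = "tooth"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.lower > self.upper:
            raise ValueError("lower CI bound exceeds upper")

    def to_dict(self) -> dict:
        return {
            "point": self.point,
            "lower": self.lower,
            "upper": self.upper,
            "n_iterations": self.n_iterations,
            "n_skipped": self.n_skipped,
        }


def clustered_bootstrap_ci(
    metric_fn: Callable[[pd.DataFrame], float],
    tooth_frame: pd.DataFrame,
    B: int = 1000,
    seed: int = 42,
    alpha: float = 0.05,
) -> BootstrapCI:
    """Percentile CI by resampling whole teeth (clusters) with replacement.

    ``tooth_frame`` holds one row per tooth; ``metric_fn`` maps such a
    frame to a scalar.  Resamples on which the metric is undefined
    (``metric_fn`` raises ValueError or returns NaN, e.g. a class
    absent) are skipped and counted; more than 50% skips aborts — the
    metric is unstable at this sample size.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if len(tooth_frame) < 2:
        raise ValueError("clustered bootstrap needs >= 2 teeth")
    point = float(metric_fn(tooth_frame))
    rng = np.random.default_rng(seed)
    n = len(tooth_frame)
    values = []
    skipped = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        sub = tooth_frame.iloc[idx]
        try:
            v = float(metric_fn(sub))
        except ValueError:
            skipped += 1
            continue
        if np.isnan(v):
            skipped += 1
            continue
        values.append(v)
    if skipped > B / 2:
        raise ValueError(
            f"metric undefined on {skipped}/{B} resamples; unstable at n={n}"
        )
    lower, upper = np.percentile(values, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return BootstrapCI(
        point=point,
        lower=float(lower),
        upper=float(upper),
        n_iterations=B,
        n_skipped=skipped,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# paired significance tests

def mcnemar_test(correct_a, correct_b) -> float:
    """Exact two-sided binomial McNemar test on discordant pairs."""
    a = np.asarray(correct_a, dtype=bool)
    b = np.asarray(correct_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("correctness vectors must be aligned")
    n01 = int(np.sum(a & ~b))
    n10 = int(np.sum(~a & b))
    n = n01 + n10
    if n == 0:
        return 1.0
    p = 2.0 * stats.binom.cdf(min(n01, n10), n, 0.5)
    return float(min(p, 1.0))


def _delong_placements(scores: np.ndarray, y: np.ndarray):
    """Midrank placement values V10 (positives) and V01 (negatives)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    all_ranks = stats.rankdata(np.concatenate([pos, neg]))
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    return v10, v01


def delong_test(scores_a, scores_b, binary_labels) -> tuple[float, float]:
    """DeLong's test for paired AUC difference.

    Returns (delta_auc = AUC_a - AUC_b, two-sided normal p).  Identical
    placements (zero variance of the difference) give p = 1 by
    convention.
    """
    y = np.asarray(binary_labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("delong_test requires both classes present")
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    if sa.shape != sb.shape or sa.shape != y.shape:
        raise ValueError("scores and labels must be aligned")
    v10a, v01a = _delong_placements(sa, y)
    v10b, v01b = _delong_placements(sb, y)
    auc_a, auc_b = float(v10a.mean()), float(v10b.mean())
    delta = auc_a - auc_b
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]))
    s01 = np.cov(np.vstack([v01a, v01b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 1e-15:
        return delta, 1.0
    z = delta / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return delta, float(min(p, 1.0))


def holm_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Step-down Holm adjustment, monotone and capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def wilcoxon_signed_rank(paired_a, paired_b) -> float:
    """Two-sided Wilcoxon signed-rank p for paired samples.

    Zero differences are dropped; exact distribution for <= 25 nonzero
    untied pairs, normal approximation with tie/continuity correction
    otherwise.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all paired differences are zero")
    exact = d.size <= 25 and len(np.unique(np.abs(d))) == d.size
    res = stats.wilcoxon(
        d, method="exact" if exact else "approx", correction=not exact
    )
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# full report

@dataclass
class MetricReport:
    """Full tooth-level evaluation of one model on the test set."""

    n_teeth: int
    multiclass: dict[str, BootstrapCI]
    per_class: dict[str, dict[str, float]]
    auc_ovr: dict[str, BootstrapCI]
    macro_auc: BootstrapCI
    contrasts: dict[str, dict[str, BootstrapCI]]
    delta_auc: dict[str, float] = field(default_factory=dict)
    threshold: float = 0.5

    def to_dict(self) -> dict:
        return {
            "n_teeth": self.n_teeth,
            "threshold": self.threshold,
            "multiclass": {k: v.to_dict() for k, v in self.multiclass.items()},
            "per_class": self.per_class,
            "auc_ovr": {k: v.to_dict() for k, v in self.auc_ovr.items()},
            "macro_auc": self.macro_auc.to_dict(),
            "contrasts": {
                c: {k: v.to_dict() for k, v in d.items()}
                for c, d in self.contrasts.items()
            },
            "delta_auc": self.delta_auc,
        }


def _tooth_frame(probs: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    frame = probs[list(CATEGORIES)].copy()
    frame["y_true"] = labels.reindex(probs.index).to_numpy()
    if frame["y_true"].isna().any():
        raise ValueError("labels missing for some predicted teeth")
    if frame["y_true"].dtype == object:
        frame["y_true"] = frame["y_true"].map(
            {c: i for i, c in enumerate(CATEGORIES)}
        )
    frame["y_true"] = frame["y_true"].astype(int)
    frame["y_pred"] = frame[list(CATEGORIES)].to_numpy().argmax(axis=1)
    return frame


def _cm(frame: pd.DataFrame) -> np.ndarray:
    return confusion_matrix(frame["y_true"], frame["y_pred"], len(CATEGORIES))


def evaluate(
    predictions: pd.DataFrame,
    labels: pd.Series,
    split: SplitAssignment | None = None,
    contrasts: Sequence[str] = CONTRASTS,
    B: int = 1000,
    seed: int = 42,
    threshold: float = 0.5,
) -> MetricReport:
    """Evaluate tooth-level predictions on the independent test set.

    ``predictions`` is the (n, 3) probability table indexed by
    tooth_id.  If ``split`` is given, every predicted tooth must belong
    to its test partition (leakage guard).  All metrics carry clustered
    bootstrap CIs (B iterations, seeded).  Binary-contrast SE/SP use
    the ``threshold`` operating point on the collapsed probability; AUC
    is threshold-free.
    """
    if split is not None:
        non_test = [
            t for t in predictions.index
            if split.assignment.get(t) != "test"
        ]
        if non_test:
            raise ValueError(
                f"leakage: non-test teeth in evaluation input: {non_test[:5]}"
            )
    frame = _tooth_frame(predictions, labels)

    def ci(fn) -> BootstrapCI:
        return clustered_bootstrap_ci(fn, frame, B=B, seed=seed)

    multiclass = {
        "accuracy": ci(lambda f: accuracy(_cm(f))),
        "balanced_accuracy": ci(lambda f: balanced_accuracy(_cm(f))),
        "macro_f1": ci(lambda f: macro_f1(_cm(f))),
    }

    cm = _cm(frame)
    per_class = {}
    for k, cat in enumerate(CATEGORIES):
        se, sp = sens_spec_per_class(cm, k)
        per_class[cat] = {"sensitivity": se, "specificity": sp}

    def ovr_auc(f: pd.DataFrame, k: int) -> float:
        return roc_auc(f[CATEGORIES[k]], (f["y_true"] == k).astype(int))

    auc_ovr = {
        cat: ci(lambda f, k=k: ovr_auc(f, k)) for k, cat in enumerate(CATEGORIES)
    }
    macro_auc = ci(
        lambda f: float(np.mean([ovr_auc(f, k) for k in range(len(CATEGORIES))]))
    )

    contrast_reports: dict[str, dict[str, BootstrapCI]] = {}
    for contrast in contrasts:
        def c_parts(f: pd.DataFrame):
            score = collapse_to_binary(
                f[list(CATEGORIES)].to_numpy(dtype=float), contrast
            )
            y_bin = collapse_labels(f["y_true"].to_numpy(), contrast)
            pred = (score > threshold).astype(int)
            return score, y_bin, pred

        def c_se(f):
            _, y_bin, pred = c_parts(f)
            if not np.any(y_bin == 1):
                raise ValueError("no positives in resample")
            return float(np.mean(pred[y_bin == 1]))

        def c_sp(f):
            _, y_bin, pred = c_parts(f)
            if not np.any(y_bin == 0):
                raise ValueError("no negatives in resample")
            return float(np.mean(1 - pred[y_bin == 0]))

        def c_ba(f):
            return (c_se(f) + c_sp(f)) / 2.0

        def c_auc(f):
            score, y_bin, _ = c_parts(f)
            return roc_auc(score, y_bin)

        contrast_reports[contrast] = {
            "sensitivity": ci(c_se),
            "specificity": ci(c_sp),
            "balanced_accuracy": ci(c_ba),
            "auc": ci(c_auc),
        }

    return MetricReport(
        n_teeth=len(frame),
        multiclass=multiclass,
        per_class=per_class,
        auc_ovr=auc_ovr,
        macro_auc=macro_auc,
        contrasts=dict(contrast_reports),
        threshold=threshold,
    )


def add_delta_auc(reports: dict[str, MetricReport]) -> dict[str, MetricReport]:
    """Fill each report's per-contrast delta AUC vs the best model.

    delta = model AUC - max AUC over models for that contrast; the best
    model's delta is 0 by construction.
    """
    for contrast in CONTRASTS:
        aucs = {
            name: r.contrasts[contrast]["auc"].point
            for name, r in reports.items()
            if contrast in r.contrasts
        }
        if not aucs:
            continue
        best = max(aucs.values())
        for name, r in reports.items():
            if contrast in r.contrasts:
                r.delta_auc[contrast] = aucs[name] - best
    return reports
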