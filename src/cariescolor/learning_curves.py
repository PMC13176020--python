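"""Training-fraction (learning-curve) experiment harness.

Each model family is retrained on 50%, 75% and 100% of the available
training teeth — subsampled group-stratified per category, seeded —
with identical preprocessing, class weighting and hyperparameters, and
evaluated on the fixed, untouched test set.  The neural validation
subset and the sound-enamel color reference are re-derived inside each
subsample, so no preprocessing ever sees teeth outside that subsample's
training portion.

The reported delta is the change in balanced accuracy relative to the
full-data run, delta = BA(1.00) - BA(fraction); it is exactly 0 at
fraction 1.00.  Subsamples at different fractions are independent (not
nested).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .colorimetry import featurize_cohort, sound_reference
from .evaluation import MetricReport, evaluate
from .models import TrainingPolicy, predict_tooth, train_model
from .records import CATEGORIES, ToothRecord
from .splitting import SplitAssignment, _round_half_up, _stratified_targets

__all__ = ["LearningCurveResult", "run_learning_curve", "results_to_frame"]

DELTA_METRIC = "balanced_accuracy"


@dataclass(frozen=True)
class LearningCurveResult:
    """One (model family, training fraction) cell of the experiment."""

    model_family: str
    fraction: float
    n_train: int
    report: MetricReport
    delta: float  # BA(1.00) - BA(fraction); 0 at fraction 1.00

    @property
    def balanced_accuracy(self) -> float:
        return self.report.multiclass[DELTA_METRIC].point


def _subsample_split(
    teeth_by_cat: dict[str, list[str]],
    test_ids: list[str],
    fraction: float,
    val_frac_of_train: float,
    rng: np.random.Generator,
) -> SplitAssignment:
    """Group-stratified subsample of the training pool at ``fraction``,
    with the validation subset re-derived inside the subsample."""
    assignment: dict[str, str] = {t: "test" for t in test_ids}
    kept_counts: dict[str, int] = {}
    kept_by_cat: dict[str, list[str]] = {}
    for cat in CATEGORIES:
        pool = sorted(teeth_by_cat[cat])
        n_keep = _round_half_up(fraction * len(pool))
        if n_keep < 1:
            raise ValueError(
                f"fraction {fraction} leaves category {cat!r} empty in training"
            )
        order = rng.permutation(len(pool))
        kept = [pool[i] for i in order[:n_keep]]
        kept_by_cat[cat] = kept
        kept_counts[cat] = n_keep
    val_targets = _stratified_targets(kept_counts, val_frac_of_train)
    for cat in CATEGORIES:
        kept = kept_by_cat[cat]
        n_val = min(val_targets[cat], len(kept) - 1)  # keep >= 1 in train
        for t in kept[:n_val]:
            assignment[t] = "validation"
        for t in kept[n_val:]:
            assignment[t] = "train"
    return SplitAssignment(
        assignment=assignment,
        seed=int(rng.integers(0, 2**31 - 1)),
        test_frac=0.0,
        val_frac_of_train=val_frac_of_train,
    )


def run_learning_curve(
    teeth: Iterable[ToothRecord],
    split: SplitAssignment,
    policies: dict[str, TrainingPolicy],
    fractions: Sequence[float] = (0.50, 0.75, 1.00),
    seed: int = 42,
    bootstrap_iterations: int = 1000,
) -> list[LearningCurveResult]:
    """Run the training-fraction experiment for every policy.

    ``fractions`` must lie in (0, 1] and include 1.0 (the full-data
    reference the deltas are computed against).  The test set is the
    fixed test partition of ``split`` for every cell.
    """
    fractions = sorted(set(float(f) for f in fractions))
    if not fractions or any(not 0 < f <= 1 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    if 1.0 not in fractions:
        raise ValueError("fractions must include 1.0 (the full-data reference)")
    teeth = list(teeth)
    by_id = {t.tooth_id: t for t in teeth}
    test_ids = split.test_ids
    pool_by_cat: dict[str, list[str]] = {cat: [] for cat in CATEGORIES}
    for tooth_id, part in split.assignment.items():
        if part != "test":
            pool_by_cat[by_id[tooth_id].category].append(tooth_id)

    labels = pd.Series(
        {t.tooth_id: t.category_index for t in teeth}, name="category"
    )
    test_teeth = [by_id[t] for t in test_ids]

    results: list[LearningCurveResult] = []
    ba_full: dict[str, float] = {}
    for fraction in sorted(fractions, reverse=True):  # 1.0 first, for deltas
        if fraction == 1.0:
            # the full-data cell is the primary run: reuse the split as-is
            sub_split = split
        else:
            sub_rng = np.random.default_rng([seed, int(round(fraction * 100))])
            sub_split = _subsample_split(
                pool_by_cat, test_ids, fraction, split.val_frac_of_train,
                sub_rng,
            )
        sub_train_teeth = [by_id[t] for t in sub_split.train_ids]
        ref = sound_reference(sub_train_teeth)
        model_teeth = (
            sub_train_teeth
            + [by_id[t] for t in sub_split.validation_ids]
            + test_teeth
        )
        features = featurize_cohort(model_teeth, ref)
        for family, policy in policies.items():
            model = train_model(features, labels, sub_split, policy)
            preds = predict_tooth(model, features.loc[test_ids])
            report = evaluate(
                preds,
                labels,
                split=sub_split,
                B=bootstrap_iterations,
                seed=seed,
            )
            ba = report.multiclass[DELTA_METRIC].point
            if fraction == 1.0:
                ba_full[family] = ba
                delta = 0.0
            else:
                delta = ba_full[family] - ba
            results.append(
                LearningCurveResult(
                    model_family=family,
                    fraction=fraction,
                    n_train=len(sub_split.train_ids)
                    + len(sub_split.validation_ids),
                    report=report,
                    delta=delta,
                )
            )
    results.sort(key=lambda r: (r.model_family, r.fraction))
    return results


def results_to_frame(results: Sequence[LearningCurveResult]) -> pd.DataFrame:
    """Flat table: model x fraction x metrics x delta."""
    rows = []
    for r in results:
        mc = r.report.multiclass
        rows.append(
            {
                "model_family": r.model_family,
                "fraction": r.fraction,
                "n_train": r.n_train,
                "accuracy": mc["accuracy"].point,
                "balanced_accuracy": mc["balanced_accuracy"].point,
                "macro_f1": mc["macro_f1"].point,
                "macro_auc": r.report.macro_auc.point,
                "delta": r.delta,
            }
        )
    return pd.DataFrame(rows)
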