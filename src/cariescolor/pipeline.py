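"""End-to-end orchestration: cohort -> features -> models -> reports.

The single entry point :func:`run_pipeline` wires the stages together
exactly as the library modules define them: generate (or accept) a
cohort, group-stratified split, sound-reference + colorimetric
featurization from the training partition only, per-family training,
tooth-level evaluation with clustered-bootstrap CIs, temperature-scaled
calibration for the neural families, and optionally the
training-fraction experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .calibration import CalibrationReport, calibrate_and_report
from .colorimetry import featurize_cohort, sound_reference
from .evaluation import MetricReport, add_delta_auc, evaluate
from .io import RunConfig
from .learning_curves import LearningCurveResult, run_learning_curve
from .models import (FittedModel, default_policies, predict_tooth,
                     train_model)
from .records import ToothRecord
from .splitting import SplitAssignment, group_stratified_split
from .synthetic_data import generate_cohort

__all__ = ["PipelineResult", "run_pipeline"]

_NEURAL = ("mlp", "deep_sets")


@dataclass
class PipelineResult:
    teeth: list[ToothRecord]
    split: SplitAssignment
    features: pd.DataFrame
    labels: pd.Series
    models: dict[str, FittedModel]
    predictions: dict[str, pd.DataFrame]
    reports: dict[str, MetricReport]
    calibration: dict[str, CalibrationReport] = field(default_factory=dict)
    learning_curve: list[LearningCurveResult] = field(default_factory=list)


def run_pipeline(
    config: RunConfig | None = None,
    teeth: list[ToothRecord] | None = None,
    with_learning_curve: bool = False,
) -> PipelineResult:
    """Run the full pipeline under ``config`` (defaults: the study
    conditions — 300 teeth 40/181/79, 90/10 split, seed 42)."""
    config = config or RunConfig()
    if teeth is None:
        teeth = generate_cohort(config.generator)
    split = group_stratified_split(
        teeth,
        test_frac=config.test_frac,
        val_frac_of_train=config.val_frac_of_train,
        seed=config.seed,
    )
    by_id = {t.tooth_id: t for t in teeth}
    ref = sound_reference([by_id[t] for t in split.train_ids])
    features = featurize_cohort(teeth, ref)
    labels = pd.Series(
        {t.tooth_id: t.category_index for t in teeth}, name="category"
    )
    policies = {
        fam: pol
        for fam, pol in default_policies(seed=config.seed).items()
        if fam in config.families
    }
    models: dict[str, FittedModel] = {}
    predictions: dict[str, pd.DataFrame] = {}
    reports: dict[str, MetricReport] = {}
    calibration: dict[str, CalibrationReport] = {}
    test_features = features.loc[split.test_ids]
    for fam, policy in policies.items():
        model = train_model(features, labels, split, policy)
        models[fam] = model
        if fam in _NEURAL and split.validation_ids:
            val_logits = model.predict_logits(
                features.loc[split.validation_ids]
            )
            test_logits = model.predict_logits(test_features)
            calibration[fam] = calibrate_and_report(
                val_logits.to_numpy(),
                labels.loc[split.validation_ids].to_numpy(),
                test_logits.to_numpy(),
                labels.loc[split.test_ids].to_numpy(),
            )
            from .calibration import apply_temperature

            probs = apply_temperature(
                test_logits.to_numpy(), calibration[fam].temperature
            )
            preds = pd.DataFrame(
                probs, index=test_logits.index, columns=test_logits.columns
            )
        else:
            preds = predict_tooth(model, test_features)
        predictions[fam] = preds
        reports[fam] = evaluate(
            preds,
            labels,
            split=split,
            B=config.bootstrap_iterations,
            seed=config.seed,
        )
    add_delta_auc(reports)
    learning_curve: list[LearningCurveResult] = []
    if with_learning_curve:
        learning_curve = run_learning_curve(
            teeth,
            split,
            policies,
            fractions=config.fractions,
            seed=config.seed,
            bootstrap_iterations=config.bootstrap_iterations,
        )
    return PipelineResult(
        teeth=teeth,
        split=split,
        features=features,
        labels=labels,
        models=models,
        predictions=predictions,
        reports=reports,
        calibration=calibration,
        learning_curve=learning_curve,
    )
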