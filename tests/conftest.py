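"""Shared fixtures: cohorts, splits, features and trained models.

Model training is session-scoped so the neural and tree families are
fitted once and reused across test modules.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from cariescolor.colorimetry import featurize_cohort, sound_reference
from cariescolor.models import default_policies, predict_tooth, train_model
from cariescolor.splitting import group_stratified_split
from cariescolor.synthetic_data import (default_config, generate_cohort,
                                        separable_config)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


class CohortRun:
    """A cohort with its split, features, labels and fitted models."""

    def __init__(self, config, families, seed=42):
        self.teeth = generate_cohort(config)
        self.by_id = {t.tooth_id: t for t in self.teeth}
        self.split = group_stratified_split(self.teeth, seed=seed)
        self.ref = sound_reference(
            [self.by_id[i] for i in self.split.train_ids]
        )
        self.features = featurize_cohort(self.teeth, self.ref)
        self.labels = pd.Series(
            {t.tooth_id: t.category_index for t in self.teeth},
            name="category",
        )
        self.models = {}
        self.test_predictions = {}
        policies = default_policies(seed=seed)
        for fam in families:
            model = train_model(self.features, self.labels, self.split,
                                policies[fam])
            self.models[fam] = model
            self.test_predictions[fam] = predict_tooth(
                model, self.features.loc[self.split.test_ids]
            )

    def test_labels(self) -> np.ndarray:
        return self.labels.loc[self.split.test_ids].to_numpy()


@pytest.fixture(scope="session")
def default_run() -> CohortRun:
    """Default study conditions (300 teeth, 40/181/79, seed 42) with the
    two neural families trained."""
    return CohortRun(default_config(), families=("mlp", "deep_sets"))


@pytest.fixture(scope="session")
def separable_run() -> CohortRun:
    """Wide-separation, zero-noise cohort with all five families trained."""
    return CohortRun(
        separable_config(),
        families=("random_forest", "xgboost", "lightgbm", "mlp", "deep_sets"),
    )


@pytest.fixture(scope="session")
def default_cohort(default_run):
    return default_run.teeth


@pytest.fixture(scope="session")
def deepsets_curve(default_run):
    """Deep Sets learning curve on the default cohort (seeded, small
    bootstrap for speed)."""
    from cariescolor.learning_curves import run_learning_curve
    from cariescolor.models import TrainingPolicy

    policies = {"deep_sets": TrainingPolicy(model_family="deep_sets", seed=42)}
    return run_learning_curve(
        default_run.teeth, default_run.split, policies,
        fractions=(0.50, 0.75, 1.00), seed=42, bootstrap_iterations=50,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20261001)
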