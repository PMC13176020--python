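"""The five classifier families and their tooth-level prediction surface.

Three gradient-boosted / bagged tree ensembles (random forest, XGBoost,
LightGBM) consume per-tooth flattened feature vectors with
inverse-frequency class weighting.  Two neural families — an MLP on the
same flattened vectors and a Deep Sets network over the per-site
feature blocks — train with focal loss, dropout, Gaussian input noise,
reduce-on-plateau learning rates and early stopping on the internal
validation set.  All predictions are produced at the tooth level as
probability simplexes over (sound, initial, moderate).

An alternative site-row representation (one row per measurement site,
tooth probabilities averaged over the 5 site rows) is available for the
flattened-input families via ``TrainingPolicy.input_mode = "site"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._nn import DeepSetsNet, MLPNet, Scaler, attention_pool  # noqa: F401
from .colorimetry import SITE_FEATURES, feature_columns
from .records import CATEGORIES, CONTRASTS, SITE_LABELS
from .splitting import SplitAssignment

__all__ = [
    "MODEL_FAMILIES",
    "TrainingPolicy",
    "ClassProbabilities",
    "FittedModel",
    "inverse_frequency_weights",
    "focal_loss",
    "attention_pool",
    "train_model",
    "predict_tooth",
    "collapse_to_binary",
    "default_policies",
]

MODEL_FAMILIES = ("random_forest", "xgboost", "lightgbm", "mlp", "deep_sets")

_NEURAL = ("mlp", "deep_sets")


@dataclass(frozen=True)
class TrainingPolicy:
    """Per-family training configuration.

    ``class_weights=None`` means inverse-frequency weights computed from
    the training-partition category counts.  The neural-only fields
    (``focal_gamma``, ``dropout_rate``, ``gaussian_noise_sd``, learning
    rate schedule, early-stopping patience) are ignored by the tree
    families, which rely on their native regularizers instead.
    """

    model_family: str
    class_weights: tuple[float, float, float] | None = None
    focal_gamma: float = 2.0
    dropout_rate: float = 0.3
    gaussian_noise_sd: float = 0.05
    learning_rate: float = 0.01
    plateau_patience: int = 10
    early_stopping_patience: int = 20
    max_epochs: int = 600
    n_estimators: int = 500
    mlp_hidden: tuple[int, int] = (64, 32)
    deepsets_encoder: tuple[int, int] = (32, 32)
    deepsets_head: int = 32
    input_mode: str = "tooth"  # "tooth" (flattened) or "site" (row-wise)
    seed: int = 42

    def __post_init__(self) -> None:
        if self.model_family not in MODEL_FAMILIES:
            raise ValueError(
                f"unknown model_family {self.model_family!r}; "
                f"expected one of {MODEL_FAMILIES}"
            )
        if self.class_weights is not None:
            if len(self.class_weights) != len(CATEGORIES) or any(
                not math.isfinite(w) or w <= 0 for w in self.class_weights
            ):
                raise ValueError("class_weights must be finite and > 0")
        if self.focal_gamma < 0:
            raise ValueError("focal_gamma must be >= 0")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.gaussian_noise_sd < 0:
            raise ValueError("gaussian_noise_sd must be >= 0")
        if self.input_mode not in ("tooth", "site"):
            raise ValueError("input_mode must be 'tooth' or 'site'")
        if self.input_mode == "site" and self.model_family == "deep_sets":
            raise ValueError("deep_sets consumes site sets natively; "
                             "input_mode applies to the flattened families")


def default_policies(seed: int = 42) -> dict[str, TrainingPolicy]:
    """One default policy per model family."""
    return {fam: TrainingPolicy(model_family=fam, seed=seed)
            for fam in MODEL_FAMILIES}


@dataclass(frozen=True)
class ClassProbabilities:
    """A tooth's predicted probability simplex over the 3 categories."""

    tooth_id: str
    probs: tuple[float, float, float]

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (3,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-6:
            raise ValueError(
                f"probs must be a 3-simplex (>=0, sum 1 within 1e-6), got {self.probs}"
            )


def inverse_frequency_weights(counts: Sequence[int]) -> np.ndarray:
    """Balanced class weights w_k = N / (K n_k).

    Their count-weighted mean is 1, so the total loss scale is
    preserved while under-represented classes contribute more.
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 1):
        raise ValueError("every class count must be >= 1")
    n_total = counts.sum()
    return n_total / (len(counts) * counts)


def focal_loss(
    probs: Sequence[float],
    true_class: int,
    gamma: float,
    weights: Sequence[float] | None = None,
) -> float:
    """Focal loss -w_y (1 - p_y)^gamma log(p_y) for one prediction.

    Down-weights well-classified examples by (1 - p_y)^gamma; gamma = 0
    recovers weighted cross-entropy.  p_y is floored at 1e-12.
    """
    p = np.asarray(probs, dtype=float)
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("probs must form a probability simplex")
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    w = 1.0 if weights is None else float(weights[true_class])
    py = max(float(p[true_class]), 1e-12)
    return -w * (1.0 - py) ** gamma * math.log(py)


def collapse_to_binary(probs, contrast: str):
    """Collapse 3-class probabilities to a binary contrast score.

    ``early``     (ICDAS 1-4 vs 0):   p(initial) + p(moderate)
    ``operative`` (ICDAS 3-4 vs 0-2): p(moderate)

    Accepts a ClassProbabilities, a 3-vector, or an (n, 3) array /
    DataFrame; returns a float or an aligned vector accordingly.
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"contrast must be one of {CONTRASTS}, got {contrast!r}")
    if isinstance(probs, ClassProbabilities):
        p = np.asarray(probs.probs, dtype=float)
        return float(p[1] + p[2]) if contrast == "early" else float(p[2])
    if isinstance(probs, pd.DataFrame):
        arr = probs[list(CATEGORIES)].to_numpy(dtype=float)
        out = arr[:, 1] + arr[:, 2] if contrast == "early" else arr[:, 2]
        return pd.Series(out, index=probs.index, name=contrast)
    arr = np.asarray(probs, dtype=float)
    if arr.ndim == 1:
        return float(arr[1] + arr[2]) if contrast == "early" else float(arr[2])
    return arr[:, 1] + arr[:, 2] if contrast == "early" else arr[:, 2]


def collapse_labels(labels: Sequence[int], contrast: str) -> np.ndarray:
    """Collapse 3-category labels (0/1/2) to the binary contrast."""
    y = np.asarray(labels, dtype=int)
    if contrast == "early":
        return (y >= 1).astype(int)
    if contrast == "operative":
        return (y >= 2).astype(int)
    raise ValueError(f"contrast must be one of {CONTRASTS}, got {contrast!r}")


# ---------------------------------------------------------------------------
# feature-table plumbing

def _check_schema(features: pd.DataFrame) -> None:
    expected = feature_columns()
    if list(features.columns) != expected:
        raise ValueError(
            "feature table schema mismatch: expected the canonical "
            f"{len(expected)} columns produced by featurize_cohort"
        )


def _site_blocks(features: pd.DataFrame) -> np.ndarray:
    """(n, 5, 10) per-site blocks: 7 site features + 3 tooth means."""
    means = features[["mean_L", "mean_a", "mean_b"]].to_numpy(dtype=float)
    blocks = []
    for label in SITE_LABELS:
        cols = [f"{label}__{f}" for f in SITE_FEATURES]
        site = features[cols].to_numpy(dtype=float)
        blocks.append(np.concatenate([site, means], axis=1))
    return np.stack(blocks, axis=1)


def _site_rows(features: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Row-per-site representation: (n*5, 10) plus the owning-row index."""
    blocks = _site_blocks(features)
    n, m, d = blocks.shape
    owner = np.repeat(np.arange(n), m)
    return blocks.reshape(n * m, d), owner


def _normalize_labels(labels: pd.Series) -> pd.Series:
    if labels.dtype == object or str(labels.dtype).startswith("category"):
        return labels.map({c: i for i, c in enumerate(CATEGORIES)}).astype(int)
    return labels.astype(int)


@dataclass
class FittedModel:
    """A trained classifier bound to its feature schema and scaler."""

    family: str
    policy: TrainingPolicy
    columns: list[str] = field(repr=False)
    estimator: object = field(repr=False)
    scaler: Scaler | None = field(default=None, repr=False)
    class_weights: np.ndarray | None = field(default=None, repr=False)

    def _prepare(self, features: pd.DataFrame):
        _check_schema(features)
        if self.family == "deep_sets":
            X = _site_blocks(features)
            return self.scaler.transform(X)
        if self.policy.input_mode == "site":
            X, owner = _site_rows(features)
            if self.scaler is not None:
                X = self.scaler.transform(X)
            elif isinstance(X, np.ndarray):
                X = pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])
            return X, owner
        X = features.to_numpy(dtype=float)
        if self.scaler is not None:
            X = self.scaler.transform(X)
        elif isinstance(X, np.ndarray):
            X = pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])
        return X

    def predict_proba(self, features: pd.DataFrame) -> pd.DataFrame:
        """One probability simplex per tooth, indexed by tooth_id."""
        if self.family == "deep_sets":
            P = self.estimator.predict_proba(self._prepare(features))
        elif self.policy.input_mode == "site":
            X, owner = self._prepare(features)
            P_site = self.estimator.predict_proba(X)
            n = len(features)
            P = np.zeros((n, len(CATEGORIES)))
            np.add.at(P, owner, P_site)
            P /= len(SITE_LABELS)
        else:
            P = self.estimator.predict_proba(self._prepare(features))
        P = np.clip(P, 0.0, 1.0)
        P = P / P.sum(axis=1, keepdims=True)
        return pd.DataFrame(P, index=features.index, columns=list(CATEGORIES))

    def predict_logits(self, features: pd.DataFrame) -> pd.DataFrame:
        """Raw logits (neural families only), for temperature scaling."""
        if self.family not in _NEURAL:
            raise ValueError("logits are only defined for the neural families")
        Z = self.estimator.predict_logits(self._prepare(features))
        return pd.DataFrame(Z, index=features.index, columns=list(CATEGORIES))

    def class_probabilities(self, features: pd.DataFrame) -> list[ClassProbabilities]:
        P = self.predict_proba(features)
        return [
            ClassProbabilities(tooth_id=str(t), probs=tuple(row))
            for t, row in zip(P.index, P.to_numpy())
        ]


def _leakage_guard(split: SplitAssignment, used_ids: Iterable[str]) -> None:
    test = set(split.test_ids)
    leaked = test.intersection(used_ids)
    if leaked:
        raise ValueError(
            f"leakage: test teeth {sorted(leaked)[:5]}... appear in the "
            "training input"
        )


def train_model(
    features: pd.DataFrame,
    labels: pd.Series,
    split: SplitAssignment,
    policy: TrainingPolicy,
) -> FittedModel:
    """Fit one classifier family on the training partition of ``split``.

    Tree families train on train + validation teeth (they use internal
    mechanisms rather than an explicit validation set); neural families
    fit on the train partition with early stopping on the validation
    partition.  The test partition is never touched: only train and
    validation labels are read, so a ``labels`` series missing the test
    teeth trains identically.
    """
    _check_schema(features)
    labels = _normalize_labels(labels)
    train_ids = [t for t in features.index if split.assignment.get(t) == "train"]
    val_ids = [t for t in features.index if split.assignment.get(t) == "validation"]
    if not train_ids:
        raise ValueError("no training teeth found in the feature table")
    _leakage_guard(split, train_ids + val_ids)

    if policy.model_family in _NEURAL:
        fit_ids, es_ids = train_ids, val_ids
    else:
        fit_ids, es_ids = train_ids + val_ids, []

    y_fit = labels.loc[fit_ids].to_numpy()
    counts = np.bincount(y_fit, minlength=len(CATEGORIES))
    if np.any(counts == 0):
        raise ValueError("every category must appear in the training partition")
    if policy.class_weights is None:
        weights = inverse_frequency_weights(counts)
    else:
        weights = np.asarray(policy.class_weights, dtype=float)

    X_fit_df = features.loc[fit_ids]

    if policy.model_family == "deep_sets":
        X = _site_blocks(X_fit_df)
        scaler = Scaler().fit(X)
        net = DeepSetsNet(
            n_in=X.shape[-1],
            n_classes=len(CATEGORIES),
            encoder=policy.deepsets_encoder,
            head=policy.deepsets_head,
            dropout=policy.dropout_rate,
            noise_sd=policy.gaussian_noise_sd,
            gamma=policy.focal_gamma,
            class_weights=weights,
            lr=policy.learning_rate,
            max_epochs=policy.max_epochs,
            patience=policy.early_stopping_patience,
            plateau_patience=policy.plateau_patience,
            seed=policy.seed,
        )
        Xv = yv = None
        if es_ids:
            Xv = scaler.transform(_site_blocks(features.loc[es_ids]))
            yv = labels.loc[es_ids].to_numpy()
        net.fit(scaler.transform(X), y_fit, Xv, yv)
        return FittedModel(policy.model_family, policy, list(features.columns),
                           net, scaler, weights)

    if policy.model_family == "mlp":
        if policy.input_mode == "site":
            X, owner = _site_rows(X_fit_df)
            y_rows = y_fit[owner]
        else:
            X, y_rows = X_fit_df.to_numpy(dtype=float), y_fit
        scaler = Scaler().fit(X)
        net = MLPNet(
            n_in=X.shape[1],
            n_classes=len(CATEGORIES),
            hidden=policy.mlp_hidden,
            dropout=policy.dropout_rate,
            noise_sd=policy.gaussian_noise_sd,
            gamma=policy.focal_gamma,
            class_weights=weights,
            lr=policy.learning_rate,
            max_epochs=policy.max_epochs,
            patience=policy.early_stopping_patience,
            plateau_patience=policy.plateau_patience,
            seed=policy.seed,
        )
        Xv = yv = None
        if es_ids:
            if policy.input_mode == "site":
                Xv, owner_v = _site_rows(features.loc[es_ids])
                yv = labels.loc[es_ids].to_numpy()[owner_v]
            else:
                Xv = features.loc[es_ids].to_numpy(dtype=float)
                yv = labels.loc[es_ids].to_numpy()
            Xv = scaler.transform(Xv)
        net.fit(scaler.transform(X), y_rows, Xv, yv)
        return FittedModel(policy.model_family, policy, list(features.columns),
                           net, scaler, weights)

    # tree families; generic column names keep the two input modes
    # schema-consistent for the library estimators
    if policy.input_mode == "site":
        X, owner = _site_rows(X_fit_df)
        y_rows = y_fit[owner]
    else:
        X, y_rows = X_fit_df.to_numpy(dtype=float), y_fit
    X = pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])
    sample_weight = weights[y_rows]
    if policy.model_family == "random_forest":
        from sklearn.ensemble import RandomForestClassifier

        est = RandomForestClassifier(
            n_estimators=policy.n_estimators,
            class_weight={i: float(w) for i, w in enumerate(weights)},
            random_state=policy.seed,
            n_jobs=1,
        )
        est.fit(X, y_rows)
    elif policy.model_family == "xgboost":
        from xgboost import XGBClassifier

        est = XGBClassifier(
            n_estimators=policy.n_estimators,
            learning_rate=0.1,
            max_depth=4,
            subsample=0.9,
            reg_lambda=1.0,
            objective="multi:softprob",
            num_class=len(CATEGORIES),
            random_state=policy.seed,
            n_jobs=1,
            verbosity=0,
        )
        est.fit(X, y_rows, sample_weight=sample_weight)
    elif policy.model_family == "lightgbm":
        from lightgbm import LGBMClassifier

        est = LGBMClassifier(
            n_estimators=policy.n_estimators,
            learning_rate=0.1,
            subsample=0.9,
            subsample_freq=1,
            reg_lambda=1.0,
            random_state=policy.seed,
            n_jobs=1,
            verbose=-1,
        )
        est.fit(X, y_rows, sample_weight=sample_weight)
    else:  # pragma: no cover - guarded by TrainingPolicy
        raise ValueError(policy.model_family)
    return FittedModel(policy.model_family, policy, list(features.columns),
                       est, None, weights)


def predict_tooth(model: FittedModel, features: pd.DataFrame) -> pd.DataFrame:
    """Tooth-level probability simplexes for every row of ``features``."""
    return model.predict_proba(features)
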