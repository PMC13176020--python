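"""Post-hoc probability calibration and Expected Calibration Error.

Neural-model logits are calibrated by temperature scaling: a single
scalar T > 0, fitted on the internal validation set by minimizing the
negative log-likelihood of softmax(logits / T).  Dividing logits by a
positive scalar is a monotone transform per tooth, so predicted classes
never change — only confidences.  Tree-model outputs are left
uncalibrated.

ECE uses the standard convention: confidence = max predicted
probability, equal-width bins on [0, 1] (10 by default), and
ECE = sum_b (count_b / N) |accuracy_b - mean confidence_b|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = [
    "CalibrationReport",
    "expected_calibration_error",
    "bin_table",
    "temperature_scale",
    "apply_temperature",
    "calibrate_and_report",
]


def _as_prob_array(probs) -> np.ndarray:
    P = np.asarray(probs, dtype=float)
    if P.ndim != 2 or P.shape[0] == 0:
        raise ValueError("probs must be a non-empty (n, K) array")
    if np.any(P < -1e-9) or np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("each row of probs must be a probability simplex")
    return P


def bin_table(probs, labels, n_bins: int = 10) -> pd.DataFrame:
    """Reliability-diagram table: mean confidence, accuracy, count per bin."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    P = _as_prob_array(probs)
    y = np.asarray(labels, dtype=int)
    conf = P.max(axis=1)
    correct = (P.argmax(axis=1) == y).astype(float)
    idx = np.minimum((conf * n_bins).astype(int), n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = idx == b
        count = int(mask.sum())
        rows.append(
            {
                "bin_lower": b / n_bins,
                "bin_upper": (b + 1) / n_bins,
                "confidence": float(conf[mask].mean()) if count else np.nan,
                "accuracy": float(correct[mask].mean()) if count else np.nan,
                "count": count,
            }
        )
    return pd.DataFrame(rows)


def expected_calibration_error(probs, labels, n_bins: int = 10) -> float:
    """Binned average absolute gap between confidence and accuracy."""
    table = bin_table(probs, labels, n_bins)
    n = table["count"].sum()
    occupied = table["count"] > 0
    gaps = (table.loc[occupied, "accuracy"] - table.loc[occupied, "confidence"]).abs()
    return float((table.loc[occupied, "count"] / n * gaps).sum())


def _nll(logits: np.ndarray, y: np.ndarray, T: float) -> float:
    z = logits / T
    z = z - z.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    return float(-logp[np.arange(len(y)), y].mean())


def temperature_scale(logits, labels) -> float:
    """Fit the temperature T > 0 minimizing validation NLL.

    1-D bounded minimization over log T; converged to well below 1e-6
    in T around the optimum.

    Raises
    ------
    ValueError
        If fewer than 2 teeth or a single-class validation set is given
        (the NLL is then minimized by T -> 0, which is degenerate).
    """
    Z = np.asarray(logits, dtype=float)
    y = np.asarray(labels, dtype=int)
    if Z.ndim != 2 or Z.shape[0] < 2:
        raise ValueError("temperature scaling needs >= 2 validation teeth")
    if len(np.unique(y)) < 2:
        raise ValueError(
            "degenerate single-class validation set; temperature is not "
            "identifiable"
        )
    res = minimize_scalar(
        lambda logT: _nll(Z, y, float(np.exp(logT))),
        bounds=(-7.0, 7.0),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(np.exp(res.x))


def apply_temperature(logits, temperature: float) -> np.ndarray:
    """softmax(logits / T); argmax-preserving for any T > 0."""
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    Z = np.asarray(logits, dtype=float) / temperature
    Z = Z - Z.max(axis=1, keepdims=True)
    e = np.exp(Z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass(frozen=True)
class CalibrationReport:
    """ECE before/after temperature scaling plus the reliability table."""

    ece_before: float
    ece_after: float
    temperature: float
    n_bins: int
    table_before: pd.DataFrame
    table_after: pd.DataFrame

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")

    def to_dict(self) -> dict:
        return {
            "ece_before": self.ece_before,
            "ece_after": self.ece_after,
            "temperature": self.temperature,
            "n_bins": self.n_bins,
        }


def calibrate_and_report(
    val_logits,
    val_labels,
    eval_logits,
    eval_labels,
    n_bins: int = 10,
) -> CalibrationReport:
    """Fit T on validation logits; report ECE before/after on eval data."""
    T = temperature_scale(val_logits, val_labels)
    probs_before = apply_temperature(eval_logits, 1.0)
    probs_after = apply_temperature(eval_logits, T)
    return CalibrationReport(
        ece_before=expected_calibration_error(probs_before, eval_labels, n_bins),
        ece_after=expected_calibration_error(probs_after, eval_labels, n_bins),
        temperature=T,
        n_bins=n_bins,
        table_before=bin_table(probs_before, eval_labels, n_bins),
        table_after=bin_table(probs_after, eval_labels, n_bins),
    )
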