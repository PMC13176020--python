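"""Colorimetric feature engineering for site-level CIELAB readings.

Raw readings are transformed into the per-tooth / per-site feature set
used by the classifiers: overall tooth color (mean L*, a*, b*),
site-specific deviations from the tooth mean (dL*, da*, db*), chroma
C* = sqrt(a*^2 + b*^2), hue angle h in degrees [0, 360), and two color
differences dE per site — against the tooth's own mean color and
against the mean color of sound (ICDAS 0) teeth in the training
partition (the clinically relevant "sound enamel" reference).

dE uses the CIE76 Euclidean form sqrt(dL^2 + da^2 + db^2), the
canonical default in dental color science; it keeps the dE values
consistent with the dL/da/db decomposition.  Chroma and hue are
computed on raw site a*, b* (not on deltas), as descriptors of each
site's own color.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .records import SITE_LABELS, SiteMeasurement, ToothRecord

__all__ = [
    "SoundReference",
    "ColorFeatureSet",
    "chroma",
    "hue_deg",
    "delta_e",
    "sound_reference",
    "featurize_tooth",
    "featurize_cohort",
    "feature_columns",
    "SITE_FEATURES",
]

#: Per-site engineered features, in column order.
SITE_FEATURES: tuple[str, ...] = (
    "dL",
    "da",
    "db",
    "chroma",
    "hue_deg",
    "dE_tooth",
    "dE_sound",
)


def _check_finite(*values: float) -> None:
    for v in values:
        if not math.isfinite(v):
            raise ValueError(f"non-finite input {v!r}")


def chroma(a: float, b: float) -> float:
    """Chroma C* = sqrt(a*^2 + b*^2): the color intensity of (a*, b*)."""
    _check_finite(a, b)
    return math.hypot(a, b)


def hue_deg(a: float, b: float) -> float:
    """Hue angle of (a*, b*) in degrees, mapped to [0, 360).

    Four-quadrant arctangent of b* over a*.  The achromatic origin
    (0, 0) returns 0 by convention.
    """
    _check_finite(a, b)
    if a == 0.0 and b == 0.0:
        return 0.0
    deg = math.degrees(math.atan2(b, a))
    return deg % 360.0


def delta_e(lab1: Sequence[float], lab2: Sequence[float]) -> float:
    """CIE76 color difference sqrt(dL^2 + da^2 + db^2); symmetric."""
    v1 = np.asarray(lab1, dtype=float)
    v2 = np.asarray(lab2, dtype=float)
    if v1.shape != (3,) or v2.shape != (3,):
        raise ValueError("delta_e expects two 3-vectors")
    if not (np.all(np.isfinite(v1)) and np.all(np.isfinite(v2))):
        raise ValueError("non-finite CIELAB input")
    return float(np.linalg.norm(v1 - v2))


@dataclass(frozen=True)
class SoundReference:
    """Mean CIELAB color of sound-category teeth (training partition only).

    Averages over all site measurements of the sound teeth, weighting
    every reading equally (identical to averaging tooth means here,
    since every tooth contributes the same number of sites).
    """

    ref_L: float
    ref_a: float
    ref_b: float
    n_teeth: int

    def __post_init__(self) -> None:
        if self.n_teeth < 1:
            raise ValueError("SoundReference requires n_teeth >= 1")

    @property
    def lab(self) -> tuple[float, float, float]:
        return (self.ref_L, self.ref_a, self.ref_b)


def sound_reference(training_teeth: Iterable[ToothRecord]) -> SoundReference:
    """Channel-wise mean color over all sites of sound training teeth.

    Must be computed exclusively from the training partition — passing
    validation or test teeth here leaks the reference.  Carious teeth in
    the input are ignored.

    Raises
    ------
    ValueError
        If the input contains no sound-category tooth.  The leakage-safe
        remedy is to recompute the split (e.g. a different seed), never
        to borrow sound teeth from validation or test.
    """
    sound = [t for t in training_teeth if t.category == "sound"]
    if not sound:
        raise ValueError(
            "no sound (ICDAS 0) tooth in the training partition; recompute the "
            "split with a different seed — do not borrow sound teeth from "
            "validation or test"
        )
    labs = np.array([s.lab for t in sound for s in t.sites], dtype=float)
    mean = labs.mean(axis=0)
    return SoundReference(
        ref_L=float(mean[0]),
        ref_a=float(mean[1]),
        ref_b=float(mean[2]),
        n_teeth=len(sound),
    )


@dataclass(frozen=True)
class ColorFeatureSet:
    """Engineered colorimetric features for one tooth.

    ``site_features`` maps each site label to its 7-tuple of values in
    :data:`SITE_FEATURES` order.  Per tooth, the five dL (likewise da,
    db) values sum to zero by construction.
    """

    tooth_id: str
    mean_L: float
    mean_a: float
    mean_b: float
    site_features: dict[str, tuple[float, ...]]

    def flat(self) -> np.ndarray:
        """Flattened vector: 3 means then the 5x7 site block in
        canonical site-label order (38 values)."""
        parts = [self.mean_L, self.mean_a, self.mean_b]
        for label in SITE_LABELS:
            parts.extend(self.site_features[label])
        return np.asarray(parts, dtype=float)


def feature_columns() -> list[str]:
    """Column names of the flattened per-tooth feature vector."""
    cols = ["mean_L", "mean_a", "mean_b"]
    for label in SITE_LABELS:
        cols.extend(f"{label}__{f}" for f in SITE_FEATURES)
    return cols


def featurize_tooth(tooth: ToothRecord, ref: SoundReference) -> ColorFeatureSet:
    """Compute the full engineered feature set for one tooth.

    Deterministic, and invariant to the ordering of the five input
    sites (per-site outputs are keyed by site label).
    """
    labs = {s.site_label: np.asarray(s.lab, dtype=float) for s in tooth.sites}
    mean = np.mean([labs[label] for label in SITE_LABELS], axis=0)
    ref_lab = np.asarray(ref.lab, dtype=float)
    site_features: dict[str, tuple[float, ...]] = {}
    for label in SITE_LABELS:
        lab = labs[label]
        d = lab - mean
        site_features[label] = (
            float(d[0]),
            float(d[1]),
            float(d[2]),
            chroma(float(lab[1]), float(lab[2])),
            hue_deg(float(lab[1]), float(lab[2])),
            delta_e(lab, mean),
            delta_e(lab, ref_lab),
        )
    return ColorFeatureSet(
        tooth_id=tooth.tooth_id,
        mean_L=float(mean[0]),
        mean_a=float(mean[1]),
        mean_b=float(mean[2]),
        site_features=site_features,
    )


def featurize_cohort(
    teeth: Iterable[ToothRecord], ref: SoundReference
) -> pd.DataFrame:
    """Feature table with one row per tooth, indexed by tooth_id.

    Columns are :func:`feature_columns`: the 3 tooth means followed by
    the 5x7 per-site feature block in fixed site-label order.
    """
    teeth = list(teeth)
    rows = [featurize_tooth(t, ref).flat() for t in teeth]
    return pd.DataFrame(
        rows,
        index=pd.Index([t.tooth_id for t in teeth], name="tooth_id"),
        columns=feature_columns(),
    )
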