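"""Core domain records: site-level CIELAB measurements and tooth records.

A tooth is the analytical unit: one ICDAS score (0-4), one severity
category, and an unordered set of exactly five occlusal measurement
sites (two buccal cusp slopes, two mesial cusp slopes, the central pit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

#: Fixed vocabulary of the five occlusal measurement sites, in the
#: canonical order used for flattened feature vectors.
SITE_LABELS: tuple[str, ...] = (
    "buccal_slope_1",
    "buccal_slope_2",
    "mesial_slope_1",
    "mesial_slope_2",
    "central_pit",
)

#: Severity categories, in label-encoding order (0, 1, 2).
CATEGORIES: tuple[str, ...] = ("sound", "initial", "moderate")

#: Binary clinical contrasts: early lesion detection (ICDAS 1-4 vs 0)
#: and operative-level detection (ICDAS 3-4 vs 0-2).
CONTRASTS: tuple[str, ...] = ("early", "operative")


def icdas_to_category(icdas: int) -> str:
    """Collapse an ICDAS score 0-4 to its severity category.

    0 -> sound, 1-2 -> initial, 3-4 -> moderate.
    """
    if not isinstance(icdas, (int,)) or isinstance(icdas, bool):
        raise TypeError(f"ICDAS score must be an integer, got {icdas!r}")
    if icdas == 0:
        return "sound"
    if icdas in (1, 2):
        return "initial"
    if icdas in (3, 4):
        return "moderate"
    raise ValueError(f"ICDAS score must be in 0..4, got {icdas}")


@dataclass(frozen=True)
class SiteMeasurement:
    """One CIELAB reading at one named occlusal site of one tooth."""

    tooth_id: str
    site_label: str
    L: float
    a: float
    b: float

    def __post_init__(self) -> None:
        if self.site_label not in SITE_LABELS:
            raise ValueError(
                f"unknown site_label {self.site_label!r}; "
                f"expected one of {SITE_LABELS}"
            )
        for name in ("L", "a", "b"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"non-finite {name}* value for {self.tooth_id}")
        if not 0.0 <= self.L <= 100.0:
            raise ValueError(
                f"L* must lie in [0, 100], got {self.L} for {self.tooth_id}"
            )

    @property
    def lab(self) -> tuple[float, float, float]:
        return (self.L, self.a, self.b)


@dataclass(frozen=True)
class ToothRecord:
    """A tooth: ICDAS score, severity category, and its 5 site readings.

    The five sites are an unordered set; they are stored in canonical
    site-label order for reproducibility, but no downstream computation
    may depend on their ordering.
    """

    tooth_id: str
    icdas: int
    sites: tuple[SiteMeasurement, ...] = field(default=())

    def __post_init__(self) -> None:
        icdas_to_category(self.icdas)  # range check
        if len(self.sites) != len(SITE_LABELS):
            raise ValueError(
                f"tooth {self.tooth_id!r} has {len(self.sites)} sites; "
                f"exactly {len(SITE_LABELS)} required"
            )
        labels = sorted(s.site_label for s in self.sites)
        if labels != sorted(SITE_LABELS):
            raise ValueError(
                f"tooth {self.tooth_id!r} sites must carry the 5 distinct "
                f"labels {SITE_LABELS}, got {labels}"
            )
        if any(s.tooth_id != self.tooth_id for s in self.sites):
            raise ValueError(
                f"all sites of tooth {self.tooth_id!r} must share its tooth_id"
            )
        # store in canonical order so equal teeth compare equal
        object.__setattr__(
            self,
            "sites",
            tuple(sorted(self.sites, key=lambda s: SITE_LABELS.index(s.site_label))),
        )

    @property
    def category(self) -> str:
        """Severity category, the deterministic image of the ICDAS score."""
        return icdas_to_category(self.icdas)

    @property
    def category_index(self) -> int:
        return CATEGORIES.index(self.category)

    def site(self, label: str) -> SiteMeasurement:
        for s in self.sites:
            if s.site_label == label:
                return s
        raise KeyError(label)
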