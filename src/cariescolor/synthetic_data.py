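"""Seeded synthetic cohorts of site-level CIELAB measurements.

The generator emulates the structure of an in-vitro occlusal caries
dataset: 300 extracted teeth with tooth-level ICDAS labels (40 sound,
181 initial carious, 79 moderate carious), five occlusal measurement
sites per tooth, class-conditional color shifts of lesions relative to
sound enamel, site-localised lesion color deviations within carious
teeth, and additive per-channel measurement noise.

Model: each tooth draws a base CIELAB color from its category's
population mean with Gaussian between-tooth scatter.  In carious teeth
a subset of sites additionally receives a lesion shift (lightness drop,
yellow/brown drift), scaled x1 for initial and x2 for moderate lesions,
reflecting the monotone color separation of progressing demineralization
(white-spot opacity / brownish discoloration).  Every site reading then
gets i.i.d. Gaussian measurement noise per channel, and L* is clipped to
the valid [0, 100] range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .records import CATEGORIES, SITE_LABELS, SiteMeasurement, ToothRecord

__all__ = ["GeneratorConfig", "default_config", "generate_cohort"]

#: Severity scaling of the lesion-site shift per category.
_SEVERITY_SCALE = {"sound": 0.0, "initial": 1.0, "moderate": 2.0}

#: ICDAS integers available within each category.
_CATEGORY_ICDAS = {"sound": (0,), "initial": (1, 2), "moderate": (3, 4)}


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic cohort generator.

    Attributes
    ----------
    class_counts
        Number of teeth per category ``(sound, initial, moderate)``.
    class_mean_lab
        Per-category population mean ``(L*, a*, b*)`` of the base tooth
        color, keyed by category name.
    tooth_sd
        Between-tooth standard deviation per channel.
    lesion_site_shift
        Additional ``(L*, a*, b*)`` shift applied to lesion-affected
        sites of carious teeth, scaled by severity (x1 initial,
        x2 moderate).
    n_lesion_sites
        How many of the 5 sites carry the lesion shift in carious teeth.
    noise_sd
        Per-channel i.i.d. Gaussian measurement noise.
    seed
        Seed of the generator's random stream.
    """

    class_counts: tuple[int, int, int] = (40, 181, 79)
    class_mean_lab: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "sound": (74.0, 2.0, 16.0),
            "initial": (72.0, 2.5, 17.5),
            "moderate": (69.5, 3.2, 20.0),
        }
    )
    tooth_sd: tuple[float, float, float] = (3.5, 1.2, 3.0)
    lesion_site_shift: tuple[float, float, float] = (-3.0, 0.8, 2.0)
    n_lesion_sites: int = 2
    noise_sd: float = 2.0
    seed: int = 42

    def __post_init__(self) -> None:
        if len(self.class_counts) != len(CATEGORIES):
            raise ValueError("class_counts must have one entry per category")
        if any(c < 0 for c in self.class_counts):
            raise ValueError("class_counts must all be >= 0")
        if set(self.class_mean_lab) != set(CATEGORIES):
            raise ValueError(f"class_mean_lab must be keyed by {CATEGORIES}")
        for cat, mean in self.class_mean_lab.items():
            if len(mean) != 3 or not all(math.isfinite(v) for v in mean):
                raise ValueError(f"class_mean_lab[{cat!r}] must be a finite 3-vector")
        if len(self.tooth_sd) != 3 or any(
            not math.isfinite(v) or v < 0 for v in self.tooth_sd
        ):
            raise ValueError("tooth_sd must be a finite, non-negative 3-vector")
        if len(self.lesion_site_shift) != 3 or any(
            not math.isfinite(v) for v in self.lesion_site_shift
        ):
            raise ValueError("lesion_site_shift must be a finite 3-vector")
        if not 0 <= self.n_lesion_sites <= len(SITE_LABELS):
            raise ValueError("n_lesion_sites must lie in [0, 5]")
        if not math.isfinite(self.noise_sd) or self.noise_sd < 0:
            raise ValueError("noise_sd must be finite and >= 0")

    @property
    def n_teeth(self) -> int:
        return sum(self.class_counts)


def default_config(seed: int = 42) -> GeneratorConfig:
    """The default study conditions: 300 teeth split 40/181/79.

    Class means are ordered so that lesion severity decreases L* and
    increases b* (the white-spot / brown-discoloration direction).
    Between-class separation is of the same order as the between-tooth
    scatter, so severity is recoverable by the classifiers — clearly
    above chance — but deliberately not trivially separable once
    measurement noise is added: the domain's color gradients are subtle
    and continuous.
    """
    return GeneratorConfig(seed=seed)


def separable_config(seed: int = 42) -> GeneratorConfig:
    """A degenerate wide-separation, zero-noise configuration.

    Classes sit ~20 L* units apart with no between-tooth scatter and no
    measurement noise: every classifier family should recover the labels
    perfectly.  Used for separability sanity checks.
    """
    return GeneratorConfig(
        class_mean_lab={
            "sound": (90.0, 0.0, 10.0),
            "initial": (70.0, 5.0, 20.0),
            "moderate": (50.0, 10.0, 30.0),
        },
        tooth_sd=(0.5, 0.1, 0.3),
        noise_sd=0.0,
        seed=seed,
    )


def generate_cohort(config: GeneratorConfig) -> list[ToothRecord]:
    """Generate a seeded cohort of teeth under ``config``.

    Fully reproducible for a fixed seed.  Within the initial (ICDAS 1-2)
    and moderate (ICDAS 3-4) categories the specific ICDAS integer is
    assigned uniformly at random; the pipeline only consumes the
    3-category label and the two binary contrasts derived from it.
    """
    rng = np.random.default_rng(config.seed)
    teeth: list[ToothRecord] = []
    counter = 0
    for cat, count in zip(CATEGORIES, config.class_counts):
        mean = np.asarray(config.class_mean_lab[cat], dtype=float)
        sd = np.asarray(config.tooth_sd, dtype=float)
        shift = np.asarray(config.lesion_site_shift, dtype=float)
        scale = _SEVERITY_SCALE[cat]
        for _ in range(count):
            counter += 1
            tooth_id = f"T{counter:04d}"
            icdas = int(rng.choice(_CATEGORY_ICDAS[cat]))
            base = mean + rng.normal(0.0, 1.0, size=3) * sd
            lesion_sites: set[int] = set()
            if scale > 0 and config.n_lesion_sites > 0:
                lesion_sites = set(
                    rng.choice(
                        len(SITE_LABELS), size=config.n_lesion_sites, replace=False
                    ).tolist()
                )
            sites = []
            for i, label in enumerate(SITE_LABELS):
                lab = base.copy()
                if i in lesion_sites:
                    lab = lab + scale * shift
                lab = lab + rng.normal(0.0, config.noise_sd, size=3)
                sites.append(
                    SiteMeasurement(
                        tooth_id=tooth_id,
                        site_label=label,
                        L=float(np.clip(lab[0], 0.0, 100.0)),
                        a=float(lab[1]),
                        b=float(lab[2]),
                    )
                )
            teeth.append(ToothRecord(tooth_id=tooth_id, icdas=icdas, sites=tuple(sites)))
    return teeth
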