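"""File formats and run configuration.

Canonical interchange formats, all human-diffable text:

* measurement CSV — ``tooth_id, site_label, icdas, L, a, b``; one row
  per site, exactly 5 rows per tooth;
* feature CSV — one row per tooth, the canonical flattened columns;
* split CSV — ``tooth_id, partition, seed``;
* report JSON — metric reports plus a manifest (package version,
  config hash, seed) so every artifact is traceable to its run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

from . import __version__
from .records import SITE_LABELS, SiteMeasurement, ToothRecord
from .synthetic_data import GeneratorConfig

__all__ = [
    "RunConfig",
    "read_measurements",
    "write_measurements",
    "read_split",
    "write_split",
    "write_report",
]

MEASUREMENT_COLUMNS = ["tooth_id", "site_label", "icdas", "L", "a", "b"]


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (YAML-loadable)."""

    seed: int = 42
    test_frac: float = 0.10
    val_frac_of_train: float = 0.15
    bootstrap_iterations: int = 1000
    families: tuple[str, ...] = (
        "random_forest", "xgboost", "lightgbm", "mlp", "deep_sets"
    )
    fractions: tuple[float, ...] = (0.50, 0.75, 1.00)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        gen = GeneratorConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw.pop("generator", {}).items()
        })
        for key in ("families", "fractions"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(generator=gen, **raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def write_measurements(teeth: Iterable[ToothRecord], path: str | Path) -> None:
    rows = [
        {
            "tooth_id": t.tooth_id,
            "site_label": s.site_label,
            "icdas": t.icdas,
            "L": s.L,
            "a": s.a,
            "b": s.b,
        }
        for t in teeth
        for s in t.sites
    ]
    pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS).to_csv(path, index=False)


def read_measurements(path: str | Path) -> list[ToothRecord]:
    """Parse and validate a measurement CSV into tooth records.

    Enforces the 5-distinct-sites-per-tooth rule and a uniform ICDAS
    score per tooth; every violation is reported with the offending
    tooth and row numbers.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in MEASUREMENT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"measurement CSV is missing columns {missing}")
    for col in ("L", "a", "b"):
        bad = frame.index[pd.to_numeric(frame[col], errors="coerce").isna()]
        if len(bad):
            raise ValueError(
                f"non-numeric {col} values at rows {(bad + 2).tolist()[:5]}"
            )
    teeth: list[ToothRecord] = []
    errors: list[str] = []
    for tooth_id, grp in frame.groupby("tooth_id", sort=False):
        rows = (grp.index + 2).tolist()  # 1-based incl. header
        icdas_vals = sorted(set(int(v) for v in grp["icdas"]))
        if len(icdas_vals) != 1:
            errors.append(
                f"tooth {tooth_id!r}: non-uniform ICDAS {icdas_vals} "
                f"(rows {rows})"
            )
            continue
        if len(grp) != len(SITE_LABELS):
            errors.append(
                f"tooth {tooth_id!r}: {len(grp)} rows, expected "
                f"{len(SITE_LABELS)} (rows {rows})"
            )
            continue
        labels = sorted(grp["site_label"])
        if labels != sorted(SITE_LABELS):
            errors.append(
                f"tooth {tooth_id!r}: site labels {labels} do not form the "
                f"5-site vocabulary (rows {rows})"
            )
            continue
        try:
            sites = tuple(
                SiteMeasurement(
                    tooth_id=str(tooth_id),
                    site_label=str(r.site_label),
                    L=float(r.L),
                    a=float(r.a),
                    b=float(r.b),
                )
                for r in grp.itertuples()
            )
            teeth.append(
                ToothRecord(tooth_id=str(tooth_id), icdas=icdas_vals[0],
                            sites=sites)
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"tooth {tooth_id!r} (rows {rows}): {exc}")
    if errors:
        raise ValueError("invalid measurement CSV:\n" + "\n".join(errors))
    return teeth


def write_split(split, path: str | Path) -> None:
    split.to_frame().to_csv(path, index=False)


def read_split(path: str | Path):
    from .splitting import SplitAssignment

    frame = pd.read_csv(path)
    seed = int(frame["seed"].iloc[0]) if len(frame) else 0
    return SplitAssignment(
        assignment=dict(zip(frame["tooth_id"].astype(str), frame["partition"])),
        seed=seed,
        test_frac=float("nan"),
        val_frac_of_train=float("nan"),
    )


def write_report(payload: dict, path: str | Path, config: RunConfig) -> None:
    """Serialize a report with its run manifest."""
    manifest = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }
    out = {"manifest": manifest, **payload}
    Path(path).write_text(json.dumps(out, indent=2, sort_keys=True))
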