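"""Leakage-safe, group-stratified partitioning of teeth.

All five site measurements of a tooth travel together (group = tooth),
and the three severity categories are represented proportionally in
each partition.  The study design is a hold-out split: 90% training /
10% test, with 15% of the training portion further allocated as an
internal validation set for the neural models.

Rounding rule: per-category targets are round-half-up of
``count x fraction``; any global surplus or deficit against the
round-half-up total is corrected in the largest category.  This rule is
fixed for determinism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .records import CATEGORIES, SITE_LABELS, ToothRecord

__all__ = ["SplitAssignment", "group_stratified_split", "category_counts"]

PARTITIONS = ("train", "validation", "test")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class SplitAssignment:
    """Tooth -> partition map with the seed and fractions that produced it."""

    assignment: dict[str, str]
    seed: int
    test_frac: float
    val_frac_of_train: float

    def ids(self, partition: str) -> list[str]:
        if partition not in PARTITIONS:
            raise ValueError(f"unknown partition {partition!r}")
        return [t for t, p in self.assignment.items() if p == partition]

    @property
    def train_ids(self) -> list[str]:
        return self.ids("train")

    @property
    def validation_ids(self) -> list[str]:
        return self.ids("validation")

    @property
    def test_ids(self) -> list[str]:
        return self.ids("test")

    def partition_of(self, tooth_id: str) -> str:
        return self.assignment[tooth_id]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tooth_id": list(self.assignment),
                "partition": list(self.assignment.values()),
                "seed": self.seed,
            }
        )


def _stratified_targets(counts: dict[str, int], frac: float) -> dict[str, int]:
    """Round-half-up per category, global correction in the largest one."""
    targets = {cat: _round_half_up(n * frac) for cat, n in counts.items()}
    total_target = _round_half_up(sum(counts.values()) * frac)
    surplus = sum(targets.values()) - total_target
    if surplus != 0:
        largest = max(counts, key=lambda c: (counts[c], c))
        targets[largest] = max(0, min(counts[largest], targets[largest] - surplus))
    return targets


def group_stratified_split(
    teeth: Iterable[ToothRecord],
    test_frac: float = 0.10,
    val_frac_of_train: float = 0.15,
    seed: int = 42,
) -> SplitAssignment:
    """Partition teeth into train/validation/test, stratified by category.

    Within each category the teeth are shuffled under ``seed``;
    ``round(count x test_frac)`` go to test, then
    ``round(remaining x val_frac_of_train)`` to validation, the rest to
    train.  Deterministic per seed.  Set ``val_frac_of_train=0`` for the
    tree-model split (no internal validation set).

    Raises
    ------
    ValueError
        If a category is empty or too small to place at least one tooth
        in the training partition.
    """
    teeth = list(teeth)
    if not 0.0 < test_frac < 1.0:
        raise ValueError("test_frac must lie in (0, 1)")
    if not 0.0 <= val_frac_of_train < 1.0:
        raise ValueError("val_frac_of_train must lie in [0, 1)")
    by_cat: dict[str, list[str]] = {cat: [] for cat in CATEGORIES}
    for t in teeth:
        by_cat[t.category].append(t.tooth_id)
    present = {cat: ids for cat, ids in by_cat.items() if ids}
    if not present:
        raise ValueError("no teeth to split")
    for cat in CATEGORIES:
        if not by_cat[cat]:
            raise ValueError(f"category {cat!r} is empty; cannot stratify")

    counts = {cat: len(ids) for cat, ids in by_cat.items()}
    test_targets = _stratified_targets(counts, test_frac)
    remaining = {cat: counts[cat] - test_targets[cat] for cat in counts}
    val_targets = _stratified_targets(remaining, val_frac_of_train)

    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    for cat in CATEGORIES:
        ids = sorted(by_cat[cat])
        order = rng.permutation(len(ids))
        shuffled = [ids[i] for i in order]
        n_test = test_targets[cat]
        n_val = val_targets[cat]
        n_train = len(ids) - n_test - n_val
        if n_train < 1:
            raise ValueError(
                f"category {cat!r} has {len(ids)} teeth; the requested "
                f"fractions leave {n_train} in train (need >= 1)"
            )
        for tooth_id in shuffled[:n_test]:
            assignment[tooth_id] = "test"
        for tooth_id in shuffled[n_test : n_test + n_val]:
            assignment[tooth_id] = "validation"
        for tooth_id in shuffled[n_test + n_val :]:
            assignment[tooth_id] = "train"
    # report in input order
    assignment = {t.tooth_id: assignment[t.tooth_id] for t in teeth}
    return SplitAssignment(
        assignment=assignment,
        seed=seed,
        test_frac=test_frac,
        val_frac_of_train=val_frac_of_train,
    )


def category_counts(teeth: Iterable[ToothRecord]) -> pd.DataFrame:
    """Per-category tooth and site counts with percentages.

    Sites = teeth x 5 (every tooth contributes its 5 occlusal sites).
    Returns a frame indexed by category plus a ``total`` row.
    """
    teeth = list(teeth)
    n_sites_per_tooth = len(SITE_LABELS)
    counts = {cat: 0 for cat in CATEGORIES}
    for t in teeth:
        counts[t.category] += 1
    total = sum(counts.values())
    rows = []
    for cat in CATEGORIES:
        n = counts[cat]
        rows.append(
            {
                "teeth": n,
                "teeth_pct": 100.0 * n / total if total else 0.0,
                "sites": n * n_sites_per_tooth,
                "sites_pct": 100.0 * n / total if total else 0.0,
            }
        )
    frame = pd.DataFrame(rows, index=pd.Index(CATEGORIES, name="category"))
    frame.loc["total"] = [
        total,
        100.0 if total else 0.0,
        total * n_sites_per_tooth,
        100.0 if total else 0.0,
    ]
    return frame
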