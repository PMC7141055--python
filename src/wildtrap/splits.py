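"""Train/test partition protocols for camera-trap evaluation.

Two protocols are implemented:

* **trained-location split** — a single seeded random permutation of all
  images, first ~90% train, rest test.  Every test background was seen
  during training, so this measures within-domain performance.
* **untrained-location k-fold** — locations (in their deterministic
  catalog order) are cut into k contiguous blocks; each fold tests one
  block and trains on the rest, so no test image's location ever appears
  in training.  This measures generalization to unseen sites, the
  protocol under which camera-trap classifiers degrade.

The fold-boundary rule is ``b_i = round(L * i / k)`` (half-up), which
yields contiguous test blocks whose sizes differ by at most one — e.g.
36 locations in 5 folds gives blocks of sizes (7, 7, 8, 7, 7).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .catalog import Catalog

__all__ = [
    "SplitAssignment",
    "FoldPlan",
    "trained_location_split",
    "location_kfold_plan",
    "materialize_fold",
    "verify_no_location_leakage",
]

TRAINED = "trained_location"
UNTRAINED = "untrained_location"


@dataclass(frozen=True)
class SplitAssignment:
    """Train/test membership for one experiment.

    Invariants: train and test are disjoint; their union covers all
    non-augmented catalog ids; augmented records never land in test.
    """

    protocol: str
    train_ids: frozenset[str]
    test_ids: frozenset[str]
    seed: int = 0
    fold_index: int | None = None

    def save_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["image_id", "role", "fold_index"])
            fold = "" if self.fold_index is None else self.fold_index
            for i in sorted(self.train_ids):
                w.writerow([i, "train", fold])
            for i in sorted(self.test_ids):
                w.writerow([i, "test", fold])


@dataclass(frozen=True)
class FoldPlan:
    """k contiguous location blocks; fold i tests block i and trains on
    the complement."""

    k: int
    folds: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]  # (train_locs, test_locs)

    def test_locations(self, fold_index: int) -> tuple[str, ...]:
        return self.folds[fold_index][1]


def trained_location_split(catalog: Catalog, test_fraction: float = 0.10,
                           seed: int = 0) -> SplitAssignment:
    """Random image-level split: a seeded permutation of the records,
    first ``ceil((1 - test_fraction) * N)`` train, remainder test.

    Only non-augmented records enter the permutation; any augmented
    records already present are forced into the training side.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    base = [r.image_id for r in catalog if not r.is_augmented]
    if len(base) < 2:
        raise ValueError("need at least 2 non-augmented records to split")
    perm = np.random.default_rng(seed).permutation(len(base))
    n_train = math.ceil((1.0 - test_fraction) * len(base))
    train = {base[i] for i in perm[:n_train]}
    train.update(r.image_id for r in catalog if r.is_augmented)
    test = {base[i] for i in perm[n_train:]}
    return SplitAssignment(TRAINED, frozenset(train), frozenset(test), seed=seed)


def location_kfold_plan(locations: Sequence[str], k: int = 5) -> FoldPlan:
    """Contiguous location-blocked k-fold plan over the given ordering.

    Boundaries are ``b_i = round(L * i / k)`` (round half up), so each
    fold's test block is locations ``b_{i-1}..b_i`` and blocks differ in
    size by at most one.
    """
    L = len(locations)
    if k < 2:
        raise ValueError("k must be >= 2")
    if L < k:
        raise ValueError(f"need at least k={k} locations, got {L}")
    bounds = [int(math.floor(L * i / k + 0.5)) for i in range(k + 1)]
    folds = []
    for i in range(k):
        test = tuple(locations[bounds[i]:bounds[i + 1]])
        train = tuple(locations[:bounds[i]]) + tuple(locations[bounds[i + 1]:])
        folds.append((train, test))
    return FoldPlan(k=k, folds=tuple(folds))


def materialize_fold(catalog: Catalog, plan: FoldPlan, fold_index: int,
                     seed: int = 0) -> SplitAssignment:
    """Image-level assignment for one fold: test = every image at a test
    location, train = every image at a train location.

    Augmented records at test locations are dropped entirely (keeping
    them anywhere would leak the held-out backgrounds into training).
    """
    train_locs, test_locs = plan.folds[fold_index]
    train_set, test_set = set(train_locs), set(test_locs)
    train, test = [], []
    for r in catalog:
        if r.location_id in test_set:
            if not r.is_augmented:
                test.append(r.image_id)
        elif r.location_id in train_set:
            train.append(r.image_id)
    return SplitAssignment(UNTRAINED, frozenset(train), frozenset(test),
                           seed=seed, fold_index=fold_index)


def verify_no_location_leakage(split: SplitAssignment, catalog: Catalog) -> bool:
    """True iff the location sets behind train and test images are
    disjoint — the defining property of the untrained-location protocol."""
    loc = {r.image_id: r.location_id for r in catalog}
    train_locs = {loc[i] for i in split.train_ids if i in loc}
    test_locs = {loc[i] for i in split.test_ids if i in loc}
    return not (train_locs & test_locs)
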