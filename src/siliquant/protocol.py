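"""Deterministic study-design arithmetic: dataset split, training
schedule, genetic-map summary.

These are the desk-verifiable bookkeeping numbers of an annotate /
train / map campaign; no model is trained here.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .datatypes import ValidationError


@dataclass
class SplitPlan:
    """A reproducible train/test partition of annotated image ids."""

    n_total: int
    train_fraction: float
    train_ids: list
    test_ids: list
    seed: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "n_total": self.n_total,
                    "train_fraction": self.train_fraction,
                    "seed": self.seed,
                    "train_ids": list(self.train_ids),
                    "test_ids": list(self.test_ids),
                },
                fh,
                indent=1,
            )


def split_dataset(item_ids, train_fraction: float = 0.8, seed: int = 0) -> SplitPlan:
    """Uniform random partition with a floor-sized training set.

    The training-set size is floor(n * fraction), so it depends only on
    n and the fraction, never on the seed.  The partition is disjoint and
    exhaustive and reproducible under the seed.
    """
    item_ids = list(item_ids)
    if not item_ids:
        raise ValidationError("cannot split an empty dataset")
    if not 0 < train_fraction < 1:
        raise ValidationError("train_fraction must be in (0, 1)")
    n_train = math.floor(len(item_ids) * train_fraction)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(item_ids))
    train = [item_ids[i] for i in sorted(order[:n_train])]
    test = [item_ids[i] for i in sorted(order[n_train:])]
    return SplitPlan(
        n_total=len(item_ids),
        train_fraction=train_fraction,
        train_ids=train,
        test_ids=test,
        seed=seed,
    )


def training_iteration_count(
    epochs: int, n_train: int, batch_per_device: int = 1, n_devices: int = 1
) -> int:
    """Total optimiser iterations: epochs x ceil(n_train / effective batch).

    The last partial batch of an epoch still costs one iteration, hence
    the ceiling.
    """
    if min(epochs, n_train, batch_per_device, n_devices) <= 0:
        raise ValidationError("all schedule arguments must be positive integers")
    effective_batch = batch_per_device * n_devices
    return epochs * math.ceil(n_train / effective_batch)


def genetic_map_summary(per_chromosome_marker_counts) -> tuple[int, int]:
    """(total marker count, number of chromosomes) of a genetic map."""
    counts = list(per_chromosome_marker_counts)
    if not counts:
        raise ValidationError("marker counts are empty")
    if any(c <= 0 for c in counts):
        raise ValidationError("marker counts must be positive")
    return int(sum(counts)), len(counts)
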