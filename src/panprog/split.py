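"""Spatial subset sampling: a maximally dispersed, class-stratified split.

Within each prognosis class a seed sample is drawn at random, then samples
are greedily added in farthest-point order (each new sample maximizes its
mean distance to the already-selected set). The first two-thirds of each
class's ordering become the training set; the remainder is the test set.
The only random element is the per-class seed sample — everything else is
deterministic, with ties broken by smallest sample index.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .datatypes import HIGH_OS, LOW_OS, CohortLabels, ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class SplitAssignment:
    train_ids: list[str]
    test_ids: list[str]
    seed_sample: dict = field(default_factory=dict)  # class -> seed sample id
    rng_seed: int = 0
    train_fraction: float = 2.0 / 3.0

    def to_json(self) -> str:
        return json.dumps(
            {
                "train_ids": self.train_ids,
                "test_ids": self.test_ids,
                "seed_sample": self.seed_sample,
                "rng_seed": self.rng_seed,
                "train_fraction": self.train_fraction,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "SplitAssignment":
        return cls(**json.loads(text))


def pairwise_distances(matrix: ExpressionMatrix, standardize: bool = True) -> pd.DataFrame:
    """Euclidean distances between sample vectors, optionally z-scored per feature.

    Zero-variance features receive zero weight under standardization (they
    cannot separate samples), with a logged note.
    """
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples")
    X = matrix.data.to_numpy(dtype=float).T  # samples x features
    if standardize:
        sd = X.std(axis=0)
        flat = sd == 0
        if flat.any():
            logger.info("%d zero-variance features given zero weight", int(flat.sum()))
        sd[flat] = 1.0
        X = (X - X.mean(axis=0)) / sd
        X[:, flat] = 0.0
    dist = squareform(pdist(X, metric="euclidean"))
    ids = matrix.sample_ids
    return pd.DataFrame(dist, index=ids, columns=ids)


def farthest_point_order(distances: pd.DataFrame | np.ndarray, start: int) -> list[int]:
    """Greedy farthest-point ordering of all samples from a start index.

    Position 1 is ``start``; each subsequent position takes the unselected
    sample with the largest mean distance to everything already selected.
    Ties break to the smallest sample index; deterministic given ``start``.
    Returns positional indices into the distance table.
    """
    D = distances.to_numpy() if isinstance(distances, pd.DataFrame) else np.asarray(distances)
    n = D.shape[0]
    if not 0 <= start < n:
        raise ValueError(f"start index {start} out of range")
    order = [start]
    remaining = np.ones(n, dtype=bool)
    remaining[start] = False
    dist_sum = D[start].astype(float).copy()
    while remaining.any():
        mean_dist = np.where(remaining, dist_sum / len(order), -np.inf)
        nxt = int(np.argmax(mean_dist))  # argmax returns the first (smallest) index on ties
        order.append(nxt)
        remaining[nxt] = False
        dist_sum += D[nxt]
    return order


def spatial_subset_split(
    matrix: ExpressionMatrix,
    labels: CohortLabels,
    train_fraction: float = 2.0 / 3.0,
    rng_seed: int = 0,
    standardize: bool = True,
) -> SplitAssignment:
    """Class-stratified farthest-point split of a cohort.

    Within each class independently: draw the seed sample from ``rng_seed``,
    order the class by :func:`farthest_point_order`, and send the first
    ``round(train_fraction * n_class)`` samples (round half up) to training.
    """
    rng = np.random.default_rng(rng_seed)
    lab = labels.for_samples(matrix.sample_ids)
    train: list[str] = []
    test: list[str] = []
    seeds: dict[str, str] = {}
    for cls in (HIGH_OS, LOW_OS):
        ids = [s for s in matrix.sample_ids if lab[s] == cls]
        if len(ids) < 3:
            raise ValueError(f"class {cls} has {len(ids)} samples; need at least 3")
        sub = matrix.subset_samples(ids)
        D = pairwise_distances(sub, standardize=standardize)
        start = int(rng.integers(len(ids)))
        order = farthest_point_order(D, start)
        n_train = int(np.floor(train_fraction * len(ids) + 0.5))  # round half up
        train.extend(ids[i] for i in order[:n_train])
        test.extend(ids[i] for i in order[n_train:])
        seeds[cls] = ids[start]
    return SplitAssignment(
        train_ids=train,
        test_ids=test,
        seed_sample=seeds,
        rng_seed=rng_seed,
        train_fraction=train_fraction,
    )
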