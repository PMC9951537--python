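"""SMOTE oversampling of the minority (toxic) class in fingerprint space.

Each synthetic sample is a point on the segment between a uniformly chosen
minority sample x_i and one of its k nearest minority neighbours x_nn
(Euclidean metric): x_i + u * (x_nn - x_i) with u ~ Uniform[0, 1]. Synthetic
coordinates are kept continuous — binary fingerprint bits become fractional —
because tree ensembles split on thresholds and rounding would collapse many
synthetic points back onto real ones.

Oversampling is applied inside each training fold only (see learners); the
synthetic flag on the returned dataset guards against leakage into validation
or test partitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .dataset import LabeledDataset


@dataclass(frozen=True)
class SmoteConfig:
    k_neighbors: int = 5
    target_ratio: float = 1.0  # minority/majority ratio after oversampling
    seed: int = 0

    def __post_init__(self):
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if not 0 < self.target_ratio <= 1:
            raise ValueError("target_ratio must be in (0, 1]")


def smote_oversample(minority_rows: np.ndarray, config: SmoteConfig, n_synthetic: int,
                     return_provenance: bool = False):
    """Generate ``n_synthetic`` interpolated rows from the minority class.

    With ``return_provenance`` the triple (seed_index, neighbor_index, u) per
    synthetic row is returned alongside, so callers can verify each row is the
    exact convex combination it claims to be.
    """
    minority_rows = np.asarray(minority_rows, dtype=float)
    n = minority_rows.shape[0]
    if n < config.k_neighbors + 1:
        raise ValueError(
            f"SMOTE needs at least k_neighbors+1={config.k_neighbors + 1} minority rows, "
            f"got {n}; reduce k_neighbors"
        )
    if n_synthetic < 1:
        raise ValueError("n_synthetic must be >= 1")
    rng = np.random.default_rng(config.seed)
    nn = NearestNeighbors(n_neighbors=config.k_neighbors + 1).fit(minority_rows)
    # Column 0 is the point itself; columns 1..k are the k nearest neighbours.
    neighbor_idx = nn.kneighbors(minority_rows, return_distance=False)[:, 1:]

    seed_idx = rng.integers(0, n, size=n_synthetic)
    nn_choice = rng.integers(0, config.k_neighbors, size=n_synthetic)
    u = rng.uniform(0.0, 1.0, size=n_synthetic)
    nn_idx = neighbor_idx[seed_idx, nn_choice]
    x_i = minority_rows[seed_idx]
    x_nn = minority_rows[nn_idx]
    synthetic = x_i + u[:, None] * (x_nn - x_i)
    if return_provenance:
        return synthetic, (seed_idx, nn_idx, u)
    return synthetic


def balance_training_fold(fold: LabeledDataset, config: SmoteConfig) -> LabeledDataset:
    """Oversample the minority class of a training fold to ``target_ratio``.

    Original rows are preserved unmodified; synthetic rows are appended with
    the synthetic flag set, the minority label, and a log-LD50 target
    interpolated is NOT meaningful for them (set to NaN) — they are classifier
    training rows only.
    """
    n_neg, n_pos = fold.class_counts
    if n_neg == 0 or n_pos == 0:
        raise ValueError("training fold must contain both classes")
    minority_label = 1 if n_pos < n_neg else 0
    n_min = min(n_pos, n_neg)
    n_maj = max(n_pos, n_neg)
    target_min = int(round(config.target_ratio * n_maj))
    n_synthetic = target_min - n_min
    if n_synthetic <= 0:
        return fold

    minority_rows = fold.X[fold.y_label == minority_label]
    synthetic = smote_oversample(minority_rows, config, n_synthetic)
    n = len(fold)
    return LabeledDataset(
        ids=np.concatenate([fold.ids, np.array([f"synthetic_{i}" for i in range(n_synthetic)], dtype=object)]),
        X=np.vstack([fold.X, synthetic]),
        y_label=np.concatenate([fold.y_label, np.full(n_synthetic, minority_label, dtype=int)]),
        y_log=np.concatenate([fold.y_log, np.full(n_synthetic, np.nan)]),
        categories=np.concatenate([fold.categories, np.full(n_synthetic, "synthetic", dtype=object)]),
        species=fold.species,
        n_bits=fold.n_bits,
        synthetic=np.concatenate([fold.synthetic, np.ones(n_synthetic, dtype=bool)]),
        train_ids=fold.train_ids,
        test_ids=fold.test_ids,
    )
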