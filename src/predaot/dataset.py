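"""LabeledDataset: fingerprints, binary labels, log LD50 targets, GHS categories."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .chem import CompoundRecord, featurize_records
from .labeling import binary_labels, ghs_categories


@dataclass
class LabeledDataset:
    """Aligned arrays for one species' compounds.

    ``y_label`` is 1 for toxic (LD50 <= 300 mg/kg), 0 otherwise; ``y_log`` is
    log10 LD50 in mg/kg. ``synthetic`` flags SMOTE-generated rows, which must
    never leave a training fold.
    """

    ids: np.ndarray          # object/str array, shape (n,)
    X: np.ndarray            # float array, shape (n, n_bits)
    y_label: np.ndarray      # int {0,1}, shape (n,)
    y_log: np.ndarray        # float, shape (n,)
    categories: np.ndarray   # GHS category strings, shape (n,)
    species: str
    n_bits: int
    synthetic: np.ndarray = field(default=None)  # bool, shape (n,)
    train_ids: frozenset | None = None
    test_ids: frozenset | None = None

    def __post_init__(self):
        n = len(self.ids)
        if self.synthetic is None:
            self.synthetic = np.zeros(n, dtype=bool)
        for name in ("X", "y_label", "y_log", "categories", "synthetic"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match ids")

    def __len__(self) -> int:
        return len(self.ids)

    def subset(self, mask_or_idx) -> "LabeledDataset":
        idx = np.asarray(mask_or_idx)
        return LabeledDataset(
            ids=self.ids[idx],
            X=self.X[idx],
            y_label=self.y_label[idx],
            y_log=self.y_log[idx],
            categories=self.categories[idx],
            species=self.species,
            n_bits=self.n_bits,
            synthetic=self.synthetic[idx],
            train_ids=self.train_ids,
            test_ids=self.test_ids,
        )

    @property
    def class_counts(self) -> tuple[int, int]:
        """(n_less_or_non_toxic, n_toxic)."""
        return int(np.sum(self.y_label == 0)), int(np.sum(self.y_label == 1))


def build_dataset(records: Sequence[CompoundRecord], n_bits: int = 2048) -> LabeledDataset:
    """Featurize one species' records and attach labels/targets/categories."""
    species = {r.species for r in records}
    if len(species) != 1:
        raise ValueError(f"records must be single-species, got {sorted(species)}")
    fm = featurize_records(records, n_bits=n_bits)
    ld50 = np.array([r.ld50_mg_per_kg for r in records], dtype=float)
    return LabeledDataset(
        ids=np.array(fm.ids, dtype=object),
        X=fm.bits.astype(np.float64),
        y_label=binary_labels(ld50),
        y_log=np.array([r.log_ld50 for r in records], dtype=float),
        categories=ghs_categories(ld50),
        species=species.pop(),
        n_bits=n_bits,
    )
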