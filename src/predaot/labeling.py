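"""Binary toxicity labels and GHS acute-oral-toxicity categories.

The binary rule is exact: a compound is "toxic" iff its LD50 is at or below
300 mg/kg, otherwise "less or non-toxic". The five GHS categories tile the
positive axis at 5 / 50 / 300 / 2000 / 5000 mg/kg; anything above 5000 mg/kg
is reported as unclassified ("NC"). Boundary convention: lower-inclusive,
upper-exclusive, except category 3 whose upper bound (300) is inclusive so the
category partition agrees with the binary <=300 rule everywhere; the bounds
above 300 are shifted to open-below accordingly.
"""

from __future__ import annotations

import enum
import math
from typing import Mapping

import numpy as np

TOXIC_THRESHOLD_MG_PER_KG = 300.0

#: (low, high) bounds in mg/kg; low-inclusive/high-exclusive below 300,
#: low-exclusive/high-inclusive above (so 300 itself is category 3 = toxic).
GHS_BOUNDS: Mapping[str, tuple[float, float]] = {
    "1": (0.0, 5.0),
    "2": (5.0, 50.0),
    "3": (50.0, 300.0),
    "4": (300.0, 2000.0),
    "5": (2000.0, 5000.0),
    "NC": (5000.0, math.inf),
}


class ToxLabel(str, enum.Enum):
    TOXIC = "toxic"
    LESS_OR_NON_TOXIC = "less_or_non_toxic"


class GHSCategory(str, enum.Enum):
    CAT1 = "1"
    CAT2 = "2"
    CAT3 = "3"
    CAT4 = "4"
    CAT5 = "5"
    UNCLASSIFIED = "NC"

    @property
    def is_toxic(self) -> bool:
        return self in (GHSCategory.CAT1, GHSCategory.CAT2, GHSCategory.CAT3)


def _check_positive(ld50) -> None:
    arr = np.asarray(ld50, dtype=float)
    if not np.all(arr > 0):
        raise ValueError("LD50 must be positive (mg/kg)")


def label_binary(ld50_mg_per_kg: float) -> ToxLabel:
    """Toxic iff LD50 <= 300 mg/kg (inclusive)."""
    _check_positive(ld50_mg_per_kg)
    return ToxLabel.TOXIC if ld50_mg_per_kg <= TOXIC_THRESHOLD_MG_PER_KG else ToxLabel.LESS_OR_NON_TOXIC


def binary_labels(ld50_mg_per_kg) -> np.ndarray:
    """Vectorized binary labeling: 1 = toxic, 0 = less or non-toxic."""
    arr = np.asarray(ld50_mg_per_kg, dtype=float)
    _check_positive(arr)
    return (arr <= TOXIC_THRESHOLD_MG_PER_KG).astype(int)


def assign_ghs_category(ld50_mg_per_kg: float) -> GHSCategory:
    """Map a positive LD50 (mg/kg) to exactly one GHS acute-oral category."""
    _check_positive(ld50_mg_per_kg)
    v = float(ld50_mg_per_kg)
    if v < 5:
        return GHSCategory.CAT1
    if v < 50:
        return GHSCategory.CAT2
    if v <= 300:
        return GHSCategory.CAT3
    if v <= 2000:
        return GHSCategory.CAT4
    if v <= 5000:
        return GHSCategory.CAT5
    return GHSCategory.UNCLASSIFIED


def ghs_categories(ld50_mg_per_kg) -> np.ndarray:
    """Vectorized category assignment; returns an array of category strings."""
    arr = np.asarray(ld50_mg_per_kg, dtype=float)
    _check_positive(arr)
    conds = [arr < 5, arr < 50, arr <= 300, arr <= 2000, arr <= 5000]
    return np.select(conds, ["1", "2", "3", "4", "5"], default="NC")


def log10_transform(ld50_mg_per_kg: float) -> float:
    _check_positive(ld50_mg_per_kg)
    return float(np.log10(ld50_mg_per_kg))


def inverse_log10(x: float) -> float:
    return float(10.0 ** np.asarray(x, dtype=float))


def summarize_counts(ld50_mg_per_kg) -> dict:
    """Dataset bookkeeping: per-GHS-category and binary-label counts.

    Returns ``{"per_category": {cat: n}, "toxic": n, "less_or_non_toxic": n,
    "total": n}``. The binary counts are derived from the same values via the
    300 mg/kg rule, so ``toxic == per_category['1'] + ['2'] + ['3']`` always.
    """
    cats = ghs_categories(ld50_mg_per_kg)
    labels = binary_labels(ld50_mg_per_kg)
    per_category = {c.value: int(np.sum(cats == c.value)) for c in GHSCategory}
    return {
        "per_category": per_category,
        "toxic": int(labels.sum()),
        "less_or_non_toxic": int((1 - labels).sum()),
        "total": int(labels.size),
    }
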