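"""Synthetic compound fixtures with the statistical structure the cascade assumes.

Molecules are assembled from a small fragment grammar (alkane chains with
ether/amine/aromatic/cycloalkyl/halide branches, <= 20 heavy atoms), which
guarantees parseable SMILES and diverse fingerprints without any external
compound library. A designated fraction of molecules carries a nitrile
"toxicophore" fragment; log10 LD50 is then a linear function of fingerprint
bits — a large negative weight on the nitrile's characteristic ECFP4 bit, a
few modest modifier-bit effects, plus Gaussian noise — so the binary toxic
label (LD50 <= 300 mg/kg) is learnable from the fingerprint and the realized
toxic fraction tracks the requested one. The non-toxic baseline sits at
log10 LD50 = 3.3 (~2000 mg/kg), skewing the distribution toward GHS
categories 4 and 5 as in real acute-oral datasets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from rdkit import Chem

from .chem import CompoundRecord, compute_ecfp4
from .labeling import TOXIC_THRESHOLD_MG_PER_KG

BASELINE_LOG_LD50 = 3.3       # non-toxic center, log10 mg/kg (~2000 mg/kg)
TOXICOPHORE_EFFECT = -1.6     # shift for the nitrile bit (-> ~50 mg/kg center)
MODIFIER_EFFECTS = (0.3, -0.25, 0.2)

_BRANCHES = ["C", "CC", "O", "N", "OC", "CCC", "C(C)C", "c1ccccc1",
             "C1CCCCC1", "N(C)C", "OCC", "Cl"]


@dataclass(frozen=True)
class FixtureSpec:
    n_compounds: int
    toxic_fraction: float = 0.25
    effect_bits: tuple | None = None   # explicit bit indices; None = auto-derived
    noise_sd: float = 0.2              # log10 units
    seed: int = 0
    species: str = "mouse"
    n_bits: int = 2048

    def __post_init__(self):
        if self.n_compounds < 50:
            raise ValueError("n_compounds must be >= 50")
        if not 0 < self.toxic_fraction < 1:
            raise ValueError("toxic_fraction must be in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def toxicophore_bit(n_bits: int = 2048) -> int:
    """The ECFP4 bit characteristic of the nitrile group, for a given bit length.

    Computed as the smallest bit set by nitriles of two different chain lengths
    but by neither parent alkane — i.e. a bit that depends only on the C#N
    environment, not on the rest of the molecule.
    """
    on = lambda s: set(np.flatnonzero(compute_ecfp4(s, n_bits)))
    bits = (on("CC#N") & on("CCCC#N")) - (on("CC") | on("CCCC"))
    if not bits:
        raise ValueError(f"no nitrile-specific bit at n_bits={n_bits}; increase n_bits")
    return min(bits)


def _random_molecule(rng: np.random.Generator, with_toxicophore: bool) -> str:
    length = int(rng.integers(3, 9))
    n_branch_sites = max(length - 2, 1)
    n_branches = int(rng.integers(0, min(3, n_branch_sites) + 1))
    positions = rng.choice(np.arange(1, length - 1), size=n_branches, replace=False) \
        if n_branches and length > 2 else []
    atoms = ["C"] * length
    for pos in positions:
        atoms[int(pos)] = "C(" + _BRANCHES[int(rng.integers(len(_BRANCHES)))] + ")"
    smiles = "".join(atoms)
    if with_toxicophore:
        smiles += "C#N"
    return smiles


def _pick_modifier_bits(bits: np.ndarray, exclude: int, rng: np.random.Generator,
                        k: int = 3) -> list[int]:
    """Bits with intermediate prevalence carry regression signal; pick k of them."""
    prevalence = bits.mean(axis=0)
    candidates = np.flatnonzero((prevalence >= 0.15) & (prevalence <= 0.7))
    candidates = candidates[candidates != exclude]
    if len(candidates) < k:
        raise ValueError("fingerprint cohort too uniform to pick modifier bits")
    order = np.lexsort((candidates, np.abs(prevalence[candidates] - 0.4)))
    return [int(candidates[i]) for i in order[:k]]


def generate_fixture(spec: FixtureSpec) -> list[CompoundRecord]:
    """Generate a deterministic synthetic compound table per the spec.

    log10 LD50 = baseline + sum(effect-bit weights over set bits) + noise.
    With the default auto-derived effect bits, the first effect bit is the
    nitrile toxicophore bit (weight -1.6) attached to round(n * toxic_fraction)
    molecules, so the realized toxic fraction matches the requested one to
    within label noise at the 300 mg/kg boundary.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_compounds
    n_tox = int(round(n * spec.toxic_fraction))
    with_tox = np.zeros(n, dtype=bool)
    with_tox[rng.permutation(n)[:n_tox]] = True

    seen: set[str] = set()
    raw, canonical = [], []
    for i in range(n):
        for _ in range(1000):
            smi = _random_molecule(rng, bool(with_tox[i]))
            mol = Chem.MolFromSmiles(smi)
            assert mol is not None, f"fragment grammar produced unparseable SMILES {smi!r}"
            if mol.GetNumHeavyAtoms() > 20:
                continue
            can = Chem.MolToSmiles(mol)
            if can not in seen:
                seen.add(can)
                raw.append(smi)
                canonical.append(can)
                break
        else:
            raise RuntimeError("could not generate enough unique molecules; reduce n_compounds")

    bits = np.vstack([compute_ecfp4(c, spec.n_bits) for c in canonical]).astype(float)

    if spec.effect_bits is not None:
        effect_bits = [int(b) for b in spec.effect_bits]
        weights = [TOXICOPHORE_EFFECT] + [MODIFIER_EFFECTS[j % len(MODIFIER_EFFECTS)]
                                          for j in range(len(effect_bits) - 1)]
    else:
        tox_bit = toxicophore_bit(spec.n_bits)
        effect_bits = [tox_bit] + _pick_modifier_bits(bits, tox_bit, rng)
        weights = [TOXICOPHORE_EFFECT, *MODIFIER_EFFECTS]

    log_ld50 = BASELINE_LOG_LD50 + bits[:, effect_bits] @ np.asarray(weights)
    if spec.noise_sd > 0:
        log_ld50 = log_ld50 + rng.normal(0.0, spec.noise_sd, size=n)

    records = []
    for i in range(n):
        records.append(CompoundRecord(
            compound_id=f"cpd_{i:06d}",
            smiles_raw=raw[i],
            smiles_canonical=canonical[i],
            species=spec.species,
            ld50_mg_per_kg=float(10.0 ** log_ld50[i]),
            log_ld50=float(log_ld50[i]),
        ))
    return records


def worked_confusion_example():
    """A fixed 20-sample (scores, labels) instance with brute-force metrics.

    The expected values are computed here by independent means — exhaustive
    positive/negative pair concordance for AUROC (ties count 1/2) and direct
    formula evaluation for ACC/MCC/PPV/NPV — so they can pin any metric
    implementation.
    """
    scores = np.array([0.95, 0.90, 0.85, 0.80, 0.75, 0.70, 0.65, 0.60, 0.55, 0.50,
                       0.50, 0.45, 0.40, 0.35, 0.30, 0.25, 0.20, 0.15, 0.10, 0.05])
    labels = np.array([1, 1, 0, 1, 1, 0, 1, 0, 1, 1,
                       0, 0, 1, 0, 0, 1, 0, 0, 0, 0])
    threshold = 0.5

    pred = (scores >= threshold).astype(int)
    tp = sum(1 for p, l in zip(pred, labels) if p == 1 and l == 1)
    fp = sum(1 for p, l in zip(pred, labels) if p == 1 and l == 0)
    tn = sum(1 for p, l in zip(pred, labels) if p == 0 and l == 0)
    fn = sum(1 for p, l in zip(pred, labels) if p == 0 and l == 1)

    concordant = 0.0
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    for sp in pos:
        for sn in neg:
            concordant += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    auroc = concordant / (len(pos) * len(neg))

    acc = (tp + tn) / 20
    mcc = (tp * tn - fp * fn) / math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    ppv = tp / (tp + fp)
    npv = tn / (tn + fn)

    expected = {"acc": acc, "auroc": auroc, "mcc": mcc, "ppv": ppv, "npv": npv,
                "confusion": (tp, fp, tn, fn)}
    return scores, labels, expected
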