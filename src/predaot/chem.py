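"""Molecule parsing, canonicalization, ECFP4 featurization, and compound tables.

Compounds enter the pipeline as SMILES strings paired with a species tag and an
LD50 in mg/kg. All downstream modelling works on the canonical SMILES and a
fixed-length ECFP4 (Morgan radius-2, i.e. maximum substructure diameter 4) bit
vector.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

log = logging.getLogger(__name__)

# RDKit writes its own parse diagnostics to stderr; we report failures ourselves.
RDLogger.DisableLog("rdApp.error")

SPECIES = ("mouse", "rat")

REQUIRED_COLUMNS = ("id", "smiles", "species", "ld50_mg_per_kg")


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed; names the offending input."""

    def __init__(self, smiles: str):
        super().__init__(f"unparseable SMILES: {smiles!r}")
        self.smiles = smiles


class SchemaError(ValueError):
    """Raised when a compound table is missing required columns or is empty."""


@dataclass(frozen=True)
class CompoundRecord:
    """One molecule with its species-specific acute oral toxicity.

    ``log_ld50`` is log10 of the mg/kg value; models are trained on this scale.
    """

    compound_id: str
    smiles_raw: str
    smiles_canonical: str
    species: str
    ld50_mg_per_kg: float
    log_ld50: float

    def __post_init__(self):
        if self.species not in SPECIES:
            raise ValueError(f"species must be one of {SPECIES}, got {self.species!r}")
        if not self.ld50_mg_per_kg > 0:
            raise ValueError(f"ld50_mg_per_kg must be positive, got {self.ld50_mg_per_kg}")
        if abs(self.log_ld50 - math.log10(self.ld50_mg_per_kg)) > 1e-9:
            raise ValueError("log_ld50 inconsistent with ld50_mg_per_kg")


@dataclass(frozen=True)
class FingerprintMatrix:
    """ECFP4 bit matrix (n compounds x n_bits) aligned to an id list."""

    ids: tuple[str, ...]
    bits: np.ndarray  # shape (n, n_bits), dtype uint8, values in {0, 1}
    n_bits: int
    diameter: int = 4

    def __post_init__(self):
        if self.bits.shape != (len(self.ids), self.n_bits):
            raise ValueError("bits shape does not match ids / n_bits")


def make_record(compound_id: str, smiles: str, species: str, ld50_mg_per_kg: float,
                strip_salts: bool = True) -> CompoundRecord:
    """Build a validated record, canonicalizing the SMILES."""
    canonical = canonicalize_smiles(smiles, strip_salts=strip_salts)
    return CompoundRecord(
        compound_id=str(compound_id),
        smiles_raw=smiles,
        smiles_canonical=canonical,
        species=species,
        ld50_mg_per_kg=float(ld50_mg_per_kg),
        log_ld50=math.log10(ld50_mg_per_kg),
    )


def _largest_fragment(mol: Chem.Mol) -> Chem.Mol:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return mol
    return max(frags, key=lambda m: m.GetNumHeavyAtoms())


def canonicalize_smiles(smiles: str, strip_salts: bool = True) -> str:
    """Return RDKit's canonical SMILES; idempotent.

    With ``strip_salts`` (default), dot-disconnected salts/mixtures are reduced
    to the largest covalent fragment before canonicalization — the common QSAR
    convention for fingerprint models.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        raise SmilesParseError(smiles)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    if strip_salts and "." in smiles:
        mol = _largest_fragment(mol)
        log.debug("stripped salt/mixture fragments from %r", smiles)
    return Chem.MolToSmiles(mol)


def compute_ecfp4(smiles_canonical: str, n_bits: int = 2048) -> np.ndarray:
    """ECFP4 fingerprint (Morgan, radius 2) hashed to ``n_bits`` bits.

    Deterministic and invariant to SMILES aliases of the same molecule: the
    input is re-parsed, so any parseable SMILES of the molecule yields the
    identical bit vector.
    """
    if n_bits < 64:
        raise ValueError(f"n_bits must be >= 64, got {n_bits}")
    mol = Chem.MolFromSmiles(smiles_canonical)
    if mol is None:
        raise SmilesParseError(smiles_canonical)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    arr = np.zeros(n_bits, dtype=np.uint8)
    arr[list(fp.GetOnBits())] = 1
    return arr


def featurize_records(records: Sequence[CompoundRecord], n_bits: int = 2048) -> FingerprintMatrix:
    """Featurize records into a FingerprintMatrix, caching by canonical SMILES."""
    cache: dict[str, np.ndarray] = {}
    rows = []
    for rec in records:
        row = cache.get(rec.smiles_canonical)
        if row is None:
            row = compute_ecfp4(rec.smiles_canonical, n_bits)
            cache[rec.smiles_canonical] = row
        rows.append(row)
    bits = np.vstack(rows) if rows else np.zeros((0, n_bits), dtype=np.uint8)
    return FingerprintMatrix(ids=tuple(r.compound_id for r in records), bits=bits, n_bits=n_bits)


def _detect_sep(path: Path) -> str:
    header = path.read_text().splitlines()[0] if path.read_text().strip() else ""
    return "\t" if "\t" in header else ","


def read_compound_table(path: str | Path, strip_salts: bool = True,
                        collapse_duplicates: bool = True) -> list[CompoundRecord]:
    """Read a delimited compound table into validated records.

    Required columns: ``id, smiles, species, ld50_mg_per_kg`` (comma or tab
    separated, auto-detected). Rows with unparseable SMILES or non-positive
    LD50 are logged and dropped. Duplicate (canonical SMILES, species) pairs
    are collapsed to a single record whose LD50 is the geometric mean of the
    duplicates — i.e. the arithmetic mean on the log10 scale the models use.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if not path.read_text().strip():
        raise SchemaError(f"empty compound table: {path}")
    df = pd.read_csv(path, sep=_detect_sep(path))
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"compound table {path} missing required columns: {missing}")
    if df.empty:
        raise SchemaError(f"compound table {path} has a header but no rows")

    records: list[CompoundRecord] = []
    n_dropped = 0
    for _, row in df.iterrows():
        ld50 = row["ld50_mg_per_kg"]
        try:
            ld50 = float(ld50)
        except (TypeError, ValueError):
            ld50 = float("nan")
        if not ld50 > 0:
            log.warning("dropping row id=%r: non-positive or invalid LD50 %r", row["id"], row["ld50_mg_per_kg"])
            n_dropped += 1
            continue
        try:
            records.append(make_record(row["id"], str(row["smiles"]), str(row["species"]), ld50,
                                       strip_salts=strip_salts))
        except SmilesParseError:
            log.warning("dropping row id=%r: unparseable SMILES %r", row["id"], row["smiles"])
            n_dropped += 1
        except ValueError as exc:
            log.warning("dropping row id=%r: %s", row["id"], exc)
            n_dropped += 1
    if n_dropped:
        log.info("dropped %d invalid rows from %s", n_dropped, path)
    if collapse_duplicates:
        records = _collapse_duplicates(records)
    return records


def _collapse_duplicates(records: list[CompoundRecord]) -> list[CompoundRecord]:
    """Collapse duplicate (canonical SMILES, species) records; geometric-mean LD50."""
    groups: dict[tuple[str, str], list[CompoundRecord]] = {}
    order: list[tuple[str, str]] = []
    for rec in records:
        key = (rec.smiles_canonical, rec.species)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(rec)
    out = []
    for key in order:
        grp = groups[key]
        if len(grp) == 1:
            out.append(grp[0])
            continue
        mean_log = float(np.mean([r.log_ld50 for r in grp]))
        rep = grp[0]
        log.info("collapsed %d duplicate records of %s (%s) to geometric-mean LD50",
                 len(grp), key[0], key[1])
        out.append(replace(rep, ld50_mg_per_kg=10.0 ** mean_log, log_ld50=mean_log))
    return out


def write_compound_table(records: Iterable[CompoundRecord], path: str | Path, sep: str = ",") -> None:
    """Write records back to a delimited table, with canonical SMILES and log LD50."""
    records = list(records)
    df = pd.DataFrame(
        [
            {
                "id": r.compound_id,
                "smiles": r.smiles_raw,
                "species": r.species,
                "ld50_mg_per_kg": r.ld50_mg_per_kg,
                "smiles_canonical": r.smiles_canonical,
                "log_ld50": r.log_ld50,
            }
            for r in records
        ]
    )
    df.to_csv(path, sep=sep, index=False)
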