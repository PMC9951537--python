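"""Run configuration, stratified train/test split, and the end-to-end pipeline.

Defaults mirror the study protocol: 80/20 stratified split, fivefold CV,
300 mg/kg binary threshold, 2048-bit ECFP4, fold-internal SMOTE. A single
global seed fans out to per-stage seeds through numpy's SeedSequence
(spawn order: split, fixture, training), so one integer reproduces a run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Sequence

import numpy as np

from .cascade import save_bundle, train_cascade
from .chem import CompoundRecord, read_compound_table
from .evaluation import evaluate_cascade
from .labeling import binary_labels
from .resampling import SmoteConfig

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    species: str = "mouse"
    input_path: str = ""
    output_dir: str = "predaot_run"
    split_fraction: float = 0.8
    seed: int = 0
    n_bits: int = 2048
    folds: int = 5
    smote_k_neighbors: int = 5
    smote_target_ratio: float = 1.0
    score_threshold: float = 0.5
    # Comma-separated candidate lists; parsed into the hyperparameter grid.
    grid_n_estimators: str = "100,300,500"
    grid_max_depth: str = "none,16,32"
    grid_max_features: str = "sqrt,0.3"

    def validate(self) -> "RunConfig":
        if self.species not in ("mouse", "rat"):
            raise ConfigError(f"species must be mouse or rat, got {self.species!r}")
        if not 0 < self.split_fraction < 1:
            raise ConfigError(f"split_fraction must be in (0, 1), got {self.split_fraction}")
        if not 0 < self.score_threshold < 1:
            raise ConfigError("score_threshold must be in (0, 1)")
        if self.folds < 2:
            raise ConfigError("folds must be >= 2")
        if self.n_bits < 64:
            raise ConfigError("n_bits must be >= 64")
        return self

    def grid(self) -> dict:
        def parse(tok: str):
            tok = tok.strip()
            if tok.lower() == "none":
                return None
            if tok in ("sqrt", "log2"):
                return tok
            return float(tok) if "." in tok else int(tok)

        return {
            "n_estimators": [parse(t) for t in self.grid_n_estimators.split(",")],
            "max_depth": [parse(t) for t in self.grid_max_depth.split(",")],
            "max_features": [parse(t) for t in self.grid_max_features.split(",")],
        }

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Parse a flat ``key = value`` config file ('#' comments allowed)."""
        known = {f.name: f.type for f in fields(cls)}
        values: dict = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
            key, _, val = (p.strip() for p in line.partition("="))
            if key not in known:
                raise ConfigError(f"{path}:{lineno}: unknown config key {key!r}")
            values[key] = val
        values.update({k: v for k, v in overrides.items() if v is not None})
        coerced = {}
        for f in fields(cls):
            if f.name not in values:
                continue
            raw = values[f.name]
            if isinstance(raw, str) and f.type in ("int", "float"):
                raw = int(raw) if f.type == "int" else float(raw)
            coerced[f.name] = raw
        return cls(**coerced).validate()


def stage_seeds(seed: int) -> dict:
    """Fan a global seed out to per-stage seeds (documented spawn order)."""
    children = np.random.SeedSequence(seed).spawn(3)
    return {name: int(ss.generate_state(1)[0] % (2**31))
            for name, ss in zip(("split", "fixture", "train"), children)}


def split_dataset(records: Sequence[CompoundRecord], fraction: float = 0.8,
                  seed: int = 0) -> tuple[frozenset, frozenset]:
    """Stratified (by binary label) train/test split of compound identifiers.

    Disjoint, exhaustive, per-stratum size within one sample of ``fraction``,
    reproducible by seed.
    """
    if len(records) < 10:
        raise ValueError("need at least 10 records to split")
    if not 0 < fraction < 1:
        raise ConfigError("split fraction must be in (0, 1)")
    ld50 = np.array([r.ld50_mg_per_kg for r in records])
    labels = binary_labels(ld50)
    ids = np.array([r.compound_id for r in records], dtype=object)
    rng = np.random.default_rng(seed)
    train, test = [], []
    for lab in (0, 1):
        stratum = np.flatnonzero(labels == lab)
        stratum = stratum[rng.permutation(len(stratum))]
        n_train = int(round(fraction * len(stratum)))
        train.extend(ids[stratum[:n_train]])
        test.extend(ids[stratum[n_train:]])
    return frozenset(train), frozenset(test)


def run_pipeline(config: RunConfig) -> dict:
    """Read → split → train → evaluate; write bundle and report to output_dir.

    Every stage logs its row counts and seeds. Test rows are never touched
    before the evaluation stage (asserted via the id split). Returns paths of
    the produced artifacts.
    """
    config.validate()
    seeds = stage_seeds(config.seed)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    records = read_compound_table(config.input_path)
    records = [r for r in records if r.species == config.species]
    if not records:
        raise ValueError(f"no {config.species} records in {config.input_path}")
    log.info("stage=read species=%s n=%d", config.species, len(records))

    train_ids, test_ids = split_dataset(records, config.split_fraction, seeds["split"])
    assert not (train_ids & test_ids)
    train_recs = [r for r in records if r.compound_id in train_ids]
    test_recs = [r for r in records if r.compound_id in test_ids]
    log.info("stage=split seed=%d n_train=%d n_test=%d", seeds["split"],
             len(train_recs), len(test_recs))

    model = train_cascade(
        train_recs,
        n_bits=config.n_bits,
        classifier_grid=config.grid(),
        regressor_grid=config.grid(),
        smote=SmoteConfig(config.smote_k_neighbors, config.smote_target_ratio,
                          seed=seeds["train"]),
        folds=config.folds,
        seed=seeds["train"],
        score_threshold=config.score_threshold,
    )
    bundle_dir = out / "bundle"
    save_bundle(model, bundle_dir)
    log.info("stage=train seed=%d bundle=%s cv=%s", seeds["train"], bundle_dir, model.cv_scores)

    report = evaluate_cascade(model, test_recs)
    report_json = out / "report.json"
    report_json.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
    report_txt = out / "report.txt"
    report_txt.write_text(report.to_text() + "\n")
    log.info("stage=evaluate n_test=%d report=%s", len(test_recs), report_json)

    return {"bundle": str(bundle_dir), "report_json": str(report_json),
            "report_txt": str(report_txt)}
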