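"""The classify-then-regress cascade: one classifier routing to two regressors.

A compound is first classified toxic (LD50 <= 300 mg/kg) or less-or-non-toxic
from its ECFP4 fingerprint; its quantitative log10 LD50 is then predicted by
the regressor trained only on that regime's compounds. Exactly one regressor
is consulted per compound, and its output is not clipped to the regime — a
toxic-routed compound may receive a predicted LD50 slightly above 300 mg/kg;
the reported GHS category always derives from the predicted mg/kg value, with
a flag set when it disagrees with the classifier's label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np

from .chem import CompoundRecord, SmilesParseError, canonicalize_smiles, compute_ecfp4
from .dataset import LabeledDataset, build_dataset
from .labeling import TOXIC_THRESHOLD_MG_PER_KG, GHSCategory, ToxLabel, assign_ghs_category
from .learners import (
    DEFAULT_CLASSIFIER_GRID,
    DEFAULT_REGRESSOR_GRID,
    HyperGrid,
    grid_search_cv,
    make_model,
)
from .resampling import SmoteConfig

BUNDLE_FORMAT_VERSION = 1


@dataclass
class CascadeModel:
    species: str
    classifier: object
    toxic_regressor: object
    nontoxic_regressor: object
    n_bits: int
    score_threshold: float = 0.5
    threshold_mg_per_kg: float = TOXIC_THRESHOLD_MG_PER_KG
    hyperparams: dict = field(default_factory=dict)
    train_ids: frozenset = field(default_factory=frozenset)
    cv_scores: dict = field(default_factory=dict)


@dataclass(frozen=True)
class Prediction:
    compound_id: str
    species: str
    predicted_label: ToxLabel
    classifier_score: float
    predicted_log_ld50: float
    predicted_ld50_mg_per_kg: float
    predicted_ghs_category: GHSCategory
    label_category_disagreement: bool


def train_cascade(records: Sequence[CompoundRecord], n_bits: int = 2048,
                  classifier_grid: dict | None = None, regressor_grid: dict | None = None,
                  smote: SmoteConfig | None = None, folds: int = 5, seed: int = 0,
                  score_threshold: float = 0.5) -> CascadeModel:
    """Train the full cascade for one species.

    The classifier is grid-searched (fivefold stratified CV, fold-internal
    SMOTE, selected by accuracy) on all training records; each regressor is
    grid-searched (fivefold CV, selected by RMSE on log10 LD50) on its regime
    only — the two regressor training sets partition the records by the binary
    label. All three share the featurization config.
    """
    ds = build_dataset(records, n_bits=n_bits)
    n_neg, n_pos = ds.class_counts
    if n_pos < folds or n_neg < folds:
        raise ValueError(
            f"each regime needs >= {folds} compounds for {folds}-fold CV "
            f"(got toxic={n_pos}, less_or_non_toxic={n_neg})"
        )
    rng = np.random.default_rng(seed)
    seeds = {k: int(rng.integers(2**31)) for k in
             ("cls_search", "tox_search", "nontox_search", "cls_fit", "tox_fit", "nontox_fit", "smote")}
    if smote is None:
        smote = SmoteConfig(seed=seeds["smote"])

    cls_grid = HyperGrid(classifier_grid or DEFAULT_CLASSIFIER_GRID)
    reg_grid = HyperGrid(regressor_grid or DEFAULT_REGRESSOR_GRID)

    toxic_ds = ds.subset(ds.y_label == 1)
    nontoxic_ds = ds.subset(ds.y_label == 0)

    cls_params, cls_cv_acc = grid_search_cv(ds, cls_grid, "classification", folds=folds,
                                            smote=smote, seed=seeds["cls_search"])
    tox_params, tox_cv_rmse = grid_search_cv(toxic_ds, reg_grid, "regression", folds=folds,
                                             seed=seeds["tox_search"])
    nontox_params, nontox_cv_rmse = grid_search_cv(nontoxic_ds, reg_grid, "regression", folds=folds,
                                                   seed=seeds["nontox_search"])

    from .resampling import balance_training_fold

    balanced = balance_training_fold(ds, SmoteConfig(smote.k_neighbors, smote.target_ratio,
                                                     seed=smote.seed))
    classifier = make_model("classification", cls_params, seeds["cls_fit"])
    classifier.fit(balanced.X, balanced.y_label)
    toxic_regressor = make_model("regression", tox_params, seeds["tox_fit"])
    toxic_regressor.fit(toxic_ds.X, toxic_ds.y_log)
    nontoxic_regressor = make_model("regression", nontox_params, seeds["nontox_fit"])
    nontoxic_regressor.fit(nontoxic_ds.X, nontoxic_ds.y_log)

    return CascadeModel(
        species=ds.species,
        classifier=classifier,
        toxic_regressor=toxic_regressor,
        nontoxic_regressor=nontoxic_regressor,
        n_bits=n_bits,
        score_threshold=score_threshold,
        hyperparams={"classifier": cls_params, "toxic_regressor": tox_params,
                     "nontoxic_regressor": nontox_params},
        train_ids=frozenset(str(i) for i in ds.ids),
        cv_scores={"classifier_cv_acc": cls_cv_acc, "toxic_cv_rmse": tox_cv_rmse,
                   "nontoxic_cv_rmse": nontox_cv_rmse},
    )


def _predict_from_fp(model: CascadeModel, fp: np.ndarray, compound_id: str) -> Prediction:
    X = fp.reshape(1, -1).astype(np.float64)
    score = float(model.classifier.predict_proba(X)[0, 1])
    is_toxic = score >= model.score_threshold
    regressor = model.toxic_regressor if is_toxic else model.nontoxic_regressor
    log_ld50 = float(regressor.predict(X)[0])
    ld50 = float(10.0 ** log_ld50)
    label = ToxLabel.TOXIC if is_toxic else ToxLabel.LESS_OR_NON_TOXIC
    category = assign_ghs_category(ld50)
    disagree = category.is_toxic != is_toxic
    return Prediction(
        compound_id=compound_id,
        species=model.species,
        predicted_label=label,
        classifier_score=score,
        predicted_log_ld50=log_ld50,
        predicted_ld50_mg_per_kg=ld50,
        predicted_ghs_category=category,
        label_category_disagreement=disagree,
    )


def predict(model: CascadeModel, smiles: str, compound_id: str = "query") -> Prediction:
    """Predict one compound; raises SmilesParseError on unparseable input."""
    canonical = canonicalize_smiles(smiles)
    fp = compute_ecfp4(canonical, model.n_bits)
    return _predict_from_fp(model, fp, compound_id)


def predict_batch(model: CascadeModel, smiles_list: Sequence[str],
                  ids: Sequence[str] | None = None):
    """Predict a batch, order-preserving; parse failures become error entries.

    Returns (predictions, errors): predictions is a list with one Prediction
    per valid input, errors a list of (index, smiles, message).
    """
    if ids is None:
        ids = [f"q{i}" for i in range(len(smiles_list))]
    predictions, errors = [], []
    for i, (cid, smi) in enumerate(zip(ids, smiles_list)):
        try:
            predictions.append(predict(model, smi, compound_id=str(cid)))
        except SmilesParseError as exc:
            errors.append((i, smi, str(exc)))
    return predictions, errors


def predict_both_species(mouse_model: CascadeModel, rat_model: CascadeModel, smiles: str,
                         compound_id: str = "query") -> tuple:
    """Two independent predictions sharing one featurization pass."""
    for m, sp in ((mouse_model, "mouse"), (rat_model, "rat")):
        if m is None:
            raise ValueError(f"{sp} model is not loaded")
    if mouse_model.n_bits != rat_model.n_bits:
        raise ValueError("models disagree on fingerprint length")
    canonical = canonicalize_smiles(smiles)
    fp = compute_ecfp4(canonical, mouse_model.n_bits)
    return (_predict_from_fp(mouse_model, fp, compound_id),
            _predict_from_fp(rat_model, fp, compound_id))


def save_bundle(model: CascadeModel, path: str | Path) -> None:
    """Serialize a trained cascade to a versioned on-disk bundle directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "format_version": BUNDLE_FORMAT_VERSION,
        "species": model.species,
        "n_bits": model.n_bits,
        "score_threshold": model.score_threshold,
        "threshold_mg_per_kg": model.threshold_mg_per_kg,
        "hyperparams": model.hyperparams,
        "cv_scores": model.cv_scores,
        "train_ids": sorted(model.train_ids),
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=2, default=str))
    joblib.dump({"classifier": model.classifier, "toxic_regressor": model.toxic_regressor,
                 "nontoxic_regressor": model.nontoxic_regressor}, path / "models.joblib")


def load_bundle(path: str | Path) -> CascadeModel:
    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"not a model bundle (no meta.json): {path}")
    meta = json.loads(meta_path.read_text())
    if meta["format_version"] != BUNDLE_FORMAT_VERSION:
        raise ValueError(f"unsupported bundle format version {meta['format_version']}")
    models = joblib.load(path / "models.joblib")
    return CascadeModel(
        species=meta["species"],
        classifier=models["classifier"],
        toxic_regressor=models["toxic_regressor"],
        nontoxic_regressor=models["nontoxic_regressor"],
        n_bits=meta["n_bits"],
        score_threshold=meta["score_threshold"],
        threshold_mg_per_kg=meta["threshold_mg_per_kg"],
        hyperparams=meta["hyperparams"],
        train_ids=frozenset(meta["train_ids"]),
        cv_scores=meta["cv_scores"],
    )
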