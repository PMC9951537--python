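"""Evaluation reports: classification metrics, per-regime and per-GHS-category
regression error, and rank correlations against external predictors.

Regime RMSE/R^2 are computed on the log10 mg/kg scale; per-category RMSE is on
the raw mg/kg scale (the only scale on which the large-category errors are
meaningful). Regime metrics are reported twice — routed by the true binary
label and by the predicted label — with the truth-routed variant as the
headline, since either routing is defensible for a cascade.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cascade import CascadeModel, _predict_from_fp
from .chem import CompoundRecord
from .dataset import build_dataset
from .labeling import GHSCategory
from .learners import (
    ClassifierMetrics,
    RegressorMetrics,
    compute_classifier_metrics,
    compute_regressor_metrics,
    rank_correlations,
)

log = logging.getLogger(__name__)

_CAT_ORDER = [c.value for c in GHSCategory]


@dataclass
class EvaluationReport:
    species: str
    n_test: int
    classifier_metrics: ClassifierMetrics
    regressor_metrics: dict            # {"truth_routed"/"prediction_routed": {"toxic"/"less_or_non_toxic": RegressorMetrics}}
    per_category_rmse_mg_per_kg: dict  # category -> RMSE (mg/kg); absent categories omitted
    per_category_counts: dict          # category -> n (all categories, possibly 0)
    binary_counts: dict                # {"toxic": n, "less_or_non_toxic": n}
    correlations: tuple                # (pearson_r, spearman_r) on log10 scale
    ids: np.ndarray = field(repr=False, default=None)
    pred_log: np.ndarray = field(repr=False, default=None)
    truth_log: np.ndarray = field(repr=False, default=None)
    categories: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        cm = self.classifier_metrics
        return {
            "species": self.species,
            "n_test": self.n_test,
            "classifier": {"acc": cm.acc, "auroc": cm.auroc, "mcc": cm.mcc,
                           "ppv": cm.ppv, "npv": cm.npv,
                           "confusion_tp_fp_tn_fn": list(cm.confusion)},
            "regression_log10": {
                routing: {regime: {"rmse": m.rmse, "r2": m.r2, "n": m.n}
                          for regime, m in regimes.items()}
                for routing, regimes in self.regressor_metrics.items()
            },
            "per_category_rmse_mg_per_kg": self.per_category_rmse_mg_per_kg,
            "per_category_counts": self.per_category_counts,
            "binary_counts": self.binary_counts,
            "correlations": {"pearson_r": self.correlations[0], "spearman_r": self.correlations[1]},
        }

    def to_text(self) -> str:
        cm = self.classifier_metrics
        fmt = lambda v: "undef" if v is None else f"{v:.4f}"
        lines = [
            f"Evaluation report — species: {self.species}, n_test: {self.n_test}",
            "",
            "Classifier (test set)",
            f"  ACC {fmt(cm.acc)}  AUROC {fmt(cm.auroc)}  MCC {fmt(cm.mcc)}  "
            f"PPV {fmt(cm.ppv)}  NPV {fmt(cm.npv)}",
            f"  confusion TP/FP/TN/FN: {cm.confusion}",
            "",
            "Regression (log10 mg/kg)",
        ]
        for routing, regimes in self.regressor_metrics.items():
            for regime, m in regimes.items():
                lines.append(f"  [{routing}] {regime:<18} RMSE {fmt(m.rmse)}  R2 {fmt(m.r2)}  (n={m.n})")
        lines += ["", "Per-GHS-category RMSE (mg/kg scale)"]
        for cat in _CAT_ORDER:
            n = self.per_category_counts.get(cat, 0)
            if cat in self.per_category_rmse_mg_per_kg:
                lines.append(f"  category {cat:<3} RMSE {self.per_category_rmse_mg_per_kg[cat]:10.2f}  (n={n})")
            else:
                lines.append(f"  category {cat:<3} (empty, n=0)")
        p, s = self.correlations
        lines += ["", f"Correlations (log10): Pearson r {fmt(p)}, Spearman r {fmt(s)}"]
        return "\n".join(lines)


def per_category_rmse(pred_mg_per_kg, truth_mg_per_kg, categories) -> dict:
    """RMSE on the untransformed mg/kg scale within each true GHS category.

    Empty categories are omitted from the returned map (not NaN-propagated);
    the companion count map covers every category.
    """
    pred = np.asarray(pred_mg_per_kg, dtype=float)
    truth = np.asarray(truth_mg_per_kg, dtype=float)
    cats = np.asarray(categories)
    if not (pred.shape == truth.shape == cats.shape):
        raise ValueError("pred, truth and categories must be aligned")
    out = {}
    for cat in _CAT_ORDER:
        mask = cats == cat
        if mask.any():
            out[cat] = float(np.sqrt(np.mean((pred[mask] - truth[mask]) ** 2)))
    return out


def _pooled_grouped_identity(pred_mg, truth_mg, cats, rmse_map, counts):
    """Exact identity: count-weighted mean of per-category MSE == pooled MSE."""
    pooled = float(np.mean((np.asarray(pred_mg) - np.asarray(truth_mg)) ** 2))
    weighted = sum(counts[c] * rmse_map[c] ** 2 for c in rmse_map) / sum(
        counts[c] for c in rmse_map)
    if not np.isclose(pooled, weighted, rtol=1e-9, atol=1e-9):
        raise AssertionError(
            f"pooled-vs-grouped MSE identity violated: pooled={pooled!r}, grouped={weighted!r}")


def evaluate_cascade(model: CascadeModel, test: Sequence[CompoundRecord]) -> EvaluationReport:
    """Evaluate a trained cascade on held-out records.

    Test identifiers must be disjoint from the model's training identifiers
    (hard error otherwise — leakage guard). All metrics are computed: the
    classifier table, per-regime RMSE/R^2 on log10 LD50 under both routings,
    per-true-category RMSE in mg/kg for the cascade's final predictions, and
    Pearson/Spearman correlations between predicted and true log10 LD50.
    """
    ds = build_dataset(test, n_bits=model.n_bits)
    overlap = set(str(i) for i in ds.ids) & set(model.train_ids)
    if overlap:
        raise ValueError(f"test set overlaps training identifiers: {sorted(overlap)[:5]}...")

    scores = model.classifier.predict_proba(ds.X)[:, 1]
    cls_metrics = compute_classifier_metrics(scores, ds.y_label, threshold=model.score_threshold)
    pred_label = (scores >= model.score_threshold).astype(int)

    pred_tox = model.toxic_regressor.predict(ds.X)
    pred_nontox = model.nontoxic_regressor.predict(ds.X)
    pred_log = np.where(pred_label == 1, pred_tox, pred_nontox)  # the cascade's output

    regressor_metrics = {}
    for routing, route in (("truth_routed", ds.y_label), ("prediction_routed", pred_label)):
        regimes = {}
        for regime, lab in (("toxic", 1), ("less_or_non_toxic", 0)):
            mask = route == lab
            if mask.any():
                routed_pred = np.where(route == 1, pred_tox, pred_nontox)[mask]
                regimes[regime] = compute_regressor_metrics(routed_pred, ds.y_log[mask])
            else:
                regimes[regime] = RegressorMetrics(rmse=float("nan"), r2=None, n=0,
                                                   undefined=("rmse", "r2"))
        regressor_metrics[routing] = regimes

    pred_mg = 10.0 ** pred_log
    truth_mg = 10.0 ** ds.y_log
    rmse_map = per_category_rmse(pred_mg, truth_mg, ds.categories)
    counts = {c: int(np.sum(ds.categories == c)) for c in _CAT_ORDER}
    _pooled_grouped_identity(pred_mg, truth_mg, ds.categories, rmse_map, counts)

    corr = rank_correlations(pred_log, ds.y_log) if len(ds) >= 3 else (None, None)

    return EvaluationReport(
        species=model.species,
        n_test=len(ds),
        classifier_metrics=cls_metrics,
        regressor_metrics=regressor_metrics,
        per_category_rmse_mg_per_kg=rmse_map,
        per_category_counts=counts,
        binary_counts={"toxic": int(ds.y_label.sum()),
                       "less_or_non_toxic": int((1 - ds.y_label).sum())},
        correlations=corr,
        ids=np.asarray(ds.ids),
        pred_log=pred_log,
        truth_log=ds.y_log,
        categories=ds.categories,
    )


def compare_predictors(report: EvaluationReport, external_predictions: pd.DataFrame,
                       name: str = "external", mg_per_kg_scale: bool = False) -> pd.DataFrame:
    """Side-by-side comparison of the cascade with an external predictor.

    ``external_predictions`` needs columns ``id`` and ``prediction``. Ids that
    do not match the report's test set are listed and excluded with a warning.
    If the external predictor reports LD50 in mg/kg, per-category RMSE is
    compared on that scale; on an arbitrary (possibly monotone-transformed)
    scale only correlations are reported, since RMSE would be meaningless.
    """
    if report.ids is None:
        raise ValueError("report carries no per-compound predictions")
    missing = [c for c in ("id", "prediction") if c not in external_predictions.columns]
    if missing:
        raise ValueError(f"external predictions missing columns: {missing}")
    ext = external_predictions.set_index(external_predictions["id"].astype(str))["prediction"]
    own_ids = np.array([str(i) for i in report.ids])
    matched = np.isin(own_ids, ext.index.to_numpy())
    unmatched_ext = sorted(set(ext.index) - set(own_ids))
    if unmatched_ext or not matched.all():
        log.warning("excluded %d external-only and %d test-only ids from comparison",
                    len(unmatched_ext), int((~matched).sum()))
    idx = np.where(matched)[0]
    if idx.size < 3:
        raise ValueError("fewer than 3 aligned compounds; cannot compare")
    ext_vals = ext.loc[own_ids[idx]].to_numpy(dtype=float)
    truth_log = report.truth_log[idx]
    own_log = report.pred_log[idx]
    cats = report.categories[idx]

    rows = []
    own_p, own_s = rank_correlations(own_log, truth_log)
    rows.append({"predictor": "predaot", "scope": "correlation",
                 "pearson_r": own_p, "spearman_r": own_s})
    if mg_per_kg_scale:
        ext_log = np.log10(np.clip(ext_vals, np.finfo(float).tiny, None))
        ext_p, ext_s = rank_correlations(ext_log, truth_log)
        truth_mg = 10.0 ** truth_log
        for pname, pred_mg in (("predaot", 10.0 ** own_log), (name, ext_vals)):
            for cat, rmse in per_category_rmse(pred_mg, truth_mg, cats).items():
                rows.append({"predictor": pname, "scope": f"category_{cat}_rmse_mg_per_kg",
                             "rmse": rmse})
    else:
        ext_p, ext_s = rank_correlations(ext_vals, truth_log)
    rows.insert(1, {"predictor": name, "scope": "correlation",
                    "pearson_r": ext_p, "spearman_r": ext_s})
    return pd.DataFrame(rows)
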