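"""Gradient-boosted tree classification and cross-dataset transfer.

A pre-tuned XGBoost ensemble (eta 0.7, 20 rounds, gamma 0.001, max depth
5, min child weight 10) is trained on a stratified random 80% of the
source dataset's binned features, evaluated on the held-out 20%, and
applied to the target. Two modes:

* **multiclass** — one softmax model over all source cell types; each
  target cell gets a probability row summing to 1.
* **per-type binary** — one logistic model per source cell type
  (positive = that type, negative = every other source cell), with the
  label-dependent feature-selection steps re-run per type. A target cell
  whose maximal per-type score falls below a threshold is assigned
  ``"unknown"``, flagging candidate novel cell types.

Binned codes are fed to the trees as ordinal integers 0-3; tree splits
handle ordinals natively.
"""

from __future__ import annotations

import json
import logging
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.model_selection import train_test_split

from ._errors import DegenerateDataError, InputError
from .core_data import GeneExpressionDataset, source_usable_mask
from .evaluate import accuracy, majority_vote_accuracy
from .feature_engineering import (
    BinnedMatrix,
    FeatureSet,
    prepare_pooled,
    select_and_bin,
)

__all__ = [
    "DEFAULT_HYPERPARAMETERS",
    "UNKNOWN_LABEL",
    "CastleModel",
    "ScoreMatrix",
    "TransferResult",
    "train_model",
    "predict",
    "run_multiclass",
    "run_per_type",
    "assign_with_threshold",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

UNKNOWN_LABEL = "unknown"

#: Pre-tuned boosting parameters; nround is the number of boosting rounds.
DEFAULT_HYPERPARAMETERS = {
    "eta": 0.7,
    "nround": 20,
    "gamma": 0.001,
    "max_depth": 5,
    "min_child_weight": 10,
}


@dataclass
class CastleModel:
    """A trained ensemble bound to its feature set and class order."""

    ensemble: xgb.XGBClassifier
    feature_set: FeatureSet
    class_order: list[str]
    mode: str  # "multiclass" or "binary:<type>"
    hyperparameters: dict
    train_seed: int


@dataclass
class ScoreMatrix:
    """Cells x cell-types membership scores in [0, 1].

    Multiclass rows sum to 1; in per-type mode each column comes from an
    independent binary classifier, so rows need not sum to 1.
    """

    scores: np.ndarray
    cell_ids: list[str]
    type_ids: list[str]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.shape != (len(self.cell_ids), len(self.type_ids)):
            raise InputError(
                f"score shape {self.scores.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.type_ids)} types"
            )
        if self.scores.size and (
            self.scores.min() < -1e-9 or self.scores.max() > 1 + 1e-9
        ):
            raise InputError("scores must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.cell_ids, columns=self.type_ids)


@dataclass
class TransferResult:
    """Per-repeat accuracies of a transfer run plus the majority-vote floor."""

    predicted_labels: list[str]
    heldout_accuracy_runs: list[float]
    target_accuracy_runs: list[float]
    majority_vote_accuracy: float
    scores: ScoreMatrix | None = None
    feature_set: FeatureSet | None = None

    def __post_init__(self) -> None:
        if len(self.heldout_accuracy_runs) != len(self.target_accuracy_runs):
            raise InputError("held-out and target accuracy lists must have equal length")

    @property
    def n_repeats(self) -> int:
        return len(self.heldout_accuracy_runs)

    @property
    def heldout_mean(self) -> float:
        return float(np.mean(self.heldout_accuracy_runs))

    @property
    def heldout_sd(self) -> float:
        return float(np.std(self.heldout_accuracy_runs, ddof=1)) if self.n_repeats > 1 else 0.0

    @property
    def target_mean(self) -> float:
        return float(np.mean(self.target_accuracy_runs))

    @property
    def target_sd(self) -> float:
        return float(np.std(self.target_accuracy_runs, ddof=1)) if self.n_repeats > 1 else 0.0


def _make_classifier(hp: dict, n_classes: int, seed: int) -> xgb.XGBClassifier:
    objective = "multi:softprob" if n_classes > 2 else "binary:logistic"
    return xgb.XGBClassifier(
        n_estimators=int(hp.get("nround", 20)),
        learning_rate=float(hp.get("eta", 0.7)),
        gamma=float(hp.get("gamma", 0.001)),
        max_depth=int(hp.get("max_depth", 5)),
        min_child_weight=float(hp.get("min_child_weight", 10)),
        objective=objective,
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
        base_score=0.5,
    )


def train_model(
    source_binned: BinnedMatrix,
    labels,
    mode: str = "multiclass",
    hyperparameters: dict | None = None,
    train_frac: float = 0.8,
    seed: int = 0,
    feature_set: FeatureSet | None = None,
) -> tuple[CastleModel, float]:
    """Train on a stratified random ``train_frac`` of the source.

    Returns the model and its accuracy (percent) on the held-out cells.
    """
    hp = dict(DEFAULT_HYPERPARAMETERS, **(hyperparameters or {}))
    labels = np.asarray([str(l) for l in labels])
    if len(labels) != source_binned.codes.shape[0]:
        raise InputError("labels must align with binned source cells")
    class_order = sorted(np.unique(labels).tolist())
    if len(class_order) < 2:
        raise DegenerateDataError("training requires at least two classes")
    y = np.searchsorted(np.asarray(class_order), labels)

    idx = np.arange(len(labels))
    try:
        train_idx, test_idx = train_test_split(
            idx, train_size=train_frac, stratify=y, random_state=seed
        )
    except ValueError as e:
        raise DegenerateDataError(
            "stratified split failed (a class has too few cells to appear in "
            f"both folds; merge or drop rare classes): {e}"
        ) from e
    if len(np.unique(y[train_idx])) < len(class_order):
        raise DegenerateDataError(
            "a class is absent from the training split; too few cells per class"
        )

    clf = _make_classifier(hp, len(class_order), seed)
    X = source_binned.codes.astype(np.float32)
    clf.fit(X[train_idx], y[train_idx])
    heldout = 100.0 * float(np.mean(clf.predict(X[test_idx]) == y[test_idx]))

    fset = feature_set or FeatureSet(
        genes=list(source_binned.feature_ids),
        provenance={g: ["mi_selected"] for g in source_binned.feature_ids},
        bin_edges=source_binned.edge_spec,
    )
    model = CastleModel(clf, fset, class_order, mode, hp, seed)
    return model, heldout


def predict(model: CastleModel, target_binned: BinnedMatrix) -> ScoreMatrix:
    """Score every target cell against every class of the model."""
    if list(target_binned.feature_ids) != list(model.feature_set.genes):
        missing = set(model.feature_set.genes) - set(target_binned.feature_ids)
        extra = set(target_binned.feature_ids) - set(model.feature_set.genes)
        raise InputError(
            f"target features do not match the model: missing {sorted(missing)[:5]}, "
            f"extra {sorted(extra)[:5]}"
        )
    proba = model.ensemble.predict_proba(target_binned.codes.astype(np.float32))
    if proba.shape[1] == 2 and len(model.class_order) == 2:
        scores = proba  # binary: keep both class columns, ordered by class_order
    else:
        scores = proba
    if model.mode == "multiclass":
        scores = scores / scores.sum(axis=1, keepdims=True)
    cell_ids = [f"cell{i}" for i in range(scores.shape[0])]
    return ScoreMatrix(scores, cell_ids, list(model.class_order))


def assign_with_threshold(scores: ScoreMatrix, threshold: float) -> list[str]:
    """Argmax label per cell, or ``"unknown"`` when the max score is below
    the threshold. Ties go to the first type in column order."""
    if not scores.type_ids:
        raise InputError("score matrix has no type columns")
    out = []
    for row in scores.scores:
        j = int(np.argmax(row))  # argmax takes the first maximum: the tie-break
        out.append(scores.type_ids[j] if row[j] >= threshold else UNKNOWN_LABEL)
    return out


def run_multiclass(
    source: GeneExpressionDataset,
    target: GeneExpressionDataset,
    n_repeats: int = 10,
    base_seed: int = 0,
    k: int = 100,
    r_max: float = 0.9,
    min_cells: int = 10,
    hyperparameters: dict | None = None,
    train_frac: float = 0.8,
) -> TransferResult:
    """Multiclass transfer: train on the source, classify the target.

    Features are engineered once on the full (usable) source plus target;
    each repeat redraws only the stratified 80/20 split, so run-to-run
    variation isolates the split. Target accuracy is evaluated against the
    target's labels, skipping cells with excluded annotations; the
    majority-vote floor (share of target cells carrying the source's most
    frequent label) is reported alongside.
    """
    usable = source_usable_mask(source.labels)
    src = source.subset_cells(usable)
    if src.n_cells == 0:
        raise DegenerateDataError("no usable source cells after label exclusion")
    fset, src_binned, tgt_binned = _engineer(src, target, src.labels, k, r_max, min_cells)

    heldout_runs: list[float] = []
    target_runs: list[float] = []
    score_sum: np.ndarray | None = None
    class_order: list[str] = []
    for rep in range(n_repeats):
        seed = base_seed + rep
        model, heldout = train_model(
            src_binned, src.labels, "multiclass", hyperparameters,
            train_frac=train_frac, seed=seed, feature_set=fset,
        )
        sm = predict(model, tgt_binned)
        preds = [sm.type_ids[j] for j in np.argmax(sm.scores, axis=1)]
        target_runs.append(accuracy(target.labels, preds))
        heldout_runs.append(heldout)
        score_sum = sm.scores if score_sum is None else score_sum + sm.scores
        class_order = sm.type_ids
        logger.info(
            "repeat %d: held-out %.1f%%, target %.1f%%", rep, heldout, target_runs[-1]
        )

    mean_scores = score_sum / n_repeats
    final_scores = ScoreMatrix(mean_scores, list(target.cell_ids), class_order)
    predicted = [class_order[j] for j in np.argmax(mean_scores, axis=1)]
    mv = majority_vote_accuracy(src.labels, target.labels)
    return TransferResult(predicted, heldout_runs, target_runs, mv,
                          scores=final_scores, feature_set=fset)


def run_per_type(
    source: GeneExpressionDataset,
    target: GeneExpressionDataset,
    threshold: float = 0.8,
    n_repeats: int = 1,
    base_seed: int = 0,
    k: int = 100,
    r_max: float = 0.9,
    min_cells: int = 10,
    hyperparameters: dict | None = None,
    train_frac: float = 0.8,
) -> tuple[ScoreMatrix, list[str]]:
    """One binary classifier per source cell type; threshold-based assignment.

    The label-independent steps (gene alignment, rare-gene filtering,
    top-mean selection) run once; the label-dependent selection and the
    classifier are re-run per type against that type's 0/1 indicator.
    Target cells whose best per-type score falls below ``threshold`` are
    labeled ``"unknown"`` — candidates for cell types absent from the source.
    """
    usable = source_usable_mask(source.labels)
    src = source.subset_cells(usable)
    if src.n_cells == 0:
        raise DegenerateDataError("no usable source cells after label exclusion")
    prep = prepare_pooled(src, target, k=k, min_cells=min_cells)

    types = sorted(set(src.labels))
    if not types:
        raise DegenerateDataError("no source cell types")
    columns: dict[str, np.ndarray] = {}
    src_labels = np.asarray(src.labels)
    for t in types:
        pos = src_labels == t
        if pos.sum() < 2 or (~pos).sum() < 2:
            warnings.warn(
                f"cell type {t!r} has too few positive or negative source cells; skipped",
                stacklevel=2,
            )
            continue
        indicator = np.where(pos, "positive", "negative")
        fset, src_binned, tgt_binned = select_and_bin(prep, indicator, k=k, r_max=r_max)
        col_sum = np.zeros(target.n_cells)
        for rep in range(n_repeats):
            model, heldout = train_model(
                src_binned, indicator, f"binary:{t}", hyperparameters,
                train_frac=train_frac, seed=base_seed + rep, feature_set=fset,
            )
            sm = predict(model, tgt_binned)
            col_sum += sm.scores[:, sm.type_ids.index("positive")]
        columns[t] = col_sum / n_repeats
        logger.info("type %s: %d features, last held-out %.1f%%",
                    t, len(fset.genes), heldout)

    if not columns:
        raise DegenerateDataError("no cell type had enough cells to train")
    type_ids = sorted(columns)
    scores = ScoreMatrix(
        np.column_stack([columns[t] for t in type_ids]),
        list(target.cell_ids),
        type_ids,
    )
    return scores, assign_with_threshold(scores, threshold)


def _engineer(src, target, labels, k, r_max, min_cells):
    from .feature_engineering import engineer_features

    return engineer_features(src, target, labels, k=k, r_max=r_max, min_cells=min_cells)


def save_model(model: CastleModel, bundle_dir: str) -> None:
    """Persist a model as a directory bundle (ensemble dump + JSON metadata)."""
    os.makedirs(bundle_dir, exist_ok=True)
    # persist the booster itself; the sklearn wrapper is rebuilt on load
    model.ensemble.get_booster().save_model(os.path.join(bundle_dir, "ensemble.json"))
    with open(os.path.join(bundle_dir, "featureset.json"), "w") as fh:
        fh.write(model.feature_set.to_json())
    with open(os.path.join(bundle_dir, "metadata.json"), "w") as fh:
        json.dump(
            {
                "mode": model.mode,
                "class_order": model.class_order,
                "hyperparameters": model.hyperparameters,
                "train_seed": model.train_seed,
            },
            fh,
            indent=2,
        )


def load_model(bundle_dir: str) -> CastleModel:
    with open(os.path.join(bundle_dir, "metadata.json")) as fh:
        meta = json.load(fh)
    with open(os.path.join(bundle_dir, "featureset.json")) as fh:
        fset = FeatureSet.from_json(fh.read())
    clf = _make_classifier(meta["hyperparameters"], len(meta["class_order"]), meta["train_seed"])
    booster = xgb.Booster()
    booster.load_model(os.path.join(bundle_dir, "ensemble.json"))
    clf._Booster = booster
    clf.n_classes_ = len(meta["class_order"])
    return CastleModel(clf, fset, meta["class_order"], meta["mode"],
                       meta["hyperparameters"], meta["train_seed"])
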