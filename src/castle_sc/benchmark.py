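"""A deliberately simple transfer baseline to compare against.

Select the five genes with the highest mean expression over the pooled
cells of both datasets and fit an ordinary least-squares regression on
their continuous log-scale values — one 0/1 regression per class, the
predicted class being the argmax of the fitted values. The same
stratified 80/20 split protocol and seeds as the boosted-tree workflow
are used, so paired accuracy comparisons across repeats are valid.

No binning and no correlation pruning: the baseline is mean selection
plus linear regression, nothing more.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import train_test_split

from ._errors import DegenerateDataError, InputError
from .core_data import GeneExpressionDataset, source_usable_mask
from .evaluate import accuracy, majority_vote_accuracy
from .classify import TransferResult
from .feature_engineering import align_common_genes, select_top_mean

__all__ = ["LinearBenchmarkModel", "benchmark_top_mean_linear"]

logger = logging.getLogger(__name__)


@dataclass
class LinearBenchmarkModel:
    """Per-class OLS weights over the selected genes (column order:
    intercept first)."""

    coef: np.ndarray  # classes x (1 + n_genes)
    class_order: list[str]
    selected_genes: list[str]

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        design = np.column_stack([np.ones(len(X)), X])
        return design @ self.coef.T

    def predict_labels(self, X: np.ndarray) -> list[str]:
        fitted = self.decision_values(X)
        return [self.class_order[j] for j in np.argmax(fitted, axis=1)]


def _fit_ols_one_vs_all(X: np.ndarray, labels: np.ndarray) -> LinearBenchmarkModel:
    class_order = sorted(np.unique(labels).tolist())
    if len(class_order) < 2:
        raise DegenerateDataError("benchmark requires at least two classes")
    design = np.column_stack([np.ones(len(X)), X])
    coefs = []
    rank = np.linalg.matrix_rank(design)
    ridge = rank < design.shape[1]
    if ridge:
        logger.info("rank-deficient design; ridge fallback (penalty 1e-8)")
    for cls in class_order:
        y = (labels == cls).astype(np.float64)
        if ridge:
            A = design.T @ design + 1e-8 * np.eye(design.shape[1])
            beta = np.linalg.solve(A, design.T @ y)
        else:
            beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        coefs.append(beta)
    return LinearBenchmarkModel(np.vstack(coefs), class_order, [])


def benchmark_top_mean_linear(
    source: GeneExpressionDataset,
    target: GeneExpressionDataset,
    k: int = 5,
    n_repeats: int = 10,
    base_seed: int = 0,
    train_frac: float = 0.8,
) -> TransferResult:
    """Run the top-mean + linear-regression baseline with the standard
    80/20 x repeats protocol."""
    usable = source_usable_mask(source.labels)
    src = source.subset_cells(usable)
    if src.n_cells == 0:
        raise DegenerateDataError("no usable source cells after label exclusion")
    src_a, tgt_a, _ = align_common_genes(src, target)
    genes = select_top_mean(src_a, tgt_a, k=k)
    Xs = src_a.subset_genes(genes).matrix
    Xt = tgt_a.subset_genes(genes).matrix
    labels = np.asarray(src.labels)

    heldout_runs, target_runs = [], []
    last_preds: list[str] = []
    classes = sorted(np.unique(labels).tolist())
    y_codes = np.searchsorted(np.asarray(classes), labels)
    idx = np.arange(len(labels))
    for rep in range(n_repeats):
        seed = base_seed + rep
        try:
            tr, te = train_test_split(
                idx, train_size=train_frac, stratify=y_codes, random_state=seed
            )
        except ValueError as e:
            raise DegenerateDataError(f"stratified split failed: {e}") from e
        model = _fit_ols_one_vs_all(Xs[tr], labels[tr])
        model.selected_genes = genes
        heldout_runs.append(
            accuracy(labels[te], model.predict_labels(Xs[te]), include_excluded=True)
        )
        last_preds = model.predict_labels(Xt)
        target_runs.append(accuracy(target.labels, last_preds))
    mv = majority_vote_accuracy(src.labels, target.labels)
    return TransferResult(last_preds, heldout_runs, target_runs, mv)
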