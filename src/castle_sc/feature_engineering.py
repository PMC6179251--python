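"""Feature engineering for cross-dataset transfer.

The pipeline reduces two aligned expression matrices to a small, shared,
discretized feature space:

1. restrict both datasets to their common genes;
2. drop rarely expressed genes (non-zero in fewer than ``min_cells``
   cells, counted over the pooled cells of both datasets);
3. select the ``k`` genes with the highest pooled mean expression;
4. select the ``k`` genes with the highest plug-in mutual information
   between the gene's ordinal bin code and the class label, computed on
   the source only;
5. take the union of the two selections (between ``k`` and ``2k`` genes);
6. greedily drop one gene of every pair whose Pearson correlation on the
   pooled continuous values exceeds ``r_max``;
7. discretize to four ordinal bins [0], (0,1], (1,6], (6,inf);
8. drop genes whose bin code is constant over the pooled cells.

All tie-breaks are deterministic (statistic descending, then gene id
ascending) so identical inputs yield identical feature sets.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import DegenerateDataError, InputError
from .core_data import GeneExpressionDataset

__all__ = [
    "FeatureSet",
    "BinnedMatrix",
    "DEFAULT_BIN_EDGES",
    "align_common_genes",
    "filter_rare_genes",
    "select_top_mean",
    "bin_values",
    "mutual_information",
    "select_top_mi",
    "prune_correlated",
    "drop_constant_bins",
    "engineer_features",
    "PooledPrep",
    "prepare_pooled",
    "select_and_bin",
]

logger = logging.getLogger(__name__)

#: Upper edges delimiting the four ordinal bins [0], (0,1], (1,6], (6, inf).
DEFAULT_BIN_EDGES = (0.0, 1.0, 6.0)


@dataclass
class FeatureSet:
    """The genes surviving the selection pipeline, with provenance.

    ``genes`` are ordered by selection priority (mutual-information picks
    by descending MI, then mean picks by descending pooled mean).
    ``provenance`` maps each retained gene to the subset of
    ``{"mean_selected", "mi_selected"}`` that picked it. ``dropped`` maps
    each removed gene to the reason (``correlated_with:<gene>``,
    ``zero_variance`` or ``constant_bin``).
    """

    genes: list[str]
    provenance: dict[str, list[str]]
    bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES
    dropped: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.genes:
            raise DegenerateDataError("feature set is empty")
        overlap = set(self.genes) & set(self.dropped)
        if overlap:
            raise InputError(f"genes both retained and dropped: {sorted(overlap)[:5]}")
        for g in self.genes:
            if not self.provenance.get(g):
                raise InputError(f"retained gene {g!r} has no provenance tag")

    def to_json(self) -> str:
        return json.dumps(
            {
                "genes": self.genes,
                "provenance": self.provenance,
                "bin_edges": list(self.bin_edges),
                "dropped": self.dropped,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "FeatureSet":
        d = json.loads(text)
        return cls(
            genes=list(d["genes"]),
            provenance={k: list(v) for k, v in d["provenance"].items()},
            bin_edges=tuple(d["bin_edges"]),
            dropped=dict(d["dropped"]),
        )


@dataclass
class BinnedMatrix:
    """Cells x features matrix of ordinal bin codes in {0, 1, 2, 3}."""

    codes: np.ndarray
    feature_ids: list[str]
    edge_spec: tuple[float, ...] = DEFAULT_BIN_EDGES

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if self.codes.ndim != 2:
            raise InputError("code matrix must be 2-D")
        if self.codes.shape[1] != len(self.feature_ids):
            raise InputError(
                f"{len(self.feature_ids)} feature ids for "
                f"{self.codes.shape[1]} code columns"
            )
        if self.codes.size and not np.isin(self.codes, (0, 1, 2, 3)).all():
            raise InputError("bin codes must lie in {0,1,2,3}")

    def subset(self, feature_ids: list[str]) -> "BinnedMatrix":
        index = {g: j for j, g in enumerate(self.feature_ids)}
        cols = [index[g] for g in feature_ids]
        return BinnedMatrix(self.codes[:, cols], list(feature_ids), self.edge_spec)


def align_common_genes(
    source: GeneExpressionDataset, target: GeneExpressionDataset
) -> tuple[GeneExpressionDataset, GeneExpressionDataset, list[str]]:
    """Restrict both datasets to their shared genes, in source order."""
    if source.n_genes == 0 or target.n_genes == 0:
        raise InputError("cannot align an empty dataset")
    target_set = set(target.gene_ids)
    common = [g for g in source.gene_ids if g in target_set]
    if not common:
        raise DegenerateDataError("no shared genes between source and target")
    return source.subset_genes(common), target.subset_genes(common), common


def filter_rare_genes(
    source: GeneExpressionDataset,
    target: GeneExpressionDataset,
    min_cells: int = 10,
    pooled: bool = True,
) -> tuple[GeneExpressionDataset, GeneExpressionDataset]:
    """Drop genes with non-zero values in fewer than ``min_cells`` cells.

    Counting pools the cells of both datasets by default; ``pooled=False``
    requires the threshold within each dataset separately.
    """
    if source.gene_ids != target.gene_ids:
        raise InputError("datasets must be gene-aligned before rare-gene filtering")
    nz_src = np.count_nonzero(source.matrix, axis=0)
    nz_tgt = np.count_nonzero(target.matrix, axis=0)
    if pooled:
        keep = (nz_src + nz_tgt) >= min_cells
    else:
        keep = (nz_src >= min_cells) & (nz_tgt >= min_cells)
    if not keep.any():
        raise DegenerateDataError(
            f"every gene is non-zero in fewer than {min_cells} cells"
        )
    kept = [g for g, k in zip(source.gene_ids, keep) if k]
    return source.subset_genes(kept), target.subset_genes(kept)


def _top_k_desc(gene_ids: list[str], stat: np.ndarray, k: int) -> list[str]:
    """Top-k gene ids by statistic, ties broken by gene id ascending."""
    order = sorted(range(len(gene_ids)), key=lambda j: (-stat[j], gene_ids[j]))
    return [gene_ids[j] for j in order[: min(k, len(gene_ids))]]


def select_top_mean(
    source: GeneExpressionDataset, target: GeneExpressionDataset, k: int = 100
) -> list[str]:
    """Genes with the highest mean expression over the pooled cells."""
    if source.gene_ids != target.gene_ids:
        raise InputError("datasets must be gene-aligned")
    if source.n_genes == 0:
        raise InputError("no genes to select from")
    total = source.matrix.sum(axis=0) + target.matrix.sum(axis=0)
    pooled_mean = total / (source.n_cells + target.n_cells)
    return _top_k_desc(source.gene_ids, pooled_mean, k)


def bin_values(matrix: np.ndarray, edges=DEFAULT_BIN_EDGES, feature_ids=None) -> BinnedMatrix:
    """Discretize expression values to ordinal codes.

    With the default edges, code 0 <=> value == 0, 1 <=> 0 < v <= 1,
    2 <=> 1 < v <= 6, 3 <=> v > 6. Codes must never be re-binned: the map
    is not the identity on code space (3 -> 2).
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.ndim == 1:
        matrix = matrix[:, None]
    if (matrix < 0).any():
        raise InputError("cannot bin negative expression values")
    # right-closed intervals: searchsorted side="left" puts v==edge in the lower bin
    codes = np.searchsorted(np.asarray(edges, dtype=np.float64), matrix, side="left")
    codes = codes.astype(np.int8)
    if feature_ids is None:
        feature_ids = [f"f{j}" for j in range(matrix.shape[1])]
    return BinnedMatrix(codes, list(feature_ids), tuple(edges))


def mutual_information(x, y) -> float:
    """Plug-in mutual information I(X;Y) in bits between two nominal vectors.

    Empirical joint probabilities; cells with zero joint probability
    contribute nothing.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise InputError("mutual information needs at least two observations")
    joint = pd.crosstab(pd.Series(x), pd.Series(y)).to_numpy(dtype=np.float64)
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    return float((pxy[nz] * np.log2(pxy[nz] / (px @ py)[nz])).sum())


def _mi_all_features(codes: np.ndarray, labels) -> np.ndarray:
    """Vectorized plug-in MI of every code column against the labels."""
    labels = np.asarray(labels)
    classes, y = np.unique(labels, return_inverse=True)
    n = codes.shape[0]
    # joint counts N[v, c, g] from boolean masks; codes lie in {0..3}
    pxy = np.zeros((4, len(classes), codes.shape[1]))
    for v in range(4):
        vm = codes == v
        for c in range(len(classes)):
            pxy[v, c] = vm[y == c].sum(axis=0)
    pxy /= n
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = pxy * np.log2(pxy / (px * py))
    return np.nansum(terms, axis=(0, 1))


def select_top_mi(source_codes: BinnedMatrix, labels, k: int = 100) -> list[str]:
    """Genes whose bin codes carry the most information about the label.

    Computed on the source dataset only.
    """
    labels = np.asarray(labels)
    if len(labels) != source_codes.codes.shape[0]:
        raise InputError("label count does not match cell count")
    if len(np.unique(labels)) < 2:
        raise DegenerateDataError("mutual information undefined for one class")
    mi = _mi_all_features(source_codes.codes, labels)
    return _top_k_desc(source_codes.feature_ids, mi, k)


def prune_correlated(
    values: np.ndarray,
    feature_order: list[str],
    r_max: float = 0.9,
    use_abs: bool = False,
) -> tuple[list[str], dict[str, str]]:
    """Greedy correlation pruning in priority order.

    ``values`` holds the pooled continuous expression, columns aligned with
    ``feature_order`` (highest priority first). Scanning in that order, a
    feature is dropped iff its Pearson correlation with an already-retained
    feature strictly exceeds ``r_max`` (signed by default; ``use_abs``
    applies the threshold to \\|r\\|). Zero-variance columns have undefined
    correlation and are dropped with reason ``zero_variance``.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.shape[1] != len(feature_order):
        raise InputError("values columns must align with feature_order")
    if not feature_order:
        raise InputError("no features to prune")
    std = values.std(axis=0)
    retained: list[int] = []
    dropped: dict[str, str] = {}
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(values, rowvar=False) if len(feature_order) > 1 else np.ones((1, 1))
    for j, gene in enumerate(feature_order):
        if std[j] == 0:
            dropped[gene] = "zero_variance"
            continue
        partner = None
        for i in retained:
            r = corr[i, j]
            if (abs(r) if use_abs else r) > r_max:
                partner = feature_order[i]
                break
        if partner is None:
            retained.append(j)
        else:
            dropped[gene] = f"correlated_with:{partner}"
    return [feature_order[j] for j in retained], dropped


def drop_constant_bins(
    binned: BinnedMatrix, pooled_with: BinnedMatrix | None = None
) -> tuple[BinnedMatrix, list[str]]:
    """Remove features whose bin code is constant over the (pooled) cells.

    When ``pooled_with`` is given (the other dataset's codes for the same
    features), constancy is judged on the stacked cells of both.
    """
    codes = binned.codes
    if pooled_with is not None:
        if pooled_with.feature_ids != binned.feature_ids:
            raise InputError("pooled matrices must share the feature set")
        codes = np.vstack([binned.codes, pooled_with.codes])
    if codes.size == 0:
        raise InputError("empty binned matrix")
    varying = (codes != codes[0]).any(axis=0)
    if not varying.any():
        raise DegenerateDataError("no informative features: all bins constant")
    kept = [g for g, v in zip(binned.feature_ids, varying) if v]
    removed = [g for g, v in zip(binned.feature_ids, varying) if not v]
    return binned.subset(kept), removed


@dataclass
class PooledPrep:
    """Label-independent pipeline state: aligned, rare-filtered datasets.

    Computed once per source/target pair and reused across the per-type
    binary runs, which only redo the label-dependent steps.
    """

    source: GeneExpressionDataset
    target: GeneExpressionDataset
    mean_selected: list[str]
    pooled_means: dict[str, float]


def prepare_pooled(
    source: GeneExpressionDataset,
    target: GeneExpressionDataset,
    k: int = 100,
    min_cells: int = 10,
) -> PooledPrep:
    """Steps independent of the class label: align, rare-filter, top-mean."""
    src_a, tgt_a, common = align_common_genes(source, target)
    logger.info("gene intersection: %d shared genes", len(common))
    src_f, tgt_f = filter_rare_genes(src_a, tgt_a, min_cells=min_cells)
    logger.info("rare-gene filter (min_cells=%d): %d genes", min_cells, src_f.n_genes)
    mean_sel = select_top_mean(src_f, tgt_f, k=k)
    total = src_f.matrix.sum(axis=0) + tgt_f.matrix.sum(axis=0)
    pooled = total / (src_f.n_cells + tgt_f.n_cells)
    return PooledPrep(src_f, tgt_f, mean_sel, dict(zip(src_f.gene_ids, pooled)))


def select_and_bin(
    prep: PooledPrep,
    labels,
    k: int = 100,
    r_max: float = 0.9,
    edges=DEFAULT_BIN_EDGES,
    use_abs_corr: bool = False,
) -> tuple[FeatureSet, BinnedMatrix, BinnedMatrix]:
    """Label-dependent steps: MI selection, union, pruning, binning."""
    src, tgt = prep.source, prep.target
    src_codes_all = bin_values(src.matrix, edges, src.gene_ids)
    mi_sel = select_top_mi(src_codes_all, labels, k=k)
    mi_vals = dict(
        zip(src.gene_ids, _mi_all_features(src_codes_all.codes, np.asarray(labels)))
    )
    mean_sel = prep.mean_selected

    union = sorted(set(mean_sel) | set(mi_sel))
    logger.info("union of mean- and MI-selected genes: %d features", len(union))

    provenance: dict[str, list[str]] = {}
    for g in union:
        tags = []
        if g in set(mi_sel):
            tags.append("mi_selected")
        if g in set(mean_sel):
            tags.append("mean_selected")
        provenance[g] = tags

    # priority: MI picks by descending MI, then mean-only picks by descending mean
    mi_part = sorted(mi_sel, key=lambda g: (-mi_vals[g], g))
    mean_only = sorted(
        (g for g in mean_sel if g not in set(mi_sel)),
        key=lambda g: (-prep.pooled_means[g], g),
    )
    priority = mi_part + mean_only

    pooled_values = np.vstack(
        [src.subset_genes(priority).matrix, tgt.subset_genes(priority).matrix]
    )
    retained, dropped = prune_correlated(pooled_values, priority, r_max, use_abs_corr)
    logger.info("correlation pruning (r_max=%.2f): %d features", r_max, len(retained))

    src_binned = bin_values(src.subset_genes(retained).matrix, edges, retained)
    tgt_binned = bin_values(tgt.subset_genes(retained).matrix, edges, retained)
    src_binned, removed = drop_constant_bins(src_binned, pooled_with=tgt_binned)
    tgt_binned = tgt_binned.subset(src_binned.feature_ids)
    for g in removed:
        dropped[g] = "constant_bin"
    logger.info("constant-bin removal: %d features", len(src_binned.feature_ids))

    fset = FeatureSet(
        genes=list(src_binned.feature_ids),
        provenance={g: provenance[g] for g in src_binned.feature_ids},
        bin_edges=tuple(edges),
        dropped=dropped,
    )
    return fset, src_binned, tgt_binned


def engineer_features(
    source: GeneExpressionDataset,
    target: GeneExpressionDataset,
    labels,
    k: int = 100,
    r_max: float = 0.9,
    min_cells: int = 10,
    edges=DEFAULT_BIN_EDGES,
    use_abs_corr: bool = False,
) -> tuple[FeatureSet, BinnedMatrix, BinnedMatrix]:
    """Run the whole selection pipeline and bin both datasets.

    ``labels`` are the source cell labels (or a binary indicator in
    per-type mode) aligned with the source's cells.
    """
    labels = np.asarray(labels)
    if len(labels) != source.n_cells:
        raise InputError("labels must align with source cells")
    prep = prepare_pooled(source, target, k=k, min_cells=min_cells)
    return select_and_bin(prep, labels, k=k, r_max=r_max, edges=edges,
                          use_abs_corr=use_abs_corr)
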