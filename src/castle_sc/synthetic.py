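"""Paired source/target scRNA-seq simulator with known ground truth.

The generator emulates the situation the transfer workflow is built for:
two experiments profiling (mostly) the same cell types, separated by
technical variation rather than biology. Raw expression is log-normal:
per cell and gene, log2(raw) ~ Normal(baseline_log_mean + shift,
baseline_log_sd), where shift = marker_effect for the marker genes of
the cell's type (marker sets are disjoint across types) and 0
otherwise. Three batch-effect axes distinguish the target from the
source:

* **library depth** — target raw values are multiplied by
  ``depth_factor_target`` before anything else (doubling the reads per
  cell doubles every gene's measured expression);
* **dropout** — each entry is independently zeroed with a
  dataset-specific probability, applied after depth scaling because
  deeper sequencing recovers more lowly expressed genes;
* **gene universe** — only ``gene_overlap_frac`` of each dataset's
  genes are shared; the rest are private to one dataset, as happens
  with differing annotation pipelines.

The target may additionally contain novel cell types absent from the
source, for exercising unknown-cell detection. Both matrices are
returned on the log2(x+1) scale. All randomness derives from the
config's seed.

The defaults constitute the standard test fixture: 5 types, 2000 genes,
20 markers per type, a 3 log2-unit marker effect, 300 source cells per
type, an imbalanced target, dropout 0.3 (source) / 0.5 (target) and a
2x target depth factor.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from ._errors import InputError
from .core_data import GeneExpressionDataset

__all__ = ["SimulationConfig", "simulate_pair", "standard_config"]


@dataclass
class SimulationConfig:
    """Knobs of the paired-dataset generator; defaults = standard fixture."""

    n_genes: int = 2000
    n_types: int = 5
    n_markers_per_type: int = 20
    cells_per_type_source: tuple[int, ...] = (300, 300, 300, 300, 300)
    cells_per_type_target: tuple[int, ...] = (400, 200, 100, 50, 25)
    marker_effect: float = 3.0  # log2-units upward shift of a type's markers
    baseline_log_mean: float = 3.5  # log-normal location, log2 raw units
    baseline_log_sd: float = 1.25  # log-normal scale, log2 raw units
    dropout_source: float = 0.3
    dropout_target: float = 0.5
    depth_factor_target: float = 2.0  # multiplicative raw-scale depth ratio
    gene_overlap_frac: float = 0.9  # fraction of each dataset's genes shared
    novel_types_target: int = 0  # extra types present only in the target
    novel_cells_per_type: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        self.cells_per_type_source = tuple(int(c) for c in self.cells_per_type_source)
        self.cells_per_type_target = tuple(int(c) for c in self.cells_per_type_target)
        if len(self.cells_per_type_source) != self.n_types:
            raise InputError(
                f"cells_per_type_source has {len(self.cells_per_type_source)} "
                f"entries for n_types={self.n_types}"
            )
        if len(self.cells_per_type_target) != self.n_types:
            raise InputError(
                f"cells_per_type_target has {len(self.cells_per_type_target)} "
                f"entries for n_types={self.n_types}"
            )
        if not (0 < self.gene_overlap_frac <= 1):
            raise InputError("gene_overlap_frac must lie in (0, 1]")
        if not (0 <= self.dropout_source < 1 and 0 <= self.dropout_target < 1):
            raise InputError("dropout probabilities must lie in [0, 1)")
        if self.depth_factor_target <= 0:
            raise InputError("depth_factor_target must be positive")
        if self.marker_effect < 0:
            raise InputError("marker_effect must be non-negative")
        total_types = self.n_types + self.novel_types_target
        n_shared = round(self.gene_overlap_frac * self.n_genes)
        if total_types * self.n_markers_per_type > n_shared:
            raise InputError(
                "not enough shared genes for disjoint marker sets: "
                f"{total_types} types x {self.n_markers_per_type} markers "
                f"> {n_shared} shared genes"
            )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        d = json.loads(text)
        d["cells_per_type_source"] = tuple(d["cells_per_type_source"])
        d["cells_per_type_target"] = tuple(d["cells_per_type_target"])
        return cls(**d)


def standard_config(seed: int = 0, novel_types: int = 0) -> SimulationConfig:
    """The standard fixture, optionally with novel target-only types."""
    return SimulationConfig(novel_types_target=novel_types, seed=seed)


def _raw_block(rng, n_genes, shift_cols, n_cells, loc, scale, marker_effect):
    """Log-normal raw expression for one cell type: cells x genes."""
    means = np.full(n_genes, loc)
    means[shift_cols] += marker_effect
    log2raw = means[None, :] + rng.normal(0.0, scale, size=(n_cells, n_genes))
    return np.exp2(log2raw)


def simulate_pair(
    config: SimulationConfig,
) -> tuple[GeneExpressionDataset, GeneExpressionDataset, dict[str, list[str]]]:
    """Generate a labeled source/target pair plus the true marker map.

    Returns ``(source, target, truth)`` where ``truth`` maps each cell
    type (including novel target-only types) to its marker gene ids.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    n_shared = round(cfg.gene_overlap_frac * cfg.n_genes)
    n_private = cfg.n_genes - n_shared
    n_universe = n_shared + 2 * n_private
    gene_ids = [f"G{j:05d}" for j in range(n_universe)]
    shared = list(range(n_shared))
    src_gene_idx = shared + list(range(n_shared, n_shared + n_private))
    tgt_gene_idx = shared + list(range(n_shared + n_private, n_universe))

    total_types = cfg.n_types + cfg.novel_types_target
    type_names = [f"type_{t}" for t in range(cfg.n_types)] + [
        f"novel_{t}" for t in range(cfg.novel_types_target)
    ]
    marker_pool = rng.permutation(n_shared)[: total_types * cfg.n_markers_per_type]
    truth: dict[str, list[str]] = {}
    markers: dict[str, np.ndarray] = {}
    for t, name in enumerate(type_names):
        cols = np.sort(
            marker_pool[t * cfg.n_markers_per_type : (t + 1) * cfg.n_markers_per_type]
        )
        markers[name] = cols
        truth[name] = [gene_ids[j] for j in cols]

    def build(gene_idx, type_cells, dropout, depth, prefix):
        gene_index_map = {g: j for j, g in enumerate(gene_idx)}
        blocks, labels = [], []
        for name, n_cells in type_cells:
            cols = np.array(
                [gene_index_map[g] for g in markers[name] if g in gene_index_map],
                dtype=int,
            )
            raw = _raw_block(
                rng, len(gene_idx), cols, n_cells,
                cfg.baseline_log_mean, cfg.baseline_log_sd, cfg.marker_effect,
            )
            blocks.append(raw)
            labels += [name] * n_cells
        raw = np.vstack(blocks) * depth
        if dropout > 0:
            raw *= rng.random(raw.shape) >= dropout
        mat = np.log2(raw + 1.0)
        cell_ids = [f"{prefix}{i:05d}" for i in range(raw.shape[0])]
        return GeneExpressionDataset(
            mat, [gene_ids[j] for j in gene_idx], cell_ids, labels
        )

    source = build(
        src_gene_idx,
        [(f"type_{t}", cfg.cells_per_type_source[t]) for t in range(cfg.n_types)],
        cfg.dropout_source,
        1.0,
        "S",
    )
    target_types = [
        (f"type_{t}", cfg.cells_per_type_target[t]) for t in range(cfg.n_types)
    ] + [
        (f"novel_{t}", cfg.novel_cells_per_type) for t in range(cfg.novel_types_target)
    ]
    target = build(
        tgt_gene_idx, target_types, cfg.dropout_target, cfg.depth_factor_target, "T"
    )
    return source, target, truth
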