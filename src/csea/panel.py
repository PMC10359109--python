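"""Expression panels and tissue-cell-type (TC) signature derivation.

A *panel* is one annotated single-cell experiment: a genes x cells count
matrix with a cell-type label for every cell, plus tissue-level metadata.
Signature genes for each TC are obtained by

1. dropping cell types with too few cells (the one-vs-rest contrast needs
   a populated focal group),
2. dropping lowly expressed genes,
3. normalizing counts to log2(CPM + 1),
4. scoring every gene in every TC with the t-statistic of a one-vs-rest
   indicator regression fitted across all cells of the panel, and
5. keeping the top fraction (default 5%) of genes per TC by t-statistic.

The t-statistic of the indicator coefficient in ``expr ~ 1 + 1[cell in TC]``
is identical to the pooled-variance two-sample t comparing focal cells with
all remaining cells; it is computed here from group sufficient statistics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._util import normalize_symbol

logger = logging.getLogger(__name__)

DEVELOPMENTAL_STAGES = ("fetal", "neonatal", "adult", "unspecified")


class DegenerateInputError(ValueError):
    """An input that the pipeline cannot meaningfully process."""


@dataclass(frozen=True)
class PanelMetadata:
    """Provenance of a panel; ontology IDs are carried as opaque text."""

    panel_id: str
    tissue: str = ""
    organ_system: str = ""
    developmental_stage: str = "unspecified"
    uberon_id: str | None = None
    cl_ids: dict[str, str] | None = None

    def __post_init__(self):
        if self.developmental_stage not in DEVELOPMENTAL_STAGES:
            raise ValueError(
                f"developmental_stage must be one of {DEVELOPMENTAL_STAGES}, "
                f"got {self.developmental_stage!r}"
            )


@dataclass
class ExpressionPanel:
    """Count matrix (genes x cells) with per-cell cell-type labels.

    Invariants enforced at construction: dimensions match the id lists,
    gene symbols are unique, every cell carries exactly one label, and all
    counts are non-negative integers.
    """

    counts: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    cell_types: list[str]
    metadata: PanelMetadata

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D genes x cells matrix")
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError("gene_ids length does not match counts rows")
        if len(self.cell_ids) != n_cells:
            raise ValueError("cell_ids length does not match counts columns")
        if len(self.cell_types) != n_cells:
            raise ValueError("every cell needs exactly one cell-type label")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("gene symbols must be unique")
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("cell ids must be unique")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integral")
            self.counts = self.counts.astype(np.int64)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def cell_type_of(self) -> dict[str, str]:
        return dict(zip(self.cell_ids, self.cell_types))

    def cell_type_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for ct in self.cell_types:
            sizes[ct] = sizes.get(ct, 0) + 1
        return sizes

    @classmethod
    def from_frames(
        cls,
        counts: pd.DataFrame,
        annotations: pd.DataFrame,
        metadata: PanelMetadata,
    ) -> "ExpressionPanel":
        """Build a panel from a genes x cells frame and a cell annotation table.

        ``annotations`` needs columns ``cell_id`` and ``cell_type``; extra
        columns are ignored. Gene symbols are normalized (stripped,
        upper-cased); when two rows collapse onto one symbol the row with
        the larger total count is kept and the collision is logged.
        """
        if not {"cell_id", "cell_type"} <= set(annotations.columns):
            raise ValueError("annotation table needs cell_id and cell_type columns")
        ann = annotations.set_index("cell_id")["cell_type"]
        missing = [c for c in counts.columns if c not in ann.index]
        if missing:
            raise ValueError(f"cells without annotation: {missing[:5]}")

        symbols = [normalize_symbol(g) for g in counts.index]
        totals = counts.to_numpy().sum(axis=1)
        keep: dict[str, int] = {}
        for i, sym in enumerate(symbols):
            if sym in keep:
                logger.warning(
                    "duplicate gene symbol %s after normalization; keeping the "
                    "row with the larger total count",
                    sym,
                )
                if totals[i] <= totals[keep[sym]]:
                    continue
            keep[sym] = i
        rows = sorted(keep.values())
        matrix = counts.to_numpy()[rows, :]
        gene_ids = [symbols[i] for i in rows]
        cell_ids = [str(c) for c in counts.columns]
        cell_types = [str(ann[c]) for c in counts.columns]
        return cls(matrix, gene_ids, cell_ids, cell_types, metadata)


@dataclass
class TStatMatrix:
    """Genes x cell-types matrix of one-vs-rest t-statistics."""

    values: np.ndarray
    gene_ids: list[str]
    tc_labels: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.tc_labels)):
            raise ValueError("t-statistic matrix shape does not match id lists")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("t-statistics must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.tc_labels)


@dataclass
class SignaturePanel:
    """Per-TC signature gene sets plus the t-statistics they came from.

    ``signatures`` maps TC label -> gene list ordered by descending
    t-statistic (ties broken lexicographically); every signature has
    ``max(1, floor(top_fraction * |universe|))`` genes.
    """

    panel_id: str
    universe: list[str]
    signatures: dict[str, list[str]]
    tstats: TStatMatrix
    top_fraction: float = 0.05
    metadata: PanelMetadata | None = None

    def __post_init__(self):
        uni = set(self.universe)
        k = signature_size(len(self.universe), self.top_fraction)
        for tc, genes in self.signatures.items():
            if not set(genes) <= uni:
                raise ValueError(f"signature for {tc} contains genes outside universe")
            if len(genes) != k:
                raise ValueError(
                    f"signature for {tc} has {len(genes)} genes, expected {k}"
                )

    @property
    def tc_labels(self) -> list[str]:
        return list(self.signatures)

    @property
    def tc_ids(self) -> list[str]:
        return [f"{self.panel_id}|{tc}" for tc in self.signatures]

    def signature_of(self, tc_id: str) -> list[str]:
        panel_id, _, label = tc_id.partition("|")
        if panel_id != self.panel_id or label not in self.signatures:
            raise KeyError(tc_id)
        return self.signatures[label]


def signature_size(n_universe: int, top_fraction: float) -> int:
    """Signature length: floor of the top fraction, clamped to at least 1."""
    return max(1, math.floor(top_fraction * n_universe))


def normalize_log2_cpm(counts: np.ndarray, cell_ids: list[str] | None = None) -> np.ndarray:
    """log2(CPM + 1) per-cell library-size normalization.

    Entry (g, c) becomes ``log2(counts[g, c] / colsum(c) * 1e6 + 1)``.
    A cell with zero total count has no defined library size and is
    rejected with :class:`DegenerateInputError` naming the cell.
    """
    counts = np.asarray(counts, dtype=float)
    libsize = counts.sum(axis=0)
    zero = np.flatnonzero(libsize == 0)
    if zero.size:
        name = cell_ids[zero[0]] if cell_ids is not None else f"column {zero[0]}"
        raise DegenerateInputError(
            f"cell {name} has zero total count; cannot compute CPM"
        )
    return np.log2(counts / libsize * 1e6 + 1.0)


def filter_genes(
    panel: ExpressionPanel,
    min_cells: int = 3,
    min_fraction: float = 0.001,
) -> ExpressionPanel:
    """Drop lowly expressed genes.

    A gene is retained when it is detected (count > 0) in at least
    ``max(min_cells, ceil(min_fraction * n_cells))`` cells.
    """
    if min_cells < 0 or not 0 <= min_fraction <= 1:
        raise ValueError("min_cells must be >= 0 and min_fraction in [0, 1]")
    threshold = max(min_cells, math.ceil(min_fraction * panel.n_cells))
    detected = (panel.counts > 0).sum(axis=1)
    keep = detected >= threshold
    n_dropped = int((~keep).sum())
    if not keep.any():
        raise DegenerateInputError("gene filter removed every gene")
    logger.info(
        "gene filter (detected in >= %d cells): dropped %d of %d genes",
        threshold, n_dropped, panel.n_genes,
    )
    return replace(
        panel,
        counts=panel.counts[keep, :],
        gene_ids=[g for g, k in zip(panel.gene_ids, keep) if k],
    )


def filter_cell_types(panel: ExpressionPanel, min_cells: int = 30) -> ExpressionPanel:
    """Drop every cell whose cell-type has fewer than ``min_cells`` members.

    At least two cell types must survive: the one-vs-rest t-statistic needs
    a focal group and a non-empty complement.
    """
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    sizes = panel.cell_type_sizes()
    retained_types = {ct for ct, n in sizes.items() if n >= min_cells}
    if len(retained_types) < 2:
        raise DegenerateInputError(
            f"only {len(retained_types)} cell type(s) with >= {min_cells} cells; "
            "at least 2 are required for a one-vs-rest contrast"
        )
    keep = np.array([ct in retained_types for ct in panel.cell_types])
    dropped = sorted(set(sizes) - retained_types)
    if dropped:
        logger.info("cell-type filter (>= %d cells): dropped %s", min_cells, dropped)
    return replace(
        panel,
        counts=panel.counts[:, keep],
        cell_ids=[c for c, k in zip(panel.cell_ids, keep) if k],
        cell_types=[t for t, k in zip(panel.cell_types, keep) if k],
    )


def compute_tc_tstats(
    norm: np.ndarray,
    labels: list[str],
    gene_ids: list[str] | None = None,
) -> TStatMatrix:
    """One-vs-rest t-statistic per gene and cell type.

    Equivalent to the t-statistic of the group indicator in an ordinary
    least-squares fit ``expr_g ~ intercept + 1[cell in tc]`` over all cells;
    computed from pooled-variance two-sample sufficient statistics. A gene
    with zero residual variance for a contrast gets t = 0.
    """
    norm = np.asarray(norm, dtype=float)
    n_genes, n_cells = norm.shape
    labels = list(labels)
    if len(labels) != n_cells:
        raise ValueError("one label per cell required")
    tc_labels = sorted(set(labels))
    if len(tc_labels) < 2:
        raise ValueError("need at least 2 distinct cell types")
    counts = {tc: labels.count(tc) for tc in tc_labels}
    bad = [tc for tc, n in counts.items() if n < 2]
    if bad:
        raise ValueError(f"cell types with a single cell: {bad}")
    if gene_ids is None:
        gene_ids = [f"G{i}" for i in range(n_genes)]

    values = np.zeros((n_genes, len(tc_labels)))
    label_arr = np.array(labels)
    for j, tc in enumerate(tc_labels):
        focal = label_arr == tc
        x1 = norm[:, focal]
        x0 = norm[:, ~focal]
        n1, n0 = x1.shape[1], x0.shape[1]
        m1 = x1.mean(axis=1)
        m0 = x0.mean(axis=1)
        # deviation form keeps near-constant genes numerically at zero
        ss1 = ((x1 - m1[:, None]) ** 2).sum(axis=1)
        ss0 = ((x0 - m0[:, None]) ** 2).sum(axis=1)
        pooled = (ss1 + ss0) / (n1 + n0 - 2)
        scale = 1.0 + m1**2 + m0**2
        degenerate = pooled <= 1e-12 * scale
        se = np.sqrt(np.where(degenerate, 1.0, pooled) * (1.0 / n1 + 1.0 / n0))
        t = (m1 - m0) / se
        t[degenerate] = 0.0
        values[:, j] = t
    return TStatMatrix(values, list(gene_ids), tc_labels)


def select_signatures(
    tstats: TStatMatrix,
    universe: list[str] | None = None,
    top_fraction: float = 0.05,
    panel_id: str = "panel",
    metadata: PanelMetadata | None = None,
) -> SignaturePanel:
    """Keep the top fraction of genes per TC by t-statistic.

    Signature length is ``max(1, floor(top_fraction * |universe|))``; ties
    at the cutoff are broken by lexicographic gene symbol so the selection
    is deterministic.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    if universe is None:
        universe = list(tstats.gene_ids)
    if not universe:
        raise ValueError("empty gene universe")
    uni_set = set(universe)
    idx = [i for i, g in enumerate(tstats.gene_ids) if g in uni_set]
    genes = [tstats.gene_ids[i] for i in idx]
    k = signature_size(len(universe), top_fraction)
    signatures: dict[str, list[str]] = {}
    for j, tc in enumerate(tstats.tc_labels):
        col = tstats.values[idx, j]
        order = sorted(range(len(genes)), key=lambda i: (-col[i], genes[i]))
        signatures[tc] = [genes[i] for i in order[:k]]
    return SignaturePanel(
        panel_id=panel_id,
        universe=sorted(uni_set),
        signatures=signatures,
        tstats=tstats,
        top_fraction=top_fraction,
        metadata=metadata,
    )


def build_signature_panel(
    panel: ExpressionPanel,
    top_fraction: float = 0.05,
    min_cells_per_type: int = 30,
    gene_min_cells: int = 3,
    gene_min_fraction: float = 0.001,
) -> SignaturePanel:
    """Full pipeline: cell-type filter, gene filter, normalize, t-stats, top-k."""
    panel = filter_cell_types(panel, min_cells=min_cells_per_type)
    panel = filter_genes(panel, min_cells=gene_min_cells, min_fraction=gene_min_fraction)
    norm = normalize_log2_cpm(panel.counts, panel.cell_ids)
    tstats = compute_tc_tstats(norm, panel.cell_types, panel.gene_ids)
    return select_signatures(
        tstats,
        universe=list(panel.gene_ids),
        top_fraction=top_fraction,
        panel_id=panel.metadata.panel_id,
        metadata=panel.metadata,
    )
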