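"""Synthetic single-cell panels and trait-associated gene set (TAG) fixtures.

The generator produces the statistical structure the pipeline assumes:
sparse negative-binomial count matrices with disjoint marker gene sets
planted per cell type (markers get a multiplicative lift of the mean in
their own cell type only), and TAG collections whose lengths follow a
log-uniform law over the 20-2000 range typical of gene-based association
study output. Everything is exactly regenerable from (parameters, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .panel import ExpressionPanel, PanelMetadata

logger = logging.getLogger(__name__)


@dataclass
class SyntheticTruth:
    """Planted-marker assignments and every generator parameter."""

    marker_of: dict[str, list[str]]
    effect_size: float
    baseline_mean: float
    dispersion: float
    seed: int
    tag_length_distribution: str = "log-uniform over [20, 2000]"

    def __post_init__(self):
        all_markers = [g for genes in self.marker_of.values() for g in genes]
        if len(all_markers) != len(set(all_markers)):
            raise ValueError("marker sets must be disjoint across cell types")


def _negative_binomial(rng: np.random.Generator, mean: np.ndarray, dispersion: float):
    """Gamma-Poisson counts with Var = mean + dispersion * mean^2."""
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean / shape)
    return rng.poisson(lam)


def simulate_panel(
    n_genes: int = 2000,
    cell_types: dict[str, int] | None = None,
    n_markers_per_tc: int = 20,
    effect_size: float = 4.0,
    baseline_mean: float = 0.5,
    dispersion: float = 0.3,
    seed: int = 0,
    panel_id: str = "SIM",
    metadata: PanelMetadata | None = None,
) -> tuple[ExpressionPanel, SyntheticTruth]:
    """Simulate an annotated count matrix with planted cell-type markers.

    Baseline counts are negative binomial (``Var = m + d*m^2``); each cell
    type owns ``n_markers_per_tc`` marker genes whose mean is multiplied
    by ``effect_size`` in that cell type's cells only. ``effect_size = 1``
    (or 0, treated as "no lift") yields a pure null panel.
    """
    cell_types = cell_types or {"alpha": 100, "beta": 100, "gamma": 100, "delta": 100}
    labels = sorted(cell_types)
    if any(n < 2 for n in cell_types.values()):
        raise ValueError("every cell type needs at least 2 cells")
    if n_markers_per_tc * len(labels) > n_genes:
        raise ValueError(
            f"cannot plant {n_markers_per_tc} markers for {len(labels)} cell "
            f"types in {n_genes} genes"
        )
    rng = np.random.default_rng(seed)
    # fixed-width names keep pools nested across panels of different sizes
    width = max(5, len(str(n_genes)))
    gene_ids = [f"G{i:0{width}d}" for i in range(n_genes)]
    marker_pool = rng.choice(n_genes, size=n_markers_per_tc * len(labels), replace=False)
    marker_of = {
        tc: sorted(gene_ids[g] for g in marker_pool[k * n_markers_per_tc:(k + 1) * n_markers_per_tc])
        for k, tc in enumerate(labels)
    }

    cell_ids, cell_labels = [], []
    for tc in labels:
        for i in range(cell_types[tc]):
            cell_ids.append(f"{panel_id}_{tc}_{i:04d}")
            cell_labels.append(tc)
    n_cells = len(cell_ids)

    mean = np.full((n_genes, n_cells), baseline_mean)
    lift = effect_size if effect_size > 0 else 1.0
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    col = 0
    for tc in labels:
        n = cell_types[tc]
        rows = [gene_index[g] for g in marker_of[tc]]
        mean[np.ix_(rows, range(col, col + n))] *= lift
        col += n
    counts = _negative_binomial(rng, mean, dispersion).astype(np.int64)

    metadata = metadata or PanelMetadata(
        panel_id=panel_id, tissue="synthetic tissue", organ_system="synthetic",
        developmental_stage="unspecified",
    )
    panel = ExpressionPanel(counts, gene_ids, cell_ids, cell_labels, metadata)
    truth = SyntheticTruth(
        marker_of=marker_of,
        effect_size=effect_size,
        baseline_mean=baseline_mean,
        dispersion=dispersion,
        seed=seed,
    )
    return panel, truth


def log_uniform_lengths(rng: np.random.Generator, n: int, lo: int = 20, hi: int = 2000):
    """Integer lengths with log10 uniform on [log lo, log hi]."""
    return np.round(10 ** rng.uniform(np.log10(lo), np.log10(hi), size=n)).astype(int)


@dataclass
class EnrichmentSpec:
    """Make simulated TAGs moderately specific to one signature.

    A ``fraction`` of each TAG's genes is drawn from ``signature`` instead
    of uniformly from the universe.
    """

    signature: list[str]
    fraction: float

    def __post_init__(self):
        if not 0 <= self.fraction <= 1:
            raise ValueError("fraction must be in [0, 1]")


def simulate_tags(
    n_tags: int,
    universe,
    length_sampler=None,
    enrichment_spec: EnrichmentSpec | None = None,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Simulate a TAG collection over a gene universe.

    Null TAGs are uniform draws without replacement; with an
    ``enrichment_spec`` a stated fraction of each TAG comes from one TC's
    signature genes. Lengths default to log-uniform over
    [20, 2000] ∩ [1, |universe|].
    """
    universe = sorted(set(universe))
    n_uni = len(universe)
    rng = np.random.default_rng(seed)
    if length_sampler is None:
        hi = min(2000, n_uni)
        lo = min(20, hi)
        def length_sampler(r, n):  # noqa: E731 - default sampler
            return log_uniform_lengths(r, n, lo, hi)
    lengths = np.asarray(length_sampler(rng, n_tags), dtype=int)
    if np.any(lengths > n_uni):
        raise ValueError("requested TAG length exceeds the universe size")
    if np.any(lengths < 1):
        raise ValueError("TAG lengths must be >= 1")

    uni_arr = np.array(universe)
    tags: dict[str, list[str]] = {}
    width = len(str(max(n_tags - 1, 1)))
    sig = np.array(sorted(set(enrichment_spec.signature))) if enrichment_spec else None
    for t in range(n_tags):
        L = int(lengths[t])
        if sig is not None:
            n_sig = min(int(round(enrichment_spec.fraction * L)), sig.size, L)
            chosen_sig = rng.choice(sig, size=n_sig, replace=False)
            rest_pool = np.setdiff1d(uni_arr, chosen_sig, assume_unique=False)
            chosen_rest = rng.choice(rest_pool, size=L - n_sig, replace=False)
            genes = np.concatenate([chosen_sig, chosen_rest])
        else:
            genes = rng.choice(uni_arr, size=L, replace=False)
        tags[f"TAG{t:0{width}d}"] = sorted(genes.tolist())
    return tags


def filter_tag_length(
    tags: dict[str, list[str]],
    min_len: int = 20,
    max_len: int = 2000,
) -> dict[str, list[str]]:
    """Keep TAGs whose size lies in [min_len, max_len] (inclusive bounds)."""
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    kept = {t: g for t, g in tags.items() if min_len <= len(set(g)) <= max_len}
    too_short = sum(1 for g in tags.values() if len(set(g)) < min_len)
    too_long = sum(1 for g in tags.values() if len(set(g)) > max_len)
    logger.info(
        "TAG length filter [%d, %d]: removed %d too short, %d too long",
        min_len, max_len, too_short, too_long,
    )
    return kept
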