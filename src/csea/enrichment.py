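"""Over-representation (CSEA) test of a query gene list against TC signatures.

The raw enrichment p-value for one tissue-cell type is the one-sided
hypergeometric upper tail P(X >= a) for the 2x2 table

    a = |query ∩ signature|        b = n_mapped - a
    c = |signature| - a            d = |universe| - |signature| - b

with the panel's post-filter gene universe as the sampling population.
For a one-sided 2x2 table this coincides with Fisher's exact test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._util import dedupe_preserving_order, normalize_symbol
from .panel import SignaturePanel


@dataclass
class QueryGeneList:
    """An input gene list mapped onto an active gene universe."""

    raw_symbols: list[str]
    mapped: list[str]
    n_input: int
    n_mapped: int

    @classmethod
    def from_symbols(cls, symbols, universe) -> "QueryGeneList":
        raw = list(symbols)
        normalized = dedupe_preserving_order(normalize_symbol(s) for s in raw if s.strip())
        uni = set(universe)
        mapped = [s for s in normalized if s in uni]
        return cls(raw, mapped, len(normalized), len(mapped))


@dataclass
class EnrichmentCell:
    """Raw CSEA result for one tissue-cell type."""

    tc_id: str
    p_raw: float
    overlap: list[str]
    table: tuple[int, int, int, int]


def csea_raw(
    query: QueryGeneList,
    signature,
    universe,
    tc_id: str = "",
) -> EnrichmentCell:
    """One-sided hypergeometric over-representation test.

    ``p_raw = P(X >= a)`` with population ``|universe|``, ``|signature|``
    successes and ``n_mapped`` draws. A query with no mapped genes yields
    p = 1 with a warning rather than an error: no evidence, not a failure.
    """
    sig = set(signature)
    uni = set(universe)
    if not sig <= uni:
        raise ValueError("signature must be a subset of the universe")
    if not set(query.mapped) <= uni:
        raise ValueError("query.mapped must lie inside the universe")
    if not 1 <= len(sig) <= len(uni):
        raise ValueError("need |universe| >= |signature| >= 1")
    overlap = sorted(set(query.mapped) & sig)
    a = len(overlap)
    n = query.n_mapped
    if n == 0:
        warnings.warn(f"query has no genes mapped to the universe (tc {tc_id!r})")
        return EnrichmentCell(tc_id, 1.0, [], (0, 0, len(sig), len(uni) - len(sig)))
    N, K = len(uni), len(sig)
    p = float(stats.hypergeom.sf(a - 1, N, K, n))
    p = min(1.0, max(p, np.nextafter(0, 1)))
    table = (a, n - a, K - a, N - K - (n - a))
    return EnrichmentCell(tc_id, p, overlap, table)


def query_panel(query, panel: SignaturePanel) -> list[EnrichmentCell]:
    """Run csea_raw for every TC of one signature panel, in panel TC order.

    ``query`` may be a QueryGeneList (already mapped to this panel's
    universe) or any iterable of raw symbols.
    """
    if not isinstance(query, QueryGeneList):
        query = QueryGeneList.from_symbols(query, panel.universe)
    return [
        csea_raw(query, panel.signatures[tc], panel.universe, tc_id=tc_id)
        for tc, tc_id in zip(panel.tc_labels, panel.tc_ids)
    ]


def batch_raw_pvalues(gene_sets: dict[str, set], panel: SignaturePanel) -> np.ndarray:
    """Raw CSEA p-values for many gene sets against every TC of one panel.

    Vectorized equivalent of per-pair :func:`csea_raw` calls (sets are
    mapped to the panel universe first); returns an (n_sets, n_tcs) array
    in the order of ``gene_sets`` / ``panel.tc_ids``.
    """
    uni_index = {g: i for i, g in enumerate(panel.universe)}
    N = len(uni_index)
    n_sets = len(gene_sets)
    tc_labels = panel.tc_labels
    member = np.zeros((N, n_sets), dtype=np.int32)
    n_mapped = np.zeros(n_sets, dtype=np.int64)
    for s, genes in enumerate(gene_sets.values()):
        idx = [uni_index[g] for g in set(genes) if g in uni_index]
        member[idx, s] = 1
        n_mapped[s] = len(idx)
    sig = np.zeros((len(tc_labels), N), dtype=np.int32)
    K = np.zeros(len(tc_labels), dtype=np.int64)
    for j, tc in enumerate(tc_labels):
        idx = [uni_index[g] for g in panel.signatures[tc]]
        sig[j, idx] = 1
        K[j] = len(idx)
    overlap = sig @ member  # (n_tcs, n_sets)
    with np.errstate(invalid="ignore"):
        p = stats.hypergeom.sf(overlap - 1, N, K[:, None], n_mapped[None, :])
    p = np.where(n_mapped[None, :] == 0, 1.0, p)
    return np.clip(p.T, np.nextafter(0, 1), 1.0)
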