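"""Rank-based permutation adjustment of raw CSEA p-values.

Raw over-representation p-values depend strongly on signature and query
lengths, so they are not comparable across tissue-cell types (TCs). The
adjustment ranks the query's raw p-value against a reference of
precomputed raw p-values for a large collection of trait-associated gene
sets (TAGs), per TC:

    p_perm(i) = rank(p_raw(i), reference column i) / n_tags * factor

where ``factor``, the *cumulative factor*, is the proportion of reference
TAGs at least as long as the query list. A second rank, across the query's
own raw p-values over all TCs,

    p_tc(i) = rank(p_raw(i), p_raw over all TCs) / n_tcs

captures relative specificity. The two are combined by Fisher's method:
-2 ln(p_perm * p_tc) referred to a chi-squared distribution with 4
degrees of freedom (2 p-values x 2 df each).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import RunConfig, annotate_significance
from .enrichment import QueryGeneList, batch_raw_pvalues, query_panel
from .panel import SignaturePanel
from ._util import dedupe_preserving_order, normalize_symbol


@dataclass
class TAGReference:
    """Reference TAG collection plus its precomputed raw p-value matrix.

    ``p_matrix`` is a (n_tags x n_tcs) DataFrame indexed by tag_id with
    tc_id columns; entries are raw CSEA p-values in (0, 1]. Columns are
    always matched by tc_id, never by position.
    """

    tag_sets: dict[str, list[str]]
    tag_lengths: dict[str, int]
    p_matrix: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if set(self.tag_sets) != set(self.p_matrix.index):
            raise ValueError("p_matrix rows must match tag_sets ids")
        for t, genes in self.tag_sets.items():
            if self.tag_lengths.get(t) != len(set(genes)):
                raise ValueError(f"tag_lengths inconsistent for {t}")
        vals = self.p_matrix.to_numpy()
        if np.any(vals <= 0) or np.any(vals > 1):
            raise ValueError("p_matrix entries must lie in (0, 1]")

    @property
    def tc_ids(self) -> list[str]:
        return list(self.p_matrix.columns)

    @property
    def n_tags(self) -> int:
        return len(self.tag_sets)

    def column(self, tc_id: str) -> np.ndarray:
        if tc_id not in self.p_matrix.columns:
            raise KeyError(f"tc_id {tc_id!r} not in reference")
        return self.p_matrix[tc_id].to_numpy()


@dataclass
class QueryResult:
    """Adjusted enrichment result for one query across all TCs.

    ``table`` holds one row per TC, sorted by ascending combined p-value
    (tc_id breaks ties), with raw, permutation, cross-TC and combined
    p-values, the overlap genes and significance flags.
    """

    table: pd.DataFrame
    cumulative_factor: float
    n_input: int
    n_mapped: int
    n_mapped_by_panel: dict[str, int]
    bonferroni_threshold: float
    nominal_threshold: float


def build_reference(
    tag_sets: dict[str, list[str]],
    panels: list[SignaturePanel],
    meta: dict | None = None,
) -> TAGReference:
    """Precompute the raw CSEA p-value of every TAG against every TC."""
    if not tag_sets:
        raise ValueError("empty TAG collection")
    if not panels:
        raise ValueError("need at least one signature panel")
    sets = {t: set(g) for t, g in tag_sets.items()}
    blocks = []
    for panel in panels:
        block = pd.DataFrame(
            batch_raw_pvalues(sets, panel),
            index=list(tag_sets),
            columns=panel.tc_ids,
        )
        blocks.append(block)
    p_matrix = pd.concat(blocks, axis=1)
    lengths = {t: len(s) for t, s in sets.items()}
    return TAGReference(dict(tag_sets), lengths, p_matrix, meta or {})


def cumulative_factor(query_len: int, tag_lengths) -> float:
    """Proportion of reference TAGs at least as long as the query list.

    A factor of exactly 0 (query longer than every TAG) is floored to
    1 / n_tags so downstream permutation p-values stay positive.
    """
    lengths = np.asarray(list(tag_lengths), dtype=int)
    if query_len < 1:
        raise ValueError("query_len must be >= 1")
    if lengths.size == 0:
        raise ValueError("tag_lengths must be non-empty")
    factor = float((lengths >= query_len).sum()) / lengths.size
    if factor == 0.0:
        warnings.warn(
            "query is longer than every reference TAG; flooring the "
            "cumulative factor to 1/n_tags"
        )
        factor = 1.0 / lengths.size
    return factor


def p_perm(p_raw: float, ref_column, factor: float = 1.0) -> float:
    """Permutation p-value: tie-inclusive rank in the reference, scaled.

    rank = max(1, |{p in reference : p <= p_raw}|); the result
    rank / n * factor is capped at 1.
    """
    ref = np.asarray(ref_column, dtype=float)
    if ref.size == 0:
        raise ValueError("reference column must be non-empty")
    if not 0 < factor <= 1:
        raise ValueError("factor must be in (0, 1]")
    rank = max(1, int((ref <= p_raw).sum()))
    return min(1.0, rank / ref.size * factor)


def p_tc(p_raw_i: float, all_tc_p) -> float:
    """Cross-TC rank p-value: tie-inclusive rank of TC i among all TCs.

    The vector must contain TC i's own raw p-value, so the result is
    always >= 1 / n_tcs.
    """
    vec = np.asarray(all_tc_p, dtype=float)
    if not np.any(vec == p_raw_i):
        raise ValueError("all_tc_p must contain p_raw_i itself")
    return float((vec <= p_raw_i).sum()) / vec.size


def combine_pvalues(pp: float, pt: float) -> tuple[float, float]:
    """Fisher's method for the two rank p-values.

    chi2 = -2 ln(pp * pt) is referred to a chi-squared distribution with
    4 degrees of freedom; the closed form of the upper tail is
    (pp*pt) * (1 - ln(pp*pt)).
    """
    if not (0 < pp <= 1 and 0 < pt <= 1):
        raise ValueError("both p-values must lie in (0, 1]")
    chi2_stat = -2.0 * math.log(pp * pt)
    p_combined = float(stats.chi2.sf(chi2_stat, df=4))
    return chi2_stat, min(1.0, p_combined)


def run_query(
    query,
    panels: list[SignaturePanel],
    reference: TAGReference,
    config: RunConfig | None = None,
) -> QueryResult:
    """Full adjusted enrichment of one gene list across a set of panels.

    Per TC: raw hypergeometric p (against that panel's universe), then the
    reference-rank permutation p (cumulative factor computed once per
    query from the unique input length), the cross-TC rank p over the
    query's own raw p-values, and the Fisher-combined p. Rows are sorted
    ascending by combined p with tc_id as tie-break. Significance flags
    use strict comparison against ``bonferroni_alpha / n_tcs`` and the
    nominal threshold.
    """
    config = config or RunConfig()
    if isinstance(query, QueryGeneList):
        normalized = dedupe_preserving_order(
            normalize_symbol(s) for s in query.raw_symbols if s.strip()
        )
    else:
        normalized = dedupe_preserving_order(
            normalize_symbol(s) for s in query if str(s).strip()
        )
    n_input = len(normalized)
    if not config.min_query_len <= n_input <= config.max_query_len:
        warnings.warn(
            f"query has {n_input} genes; suggested range is "
            f"[{config.min_query_len}, {config.max_query_len}]"
        )

    factor = cumulative_factor(max(1, n_input), reference.tag_lengths.values())

    rows = []
    mapped_union: set[str] = set()
    n_mapped_by_panel: dict[str, int] = {}
    for panel in panels:
        q = QueryGeneList.from_symbols(normalized, panel.universe)
        mapped_union.update(q.mapped)
        n_mapped_by_panel[panel.panel_id] = q.n_mapped
        meta = panel.metadata
        for cell in query_panel(q, panel):
            rows.append(
                {
                    "tc_id": cell.tc_id,
                    "panel_id": panel.panel_id,
                    "tissue": meta.tissue if meta else "",
                    "organ_system": meta.organ_system if meta else "",
                    "developmental_stage": meta.developmental_stage if meta else "",
                    "cell_type": cell.tc_id.partition("|")[2],
                    "p_raw": cell.p_raw,
                    "n_overlap": len(cell.overlap),
                    "overlap_genes": ",".join(cell.overlap),
                }
            )
    df = pd.DataFrame(rows)
    missing = [t for t in df["tc_id"] if t not in reference.p_matrix.columns]
    if missing:
        raise ValueError(f"reference lacks columns for TCs: {missing[:5]}")

    all_tc_p = df["p_raw"].to_numpy()
    df["p_perm"] = [
        p_perm(p, reference.column(tc), factor)
        for p, tc in zip(all_tc_p, df["tc_id"])
    ]
    df["p_tc"] = [p_tc(p, all_tc_p) for p in all_tc_p]
    combined = [combine_pvalues(pp, pt) for pp, pt in zip(df["p_perm"], df["p_tc"])]
    df["chi2_stat"] = [c[0] for c in combined]
    df["p_combined"] = [c[1] for c in combined]

    n_tcs = len(df)
    bonf, nominal, threshold = annotate_significance(
        df["p_combined"].to_numpy(), n_tcs, config
    )
    df["bonferroni_flag"] = bonf
    df["nominal_flag"] = nominal
    df = df.sort_values(["p_combined", "tc_id"], kind="mergesort").reset_index(drop=True)
    cols = [
        "tc_id", "panel_id", "tissue", "organ_system", "developmental_stage",
        "cell_type", "p_raw", "p_perm", "p_tc", "chi2_stat", "p_combined",
        "n_overlap", "overlap_genes", "bonferroni_flag", "nominal_flag",
    ]
    return QueryResult(
        table=df[cols],
        cumulative_factor=factor,
        n_input=n_input,
        n_mapped=len(mapped_union),
        n_mapped_by_panel=n_mapped_by_panel,
        bonferroni_threshold=threshold,
        nominal_threshold=config.nominal_p,
    )


def z_from_p(p) -> np.ndarray | float:
    """Convert p-values to Z-scores via the standard normal quantile.

    z = Phi^{-1}(1 - p); p is clamped into the open unit interval with a
    warning (p = 0 or 1 has no finite Z).
    """
    arr = np.atleast_1d(np.asarray(p, dtype=float))
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    lo, hi = 1e-300, 1.0 - 1e-16
    if np.any((arr <= 0) | (arr >= 1)):
        warnings.warn("p-values at 0 or 1 clamped into the open interval")
    z = stats.norm.isf(np.clip(arr, lo, hi))
    return z if np.ndim(p) else float(z[0])


def summarize_by_group(
    results: pd.DataFrame,
    group_col: str,
    p_col: str = "p_raw",
    signature_length_of: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Group means of enrichment Z-scores (and signature lengths).

    ``results`` needs ``group_col`` and ``p_col`` columns plus tc_id when
    ``signature_length_of`` (tc_id -> signature length) is given. Returns
    one row per group with mean_z and, when available,
    mean_signature_length.
    """
    df = results.copy()
    df["_z"] = z_from_p(df[p_col].to_numpy())
    out = df.groupby(group_col)["_z"].mean().rename("mean_z").to_frame()
    if signature_length_of is not None:
        df["_len"] = df["tc_id"].map(signature_length_of)
        out["mean_signature_length"] = df.groupby(group_col)["_len"].mean()
    return out.reset_index()
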