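"""File formats: GMT gene sets, count matrices, annotations, result bundles.

Everything is plain text. A *signature bundle* is a directory holding
``signatures.gmt`` (one line per TC, name ``panelID|tcLabel``),
``tstats.tsv`` (full genes x TC t-statistic matrix; its index doubles as
the panel's gene universe) and ``panel.json`` (metadata + top fraction).
A *reference bundle* holds ``tags.gmt``, ``p_matrix.tsv`` (first column
tag_id, header tc_ids) and ``manifest.json``.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread

from ._util import dedupe_preserving_order, normalize_symbol, sha256_of_file
from .panel import PanelMetadata, SignaturePanel, TStatMatrix
from .permutation import QueryResult, TAGReference

FLOAT_FMT = "%.10g"


class GMTFormatError(ValueError):
    """A malformed GMT line, reported with its line number."""


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT file into an ordered ``{set_name: gene_list}`` mapping.

    Each line: name, description, then >= 1 gene, tab-separated. CRLF and
    LF line endings parse identically; duplicate genes within a line are
    dropped with a warning.
    """
    sets: dict[str, list[str]] = {}
    with open(path, newline="") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3 or not fields[0] or not any(fields[2:]):
                raise GMTFormatError(
                    f"{path}:{lineno}: expected name, description and >= 1 gene"
                )
            genes = [normalize_symbol(g) for g in fields[2:] if g.strip()]
            unique = dedupe_preserving_order(genes)
            if len(unique) < len(genes):
                warnings.warn(
                    f"{path}:{lineno}: {len(genes) - len(unique)} duplicate "
                    f"gene(s) in set {fields[0]!r} dropped"
                )
            if fields[0] in sets:
                raise GMTFormatError(f"{path}:{lineno}: duplicate set name {fields[0]!r}")
            sets[fields[0]] = unique
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, descriptions=None) -> None:
    descriptions = descriptions or {}
    with open(path, "w", newline="\n") as fh:
        for name, genes in sets.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    """One gene symbol per line; blank lines and '#' comments skipped.

    A .gmt path is accepted too: its first set is taken.
    """
    path = Path(path)
    if path.suffix.lower() == ".gmt":
        sets = read_gmt(path)
        return next(iter(sets.values()))
    out = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Tab-separated genes x cells matrix; header row of cell ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def read_counts_mtx(matrix: str | Path, genes: str | Path, cells: str | Path) -> pd.DataFrame:
    """Matrix-market triplet file plus one-per-line gene and cell id lists."""
    raw = mmread(matrix)
    m = np.asarray(raw.todense() if hasattr(raw, "todense") else raw)
    gene_ids = [l.strip() for l in Path(genes).read_text().splitlines() if l.strip()]
    cell_ids = [l.strip() for l in Path(cells).read_text().splitlines() if l.strip()]
    if m.shape != (len(gene_ids), len(cell_ids)):
        raise ValueError(
            f"matrix shape {m.shape} does not match {len(gene_ids)} genes x "
            f"{len(cell_ids)} cells"
        )
    return pd.DataFrame(m, index=gene_ids, columns=cell_ids)


def read_cell_annotations(path: str | Path) -> pd.DataFrame:
    """Tab-separated table with at least cell_id and cell_type columns."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"cell_id", "cell_type"} <= set(df.columns):
        raise ValueError(f"{path}: header must include cell_id and cell_type")
    return df


# -- signature bundles -------------------------------------------------------

def save_signature_panel(sp: SignaturePanel, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gmt = {f"{sp.panel_id}|{tc}": genes for tc, genes in sp.signatures.items()}
    meta = sp.metadata
    desc = {
        f"{sp.panel_id}|{tc}": (meta.tissue if meta else "na") or "na"
        for tc in sp.signatures
    }
    write_gmt(gmt, outdir / "signatures.gmt", desc)
    sp.tstats.to_frame().to_csv(outdir / "tstats.tsv", sep="\t", float_format=FLOAT_FMT)
    payload = {
        "panel_id": sp.panel_id,
        "top_fraction": sp.top_fraction,
        "n_universe": len(sp.universe),
        "metadata": None
        if meta is None
        else {
            "panel_id": meta.panel_id,
            "tissue": meta.tissue,
            "organ_system": meta.organ_system,
            "developmental_stage": meta.developmental_stage,
            "uberon_id": meta.uberon_id,
            "cl_ids": meta.cl_ids,
        },
    }
    (outdir / "panel.json").write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def load_signature_panel(indir: str | Path) -> SignaturePanel:
    indir = Path(indir)
    payload = json.loads((indir / "panel.json").read_text())
    tdf = pd.read_csv(indir / "tstats.tsv", sep="\t", index_col=0)
    tstats = TStatMatrix(tdf.to_numpy(), [str(g) for g in tdf.index], list(tdf.columns))
    gmt = read_gmt(indir / "signatures.gmt")
    panel_id = payload["panel_id"]
    signatures = {name.partition("|")[2]: genes for name, genes in gmt.items()}
    meta = payload.get("metadata")
    return SignaturePanel(
        panel_id=panel_id,
        universe=sorted(tdf.index.astype(str)),
        signatures=signatures,
        tstats=tstats,
        top_fraction=payload["top_fraction"],
        metadata=None if meta is None else PanelMetadata(**meta),
    )


# -- reference bundles -------------------------------------------------------

def save_reference(ref: TAGReference, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_gmt(ref.tag_sets, outdir / "tags.gmt")
    ref.p_matrix.to_csv(
        outdir / "p_matrix.tsv", sep="\t", index_label="tag_id", float_format=FLOAT_FMT
    )
    manifest = dict(ref.meta)
    manifest["n_tags"] = ref.n_tags
    manifest["tc_ids"] = ref.tc_ids
    manifest["tags_gmt_sha256"] = sha256_of_file(outdir / "tags.gmt")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def load_reference(indir: str | Path) -> TAGReference:
    indir = Path(indir)
    tag_sets = read_gmt(indir / "tags.gmt")
    p_matrix = pd.read_csv(indir / "p_matrix.tsv", sep="\t", index_col="tag_id")
    meta = {}
    manifest = indir / "manifest.json"
    if manifest.exists():
        meta = json.loads(manifest.read_text())
    lengths = {t: len(set(g)) for t, g in tag_sets.items()}
    return TAGReference(tag_sets, lengths, p_matrix, meta)


# -- results -----------------------------------------------------------------

def write_query_result(result: QueryResult, path: str | Path) -> None:
    """QueryResult table as TSV, with thresholds echoed in a header comment."""
    with open(path, "w", newline="\n") as fh:
        fh.write(
            f"# bonferroni_threshold={result.bonferroni_threshold:.6g}\t"
            f"nominal_threshold={result.nominal_threshold:.6g}\t"
            f"cumulative_factor={result.cumulative_factor:.6g}\t"
            f"n_input={result.n_input}\tn_mapped={result.n_mapped}\n"
        )
        result.table.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FMT)


def write_plotting_table(result: QueryResult, path: str | Path) -> None:
    """Long-format table for jitter-plot style views of the result.

    One row per (TC, stratification), with the stratifications the result
    carries: organ system, developmental stage + organ system, tissue and
    general cell type.
    """
    df = result.table
    blocks = []
    strata = {
        "organ_system": df["organ_system"],
        "stage_organ_system": df["developmental_stage"] + " " + df["organ_system"],
        "tissue": df["tissue"],
        "cell_type": df["cell_type"],
    }
    for name, group in strata.items():
        block = df[["tc_id", "p_raw", "p_combined"]].copy()
        block.insert(0, "stratification", name)
        block.insert(1, "group", group)
        blocks.append(block)
    long = pd.concat(blocks, ignore_index=True)
    long["neg_log10_p_raw"] = -np.log10(long["p_raw"])
    long["neg_log10_p_combined"] = -np.log10(long["p_combined"])
    long.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
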