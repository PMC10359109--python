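"""Shared helpers: gene-symbol normalization, checksums."""

from __future__ import annotations

import hashlib
from pathlib import Path


def normalize_symbol(symbol: str) -> str:
    """Canonical form of a gene symbol: whitespace-stripped, upper-cased."""
    return symbol.strip().upper()


def dedupe_preserving_order(items):
    """Unique items in first-seen order."""
    seen = set()
    out = []
    for it in items:
        if it not in seen:
            seen.add(it)
            out.append(it)
    return out


def sha256_of_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
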