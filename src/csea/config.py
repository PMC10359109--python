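"""Run configuration and significance annotation."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np


@dataclass
class RunConfig:
    """All tunable thresholds of the pipeline, with their defaults.

    ``bonferroni_alpha / n_tcs`` gives the Bonferroni-corrected
    significance line (3.69e-5 for 1355 tissue-cell types); ``nominal_p``
    is the fixed nominal line. Query-length bounds are advisory: queries
    outside [min_query_len, max_query_len] trigger a warning, not an error.
    """

    top_fraction: float = 0.05
    min_cells_per_type: int = 30
    gene_min_cells: int = 3
    gene_min_fraction: float = 0.001
    tag_min_len: int = 20
    tag_max_len: int = 2000
    min_query_len: int = 20
    max_query_len: int = 2000
    bonferroni_alpha: float = 0.05
    nominal_p: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must be in (0, 1]")
        for name in ("bonferroni_alpha", "nominal_p"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.tag_min_len > self.tag_max_len:
            raise ValueError("tag length bounds out of order")
        if self.min_query_len > self.max_query_len:
            raise ValueError("query length bounds out of order")

    def to_text(self) -> str:
        return "\n".join(f"{f.name} = {getattr(self, f.name)}" for f in fields(self))

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Parse a flat ``key = value`` text file ('#' starts a comment)."""
        kwargs = {}
        types = {f.name: f.type for f in fields(cls)}
        casts = {"int": int, "float": float}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in types:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            kwargs[key] = casts.get(str(types[key]), float)(value)
        return cls(**kwargs)


def bonferroni_threshold(n_tcs: int, alpha: float = 0.05) -> float:
    """Family-wise threshold alpha / n_tcs."""
    if n_tcs < 1:
        raise ValueError("n_tcs must be >= 1")
    return alpha / n_tcs


def annotate_significance(
    p_combined,
    n_tcs: int,
    config: RunConfig | None = None,
):
    """Flag p-values against the Bonferroni and nominal lines (strict <).

    Returns ``(bonferroni_flags, nominal_flags, threshold)`` where
    ``threshold = bonferroni_alpha / n_tcs``.
    """
    config = config or RunConfig()
    threshold = bonferroni_threshold(n_tcs, config.bonferroni_alpha)
    p = np.asarray(p_combined, dtype=float)
    return p < threshold, p < config.nominal_p, threshold
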