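"""Seed gene selection.

Seeds anchor driver-network expansion: per subtype, genes ranking in the top
5% by subtype-average copy-number score AND in the top 10% by pooled
CNA-expression correlation.  Rank cutoffs use ceil(fraction * N) and retain
all genes tied at the boundary, so selection is invariant to sort order and
to any strictly monotone transform of the score vectors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class SeedSet:
    """Per-subtype seed genes with the scores that selected them."""

    subtype: str
    seeds: set[str]
    table: pd.DataFrame  # index gene; columns avg_cna_score, cna_expr_corr

    def __len__(self) -> int:
        return len(self.seeds)

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.insert(0, "subtype", self.subtype)
        out.to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SeedSet":
        df = pd.read_csv(path, sep="\t", index_col="gene")
        subtype = str(df["subtype"].iloc[0]) if "subtype" in df and len(df) else ""
        cols = [c for c in ("avg_cna_score", "cna_expr_corr") if c in df.columns]
        return cls(subtype=subtype, seeds=set(df.index.astype(str)), table=df[cols])


def _top_mask(values: np.ndarray, k: int) -> np.ndarray:
    """Boolean mask of the k largest values, keeping boundary ties."""
    if k >= len(values):
        return np.ones(len(values), dtype=bool)
    cutoff = np.partition(values, len(values) - k)[len(values) - k]
    return values >= cutoff


def select_seeds(
    scores: pd.Series,
    correlations: pd.Series,
    top_frac_cna: float = 0.05,
    top_frac_corr: float = 0.10,
    mode: str = "absolute",
    corr_absolute: bool = False,
    subtype: str = "",
) -> SeedSet:
    """Intersect the top CNA-score and top CNA-expression-correlation genes.

    Parameters
    ----------
    scores:
        gene -> subtype-average discrete CNA score.
    correlations:
        gene -> pooled CNA-expression Pearson correlation.
    mode:
        ``"absolute"`` ranks by \\|score\\| so recurrently deleted genes can
        seed networks too; ``"amplification"`` ranks by signed score
        (amplification-only seeds).
    corr_absolute:
        rank correlations by magnitude instead of signed value (default
        signed: amplification should raise expression).

    The gene universe is the intersection of both inputs; an empty result is
    returned with a warning, not an error.
    """
    if mode not in ("absolute", "amplification"):
        raise ValueError(f"unknown seed-selection mode {mode!r}")
    if not (0 < top_frac_cna <= 1 and 0 < top_frac_corr <= 1):
        raise ValueError("selection fractions must lie in (0, 1]")
    universe = scores.index.intersection(correlations.index)
    n = len(universe)
    if n == 0:
        raise ValueError("scores and correlations share no genes")
    s = scores.loc[universe].to_numpy(float)
    c = correlations.loc[universe].to_numpy(float)
    s_rank = np.abs(s) if mode == "absolute" else s
    c_rank = np.abs(c) if corr_absolute else c
    k_cna = math.ceil(top_frac_cna * n)
    k_corr = math.ceil(top_frac_corr * n)
    mask = _top_mask(s_rank, k_cna) & _top_mask(c_rank, k_corr)
    genes = set(universe[mask])
    if not genes:
        log.warning("seed selection for %s: empty intersection over %d genes", subtype, n)
    table = pd.DataFrame(
        {"avg_cna_score": s[mask], "cna_expr_corr": c[mask]},
        index=pd.Index(universe[mask], name="gene"),
    ).sort_index()
    return SeedSet(subtype=subtype, seeds=genes, table=table)
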