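"""siRNA knockdown screen scoring.

A gene is *functionally validated* in a cell line when at least two of its
siRNAs significantly reduce viability relative to the control wells (one-
sided Welch t-test per siRNA).  The group-level *viability score* is the
mean over genes of the fraction of the group's cell lines in which the gene
validated; sweeping the significance threshold yields a curve that compares
gene sets (driver-network members vs plain differential-expression picks).

Screens arrive as a tidy table with columns
``gene, sirna_id, cell_line, group, replicate, viability, is_control``;
control rows are matched by cell line.  Cell-line and siRNA counts are taken
from the data, never hard-coded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

SCREEN_COLUMNS = ["gene", "sirna_id", "cell_line", "group", "replicate",
                  "viability", "is_control"]

_P_FLOOR = 1e-300  # keeps "significant iff p <= alpha" vacuous only at alpha >= 1


@dataclass
class ScreenResult:
    """All measurements for one gene in one cell line."""

    gene: str
    cell_line: str
    group: str
    sirna_viability: dict[str, np.ndarray]
    control_viability: np.ndarray


def load_screen(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SCREEN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: screen table lacks columns {missing}")
    df["is_control"] = df["is_control"].astype(bool)
    df["viability"] = df["viability"].astype(float)
    if (df["viability"] < 0).any():
        raise ValueError(f"{path}: negative viability values")
    return df


def screen_results(df: pd.DataFrame) -> list[ScreenResult]:
    """Split a tidy screen table into per-(gene, cell line) records."""
    out: list[ScreenResult] = []
    controls = {
        line: grp["viability"].to_numpy(float)
        for line, grp in df[df["is_control"]].groupby("cell_line", sort=True)
    }
    tested = df[~df["is_control"]]
    for (gene, line), grp in tested.groupby(["gene", "cell_line"], sort=True):
        if line not in controls:
            raise ValueError(f"cell line {line!r} has no control wells")
        sirnas = {
            str(sid): g["viability"].to_numpy(float)
            for sid, g in grp.groupby("sirna_id", sort=True)
        }
        out.append(ScreenResult(
            gene=str(gene), cell_line=str(line),
            group=str(grp["group"].iloc[0]),
            sirna_viability=sirnas,
            control_viability=controls[line],
        ))
    return out


def sirna_pvalues(result: ScreenResult) -> dict[str, float]:
    """One-sided Welch p-value per siRNA for viability *reduction* vs control.

    Degenerate comparisons (no variance anywhere, identical means) get
    p = 0.5 via the t = 0 convention of the underlying test; undefined
    results fall back to p = 1.
    """
    if result.control_viability.size == 0:
        raise ValueError(f"{result.gene}/{result.cell_line}: missing control wells")
    out = {}
    for sid, vals in result.sirna_viability.items():
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.ttest_ind(vals, result.control_viability,
                                  equal_var=False, alternative="less")
            p = float(res.pvalue)
        if not np.isfinite(p):
            p = 1.0
        out[sid] = float(np.clip(p, _P_FLOOR, 1.0))
    return out


def gene_validated(result: ScreenResult, alpha: float, min_sirnas: int = 2) -> bool:
    """True iff >= ``min_sirnas`` siRNAs significantly reduce viability at ``alpha``."""
    pvals = sirna_pvalues(result)
    return sum(p <= alpha for p in pvals.values()) >= min_sirnas


def viability_score(
    results: list[ScreenResult],
    gene_set: set[str],
    group: str,
    alpha: float,
    min_sirnas: int = 2,
) -> float:
    """Mean over genes of the validated-line fraction within a cell-line group."""
    if not gene_set:
        raise ValueError("empty gene set")
    per_gene: dict[str, list[bool]] = {}
    for r in results:
        if r.gene in gene_set and r.group == group:
            per_gene.setdefault(r.gene, []).append(
                gene_validated(r, alpha, min_sirnas=min_sirnas))
    if not per_gene:
        raise ValueError(f"no screen data for the gene set in group {group!r}")
    fracs = [np.mean(calls) for calls in per_gene.values()]
    return float(np.mean(fracs))


def viability_curve(
    results: list[ScreenResult],
    gene_set: set[str],
    group: str,
    alphas: list[float],
    min_sirnas: int = 2,
) -> pd.DataFrame:
    """Viability score across a sweep of significance thresholds.

    ``alphas`` must be sorted ascending; the resulting score column is
    monotone non-decreasing in alpha on any fixed data set.
    """
    if list(alphas) != sorted(alphas):
        raise ValueError("alphas must be sorted ascending")
    scores = [viability_score(results, gene_set, group, a, min_sirnas=min_sirnas)
              for a in alphas]
    return pd.DataFrame({"alpha": list(alphas), "score": scores})
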