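"""Differential expression and differential co-expression statistics.

Two node/edge criteria drive network expansion:

* **Differential overexpression** (per probe, subtype vs rest): the union of
  the top 2% of probes by Welch t-test p-value and the top 1% by median
  expression difference, restricted to probes whose median difference is
  positive (only overexpression expands networks; downregulated genes can
  still enter via seeds or co-expression).  A Bonferroni-significance flag is
  recorded alongside the rank selection.

* **Differential co-expression** (per network edge): Pearson correlation of
  the endpoint genes within the subtype minus the correlation over all other
  samples.  Edges in the top 0.2% of this difference qualify.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# small rank helpers shared across modules
# ---------------------------------------------------------------------------

def top_k_cutoff(values: np.ndarray, k: int, largest: bool = True) -> float:
    """Value of the k-th largest (or smallest) element."""
    k = min(max(k, 1), len(values))
    if largest:
        return float(np.partition(values, len(values) - k)[len(values) - k])
    return float(np.partition(values, k - 1)[k - 1])


def group_columns(labels: pd.Series, samples: list[str], subtype: str
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Index arrays of subtype vs rest within ``samples`` (ordered)."""
    lab = labels.loc[samples].to_numpy()
    idx = np.arange(len(samples))
    return idx[lab == subtype], idx[lab != subtype]


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

@dataclass
class DifferentialExpressionResult:
    """Per-probe test results plus the rank-selected probe and gene sets."""

    subtype: str
    p_values: pd.Series
    median_diff: pd.Series
    bonferroni_significant: pd.Series
    selected_probes: set[str]
    selected_by: pd.Series  # probe -> 'p' | 'median' | 'both' for selected probes
    selected_genes: set[str]
    p_cutoff: float
    median_cutoff: float
    params: dict = field(default_factory=dict)


def welch_pvalues(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise two-tailed Welch t-test p-values (probes x samples inputs).

    Degenerate probes (zero variance in both groups with equal means, or
    too few observations) get p = 1.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False, nan_policy="omit")
        p = np.asarray(res.pvalue, dtype=float)
    return np.where(np.isfinite(p), p, 1.0)


def differential_expression(
    expr: pd.DataFrame,
    probe_map: pd.Series,
    labels: pd.Series,
    subtype: str,
    top_frac_p: float = 0.02,
    top_frac_median: float = 0.01,
    bonferroni_alpha: float = 0.05,
    strict_bonferroni: bool = False,
) -> DifferentialExpressionResult:
    """Select subtype-overexpressed probes and map them to genes.

    Probes are ranked by raw Welch p (ascending, top ``top_frac_p``) and by
    median(subtype) - median(rest) (descending, top ``top_frac_median``);
    the union is kept, restricted to positive median differences.  Boundary
    ties are retained.  ``strict_bonferroni`` additionally requires
    p <= bonferroni_alpha / n_probes.
    """
    samples = [s for s in expr.columns if s in labels.index]
    cols_in, cols_out = group_columns(labels, samples, subtype)
    if len(cols_in) < 2 or len(cols_out) < 2:
        raise ValueError(
            f"differential expression needs >=2 samples per group "
            f"(got {len(cols_in)} {subtype!r} vs {len(cols_out)} rest)")
    X = expr[samples].to_numpy(float)
    p = welch_pvalues(X[:, cols_in], X[:, cols_out])
    md = np.nanmedian(X[:, cols_in], axis=1) - np.nanmedian(X[:, cols_out], axis=1)

    n_probes = len(expr.index)
    p_cutoff = top_k_cutoff(p, math.ceil(top_frac_p * n_probes), largest=False)
    md_cutoff = top_k_cutoff(md, math.ceil(top_frac_median * n_probes), largest=True)
    sel_p = p <= p_cutoff
    sel_m = md >= md_cutoff
    bonf = p <= bonferroni_alpha / n_probes
    selected = (sel_p | sel_m) & (md > 0)
    if strict_bonferroni:
        selected &= bonf

    probes = expr.index
    by = np.where(sel_p & sel_m, "both", np.where(sel_p, "p", "median"))
    selected_probes = set(probes[selected])
    mapped = probe_map.loc[probe_map.index.intersection(probes[selected])]
    n_unmapped = len(selected_probes) - len(mapped)
    if n_unmapped:
        log.info("%s: %d selected probe(s) without gene mapping ignored", subtype, n_unmapped)
    return DifferentialExpressionResult(
        subtype=subtype,
        p_values=pd.Series(p, index=probes, name="p_value"),
        median_diff=pd.Series(md, index=probes, name="median_diff"),
        bonferroni_significant=pd.Series(bonf, index=probes, name="bonferroni_significant"),
        selected_probes=selected_probes,
        selected_by=pd.Series(by[selected], index=probes[selected], name="selected_by"),
        selected_genes=set(mapped),
        p_cutoff=p_cutoff,
        median_cutoff=md_cutoff,
        params={
            "top_frac_p": top_frac_p,
            "top_frac_median": top_frac_median,
            "bonferroni_alpha": bonferroni_alpha,
            "strict_bonferroni": strict_bonferroni,
        },
    )


def de_result_table(de: DifferentialExpressionResult, probe_map: pd.Series) -> pd.DataFrame:
    """Tidy per-probe table (probe, gene, p, Bonferroni flag, median diff, selected_by)."""
    df = pd.DataFrame({
        "gene": probe_map.reindex(de.p_values.index),
        "p_value": de.p_values,
        "bonferroni_significant": de.bonferroni_significant,
        "median_diff": de.median_diff,
        "selected_by": de.selected_by.reindex(de.p_values.index, fill_value=""),
    })
    df.index.name = "probe"
    return df


# ---------------------------------------------------------------------------
# differential co-expression
# ---------------------------------------------------------------------------

@dataclass
class EdgeDifferentialCorrelation:
    """Differential correlation of one network edge.

    ``delta = r_in - r_out`` where r_in is the Pearson correlation over the
    subtype's samples and r_out over all remaining samples.  A constant
    vector on either side makes that correlation 0 and sets the degeneracy
    flag rather than dropping the edge.
    """

    gene_a: str
    gene_b: str
    r_in: float
    r_out: float
    probe_a: str
    probe_b: str
    degenerate: bool = False

    @property
    def delta(self) -> float:
        return self.r_in - self.r_out


def standardize_rows(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise z-scores (population SD); constant rows become all-zero.

    Returns (Z, ok) where ``ok`` flags rows with positive variance.  With
    this convention the Pearson correlation of rows i, j is mean(Z_i * Z_j),
    and any correlation involving a constant row is 0 (degenerate).
    """
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    ok = sd[:, 0] > 0
    Z = np.where(sd > 0, (X - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return Z, ok


def pearson_rows(Z: np.ndarray, ia: np.ndarray, ib: np.ndarray) -> np.ndarray:
    """Pearson r between standardized rows ia and ib (vectorised)."""
    return np.einsum("ij,ij->i", Z[ia], Z[ib]) / Z.shape[1]


def edge_differential_correlation(
    edge: tuple[str, str],
    expr: pd.DataFrame,
    probe_map: pd.Series,
    labels: pd.Series,
    subtype: str,
) -> EdgeDifferentialCorrelation:
    """Differential Pearson correlation for a single gene pair.

    For multi-probe genes the probe pair with the largest in-subtype \\|r\\|
    is used for both correlations.  Requires >=3 samples in each group and
    >=1 probe per endpoint.  Symmetric in the two endpoints.
    """
    gene_a, gene_b = edge
    samples = [s for s in expr.columns if s in labels.index]
    cols_in, cols_out = group_columns(labels, samples, subtype)
    if len(cols_in) < 3 or len(cols_out) < 3:
        raise ValueError("differential correlation needs >=3 samples per group")
    probes_a = list(probe_map.index[(probe_map == gene_a) & probe_map.index.isin(expr.index)])
    probes_b = list(probe_map.index[(probe_map == gene_b) & probe_map.index.isin(expr.index)])
    if not probes_a or not probes_b:
        raise ValueError(f"edge {edge}: both genes need >=1 expression probe")

    X = expr.loc[probes_a + probes_b, samples].to_numpy(float)
    Z_in, ok_in = standardize_rows(X[:, cols_in])
    Z_out, ok_out = standardize_rows(X[:, cols_out])
    na, nb = len(probes_a), len(probes_b)
    ia, ib = np.meshgrid(np.arange(na), np.arange(na, na + nb), indexing="ij")
    ia, ib = ia.ravel(), ib.ravel()
    r_in = pearson_rows(Z_in, ia, ib)
    best = int(np.argmax(np.abs(r_in)))
    r_out = pearson_rows(Z_out, ia[best:best + 1], ib[best:best + 1])[0]
    degen = not (ok_in[ia[best]] and ok_in[ib[best]] and ok_out[ia[best]] and ok_out[ib[best]])
    return EdgeDifferentialCorrelation(
        gene_a=gene_a, gene_b=gene_b,
        r_in=float(r_in[best]), r_out=float(r_out),
        probe_a=probes_a[ia[best]], probe_b=probes_b[ib[best] - na],
        degenerate=degen,
    )


def coexpression_threshold(all_deltas: np.ndarray | list[float],
                           top_frac: float = 0.002) -> float:
    """Qualification threshold: the k-th largest delta, k = max(1, floor(top_frac * n)).

    An edge qualifies iff its delta >= threshold, so (up to ties) a fraction
    ``top_frac`` of the edges qualify; with ``top_frac=1`` every edge does.
    """
    deltas = np.asarray(all_deltas, dtype=float)
    if deltas.size == 0:
        raise ValueError("empty delta distribution")
    k = max(1, math.floor(top_frac * deltas.size))
    return top_k_cutoff(deltas, k, largest=True)


# ---------------------------------------------------------------------------
# resampled differential-expression frequencies (control comparison)
# ---------------------------------------------------------------------------

def resampled_de_frequencies(
    expr: pd.DataFrame,
    probe_map: pd.Series,
    labels: pd.Series,
    subtype: str,
    sample_frac: float = 0.8,
    reps: int = 1000,
    rng_seed: int = 0,
    **de_kwargs,
) -> pd.Series:
    """Fraction of stratified subsample repetitions selecting each gene as DE.

    Mirrors the resampling used for driver-network membership, but for the
    plain differential-expression gene lists (the non-network control).
    """
    from .expansion import stratified_subsample  # local import avoids a cycle

    samples = [s for s in expr.columns if s in labels.index]
    counts: dict[str, int] = {}
    children = np.random.SeedSequence(rng_seed).spawn(reps)
    for child in children:
        rng = np.random.default_rng(child)
        cols = stratified_subsample(labels, samples, sample_frac, rng)
        de = differential_expression(expr[cols], probe_map, labels, subtype, **de_kwargs)
        for g in de.selected_genes:
            counts[g] = counts.get(g, 0) + 1
    return pd.Series({g: c / reps for g, c in sorted(counts.items())}, dtype=float)
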