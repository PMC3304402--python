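"""Cohort containers and copy-number / expression summary statistics.

A cohort bundles a probe-level expression matrix (log-scale), a probe -> gene
map, a gene-level copy-number matrix (continuous log-ratios or discrete
-1/0/+1 calls), and mutually exclusive subtype labels.  All statistics run on
the intersection of expression and copy-number sample identifiers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DISCRETE_VALUES = (-1, 0, 1)


@dataclass
class CNAMatrix:
    """Gene x sample copy-number matrix.

    ``values`` holds continuous log-ratios when ``is_discrete`` is False,
    otherwise integer calls in {-1, 0, 1} (deleted / unchanged / amplified).
    """

    values: pd.DataFrame
    is_discrete: bool = False

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("CNA matrix has duplicate gene ids")
        if self.is_discrete:
            arr = self.values.to_numpy()
            if not np.isin(arr[np.isfinite(arr)], DISCRETE_VALUES).all():
                raise ValueError("discrete CNA matrix must contain only -1, 0, 1")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class OmicsCohort:
    """Expression + probe map + CNA + subtype labels for one cohort.

    ``expression``: probes x samples DataFrame (log intensities).
    ``probe_map``: Series probe_id -> gene symbol (many-to-one allowed).
    ``labels``: Series sample_id -> subtype, mutually exclusive classes.
    """

    expression: pd.DataFrame
    probe_map: pd.Series
    cna: CNAMatrix
    labels: pd.Series
    name: str = ""

    def __post_init__(self) -> None:
        if self.expression.index.has_duplicates:
            raise ValueError("expression matrix has duplicate probe ids")
        if self.expression.columns.has_duplicates or self.cna.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        self.probe_map = self.probe_map.astype(str).str.upper()
        if (self.probe_map == "").any():
            raise ValueError("probe map contains empty gene symbols")
        n_unmapped = (~self.expression.index.isin(self.probe_map.index)).sum()
        if n_unmapped:
            log.info("%s: %d probe(s) absent from probe map are ignored", self.name, n_unmapped)
        shared = [s for s in self.expression.columns if s in set(self.cna.values.columns)]
        if not shared:
            raise ValueError("expression and CNA matrices share no sample ids")
        missing_labels = [s for s in shared if s not in self.labels.index]
        if missing_labels:
            raise ValueError(f"samples without subtype label: {missing_labels[:5]}")
        self._shared_samples = shared
        log.info(
            "%s: %d shared expression/CNA samples (%d expression, %d CNA)",
            self.name, len(shared), self.expression.shape[1], self.cna.values.shape[1],
        )

    @property
    def shared_samples(self) -> list[str]:
        """Samples present in both data types; all analyses run on these."""
        return list(self._shared_samples)

    @property
    def subtypes(self) -> list[str]:
        return sorted(self.labels.loc[self.shared_samples].unique())

    def genes_with_both_data(self) -> set[str]:
        """Genes with a CNA row and at least one mapped expression probe."""
        expr_genes = set(self.probe_map.loc[self.probe_map.index.intersection(self.expression.index)])
        return expr_genes & set(self.cna.values.index)


# ---------------------------------------------------------------------------
# loaders (TSV formats; see README for column conventions)
# ---------------------------------------------------------------------------

def load_expression(path: str | Path, max_missing_frac: float = 0.2) -> pd.DataFrame:
    """Read a probes x samples TSV (first column probe_id, header sample ids).

    Probes with more than ``max_missing_frac`` missing values are dropped
    (logged); remaining missing values are handled pairwise-complete by the
    downstream statistics.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df = df.astype(float)
    frac_missing = df.isna().mean(axis=1)
    bad = frac_missing > max_missing_frac
    if bad.any():
        log.info("%s: dropped %d probe(s) with >%.0f%% missing values",
                 path, int(bad.sum()), 100 * max_missing_frac)
        df = df.loc[~bad]
    if df.empty:
        raise ValueError(f"{path}: no probes left after missing-value filtering")
    return df


def load_probe_map(path: str | Path) -> pd.Series:
    """Read a 2-column TSV probe_id -> gene_symbol."""
    df = pd.read_csv(path, sep="\t", header=None, names=["probe_id", "gene"], dtype=str)
    if df["probe_id"].iloc[0].lower() in ("probe", "probe_id"):
        df = df.iloc[1:]
    s = df.set_index("probe_id")["gene"].str.upper()
    if s.empty:
        raise ValueError(f"{path}: empty probe map")
    return s


def load_cna(path: str | Path, is_discrete: bool | None = None) -> CNAMatrix:
    """Read a genes x samples TSV (first column gene symbol).

    Discreteness is auto-detected (all values in {-1,0,1}) unless given.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str).str.upper()
    df = df.astype(float)
    if is_discrete is None:
        arr = df.to_numpy()
        is_discrete = bool(np.isin(arr[np.isfinite(arr)], DISCRETE_VALUES).all())
    return CNAMatrix(df, is_discrete=is_discrete)


def load_labels(path: str | Path) -> pd.Series:
    """Read a 2-column TSV sample_id -> subtype."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "subtype"], dtype=str)
    if df["sample_id"].iloc[0].lower() in ("sample", "sample_id"):
        df = df.iloc[1:]
    s = df.set_index("sample_id")["subtype"]
    if s.index.has_duplicates:
        raise ValueError(f"{path}: duplicate sample ids in label file")
    return s


# ---------------------------------------------------------------------------
# copy-number scores
# ---------------------------------------------------------------------------

def discretize_cna(cna: CNAMatrix, gain_threshold: float = 0.3,
                   loss_threshold: float = -0.3) -> CNAMatrix:
    """Threshold continuous log-ratios into -1/0/+1 calls.

    An entry becomes +1 (amplified) when >= ``gain_threshold``, -1 (deleted)
    when <= ``loss_threshold``, 0 otherwise.
    """
    if cna.is_discrete:
        raise ValueError("CNA matrix is already discrete")
    if not (gain_threshold > 0 > loss_threshold):
        raise ValueError("need gain_threshold > 0 > loss_threshold")
    arr = cna.values.to_numpy()
    calls = np.zeros_like(arr)
    calls[arr >= gain_threshold] = 1
    calls[arr <= loss_threshold] = -1
    calls[~np.isfinite(arr)] = 0
    out = pd.DataFrame(calls, index=cna.values.index, columns=cna.values.columns)
    return CNAMatrix(out, is_discrete=True)


def average_cna_score(disc: CNAMatrix, labels: pd.Series, subtype: str,
                      samples: list[str] | None = None) -> pd.Series:
    """Per-gene mean of discrete calls over the subtype's samples.

    Bounded in [-1, 1]; equals 1 iff the gene is amplified in every sample
    of the subtype.  ``samples`` restricts the analysed set (defaults to all
    labelled CNA samples).
    """
    if not disc.is_discrete:
        raise ValueError("average_cna_score needs a discrete CNA matrix")
    pool = [s for s in (samples if samples is not None else disc.values.columns)
            if s in labels.index and s in set(disc.values.columns)]
    cols = [s for s in pool if labels[s] == subtype]
    if not cols:
        raise ValueError(f"subtype {subtype!r} has no samples")
    return disc.values[cols].mean(axis=1)


def cna_expression_correlation(cohort: OmicsCohort, use_discrete: bool = True,
                               gain_threshold: float = 0.3,
                               loss_threshold: float = -0.3,
                               min_samples: int = 3) -> pd.Series:
    """Pooled (all-subtypes) Pearson correlation of CNA score vs expression.

    Subtype-specific amplification makes a gene's calls constant within the
    subtype, so the correlation pools every shared sample.  For multi-probe
    genes the representative probe is the one with the highest absolute
    correlation.  Genes with a constant CNA vector, fewer than
    ``min_samples`` complete pairs, or no usable probe are omitted (logged).
    """
    calls = cohort.cna if (cohort.cna.is_discrete or not use_discrete) else \
        discretize_cna(cohort.cna, gain_threshold, loss_threshold)
    shared = cohort.shared_samples
    probes = cohort.expression.index.intersection(cohort.probe_map.index)
    genes_of_probes = cohort.probe_map.loc[probes]
    keep = genes_of_probes.isin(calls.values.index)
    probes = probes[keep.to_numpy()]
    genes_of_probes = genes_of_probes[keep]
    if len(probes) == 0:
        return pd.Series(dtype=float)

    X = cohort.expression.loc[probes, shared].to_numpy(float)
    C = calls.values.loc[genes_of_probes, shared].to_numpy(float)
    M = np.isfinite(X) & np.isfinite(C)
    n = M.sum(axis=1)
    Xm = np.where(M, X, 0.0)
    Cm = np.where(M, C, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mx = Xm.sum(1) / n
        mc = Cm.sum(1) / n
        sxx = (Xm**2).sum(1) / n - mx**2
        scc = (Cm**2).sum(1) / n - mc**2
        sxc = (Xm * Cm).sum(1) / n - mx * mc
        r = sxc / np.sqrt(sxx * scc)
    bad = (n < min_samples) | (scc <= 0) | (sxx <= 0) | ~np.isfinite(r)
    r[bad] = np.nan

    per_probe = pd.DataFrame({"gene": genes_of_probes.to_numpy(), "r": r}, index=probes)
    out: dict[str, float] = {}
    n_omitted = 0
    for gene, grp in per_probe.groupby("gene", sort=True):
        vals = grp["r"].to_numpy()
        if np.isnan(vals).all():
            n_omitted += 1
            continue
        out[gene] = float(vals[np.nanargmax(np.abs(vals))])
    if n_omitted:
        log.info("%s: omitted %d gene(s) with undefined CNA-expression correlation",
                 cohort.name, n_omitted)
    return pd.Series(out, dtype=float)


def collapse_probes(expr: pd.DataFrame, probe_map: pd.Series,
                    rule: str = "max_variance",
                    partner: pd.DataFrame | pd.Series | None = None,
                    ) -> tuple[pd.DataFrame, pd.Series]:
    """Collapse a probe-level matrix to one representative row per gene.

    ``rule="max_variance"`` keeps the most variable probe;
    ``rule="max_abs_correlation_vs_partner"`` keeps the probe whose Pearson
    correlation with the partner vector has the largest magnitude.
    ``partner`` is a Series (one vector, aligned on samples) or a genes x
    samples DataFrame (per-gene partner, e.g. copy-number calls).

    Returns the gene-level matrix and a Series gene -> chosen probe.  Output
    rows are always copies of input rows; nothing is averaged or invented.
    """
    if rule not in ("max_variance", "max_abs_correlation_vs_partner"):
        raise ValueError(f"unknown collapse rule {rule!r}")
    if probe_map.empty:
        raise ValueError("empty probe map")
    probes = expr.index.intersection(probe_map.index)
    if len(probes) == 0:
        raise ValueError("no probes in common between matrix and probe map")
    genes = probe_map.loc[probes]

    if rule == "max_variance":
        score = expr.loc[probes].var(axis=1, ddof=1).to_numpy()
    else:
        if partner is None:
            raise ValueError("rule max_abs_correlation_vs_partner needs a partner")
        X = expr.loc[probes].to_numpy(float)
        if isinstance(partner, pd.Series):
            P = np.broadcast_to(partner.loc[expr.columns].to_numpy(float), X.shape)
        else:
            keep = genes.isin(partner.index).to_numpy()
            probes, genes = probes[keep], genes[keep]
            X = X[keep]
            P = partner.loc[genes, expr.columns].to_numpy(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            Xz = X - X.mean(1, keepdims=True)
            Pz = P - P.mean(1, keepdims=True)
            num = (Xz * Pz).sum(1)
            den = np.sqrt((Xz**2).sum(1) * (Pz**2).sum(1))
            score = np.abs(num / den)
        score = np.where(np.isfinite(score), score, -np.inf)

    tbl = pd.DataFrame({"gene": genes.to_numpy(), "score": score}, index=probes)
    chosen = {g: grp["score"].idxmax() for g, grp in tbl.groupby("gene", sort=True)}
    mapping = pd.Series(chosen, name="probe_id")
    collapsed = expr.loc[mapping.to_numpy()]
    collapsed.index = mapping.index
    return collapsed, mapping
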