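"""Driver-network expansion.

Starting from copy-number-anchored seed genes, the network grows through the
interactome: a neighbour of any current member joins if it is differentially
overexpressed, and a neighbour of a *differentially expressed* member joins
if their connecting edge's differential correlation clears the global top-
0.2% threshold.  The process iterates to a fixed point, which is independent
of processing order because both inclusion predicates are fixed once the
differential-expression set and the co-expression threshold are computed.

Membership is then stabilised by resampling: the expansion is repeated on
stratified 80% subsamples (recomputing the differential-expression selection
and the co-expression threshold each time) and only genes appearing in at
least half of the repetitions are kept.
"""

from __future__ import annotations

import logging
import math
from collections import Counter, deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .differential_stats import (
    DifferentialExpressionResult,
    coexpression_threshold,
    pearson_rows,
    standardize_rows,
    top_k_cutoff,
    welch_pvalues,
)
from .network_space import NetworkSpace
from .seed_selection import SeedSet

log = logging.getLogger(__name__)

#: inclusion reasons, in precedence order
REASONS = ("seed+differential_expression", "seed", "differential_expression", "coexpression_only")


# ---------------------------------------------------------------------------
# pure fixed-point expansion (graph + labellings only)
# ---------------------------------------------------------------------------

def fixed_point_members(
    seeds: set[str],
    adjacency: dict[str, set[str]],
    de_genes: set[str],
    qualifying_edges,
) -> tuple[set[str], dict[str, str]]:
    """Grow the member set from ``seeds`` to its fixed point.

    A non-member neighbour ``v`` of a member ``m`` is included when
    ``v in de_genes``, or when ``m in de_genes`` and the edge (m, v)
    qualifies by differential co-expression.  ``qualifying_edges`` is a set
    of unordered gene pairs or a prebuilt adjacency dict.

    Returns the member set and a per-member inclusion reason.  Seeds absent
    from the adjacency are retained as isolated members.
    """
    if isinstance(qualifying_edges, dict):
        qual_adj = qualifying_edges
    else:
        qual_adj: dict[str, set[str]] = {}
        for a, b in qualifying_edges:
            qual_adj.setdefault(a, set()).add(b)
            qual_adj.setdefault(b, set()).add(a)

    reasons: dict[str, str] = {}
    queue: deque[str] = deque()
    for s in sorted(seeds):
        reasons[s] = "seed+differential_expression" if s in de_genes else "seed"
        queue.append(s)
    members = set(reasons)
    while queue:
        m = queue.popleft()
        m_de = m in de_genes
        m_qual = qual_adj.get(m, ()) if m_de else ()
        for v in adjacency.get(m, ()):
            if v in members:
                continue
            if v in de_genes:
                reasons[v] = "differential_expression"
            elif v in m_qual:
                reasons[v] = "coexpression_only"
            else:
                continue
            members.add(v)
            queue.append(v)
    return members, reasons


# ---------------------------------------------------------------------------
# expansion context: arrays prepared once per (network, cohort, subtype)
# ---------------------------------------------------------------------------

@dataclass
class ExpansionContext:
    """Precomputed arrays tying a network space to one cohort and subtype."""

    subtype: str
    samples: list[str]
    X: np.ndarray                       # probes x samples
    probe_ids: np.ndarray               # row -> probe id
    gene_of_row: np.ndarray             # row -> gene symbol ('' if unmapped)
    in_mask: np.ndarray                 # sample -> belongs to subtype
    adjacency: dict[str, set[str]]
    edges: list[tuple[str, str]]        # unordered gene pairs with probes on both ends
    pair_a: np.ndarray                  # candidate probe-pair row indices
    pair_b: np.ndarray
    pair_edge: np.ndarray               # probe pair -> edge index
    edge_starts: np.ndarray             # reduceat starts per edge

    @property
    def n_probes(self) -> int:
        return self.X.shape[0]

    def columns_for(self, sample_ids: list[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.samples)}
        return np.array(sorted(pos[s] for s in sample_ids), dtype=int)


def prepare_expansion_context(
    net: NetworkSpace,
    expr: pd.DataFrame,
    probe_map: pd.Series,
    labels: pd.Series,
    subtype: str,
    respect_direction: bool = False,
) -> ExpansionContext:
    samples = [s for s in expr.columns if s in labels.index]
    if not samples:
        raise ValueError("no labelled samples in expression matrix")
    X = expr[samples].to_numpy(float)
    probe_ids = np.asarray(expr.index, dtype=object)
    mapped = expr.index.isin(probe_map.index)
    gene_of_row = np.array(
        [probe_map[p] if ok else "" for p, ok in zip(expr.index, mapped)], dtype=object
    )
    gene_rows: dict[str, list[int]] = {}
    for i, g in enumerate(gene_of_row):
        if g:
            gene_rows.setdefault(g, []).append(i)

    edges = [(a, b) for a, b in net.gene_pairs() if a in gene_rows and b in gene_rows]
    pa: list[int] = []
    pb: list[int] = []
    starts: list[int] = []
    sizes: list[int] = []
    pos = 0
    for a, b in edges:
        ra, rb = gene_rows[a], gene_rows[b]
        starts.append(pos)
        sizes.append(len(ra) * len(rb))
        for i in ra:
            for j in rb:
                pa.append(i)
                pb.append(j)
        pos += len(ra) * len(rb)
    lab = labels.loc[samples].to_numpy()
    return ExpansionContext(
        subtype=subtype,
        samples=samples,
        X=X,
        probe_ids=probe_ids,
        gene_of_row=gene_of_row,
        in_mask=(lab == subtype),
        adjacency=net.adjacency(respect_direction=respect_direction),
        edges=edges,
        pair_a=np.asarray(pa, dtype=int),
        pair_b=np.asarray(pb, dtype=int),
        pair_edge=np.repeat(np.arange(len(edges)), sizes) if edges else np.empty(0, int),
        edge_starts=np.asarray(starts, dtype=int),
    )


def _group_argmax(values: np.ndarray, starts: np.ndarray, group_id: np.ndarray) -> np.ndarray:
    """Index of the max value within each contiguous group (first on ties)."""
    gmax = np.maximum.reduceat(values, starts)
    is_max = values == gmax[group_id]
    sel = np.full(len(starts), len(values), dtype=int)
    np.minimum.at(sel, group_id[is_max], np.flatnonzero(is_max))
    return sel


def edge_deltas(
    ctx: ExpansionContext,
    cols: np.ndarray,
    row_lookup: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-edge (r_in, r_out, delta, chosen probe-pair index) for a column subset.

    For multi-probe endpoints the probe pair with the largest in-subtype
    \\|r\\| is chosen and reused for r_out.  ``row_lookup`` remaps probe rows
    (used by the label-permutation null); identity when omitted.
    """
    if not len(ctx.edges):
        e = np.empty(0)
        return e, e, e, np.empty(0, int)
    cols_in = cols[ctx.in_mask[cols]]
    cols_out = cols[~ctx.in_mask[cols]]
    Z_in, _ = standardize_rows(ctx.X[:, cols_in])
    Z_out, _ = standardize_rows(ctx.X[:, cols_out])
    ia = ctx.pair_a if row_lookup is None else row_lookup[ctx.pair_a]
    ib = ctx.pair_b if row_lookup is None else row_lookup[ctx.pair_b]
    r_in_pairs = pearson_rows(Z_in, ia, ib)
    sel = _group_argmax(np.abs(r_in_pairs), ctx.edge_starts, ctx.pair_edge)
    r_in = r_in_pairs[sel]
    r_out = pearson_rows(Z_out, ia[sel], ib[sel])
    return r_in, r_out, r_in - r_out, sel


def de_selection(
    ctx: ExpansionContext,
    cols: np.ndarray,
    top_frac_p: float = 0.02,
    top_frac_median: float = 0.01,
) -> np.ndarray:
    """Boolean row mask of differentially overexpressed probes on a column subset."""
    cols_in = cols[ctx.in_mask[cols]]
    cols_out = cols[~ctx.in_mask[cols]]
    if len(cols_in) < 2 or len(cols_out) < 2:
        raise ValueError("differential expression needs >=2 samples per group")
    p = welch_pvalues(ctx.X[:, cols_in], ctx.X[:, cols_out])
    md = np.nanmedian(ctx.X[:, cols_in], axis=1) - np.nanmedian(ctx.X[:, cols_out], axis=1)
    p_cut = top_k_cutoff(p, math.ceil(top_frac_p * ctx.n_probes), largest=False)
    md_cut = top_k_cutoff(md, math.ceil(top_frac_median * ctx.n_probes), largest=True)
    return ((p <= p_cut) | (md >= md_cut)) & (md > 0)


def qualifying_adjacency(ctx: ExpansionContext, delta: np.ndarray,
                         threshold: float) -> dict[str, set[str]]:
    qual: dict[str, set[str]] = {}
    for e in np.flatnonzero(delta >= threshold):
        a, b = ctx.edges[e]
        qual.setdefault(a, set()).add(b)
        qual.setdefault(b, set()).add(a)
    return qual


def run_single_expansion(
    ctx: ExpansionContext,
    seeds: set[str],
    cols: np.ndarray | None = None,
    top_frac_p: float = 0.02,
    top_frac_median: float = 0.01,
    top_frac_coexpr: float = 0.002,
    delta_threshold: float | None = None,
    de_genes: set[str] | None = None,
) -> dict:
    """One full expansion on a column subset; returns members, reasons, stats."""
    if cols is None:
        cols = np.arange(len(ctx.samples))
    if de_genes is None:
        rows = de_selection(ctx, cols, top_frac_p, top_frac_median)
        de_genes = set(ctx.gene_of_row[rows]) - {""}
    r_in, r_out, delta, sel = edge_deltas(ctx, cols)
    if delta_threshold is None:
        delta_threshold = coexpression_threshold(delta, top_frac_coexpr) if len(delta) else np.inf
    qual = qualifying_adjacency(ctx, delta, delta_threshold)
    members, reasons = fixed_point_members(seeds, ctx.adjacency, de_genes, qual)
    return {
        "members": members,
        "reasons": reasons,
        "de_genes": de_genes,
        "r_in": r_in,
        "r_out": r_out,
        "delta": delta,
        "threshold": float(delta_threshold),
    }


# ---------------------------------------------------------------------------
# driver-network container
# ---------------------------------------------------------------------------

@dataclass
class DriverNetwork:
    """A grown driver-network: members, reasons, stability, induced edges."""

    subtype: str
    members: set[str]
    seeds: set[str]
    inclusion_reason: dict[str, str]
    membership_frequency: dict[str, float]
    edges: pd.DataFrame
    delta_threshold: float
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)

    def node_table(self) -> pd.DataFrame:
        genes = sorted(self.members)
        return pd.DataFrame({
            "gene": genes,
            "subtype": self.subtype,
            "inclusion_reason": [self.inclusion_reason.get(g, "") for g in genes],
            "membership_frequency": [self.membership_frequency.get(g, float("nan")) for g in genes],
            "is_seed": [g in self.seeds for g in genes],
        })

    def edge_table(self) -> pd.DataFrame:
        return self.edges

    def components(self) -> list[set[str]]:
        """Connected components over the induced edges (satellites included)."""
        adj: dict[str, set[str]] = {g: set() for g in self.members}
        for r in self.edges.itertuples():
            adj[r.source].add(r.target)
            adj[r.target].add(r.source)
        seen: set[str] = set()
        comps = []
        for g in sorted(self.members):
            if g in seen:
                continue
            comp, stack = set(), [g]
            while stack:
                x = stack.pop()
                if x in comp:
                    continue
                comp.add(x)
                stack.extend(adj[x] - comp)
            seen |= comp
            comps.append(comp)
        return comps

    def largest_component(self) -> set[str]:
        comps = self.components()
        return max(comps, key=len) if comps else set()


def _induced_edges(net: NetworkSpace, members: set[str],
                   ctx: ExpansionContext, run: dict) -> pd.DataFrame:
    """Induced edge list annotated with (r_in, r_out, delta) where computed."""
    idx = {pair: i for i, pair in enumerate(ctx.edges)}
    rows = []
    for e in net.edges:
        if e.source in members and e.target in members:
            i = idx.get(e.pair)
            rows.append({
                "source": e.source, "target": e.target,
                "directed": e.directed, "provenance": e.provenance,
                "r_in": run["r_in"][i] if i is not None else np.nan,
                "r_out": run["r_out"][i] if i is not None else np.nan,
                "delta": run["delta"][i] if i is not None else np.nan,
            })
    cols = ["source", "target", "directed", "provenance", "r_in", "r_out", "delta"]
    return pd.DataFrame(rows, columns=cols)


def _seed_genes(seeds) -> set[str]:
    return set(seeds.seeds) if isinstance(seeds, SeedSet) else set(seeds)


def expand_driver_network(
    seeds,
    net: NetworkSpace,
    de: DifferentialExpressionResult,
    delta_threshold: float,
    cohort,
    respect_direction: bool = False,
) -> DriverNetwork:
    """Single-run expansion with a precomputed DE result and delta threshold.

    ``seeds`` is a :class:`SeedSet` or a plain set of gene symbols; seeds
    absent from the network space are retained as isolated members (logged).
    """
    seed_genes = _seed_genes(seeds)
    if not seed_genes:
        raise ValueError("expansion needs at least one seed gene")
    missing = seed_genes - net.nodes
    if missing:
        log.warning("%d seed(s) absent from network space kept as isolated members: %s",
                    len(missing), sorted(missing)[:5])
    ctx = prepare_expansion_context(
        net, cohort.expression, cohort.probe_map, cohort.labels, de.subtype,
        respect_direction=respect_direction)
    run = run_single_expansion(
        ctx, seed_genes, delta_threshold=delta_threshold, de_genes=set(de.selected_genes))
    members, reasons = run["members"], run["reasons"]
    return DriverNetwork(
        subtype=de.subtype,
        members=members,
        seeds=seed_genes,
        inclusion_reason=reasons,
        membership_frequency={g: 1.0 for g in members},
        edges=_induced_edges(net, members, ctx, run),
        delta_threshold=float(delta_threshold),
        params={"resampled": False},
    )


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def stratified_subsample(labels: pd.Series, samples: list[str],
                         sample_frac: float, rng: np.random.Generator) -> list[str]:
    """Draw floor(frac * n_s) samples per subtype without replacement.

    Preserves subtype proportions so no class vanishes from a repetition.
    Raises if any stratum would drop below 2 samples.
    """
    if not (0 < sample_frac <= 1):
        raise ValueError("sample_frac must lie in (0, 1]")
    chosen: list[str] = []
    for st in sorted(set(labels.loc[samples])):
        ids = [s for s in samples if labels[s] == st]
        k = math.floor(sample_frac * len(ids))
        if k < 2:
            raise ValueError(
                f"subsample leaves {k} sample(s) for subtype {st!r}; "
                "use a larger sample_frac or more samples")
        chosen.extend(rng.choice(ids, size=k, replace=False))
    order = {s: i for i, s in enumerate(samples)}
    return sorted(chosen, key=order.__getitem__)


def resampled_driver_network(
    seeds,
    net: NetworkSpace,
    cohort,
    subtype: str,
    sample_frac: float = 0.8,
    reps: int = 1000,
    membership_min: float = 0.5,
    rng_seed: int = 0,
    keep_seeds: bool = True,
    recompute_threshold: bool = True,
    top_frac_p: float = 0.02,
    top_frac_median: float = 0.01,
    top_frac_coexpr: float = 0.002,
    respect_direction: bool = False,
) -> DriverNetwork:
    """Expansion stabilised over stratified subsample repetitions.

    Each repetition redraws ``sample_frac`` of the samples (stratified by
    subtype), recomputes the differential-expression selection and (by
    default) the co-expression threshold, and expands from the *same* seeds.
    Genes appearing in at least ``membership_min`` of the repetitions form
    the final network; seeds are exempt from the frequency filter unless
    ``keep_seeds=False``.  Frequencies are reported for every gene that ever
    entered.  The whole schedule is reproducible from ``rng_seed``.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    seed_genes = _seed_genes(seeds)
    if not seed_genes:
        raise ValueError("expansion needs at least one seed gene")
    missing = seed_genes - net.nodes
    if missing:
        log.warning("%d seed(s) absent from network space kept as isolated members",
                    len(missing))
    ctx = prepare_expansion_context(
        net, cohort.expression, cohort.probe_map, cohort.labels, subtype,
        respect_direction=respect_direction)
    frac_kwargs = dict(top_frac_p=top_frac_p, top_frac_median=top_frac_median,
                       top_frac_coexpr=top_frac_coexpr)
    full_run = run_single_expansion(ctx, seed_genes, **frac_kwargs)

    counts: Counter[str] = Counter()
    reason_counts: dict[str, Counter] = {}
    children = np.random.SeedSequence(rng_seed).spawn(reps)
    for child in children:
        rng = np.random.default_rng(child)
        sub = stratified_subsample(cohort.labels, ctx.samples, sample_frac, rng)
        cols = ctx.columns_for(sub)
        run = run_single_expansion(
            ctx, seed_genes, cols=cols,
            delta_threshold=None if recompute_threshold else full_run["threshold"],
            **frac_kwargs)
        counts.update(run["members"])
        for g, r in run["reasons"].items():
            reason_counts.setdefault(g, Counter())[r] += 1

    freq = {g: c / reps for g, c in counts.items()}
    members = {g for g, f in freq.items() if f >= membership_min}
    if keep_seeds:
        members |= seed_genes
    else:
        members &= set(freq)

    precedence = {r: i for i, r in enumerate(REASONS)}
    reasons: dict[str, str] = {}
    for g in members:
        if g in full_run["reasons"]:
            reasons[g] = full_run["reasons"][g]
        elif g in reason_counts:
            reasons[g] = min(reason_counts[g].items(),
                             key=lambda kv: (-kv[1], precedence[kv[0]]))[0]
        else:  # seed that never expanded (should not happen, but stay total)
            reasons[g] = "seed"
    dn = DriverNetwork(
        subtype=subtype,
        members=members,
        seeds=seed_genes,
        inclusion_reason=reasons,
        membership_frequency={g: freq.get(g, 0.0) for g in set(freq) | members},
        edges=_induced_edges(net, members, ctx, full_run),
        delta_threshold=full_run["threshold"],
        params={
            "resampled": True, "sample_frac": sample_frac, "reps": reps,
            "membership_min": membership_min, "rng_seed": rng_seed,
            "keep_seeds": keep_seeds, "recompute_threshold": recompute_threshold,
            **frac_kwargs,
        },
    )
    log.info("%s driver-network: %d members (%d seeds) after %d reps",
             subtype, len(dn.members), len(seed_genes), reps)
    return dn
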