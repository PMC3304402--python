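"""Cross-cohort reproducibility: normalised overlap and permutation nulls.

Driver-networks grown independently in two cohorts are compared by the
Jaccard-style normalised overlap |A ∩ B| / |A ∪ B|.  Statistical significance
comes from two randomisation schemes:

* **seed randomisation** — random seed sets of the observed size, identical
  in both cohorts, expanded with the real expression data;
* **expression randomisation** — the true seeds, but the probe identity
  labels of each expression matrix are shuffled independently per cohort
  (rows keep their values, so the number of selected probes is preserved).

Each scheme yields a null distribution of overlaps and an add-one empirical
p-value.  Nulls use single-run (non-resampled) expansion per repetition for
tractability; ``resample_reps`` switches on the full inner resampling loop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .differential_stats import coexpression_threshold, resampled_de_frequencies
from .expansion import (
    de_selection,
    edge_deltas,
    fixed_point_members,
    prepare_expansion_context,
    qualifying_adjacency,
    resampled_driver_network,
)
from .network_space import NetworkSpace
from .seed_selection import SeedSet

log = logging.getLogger(__name__)


def normalized_overlap(a: set, b: set) -> float:
    """|a ∩ b| / |a ∪ b|; 0 when both sets are empty."""
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def empirical_pvalue(observed: float, null: np.ndarray | list[float]) -> float:
    """Add-one permutation p-value: (1 + #{null >= observed}) / (1 + reps).

    Never exactly zero at finite repetitions; monotone non-increasing in
    the observed value.
    """
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("empty null distribution")
    return (1 + int((null >= observed).sum())) / (1 + null.size)


@dataclass
class NullDistribution:
    """Overlaps from one randomisation scheme plus the observed value."""

    scheme: str
    overlaps: np.ndarray
    observed: float | None = None
    details: dict = field(default_factory=dict)

    @property
    def reps(self) -> int:
        return int(self.overlaps.size)

    @property
    def p_value(self) -> float:
        if self.observed is None:
            raise ValueError("no observed overlap attached")
        return empirical_pvalue(self.observed, self.overlaps)

    @property
    def exceed_count(self) -> int:
        """Raw #{null >= observed} (the plain, non-add-one numerator)."""
        if self.observed is None:
            raise ValueError("no observed overlap attached")
        return int((self.overlaps >= self.observed).sum())

    def summary(self) -> dict:
        out = {
            "scheme": self.scheme,
            "reps": self.reps,
            "null_mean": float(self.overlaps.mean()),
            "null_sd": float(self.overlaps.std(ddof=1)) if self.reps > 1 else 0.0,
        }
        if self.observed is not None:
            out.update(observed=self.observed, p_value=self.p_value,
                       exceed_count=self.exceed_count)
        return out


def overlap_of_de_genes(freq_a: pd.Series, freq_b: pd.Series,
                        min_freq: float = 0.5) -> float:
    """Normalised overlap of the two >=50%-frequency resampled DE gene sets.

    The control comparison: how reproducible plain differential expression is
    across cohorts, without the network step.
    """
    a = set(freq_a.index[freq_a >= min_freq])
    b = set(freq_b.index[freq_b >= min_freq])
    return normalized_overlap(a, b)


# ---------------------------------------------------------------------------
# per-cohort expansion state reused across null repetitions
# ---------------------------------------------------------------------------

@dataclass
class _CohortState:
    ctx: object
    de_rows: np.ndarray           # indices of selected probe rows
    de_genes: set[str]
    delta: np.ndarray
    threshold: float
    qual_adj: dict
    fracs: dict


def _prepare_state(net: NetworkSpace, cohort, subtype: str,
                   top_frac_p: float, top_frac_median: float,
                   top_frac_coexpr: float) -> _CohortState:
    ctx = prepare_expansion_context(
        net, cohort.expression, cohort.probe_map, cohort.labels, subtype)
    cols = np.arange(len(ctx.samples))
    mask = de_selection(ctx, cols, top_frac_p, top_frac_median)
    de_genes = set(ctx.gene_of_row[mask]) - {""}
    _, _, delta, _ = edge_deltas(ctx, cols)
    thr = coexpression_threshold(delta, top_frac_coexpr) if len(delta) else np.inf
    return _CohortState(
        ctx=ctx, de_rows=np.flatnonzero(mask), de_genes=de_genes,
        delta=delta, threshold=thr,
        qual_adj=qualifying_adjacency(ctx, delta, thr),
        fracs={"top_frac_p": top_frac_p, "top_frac_median": top_frac_median,
               "top_frac_coexpr": top_frac_coexpr},
    )


def _members_under_permutation(state: _CohortState, sigma: np.ndarray,
                               seeds: set[str]) -> set[str]:
    """Expansion members after relabelling probe rows by permutation sigma.

    Row r carries the label originally at position sigma[r].  Shuffling
    labels leaves each row's test statistics and each row pair's correlation
    unchanged, so the selected *rows* and the standardized matrices are
    reused; only the row -> gene assignment and the edge -> row lookup move.
    This is algebraically identical to permuting the index of the expression
    matrix and rerunning the full selection.
    """
    ctx = state.ctx
    inv = np.argsort(sigma)
    de_genes = set(ctx.gene_of_row[sigma[state.de_rows]]) - {""}
    cols = np.arange(len(ctx.samples))
    _, _, delta, _ = edge_deltas(ctx, cols, row_lookup=inv)
    thr = coexpression_threshold(delta, state.fracs["top_frac_coexpr"]) if len(delta) else np.inf
    qual = qualifying_adjacency(ctx, delta, thr)
    members, _ = fixed_point_members(seeds, ctx.adjacency, de_genes, qual)
    return members


# ---------------------------------------------------------------------------
# null models
# ---------------------------------------------------------------------------

def seed_randomization_null(
    cohorts: tuple,
    net: NetworkSpace,
    n_seeds: int,
    subtype: str,
    reps: int = 1000,
    rng_seed: int = 0,
    observed: float | None = None,
    top_frac_p: float = 0.02,
    top_frac_median: float = 0.01,
    top_frac_coexpr: float = 0.002,
    resample_reps: int = 0,
    keep_seed_sets: bool = True,
) -> NullDistribution:
    """Null overlaps from random seed sets shared by both cohorts.

    Per repetition one random seed set (of the observed size) is drawn from
    the genes that are in the network and carry both data types in both
    cohorts, the expansion runs in each cohort with its original expression
    data, and the normalised overlap of the two member sets is recorded.
    """
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    a, b = cohorts
    universe = sorted(net.nodes & a.genes_with_both_data() & b.genes_with_both_data())
    if len(universe) < n_seeds:
        raise ValueError(
            f"seed universe has {len(universe)} genes < n_seeds={n_seeds}")
    states = [
        _prepare_state(net, c, subtype, top_frac_p, top_frac_median, top_frac_coexpr)
        for c in (a, b)
    ]
    rng = np.random.default_rng(np.random.SeedSequence(rng_seed))
    overlaps = np.empty(reps)
    seed_sets: list[tuple[str, ...]] = []
    for i in range(reps):
        seeds = set(rng.choice(universe, size=n_seeds, replace=False))
        if keep_seed_sets:
            seed_sets.append(tuple(sorted(seeds)))
        member_sets = []
        for c, st in zip((a, b), states):
            if resample_reps:
                dn = resampled_driver_network(
                    seeds, net, c, subtype, reps=resample_reps,
                    rng_seed=int(rng.integers(2**31)),
                    top_frac_p=top_frac_p, top_frac_median=top_frac_median,
                    top_frac_coexpr=top_frac_coexpr)
                member_sets.append(dn.members)
            else:
                members, _ = fixed_point_members(
                    seeds, st.ctx.adjacency, st.de_genes, st.qual_adj)
                member_sets.append(members)
        overlaps[i] = normalized_overlap(*member_sets)
    return NullDistribution(
        scheme="seed_randomisation", overlaps=overlaps, observed=observed,
        details={"n_seeds": n_seeds, "universe_size": len(universe),
                 "seed_sets": seed_sets},
    )


def expression_randomization_null(
    cohorts: tuple,
    net: NetworkSpace,
    seeds,
    subtype: str,
    reps: int = 1000,
    rng_seed: int = 0,
    observed: float | None = None,
    top_frac_p: float = 0.02,
    top_frac_median: float = 0.01,
    top_frac_coexpr: float = 0.002,
) -> NullDistribution:
    """Null overlaps from independent probe-label shuffles of each cohort.

    The true seeds are kept; per repetition each cohort's expression rows
    keep their values but are reassigned probe identities by an independent
    uniform permutation, the expansion reruns, and the overlap is recorded.
    """
    seed_genes = set(seeds.seeds) if isinstance(seeds, SeedSet) else set(seeds)
    if not seed_genes:
        raise ValueError("expression randomisation needs the true seed set")
    a, b = cohorts
    states = [
        _prepare_state(net, c, subtype, top_frac_p, top_frac_median, top_frac_coexpr)
        for c in (a, b)
    ]
    rng = np.random.default_rng(np.random.SeedSequence(rng_seed))
    overlaps = np.empty(reps)
    for i in range(reps):
        member_sets = []
        for st in states:
            sigma = rng.permutation(st.ctx.n_probes)
            member_sets.append(_members_under_permutation(st, sigma, seed_genes))
        overlaps[i] = normalized_overlap(*member_sets)
    return NullDistribution(
        scheme="expression_randomisation", overlaps=overlaps, observed=observed,
        details={"n_seeds": len(seed_genes)},
    )


# ---------------------------------------------------------------------------
# one-call report
# ---------------------------------------------------------------------------

def reproducibility_report(
    cohort_a,
    cohort_b,
    net: NetworkSpace,
    seeds,
    subtype: str,
    reps_null: int = 1000,
    rng_seed: int = 0,
    observed_reps: int = 200,
    sample_frac: float = 0.8,
    membership_min: float = 0.5,
    de_control: bool = True,
    **fracs,
) -> dict:
    """Observed cross-cohort overlap, both nulls, and the DE-control overlap.

    The observed networks use the full resampling pipeline (the same seeds in
    both cohorts); nulls use single-run expansion per repetition.  Returns a
    dict with the two driver-networks, the observed overlap, both
    :class:`NullDistribution` objects, the resampled-DE control overlap, and
    a tidy ``summary`` DataFrame (scheme, null mean ± sd, observed, p).
    """
    ss = np.random.SeedSequence(rng_seed).spawn(5)
    seed_ints = [int(s.generate_state(1)[0] % 2**31) for s in ss]
    nets = {}
    for tag, cohort, si in (("a", cohort_a, seed_ints[0]), ("b", cohort_b, seed_ints[1])):
        nets[tag] = resampled_driver_network(
            seeds, net, cohort, subtype, sample_frac=sample_frac,
            reps=observed_reps, membership_min=membership_min, rng_seed=si, **fracs)
    observed = normalized_overlap(nets["a"].members, nets["b"].members)
    seed_genes = set(seeds.seeds) if isinstance(seeds, SeedSet) else set(seeds)
    null_seed = seed_randomization_null(
        (cohort_a, cohort_b), net, n_seeds=len(seed_genes), subtype=subtype,
        reps=reps_null, rng_seed=seed_ints[2], observed=observed, **fracs)
    null_expr = expression_randomization_null(
        (cohort_a, cohort_b), net, seeds, subtype,
        reps=reps_null, rng_seed=seed_ints[3], observed=observed, **fracs)
    de_overlap = None
    if de_control:
        freqs = [
            resampled_de_frequencies(
                c.expression, c.probe_map, c.labels, subtype,
                sample_frac=sample_frac, reps=observed_reps,
                rng_seed=seed_ints[4])
            for c in (cohort_a, cohort_b)
        ]
        de_overlap = overlap_of_de_genes(*freqs)
    summary = pd.DataFrame([null_seed.summary(), null_expr.summary()])
    return {
        "network_a": nets["a"],
        "network_b": nets["b"],
        "observed_overlap": observed,
        "seed_null": null_seed,
        "expression_null": null_expr,
        "de_control_overlap": de_overlap,
        "summary": summary,
    }
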