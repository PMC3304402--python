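"""Synthetic cohorts with planted subtype-specific driver modules.

The generator emulates the data structure the method assumes: a scale-free
interactome, a cohort of samples split into mutually exclusive subtypes, a
handful of *planted seed genes* recurrently amplified in the target subtype
whose expression tracks their copy number, a *planted module* (the seeds'
network neighbourhood) overexpressed in the target subtype, and a latent
factor shared by a subset of module edges that induces subtype-specific
co-expression.  Ground truth is returned alongside the cohort so recovery
can be measured; the truth leaks into the matrices only through these
stated mechanisms.

Defaults describe a mid-sized two-channel microarray study: 2000 genes,
60 samples over three subtypes (20/10/30), amplification log-ratio 1.0
called at +/-0.3, expression effects of two noise standard deviations, and
within-subtype co-expression of 0.8 on planted edges.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .evaluation import SCREEN_COLUMNS
from .network_space import InteractionEdge, NetworkSpace
from .omics_data import CNAMatrix, OmicsCohort, discretize_cna

log = logging.getLogger(__name__)


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic-cohort generator (see module docstring)."""

    n_genes: int = 2000
    mean_degree: float = 4.0
    n_samples_per_subtype: dict[str, int] = field(
        default_factory=lambda: {"ER+": 20, "HER2+": 10, "TNBC": 30})
    target_subtype: str = "TNBC"
    n_seed_genes: int = 4
    module_radius: int = 1
    seed_degree_range: tuple[int, int] = (3, 8)
    cna_gain_prob_in_target: float = 0.9
    cna_unstable_gene_frac: float = 0.10
    cna_unstable_rate_range: tuple[float, float] = (0.05, 0.4)
    sporadic_cna_rate: float = 0.002
    gain_value: float = 1.0
    cna_noise_sd: float = 0.05
    expression_effect: float = 2.0       # in units of noise_sd
    coexpression_strength: float = 0.8   # within-subtype Pearson r on planted edges
    coexpression_edge_frac: float = 0.5
    noise_sd: float = 1.0
    multiprobe_fraction: float = 0.1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cna_gain_prob_in_target", "cna_unstable_gene_frac",
                     "sporadic_cna_rate", "coexpression_strength",
                     "coexpression_edge_frac", "multiprobe_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.coexpression_strength >= 1:
            raise ValueError("coexpression_strength must be < 1")
        if self.expression_effect < 0 or self.module_radius < 0:
            raise ValueError("effect and radius must be non-negative")
        if self.target_subtype not in self.n_samples_per_subtype:
            raise ValueError("target_subtype missing from n_samples_per_subtype")


@dataclass
class SyntheticTruth:
    """Planted ground truth for one generated study."""

    seed_genes: set[str]
    module_genes: set[str]
    coexpression_edges: set[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.seed_genes <= self.module_genes:
            raise ValueError("planted seeds must be contained in the planted module")


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

def generate_network(
    n_genes: int = 2000,
    mean_degree: float = 4.0,
    rng_seed: int = 0,
    directed_fraction: float = 0.3,
) -> NetworkSpace:
    """Scale-free interactome via preferential attachment.

    Gene symbols are ``G00001`` .. ; a ``directed_fraction`` of edges is
    marked as directed transcription-regulatory or signalling links (split
    evenly, random orientation), the rest as undirected PPI.
    """
    if n_genes < 10:
        raise ValueError("need at least 10 genes")
    m = max(1, round(mean_degree / 2))
    g = nx.barabasi_albert_graph(n_genes, m, seed=rng_seed)
    rng = np.random.default_rng(np.random.SeedSequence(rng_seed).spawn(1)[0])
    names = {i: f"G{i + 1:05d}" for i in g.nodes}
    edges: list[InteractionEdge] = []
    for u, v in sorted(g.edges()):
        a, b = names[u], names[v]
        if rng.random() < directed_fraction:
            prov = "tf" if rng.random() < 0.5 else "signalling"
            if rng.random() < 0.5:
                a, b = b, a
            edges.append(InteractionEdge(a, b, True, prov))
        else:
            edges.append(InteractionEdge(a, b, False, "ppi"))
    return NetworkSpace(edges)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def plant_truth(net: NetworkSpace, cfg: GeneratorConfig,
                rng: np.random.Generator) -> SyntheticTruth:
    """Choose seed genes and the module they anchor.

    Seeds are drawn from mid-degree nodes (the configured degree range) so
    the radius-``module_radius`` neighbourhood stays a module, not half the
    graph; the range widens with a warning if too few candidates exist.
    """
    lo, hi = cfg.seed_degree_range
    candidates = sorted(n for n in net.nodes if lo <= net.degree(n) <= hi)
    if len(candidates) < cfg.n_seed_genes:
        log.warning("only %d nodes with degree in [%d, %d]; widening to all nodes",
                    len(candidates), lo, hi)
        candidates = sorted(net.nodes)
    seeds = set(rng.choice(candidates, size=cfg.n_seed_genes, replace=False))
    module = set(seeds)
    frontier = set(seeds)
    for hop in range(cfg.module_radius):
        frontier = {v for m in frontier for v in net.neighbors(m)} - module
        if not frontier:
            log.warning("module closed after %d hop(s); radius %d exceeds reach",
                        hop, cfg.module_radius)
            break
        module |= frontier
    pool = sorted(
        pair for pair in net.gene_pairs()
        if pair[0] in module and pair[1] in module
    )
    k = round(cfg.coexpression_edge_frac * len(pool))
    chosen = rng.choice(len(pool), size=k, replace=False) if k else []
    coexpr = {pool[i] for i in chosen}
    return SyntheticTruth(seed_genes=seeds, module_genes=module,
                          coexpression_edges=coexpr)


def generate_cohort(
    net: NetworkSpace,
    cfg: GeneratorConfig,
    truth: SyntheticTruth | None = None,
    rng: np.random.Generator | None = None,
    name: str = "synthetic",
    sample_prefix: str = "S",
) -> tuple[OmicsCohort, SyntheticTruth]:
    """Generate one cohort (expression + CNA + labels) around a planted module.

    Mechanisms, in order: planted seeds gain copies (log-ratio
    ``gain_value``) with probability ``cna_gain_prob_in_target`` in target-
    subtype samples over a sparse +/- background; seed expression adds
    ``expression_effect * noise_sd`` per discrete copy-number call (copy
    number drives expression); non-seed module genes add the same shift in
    target samples only (differential expression); genes on planted module
    edges share a latent factor in target samples whose loading induces a
    within-subtype Pearson correlation of ``coexpression_strength``.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.rng_seed))
    if truth is None:
        truth = plant_truth(net, cfg, rng)
    missing = truth.seed_genes - net.nodes
    if missing:
        raise ValueError(f"planted seeds not in network: {sorted(missing)[:5]}")

    genes = sorted(net.nodes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    subtypes = list(cfg.n_samples_per_subtype)
    sample_ids: list[str] = []
    label_vals: list[str] = []
    for st in subtypes:
        for _ in range(cfg.n_samples_per_subtype[st]):
            sample_ids.append(f"{sample_prefix}{len(sample_ids) + 1:03d}")
            label_vals.append(st)
    labels = pd.Series(label_vals, index=sample_ids, name="subtype")
    target_cols = np.flatnonzero(labels.to_numpy() == cfg.target_subtype)
    n_genes, n_samples = len(genes), len(sample_ids)

    # --- copy number -----------------------------------------------------
    # Background mimics real CGH structure: a minority of "unstable" genes
    # sit in recurrently altered regions with gene-specific rates and a
    # fixed direction (subtype-agnostic passengers, no expression coupling);
    # everything else only picks up rare sporadic events.  This keeps the
    # subtype-average score distribution smooth instead of piling ties at
    # one or two event counts.
    cna = rng.normal(0.0, cfg.cna_noise_sd, size=(n_genes, n_samples))
    sporadic = rng.random((n_genes, n_samples)) < cfg.sporadic_cna_rate
    signs = rng.choice([-1.0, 1.0], size=(n_genes, n_samples))
    cna = np.where(sporadic, signs * cfg.gain_value, cna)
    n_unstable = round(cfg.cna_unstable_gene_frac * n_genes)
    unstable = rng.choice(n_genes, size=n_unstable, replace=False)
    rates = rng.uniform(*cfg.cna_unstable_rate_range, size=n_unstable)
    usigns = rng.choice([-1.0, 1.0], size=n_unstable)
    for idx, rate, sign in zip(unstable, rates, usigns):
        hits = rng.random(n_samples) < rate
        cna[idx, hits] = sign * cfg.gain_value
    for g in sorted(truth.seed_genes):
        gained = rng.random(len(target_cols)) < cfg.cna_gain_prob_in_target
        cna[gene_pos[g], target_cols[gained]] = cfg.gain_value
    cna_df = pd.DataFrame(cna, index=genes, columns=sample_ids)
    cna_matrix = CNAMatrix(cna_df, is_discrete=False)
    calls = discretize_cna(cna_matrix).values.to_numpy()

    # --- expression signal (gene level) ----------------------------------
    signal = np.zeros((n_genes, n_samples))
    eff = cfg.expression_effect * cfg.noise_sd
    for g in sorted(truth.seed_genes):
        signal[gene_pos[g]] += eff * calls[gene_pos[g]]
    for g in sorted(truth.module_genes - truth.seed_genes):
        signal[gene_pos[g], target_cols] += eff
    factor_genes = sorted({g for pair in truth.coexpression_edges for g in pair})
    if factor_genes and cfg.coexpression_strength > 0:
        r = cfg.coexpression_strength
        loading = math.sqrt(r / (1 - r)) * cfg.noise_sd
        f = rng.normal(size=len(target_cols))
        for g in factor_genes:
            signal[gene_pos[g], target_cols] += loading * f

    # --- probes -----------------------------------------------------------
    two_probes = rng.random(n_genes) < cfg.multiprobe_fraction
    probe_ids: list[str] = []
    probe_gene_rows: list[int] = []
    for i, g in enumerate(genes):
        reps = 2 if two_probes[i] else 1
        for j in range(reps):
            probe_ids.append(f"{g}_p{j + 1}")
            probe_gene_rows.append(i)
    X = signal[probe_gene_rows] + rng.normal(0.0, cfg.noise_sd,
                                             size=(len(probe_ids), n_samples))
    expr = pd.DataFrame(X, index=probe_ids, columns=sample_ids)
    probe_map = pd.Series([genes[i] for i in probe_gene_rows],
                          index=probe_ids, name="gene")
    cohort = OmicsCohort(expression=expr, probe_map=probe_map,
                         cna=cna_matrix, labels=labels, name=name)
    return cohort, truth


def generate_cohort_pair(
    net: NetworkSpace,
    cfg: GeneratorConfig,
) -> tuple[OmicsCohort, OmicsCohort, SyntheticTruth]:
    """Two independent cohorts sharing the same planted truth.

    Noise, sample draws, and probe layouts are redrawn per cohort from
    separate random streams; only the planted module is common, emulating
    two studies of the same disease.
    """
    ss = np.random.SeedSequence(cfg.rng_seed).spawn(3)
    truth = plant_truth(net, cfg, np.random.default_rng(ss[0]))
    a, _ = generate_cohort(net, cfg, truth=truth, rng=np.random.default_rng(ss[1]),
                           name="cohort_a", sample_prefix="A")
    b, _ = generate_cohort(net, cfg, truth=truth, rng=np.random.default_rng(ss[2]),
                           name="cohort_b", sample_prefix="B")
    return a, b, truth


# ---------------------------------------------------------------------------
# siRNA screen
# ---------------------------------------------------------------------------

def generate_screen(
    truth: SyntheticTruth,
    effect_in_target: float,
    effect_other: float,
    rng_seed: int = 0,
    genes: list[str] | None = None,
    n_target_lines: int = 9,
    n_other_lines: int = 4,
    n_sirnas: int = 4,
    n_replicates: int = 3,
    n_control_replicates: int = 12,
    viability_noise_sd: float = 0.1,
) -> pd.DataFrame:
    """Simulate a viability screen over the planted module genes.

    Per gene, cell line, and siRNA: replicate viability =
    max(0, 1 - effect(group) + noise); control wells per line sit at 1.
    Returns a tidy table in the screen-input format.
    """
    if effect_in_target < 0 or effect_other < 0:
        raise ValueError("effects must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(rng_seed))
    if genes is None:
        genes = sorted(truth.module_genes)
    lines = [(f"T{i + 1:02d}", "target_subtype") for i in range(n_target_lines)]
    lines += [(f"O{i + 1:02d}", "other") for i in range(n_other_lines)]
    rows = []
    for line, group in lines:
        for rep in range(n_control_replicates):
            rows.append({
                "gene": "CONTROL", "sirna_id": "CTRL", "cell_line": line,
                "group": group, "replicate": rep + 1,
                "viability": max(0.0, 1.0 + rng.normal(0, viability_noise_sd)),
                "is_control": True,
            })
        effect = effect_in_target if group == "target_subtype" else effect_other
        for gene in genes:
            for s in range(n_sirnas):
                for rep in range(n_replicates):
                    v = 1.0 - effect + rng.normal(0, viability_noise_sd)
                    rows.append({
                        "gene": gene, "sirna_id": f"{gene}_si{s + 1}",
                        "cell_line": line, "group": group, "replicate": rep + 1,
                        "viability": max(0.0, v), "is_control": False,
                    })
    return pd.DataFrame(rows, columns=SCREEN_COLUMNS)


# ---------------------------------------------------------------------------
# file output (round-trips through the package loaders)
# ---------------------------------------------------------------------------

def write_cohort(cohort: OmicsCohort, outdir: str | Path) -> dict[str, Path]:
    """Write expression/probe-map/CNA/label TSVs; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "probe_map": outdir / "probe_map.tsv",
        "cna": outdir / "cna.tsv",
        "labels": outdir / "labels.tsv",
    }
    cohort.expression.to_csv(paths["expression"], sep="\t", index_label="probe_id")
    cohort.probe_map.to_csv(paths["probe_map"], sep="\t", header=False)
    cohort.cna.values.to_csv(paths["cna"], sep="\t", index_label="gene")
    cohort.labels.to_csv(paths["labels"], sep="\t", header=False)
    return paths


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    rows = [("seed", g) for g in sorted(truth.seed_genes)]
    rows += [("module", g) for g in sorted(truth.module_genes)]
    rows += [("coexpression_edge", f"{a}|{b}") for a, b in sorted(truth.coexpression_edges)]
    pd.DataFrame(rows, columns=["kind", "value"]).to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> SyntheticTruth:
    df = pd.read_csv(path, sep="\t")
    seeds = set(df.loc[df["kind"] == "seed", "value"])
    module = set(df.loc[df["kind"] == "module", "value"])
    edges = {
        tuple(v.split("|")) for v in df.loc[df["kind"] == "coexpression_edge", "value"]
    }
    return SyntheticTruth(seed_genes=seeds, module_genes=module,
                          coexpression_edges=edges)
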