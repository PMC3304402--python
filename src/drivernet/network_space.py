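"""Combined interactome network space.

The analysis runs on a single "network space" merging three kinds of
literature-curated interactions: undirected protein-protein interactions
(PPI), directed transcription-factor -> target links, and directed
signalling links.  Edges keep their provenance so the same gene pair may
carry both an undirected PPI edge and a directed regulatory edge.

Database clients are out of scope: edge lists are consumed from plain
tab-separated files (2/3-column TSV or SIF).
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

log = logging.getLogger(__name__)

PROVENANCES = ("ppi", "tf", "signalling")
#: default directedness per interaction type
DIRECTED_PROVENANCE = {"ppi": False, "tf": True, "signalling": True}


@dataclass(frozen=True)
class InteractionEdge:
    """One interaction between two gene symbols.

    PPI edges are undirected; transcription-regulatory and signalling
    edges are directed (source acts on target).
    """

    source: str
    target: str
    directed: bool
    provenance: str

    def __post_init__(self) -> None:
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if self.source == self.target:
            raise ValueError("self-loops are not representable")

    def key(self) -> tuple:
        """Deduplication key: (pair, directed, provenance).

        Undirected pairs are canonicalised so A-B and B-A collapse.
        """
        if self.directed:
            pair = (self.source, self.target)
        else:
            pair = tuple(sorted((self.source, self.target)))
        return (pair, self.directed, self.provenance)

    @property
    def pair(self) -> tuple[str, str]:
        """Unordered endpoint pair (sorted)."""
        return tuple(sorted((self.source, self.target)))


def load_edge_list(
    path: str | Path,
    provenance: str = "ppi",
    directed: bool | None = None,
    fmt: str = "tsv",
) -> list[InteractionEdge]:
    """Parse a tab-separated edge list into :class:`InteractionEdge` objects.

    Parameters
    ----------
    path:
        2- or 3-column TSV ``source<TAB>target[<TAB>provenance]``, or a SIF
        file ``source<TAB>relation<TAB>target`` when ``fmt="sif"``.  An
        optional header line starting with ``source`` is skipped.
    provenance:
        Interaction type applied to every edge without an explicit
        per-line provenance column.
    directed:
        Override directedness; defaults to the convention for the
        provenance (PPI undirected, tf/signalling directed).
    """
    if provenance not in PROVENANCES:
        raise ValueError(f"unknown provenance {provenance!r}")
    if fmt not in ("tsv", "sif"):
        raise ValueError(f"unknown edge-list format {fmt!r}")
    path = Path(path)
    edges: list[InteractionEdge] = []
    seen: set[tuple] = set()
    n_self = 0
    n_dup = 0
    with path.open() as fh:
        lines = fh.read().splitlines()
    # drop trailing blank lines but keep numbering for error messages
    rows = [(i + 1, ln) for i, ln in enumerate(lines) if ln.strip()]
    if not rows:
        raise ValueError(f"{path}: empty edge list")
    first_fields = rows[0][1].split("\t")
    if first_fields and first_fields[0].strip().lower() in ("source", "from", "gene_a", "genea"):
        rows = rows[1:]
        if not rows:
            raise ValueError(f"{path}: edge list has a header but no data rows")
    for lineno, line in rows:
        fields = [f.strip() for f in line.split("\t")]
        if fmt == "sif":
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: SIF line needs 3 columns, got {len(fields)}")
            src, tgt = fields[0], fields[2]
            prov = provenance
        else:
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected >=2 tab-separated columns")
            src, tgt = fields[0], fields[1]
            prov = provenance
            if len(fields) >= 3 and fields[2]:
                if fields[2].lower() not in PROVENANCES:
                    raise ValueError(
                        f"{path}:{lineno}: third column {fields[2]!r} is not one of {PROVENANCES}"
                    )
                prov = fields[2].lower()
        if not src or not tgt:
            raise ValueError(f"{path}:{lineno}: empty gene symbol")
        src, tgt = src.upper(), tgt.upper()
        if src == tgt:
            n_self += 1
            continue
        is_dir = DIRECTED_PROVENANCE[prov] if directed is None else directed
        edge = InteractionEdge(src, tgt, is_dir, prov)
        k = edge.key()
        if k in seen:
            n_dup += 1
            continue
        seen.add(k)
        edges.append(edge)
    if n_self:
        log.info("%s: dropped %d self-loop(s)", path, n_self)
    if n_dup:
        log.info("%s: collapsed %d duplicate edge(s)", path, n_dup)
    if not edges:
        raise ValueError(f"{path}: no usable edges after filtering")
    return edges


class NetworkSpace:
    """Merged interactome: node set plus deduplicated provenance-tagged edges.

    Adjacency queries are direction-agnostic by default (network expansion
    walks "direct neighbours" regardless of arrow direction); pass
    ``respect_direction=True`` to restrict directed edges to
    source -> target traversal.
    """

    def __init__(self, edges: Iterable[InteractionEdge]):
        self.edges: list[InteractionEdge] = []
        seen: set[tuple] = set()
        for e in edges:
            k = e.key()
            if k in seen:
                continue
            seen.add(k)
            self.edges.append(e)
        self.nodes: set[str] = set()
        self._adj: dict[str, set[str]] = {}
        self._out: dict[str, set[str]] = {}
        for e in self.edges:
            self.nodes.update((e.source, e.target))
            self._adj.setdefault(e.source, set()).add(e.target)
            self._adj.setdefault(e.target, set()).add(e.source)
            self._out.setdefault(e.source, set()).add(e.target)
            if not e.directed:
                self._out.setdefault(e.target, set()).add(e.source)
        for n in self.nodes:
            self._adj.setdefault(n, set())
            self._out.setdefault(n, set())
        log.info("network space: %d nodes, %d edges", len(self.nodes), len(self.edges))

    # -- queries ---------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def neighbors(self, gene: str, respect_direction: bool = False) -> set[str]:
        """All genes adjacent to ``gene`` via any edge.

        Raises ``KeyError`` for genes not in the network.
        """
        if gene not in self.nodes:
            raise KeyError(f"gene {gene!r} not in network space")
        table = self._out if respect_direction else self._adj
        return set(table[gene])

    def adjacency(self, respect_direction: bool = False) -> dict[str, set[str]]:
        """Adjacency mapping (copies are not made; treat as read-only)."""
        return self._out if respect_direction else self._adj

    def degree(self, gene: str) -> int:
        return len(self._adj.get(gene, ()))

    def gene_pairs(self) -> list[tuple[str, str]]:
        """Unique unordered endpoint pairs, sorted for determinism."""
        return sorted({e.pair for e in self.edges})

    # -- construction / IO ----------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "source": [e.source for e in self.edges],
                "target": [e.target for e in self.edges],
                "directed": [e.directed for e in self.edges],
                "provenance": [e.provenance for e in self.edges],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "NetworkSpace":
        df = pd.read_csv(path, sep="\t")
        need = {"source", "target", "directed", "provenance"}
        if not need.issubset(df.columns):
            raise ValueError(f"{path}: combined-network TSV needs columns {sorted(need)}")
        edges = [
            InteractionEdge(
                str(r.source).upper(),
                str(r.target).upper(),
                bool(r.directed),
                str(r.provenance),
            )
            for r in df.itertuples()
        ]
        return cls(edges)


def merge_networks(edge_lists: Sequence[Iterable[InteractionEdge]]) -> NetworkSpace:
    """Union several edge lists into one :class:`NetworkSpace`.

    An undirected PPI edge and a directed regulatory edge between the same
    pair are kept as distinct edges.
    """
    if not edge_lists:
        raise ValueError("merge_networks needs at least one edge list")
    merged: list[InteractionEdge] = []
    for lst in edge_lists:
        merged.extend(lst)
    return NetworkSpace(merged)
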