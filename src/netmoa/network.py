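"""Protein-interaction network handling and model-graph extraction.

The interaction network is an undirected simple graph over opaque gene
identifiers (Ensembl-style ``ENSG...`` strings or synthetic ``G0001``
labels).  Each edge carries a ``sources`` attribute, the set of evidence
tags (e.g. ``{"ppi", "reactome"}``) supporting the interaction.  Edge
direction is ignored throughout, matching protein-interaction semantics.

A *molecular model graph* for a seed gene set is the subgraph induced on
the seeds, with seeds that interact with no other seed removed.  Keeping
the induction seed-restricted (no connector proteins) is this package's
default; ``include_connectors=True`` additionally admits non-seed nodes
that link two or more seeds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

logger = logging.getLogger(__name__)

#: An interaction network is a plain :class:`networkx.Graph` whose edges
#: carry a ``sources`` set of evidence tags.  Validity (simple graph, no
#: self-loops) is guaranteed by the constructors in this module and can be
#: re-checked with :func:`validate_network`.
InteractionNetwork = nx.Graph


@dataclass(frozen=True)
class SeedGeneSet:
    """A labelled set of seed genes for model construction.

    Parameters
    ----------
    genes
        Gene identifiers; may contain identifiers absent from the network.
    label
        Free-text label, e.g. a disease or drug name.
    provenance
        Optional per-gene count of supporting publications.
    """

    genes: frozenset[str]
    label: str = ""
    provenance: dict[str, int] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))
        if any(not g for g in self.genes):
            raise ValueError("seed gene identifiers must be non-empty strings")

    def __len__(self) -> int:
        return len(self.genes)


class NetworkFormatError(ValueError):
    """Raised when an edge-list file line cannot be parsed."""


def new_network(edges=(), nodes=()) -> InteractionNetwork:
    """Build a validated network from ``(u, v)`` or ``(u, v, source)`` tuples.

    Self-loops are dropped and duplicate (unordered) edges merged, with the
    union of their source tags.
    """
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for edge in edges:
        u, v = edge[0], edge[1]
        src = edge[2] if len(edge) > 2 else None
        _add_interaction(g, u, v, src)
    return g


def _add_interaction(g: nx.Graph, u: str, v: str, source: str | None) -> None:
    g.add_node(u)
    g.add_node(v)
    if u == v:
        return
    sources = g.edges[u, v]["sources"] if g.has_edge(u, v) else set()
    if source:
        sources.add(source)
    g.add_edge(u, v, sources=sources)


def validate_network(network: InteractionNetwork) -> None:
    """Raise ``ValueError`` if ``network`` violates the simple-graph contract."""
    if network.is_directed() or network.is_multigraph():
        raise ValueError("interaction network must be an undirected simple graph")
    loops = list(nx.selfloop_edges(network))
    if loops:
        raise ValueError(f"interaction network contains self-loops: {loops[:5]}")


def load_network(
    path: str | Path,
    allow_sources: set[str] | None = None,
) -> InteractionNetwork:
    """Read an interaction network from a TSV edge list or SIF file.

    Accepted line shapes (whitespace/tab separated):

    * ``geneA geneB`` — untagged interaction,
    * ``geneA geneB source`` — TSV with an evidence tag,
    * ``geneA relation geneB`` — SIF; the middle token becomes the tag.

    The two 3-column dialects are distinguished per file: a file whose
    extension is ``.sif`` is read as SIF, anything else as TSV.  Self-loops
    are dropped and duplicate edges merged with the union of source tags.

    Parameters
    ----------
    allow_sources
        If given, keep only edges carrying at least one of these tags
        (untagged edges are dropped).
    """
    path = Path(path)
    sif = path.suffix.lower() == ".sif"
    g = nx.Graph()
    n_lines = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            n_lines += 1
            if len(parts) == 2:
                u, v, src = parts[0], parts[1], None
            elif len(parts) == 3:
                u, v, src = (
                    (parts[0], parts[2], parts[1]) if sif else (parts[0], parts[1], parts[2])
                )
            else:
                raise NetworkFormatError(
                    f"{path}:{lineno}: expected 2 or 3 columns, got {len(parts)}"
                )
            _add_interaction(g, u, v, src)
    if n_lines == 0:
        logger.warning("network file %s is empty", path)
    if allow_sources is not None:
        drop = [
            (u, v)
            for u, v, d in g.edges(data=True)
            if not (d["sources"] & set(allow_sources))
        ]
        g.remove_edges_from(drop)
    return g


def write_network(network: InteractionNetwork, path: str | Path) -> None:
    """Write the TSV edge-list dialect read by :func:`load_network`.

    Multi-source edges are emitted as one line per tag so that a
    load/write/load cycle round-trips to an identical graph.  Isolated
    nodes are written as single-column lines are not representable in the
    edge list, so they are skipped with a warning.
    """
    isolated = [n for n in network.nodes if network.degree(n) == 0]
    if isolated:
        logger.warning("%d isolated nodes not representable in edge list", len(isolated))
    with open(path, "w") as fh:
        for u, v in sorted(map(sorted, network.edges())):
            sources = sorted(network.edges[u, v].get("sources") or ())
            if not sources:
                fh.write(f"{u}\t{v}\n")
            for s in sources:
                fh.write(f"{u}\t{v}\t{s}\n")


def write_graphml(network: InteractionNetwork, path: str | Path) -> None:
    """Write GraphML; set-valued edge sources are joined to a ``|`` string."""
    g = network.copy()
    for _, _, d in g.edges(data=True):
        if isinstance(d.get("sources"), set):
            d["sources"] = "|".join(sorted(d["sources"]))
    nx.write_graphml(g, path)


def induced_model_graph(
    seeds: SeedGeneSet | set[str],
    network: InteractionNetwork,
    include_connectors: bool = False,
) -> InteractionNetwork:
    """Extract the molecular-model graph for a seed gene set.

    Returns the subgraph induced on ``seeds ∩ network.nodes`` with nodes of
    within-subgraph degree 0 removed: a seed belongs to the model only if
    it holds an interaction to at least one other seed.  With
    ``include_connectors`` non-seed nodes adjacent to ≥ 2 retained seeds
    are admitted as connectors (off by default).

    An empty seed set, or seeds that are all isolated, yield an empty
    graph (the latter with a warning), never an error.
    """
    genes = seeds.genes if isinstance(seeds, SeedGeneSet) else frozenset(seeds)
    present = genes & set(network.nodes)
    sub = network.subgraph(present)
    keep = {n for n in sub.nodes if sub.degree(n) > 0}
    if genes and not keep:
        logger.warning("all %d mapped seeds are isolated; model graph is empty", len(present))
    if include_connectors and keep:
        connectors = {
            n
            for n in set(network.nodes) - genes
            if sum(1 for nb in network.neighbors(n) if nb in keep) >= 2
        }
        keep |= connectors
    model = network.subgraph(keep).copy()
    return model
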