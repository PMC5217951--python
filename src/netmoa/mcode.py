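"""Molecular Complex Detection (MCODE) segmentation of model graphs.

A molecular model graph is segmented into *process units* — densely
interconnected protein clusters — with a deterministic variant of the
Molecular Complex Detection algorithm:

1. **Vertex weighting.**  Every vertex ``v`` receives the weight
   ``k_max * density(H)`` where ``H`` is the highest k-core of the
   subgraph induced by the closed neighborhood ``N[v]``, ``k_max`` its
   core number and ``density = 2|E| / (|V|(|V|-1))``.  The weight of a
   vertex of an isolated (k+1)-clique is therefore exactly ``k``.
2. **Seeded expansion.**  The highest-weight unvisited vertex seeds a
   unit.  The candidate set grows by synchronous closure: a vertex joins
   when its weight is at least ``(1 - vwp)`` times the seed weight *and*
   it holds at least ``min(attachment, |candidate|)`` edges into the
   current candidate.  The attachment requirement (default 3) keeps the
   expansion from leaking across sparse bridges between two dense
   regions — a single bridge edge between two cliques never merges them
   into one unit — while the synchronous (round-based) closure makes the
   result independent of vertex enumeration order.
3. **Post-processing.**  Candidates without a 2-core are discarded; with
   ``haircut`` each unit is trimmed to its 2-core (iterated removal of
   degree-1 members); with ``fluff`` outside neighbors whose closed
   neighborhood is denser than ``fluff_density_threshold`` are appended
   (only then may units overlap).  Units smaller than ``min_size`` are
   dropped.  Vertices trimmed from a candidate stay available as later
   seeds or members.

Units are ranked by size, then seed weight, descending; remaining ties
are broken by the lexicographically smallest member identifier, so the
segmentation is a pure function of the graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

from .network import InteractionNetwork, SeedGeneSet, induced_model_graph

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MCODEParams:
    """Parameters of the process-unit segmentation.

    Attributes
    ----------
    vwp
        Vertex weight percentage in ``[0, 1)``: expansion tolerance
        relative to the seed weight.  0.2 is the canonical default.
    min_size
        Smallest reported unit size (≥ 2; default 3).
    haircut
        Trim each unit to its 2-core.
    fluff
        Append outside neighbors with dense closed neighborhoods.
    fluff_density_threshold
        Closed-neighborhood density a fluffed node must exceed.
    attachment
        Minimum number of edges a joining vertex must hold into the
        growing candidate (capped by the current candidate size).
    """

    vwp: float = 0.2
    min_size: int = 3
    haircut: bool = True
    fluff: bool = False
    fluff_density_threshold: float = 0.5
    attachment: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.vwp < 1.0:
            raise ValueError(f"vwp must be in [0, 1), got {self.vwp}")
        if self.min_size < 2:
            raise ValueError(f"min_size must be >= 2, got {self.min_size}")
        if not 0.0 <= self.fluff_density_threshold <= 1.0:
            raise ValueError("fluff_density_threshold must be in [0, 1]")
        if self.attachment < 1:
            raise ValueError("attachment must be >= 1")


@dataclass(frozen=True)
class ProcessUnit:
    """One predicted complex: its members, expansion seed and rank."""

    members: frozenset[str]
    seed: str
    rank: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class MolecularModel:
    """A model graph together with its process-unit segmentation.

    ``features`` is the union of all unit members — the molecular features
    of the model.  Model-graph nodes assigned to no unit are kept in
    ``unassigned`` (and in the graph) but are not model features.
    """

    label: str
    graph: InteractionNetwork = field(compare=False)
    units: tuple[ProcessUnit, ...]
    features: frozenset[str]
    unassigned: frozenset[str]

    def unit_of(self, gene: str) -> int | None:
        """Rank of the first unit containing ``gene``, or ``None``."""
        for u in self.units:
            if gene in u.members:
                return u.rank
        return None


def _closed_neighborhood_density(graph: nx.Graph, v) -> float:
    h = graph.subgraph(list(graph[v]) + [v])
    n = h.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * h.number_of_edges() / (n * (n - 1))


def vertex_weight(graph: InteractionNetwork, v) -> float:
    """Core-clustering weight of ``v``: ``k_max * density(highest k-core of N[v])``."""
    if v not in graph:
        raise KeyError(f"vertex {v!r} not in graph")
    h = graph.subgraph(list(graph[v]) + [v])
    if h.number_of_edges() == 0:
        return 0.0
    core = nx.core_number(h)
    k_max = max(core.values())
    hc = h.subgraph([u for u, c in core.items() if c >= k_max])
    n = hc.number_of_nodes()
    if n < 2:
        return 0.0
    return k_max * 2.0 * hc.number_of_edges() / (n * (n - 1))


def vertex_weights(graph: InteractionNetwork) -> dict:
    """Weights of all vertices (see :func:`vertex_weight`)."""
    return {v: vertex_weight(graph, v) for v in graph}


def _two_core(graph: nx.Graph, nodes) -> set:
    core = nx.core_number(graph.subgraph(nodes))
    return {v for v, c in core.items() if c >= 2}


def _expand(graph, weights, seed, visited, params: MCODEParams) -> set:
    threshold = (1.0 - params.vwp) * weights[seed]
    eligible = {
        u for u in graph if u not in visited and u != seed and weights[u] >= threshold
    }
    cand = {seed}
    while True:
        need = min(params.attachment, len(cand))
        joined = {
            u
            for u in eligible
            if sum(1 for nb in graph[u] if nb in cand) >= need
        }
        if not joined:
            return cand
        cand |= joined
        eligible -= joined


def predict_complexes(
    graph: InteractionNetwork, params: MCODEParams | None = None
) -> list[ProcessUnit]:
    """Segment ``graph`` into process units.

    Deterministic for a given graph: identical inputs yield identical
    units regardless of node insertion order.
    """
    params = params or MCODEParams()
    weights = vertex_weights(graph)
    visited: set = set()
    raw: list[tuple[frozenset, str]] = []
    for seed in sorted(graph.nodes, key=lambda v: (-weights[v], v)):
        if seed in visited:
            continue
        cand = _expand(graph, weights, seed, visited, params)
        visited.add(seed)
        kept = _two_core(graph, cand)
        if not kept:
            continue
        if not params.haircut:
            # keep the full candidate; the 2-core only gates existence
            kept = cand
        visited |= kept
        if params.fluff:
            ring = {nb for u in kept for nb in graph[u]} - kept
            kept = kept | {
                nb
                for nb in ring
                if _closed_neighborhood_density(graph, nb)
                > params.fluff_density_threshold
            }
        if len(kept) >= params.min_size:
            raw.append((frozenset(kept), seed))
    raw.sort(key=lambda ms: (-len(ms[0]), -weights[ms[1]], min(ms[0])))
    return [
        ProcessUnit(members=members, seed=seed, rank=i + 1)
        for i, (members, seed) in enumerate(raw)
    ]


def build_molecular_model(
    seeds: SeedGeneSet,
    network: InteractionNetwork,
    params: MCODEParams | None = None,
    include_connectors: bool = False,
) -> MolecularModel:
    """Construct a molecular model: induce the model graph, then segment it.

    Composes :func:`~netmoa.network.induced_model_graph` and
    :func:`predict_complexes`; ``features`` is the union of unit members.
    An empty induced graph produces a model with no units (warning), not
    an error.
    """
    if not seeds.genes:
        raise ValueError("seed gene set is empty")
    graph = induced_model_graph(seeds, network, include_connectors=include_connectors)
    units = predict_complexes(graph, params)
    features = frozenset().union(*(u.members for u in units)) if units else frozenset()
    unassigned = frozenset(graph.nodes) - features
    if not units:
        logger.warning("model %r: induced graph yields no process units", seeds.label)
    sizes = sorted(len(u) for u in units)
    logger.info(
        "model %r: %d input features -> %d-node graph, %d units (sizes %s-%s), "
        "%d features, %d unassigned",
        seeds.label,
        len(seeds.genes),
        graph.number_of_nodes(),
        len(units),
        sizes[0] if sizes else "-",
        sizes[-1] if sizes else "-",
        len(features),
        len(unassigned),
    )
    return MolecularModel(
        label=seeds.label,
        graph=graph,
        units=tuple(units),
        features=features,
        unassigned=unassigned,
    )


def units_table(model: MolecularModel):
    """Unit membership as a two-column table (unit_rank, gene_id)."""
    import pandas as pd

    rows = [
        {"unit_rank": u.rank, "gene_id": g}
        for u in model.units
        for g in sorted(u.members)
    ]
    return pd.DataFrame(rows, columns=["unit_rank", "gene_id"])


def write_model_graphml(model: MolecularModel, path) -> None:
    """GraphML export with a ``process_unit`` node attribute (0 = unassigned)."""
    g = model.graph.copy()
    for n in g.nodes:
        g.nodes[n]["process_unit"] = model.unit_of(n) or 0
    for _, _, d in g.edges(data=True):
        if isinstance(d.get("sources"), set):
            d["sources"] = "|".join(sorted(d["sources"]))
    nx.write_graphml(g, path)
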