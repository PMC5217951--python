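"""Interference between two molecular models.

The interference analysis positions a drug against a disease by
intersecting the feature sets of the two molecular models (disease
pathophysiology vs drug mechanism of action).  Features of the disease
model that are not shared but show deregulation in supplementary
expression evidence are reported as *extra* affected features.  Each
reported gene carries a regulation state merged across evidence tables
(up / down / contradictory / association-only) and, where available,
diagnostic or prognostic biomarker flags.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import networkx as nx
import pandas as pd

from .literature import BiomarkerEvidence
from .mcode import MolecularModel

logger = logging.getLogger(__name__)

UP, DOWN, CONTRADICTORY, ASSOCIATION_ONLY = (
    "up",
    "down",
    "contradictory",
    "association_only",
)


@dataclass(frozen=True)
class RegulationCall:
    """Merged regulation state of one gene with its evidence tags."""

    gene_id: str
    state: str
    sources: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.state not in (UP, DOWN, CONTRADICTORY, ASSOCIATION_ONLY):
            raise ValueError(f"unknown regulation state {self.state!r}")


@dataclass(frozen=True)
class InterferenceReport:
    """Shared and extra deregulated features of a model pair.

    ``shared`` is ``A.features ∩ B.features``; ``extra`` the disease-model
    features deregulated in supplementary evidence but absent from the
    drug model.  ``calls`` and ``biomarkers`` are filled by
    :func:`annotate_regulation`.
    """

    model_a: MolecularModel = field(compare=False)
    model_b: MolecularModel = field(compare=False)
    shared: frozenset[str]
    extra: frozenset[str]
    calls: dict[str, RegulationCall] = field(default_factory=dict, compare=False)
    biomarkers: dict[str, frozenset[str]] = field(default_factory=dict, compare=False)

    @property
    def genes(self) -> frozenset[str]:
        return self.shared | self.extra


def interfere(
    model_a: MolecularModel,
    model_b: MolecularModel,
    extra_evidence: pd.DataFrame | None = None,
) -> InterferenceReport:
    """Overlap model A (disease) with model B (drug MoA).

    ``extra_evidence`` is a gene-level regulation table (columns
    ``gene_id``, ``direction``) such as the output of
    :func:`netmoa.diffexpr.collapse_to_genes`; its genes that belong to
    the disease model but not to the drug model become ``extra``.
    """
    a_nodes, b_nodes = set(model_a.graph.nodes), set(model_b.graph.nodes)
    if len(a_nodes) >= 100 and len(b_nodes) >= 100 and not (a_nodes & b_nodes):
        logger.warning(
            "models %r and %r share no graph nodes; identifier namespaces may differ",
            model_a.label,
            model_b.label,
        )
    shared = model_a.features & model_b.features
    if extra_evidence is not None and len(extra_evidence):
        evidence_genes = set(extra_evidence["gene_id"])
        extra = (evidence_genes & model_a.features) - shared
    else:
        extra = frozenset()
    logger.info(
        "interference %r vs %r: %d shared, %d extra features",
        model_a.label,
        model_b.label,
        len(shared),
        len(extra),
    )
    return InterferenceReport(
        model_a=model_a,
        model_b=model_b,
        shared=frozenset(shared),
        extra=frozenset(extra),
    )


def _merge_direction(directions: set[str]) -> str:
    has_up = UP in directions or CONTRADICTORY in directions
    has_down = DOWN in directions or CONTRADICTORY in directions
    if has_up and has_down:
        return CONTRADICTORY
    if has_up:
        return UP
    if has_down:
        return DOWN
    return ASSOCIATION_ONLY


def annotate_regulation(
    report: InterferenceReport,
    evidence_tables: list[tuple[str, pd.DataFrame]],
    biomarkers: list[BiomarkerEvidence] = (),
) -> InterferenceReport:
    """Attach merged regulation states and biomarker flags to a report.

    ``evidence_tables`` is a list of ``(tag, table)`` pairs; each table
    has columns ``gene_id`` and ``direction`` (``up``/``down``/
    ``contradictory``).  Directions are merged across tables per gene —
    conflicting tables yield ``contradictory`` — and report genes with no
    directional row become ``association_only``.  Idempotent and
    independent of table order.  Evidence for genes outside the report is
    ignored (counted in the log).
    """
    directions: dict[str, set[str]] = {}
    tags: dict[str, set[str]] = {}
    n_outside = 0
    for tag, table in evidence_tables:
        for gene_id, direction in zip(table["gene_id"], table["direction"]):
            if gene_id not in report.genes:
                n_outside += 1
                continue
            directions.setdefault(gene_id, set()).add(direction)
            tags.setdefault(gene_id, set()).add(tag)
    if n_outside:
        logger.info("annotate: %d evidence rows outside the report ignored", n_outside)
    calls = {
        g: RegulationCall(
            gene_id=g,
            state=_merge_direction(directions.get(g, set())),
            sources=tuple(sorted(tags.get(g, ()))),
        )
        for g in sorted(report.genes)
    }
    marks = {
        ev.gene_id: frozenset(ev.classes)
        for ev in biomarkers
        if ev.gene_id in report.genes
    }
    return replace(report, calls=calls, biomarkers=marks)


def report_table(report: InterferenceReport) -> pd.DataFrame:
    """Interference report as a TSV-ready DataFrame."""
    rows = []
    for g in sorted(report.genes):
        call = report.calls.get(g)
        rows.append(
            {
                "gene_id": g,
                "in_disease_model": g in report.model_a.features,
                "in_drug_model": g in report.model_b.features,
                "shared": g in report.shared,
                "state": call.state if call else "",
                "sources": "|".join(call.sources) if call else "",
                "biomarker": "|".join(sorted(report.biomarkers.get(g, ()))),
                "process_unit": report.model_a.unit_of(g) or 0,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "in_disease_model",
            "in_drug_model",
            "shared",
            "state",
            "sources",
            "biomarker",
            "process_unit",
        ],
    )


def write_interference_graphml(report: InterferenceReport, path) -> None:
    """Disease-model graph with interference annotations as node attributes.

    Mirrors the usual interference-network rendering: affected features
    carry their regulation state (up = red, down = green, contradictory =
    yellow, association-only = grey in the conventional colouring) and
    biomarker flags (D/P).
    """
    g = report.model_a.graph.copy()
    for n in g.nodes:
        call = report.calls.get(n)
        g.nodes[n]["affected"] = n in report.genes
        g.nodes[n]["shared"] = n in report.shared
        g.nodes[n]["state"] = call.state if call else ""
        g.nodes[n]["biomarker"] = "|".join(sorted(report.biomarkers.get(n, ())))
        g.nodes[n]["process_unit"] = report.model_a.unit_of(n) or 0
    for _, _, d in g.edges(data=True):
        if isinstance(d.get("sources"), set):
            d["sources"] = "|".join(sorted(d["sources"]))
    nx.write_graphml(g, path)
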