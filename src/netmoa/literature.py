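"""Literature-derived seed gene sets and biomarker evidence.

Seed genes for model construction come from joining an NCBI
gene2pubmed-format table (tax_id, gene_id, pubmed_id) against a MeSH
annotation table (pubmed_id, mesh_term, major_topic, pub_type): a gene
is a seed for a term when it is linked to at least one publication
annotated with that term (optionally restricted to major-topic
annotations).

Biomarker evidence applies a stricter publication filter.  A publication
qualifies when it

* carries the disease term as a *major* MeSH annotation,
* carries at least one marker term ("biological markers" or
  "genetic markers"),
* carries none of the profiling-study exclusion terms, and
* is admitted by study type: publication type "clinical trial", or
  annotated "humans" or "disease models, animal".

Genes linked to a qualifying publication gain the class *prognostic*
when the publication also carries "prognosis", and *diagnostic* when it
carries any diagnostic trigger term ("diagnosis", "diagnosis,
differential", "early diagnosis", or the disease-qualified
"<disease>/diagnosis").  A gene may carry both classes.

MeSH term matching is exact string equality after whitespace
normalization and case-folding; tree expansion is out of scope.  An
optional *mentions* table (pubmed_id, gene_id) of exact gene-symbol
matches in the marker corpus can supplement the gene2pubmed links.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .network import SeedGeneSet

logger = logging.getLogger(__name__)

DIAGNOSTIC, PROGNOSTIC = "diagnostic", "prognostic"


def _norm_term(term: str) -> str:
    return " ".join(str(term).split()).lower()


@dataclass
class Gene2PubmedTable:
    """gene2pubmed-format links: tax_id, gene_id, pubmed_id."""

    table: pd.DataFrame

    REQUIRED = ("tax_id", "gene_id", "pubmed_id")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"gene2pubmed table lacks column {col!r}")
        before = len(self.table)
        self.table = self.table.drop_duplicates(ignore_index=True)
        if len(self.table) < before:
            logger.info("gene2pubmed: dropped %d duplicate rows", before - len(self.table))

    @classmethod
    def from_tsv(cls, path: str | Path):
        df = pd.read_csv(path, sep="\t", comment="#")
        df.columns = [c.lstrip("#").strip().lower() for c in df.columns]
        df = df.rename(columns={"geneid": "gene_id", "pubmed_id": "pubmed_id"})
        return cls(df)


@dataclass
class MeshAnnotationTable:
    """Per-publication MeSH annotations: pubmed_id, mesh_term, major_topic, pub_type."""

    table: pd.DataFrame

    REQUIRED = ("pubmed_id", "mesh_term", "major_topic")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"MeSH table lacks column {col!r}")
        if (self.table["mesh_term"].astype(str).str.strip() == "").any():
            raise ValueError("MeSH table contains empty terms")
        if "pub_type" not in self.table.columns:
            self.table = self.table.assign(pub_type="")
        t = self.table
        self.table = t.assign(
            mesh_term=t["mesh_term"].map(_norm_term),
            pub_type=t["pub_type"].fillna("").map(_norm_term),
            major_topic=t["major_topic"].astype(bool),
        )

    @classmethod
    def from_tsv(cls, path: str | Path):
        return cls(pd.read_csv(path, sep="\t", comment="#"))

    def pubs_with(self, term: str, major_only: bool = False) -> set:
        """Publication ids annotated with ``term``."""
        t = self.table
        hit = t["mesh_term"] == _norm_term(term)
        if major_only:
            hit &= t["major_topic"]
        return set(t.loc[hit, "pubmed_id"])

    def pubs_with_pub_type(self, pub_type: str) -> set:
        t = self.table
        return set(t.loc[t["pub_type"] == _norm_term(pub_type), "pubmed_id"])


def extract_seed_genes(
    g2p: Gene2PubmedTable,
    mesh: MeshAnnotationTable,
    term: str,
    major_only: bool = False,
    label: str | None = None,
) -> SeedGeneSet:
    """Genes linked to at least one publication annotated with ``term``.

    ``provenance`` records the number of supporting publications per
    gene.  An absent term yields an empty set with a warning.
    """
    pubs = mesh.pubs_with(term, major_only=major_only)
    if not pubs:
        logger.warning("MeSH term %r matches no publication", term)
        return SeedGeneSet(genes=frozenset(), label=label or term)
    links = g2p.table[g2p.table["pubmed_id"].isin(pubs)]
    counts = links.groupby("gene_id")["pubmed_id"].nunique()
    return SeedGeneSet(
        genes=frozenset(counts.index),
        label=label or term,
        provenance=counts.to_dict(),
    )


@dataclass(frozen=True)
class BiomarkerFilterConfig:
    """Filter lists driving :func:`classify_biomarkers`.

    All lists are required; :meth:`for_disease` fills in the standard
    marker/exclusion/admission/trigger terms for a given disease term.
    """

    disease_major_term: str
    marker_terms: tuple[str, ...]
    exclusion_terms: tuple[str, ...]
    admission_pub_types: tuple[str, ...]
    admission_terms: tuple[str, ...]
    prognostic_triggers: tuple[str, ...]
    diagnostic_triggers: tuple[str, ...]

    def __post_init__(self) -> None:
        for name in (
            "marker_terms",
            "exclusion_terms",
            "admission_pub_types",
            "admission_terms",
            "prognostic_triggers",
            "diagnostic_triggers",
        ):
            if not getattr(self, name):
                raise ValueError(f"biomarker filter config: {name} must be non-empty")
        if not self.disease_major_term:
            raise ValueError("biomarker filter config: disease_major_term required")

    @classmethod
    def for_disease(cls, disease_term: str) -> "BiomarkerFilterConfig":
        return cls(
            disease_major_term=disease_term,
            marker_terms=("biological markers", "genetic markers"),
            exclusion_terms=(
                "gene expression studies",
                "microarray analysis",
                "proteomics",
                "metabolomics",
                "genome-wide association study",
            ),
            admission_pub_types=("clinical trial",),
            admission_terms=("humans", "disease models, animal"),
            prognostic_triggers=("prognosis",),
            diagnostic_triggers=(
                "diagnosis",
                "diagnosis, differential",
                "early diagnosis",
                f"{disease_term}/diagnosis",
            ),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "BiomarkerFilterConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        try:
            return cls(
                disease_major_term=raw["disease_major_term"],
                marker_terms=tuple(raw["marker_terms"]),
                exclusion_terms=tuple(raw["exclusion_terms"]),
                admission_pub_types=tuple(raw["admission_pub_types"]),
                admission_terms=tuple(raw["admission_terms"]),
                prognostic_triggers=tuple(raw["prognostic_triggers"]),
                diagnostic_triggers=tuple(raw["diagnostic_triggers"]),
            )
        except KeyError as err:
            raise ValueError(f"biomarker filter config: missing key {err}") from err

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        data = {
            "disease_major_term": self.disease_major_term,
            "marker_terms": list(self.marker_terms),
            "exclusion_terms": list(self.exclusion_terms),
            "admission_pub_types": list(self.admission_pub_types),
            "admission_terms": list(self.admission_terms),
            "prognostic_triggers": list(self.prognostic_triggers),
            "diagnostic_triggers": list(self.diagnostic_triggers),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass(frozen=True)
class BiomarkerEvidence:
    """Diagnostic/prognostic literature evidence for one gene."""

    gene_id: str
    classes: frozenset[str]
    publications: dict[str, frozenset] = field(compare=False)  # class -> pubmed ids

    def __post_init__(self) -> None:
        if not self.classes:
            raise ValueError("biomarker evidence must carry >= 1 class")


def qualifying_publications(
    mesh: MeshAnnotationTable, config: BiomarkerFilterConfig
) -> set:
    """Publication ids passing the marker filter (before trigger split)."""
    pubs = mesh.pubs_with(config.disease_major_term, major_only=True)
    marker = set().union(*(mesh.pubs_with(t) for t in config.marker_terms))
    pubs &= marker
    admitted = set().union(
        *(mesh.pubs_with_pub_type(pt) for pt in config.admission_pub_types)
    ) | set().union(*(mesh.pubs_with(t) for t in config.admission_terms))
    pubs &= admitted
    excluded = set().union(*(mesh.pubs_with(t) for t in config.exclusion_terms))
    return pubs - excluded


def classify_biomarkers(
    g2p: Gene2PubmedTable,
    mesh: MeshAnnotationTable,
    config: BiomarkerFilterConfig,
    mentions: pd.DataFrame | None = None,
) -> list[BiomarkerEvidence]:
    """Classify genes as diagnostic and/or prognostic disease markers.

    ``mentions`` may supply additional (pubmed_id, gene_id) links from
    exact gene-symbol matches; they are unioned with the gene2pubmed
    links of qualifying publications.  Output is sorted by gene id and
    independent of table row order.
    """
    pubs = qualifying_publications(mesh, config)
    links = g2p.table[g2p.table["pubmed_id"].isin(pubs)][["gene_id", "pubmed_id"]]
    if mentions is not None:
        extra = mentions[mentions["pubmed_id"].isin(pubs)][["gene_id", "pubmed_id"]]
        links = pd.concat([links, extra], ignore_index=True).drop_duplicates()
    trigger_pubs = {
        PROGNOSTIC: set().union(*(mesh.pubs_with(t) for t in config.prognostic_triggers)),
        DIAGNOSTIC: set().union(*(mesh.pubs_with(t) for t in config.diagnostic_triggers)),
    }
    out = []
    for gene, grp in links.groupby("gene_id", sort=True):
        gene_pubs = set(grp["pubmed_id"])
        per_class = {
            cls: frozenset(gene_pubs & tp)
            for cls, tp in trigger_pubs.items()
            if gene_pubs & tp
        }
        if per_class:
            out.append(
                BiomarkerEvidence(
                    gene_id=gene,
                    classes=frozenset(per_class),
                    publications=per_class,
                )
            )
    return out


def match_gene_mentions(
    pub_texts: pd.DataFrame, symbol_to_gene: dict[str, str]
) -> pd.DataFrame:
    """Exact whole-token gene-symbol matches in publication text.

    ``pub_texts`` needs columns ``pubmed_id`` and ``text``; matching is
    case-sensitive on whitespace-delimited tokens (fuzzy matching is out
    of scope).  Returns a (pubmed_id, gene_id) DataFrame usable as the
    ``mentions`` argument of :func:`classify_biomarkers`.
    """
    rows = []
    for pub, text in zip(pub_texts["pubmed_id"], pub_texts["text"]):
        tokens = set(str(text).split())
        for sym, gene in symbol_to_gene.items():
            if sym in tokens:
                rows.append({"pubmed_id": pub, "gene_id": gene})
    return pd.DataFrame(rows, columns=["pubmed_id", "gene_id"]).drop_duplicates(
        ignore_index=True
    )
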