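"""End-to-end orchestration: models → enrichment → DE → interference.

``run_pipeline`` drives the whole analysis from a single YAML
configuration: build the disease and drug molecular models from the
interaction network and literature-derived (or listed) seed genes,
enrich both feature sets against a pathway collection, optionally call
differential expression on a two-group matrix, and compute the
interference report with regulation states and biomarker flags.  Every
stage writes its artifacts to the output directory and a run manifest
records versions, parameters, the seed and per-stage counts, so a rerun
with the same configuration is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .diffexpr import ExpressionMatrix, TranscriptGeneMap, cluster_samples, collapse_to_genes, sam_call
from .enrichment import DEFAULT_BLOCKLIST, enrich_model, read_gmt, results_table, significant_pathways
from .interference import annotate_regulation, interfere, report_table, write_interference_graphml
from .literature import (
    BiomarkerFilterConfig,
    Gene2PubmedTable,
    MeshAnnotationTable,
    classify_biomarkers,
    extract_seed_genes,
)
from .mcode import MCODEParams, build_molecular_model, units_table, write_model_graphml
from .network import SeedGeneSet, load_network

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see ``from_yaml``)."""

    network: Path
    output_dir: Path
    disease: dict
    drug: dict
    literature: dict | None = None
    pathways: Path | None = None
    expression: dict | None = None
    biomarker_config: Path | None = None
    mcode: MCODEParams = field(default_factory=MCODEParams)
    enrichment: dict = field(default_factory=dict)
    sam: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        base = Path(path).parent
        with open(path) as fh:
            raw = yaml.safe_load(fh)

        def resolve(p):
            p = Path(p)
            return p if p.is_absolute() else (base / p)

        cfg = cls(
            network=resolve(raw["network"]),
            output_dir=resolve(raw["output_dir"]),
            disease=raw["disease"],
            drug=raw["drug"],
            literature=raw.get("literature"),
            pathways=resolve(raw["pathways"]) if raw.get("pathways") else None,
            expression=raw.get("expression"),
            biomarker_config=(
                resolve(raw["biomarker_config"]) if raw.get("biomarker_config") else None
            ),
            mcode=MCODEParams(**raw.get("mcode", {})),
            enrichment=raw.get("enrichment", {}),
            sam=raw.get("sam", {}),
        )
        if cfg.literature:
            cfg.literature = {k: resolve(v) for k, v in cfg.literature.items()}
        if cfg.expression:
            cfg.expression = {k: resolve(v) for k, v in cfg.expression.items()}
        for p in cfg.input_paths():
            if not Path(p).exists():
                raise FileNotFoundError(f"configured input does not exist: {p}")
        return cfg

    def input_paths(self):
        paths = [self.network]
        if self.pathways:
            paths.append(self.pathways)
        if self.literature:
            paths += list(self.literature.values())
        if self.expression:
            paths += list(self.expression.values())
        if self.biomarker_config:
            paths.append(self.biomarker_config)
        return paths


def _seed_set(spec: dict, g2p, mesh, label: str) -> SeedGeneSet:
    if "genes" in spec:
        return SeedGeneSet(genes=frozenset(spec["genes"]), label=label)
    if g2p is None or mesh is None:
        raise PipelineError(
            f"seed set {label!r} needs either an explicit gene list or literature tables"
        )
    return extract_seed_genes(
        g2p, mesh, spec["term"], major_only=bool(spec.get("major_only", False)), label=label
    )


def run_pipeline(config: PipelineConfig):
    """Run all stages; returns the annotated InterferenceReport.

    Optional stages degrade gracefully: without pathways there is no
    enrichment output; without expression inputs the interference report
    has no extra deregulated features and regulation states fall back to
    association-only.  A hard error in any stage aborts with the stage
    name; partial outputs stay on disk next to a FAILED marker.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"netmoa_version": __version__, "stages": {}}
    stage = "setup"
    try:
        network = load_network(config.network)
        manifest["network"] = {
            "path": str(config.network),
            "nodes": network.number_of_nodes(),
            "edges": network.number_of_edges(),
        }
        g2p = mesh = None
        if config.literature:
            g2p = Gene2PubmedTable.from_tsv(config.literature["gene2pubmed"])
            mesh = MeshAnnotationTable.from_tsv(config.literature["mesh"])

        stage = "models"
        models = {}
        for role in ("disease", "drug"):
            seeds = _seed_set(getattr(config, role), g2p, mesh, role)
            model = build_molecular_model(seeds, network, config.mcode)
            models[role] = model
            units_table(model).to_csv(out / f"model_{role}_units.tsv", sep="\t", index=False)
            write_model_graphml(model, out / f"model_{role}.graphml")
            sizes = sorted(len(u) for u in model.units)
            manifest["stages"][f"model_{role}"] = {
                "input_genes": len(seeds.genes),
                "graph_nodes": model.graph.number_of_nodes(),
                "units": len(model.units),
                "unit_sizes": sizes,
                "features": len(model.features),
            }

        stage = "enrichment"
        if config.pathways:
            collection = read_gmt(config.pathways)
            blocklist = tuple(config.enrichment.get("blocklist", DEFAULT_BLOCKLIST))
            fdr_threshold = float(config.enrichment.get("fdr_threshold", 0.05))
            mode = config.enrichment.get("mode", "exact")
            significant = {}
            for role, model in models.items():
                results = enrich_model(
                    set(model.features),
                    collection,
                    blocklist=blocklist,
                    fdr_threshold=fdr_threshold,
                    mode=mode,
                )
                results_table(results).to_csv(
                    out / f"enrichment_{role}.tsv", sep="\t", index=False
                )
                significant[role] = significant_pathways(results)
            shared_pathways = sorted(
                set(significant["disease"]) & set(significant["drug"])
            )
            pd.DataFrame({"pathway": shared_pathways}).to_csv(
                out / "shared_pathways.tsv", sep="\t", index=False
            )
            manifest["stages"]["enrichment"] = {
                "significant_disease": len(significant["disease"]),
                "significant_drug": len(significant["drug"]),
                "shared": len(shared_pathways),
            }

        stage = "differential_expression"
        gene_table = None
        if config.expression:
            matrix = ExpressionMatrix.from_tsv(
                config.expression["matrix"], config.expression["groups"]
            )
            tmap = TranscriptGeneMap.from_tsv(config.expression["transcript_map"])
            dendro = cluster_samples(matrix)
            (out / "sample_dendrogram.nwk").write_text(dendro.to_newick() + "\n")
            sam_kwargs = dict(config.sam)
            result = sam_call(
                matrix,
                delta=sam_kwargs.get("delta"),
                target_fdr=(
                    sam_kwargs.get("target_fdr", 0.05)
                    if sam_kwargs.get("delta") is None
                    else None
                ),
                n_perm=int(sam_kwargs.get("n_perm", 100)),
                rng_seed=sam_kwargs.get("rng_seed"),
            )
            result.table.to_csv(out / "sam_transcripts.tsv", sep="\t")
            gene_table = collapse_to_genes(result, tmap)
            gene_table.to_csv(out / "sam_genes.tsv", sep="\t", index=False)
            manifest["stages"]["differential_expression"] = {
                "transcripts": int(matrix.values.shape[0]),
                "groups_separate": bool(dendro.groups_separate),
                "delta": result.delta,
                "s0": result.s0,
                "est_fdr": None if pd.isna(result.est_fdr) else result.est_fdr,
                "n_called": result.n_called,
                "n_genes": int(len(gene_table)),
                "rng_seed": sam_kwargs.get("rng_seed"),
            }

        stage = "biomarkers"
        biomarkers = []
        if config.biomarker_config and g2p is not None:
            bconfig = BiomarkerFilterConfig.from_yaml(config.biomarker_config)
            biomarkers = classify_biomarkers(g2p, mesh, bconfig)
            manifest["stages"]["biomarkers"] = {"genes": len(biomarkers)}

        stage = "interference"
        report = interfere(models["disease"], models["drug"], gene_table)
        evidence = [("expression", gene_table)] if gene_table is not None else []
        report = annotate_regulation(report, evidence, biomarkers)
        report_table(report).to_csv(out / "interference.tsv", sep="\t", index=False)
        write_interference_graphml(report, out / "interference.graphml")
        manifest["stages"]["interference"] = {
            "shared": len(report.shared),
            "extra": len(report.extra),
            "biomarker_genes": len(report.biomarkers),
        }

        manifest["mcode_params"] = vars(config.mcode).copy()
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        return report
    except Exception as err:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {err}\n")
        raise PipelineError(f"pipeline stage {stage!r} failed: {err}") from err
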