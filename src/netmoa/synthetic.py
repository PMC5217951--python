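"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators emulate the study's data sources without any download:

* :func:`simulate_network` — a planted-partition interaction network:
  dense complexes (within-complex edges Bernoulli ``p_in``) embedded in
  sparse background noise (all other pairs Bernoulli ``p_out``).  The
  defaults (60 background nodes, 3 complexes of 8, ``p_in=0.9``,
  ``p_out=0.02``) are the recovery-benchmark conditions used throughout
  the tests.
* :func:`simulate_annotations` — gene2pubmed and MeSH annotation tables
  whose "disease" and "drug" literatures cover disjoint planted
  complexes and share exactly ``n_overlap`` genes placed inside
  recoverable complexes, plus biomarker-qualifying publications (and an
  excluded profiling-study decoy) for a chosen gene subset.
* :func:`simulate_expression` — a two-group (default 4 vs 4) transcript
  matrix of Gaussian log-scale intensities with a planted set of shifted
  transcripts, and the transcript→gene map with biotypes.

All generators are pure functions of their parameters and ``rng_seed``;
the returned :class:`SyntheticTruth` fully determines regeneration.
:func:`make_fixtures` materializes a complete toy study on disk: there
the complexes are planted as cliques (``p_in=1``) and the expression
effect is large, so the end-to-end ground truth (shared features, extra
deregulated features, regulation states, biomarker flags) is exact
rather than statistical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import network as netio
from .diffexpr import ExpressionMatrix, TranscriptGeneMap
from .literature import BiomarkerFilterConfig, Gene2PubmedTable, MeshAnnotationTable
from .network import InteractionNetwork

logger = logging.getLogger(__name__)

TAX_ID = 9606
DISEASE_TERM, DRUG_TERM = "disease", "drug"


@dataclass
class SyntheticTruth:
    """Ground truth accumulated across the generators."""

    rng_seed: int
    planted_units: tuple[frozenset[str], ...] = ()
    background_nodes: frozenset[str] = frozenset()
    disease_genes: frozenset[str] = frozenset()
    drug_genes: frozenset[str] = frozenset()
    seed_overlap: frozenset[str] = frozenset()
    biomarker_classes: dict[str, tuple[str, ...]] = field(default_factory=dict)
    de_genes: dict[str, str] = field(default_factory=dict)
    de_transcripts: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        data = {
            "rng_seed": self.rng_seed,
            "planted_units": [sorted(u) for u in self.planted_units],
            "background_nodes": sorted(self.background_nodes),
            "disease_genes": sorted(self.disease_genes),
            "drug_genes": sorted(self.drug_genes),
            "seed_overlap": sorted(self.seed_overlap),
            "biomarker_classes": {g: list(c) for g, c in self.biomarker_classes.items()},
            "de_genes": dict(sorted(self.de_genes.items())),
            "de_transcripts": dict(sorted(self.de_transcripts.items())),
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1, sort_keys=True)


def simulate_network(
    n_background: int = 60,
    n_complexes: int = 3,
    complex_size: int = 8,
    p_in: float = 0.9,
    p_out: float = 0.02,
    rng_seed: int = 0,
) -> tuple[InteractionNetwork, SyntheticTruth]:
    """Planted-partition network: dense complexes in sparse background."""
    if not (0.0 <= p_out < p_in <= 1.0):
        raise ValueError(f"need 0 <= p_out < p_in <= 1, got p_in={p_in} p_out={p_out}")
    if complex_size < 3:
        raise ValueError("complex_size must be >= 3")
    if n_background < 0 or n_complexes < 0:
        raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(rng_seed)
    n = n_background + n_complexes * complex_size
    nodes = [f"G{i:04d}" for i in range(1, n + 1)]
    background = nodes[:n_background]
    units = [
        frozenset(nodes[n_background + j * complex_size : n_background + (j + 1) * complex_size])
        for j in range(n_complexes)
    ]
    member_of = {g: j for j, u in enumerate(units) for g in u}
    g = netio.new_network(nodes=nodes)
    for u, v in combinations(nodes, 2):
        same = member_of.get(u, -1) == member_of.get(v, -2)
        if rng.random() < (p_in if same else p_out):
            g.add_edge(u, v, sources={"synthetic"})
    truth = SyntheticTruth(
        rng_seed=rng_seed,
        planted_units=tuple(units),
        background_nodes=frozenset(background),
    )
    return g, truth


def _overlap_blocks(n_overlap: int, units: list[frozenset], min_block: int = 3) -> list[list[str]]:
    """Split the overlap across complexes in blocks of >= min_block genes.

    Each block stays inside one complex, so the overlap genes form dense
    recoverable subgraphs in both literatures' models.
    """
    if n_overlap == 0:
        return []
    if n_overlap < min_block:
        raise ValueError(f"n_overlap must be 0 or >= {min_block} to stay recoverable")
    blocks = []
    remaining = n_overlap
    for u in units:
        if remaining == 0:
            break
        size = len(u)
        take = min(remaining, size)
        # never leave a remainder smaller than min_block
        if 0 < remaining - take < min_block:
            take = remaining - min_block
        if take < min_block:
            raise ValueError(
                f"cannot place overlap of {n_overlap} in blocks of >= {min_block} "
                f"within complexes of size {size}"
            )
        blocks.append(sorted(u)[:take])
        remaining -= take
    if remaining:
        raise ValueError(
            f"overlap of {n_overlap} infeasible for {len(units)} disease complexes"
        )
    return blocks


def simulate_annotations(
    network: InteractionNetwork,
    truth: SyntheticTruth,
    n_overlap: int = 10,
    n_pubs: int = 20,
    rng_seed: int = 0,
    n_background_seeds: int = 5,
    biomarker_classes: dict[str, tuple[str, ...]] | None = None,
) -> tuple[Gene2PubmedTable, MeshAnnotationTable, SyntheticTruth]:
    """Literature tables for a "disease" and a "drug" term with known overlap.

    The disease literature covers the first ``ceil(K/2)`` planted
    complexes, the drug literature the rest; ``n_overlap`` genes from the
    disease complexes (in within-complex blocks of ≥ 3) are additionally
    linked to the drug literature, so the two extracted seed sets share
    exactly those genes.  Each seed set also receives
    ``n_background_seeds`` disjoint background genes (literature noise
    that never reaches a process unit).

    ``biomarker_classes`` maps gene → classes drawn from
    ``{"diagnostic", "prognostic"}``; each entry emits one qualifying
    marker publication per class.  One additional profiling-study decoy
    publication (annotated "proteomics") is always emitted and must be
    rejected by the biomarker filter.
    """
    units = list(truth.planted_units)
    if not units:
        raise ValueError("truth carries no planted complexes")
    k_disease = (len(units) + 1) // 2
    disease_units, drug_units = units[:k_disease], units[k_disease:]
    blocks = _overlap_blocks(n_overlap, disease_units)
    overlap = [g for b in blocks for g in b]

    rng = np.random.default_rng(rng_seed)
    background = sorted(truth.background_nodes)
    need = 2 * n_background_seeds
    bg_pick = (
        list(rng.choice(background, size=min(need, len(background)), replace=False))
        if background
        else []
    )
    disease_genes = sorted(set().union(*disease_units)) + bg_pick[:n_background_seeds]
    drug_genes = (
        sorted(set().union(*drug_units) if drug_units else set())
        + overlap
        + bg_pick[n_background_seeds:need]
    )

    g2p_rows: list[tuple[int, str, int]] = []
    mesh_rows: list[tuple[int, str, bool, str]] = []
    next_pub = 10_000_001

    def publish(genes: list[str], term: str, n: int) -> None:
        nonlocal next_pub
        pubs = list(range(next_pub, next_pub + n))
        next_pub += n
        for p in pubs:
            mesh_rows.append((p, term, True, ""))
            mesh_rows.append((p, "humans", False, ""))
        for i, g in enumerate(genes):
            g2p_rows.append((TAX_ID, g, pubs[i % n]))

    publish(disease_genes, DISEASE_TERM, n_pubs)
    publish(drug_genes, DRUG_TERM, n_pubs)

    if biomarker_classes is None:
        biomarker_classes = {}
    trigger = {"diagnostic": "early diagnosis", "prognostic": "prognosis"}
    for gene, classes in sorted(biomarker_classes.items()):
        for cls in classes:
            if cls not in trigger:
                raise ValueError(f"unknown biomarker class {cls!r} for gene {gene}")
            pub = next_pub
            next_pub += 1
            g2p_rows.append((TAX_ID, gene, pub))
            mesh_rows += [
                (pub, DISEASE_TERM, True, ""),
                (pub, "biological markers", False, ""),
                (pub, "humans", False, ""),
                (pub, trigger[cls], False, ""),
            ]
    # profiling-study decoy: qualifies on every axis but the exclusion list
    decoy_gene = disease_genes[0]
    pub = next_pub
    next_pub += 1
    g2p_rows.append((TAX_ID, decoy_gene, pub))
    mesh_rows += [
        (pub, DISEASE_TERM, True, ""),
        (pub, "biological markers", False, ""),
        (pub, "humans", False, ""),
        (pub, "prognosis", False, ""),
        (pub, "proteomics", False, ""),
    ]

    g2p = Gene2PubmedTable(
        pd.DataFrame(g2p_rows, columns=["tax_id", "gene_id", "pubmed_id"])
    )
    mesh = MeshAnnotationTable(
        pd.DataFrame(
            mesh_rows, columns=["pubmed_id", "mesh_term", "major_topic", "pub_type"]
        )
    )
    truth.disease_genes = frozenset(disease_genes)
    truth.drug_genes = frozenset(drug_genes)
    truth.seed_overlap = frozenset(overlap)
    truth.biomarker_classes = {g: tuple(sorted(c)) for g, c in biomarker_classes.items()}
    return g2p, mesh, truth


def simulate_expression(
    n_transcripts: int = 5000,
    n_per_group: int = 4,
    n_de: int = 250,
    effect: float = 2.0,
    sigma: float = 1.0,
    transcripts_per_gene: int = 1,
    rng_seed: int = 0,
    *,
    forced: list[tuple[str, str]] | None = None,
    noncoding_fraction: float = 0.0,
) -> tuple[ExpressionMatrix, TranscriptGeneMap, SyntheticTruth]:
    """Two-group expression matrix with planted differential transcripts.

    Background values are Normal(0, sigma²); planted transcripts are
    shifted by ±``effect`` in the treated group.  Consecutive blocks of
    ``transcripts_per_gene`` transcripts map to one gene;
    ``noncoding_fraction`` of the genes get a non-protein-coding biotype.

    ``forced`` pins specific genes into the matrix: each ``(gene_id,
    direction)`` pair claims the first free gene slot and all its
    transcripts are planted with that direction (``"contradictory"``
    plants half up, half down and needs ``transcripts_per_gene >= 2``).
    Forced transcripts count toward the planted total; ``n_de`` minus the
    forced transcripts are drawn at random from the remaining rows.
    """
    if n_de > n_transcripts:
        raise ValueError("n_de cannot exceed n_transcripts")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if n_per_group < 2:
        raise ValueError("need >= 2 samples per group")
    if not 0.0 <= noncoding_fraction <= 1.0:
        raise ValueError("noncoding_fraction must be in [0, 1]")
    forced = list(forced or [])
    rng = np.random.default_rng(rng_seed)

    transcripts = [f"T{i:06d}" for i in range(1, n_transcripts + 1)]
    n_genes = (n_transcripts + transcripts_per_gene - 1) // transcripts_per_gene
    gene_names = [f"SG{j:05d}" for j in range(1, n_genes + 1)]
    for slot, (gene_id, _) in enumerate(forced):
        if slot >= n_genes:
            raise ValueError("more forced genes than gene slots")
        gene_names[slot] = gene_id
    gene_of = {
        t: gene_names[i // transcripts_per_gene] for i, t in enumerate(transcripts)
    }

    n_noncoding = int(round(noncoding_fraction * n_genes))
    noncoding = set(
        rng.choice(gene_names[len(forced):], size=min(n_noncoding, n_genes - len(forced)), replace=False)
    ) if n_noncoding else set()

    de_transcripts: dict[str, str] = {}
    for slot, (gene_id, direction) in enumerate(forced):
        rows = transcripts[slot * transcripts_per_gene : (slot + 1) * transcripts_per_gene]
        if direction == "contradictory":
            if len(rows) < 2:
                raise ValueError("contradictory forced gene needs >= 2 transcripts")
            half = len(rows) // 2
            for t in rows[:half]:
                de_transcripts[t] = "up"
            for t in rows[half:]:
                de_transcripts[t] = "down"
        elif direction in ("up", "down"):
            for t in rows:
                de_transcripts[t] = direction
        else:
            raise ValueError(f"unknown forced direction {direction!r}")
    n_random = n_de - len(de_transcripts)
    if n_random < 0:
        raise ValueError("forced transcripts exceed n_de")
    free = [t for t in transcripts if t not in de_transcripts]
    for t in rng.choice(free, size=n_random, replace=False):
        de_transcripts[t] = "up" if rng.random() < 0.5 else "down"

    samples = [f"S_t{i}" for i in range(1, n_per_group + 1)] + [
        f"S_c{i}" for i in range(1, n_per_group + 1)
    ]
    groups = {s: ("treated" if s.startswith("S_t") else "control") for s in samples}
    values = rng.normal(0.0, sigma, size=(n_transcripts, 2 * n_per_group))
    idx = {t: i for i, t in enumerate(transcripts)}
    for t, direction in de_transcripts.items():
        shift = effect if direction == "up" else -effect
        values[idx[t], :n_per_group] += shift
    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=transcripts, columns=samples), groups=groups
    )
    tmap = TranscriptGeneMap(
        pd.DataFrame(
            {
                "transcript_id": transcripts,
                "gene_id": [gene_of[t] for t in transcripts],
                "biotype": [
                    "lincRNA" if gene_of[t] in noncoding else "protein_coding"
                    for t in transcripts
                ],
            }
        )
    )
    de_genes: dict[str, str] = {}
    for t, direction in de_transcripts.items():
        g = gene_of[t]
        prev = de_genes.get(g)
        if prev is None:
            de_genes[g] = direction
        elif prev != direction:
            de_genes[g] = "contradictory"
    truth = SyntheticTruth(
        rng_seed=rng_seed, de_genes=de_genes, de_transcripts=de_transcripts
    )
    return matrix, tmap, truth


# ---------------------------------------------------------------------------
# complete toy study on disk


def make_fixtures(
    outdir: str | Path,
    rng_seed: int = 0,
    n_overlap: int = 10,
    n_extra: int = 6,
    n_background: int = 40,
    n_complexes: int = 5,
    complex_size: int = 12,
    p_out: float = 0.02,
) -> tuple[dict[str, Path], SyntheticTruth]:
    """Write a complete, internally consistent toy study to ``outdir``.

    The study plants ``n_complexes`` cliques (``p_in=1`` so recovery is
    exact); the disease literature covers the first three, the drug
    literature the rest plus ``n_overlap`` shared genes; ``n_extra``
    further disease-model genes (not shared) are strongly deregulated in
    the expression experiment, one of them with contradictory transcript
    directions.  Three genes carry biomarker publications: one shared
    gene diagnostic, one shared gene prognostic, one extra gene both.

    Returns the written paths and the combined ground truth.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    net, truth = simulate_network(
        n_background=n_background,
        n_complexes=n_complexes,
        complex_size=complex_size,
        p_in=1.0,
        p_out=p_out,
        rng_seed=rng_seed,
    )
    k_disease = (n_complexes + 1) // 2
    disease_units = list(truth.planted_units[:k_disease])

    overlap = [g for b in _overlap_blocks(n_overlap, disease_units) for g in b]
    # extra deregulated genes: disease-complex members outside the overlap
    pool = sorted(set().union(*disease_units) - set(overlap))
    if n_extra > len(pool):
        raise ValueError("n_extra exceeds available disease-model genes")
    extra = pool[:n_extra]

    biomarker_classes: dict[str, tuple[str, ...]] = {}
    if overlap:
        biomarker_classes[overlap[0]] = ("diagnostic",)
    if len(overlap) > 1:
        biomarker_classes[overlap[1]] = ("prognostic",)
    if extra:
        biomarker_classes[extra[0]] = ("diagnostic", "prognostic")

    g2p, mesh, truth = simulate_annotations(
        net,
        truth,
        n_overlap=n_overlap,
        n_pubs=12,
        rng_seed=rng_seed,
        biomarker_classes=biomarker_classes,
    )

    # shared genes with directional evidence; the rest stay association-only
    forced = [(g, "up") for g in overlap[: len(overlap) // 2]]
    forced += [(g, "up") for g in extra[: n_extra // 2]]
    forced += [(g, "down") for g in extra[n_extra // 2 : -1]]
    if extra:
        forced.append((extra[-1], "contradictory"))
    matrix, tmap, expr_truth = simulate_expression(
        n_transcripts=400,
        n_per_group=4,
        n_de=2 * len(forced) + 20,
        effect=4.0,
        sigma=0.5,
        transcripts_per_gene=2,
        rng_seed=rng_seed,
        forced=forced,
    )
    truth.de_genes = expr_truth.de_genes
    truth.de_transcripts = expr_truth.de_transcripts

    # pathway collection: one pathway per planted complex, two random
    # gene sets, and a blocklisted disease-named decoy
    rng = np.random.default_rng(rng_seed)
    all_genes = sorted(net.nodes)
    pathways = {
        f"Complex {j + 1} assembly": set(u)
        for j, u in enumerate(truth.planted_units)
    }
    for j in range(2):
        pathways[f"Random process {j + 1}"] = set(
            rng.choice(all_genes, size=15, replace=False)
        )
    pathways["Pathways in cancer"] = set(sorted(truth.planted_units[0])[:8]) | set(
        rng.choice(all_genes, size=10, replace=False)
    )

    from .enrichment import PathwayCollection, write_gmt

    collection = PathwayCollection.from_dict(pathways, background=set(all_genes))

    paths = {
        "network": outdir / "network.tsv",
        "gene2pubmed": outdir / "gene2pubmed.tsv",
        "mesh": outdir / "mesh.tsv",
        "pathways": outdir / "pathways.gmt",
        "expression": outdir / "expression.tsv",
        "groups": outdir / "groups.tsv",
        "transcript_map": outdir / "transcript_map.tsv",
        "biomarker_config": outdir / "biomarker_config.yaml",
        "truth": outdir / "truth.json",
        "config": outdir / "config.yaml",
    }
    netio.write_network(net, paths["network"])
    g2p.table.to_csv(paths["gene2pubmed"], sep="\t", index=False)
    mesh.table.to_csv(paths["mesh"], sep="\t", index=False)
    write_gmt(collection, paths["pathways"])
    matrix.values.to_csv(paths["expression"], sep="\t")
    with open(paths["groups"], "w") as fh:
        for s in matrix.values.columns:
            fh.write(f"{s}\t{matrix.groups[s]}\n")
    tmap.table.to_csv(paths["transcript_map"], sep="\t", index=False)
    BiomarkerFilterConfig.for_disease(DISEASE_TERM).to_yaml(paths["biomarker_config"])
    truth.to_json(paths["truth"])

    # paths inside the config are relative to the config file itself
    config = {
        "network": paths["network"].name,
        "pathways": paths["pathways"].name,
        "disease": {"term": DISEASE_TERM, "major_only": True},
        "drug": {"term": DRUG_TERM, "major_only": False},
        "literature": {
            "gene2pubmed": paths["gene2pubmed"].name,
            "mesh": paths["mesh"].name,
        },
        "expression": {
            "matrix": paths["expression"].name,
            "groups": paths["groups"].name,
            "transcript_map": paths["transcript_map"].name,
        },
        "biomarker_config": paths["biomarker_config"].name,
        "mcode": {},
        "enrichment": {"fdr_threshold": 0.05, "mode": "exact"},
        "sam": {"target_fdr": 0.05, "n_perm": 100, "rng_seed": int(rng_seed)},
        "output_dir": "results",
    }
    import yaml

    with open(paths["config"], "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    logger.info("toy study written to %s", outdir)
    return paths, truth
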