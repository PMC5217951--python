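# netmoa

Network-based molecular models of disease pathophysiology and drug
mechanism of action (MoA), and the *interference analysis* between
them — a computational strategy for drug repositioning.

Given an undirected protein-interaction network, literature-derived
seed gene sets, pathway gene sets (GMT), and a two-group expression
experiment, `netmoa`:

1. **builds molecular models** — the subgraph induced on the seed genes
   (seeds interacting with no other seed are dropped), segmented into
   *process units* with a deterministic Molecular Complex Detection
   (MCODE) variant using core-clustering vertex weights
   `w(v) = k_max · density(H)`, *H* the highest k-core of N[v];
2. **enriches pathways** — one-tailed hypergeometric (or EASE) tests
   with Benjamini–Hochberg FDR control and a blocklist for
   disease-named pathways;
3. **calls differential expression** — the two-class SAM statistic
   `d = (x̄_t − x̄_c)/(s + s₀)` with permutation-estimated FDR, plus
   1 − Pearson / average-linkage sample QC and transcript→gene
   collapse;
4. **computes interference** — shared features of the disease and drug
   models, extra deregulated disease-model genes, merged up/down/
   contradictory regulation states, and diagnostic/prognostic biomarker
   flags from MeSH-filtered literature evidence.

A synthetic-data module generates networks with planted complexes,
consistent literature tables, and expression matrices with known ground
truth, so the whole pipeline is testable offline.

## Worked example

The `examples/` directory has one short script per capability. The
end-to-end analysis (`examples/interference_analysis.py`) generates a
toy study — 5 planted complexes, a disease literature covering three of
them, a drug literature covering the other two plus 10 shared genes,
and an expression experiment deregulating 6 further disease genes — and
runs the full pipeline:

```
planted overlap:   10
shared features:   10
extra deregulated: 6
regulation states: {'up': 8, 'association_only': 5, 'down': 2, 'contradictory': 1}
biomarker G0041: diagnostic
biomarker G0042: prognostic
biomarker G0051: diagnostic/prognostic
```

The 10 shared features are the genes planted in both literatures and
recovered inside process units of both models; the 6 extra features are
disease-model genes the expression experiment found deregulated; states
merge the directional evidence (both directions ⇒ contradictory, none ⇒
association-only); D/P flags come from qualifying marker publications.

The same analysis is scriptable from the shell:

```sh
netmoa simulate toy --seed 7        # write the toy study
netmoa run toy/config.yaml          # models -> enrichment -> DE -> interference
```

which prints `interference: 10 shared features, 6 extra deregulated
features` and writes models (GraphML + TSV), enrichment tables, the
shared-pathway summary, SAM results, the sample dendrogram (Newick),
the interference report and a run manifest under `toy/results/`.

## Library API

```python
from netmoa import (
    load_network, SeedGeneSet, build_molecular_model, MCODEParams,
    enrich_model, read_gmt, sam_call, collapse_to_genes,
    interfere, annotate_regulation,
)

network = load_network("interactome.tsv")
disease = build_molecular_model(SeedGeneSet(genes=disease_seeds, label="disease"),
                                network, MCODEParams(vwp=0.2, min_size=3))
drug = build_molecular_model(SeedGeneSet(genes=drug_seeds, label="drug"), network)
report = interfere(disease, drug, extra_evidence=gene_table)
```

See `docs/methods.md` for the model details, parameter defaults and
their rationale, and known limitations.

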