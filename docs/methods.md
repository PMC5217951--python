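# Methods

`netmoa` implements a network-medicine workflow for positioning a drug
against a disease: build a molecular model of the disease and of the
drug's mechanism of action (MoA) on a protein-interaction network,
characterize both by pathway enrichment, call the drug's transcriptional
effect, and intersect the two models (the *interference analysis*).
This note records the models, the parameter choices, the numerical
decisions, and what the synthetic benchmarks do and do not demonstrate.

## Molecular models

A model starts from a *seed gene set* — genes tied to a disease or drug
in the literature (gene2pubmed links to publications carrying the
relevant MeSH term, optionally restricted to major-topic annotations) or
supplied as a plain list. The model graph is the subgraph of the
interaction network induced on the seeds, with seeds that interact with
no other seed removed. We deliberately keep the induction
seed-restricted: admitting non-seed "connector" proteins (available via
`include_connectors=True`) grows the model with genes that carry no
direct disease/drug evidence and makes the downstream overlap analysis
harder to interpret. Edge direction is ignored; evidence tags on edges
are carried through all exports but do not influence the topology.

## Process-unit segmentation (MCODE)

The model graph is segmented with a deterministic variant of Molecular
Complex Detection. Vertex weights are the classic core-clustering
coefficient: for vertex *v*, the highest k-core *H* of the subgraph
induced by the closed neighborhood N[v] gives weight `k_max · density(H)`,
so every vertex of an isolated (k+1)-clique weighs exactly *k*.

Seeded expansion differs from the textbook description in two respects,
both adopted for robustness and reproducibility:

* **Synchronous closure with an attachment requirement.** A vertex joins
  the growing unit when its weight is at least `(1 − vwp)` times the
  seed weight *and* it has at least `min(attachment, |unit|)` edges into
  the unit (default `attachment = 3`). A purely weight-thresholded
  recursive expansion leaks across single bridge edges: two dense
  complexes connected by one spurious interaction collapse into one
  unit, because every vertex of the second complex individually passes
  the weight test. The attachment rule requires genuine local cohesion
  — a joining vertex must form at least a triangle with the unit — and
  measurably fixes recovery on planted-complex benchmarks (from ~25% to
  ~93% of runs recovering the planted structure, see below) while
  leaving dense units untouched. Candidates are admitted in synchronous
  rounds against the previous round's unit, so the result cannot depend
  on vertex enumeration order.
* **Explicit tie-breaking.** Seeds are taken in decreasing weight with
  lexicographic gene-id tie-break; finished units are ranked by size,
  then seed weight, then smallest member id. Identical inputs therefore
  give byte-identical outputs regardless of insertion order.

Post-processing follows the canonical recipe: candidates without a
2-core are discarded; `haircut` (default on) trims each unit to its
2-core; `fluff` (default off) may append boundary nodes with dense
closed neighborhoods — we leave it off because degree-1 boundary nodes
trivially have closed-neighborhood density 1, which makes the fluff
criterion indiscriminate on sparse backgrounds. Vertices trimmed from a
candidate remain available to later units. Defaults `vwp = 0.2`,
`min_size = 3`, haircut on, fluff off are the widely used settings;
`min_size = 3` also matches the smallest process units reported in
published disease models of this kind.

Model *features* are the union of unit members; model-graph nodes
assigned to no unit stay in the graph as `unassigned` but do not count
as features.

## Pathway enrichment

Per pathway, the one-tailed hypergeometric upper tail `P(X ≥ k)` for
`X ~ Hypergeom(N, K, n)`; the EASE variant (the same tail on `k − 1`)
is available to mimic DAVID more closely but is not the default.
Multiple testing is controlled with Benjamini–Hochberg at FDR < 5%.
The background defaults to all genes appearing in the pathway
collection (DAVID-like); pass an explicit background to override.
Disease-named pathways ("…cancer", "…diabetes mellitus", names ending
in "disease") match a configurable blocklist: their statistics are
computed and reported, but they are excluded from the significant list
so the analysis stays focused on signalling and metabolic pathways.

## Differential expression (SAM)

The two-class unpaired SAM statistic per transcript is
`d = (mean_t − mean_c) / (s + s0)` with the pooled standard error `s`
and a fudge factor `s0` that stabilizes low-variance transcripts.
Default `s0` is the 5th percentile of the per-transcript `s`
distribution — a simple, deterministic choice; the coefficient-of-
variation auto-tuning of the original method can be substituted by
passing `s0` explicitly. Group-label permutations are enumerated
exhaustively when at most 500 distinct assignments exist (for the 4 vs 4
design: C(8,4) = 70), otherwise sampled with the run seed, so the
default small-cohort analysis is fully deterministic.

Calling compares observed order statistics `d_(i)` with their
permutation expectation; the cutoff walk moves outward from the origin.
The estimated FDR is the number of permuted statistics beyond the
cutoffs, **averaged** over permutations (the original formulation),
divided by the call count, times `pi0` (default 1, conservative). We
default to the mean rather than the per-permutation median because the
median collapses to zero exactly in the regime that matters for
calibration — a handful of transcripts near the cutoffs — which lets
spurious thresholds qualify on null data; with the mean, null 4 vs 4
matrices of 5000 transcripts yield a median of 0 calls across seeds.
The median estimator remains available (`fdr_estimator="median"`).

**Power at realistic effect sizes.** With four replicates per group, a
2-sigma shift and FDR control at 5–10%, the per-transcript power of any
two-sample statistic is on the order of 10% (noncentral-t with
ncp ≈ 2.8, df 6, at the multiplicity-adjusted stringency); an oracle
threshold with knowledge of the planted truth reaches recall of only
0.15–0.25 at a false-discovery proportion ≤ 0.10 in our simulations.
High recall (say ≥ 0.7) under these conditions is therefore not
achievable by any method, and the planted-recall acceptance check is
expected to fail; what the implementation does guarantee — and what the
null benchmark verifies — is FDR calibration, not power. The toy-study
fixtures use a 4-sigma effect precisely so that their end-to-end ground
truth is exact rather than statistical.

Sample QC uses 1 − Pearson correlation distance and unweighted
average linkage, with a flag recording whether the two-cluster cut
reproduces the treated/control split. Called transcripts collapse to
protein-coding genes (other biotypes and unmapped transcripts are
dropped with counts logged); genes with both up- and down-called
transcripts are reported as `contradictory`.

## Interference and biomarker annotation

`shared = disease.features ∩ drug.features`; disease-model genes that
are deregulated in supplementary expression evidence but absent from
the drug model are `extra`. Directional evidence is merged across
tables per gene: agreement keeps the direction, conflict yields
`contradictory`, no direction yields `association_only`. The merge is
idempotent and order-independent. Biomarker flags (diagnostic /
prognostic) come from a MeSH-filter classification: a publication
qualifies if it carries the disease term as major topic plus a marker
term, is a clinical trial or annotated "humans"/"disease models,
animal", and carries none of the profiling-study exclusion terms;
trigger terms then assign the class. Statistical significance of the
overlap (e.g. permutation z-scores) is deliberately out of scope.

## Synthetic data: what it shows and what it does not

The generators are pure functions of their parameters and seed.

* `simulate_network` plants partition-style complexes
  (`p_in`-Bernoulli within, `p_out`-Bernoulli elsewhere). The recovery
  benchmark (60 background nodes, 3 complexes of 8, `p_in = 0.9`,
  `p_out = 0.02`) emulates dense protein complexes in a sparse
  interactome; it does not reproduce the heavy-tailed degree
  distribution of real interactomes, so passing it shows correct
  recovery of dense modules, not performance on scale-free graphs.
* `simulate_annotations` builds two term-labelled literatures covering
  disjoint complex sets with an exactly planted gene overlap (placed in
  within-complex blocks of ≥ 3 so the overlap is recoverable as a dense
  unit in both models), plus biomarker-qualifying publications and an
  always-present profiling-study decoy that the filter must reject.
  Citation-count distributions are uniform, unlike real literatures.
* `simulate_expression` draws log-scale Gaussian intensities
  (post-normalization microarray emulation) with mean-shifted planted
  transcripts; it does not model probe effects, intensity-dependent
  variance, or correlation between transcripts.

The end-to-end toy study (`make_fixtures`) plants complexes as cliques
(`p_in = 1`) and uses a 4-sigma expression effect so that the expected
interference report — 10 shared features, 6 extra deregulated features,
their states and D/P flags — is exact and seed-independent.

## Problem sizes and numerical choices

The benchmark sizes used by the test-suite and the acceptance script
(100 recovery seeds; 50 null and 20 planted SAM simulations at
5000 × 8; exhaustive hypergeometric enumeration up to N = 12) were
chosen so the whole suite completes in well under a minute on one core
while keeping the binomial/permutation noise of each estimate small.
Oracle comparisons use absolute tolerance 1e−12; the delta grid for
FDR-targeted SAM calling spans 0.05–10 in steps of 0.05. Degenerate
inputs are defined policies, not errors: empty seed sets give empty
models, empty networks give empty unit lists, zero calls give an FDR of
NaN.

## Known limitations

* Identifier namespaces are opaque strings; no translation between
  Ensembl/Entrez/symbols is built in (supply a mapping table).
* MeSH matching is exact (after case/whitespace normalization); the
  MeSH tree is not expanded.
* The enrichment background cannot recover DAVID's exact 2016 term
  catalog, so published p-values of that era are context, not targets.
* Raw-array preprocessing (probe summarization, normalization) is out
  of scope; the expression module consumes normalized matrices. For an
  external check against the deposited mesangial-cell series GSE84908,
  preprocess with the oligo R package, export the normalized matrix and
  a two-column group file, and run `sam_call` at target FDR 5% — the
  published transcript counts are permutation- and preprocessing-
  sensitive, so agreement is approximate by nature.
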