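"""Two-class SAM analysis on a simulated 4 vs 4 expression matrix.

Thirty transcripts of 2000 carry a strong (4 sigma) treatment shift.
SAM picks the calling threshold delta so the permutation-estimated FDR
stays below 5%, then the called transcripts collapse to protein-coding
genes with an up/down/contradictory direction.
"""

from netmoa import cluster_samples, collapse_to_genes, sam_call, simulate_expression

matrix, tmap, truth = simulate_expression(
    n_transcripts=2000, n_per_group=4, n_de=30, effect=4.0, sigma=1.0,
    transcripts_per_gene=2, rng_seed=4,
)

dendro = cluster_samples(matrix)
print(f"samples separate into treated/control branches: {dendro.groups_separate}")

result = sam_call(matrix, target_fdr=0.05, rng_seed=4)
called = set(result.called.index)
planted = set(truth.de_transcripts)
print(
    f"delta={result.delta:.2f} s0={result.s0:.3f} "
    f"called={result.n_called} est_fdr={result.est_fdr:.3f}"
)
print(f"planted recovered: {len(called & planted)}/{len(planted)}, "
      f"false calls: {len(called - planted)}")

genes = collapse_to_genes(result, tmap)
print(f"gene-level calls: {len(genes)} "
      f"({(genes['direction'] == 'up').sum()} up, "
      f"{(genes['direction'] == 'down').sum()} down)")
# With a 4-sigma shift nearly every planted transcript is recovered at
# an estimated FDR below 5%; at realistic 1-2 sigma effects and four
# replicates per group, power is necessarily much lower.
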