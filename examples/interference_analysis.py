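"""Full disease-vs-drug interference analysis on the synthetic toy study.

make_fixtures writes an internally consistent study (network,
literature tables, pathway sets, expression matrix) in which 10 genes
are planted in both the disease and the drug literature and 6 further
disease-model genes are deregulated in the expression experiment.  The
pipeline must recover exactly those counts, with regulation states and
diagnostic/prognostic biomarker flags.
"""

import tempfile
from pathlib import Path

from netmoa import PipelineConfig, make_fixtures, run_pipeline

with tempfile.TemporaryDirectory() as tmp:
    paths, truth = make_fixtures(tmp, rng_seed=7, n_overlap=10, n_extra=6)
    report = run_pipeline(PipelineConfig.from_yaml(paths["config"]))

    print(f"planted overlap:   {len(truth.seed_overlap)}")
    print(f"shared features:   {len(report.shared)}")
    print(f"extra deregulated: {len(report.extra)}")
    states = {}
    for call in report.calls.values():
        states[call.state] = states.get(call.state, 0) + 1
    print(f"regulation states: {states}")
    for gene, classes in sorted(report.biomarkers.items()):
        print(f"biomarker {gene}: {'/'.join(sorted(classes))}")
    print(f"artifacts under:   {Path(tmp) / 'results'}")
# 'shared' must equal the planted overlap exactly; the extra features
# are the deregulated disease-model genes absent from the drug model,
# coloured up/down/contradictory in the exported interference network.
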