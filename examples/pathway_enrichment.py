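"""Pathway over-representation of a model feature set.

Ten of the 40 feature genes fall in a 25-gene pathway within a
500-gene background — a strong enrichment — while a disease-named
pathway is blocklisted and reported but never called significant.
"""

from netmoa import PathwayCollection, enrich_model

background = {f"G{i:03d}" for i in range(500)}
pathways = {
    "Cytokine signaling": {f"G{i:03d}" for i in range(25)},
    "Membrane transport": {f"G{i:03d}" for i in range(200, 260)},
    "Pathways in cancer": {f"G{i:03d}" for i in range(5, 45)},
}
collection = PathwayCollection.from_dict(pathways, background)
features = {f"G{i:03d}" for i in range(10)} | {f"G{i:03d}" for i in range(300, 330)}

for r in enrich_model(features, collection, fdr_threshold=0.05):
    flag = "EXCLUDED" if r.excluded else ("significant" if r.significant else "")
    print(
        f"{r.pathway:22s} k={r.k:2d}/K={r.K:3d} n={r.n} N={r.N} "
        f"p={r.p:.3g} fdr={r.fdr:.3g} {flag}"
    )
# 'Cytokine signaling' has 10 of its 25 genes among the 40 features
# (p ~ 5e-6): significant.  'Pathways in cancer' overlaps too, but the
# blocklist keeps disease-named pathways out of the significant list.
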