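"""Seed extraction and biomarker classification from literature tables."""

import random

import pandas as pd
import pytest

from netmoa.literature import (
    BiomarkerFilterConfig,
    Gene2PubmedTable,
    MeshAnnotationTable,
    classify_biomarkers,
    extract_seed_genes,
    match_gene_mentions,
)


def g2p_table(rows):
    return Gene2PubmedTable(
        pd.DataFrame(rows, columns=["tax_id", "gene_id", "pubmed_id"])
    )


def mesh_table(rows):
    return MeshAnnotationTable(
        pd.DataFrame(rows, columns=["pubmed_id", "mesh_term", "major_topic", "pub_type"])
    )


class TestExtractSeedGenes:
    def test_direct_join(self):
        g2p = g2p_table([(9606, "G1", 1), (9606, "G2", 1), (9606, "G3", 2)])
        mesh = mesh_table([(1, "nephropathy", True, ""), (2, "other", False, "")])
        seeds = extract_seed_genes(g2p, mesh, "nephropathy")
        assert seeds.genes == {"G1", "G2"}
        assert seeds.provenance == {"G1": 1, "G2": 1}

    def test_major_only_excludes_minor_annotations(self):
        g2p = g2p_table([(9606, "G1", 1)])
        mesh = mesh_table([(1, "nephropathy", False, "")])
        assert extract_seed_genes(g2p, mesh, "nephropathy", major_only=True).genes == frozenset()
        assert extract_seed_genes(g2p, mesh, "nephropathy").genes == {"G1"}

    def test_absent_term_warns_and_empties(self, caplog):
        g2p = g2p_table([(9606, "G1", 1)])
        mesh = mesh_table([(1, "x", True, "")])
        with caplog.at_level("WARNING"):
            seeds = extract_seed_genes(g2p, mesh, "missing term")
        assert seeds.genes == frozenset()
        assert "matches no publication" in caplog.text

    def test_randomized_tables_match_brute_force_join(self):
        rng = random.Random(17)
        g2p_rows = [
            (9606, f"G{rng.randint(1, 30)}", rng.randint(1, 40)) for _ in range(200)
        ]
        mesh_rows = [
            (rng.randint(1, 40), rng.choice(["a term", "b term"]), rng.random() < 0.5, "")
            for _ in range(200)
        ]
        seeds = extract_seed_genes(
            g2p_table(g2p_rows), mesh_table(mesh_rows), "a term", major_only=True
        )
        # oracle: row-by-row nested scan
        pubs = {p for p, t, m, _ in mesh_rows if t == "a term" and m}
        expected = {g for _, g, p in g2p_rows if p in pubs}
        assert seeds.genes == expected

    def test_monotone_under_row_addition(self):
        g2p_rows = [(9606, "G1", 1)]
        mesh_rows = [(1, "term", True, "")]
        base = extract_seed_genes(g2p_table(g2p_rows), mesh_table(mesh_rows), "term")
        more = extract_seed_genes(
            g2p_table(g2p_rows + [(9606, "G2", 2)]),
            mesh_table(mesh_rows + [(2, "term", True, "")]),
            "term",
        )
        assert base.genes <= more.genes

    def test_term_matching_normalizes_whitespace_and_case(self):
        g2p = g2p_table([(9606, "G1", 1)])
        mesh = mesh_table([(1, "Diabetic  Nephropathies", True, "")])
        assert extract_seed_genes(g2p, mesh, "diabetic nephropathies").genes == {"G1"}


def marker_pub(pub, disease="dn", extra=()):
    rows = [
        (pub, disease, True, ""),
        (pub, "biological markers", False, ""),
        (pub, "humans", False, ""),
    ]
    rows += [(pub, term, False, "") for term in extra]
    return rows


class TestClassifyBiomarkers:
    config = BiomarkerFilterConfig.for_disease("dn")

    def test_prognostic_rule_application(self):
        g2p = g2p_table([(9606, "G1", 1)])
        mesh = mesh_table(marker_pub(1, extra=["prognosis"]))
        (ev,) = classify_biomarkers(g2p, mesh, self.config)
        assert ev.gene_id == "G1"
        assert ev.classes == {"prognostic"}
        assert ev.publications["prognostic"] == {1}

    def test_profiling_study_excluded(self):
        g2p = g2p_table([(9606, "G1", 1)])
        mesh = mesh_table(marker_pub(1, extra=["prognosis", "proteomics"]))
        assert classify_biomarkers(g2p, mesh, self.config) == []

    def test_early_diagnosis_triggers_diagnostic(self):
        g2p = g2p_table([(9606, "G1", 1)])
        mesh = mesh_table(marker_pub(1, extra=["early diagnosis"]))
        (ev,) = classify_biomarkers(g2p, mesh, self.config)
        assert ev.classes == {"diagnostic"}

    def test_both_classes_on_one_gene(self):
        g2p = g2p_table([(9606, "G1", 1), (9606, "G1", 2)])
        mesh = mesh_table(
            marker_pub(1, extra=["prognosis"]) + marker_pub(2, extra=["diagnosis"])
        )
        (ev,) = classify_biomarkers(g2p, mesh, self.config)
        assert ev.classes == {"diagnostic", "prognostic"}

    def test_admission_requires_study_type(self):
        g2p = g2p_table([(9606, "G1", 1)])
        rows = [
            (1, "dn", True, ""),
            (1, "biological markers", False, ""),
            (1, "prognosis", False, ""),
        ]  # neither clinical trial nor humans nor animal model
        assert classify_biomarkers(g2p, mesh_table(rows), self.config) == []
        rows_ct = [r[:3] + ("clinical trial",) for r in rows[:1]] + rows[1:]
        (ev,) = classify_biomarkers(g2p, mesh_table(rows_ct), self.config)
        assert ev.classes == {"prognostic"}

    def test_disease_term_must_be_major(self):
        g2p = g2p_table([(9606, "G1", 1)])
        rows = [
            (1, "dn", False, ""),
            (1, "biological markers", False, ""),
            (1, "humans", False, ""),
            (1, "prognosis", False, ""),
        ]
        assert classify_biomarkers(g2p, mesh_table(rows), self.config) == []

    def test_row_order_independence(self):
        g2p_rows = [(9606, "G1", 1), (9606, "G2", 1), (9606, "G2", 2)]
        mesh_rows = marker_pub(1, extra=["prognosis"]) + marker_pub(
            2, extra=["diagnosis"]
        )
        fwd = classify_biomarkers(
            g2p_table(g2p_rows), mesh_table(mesh_rows), self.config
        )
        rev = classify_biomarkers(
            g2p_table(g2p_rows[::-1]), mesh_table(mesh_rows[::-1]), self.config
        )
        assert [(e.gene_id, e.classes) for e in fwd] == [
            (e.gene_id, e.classes) for e in rev
        ]

    def test_every_evidence_record_cites_a_publication(self):
        g2p = g2p_table([(9606, "G1", 1)])
        mesh = mesh_table(marker_pub(1, extra=["prognosis", "diagnosis"]))
        for ev in classify_biomarkers(g2p, mesh, self.config):
            assert all(len(pubs) >= 1 for pubs in ev.publications.values())

    def test_mentions_supplement_links(self):
        g2p = g2p_table([(9606, "G1", 99)])  # no link to the marker pub
        mesh = mesh_table(marker_pub(1, extra=["prognosis"]))
        mentions = pd.DataFrame({"pubmed_id": [1], "gene_id": ["G2"]})
        evs = classify_biomarkers(g2p, mesh, self.config, mentions=mentions)
        assert [e.gene_id for e in evs] == ["G2"]


class TestFilterConfig:
    def test_missing_list_rejected(self):
        with pytest.raises(ValueError, match="marker_terms"):
            BiomarkerFilterConfig(
                disease_major_term="dn",
                marker_terms=(),
                exclusion_terms=("x",),
                admission_pub_types=("clinical trial",),
                admission_terms=("humans",),
                prognostic_triggers=("prognosis",),
                diagnostic_triggers=("diagnosis",),
            )

    def test_yaml_round_trip(self, tmp_path):
        cfg = BiomarkerFilterConfig.for_disease("diabetic nephropathies")
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        assert BiomarkerFilterConfig.from_yaml(path) == cfg

    def test_yaml_missing_key_errors(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("disease_major_term: dn\n")
        with pytest.raises(ValueError, match="missing key"):
            BiomarkerFilterConfig.from_yaml(path)


def test_match_gene_mentions_exact_tokens_case_sensitive():
    texts = pd.DataFrame(
        {
            "pubmed_id": [1, 2, 3],
            "text": ["TNF levels rose", "tnf levels rose", "TNFSF11 unrelated"],
        }
    )
    hits = match_gene_mentions(texts, {"TNF": "ENSG_TNF"})
    assert hits.to_dict("records") == [{"pubmed_id": 1, "gene_id": "ENSG_TNF"}]
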