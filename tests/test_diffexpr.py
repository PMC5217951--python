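"""SAM statistic, permutation calling, QC clustering, gene collapse."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netmoa.diffexpr import (
    ExpressionMatrix,
    TranscriptGeneMap,
    cluster_samples,
    collapse_to_genes,
    distance_matrix,
    sam_call,
    sam_statistic,
)
from netmoa.synthetic import simulate_expression

finite_group = st.lists(
    st.floats(min_value=-50, max_value=50), min_size=2, max_size=6
)


def matrix_from(values, n_treated):
    values = np.asarray(values, dtype=float)
    cols = [f"t{i}" for i in range(n_treated)] + [
        f"c{i}" for i in range(values.shape[1] - n_treated)
    ]
    groups = {c: ("treated" if c.startswith("t") else "control") for c in cols}
    df = pd.DataFrame(values, columns=cols,
                      index=[f"T{i}" for i in range(values.shape[0])])
    return ExpressionMatrix(values=df, groups=groups)


class TestSamStatistic:
    def test_identical_groups_give_zero(self):
        assert sam_statistic([1, 2, 3], [1, 2, 3], s0=0.5) == 0.0

    def test_hand_computed_example(self):
        d = sam_statistic([1, 2, 3], [4, 5, 6], s0=0.0)
        assert d == pytest.approx(3.0 / math.sqrt(2 / 3))
        assert d == pytest.approx(3.6742, abs=1e-4)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(finite_group, finite_group)
    def test_label_swap_antisymmetry(self, a, b):
        try:
            d1 = sam_statistic(a, b, s0=0.1)
            d2 = sam_statistic(b, a, s0=0.1)
        except ZeroDivisionError:
            return
        assert d1 == pytest.approx(-d2, abs=1e-9)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(finite_group, finite_group, st.floats(min_value=-20, max_value=20))
    def test_location_invariance(self, a, b, shift):
        try:
            base = sam_statistic(a, b, s0=0.1)
        except ZeroDivisionError:
            return
        shifted = sam_statistic([x + shift for x in a], [x + shift for x in b], s0=0.1)
        assert shifted == pytest.approx(base, rel=1e-6, abs=1e-7)

    def test_scale_inverse_with_s0_zero(self):
        a, b, c = [1.0, 2.0, 4.0], [5.0, 7.0, 8.0], 3.0
        base = sam_statistic(a, b, s0=0.0)
        scaled = sam_statistic([x * c for x in a], [x * c for x in b], s0=0.0)
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_zero_variance_zero_s0_signals_degenerate(self):
        with pytest.raises(ZeroDivisionError):
            sam_statistic([1, 1, 1], [2, 2, 2], s0=0.0)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            sam_statistic([1], [2, 3], s0=0.1)


class TestSamCall:
    def test_null_matrix_large_delta_zero_calls(self):
        rng = np.random.default_rng(0)
        m = matrix_from(rng.normal(size=(300, 8)), 4)
        r = sam_call(m, delta=50.0, rng_seed=0)
        assert r.n_called == 0
        assert math.isnan(r.est_fdr)

    def test_deterministic_for_fixed_seed(self):
        m, _, _ = simulate_expression(400, 4, 20, 2.0, 1.0, rng_seed=11)
        r1 = sam_call(m, target_fdr=0.05, rng_seed=5)
        r2 = sam_call(m, target_fdr=0.05, rng_seed=5)
        pd.testing.assert_frame_equal(r1.table, r2.table)
        assert (r1.delta, r1.s0, r1.n_called) == (r2.delta, r2.s0, r2.n_called)

    def test_strong_effects_are_called_with_direction(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(500, 8)) * 0.3
        X[:5, :4] += 6.0   # strong up in treated
        X[5:10, :4] -= 6.0  # strong down
        r = sam_call(matrix_from(X, 4), target_fdr=0.05, rng_seed=1)
        called = r.called
        assert set(called.index[:0].tolist()) == set()
        up = {f"T{i}" for i in range(5)}
        down = {f"T{i}" for i in range(5, 10)}
        assert up <= set(called[called["direction"] == "up"].index)
        assert down <= set(called[called["direction"] == "down"].index)
        assert r.est_fdr < 0.05

    def test_requires_exactly_one_threshold_argument(self):
        m, _, _ = simulate_expression(50, 2, 0, 1.0, 1.0, rng_seed=0)
        with pytest.raises(ValueError):
            sam_call(m)
        with pytest.raises(ValueError):
            sam_call(m, delta=1.0, target_fdr=0.05)

    def test_degenerate_transcripts_excluded_and_reported(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 8))
        X[7] = 1.0
        X[7, :4] = 5.0  # constant within each group
        m = matrix_from(X, 4)
        r = sam_call(m, delta=0.5, rng_seed=0, s0=0.0)
        assert "T7" in r.degenerate
        assert not r.table.loc["T7", "called"]

    def test_full_enumeration_ignores_seed(self):
        m, _, _ = simulate_expression(200, 4, 10, 3.0, 1.0, rng_seed=4)
        r1 = sam_call(m, target_fdr=0.05, rng_seed=1)
        r2 = sam_call(m, target_fdr=0.05, rng_seed=999)
        assert r1.n_perm == 70  # C(8,4) balanced assignments
        pd.testing.assert_frame_equal(r1.table, r2.table)


def upgma_oracle(dist, labels):
    """Brute-force average linkage: merge heights, recomputed from the
    full original distance matrix at every step (mean over all cross
    pairs — the unweighted average-linkage definition)."""
    idx = {l: i for i, l in enumerate(labels)}

    def cdist(a, b):
        return sum(dist[idx[x]][idx[y]] for x in a for y in b) / (len(a) * len(b))

    clusters = [frozenset([l]) for l in labels]
    heights = []
    while len(clusters) > 1:
        pairs = [
            (a, b) for i, a in enumerate(clusters) for b in clusters[i + 1 :]
        ]
        a, b = min(pairs, key=lambda ab: cdist(*ab))
        heights.append(cdist(a, b))
        clusters = [c for c in clusters if c not in (a, b)] + [a | b]
    return heights


class TestClusterSamples:
    def test_duplicated_sample_merges_first_at_zero(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(100, 4))
        X[:, 1] = X[:, 0]
        m = matrix_from(X, 2)
        dend = cluster_samples(m)
        assert dend.merge[0, 2] == pytest.approx(0.0, abs=1e-12)
        first = {int(dend.merge[0, 0]), int(dend.merge[0, 1])}
        assert first == {0, 1}

    def test_negated_sample_at_distance_two(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(50, 4))
        X[:, 3] = -X[:, 2]
        dm = distance_matrix(matrix_from(X, 2))
        assert dm.iloc[2, 3] == pytest.approx(2.0)

    def test_distance_matrix_symmetric_zero_diagonal(self):
        m, _, _ = simulate_expression(100, 3, 0, 1.0, 1.0, rng_seed=5)
        dm = distance_matrix(m).to_numpy()
        assert np.allclose(dm, dm.T)
        assert np.allclose(np.diag(dm), 0.0)

    def test_merge_heights_match_upgma_oracle(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(80, 6))
        m = matrix_from(X, 3)
        dm = distance_matrix(m).to_numpy().tolist()
        expected = upgma_oracle(dm, list(m.values.columns))
        dend = cluster_samples(m)
        assert dend.merge[:, 2] == pytest.approx(expected, abs=1e-10)

    def test_separating_groups_sets_flag(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(200, 8)) * 0.1
        X[:50, :4] += 3.0  # strong group signature
        dend = cluster_samples(matrix_from(X, 4))
        assert dend.groups_separate

    def test_zero_variance_sample_named_in_error(self):
        X = np.random.default_rng(8).normal(size=(30, 4))
        X[:, 1] = 2.5
        with pytest.raises(ValueError, match="t1"):
            cluster_samples(matrix_from(X, 2))

    def test_newick_has_all_samples(self):
        m, _, _ = simulate_expression(60, 3, 0, 1.0, 1.0, rng_seed=9)
        nwk = cluster_samples(m).to_newick()
        assert nwk.endswith(";")
        for s in m.values.columns:
            assert s in nwk


class TestCollapseToGenes:
    def make_result(self, directions):
        table = pd.DataFrame(
            {
                "d": [2.0 if d == "up" else -2.0 for d in directions.values()],
                "called": True,
                "direction": list(directions.values()),
            },
            index=list(directions),
        )
        from netmoa.diffexpr import SamResult

        return SamResult(
            table=table, delta=1.0, s0=0.1, est_fdr=0.0,
            n_called=len(table), cut_up=1.0, cut_low=-1.0, n_perm=70,
        )

    def map_for(self, rows):
        return TranscriptGeneMap(
            pd.DataFrame(rows, columns=["transcript_id", "gene_id", "biotype"])
        )

    def test_two_up_transcripts_one_up_gene(self):
        r = self.make_result({"T1": "up", "T2": "up"})
        tmap = self.map_for(
            [("T1", "G1", "protein_coding"), ("T2", "G1", "protein_coding")]
        )
        out = collapse_to_genes(r, tmap)
        assert out.to_dict("records") == [
            {"gene_id": "G1", "direction": "up", "n_transcripts": 2}
        ]

    def test_opposite_transcripts_contradictory(self):
        r = self.make_result({"T1": "up", "T2": "down"})
        tmap = self.map_for(
            [("T1", "G1", "protein_coding"), ("T2", "G1", "protein_coding")]
        )
        out = collapse_to_genes(r, tmap)
        assert list(out["direction"]) == ["contradictory"]

    def test_noncoding_and_unmapped_excluded(self):
        directions = {f"T{i}": "up" for i in range(10)}
        r = self.make_result(directions)
        rows = [(f"T{i}", f"G{i}", "protein_coding") for i in range(7)]
        rows += [(f"T{i}", f"G{i}", "lincRNA") for i in range(7, 9)]
        # T9 left unmapped
        out = collapse_to_genes(r, self.map_for(rows))
        assert len(out) == 7
        assert set(out["gene_id"]) == {f"G{i}" for i in range(7)}


class TestExpressionMatrix:
    def test_missing_group_label_rejected(self):
        df = pd.DataFrame(np.zeros((3, 4)), columns=list("abcd"))
        with pytest.raises(ValueError):
            ExpressionMatrix(values=df, groups={"a": "treated", "b": "control"})

    def test_single_sample_group_rejected(self):
        df = pd.DataFrame(np.zeros((3, 3)), columns=list("abc"))
        groups = {"a": "treated", "b": "control", "c": "control"}
        with pytest.raises(ValueError):
            ExpressionMatrix(values=df, groups=groups)

    def test_tsv_round_trip(self, tmp_path):
        m, _, _ = simulate_expression(20, 2, 0, 1.0, 1.0, rng_seed=1)
        mp, gp = tmp_path / "m.tsv", tmp_path / "g.tsv"
        m.values.to_csv(mp, sep="\t")
        gp.write_text(
            "".join(f"{s}\t{m.groups[s]}\n" for s in m.values.columns)
        )
        back = ExpressionMatrix.from_tsv(mp, gp)
        assert back.groups == m.groups
        assert np.allclose(back.values.to_numpy(), m.values.to_numpy())
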