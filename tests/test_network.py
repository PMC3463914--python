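"""Pearson correlation, neighbour ranking, edge selection, graph stats."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import leafcoex as lx
from leafcoex.errors import DimensionError, DuplicateGeneError, ParameterError
from oracle import brute_network

ZONES4 = ["basal", "transitional", "maturing", "mature"]


def _frame(rows, ids=None):
    ids = ids or [f"G{i}" for i in range(len(rows))]
    return pd.DataFrame(np.asarray(rows, dtype=float), index=ids,
                        columns=ZONES4[: len(rows[0])] if len(rows[0]) <= 4
                        else [f"z{i}" for i in range(len(rows[0]))])


class TestPearson:
    def test_perfect_linear_relation(self):
        assert lx.pearson_cc([1, 2, 3, 4], [2, 4, 6, 8]) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        assert lx.pearson_cc([1, 2, 3, 4], [4, 3, 2, 1]) == pytest.approx(-1.0)

    def test_table1_tip12_vs_nip11(self, table1):
        # frozen from an exact-rational evaluation of the product-moment
        # formula on the printed RPKM values
        cc = lx.pearson_cc(
            table1.row("GRMZM2G168439"), table1.row("GRMZM2G041980")
        )
        assert cc == pytest.approx(0.9790861430511805, abs=1e-12)
        assert cc > 0.95

    def test_zero_variance_is_undefined_not_zero(self):
        assert math.isnan(lx.pearson_cc([5, 5, 5, 5], [1, 2, 3, 4]))

    def test_shape_errors(self):
        with pytest.raises(DimensionError):
            lx.pearson_cc([1, 2, 3], [1, 2])
        with pytest.raises(DimensionError):
            lx.pearson_cc([1], [2])

    @given(
        st.lists(st.floats(0, 1000), min_size=4, max_size=4),
        st.floats(min_value=0.01, max_value=100),
        st.floats(min_value=-50, max_value=50),
    )
    def test_invariant_under_positive_affine_maps(self, xs, scale, shift):
        ys = [1.0, 7.0, 3.0, 9.0]
        base = lx.pearson_cc(xs, ys)
        mapped = lx.pearson_cc([scale * v + shift for v in xs], ys)
        if math.isnan(base):
            assert math.isnan(mapped)
        else:
            assert mapped == pytest.approx(base, abs=1e-9)


class TestCorrelationMatrix:
    def test_symmetric_unit_diagonal_with_undefined_rows(self):
        df = _frame([[1, 2, 3, 4], [2, 4, 6, 8], [5, 5, 5, 5]])
        cc = lx.correlation_matrix(df)
        assert cc.loc["G0", "G1"] == pytest.approx(1.0)
        assert cc.loc["G0", "G0"] == 1.0
        assert cc.to_numpy()[np.isfinite(cc.to_numpy())].max() <= 1.0
        assert np.isnan(cc.loc["G2"]).all() and np.isnan(cc["G2"]).all()
        arr = cc.to_numpy()
        assert ((arr == arr.T) | (np.isnan(arr) & np.isnan(arr.T))).all()


class TestRankNeighbors:
    def test_descending_order_and_one_based_ranks(self):
        # cc(A,B) > cc(A,C) by construction
        df = _frame([[1, 2, 3, 4], [1.1, 2, 3, 4.2], [4, 1, 3, 2]],
                    ids=["A", "B", "C"])
        ranks = lx.rank_neighbors(lx.correlation_matrix(df))
        assert ranks.loc["A", "B"] == 1
        assert ranks.loc["A", "C"] == 2

    def test_gene_undefined_against_everything_has_empty_list(self):
        df = _frame([[5, 5, 5, 5], [1, 2, 3, 4], [2, 4, 6, 8]])
        ranks = lx.rank_neighbors(lx.correlation_matrix(df))
        assert np.isnan(ranks.loc["G0"]).all()
        # defined genes exclude the undefined one from their lists
        assert ranks.loc["G1", "G2"] == 1
        assert np.isnan(ranks.loc["G1", "G0"])

    def test_exact_ties_order_by_gene_id(self):
        # B and C are identical profiles, both cc=1 with A
        df = _frame([[1, 2, 3, 4], [2, 4, 6, 8], [2, 4, 6, 8]],
                    ids=["A", "C", "B"])
        ranks = lx.rank_neighbors(lx.correlation_matrix(df))
        assert ranks.loc["A", "B"] == 1
        assert ranks.loc["A", "C"] == 2


class TestBuildNetwork:
    def test_two_identical_pairs_give_exactly_their_edges(self):
        df = _frame(
            [[1, 2, 3, 4], [2, 4, 6, 8], [4, 3, 2, 1], [8, 6, 4, 2]],
            ids=["A", "B", "C", "D"],
        )
        g = lx.build_network(df)
        assert sorted(map(tuple, map(sorted, g.edges))) == [("A", "B"), ("C", "D")]

    def test_max_rank_zero_gives_empty_edge_set(self):
        df = _frame([[1, 2, 3, 4], [2, 4, 6, 8]])
        assert lx.build_network(df, max_rank=0).number_of_edges() == 0

    def test_table1_contains_tip12_nip11_edge(self, collapsed):
        g = lx.build_network(collapsed)
        assert g.number_of_nodes() == 23
        assert g.has_edge("GRMZM2G168439", "GRMZM2G041980")
        d = g.edges["GRMZM2G168439", "GRMZM2G041980"]
        assert d["cc"] > 0.95

    def test_undefined_profiles_never_gain_edges(self):
        df = _frame([[5, 5, 5, 5], [7, 7, 7, 7], [1, 2, 3, 4]])
        g = lx.build_network(df, min_cc=-1.0)
        assert g.degree("G0") == 0 and g.degree("G1") == 0

    def test_duplicate_ids_are_rejected(self):
        df = _frame([[1, 2, 3, 4], [1, 2, 3, 4]], ids=["A", "A"])
        with pytest.raises(DuplicateGeneError):
            lx.build_network(df)

    def test_parameter_validation(self):
        with pytest.raises(ParameterError):
            lx.NetworkParams(min_cc=1.5)
        with pytest.raises(ParameterError):
            lx.NetworkParams(rank_mode="sideways")


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 13))
        zones = int(rng.integers(4, 7))
        arr = 2.0 ** rng.normal(4, 2, (n, zones))
        min_cc = float(rng.uniform(-0.5, 0.99))
        max_rank = int(rng.integers(0, n + 2))
        mode = ["either_direction", "both_directions"][int(rng.integers(0, 2))]
        ids = [f"G{i}" for i in range(n)]
        df = pd.DataFrame(arr, index=ids, columns=[f"z{j}" for j in range(zones)])
        g = lx.build_network(df, min_cc=min_cc, max_rank=max_rank, rank_mode=mode)
        got = {tuple(sorted(e)) for e in g.edges}
        want = brute_network(
            {i: list(a) for i, a in zip(ids, arr)}, min_cc, max_rank, mode
        )
        assert got == want


class TestNetworkProperties:
    def _random_frame(self, seed, n=8):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            2.0 ** rng.normal(3, 1.5, (n, 4)),
            index=[f"G{i}" for i in range(n)],
            columns=ZONES4,
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_relabeling_genes_gives_isomorphic_network(self, seed):
        df = self._random_frame(seed)
        g1 = lx.build_network(df, min_cc=0.5)
        relabel = {f"G{i}": f"H{7 - i}" for i in range(8)}
        df2 = df.rename(index=relabel)
        g2 = lx.build_network(df2, min_cc=0.5)
        assert {tuple(sorted((relabel[u], relabel[v]))) for u, v in g1.edges} == {
            tuple(sorted(e)) for e in g2.edges
        }

    @pytest.mark.parametrize("seed", range(5))
    def test_edges_monotone_in_min_cc_and_max_rank(self, seed):
        df = self._random_frame(seed, n=10)
        loose = {tuple(sorted(e))
                 for e in lx.build_network(df, min_cc=0.3, max_rank=9).edges}
        tighter_cc = {tuple(sorted(e))
                      for e in lx.build_network(df, min_cc=0.8, max_rank=9).edges}
        tighter_rank = {tuple(sorted(e))
                        for e in lx.build_network(df, min_cc=0.3, max_rank=2).edges}
        assert tighter_cc <= loose
        assert tighter_rank <= loose

    @pytest.mark.parametrize("seed", range(5))
    def test_positive_scale_and_shift_leave_network_unchanged(self, seed):
        df = self._random_frame(seed)
        rng = np.random.default_rng(seed + 100)
        scaled = df * rng.uniform(0.1, 10, (len(df), 1)) + rng.uniform(
            0, 5, (len(df), 1)
        )
        g1 = lx.build_network(df, min_cc=0.5)
        g2 = lx.build_network(scaled, min_cc=0.5)
        assert {tuple(sorted(e)) for e in g1.edges} == {
            tuple(sorted(e)) for e in g2.edges
        }


class TestGraphStats:
    def test_empty_network_reports_zeros(self):
        stats = lx.graph_stats(nx.Graph())
        assert stats["n_nodes"] == 0 and stats["n_edges"] == 0
        assert stats["mean_clustering"] == 0.0 and stats["components"] == []

    def test_triangle(self):
        stats = lx.graph_stats(nx.complete_graph(3))
        assert stats["mean_clustering"] == pytest.approx(1.0)
        assert stats["components"][0]["diameter"] == 1

    def test_path_graph(self):
        stats = lx.graph_stats(nx.path_graph(3))
        assert stats["mean_clustering"] == pytest.approx(0.0)
        assert stats["components"][0]["diameter"] == 2
        assert stats["components"][0]["mean_path_length"] == pytest.approx(4 / 3)

    def test_singletons_reported_separately(self):
        g = nx.Graph()
        g.add_edge("A", "B")
        g.add_node("C")
        stats = lx.graph_stats(g)
        assert stats["n_components"] == 1 and stats["n_singletons"] == 1


class TestExports:
    def test_sif_graphml_edgelist(self, tmp_path, collapsed):
        g = lx.build_network(collapsed)
        sif = tmp_path / "net.sif"
        lx.network.write_sif(g, sif)
        lines = sif.read_text().splitlines()
        edge_lines = [ln for ln in lines if "\t" in ln]
        assert len(edge_lines) == g.number_of_edges()
        a, cc, b = edge_lines[0].split("\t")
        assert float(cc) > 0.95 and len(cc.split(".")[1]) == 4

        gml = tmp_path / "net.graphml"
        lx.network.write_graphml(g, gml)
        back = nx.read_graphml(gml)
        assert back.number_of_edges() == g.number_of_edges()

        el = tmp_path / "net.edges.tsv"
        lx.network.write_edgelist(g, el)
        header = el.read_text().splitlines()[0].split("\t")
        assert header == ["source", "target", "cc", "rank_ab", "rank_ba"]
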