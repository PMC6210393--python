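"""t statistics, top-N selection, network reconstruction, real vectors."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import omnirank as o
from omnirank.errors import DataError, EmptyNetworkError
from omnirank.netbuild import (
    build_quartet,
    build_real_vectors,
    pooled_t_stat,
    reconstruct_network,
    select_top_genes,
)
from omnirank.omics import OmicsLayer, zscore_normalize


def _layer(matrix, tag="mRNA", genes=None, samples=None):
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    genes = genes or [f"g{i}" for i in range(matrix.shape[0])]
    samples = samples or [f"s{j}" for j in range(matrix.shape[1])]
    return OmicsLayer(tag, matrix, genes, samples)


class TestZscore:
    def test_per_gene_closed_form(self):
        z = zscore_normalize(_layer([[1.0, 2.0, 3.0]]), axis="gene")
        np.testing.assert_allclose(z.matrix[0], [-1.2247448, 0.0, 1.2247448], atol=1e-6)

    def test_constant_row_maps_to_zero(self):
        z = zscore_normalize(_layer([[5.0, 5.0, 5.0]]), axis="gene")
        np.testing.assert_array_equal(z.matrix[0], [0.0, 0.0, 0.0])

    def test_random_matrix_recomputation_oracle(self, rng):
        z = zscore_normalize(_layer(rng.normal(2, 3, (50, 20))), axis="gene")
        assert np.all(np.abs(z.matrix.mean(axis=1)) < 1e-10)
        assert np.all(np.abs(z.matrix.std(axis=1) - 1) < 1e-10)

    def test_sample_axis(self, rng):
        z = zscore_normalize(_layer(rng.normal(size=(30, 10))), axis="sample")
        assert np.all(np.abs(z.matrix.mean(axis=0)) < 1e-10)
        assert np.all(np.abs(z.matrix.std(axis=0) - 1) < 1e-10)

    def test_empty_matrix_rejected(self):
        with pytest.raises(DataError):
            zscore_normalize(_layer(np.empty((0, 0))))


class TestPooledT:
    labels = np.array(["poor"] * 3 + ["good"] * 3)

    def test_hand_computed_example(self):
        # poor=[3,4,5], good=[1,2,3]: pooled sd 1, factor sqrt(2/3)
        layer = _layer([[3, 4, 5, 1, 2, 3]])
        t = pooled_t_stat(layer, self.labels)["t"].iloc[0]
        assert t == pytest.approx(2.449489742783178, abs=1e-12)

    def test_equal_means_give_zero(self):
        layer = _layer([[1, 2, 3, 3, 2, 1]])
        assert pooled_t_stat(layer, self.labels)["t"].iloc[0] == pytest.approx(0.0)

    def test_label_swap_negates(self, rng):
        layer = _layer(rng.normal(size=(20, 6)))
        t1 = pooled_t_stat(layer, self.labels)["t"]
        t2 = pooled_t_stat(layer, self.labels[::-1])["t"]
        np.testing.assert_allclose(t1, -t2, atol=1e-12)

    def test_matches_independent_implementation(self, rng):
        labels = np.array(["poor"] * 12 + ["good"] * 15)
        layer = _layer(rng.normal(size=(1000, 27)))
        mine = pooled_t_stat(layer, labels)["t"].to_numpy()
        ref = stats.ttest_ind(
            layer.matrix[:, labels == "poor"],
            layer.matrix[:, labels == "good"],
            axis=1,
            equal_var=True,
        ).statistic
        np.testing.assert_allclose(mine, ref, atol=1e-10)

    def test_zero_variance_gene_is_nan_and_unranked(self):
        layer = _layer([[1, 1, 1, 1, 1, 1], [3, 4, 5, 1, 2, 3]])
        tbl = pooled_t_stat(layer, self.labels)
        assert np.isnan(tbl["t"].iloc[0])
        assert select_top_genes(tbl, 5) == ["g1"]

    def test_small_group_rejected(self):
        with pytest.raises(DataError):
            pooled_t_stat(_layer([[1, 2, 3]]), np.array(["poor", "good", "good"]))


class TestTopN:
    def _table(self, ts):
        genes = list(ts)
        return pd.DataFrame(
            {"t": [ts[g] for g in genes], "abs_t": [abs(ts[g]) for g in genes]},
            index=pd.Index(genes, name="gene"),
        )

    def test_order_statistic(self):
        assert set(select_top_genes(self._table({"g1": 3.0, "g2": 1.0, "g3": -2.0}), 2)) == {"g1", "g3"}

    def test_n_exceeding_layer_returns_all(self):
        assert len(select_top_genes(self._table({"g1": 3.0, "g2": 1.0}), 10)) == 2

    def test_matches_sort_oracle(self, rng):
        ts = {f"g{i:03d}": float(t) for i, t in enumerate(rng.normal(size=300))}
        oracle = [g for g, _ in sorted(ts.items(), key=lambda kv: (-abs(kv[1]), kv[0]))][:50]
        assert select_top_genes(self._table(ts), 50) == oracle

    def test_ties_break_by_gene_id(self):
        assert select_top_genes(self._table({"gb": 1.0, "ga": -1.0, "gc": 1.0}), 2) == ["ga", "gb"]


class TestReconstruct:
    def test_minimal_rule_instance(self):
        net = reconstruct_network([("a", "b"), ("c", "d")], {"a"})
        assert net.edges == [("a", "b")] and net.nodes == ["a", "b"]
        np.testing.assert_array_equal(net.adjacency, [[0, 1], [1, 0]])

    def test_full_union_is_identity(self, rng):
        edges = [(f"g{i}", f"g{j}") for i, j in rng.integers(0, 40, (100, 2)) if i != j]
        genes = {g for e in edges for g in e}
        net = reconstruct_network(edges, genes)
        dedup = {(min(a, b), max(a, b)) for a, b in edges}
        assert set(net.edges) == dedup

    def test_matches_linear_scan_oracle(self, rng):
        edges = list(
            {(f"g{min(i, j)}", f"g{max(i, j)}") for i, j in rng.integers(0, 100, (500, 2)) if i != j}
        )
        union = {f"g{i}" for i in rng.choice(100, 30, replace=False)}
        net = reconstruct_network(edges, union)
        oracle = {(a, b) for a, b in ((min(e), max(e)) for e in edges) if a in union or b in union}
        assert set(net.edges) == oracle
        adj = net.adjacency
        assert (adj == adj.T).all() and np.diag(adj).sum() == 0

    def test_no_retained_edges_raises(self):
        with pytest.raises(EmptyNetworkError):
            reconstruct_network([("a", "b")], {"z"})

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.data())
    def test_monotone_retention(self, data):
        """Enlarging U never drops a retained edge (and adjacency stays valid)."""
        n = data.draw(st.integers(4, 20))
        pairs = data.draw(
            st.sets(
                st.tuples(st.integers(0, n - 1), st.integers(0, n - 1)).filter(lambda p: p[0] != p[1]),
                min_size=1,
                max_size=40,
            )
        )
        edges = [(f"g{a}", f"g{b}") for a, b in pairs]
        genes = sorted({g for e in edges for g in e})
        small = set(data.draw(st.sets(st.sampled_from(genes), min_size=1)))
        big = small | set(data.draw(st.sets(st.sampled_from(genes))))
        net_small = reconstruct_network(edges, small)
        net_big = reconstruct_network(edges, big)
        assert set(net_small.edges) <= set(net_big.edges)
        assert (net_big.adjacency == net_big.adjacency.T).all()
        assert np.diag(net_big.adjacency).sum() == 0


class TestRealVectors:
    def test_gene_taken_from_max_abs_t_layer(self, rng):
        genes, samples = ["gA", "gB"], [f"s{i}" for i in range(6)]
        mrna = OmicsLayer("mRNA", rng.normal(size=(2, 6)), genes, samples)
        cnv = OmicsLayer("CNV", rng.normal(size=(2, 6)), genes, samples)
        tstats = {
            "mRNA": pd.DataFrame({"abs_t": [3.1, 0.2]}, index=genes),
            "CNV": pd.DataFrame({"abs_t": [0.4, 2.0]}, index=genes),
        }
        net = reconstruct_network([("gA", "gB")], {"gA"})
        x, source = build_real_vectors([mrna, cnv], tstats, net)
        assert source == {"gA": "mRNA", "gB": "CNV"}
        np.testing.assert_array_equal(x[:, 0], mrna.matrix[0])
        np.testing.assert_array_equal(x[:, 1], cnv.matrix[1])

    def test_single_layer_is_restriction(self, small_stage, small_cohort):
        layer = small_stage.layers[0]
        tstats = {"mRNA": small_stage.tstats["mRNA"]}
        nodes_in_layer = [g for g in small_stage.network.nodes if g in layer.gene_index()]
        net = reconstruct_network(
            [e for e in small_stage.network.edges], set(nodes_in_layer)
        )
        x, source = build_real_vectors([layer], tstats, net)
        gi = layer.gene_index()
        for j, g in enumerate(net.nodes):
            np.testing.assert_array_equal(x[:, j], layer.matrix[gi[g]])

    def test_argmax_matches_scan_oracle(self, rng):
        genes = [f"g{i}" for i in range(100)]
        samples = [f"s{i}" for i in range(8)]
        layers = [
            OmicsLayer(tag, rng.normal(size=(100, 8)), genes, samples)
            for tag in o.LAYER_TAGS
        ]
        tstats = {
            layer.layer_tag: pd.DataFrame({"abs_t": rng.uniform(0, 5, 100)}, index=genes)
            for layer in layers
        }
        edges = [(genes[i], genes[i + 1]) for i in range(99)]
        net = reconstruct_network(edges, set(genes))
        _, source = build_real_vectors(layers, tstats, net)
        for g in genes:
            best = max(o.LAYER_TAGS, key=lambda tag: tstats[tag]["abs_t"][g])
            assert source[g] == best


def test_planted_gene_capture_in_top_sets(small_cohort, small_stage):
    """With effect size 2, planted genes are caught by their layer's top-N."""
    caught = [
        gene in small_stage.quartet.sets[tag] for gene, tag in small_cohort.truth.items()
    ]
    assert np.mean(caught) >= 0.95


def test_quartet_union_and_membership(small_stage):
    q = small_stage.quartet
    assert q.union == set().union(*q.sets.values())
    for tag, genes in q.sets.items():
        assert len(genes) <= q.n
        for g in genes:
            assert tag in q.memberships(g)
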