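import numpy as np
import pandas as pd
import pytest

from netimpute.network import (
    SimilarityMatrix,
    asymmetric_knn,
    knn_graph,
    load_ppi,
    mutual_knn,
    read_edgelist,
    similarity,
    write_edgelist,
)

from conftest import make_expr


def pearson_oracle(x, y):
    """Textbook Pearson formula, written independently of the implementation."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    num = n * (x * y).sum() - x.sum() * y.sum()
    den = np.sqrt(n * (x**2).sum() - x.sum() ** 2) * np.sqrt(
        n * (y**2).sum() - y.sum() ** 2
    )
    return num / den


def brute_force_knn(S, k, isolated, mutual):
    """O(p^2 k) pairwise check of the (two- or one-sided) top-k condition."""
    p = S.shape[0]

    def topk(i):
        cand = [j for j in range(p) if j != i and not isolated[j]]
        # sort by similarity descending, ties by ascending index
        cand.sort(key=lambda j: (-S[i, j], j))
        return set(cand[:k])

    neighborhoods = [set() if isolated[i] else topk(i) for i in range(p)]
    A = np.zeros((p, p), dtype=int)
    for i in range(p):
        for j in range(i + 1, p):
            in_i, in_j = j in neighborhoods[i], i in neighborhoods[j]
            if (in_i and in_j) if mutual else (in_i or in_j):
                A[i, j] = A[j, i] = 1
    return A


class TestSimilarity:
    def test_self_and_affine_pairs_are_one(self):
        g1 = np.array([1.0, 2.0, 3.0, 5.0])
        E = make_expr(np.vstack([g1, 2 * g1 + 3]), scale_tag="lognormalized")
        S = similarity(E, axis="gene")
        assert S.values[0, 0] == pytest.approx(1.0)
        assert S.values[0, 1] == pytest.approx(1.0)

    def test_matches_textbook_formula_on_hand_vectors(self):
        vecs = np.array([
            [1.0, 2.0, 3.0, 4.0],
            [2.0, 1.0, 4.0, 3.0],
            [5.0, 3.0, 2.0, 1.0],
        ])
        S = similarity(make_expr(vecs, scale_tag="lognormalized"), axis="gene")
        for i in range(3):
            for j in range(3):
                assert S.values[i, j] == pytest.approx(
                    pearson_oracle(vecs[i], vecs[j])
                )

    def test_cell_axis_correlates_columns(self):
        vals = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0]])
        S = similarity(make_expr(vals, scale_tag="lognormalized"), axis="cell")
        assert S.values.shape == (2, 2)
        assert S.values[0, 1] == pytest.approx(1.0)

    def test_zero_variance_nodes_flagged_isolated(self):
        vals = np.array([[1.0, 2.0, 3.0], [4.0, 4.0, 4.0], [3.0, 1.0, 2.0]])
        S = similarity(make_expr(vals, scale_tag="lognormalized"), axis="gene")
        assert list(S.isolated) == [False, True, False]
        assert np.all(S.values[1, [0, 2]] == 0)


class TestKnnGraphs:
    def _three_node_similarity(self):
        # top-1(g0)=g1, top-1(g1)=g0, top-1(g2)=g0
        S = np.array([
            [1.0, 0.9, 0.5],
            [0.9, 1.0, 0.2],
            [0.5, 0.2, 1.0],
        ])
        return SimilarityMatrix(S, np.array(["g0", "g1", "g2"], dtype=object),
                                "gene", np.zeros(3, bool))

    def test_mutual_k1_keeps_only_reciprocal_edge(self):
        G = mutual_knn(self._three_node_similarity(), k=1)
        A = G.adjacency.toarray()
        expected = np.zeros((3, 3), int)
        expected[0, 1] = expected[1, 0] = 1
        np.testing.assert_array_equal(A, expected)

    def test_asymmetric_k1_adds_one_sided_edge(self):
        G = asymmetric_knn(self._three_node_similarity(), k=1)
        A = G.adjacency.toarray()
        expected = np.zeros((3, 3), int)
        expected[0, 1] = expected[1, 0] = 1
        expected[0, 2] = expected[2, 0] = 1
        np.testing.assert_array_equal(A, expected)

    def test_k_equals_p_minus_1_gives_complete_graph(self):
        rng = np.random.default_rng(0)
        E = make_expr(np.abs(rng.normal(2, 1, size=(6, 12))),
                      scale_tag="lognormalized")
        S = similarity(E)
        for build in (mutual_knn, asymmetric_knn):
            A = build(S, k=5).adjacency.toarray()
            np.testing.assert_array_equal(A, 1 - np.eye(6, dtype=np.int8))

    def test_k_out_of_range_rejected(self):
        S = self._three_node_similarity()
        for bad in (0, 3):
            with pytest.raises(ValueError, match="k must"):
                mutual_knn(S, bad)

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("mutual", [True, False])
    def test_matches_brute_force_oracle(self, seed, mutual):
        rng = np.random.default_rng(seed)
        p, n = 30, 15
        vals = np.abs(rng.normal(2.0, 1.0, size=(p, n)))
        vals[seed % p] = 3.0  # one constant (isolated) gene
        E = make_expr(vals, scale_tag="lognormalized")
        S = similarity(E)
        k = int(rng.integers(1, p - 1))
        build = mutual_knn if mutual else asymmetric_knn
        A = build(S, k).adjacency.toarray()
        expected = brute_force_knn(S.values, k, S.isolated, mutual)
        np.testing.assert_array_equal(A, expected)

    def test_mutual_subset_of_asymmetric_and_degree_bound(self):
        rng = np.random.default_rng(3)
        E = make_expr(np.abs(rng.normal(2, 1, size=(40, 20))),
                      scale_tag="lognormalized")
        S = similarity(E)
        k = 6
        Am = mutual_knn(S, k).adjacency.toarray()
        Aa = asymmetric_knn(S, k).adjacency.toarray()
        assert np.all(Am <= Aa)
        assert Am.sum(axis=1).max() <= k

    def test_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(4)
        E = make_expr(np.abs(rng.normal(2, 1, size=(25, 10))),
                      scale_tag="lognormalized")
        for flavor in ("mutual_knn", "asymmetric_knn"):
            A = knn_graph(E, k=4, flavor=flavor).adjacency.toarray()
            np.testing.assert_array_equal(A, A.T)
            assert np.all(np.diag(A) == 0)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(9)
        E = make_expr(np.abs(rng.normal(2, 1, size=(20, 30))),
                      scale_tag="lognormalized")
        k = 5
        A = mutual_knn(similarity(E), k).adjacency.toarray()
        perm = rng.permutation(20)
        Ep = make_expr(E.values[perm], scale_tag="lognormalized",
                       gene_ids=[f"g{i}" for i in perm])
        Ap = mutual_knn(similarity(Ep), k).adjacency.toarray()
        np.testing.assert_array_equal(Ap, A[np.ix_(perm, perm)])

    def test_blockwise_path_identical_to_dense(self):
        rng = np.random.default_rng(12)
        E = make_expr(np.abs(rng.normal(2, 1, size=(120, 25))),
                      scale_tag="lognormalized")
        for flavor, build in (("mutual_knn", mutual_knn),
                              ("asymmetric_knn", asymmetric_knn)):
            dense = build(similarity(E), 7).adjacency.toarray()
            blocked = knn_graph(E, k=7, flavor=flavor, block_size=16).adjacency.toarray()
            np.testing.assert_array_equal(blocked, dense)


class TestPpi:
    def test_top_decile_quantile_keeps_one_of_ten(self):
        edges = pd.DataFrame({
            "geneA": [f"a{i}" for i in range(10)],
            "geneB": [f"b{i}" for i in range(10)],
            "score": list(range(1, 11)),
        })
        genes = [f"a{i}" for i in range(10)] + [f"b{i}" for i in range(10)]
        G = load_ppi(edges, genes, confidence_quantile=0.9)
        assert G.adjacency.nnz == 2  # one undirected edge
        i, j = genes.index("a9"), genes.index("b9")
        assert G.adjacency[i, j] == 1

    def test_edges_outside_expressed_genes_dropped(self):
        edges = pd.DataFrame({"geneA": ["x", "x"], "geneB": ["y", "z"],
                              "score": [1.0, 1.0]})
        G = load_ppi(edges, ["x", "y"], confidence_quantile=0.0)
        assert G.adjacency.nnz == 2
        assert G.degrees.tolist() == [1, 1]

    def test_directed_duplicates_become_single_edge(self):
        edges = pd.DataFrame({"geneA": ["a", "b"], "geneB": ["b", "a"],
                              "score": [1.0, 1.0]})
        G = load_ppi(edges, ["a", "b"], confidence_quantile=0.0)
        np.testing.assert_array_equal(G.adjacency.toarray(), [[0, 1], [1, 0]])

    def test_case_insensitive_matching_and_isolated_leftovers(self):
        edges = pd.DataFrame({"geneA": ["GeNe1"], "geneB": ["GENE2"],
                              "score": [5.0]})
        G = load_ppi(edges, ["gene1", "gene2", "gene3"], confidence_quantile=0.0)
        assert G.degrees.tolist() == [1, 1, 0]

    def test_empty_result_warns_and_is_fully_isolated(self):
        edges = pd.DataFrame({"geneA": ["p"], "geneB": ["q"], "score": [1.0]})
        with pytest.warns(UserWarning, match="isolated"):
            G = load_ppi(edges, ["x", "y"], confidence_quantile=0.0)
        assert G.adjacency.nnz == 0

    def test_string_style_file_with_header(self, tmp_path):
        path = tmp_path / "links.txt"
        path.write_text(
            "protein1 protein2 combined_score\n"
            "a b 900\n"
            "b c 100\n"
        )
        G = load_ppi(path, ["a", "b", "c"], confidence_quantile=0.5)
        assert G.adjacency.nnz == 2  # only the 900 edge survives


class TestEdgelistRoundTrip:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(2)
        E = make_expr(np.abs(rng.normal(2, 1, size=(15, 10))),
                      scale_tag="lognormalized")
        G = knn_graph(E, k=3)
        path = tmp_path / "graph.tsv"
        write_edgelist(G, path)
        back = read_edgelist(path, E.gene_ids)
        np.testing.assert_array_equal(back.adjacency.toarray(),
                                      G.adjacency.toarray())
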