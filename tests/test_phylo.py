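import dendropy
import numpy as np
import pytest
from scipy.optimize import minimize

from nndecon import (
    CommunityTree,
    build_Pq,
    classify_communities,
    community_distances,
    edge_perturbations,
    infer_steiner_pathways,
    nj_tree,
    steiner_solve,
    tree_to_newick,
)
from nndecon.phylo import SteinerSystem, elastic_energy


def random_tree(k, seed, m=10):
    """Random topology + random positive edge weights + random extant values."""
    rng = np.random.default_rng(seed)
    C = rng.normal(size=(m, k))
    tree = nj_tree(community_distances(C), extant_matrix=C)
    for e in tree.lengths:
        tree.lengths[e] = float(rng.uniform(0.1, 2.0))
    return tree, rng


def leaf_path_distances(tree):
    """Path-length distances between extant leaves through the tree."""
    import networkx as nx

    G = nx.Graph()
    for (u, v), d in tree.lengths.items():
        G.add_edge(u, v, weight=d)
    ns = tree.n_steiner
    k = tree.k
    D = np.zeros((k, k))
    for a in range(k):
        lengths = nx.single_source_dijkstra_path_length(G, ns + a)
        for b in range(k):
            D[a, b] = lengths[ns + b]
    D = (D + D.T) / 2  # kill float asymmetry from summation order
    np.fill_diagonal(D, 0.0)
    return D


class TestCommunityDistances:
    def test_identical_columns_zero(self):
        C = np.ones((4, 3))
        D = community_distances(C)
        np.testing.assert_array_equal(D, np.zeros((3, 3)))

    def test_three_four_five_triangle(self):
        C = np.array([[0.0, 3.0, 0.0], [0.0, 4.0, 1.0]])
        D = community_distances(C)
        assert D[0, 1] == pytest.approx(5.0)

    def test_metric_properties(self, rng):
        C = rng.normal(size=(6, 5))
        D = community_distances(C)
        np.testing.assert_allclose(D, D.T)
        for i in range(5):
            for j in range(5):
                for l in range(5):
                    assert D[i, j] <= D[i, l] + D[l, j] + 1e-12

    def test_too_few_communities_rejected(self):
        with pytest.raises(ValueError):
            community_distances(np.ones((4, 2)))


class TestNjTree:
    def test_three_leaves_single_steiner(self):
        D = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float)
        tree = nj_tree(D)
        assert tree.n_steiner == 1
        assert len(tree.edges) == 3
        assert {v for _, v in tree.edges} == {1, 2, 3}

    def test_five_leaves_three_steiner(self):
        rng = np.random.default_rng(0)
        C = rng.normal(size=(8, 5))
        tree = nj_tree(community_distances(C))
        assert tree.k == 5 and tree.n_steiner == 3
        assert len(tree.edges) == 2 * 5 - 3

    @pytest.mark.parametrize("k", [3, 4, 6, 9])
    def test_leaf_and_internal_counts(self, k):
        rng = np.random.default_rng(k)
        C = rng.normal(size=(7, k))
        tree = nj_tree(community_distances(C))
        assert tree.n_steiner == k - 2  # degree checks run in the constructor

    def test_additive_distances_recover_topology(self):
        """NJ is consistent: distances read off a random 6-leaf tree with
        positive branch lengths reproduce its topology (RF distance 0)."""
        source, _ = random_tree(6, seed=11)
        D = leaf_path_distances(source)
        rebuilt = nj_tree(D, names=source.extant_names)
        tns = dendropy.TaxonNamespace()
        t1 = dendropy.Tree.get(
            data=tree_to_newick(source), schema="newick", taxon_namespace=tns
        )
        t2 = dendropy.Tree.get(
            data=tree_to_newick(rebuilt), schema="newick", taxon_namespace=tns
        )
        t1.encode_bipartitions()
        t2.encode_bipartitions()
        assert dendropy.calculate.treecompare.symmetric_difference(t1, t2) == 0

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], float)
        with pytest.raises(ValueError):
            nj_tree(D)


class TestBuildPq:
    def _manual_tree(self, k, edges, lengths):
        return CommunityTree(
            k=k,
            extant_names=[f"C{i+1}" for i in range(k)],
            edges=edges,
            lengths=dict(zip(edges, lengths)),
        )

    def test_single_steiner_extant_edge_terms(self):
        # star: one Steiner node (index 0) joined to extants 1, 2, 3
        tree = self._manual_tree(3, [(0, 1), (0, 2), (0, 3)], [0.5, 1.0, 2.0])
        y = np.array([1.0, 3.0, -2.0])
        sys0 = build_Pq(tree, y)
        w = [1 / 0.5, 1 / 1.0, 1 / 2.0]
        assert sys0.P == pytest.approx(np.array([[sum(w)]]))
        assert sys0.q == pytest.approx(
            np.array([-(w[0] * 1.0 + w[1] * 3.0 + w[2] * (-2.0))])
        )

    def test_steiner_steiner_edge_term(self):
        # two Steiner nodes joined; each carries two extant leaves
        edges = [(0, 1), (0, 2), (0, 3), (1, 4), (1, 5)]
        tree = self._manual_tree(4, sorted(edges), [1.0, 2.0, 4.0, 1.0, 0.5])
        sysd = build_Pq(tree, np.zeros(4))
        w01 = 1.0
        assert sysd.P[0, 1] == pytest.approx(-w01)
        assert sysd.P[1, 0] == pytest.approx(-w01)
        np.testing.assert_allclose(sysd.P, sysd.P.T)

    def test_equals_laplacian_restriction(self):
        """P must equal the weighted graph Laplacian of the whole tree
        restricted to Steiner rows/columns (extant edges contribute only
        their weight to the Steiner diagonal)."""
        import networkx as nx

        tree, _ = random_tree(5, seed=3)
        G = nx.Graph()
        for u, v in tree.edges:
            G.add_edge(u, v, weight=tree.weight(u, v))
        L = nx.laplacian_matrix(G, nodelist=sorted(G.nodes), weight="weight").toarray()
        ns = tree.n_steiner
        sys0 = build_Pq(tree, np.zeros(tree.k))
        np.testing.assert_allclose(sys0.P, L[:ns, :ns])

    def test_positive_definite_on_random_trees(self):
        for seed in range(5):
            tree, _ = random_tree(6, seed=seed)
            P = build_Pq(tree, np.zeros(6)).P
            assert np.linalg.eigvalsh(P).min() > 0


class TestSteinerSolve:
    def test_star_center_is_weighted_mean(self):
        tree = CommunityTree(
            k=3,
            extant_names=["a", "b", "c"],
            edges=[(0, 1), (0, 2), (0, 3)],
            lengths={(0, 1): 1.0, (0, 2): 1.0, (0, 3): 1e12},
        )
        # third edge nearly weightless: x ≈ mean of y1, y2
        x = steiner_solve(build_Pq(tree, np.array([1.0, 3.0, 100.0])))
        assert x[0] == pytest.approx(2.0, abs=1e-6)

    def test_weighted_mean_hand_oracle(self):
        tree = CommunityTree(
            k=3,
            extant_names=["a", "b", "c"],
            edges=[(0, 1), (0, 2), (0, 3)],
            lengths={(0, 1): 0.5, (0, 2): 1.0, (0, 3): 1e12},
        )
        # weights 2 and 1 on y = 0 and 6 → x = (2·0 + 1·6)/3 = 2
        x = steiner_solve(build_Pq(tree, np.array([0.0, 6.0, 0.0])))
        assert x[0] == pytest.approx(2.0, abs=1e-6)

    def test_matches_numerical_minimizer(self):
        tree, rng = random_tree(6, seed=7)
        y = rng.normal(size=6)
        x_closed = steiner_solve(build_Pq(tree, y))
        res = minimize(
            lambda x: elastic_energy(tree, x, y),
            np.zeros(tree.n_steiner),
            method="BFGS",
            options={"gtol": 1e-12},
        )
        np.testing.assert_allclose(x_closed, res.x, atol=1e-6)

    def test_local_optimality_against_perturbations(self):
        tree, rng = random_tree(5, seed=9)
        y = rng.normal(size=5)
        x = steiner_solve(build_Pq(tree, y))
        U0 = elastic_energy(tree, x, y)
        for _ in range(100):
            assert U0 <= elastic_energy(tree, x + rng.normal(0, 0.1, x.shape), y)

    def test_singular_system_rejected(self):
        bad = SteinerSystem(P=np.zeros((2, 2)), q=np.ones(2))
        with pytest.raises(np.linalg.LinAlgError):
            steiner_solve(bad)


class TestInferSteiner:
    def test_identical_extant_columns_give_constant_steiner(self):
        rng = np.random.default_rng(0)
        col = rng.normal(size=8)
        C = np.tile(col[:, None], (1, 4))
        D = community_distances(C) + 1e-9 * (1 - np.eye(4))
        tree = nj_tree(D, extant_matrix=C)
        for e in tree.lengths:  # zero distances → give the tree real lengths
            tree.lengths[e] = 1.0
        infer_steiner_pathways(tree)
        for s in range(tree.n_steiner):
            np.testing.assert_allclose(tree.steiner_matrix[:, s], col, atol=1e-9)

    def test_equal_weight_star_is_arithmetic_mean(self):
        rng = np.random.default_rng(1)
        C = rng.normal(size=(6, 3))
        tree = CommunityTree(
            k=3,
            extant_names=["a", "b", "c"],
            edges=[(0, 1), (0, 2), (0, 3)],
            lengths={(0, 1): 1.0, (0, 2): 1.0, (0, 3): 1.0},
            extant_matrix=C,
        )
        infer_steiner_pathways(tree)
        np.testing.assert_allclose(tree.steiner_matrix[:, 0], C.mean(axis=1))

    def test_maximum_principle(self):
        tree, _ = random_tree(7, seed=13, m=12)
        infer_steiner_pathways(tree)
        lo = tree.extant_matrix.min(axis=1)
        hi = tree.extant_matrix.max(axis=1)
        for s in range(tree.n_steiner):
            assert np.all(tree.steiner_matrix[:, s] >= lo - 1e-9)
            assert np.all(tree.steiner_matrix[:, s] <= hi + 1e-9)


class TestEdgePerturbations:
    def _tree_with_vectors(self, parent_vec, child_vecs):
        C = np.column_stack(child_vecs)
        tree = CommunityTree(
            k=3,
            extant_names=["a", "b", "c"],
            edges=[(0, 1), (0, 2), (0, 3)],
            lengths={(0, 1): 1.0, (0, 2): 1.0, (0, 3): 1.0},
            extant_matrix=C,
            row_names=["row1", "row2", "row3"],
        )
        tree.steiner_matrix = np.asarray(parent_vec, float)[:, None]
        return tree

    def test_identical_endpoints_no_changes(self):
        v = np.array([1.0, 2.0, 3.0])
        tree = self._tree_with_vectors(v, [v, v, v])
        reports = edge_perturbations(tree, root="a")
        for r in reports:
            np.testing.assert_array_equal(r.delta, 0.0)
            assert r.large_changes == [] and r.top_gained == [] and r.top_lost == []

    def test_gain_loss_ordering_hand_oracle(self):
        parent = np.zeros(3)
        child = np.array([1.5, -0.4, 2.0])
        tree = self._tree_with_vectors(parent, [parent, child, parent])
        reports = {r.edge: r for r in edge_perturbations(tree, root="a")}
        r = reports[("S1", "b")]
        assert r.top_gained == ["row3", "row1"]
        assert r.top_lost == ["row2"]
        assert r.large_changes == ["row3", "row1"]

    def test_rerooting_flips_delta_signs(self):
        rng = np.random.default_rng(2)
        tree, _ = random_tree(5, seed=17, m=4)
        tree.row_names = [f"r{i}" for i in range(4)]
        infer_steiner_pathways(tree)
        fwd = {r.edge: r.delta for r in edge_perturbations(tree, root=tree.n_steiner)}
        rev = {r.edge: r.delta for r in edge_perturbations(tree, root=tree.n_steiner + 1)}
        flipped = [
            ((a, b), d) for (a, b), d in fwd.items() if (b, a) in rev
        ]
        assert flipped
        for (a, b), d in flipped:
            np.testing.assert_allclose(rev[(b, a)], -d)

    def test_unknown_root_rejected(self):
        tree, _ = random_tree(4, seed=19)
        infer_steiner_pathways(tree)
        with pytest.raises(ValueError):
            edge_perturbations(tree, root="nope")


class TestClassifyCommunities:
    def _annotation(self, n_patients):
        ann, samples = {}, []
        for i in range(n_patients):
            for stage in ("primary", "metastatic"):
                s = f"p{i}_{stage[0]}"
                ann[s] = (f"p{i}", stage)
                samples.append(s)
        return samples, ann

    def test_identical_fractions_all_neutral(self):
        samples, ann = self._annotation(3)
        F = np.tile(np.array([[0.5], [0.3], [0.2]]), (1, 6))
        labels = classify_communities(F, samples, ann)
        assert labels.component_labels == ["neutral"] * 3
        assert all(c == 1 for c in labels.patient_case.values())

    def test_mean_shift_rule(self):
        samples, ann = self._annotation(4)
        F = np.zeros((2, 8))
        for j, s in enumerate(samples):
            F[0, j] = 0.2 if ann[s][1] == "primary" else 0.3
        F[1] = 1 - F[0]
        labels = classify_communities(F, samples, ann)
        assert labels.component_labels[0] == "metastatic"
        assert labels.component_labels[1] == "primary"
        assert labels.delta[0] == pytest.approx(0.1)

    def test_case_assignment_for_missing_components(self):
        samples, ann = self._annotation(2)
        k = 5
        F = np.full((k, 4), 0.2)
        # patient p1 loses component 0 (case 2 under the default map)
        F[0, 2:] = 0.0
        F[1:, 2:] = 0.25
        labels = classify_communities(F, samples, ann)
        assert labels.patient_case["p0"] == 1
        assert labels.patient_case["p1"] == 2

    def test_unpaired_patient_rejected(self):
        samples, ann = self._annotation(2)
        samples = samples[:-1]  # drop p1's metastatic sample
        F = np.full((2, 3), 0.5)
        with pytest.raises(ValueError, match="p1"):
            classify_communities(F, samples, {s: ann[s] for s in samples})


class TestNewick:
    def test_round_trips_through_dendropy(self):
        tree, _ = random_tree(5, seed=23)
        t = dendropy.Tree.get(data=tree_to_newick(tree), schema="newick")
        assert len(t.leaf_nodes()) == 5
        internal = [n for n in t if not n.is_leaf()]
        assert len(internal) == 3
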