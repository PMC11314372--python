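import itertools

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare

from pcskit import jtt, phylo, synthetic


def random_additive_tree(n_leaves: int, rng: np.random.Generator):
    """A random unrooted binary tree and the additive distances it implies."""
    import networkx as g

    graph = g.Graph()
    labels = [f"L{i}" for i in range(n_leaves)]
    nodes = list(labels)
    graph.add_nodes_from(nodes)
    nxt = 0
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        inner = f"I{nxt}"
        nxt += 1
        graph.add_edge(nodes[i], inner, weight=float(rng.uniform(0.05, 1.0)))
        graph.add_edge(nodes[j], inner, weight=float(rng.uniform(0.05, 1.0)))
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [inner]
    root = f"I{nxt}"
    for node in nodes:
        graph.add_edge(node, root, weight=float(rng.uniform(0.05, 1.0)))
    paths = dict(g.all_pairs_dijkstra_path_length(graph, weight="weight"))
    mat = np.zeros((n_leaves, n_leaves))
    for a, b in itertools.combinations(range(n_leaves), 2):
        mat[a, b] = mat[b, a] = paths[labels[a]][labels[b]]
    return labels, mat, graph


def patristic(tree: phylo.TreeNode) -> dict:
    import networkx as g

    graph = g.Graph()
    counter = [0]

    def walk(node, name):
        for child, length in node.children:
            cname = child.label if child.is_leaf else f"i{counter[0]}"
            counter[0] += 1
            graph.add_edge(name, cname, weight=length)
            walk(child, cname)

    walk(tree, "root")
    return dict(g.all_pairs_dijkstra_path_length(graph, weight="weight"))


def rf_distance(newick_a: str, newick_b: str) -> int:
    tns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(data=newick_a, schema="newick", taxon_namespace=tns)
    tb = dendropy.Tree.get(data=newick_b, schema="newick", taxon_namespace=tns)
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    return treecompare.symmetric_difference(ta, tb)


def loglik(seq_a: str, seq_b: str, t: float) -> float:
    pi = jtt.equilibrium_frequencies()
    P = jtt.probability_matrix(t)
    idx_a, idx_b = jtt.encode(seq_a), jtt.encode(seq_b)
    return float(sum(np.log(pi[a] * P[a, b]) for a, b in zip(idx_a, idx_b)))


def test_identical_sequences_have_zero_distance():
    s = "".join("ACDEFGHIKLMNPQRSTVWY"[i % 20] for i in range(200))
    assert phylo.jtt_ml_distance(s, s) == 0.0


def test_ml_distance_recovers_simulated_divergence_within_3_se():
    t_true, n = 0.2, 10000
    a, b = synthetic.evolve_pair(n, t_true, seed=21)
    t_hat = phylo.jtt_ml_distance(a, b)
    # observed-information SE from the likelihood curvature at the optimum
    h = 1e-3
    d2 = (loglik(a, b, t_hat + h) - 2 * loglik(a, b, t_hat) + loglik(a, b, t_hat - h)) / h**2
    se = 1.0 / np.sqrt(-d2)
    assert abs(t_hat - t_true) < 3 * se


def test_ml_distance_is_a_local_optimum_and_symmetric():
    rng = np.random.default_rng(22)
    for k in range(50):
        t = float(rng.uniform(0.05, 1.5))
        a, b = synthetic.evolve_pair(300, t, seed=100 + k)
        t_hat = phylo.jtt_ml_distance(a, b)
        ll = loglik(a, b, t_hat)
        assert ll >= loglik(a, b, t_hat + 0.01) - 1e-9
        if t_hat > 0.011:
            assert ll >= loglik(a, b, t_hat - 0.01) - 1e-9
        assert phylo.jtt_ml_distance(b, a) == pytest.approx(t_hat, abs=1e-4)


def test_distance_requires_overlap():
    with pytest.raises(ValueError):
        phylo.jtt_ml_distance("XXXX", "AAAA")


def test_nj_three_taxa_three_point_formulas():
    dm = phylo.DistanceMatrix(["A", "B", "C"],
                              np.array([[0, 3.0, 4.0], [3.0, 0, 5.0], [4.0, 5.0, 0]]))
    tree = phylo.nj_tree(dm)
    lengths = {child.label: l for child, l in tree.children}
    assert lengths["A"] == pytest.approx(1.0)
    assert lengths["B"] == pytest.approx(2.0)
    assert lengths["C"] == pytest.approx(3.0)
    with pytest.raises(ValueError):
        phylo.nj_tree(phylo.DistanceMatrix(["A", "B"], np.zeros((2, 2))))


def test_nj_exact_on_additive_matrices():
    # NJ must reproduce the generating topology and all path lengths
    rng = np.random.default_rng(23)
    for _ in range(50):
        n = int(rng.integers(5, 13))
        labels, mat, _ = random_additive_tree(n, rng)
        tree = phylo.nj_tree(phylo.DistanceMatrix(labels, mat))
        paths = patristic(tree)
        for i, j in itertools.combinations(range(n), 2):
            assert paths[labels[i]][labels[j]] == pytest.approx(mat[i, j], abs=1e-9)


def test_nj_agrees_with_skbio_on_topology():
    import skbio

    rng = np.random.default_rng(24)
    labels, mat, _ = random_additive_tree(8, rng)
    mine = phylo.nj_tree(phylo.DistanceMatrix(labels, mat)).to_newick()
    theirs = str(skbio.tree.nj(skbio.DistanceMatrix(mat, ids=labels)))
    assert rf_distance(mine, theirs) == 0


def test_bootstrap_supports_deterministic_and_bounded():
    recs, groups, _, info = synthetic.two_group_dataset(n_per_group=4, divergence=0.15, seed=25)
    labels = [r.seq_id for r in recs]
    aligned = [r.residues[:info["domain_end"]] for r in recs]
    t1 = phylo.bootstrap_supports(labels, aligned, n_replicates=30, seed=5)
    t2 = phylo.bootstrap_supports(labels, aligned, n_replicates=30, seed=5)
    assert t1.to_newick() == t2.to_newick()

    def supports(node, out):
        for child, _ in node.children:
            if not child.is_leaf:
                if child.support is not None:
                    out.append(child.support)
                supports(child, out)
        return out

    vals = supports(t1, [])
    assert vals and all(0.0 <= v <= 100.0 for v in vals)


def test_two_cluster_dataset_splits_with_high_support():
    recs, groups, _, info = synthetic.two_group_dataset(n_per_group=5, divergence=0.1, seed=26)
    labels = [r.seq_id for r in recs]
    aligned = [r.residues[:info["domain_end"]] for r in recs]
    tree = phylo.bootstrap_supports(labels, aligned, n_replicates=100, seed=6)
    side = {sid for sid, grp in groups.items() if grp == "1"}
    support = phylo.support_for_split(tree, side)
    assert support is not None, "tree does not contain the group split"
    assert support >= 95.0
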