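"""Distance matrices, neighbor joining (against a least-squares
brute-force oracle), bootstrap, rooting and Newick round trips."""

import itertools

import dendropy
import numpy as np
import pytest

from numtscope.phylo import (
    DistanceMatrix,
    bootstrap_support,
    build_distance_matrix,
    neighbor_joining,
    read_newick,
    root_on_outgroup,
    tip_info,
    tree_splits,
    write_newick,
)


def patristic(tree):
    """Tip-to-tip path lengths as a dict keyed by sorted label pairs."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = [leaf.taxon for leaf in tree.leaf_node_iter()]
    out = {}
    for t1, t2 in itertools.combinations(taxa, 2):
        out[tuple(sorted((t1.label, t2.label)))] = pdm.patristic_distance(t1, t2)
    return out


# --- brute-force oracle over unrooted topologies -----------------------------


def enumerate_topologies(labels):
    """All unrooted binary topologies as edge lists over the labels.

    Built by inserting taxa one at a time into every edge; nodes are
    integers, tips carry their label index 0..n-1.
    """
    n = len(labels)
    base = [(n, 0), (n, 1), (n, 2)]  # star on first three tips, hub = n
    topologies = [base]
    next_internal = n + 1
    for tip in range(3, n):
        grown = []
        for edges in topologies:
            for edge in edges:
                hub = next_internal
                rest = [e for e in edges if e != edge]
                grown.append(
                    rest + [(edge[0], hub), (hub, edge[1]), (hub, tip)]
                )
        topologies = grown
        next_internal += 1
    return topologies


def least_squares_fit(edges, labels, d):
    """OLS branch lengths for a topology; returns (residual, splits)."""
    n = len(labels)
    adjacency = {}
    for a, b in edges:
        adjacency.setdefault(a, []).append(b)
        adjacency.setdefault(b, []).append(a)

    def path(u, v):
        stack = [(u, [])]
        seen = {u}
        while stack:
            node, used = stack.pop()
            if node == v:
                return used
            for nxt in adjacency[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append((nxt, used + [frozenset((node, nxt))]))
        raise AssertionError

    edge_ids = [frozenset(e) for e in edges]
    rows, y = [], []
    for i in range(n):
        for j in range(i + 1, n):
            onpath = set(path(i, j))
            rows.append([1.0 if e in onpath else 0.0 for e in edge_ids])
            y.append(d[i, j])
    coeffs, *_ = np.linalg.lstsq(np.array(rows), np.array(y), rcond=None)
    residual = float(np.sum((np.array(rows) @ coeffs - np.array(y)) ** 2))

    splits = set()
    anchor = min(labels)
    full = frozenset(labels)
    for e in edge_ids:
        a, b = tuple(e)
        # tips on b's side when edge removed
        side = set()
        stack = [b]
        seen = {a, b}
        while stack:
            node = stack.pop()
            if node < n:
                side.add(labels[node])
            for nxt in adjacency[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        split = frozenset(side)
        if anchor in split:
            split = full - split
        if 2 <= len(split) <= n - 2:
            splits.add(split)
    return residual, splits


def random_additive_matrix(n, rng):
    """Distances from a random binary tree with positive branch lengths;
    returns (labels, d, generating splits)."""
    labels = [f"t{i}" for i in range(n)]
    topo = enumerate_topologies(labels)
    edges = topo[int(rng.integers(len(topo)))]
    lengths = {frozenset(e): rng.uniform(0.1, 2.0) for e in edges}
    _, splits = least_squares_fit(edges, labels, np.zeros((n, n)))
    adjacency = {}
    for a, b in edges:
        adjacency.setdefault(a, []).append(b)
        adjacency.setdefault(b, []).append(a)
    d = np.zeros((n, n))
    for i in range(n):
        # BFS accumulating path length
        dist = {i: 0.0}
        stack = [i]
        while stack:
            node = stack.pop()
            for nxt in adjacency[node]:
                if nxt not in dist:
                    dist[nxt] = dist[node] + lengths[frozenset((node, nxt))]
                    stack.append(nxt)
        for j in range(n):
            d[i, j] = dist[j]
        d[i, i] = 0.0
    return labels, d, splits


class TestDistanceMatrix:
    def test_identical_pair_zero_under_both_models(self):
        recs = [("a", "ACGTACGT"), ("b", "ACGTACGT"), ("c", "ACGTACGA")]
        for model in ("p", "jc69"):
            dm = build_distance_matrix(recs, model)
            assert dm.d[0, 1] == 0.0

    def test_jc69_closed_form_at_quarter_divergence(self):
        seq_a = "A" * 80
        seq_b = "A" * 60 + "C" * 20  # p = 0.25
        dm = build_distance_matrix([("a", seq_a), ("b", seq_b)], "jc69")
        assert dm.d[0, 1] == pytest.approx(-0.75 * np.log(1 - (4 / 3) * 0.25))
        assert dm.d[0, 1] == pytest.approx(0.3041, abs=1e-4)

    def test_saturated_pair_capped(self):
        dm = build_distance_matrix([("a", "AAAA"), ("b", "CCCC")], "jc69")
        assert dm.d[0, 1] == 5.0

    def test_three_sequences_symmetric_zero_diagonal(self):
        dm = build_distance_matrix(
            [("a", "ACGT"), ("b", "ACGA"), ("c", "ACTT")]
        )
        assert dm.d.shape == (3, 3)
        assert np.allclose(dm.d, dm.d.T)
        assert np.all(np.diag(dm.d) == 0)


class TestNeighborJoining:
    def test_four_taxon_additive_exact_recovery(self):
        # distances generated by ((A:1,B:2):1,(C:3,D:4):1)
        labels = ["A", "B", "C", "D"]
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        tree = neighbor_joining(DistanceMatrix(labels, d))
        assert tree_splits(tree) == {frozenset({"C", "D"})}
        paths = patristic(tree)
        for (i, a), (j, b) in itertools.combinations(enumerate(labels), 2):
            assert paths[(a, b)] == pytest.approx(d[i, j])

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_additive_matrices_match_least_squares_oracle(self, n, rng):
        for _ in range(10):
            labels, d, true_splits = random_additive_matrix(n, rng)
            tree = neighbor_joining(DistanceMatrix(labels, d))
            assert tree_splits(tree) == true_splits
            # the oracle: among ALL topologies the generating one has
            # zero least-squares residual, and NJ found it
            best = min(
                least_squares_fit(edges, labels, d)
                for edges in enumerate_topologies(labels)
            )
            assert best[0] == pytest.approx(0.0, abs=1e-18)
            assert best[1] == tree_splits(tree)

    def test_label_permutation_invariance(self, rng):
        labels, d, _ = random_additive_matrix(5, rng)
        tree = neighbor_joining(DistanceMatrix(labels, d))
        perm = rng.permutation(5)
        tree_p = neighbor_joining(
            DistanceMatrix([labels[i] for i in perm], d[np.ix_(perm, perm)])
        )
        assert tree_splits(tree) == tree_splits(tree_p)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(
                DistanceMatrix(["a", "b"], np.array([[0.0, 1], [1, 0]]))
            )


class TestBootstrap:
    def make_two_clade_alignment(self, rng):
        # two 4-tip clades, 0.5 divergence between, ~0.01 within
        length = 400
        core_a = "".join("ACGT"[i] for i in rng.integers(0, 4, length))
        core_b = list(core_a)
        for pos in rng.choice(length, length // 2, replace=False):
            core_b[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[core_b[pos]]
        core_b = "".join(core_b)

        def jitter(seq):
            out = list(seq)
            for pos in rng.choice(length, 4, replace=False):
                out[pos] = {"A": "G", "C": "T", "G": "A", "T": "C"}[out[pos]]
            return "".join(out)

        return [(f"a{i}", jitter(core_a)) for i in range(4)] + [
            (f"b{i}", jitter(core_b)) for i in range(4)
        ]

    def test_clear_split_gets_high_support(self, rng):
        records = self.make_two_clade_alignment(rng)
        tree = bootstrap_support(records, n_replicates=100, seed=7)
        split = frozenset(f"b{i}" for i in range(4))
        supports = {}
        full = frozenset(lab for lab, _ in records)
        for node in tree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None or node.label is None:
                continue
            side = frozenset(x.taxon.label for x in node.leaf_iter())
            if "a0" in side:
                side = full - side
            supports[side] = int(node.label)
        assert supports[split] >= 95

    def test_single_replicate_supports_are_zero_or_hundred(self, rng):
        records = self.make_two_clade_alignment(rng)
        tree = bootstrap_support(records, n_replicates=1, seed=3)
        values = [
            int(n.label)
            for n in tree.preorder_node_iter()
            if not n.is_leaf() and n.parent_node is not None and n.label
        ]
        assert values and set(values) <= {0, 100}

    def test_fixed_seed_reproducible_and_topology_seed_free(self, rng):
        records = self.make_two_clade_alignment(rng)
        t1 = bootstrap_support(records, n_replicates=30, seed=11)
        t2 = bootstrap_support(records, n_replicates=30, seed=11)
        t3 = bootstrap_support(records, n_replicates=30, seed=99)
        labels = lambda t: {
            n.label
            for n in t.preorder_node_iter()
            if not n.is_leaf() and n.parent_node is not None
        }
        assert labels(t1) == labels(t2)
        assert tree_splits(t1) == tree_splits(t3)


class TestRooting:
    def make_tree(self):
        labels = ["A", "B", "C", "D"]
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        return neighbor_joining(DistanceMatrix(labels, d))

    def test_root_separates_outgroup_from_ingroup(self):
        tree = root_on_outgroup(self.make_tree(), "D")
        children = tree.seed_node.child_nodes()
        sides = [
            {x.taxon.label for x in c.leaf_iter()} for c in children
        ]
        assert {"D"} in sides
        assert {"A", "B", "C"} in sides

    def test_rerooting_is_idempotent(self):
        once = root_on_outgroup(self.make_tree(), "D")
        twice = root_on_outgroup(once, "D")
        assert patristic(once) == pytest.approx(patristic(twice))

    def test_patristic_distances_unchanged_by_rooting(self):
        tree = self.make_tree()
        before = patristic(tree)
        after = patristic(root_on_outgroup(tree, "C"))
        for key, val in before.items():
            assert after[key] == pytest.approx(val)

    def test_missing_outgroup_is_an_error(self):
        with pytest.raises(ValueError):
            root_on_outgroup(self.make_tree(), "Z")


class TestNewick:
    def test_basic_tree_with_support(self, tmp_path):
        path = tmp_path / "t.nwk"
        path.write_text("((A:1,B:2)90:1,C:3);\n")
        tree = read_newick(path)
        tips = sorted(x.taxon.label for x in tree.leaf_node_iter())
        assert tips == ["A", "B", "C"]
        internal = [
            n for n in tree.preorder_node_iter()
            if not n.is_leaf() and n.parent_node is not None
        ]
        assert internal[0].label == "90"

    def test_pipe_metadata_tip_parsed(self, tmp_path):
        path = tmp_path / "t.nwk"
        path.write_text("((OR407_C039|Eumastacidae|COI|clone:1,B|X|COI|ortholog:2):1,C|Y|COI|outgroup:3);\n")
        tree = read_newick(path)
        infos = [tip_info(x.taxon.label) for x in tree.leaf_node_iter()]
        assert infos[0].clone_id == "OR407_C039"
        assert infos[0].taxon == "Eumastacidae"

    def test_unbalanced_parentheses_rejected(self, tmp_path):
        path = tmp_path / "bad.nwk"
        path.write_text("((A:1,B:2):1,C:3;\n")
        with pytest.raises(Exception):
            read_newick(path)

    def test_round_trip_on_random_trees(self, rng, tmp_path):
        for k in range(20):
            n = int(rng.integers(4, 9))
            labels, d, _ = random_additive_matrix(n, rng)
            tree = neighbor_joining(DistanceMatrix(labels, d))
            path = tmp_path / f"r{k}.nwk"
            write_newick(tree, path)
            back = read_newick(path)
            assert tree_splits(back) == tree_splits(tree)
            assert patristic(back) == pytest.approx(patristic(tree), rel=1e-9)
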