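"""Distance-based tree building with bootstrap support, and Newick I/O.

The built-in engine is neighbor joining on uncorrected p or JC69
distances.  It is deliberately light-weight and deterministic: the
downstream numt classifier consumes any rooted Newick tree, so trees
inferred externally under richer models (e.g. maximum likelihood) can be
substituted at that interface; this module guarantees the pipeline is
runnable end to end without external inference.

Trees are :class:`dendropy.Tree` objects.  Tip labels follow the pipe
dialect ``id|taxon|locus|role`` so that tip metadata survives Newick
round trips; integer internal node labels are bootstrap supports.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np

from .core import Locus, Role, SequenceRecord, parse_label

__all__ = [
    "DistanceMatrix",
    "TipInfo",
    "tip_info",
    "build_distance_matrix",
    "pairwise_distance_matrix",
    "neighbor_joining",
    "bootstrap_support",
    "root_on_outgroup",
    "read_newick",
    "write_newick",
    "tree_splits",
    "JC69_SATURATION_CAP",
]

JC69_SATURATION_CAP = 5.0

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class TipInfo:
    clone_id: str
    taxon: str
    locus: Locus
    role: Role


def tip_info(label: str) -> TipInfo:
    """Parse a pipe-dialect tip label into its metadata fields."""
    rid, taxon, locus, role = parse_label(label)
    return TipInfo(clone_id=rid, taxon=taxon, locus=locus, role=role)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with ordered tip labels."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("matrix not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("nonzero diagonal")
        if not np.all(np.isfinite(self.d)) or np.any(self.d < 0):
            raise ValueError("distances must be finite and nonnegative")


def _encode(seqs: Sequence[str]) -> np.ndarray:
    length = len(seqs[0])
    arr = np.full((len(seqs), length), 4, dtype=np.uint8)
    for i, s in enumerate(seqs):
        if len(s) != length:
            raise ValueError("aligned sequences must share one length")
        for j, ch in enumerate(s):
            arr[i, j] = _CODE.get(ch, 4)
    return arr


def _pairwise_p(arr: np.ndarray, i: int, j: int) -> float:
    ok = (arr[i] < 4) & (arr[j] < 4)
    n_ok = int(ok.sum())
    if n_ok == 0:
        raise ValueError(f"sequences {i} and {j} share no comparable column")
    return float((arr[i][ok] != arr[j][ok]).sum()) / n_ok


def _jc69(p: float, cap: float) -> float:
    if p >= 0.75:
        return cap
    return min(cap, -0.75 * np.log1p(-(4.0 / 3.0) * p))


def build_distance_matrix(
    records: Sequence[SequenceRecord] | Sequence[tuple[str, str]],
    model: str = "p",
    *,
    saturation_cap: float = JC69_SATURATION_CAP,
) -> DistanceMatrix:
    """Pairwise distances from an alignment under ``p`` or ``jc69``.

    Pairwise deletion: gap and N columns are excluded per pair.  Under
    JC69, saturated pairs (p >= 0.75, where the correction diverges) are
    set to ``saturation_cap`` substitutions/site.
    """
    if model not in ("p", "jc69"):
        raise ValueError(f"unknown model {model!r}")
    if isinstance(records[0], SequenceRecord):
        labels = [r.label() for r in records]
        seqs = [r.residues for r in records]
    else:
        labels = [lab for lab, _ in records]
        seqs = [s for _, s in records]
    arr = _encode(seqs)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = _pairwise_p(arr, i, j)
            d[i, j] = d[j, i] = p if model == "p" else _jc69(p, saturation_cap)
    return DistanceMatrix(labels=labels, d=d)


def pairwise_distance_matrix(
    records: Sequence[SequenceRecord],
    model: str = "p",
    *,
    saturation_cap: float = JC69_SATURATION_CAP,
) -> DistanceMatrix:
    """Distances from *unaligned* sequences via pairwise global alignment.

    Each pair is aligned independently (free end gaps on the shorter
    role); useful when indels make a common alignment unavailable.
    """
    from .characterize import align_pair, p_distance as aln_p_distance

    labels = [r.label() for r in records]
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = align_pair(records[i].degapped, records[j].degapped)
            p = aln_p_distance(aln)
            d[i, j] = d[j, i] = p if model == "p" else _jc69(p, saturation_cap)
    return DistanceMatrix(labels=labels, d=d)


def neighbor_joining(m: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion are broken by label order.  Negative branch
    lengths are clamped to zero with the deficit transferred to the
    sister branch, so path lengths through each cherry are preserved.
    The returned tree is unrooted in spirit; it is stored with an
    arbitrary bifurcating root whose two child edges split the final
    join length equally.
    """
    n = len(m.labels)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 tips")
    taxa = dendropy.TaxonNamespace(m.labels)
    nodes = []
    for label in m.labels:
        node = dendropy.Node()
        node.taxon = taxa.get_taxon(label)
        nodes.append(node)
    # sort keys: smallest original label of each cluster, for tie-breaks
    keys = list(m.labels)
    d = m.d.copy()
    active = list(range(n))

    while len(active) > 2:
        k = len(active)
        r = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(k):
            for aj in range(ai + 1, k):
                i, j = active[ai], active[aj]
                q = (k - 2) * d[i, j] - r[i] - r[j]
                tie = tuple(sorted((keys[i], keys[j])))
                cand = (q, tie, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        bi = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (k - 2))
        bj = d[i, j] - bi
        # clamp negatives, moving the deficit onto the sister branch
        if bi < 0:
            bj += bi
            bi = 0.0
        if bj < 0:
            bi += bj
            bj = 0.0
        bi, bj = max(bi, 0.0), max(bj, 0.0)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = bi
        nodes[j].edge.length = bj
        # distances from the new cluster u to every other active cluster
        new_row = np.zeros(d.shape[0] + 1)
        for x in active:
            if x in (i, j):
                continue
            new_row[x] = 0.5 * (d[i, x] + d[j, x] - d[i, j])
        d = np.pad(d, ((0, 1), (0, 1)))
        u = d.shape[0] - 1
        d[u, :-1] = new_row[:-1]
        d[:-1, u] = new_row[:-1]
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))
        active = [x for x in active if x not in (i, j)] + [u]

    i, j = active
    root = dendropy.Node()
    root.add_child(nodes[i])
    root.add_child(nodes[j])
    half = max(d[i, j], 0.0) / 2
    nodes[i].edge.length = half
    nodes[j].edge.length = half
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    tree.is_rooted = True
    return tree


def tree_splits(tree: dendropy.Tree, *, nontrivial_only: bool = True) -> set[frozenset]:
    """Unrooted bipartitions, each encoded as the side of the split that
    does not contain the lexicographically smallest tip label."""
    leaves = sorted(x.taxon.label for x in tree.leaf_node_iter())
    anchor = leaves[0]
    full = frozenset(leaves)
    splits: set[frozenset] = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(x.taxon.label for x in node.leaf_iter())
        if anchor in side:
            side = full - side
        if nontrivial_only and (len(side) < 2 or len(side) > len(full) - 2):
            continue
        splits.add(side)
    return splits


def bootstrap_support(
    records: Sequence[SequenceRecord] | Sequence[tuple[str, str]],
    n_replicates: int = 1000,
    seed: int = 0,
    model: str = "p",
) -> dendropy.Tree:
    """NJ point-estimate tree with bootstrap supports on internal nodes.

    Alignment columns are resampled with replacement ``n_replicates``
    times; support is the percentage of replicate NJ trees containing
    each internal bipartition of the point-estimate tree, stored as an
    integer node label.  The point-estimate topology itself does not
    depend on the seed.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if isinstance(records[0], SequenceRecord):
        pairs = [(r.label(), r.residues) for r in records]
    else:
        pairs = list(records)
    tree = neighbor_joining(build_distance_matrix(pairs, model))
    length = len(pairs[0][1])
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {s: 0 for s in tree_splits(tree)}
    labels = [lab for lab, _ in pairs]
    seqs = [s for _, s in pairs]
    for _ in range(n_replicates):
        cols = rng.integers(0, length, size=length)
        resampled = [
            (lab, "".join(s[c] for c in cols)) for lab, s in zip(labels, seqs)
        ]
        try:
            rep_tree = neighbor_joining(build_distance_matrix(resampled, model))
        except ValueError:  # a pair with no comparable resampled column
            continue
        rep_splits = tree_splits(rep_tree)
        for s in counts:
            if s in rep_splits:
                counts[s] += 1

    leaves_sorted = sorted(labels)
    anchor = leaves_sorted[0]
    full = frozenset(leaves_sorted)
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(x.taxon.label for x in node.leaf_iter())
        if anchor in side:
            side = full - side
        if side in counts:
            node.label = str(round(100 * counts[side] / n_replicates))
    return tree


def root_on_outgroup(tree: dendropy.Tree, outgroup: str) -> dendropy.Tree:
    """Root (a copy of) the tree at the midpoint of the outgroup's
    terminal branch.  ``outgroup`` is the full tip label."""
    tree = tree.clone(depth=1)
    tip = None
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label == outgroup:
            tip = leaf
            break
    if tip is None:
        raise ValueError(f"outgroup tip {outgroup!r} not found")
    edge = tip.edge
    length = edge.length or 0.0
    if tip.parent_node is tree.seed_node and len(tree.seed_node.child_nodes()) == 2:
        # already rooted on this terminal branch; just rebalance to midpoint
        sibling = [c for c in tree.seed_node.child_nodes() if c is not tip][0]
        total = length + (sibling.edge.length or 0.0)
        tip.edge.length = total / 2
        sibling.edge.length = total / 2
        tree.is_rooted = True
        return tree
    tree.reroot_at_edge(edge, length1=length / 2, length2=length / 2)
    tree.is_rooted = True
    # rerooting can leave the old root as a degree-2 node; remove it
    tree.suppress_unifurcations()
    return tree


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a Newick tree; integer internal node labels are supports."""
    tree = dendropy.Tree.get(
        path=str(path),
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    labels = [x.taxon.label for x in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValueError(f"duplicate tip labels in {path}")
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    """Write Newick with branch lengths (10 significant digits) and
    internal node labels (supports)."""
    text = tree.as_string(
        schema="newick",
        unquoted_underscores=True,
        suppress_rooting=True,
        real_value_format_specifier=".10g",
    )
    Path(path).write_text(text)
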