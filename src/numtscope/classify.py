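"""Stage 2: tree-based classification and dating of numts.

Numts fall into two classes by their placement relative to the
contemporary mitochondrial ortholog:

* **neonumt** — a recent insertion that still clusters with the ortholog,
  typically in a polytomy; operationally, no other taxon's ortholog (or
  the outgroup) branches off the path between the numt and the focal
  ortholog, and the *internal* path between them (patristic distance
  minus both terminal branches) is at most ``delta`` substitutions/site.  A long
  terminal branch alone never disqualifies a neonumt: an insertion into
  a fast-evolving nuclear region lengthens only the terminal branch.
* **paleonumt** — everything else: insertions predating the contemporary
  mitochondrial haplotype, attaching outside the species clade or deep
  within it.

Numt-only clades spanning two or more species ("synaponumts") indicate
insertion in the most recent common ancestor of those species; a fossil
calibration table bounding the age of that ancestor then yields a
maximum insertion age.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import dendropy
import pandas as pd

from .core import Role
from .phylo import TipInfo, tip_info

__all__ = [
    "Verdict",
    "NumtClassification",
    "SynaponumtClade",
    "CalibrationRow",
    "FossilCalibration",
    "DatedInsertion",
    "classify_numts",
    "tally_classes",
    "detect_synaponumts",
    "date_insertion",
    "collapse_weak_edges",
    "DEFAULT_EPSILON",
    "DEFAULT_DELTA",
    "DEFAULT_SUPPORT_MIN",
]

DEFAULT_EPSILON = 1e-6  # branch lengths below this collapse into polytomies
DEFAULT_DELTA = 0.02  # max internal path (subs/site) for a neonumt verdict
DEFAULT_SUPPORT_MIN = 50  # bootstrap % below which an edge is collapsed


@dataclass(frozen=True)
class NumtClassification:
    clone_id: str
    verdict: str  # "paleonumt" | "neonumt"
    internal_path_to_ortholog: float
    terminal_branch_length: float
    within_species_clade: bool
    support_at_attachment: int | None = None


class Verdict:
    PALEONUMT = "paleonumt"
    NEONUMT = "neonumt"


@dataclass
class SynaponumtClade:
    member_clone_ids: list[str]
    member_species: set[str]
    support: int | None
    member_distance_to_ortholog: dict[str, float]
    mrca_label: str

    @property
    def n_species(self) -> int:
        return len(self.member_species)


@dataclass(frozen=True)
class CalibrationRow:
    species_set: frozenset[str]
    fossil_group: str
    age_min_my: float
    age_max_my: float
    citation: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.age_min_my <= self.age_max_my:
            raise ValueError("calibration ages must be positive with min <= max")


@dataclass
class FossilCalibration:
    """A table of fossil age constraints on species-set ancestors."""

    rows: list[CalibrationRow]

    @classmethod
    def from_csv(cls, path: str | Path) -> "FossilCalibration":
        """CSV columns: species_set (semicolon-joined), fossil_group,
        age_min_my, age_max_my, citation."""
        frame = pd.read_csv(path)
        rows = [
            CalibrationRow(
                species_set=frozenset(
                    s.strip() for s in str(rec.species_set).split(";") if s.strip()
                ),
                fossil_group=str(rec.fossil_group),
                age_min_my=float(rec.age_min_my),
                age_max_my=float(rec.age_max_my),
                citation=str(getattr(rec, "citation", "")),
            )
            for rec in frame.itertuples(index=False)
        ]
        return cls(rows=rows)


@dataclass(frozen=True)
class DatedInsertion:
    calibrated: bool
    age_min_my: float | None = None
    age_max_my: float | None = None
    row: CalibrationRow | None = None


def _node_support(node: dendropy.Node) -> int | None:
    label = getattr(node, "label", None)
    if label is None:
        return None
    try:
        return int(round(float(label)))
    except (TypeError, ValueError):
        return None


def _leaf_infos(tree: dendropy.Tree) -> dict[dendropy.Node, TipInfo]:
    return {leaf: tip_info(leaf.taxon.label) for leaf in tree.leaf_node_iter()}


def collapse_weak_edges(
    tree: dendropy.Tree,
    epsilon: float = DEFAULT_EPSILON,
    support_min: int | None = DEFAULT_SUPPORT_MIN,
) -> dendropy.Tree:
    """Collapse internal edges shorter than ``epsilon`` or with bootstrap
    support below ``support_min`` into polytomies (on a copy).

    An edge with no support annotation is collapsed on length alone.
    The collapsed edge's length is added to the child edges so
    root-to-tip path lengths are preserved.
    """
    tree = tree.clone(depth=1)
    to_collapse = []
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        length = node.edge.length or 0.0
        support = _node_support(node)
        weak_support = (
            support_min is not None and support is not None and support < support_min
        )
        if length < epsilon or weak_support:
            to_collapse.append(node)
    for node in to_collapse:
        parent = node.parent_node
        length = node.edge.length or 0.0
        for child in list(node.child_nodes()):
            node.remove_child(child)
            parent.add_child(child)
            child.edge.length = (child.edge.length or 0.0) + length
        parent.remove_child(node)
    return tree


def _patristic(tree: dendropy.Tree) -> dict[tuple[str, str], float]:
    pdm = tree.phylogenetic_distance_matrix()
    out: dict[tuple[str, str], float] = {}
    taxa = [leaf.taxon for leaf in tree.leaf_node_iter()]
    for i, t1 in enumerate(taxa):
        for t2 in taxa[i + 1 :]:
            val = float(pdm.patristic_distance(t1, t2))
            out[(t1.label, t2.label)] = val
            out[(t2.label, t1.label)] = val
    return out


def classify_numts(
    tree: dendropy.Tree,
    focal_taxon: str,
    epsilon: float = DEFAULT_EPSILON,
    delta: float = DEFAULT_DELTA,
    support_min: int | None = DEFAULT_SUPPORT_MIN,
) -> list[NumtClassification]:
    """Assign a paleonumt/neonumt verdict to every focal-taxon numt tip.

    The tree must be rooted (outgroup rooting upstream) and contain
    exactly one ortholog tip for ``focal_taxon``.  Weak edges are first
    collapsed (see :func:`collapse_weak_edges`); the verdict rule is then
    purely topological plus the internal-path threshold ``delta``.
    """
    work = collapse_weak_edges(tree, epsilon=epsilon, support_min=support_min)
    infos = _leaf_infos(work)
    ortho_tips = [
        leaf
        for leaf, info in infos.items()
        if info.role is Role.ORTHOLOG and info.taxon == focal_taxon
    ]
    if len(ortho_tips) != 1:
        raise ValueError(
            f"expected exactly one ortholog tip for {focal_taxon!r}, "
            f"found {len(ortho_tips)}"
        )
    ortho = ortho_tips[0]
    numt_tips = [
        leaf
        for leaf, info in infos.items()
        if info.role is Role.CLONE and info.taxon == focal_taxon
    ]
    dist = _patristic(work)

    def ancestors_below(node: dendropy.Node, stop: dendropy.Node) -> list:
        out = []
        cursor = node.parent_node
        while cursor is not None and cursor is not stop:
            out.append(cursor)
            cursor = cursor.parent_node
        return out

    def has_foreign_ortholog(node: dendropy.Node) -> bool:
        return any(
            infos[leaf].role in (Role.ORTHOLOG, Role.OUTGROUP)
            and infos[leaf].taxon != focal_taxon
            for leaf in node.leaf_iter()
        )

    results = []
    for q in sorted(numt_tips, key=lambda x: x.taxon.label):
        mrca = work.mrca(taxa=[q.taxon, ortho.taxon])
        # the numt shares a (possibly polytomous) clade with the ortholog
        # unless another taxon's ortholog branches off the path between
        # them, i.e. hangs off a node strictly inside the connecting clade
        path_nodes = set(ancestors_below(q, mrca)) | set(
            ancestors_below(ortho, mrca)
        )
        on_path = path_nodes | {q, ortho, mrca}
        foreign_ortholog = any(
            has_foreign_ortholog(child)
            for node in path_nodes
            for child in node.child_nodes()
            if child not in on_path
        )
        term_q = q.edge.length or 0.0
        term_o = ortho.edge.length or 0.0
        internal = max(dist[(q.taxon.label, ortho.taxon.label)] - term_q - term_o, 0.0)
        within = not foreign_ortholog
        verdict = (
            Verdict.NEONUMT if within and internal <= delta else Verdict.PALEONUMT
        )
        results.append(
            NumtClassification(
                clone_id=infos[q].clone_id,
                verdict=verdict,
                internal_path_to_ortholog=internal,
                terminal_branch_length=term_q,
                within_species_clade=within,
                support_at_attachment=_node_support(q.parent_node),
            )
        )
    return results


def tally_classes(
    classified: Iterable[tuple[str, str, str]],
) -> pd.DataFrame:
    """Tally (taxon, locus, verdict) triples into per-taxon/locus counts.

    Returns a DataFrame with columns taxon, locus, n_paleonumt,
    n_neonumt plus a per-locus ``Total`` row.
    """
    frame = pd.DataFrame(classified, columns=["taxon", "locus", "verdict"])
    if frame.empty:
        return pd.DataFrame(
            columns=["taxon", "locus", "n_paleonumt", "n_neonumt"]
        )
    counts = (
        frame.groupby(["taxon", "locus", "verdict"]).size().unstack(fill_value=0)
    )
    for col in (Verdict.PALEONUMT, Verdict.NEONUMT):
        if col not in counts:
            counts[col] = 0
    counts = counts.rename(
        columns={Verdict.PALEONUMT: "n_paleonumt", Verdict.NEONUMT: "n_neonumt"}
    )[["n_paleonumt", "n_neonumt"]].reset_index()
    totals = (
        counts.groupby("locus")[["n_paleonumt", "n_neonumt"]]
        .sum()
        .reset_index()
        .assign(taxon="Total")
    )
    return pd.concat([counts, totals], ignore_index=True)[
        ["taxon", "locus", "n_paleonumt", "n_neonumt"]
    ]


def detect_synaponumts(
    tree: dendropy.Tree,
    min_species: int = 2,
    support_min: int | None = DEFAULT_SUPPORT_MIN,
) -> list[SynaponumtClade]:
    """Find maximal numt-only clades spanning >= ``min_species`` species.

    A candidate clade contains only clone-role tips, spans at least
    ``min_species`` distinct taxa, and (when support annotations are
    present) has support >= ``support_min``.  Only candidates with no
    candidate ancestor are reported, so the output is pairwise
    non-nested.  Low-support multi-species numt clades can reflect
    long-branch artifacts; interpret supports accordingly.
    """
    infos = _leaf_infos(tree)
    dist = _patristic(tree)
    ortho_by_taxon = {
        info.taxon: leaf.taxon.label
        for leaf, info in infos.items()
        if info.role is Role.ORTHOLOG
    }

    def is_candidate(node: dendropy.Node) -> bool:
        if node.is_leaf() or node.parent_node is None:
            return False
        leaves = list(node.leaf_iter())
        if any(infos[x].role is not Role.CLONE for x in leaves):
            return False
        species = {infos[x].taxon for x in leaves}
        if len(species) < min_species:
            return False
        support = _node_support(node)
        if support_min is not None and support is not None and support < support_min:
            return False
        return True

    clades = []
    stack = [(tree.seed_node, False)]
    while stack:
        node, ancestor_hit = stack.pop()
        if is_candidate(node) and not ancestor_hit:
            leaves = sorted(node.leaf_iter(), key=lambda x: x.taxon.label)
            members = [infos[x].clone_id for x in leaves]
            species = {infos[x].taxon for x in leaves}
            member_dist = {}
            for leaf in leaves:
                own = ortho_by_taxon.get(infos[leaf].taxon)
                if own is not None:
                    member_dist[infos[leaf].clone_id] = dist[
                        (leaf.taxon.label, own)
                    ]
            clades.append(
                SynaponumtClade(
                    member_clone_ids=members,
                    member_species=species,
                    support=_node_support(node),
                    member_distance_to_ortholog=member_dist,
                    mrca_label="+".join(sorted(species)),
                )
            )
            ancestor_hit = True
        for child in node.child_nodes():
            stack.append((child, ancestor_hit))
    clades.sort(key=lambda c: c.mrca_label)
    return clades


def date_insertion(
    clade: SynaponumtClade | Iterable[str],
    calib: FossilCalibration,
) -> DatedInsertion:
    """Maximum insertion age for a multi-species numt clade.

    The most specific calibration row whose species set covers the
    clade's species set is used (smallest covering set; ties broken by
    smaller maximum age).  The fossil interval bounds the age of the
    clade's MRCA and hence the latest epoch by which the shared
    insertion must have happened.  With no covering row the result is
    uncalibrated, not an error.
    """
    species = (
        clade.member_species
        if isinstance(clade, SynaponumtClade)
        else set(clade)
    )
    covering = [row for row in calib.rows if species <= row.species_set]
    if not covering:
        return DatedInsertion(calibrated=False)
    best = min(covering, key=lambda r: (len(r.species_set), r.age_max_my))
    return DatedInsertion(
        calibrated=True,
        age_min_my=best.age_min_my,
        age_max_my=best.age_max_my,
        row=best,
    )
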