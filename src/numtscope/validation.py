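"""Simulation-based calibration experiments for the pipeline.

Because the verdicts of the tree-based classifier have no closed-form
accuracy, the package validates its default thresholds against the
simulator's ground truth: planted insertions of known age must be
recovered as neonumts/paleonumts, planted ancestral insertions must be
recovered as multi-species synaponumt clades, and the matched-pairs
symmetry test must hold its nominal type-I error rate under a
stationary, time-reversible null.
"""

from __future__ import annotations

import numpy as np

from .characterize import PairwiseAlignment, bowker_symmetry_test
from .classify import classify_numts, detect_synaponumts
from .pipeline import infer_tree
from .simulate import (
    SimulationConfig,
    _draw_stationary,
    evolve_sequence,
    numt_truth_class,
    simulate,
    simulate_species_tree,
)

__all__ = [
    "classifier_concordance",
    "synaponumt_detection_rate",
    "bowker_type_i_rate",
]


def _shortest_terminal_taxon(seed: int, n_taxa: int, root_age: float) -> str:
    """Focal taxon = tip with the shortest terminal branch, so that an
    old planted insertion falls on an ancestral branch."""
    tree = simulate_species_tree(n_taxa, root_age, seed)
    leaf = min(
        tree.leaf_node_iter(), key=lambda x: (x.edge.length, x.taxon.label)
    )
    return leaf.taxon.label


def classifier_concordance(
    n_replicates: int = 100,
    seed: int = 0,
    *,
    young_age: float = 0.1,
    old_age: float = 50.0,
    n_taxa: int = 6,
    root_age: float = 100.0,
) -> tuple[float, int]:
    """Truth-vs-verdict concordance for planted insertions of known age.

    Per replicate: a Yule species tree, one insertion at ``young_age``
    MY (on the focal terminal branch; true neonumt) and one at
    ``old_age`` MY on the focal lineage (ancestral whenever the focal
    terminal branch is younger; true paleonumt), NJ on the numt +
    ortholog + outgroup alignment, outgroup rooting, classification at
    default thresholds.  Returns (concordance, n classified).
    """
    ok = total = 0
    for rep in range(n_replicates):
        rep_seed = seed + rep
        focal = _shortest_terminal_taxon(rep_seed, n_taxa, root_age)
        cfg = SimulationConfig(
            seed=rep_seed,
            n_taxa=n_taxa,
            root_age=root_age,
            insertion_rate=0.0,
            indel_rate=0.0,
            duplication_rate=0.0,
            retention_prob=1.0,
            clones_per_sample=0,
            planted_insertions=((young_age, focal), (old_age, focal)),
        )
        result = simulate(cfg)
        records = result.ortholog_records() + result.numt_records(taxa=[focal])
        tree = infer_tree(records)
        truth = {
            c.copy_id: numt_truth_class(c, result.numts)
            for c in result.numts
            if c.taxon == focal
        }
        for cls in classify_numts(tree, focal):
            expected = truth[cls.clone_id]
            # a shared ancestral copy is still an old (paleo) insertion
            # from the focal taxon's standpoint
            if expected == "synaponumt-member":
                expected = "paleonumt"
            total += 1
            ok += expected == cls.verdict
    return ok / total, total


def synaponumt_detection_rate(
    n_replicates: int = 100,
    seed: int = 0,
    *,
    n_taxa: int = 6,
    root_age: float = 100.0,
    bootstrap: int = 100,
) -> tuple[float, int]:
    """Recovery rate of a planted ancestral insertion as a synaponumt.

    Per replicate the insertion is planted just above the most recent
    speciation node (so it is shared by >= 2 species) with retention 1;
    detection requires a supported numt-only clade spanning >= 2
    species on the bootstrapped NJ tree.
    """
    hits = 0
    for rep in range(n_replicates):
        rep_seed = seed + rep
        tree = simulate_species_tree(n_taxa, root_age, rep_seed)
        node = min(
            (x for x in tree.preorder_node_iter() if not x.is_leaf()),
            key=lambda x: x.age,
        )
        carrier = next(iter(node.leaf_iter())).taxon.label
        parent_age = (
            node.parent_node.age if node.parent_node is not None else root_age
        )
        age = min(node.age + 10.0, (node.age + parent_age) / 2)
        cfg = SimulationConfig(
            seed=rep_seed,
            n_taxa=n_taxa,
            root_age=root_age,
            insertion_rate=0.0,
            indel_rate=0.0,
            duplication_rate=0.0,
            retention_prob=1.0,
            clones_per_sample=0,
            planted_insertions=((age, carrier),),
        )
        result = simulate(cfg)
        records = result.ortholog_records() + result.numt_records()
        inferred = infer_tree(records, bootstrap=bootstrap, seed=rep_seed)
        clades = detect_synaponumts(inferred, min_species=2)
        hits += any(len(c.member_species) >= 2 for c in clades)
    return hits / n_replicates, n_replicates


def bowker_type_i_rate(
    n_pairs: int = 1000,
    seed: int = 0,
    *,
    length: int = 600,
    divergence_my: float = 10.0,
    rate: float = 0.01,
    base_freqs: tuple[float, float, float, float] = (0.35, 0.15, 0.15, 0.35),
    kappa: float = 4.0,
    alpha: float = 0.05,
) -> tuple[float, int]:
    """Rejection rate of the symmetry test under its null.

    Pairs of sequences evolved independently from a stationary ancestor
    under time-reversible HKY have a symmetric expected divergence
    matrix, so rejections at ``alpha`` are type-I errors.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_pairs):
        ancestor = "".join(
            "ACGT"[b] for b in _draw_stationary(length, base_freqs, rng)
        )
        left = evolve_sequence(ancestor, divergence_my, rate, base_freqs,
                               kappa, rng)
        right = evolve_sequence(ancestor, divergence_my, rate, base_freqs,
                                kappa, rng)
        res = bowker_symmetry_test(PairwiseAlignment(left, right))
        rejections += res.p < alpha
    return rejections / n_pairs, n_pairs
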