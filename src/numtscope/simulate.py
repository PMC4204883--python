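"""Forward simulation of mtDNA evolution with numt insertion.

The generator emulates the data a PCR-cloning survey of nuclear
mitochondrial pseudogenes produces: for each taxon of a species tree it
emits a mitochondrial ortholog and a set of cloned sequences that are a
mixture of the ortholog and numts of varying insertion age, together
with per-clone ground truth.

Two evolutionary regimes are simulated.  The mitochondrial lineage
evolves fast under an HKY model stationary at an AT-rich composition
(default 70% AT), optionally with a codon-aware mask that keeps the
ortholog free of in-frame stop codons (purifying selection on an intact
gene).  Once inserted into the nucleus, a numt evolves slowly
(``nuclear_rate_multiplier`` x the mitochondrial rate, default 0.1)
toward a uniform nuclear base composition, and is exposed to indels and
duplication — so old numts show decayed AT bias, frameshifts and
premature stops, while the ortholog does not.  Cloning adds independent
per-clone polymerase errors at 0.015% per bp by default, matching the
fidelity of a proofreading enzyme mix (0.0987 expected errors on a
658-bp COI barcode fragment).

Times are in MY; substitution distances are rate x MY in
substitutions/site.  All randomness flows from one seeded generator, so
a fixed seed gives byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.linalg import expm

from .core import Locus, Role, SequenceRecord, write_fasta
from .phylo import write_newick

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "NumtCopy",
    "simulate_species_tree",
    "hky_rate_matrix",
    "hky_transition_matrix",
    "evolve_sequence",
    "simulate",
]

BASES = "ACGT"
_STOPS_T5 = ("TAA", "TAG")  # invertebrate mitochondrial code


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated survey.

    Defaults mirror the cloning survey the package models: ~50 clones
    per PCR, a 658-bp COI-style fragment, 0.015% per-bp polymerase
    error, AT-rich mitochondrial composition, and an order-of-magnitude
    slower nuclear substitution regime.
    """

    n_taxa: int = 6
    root_age: float = 100.0
    seq_length: int = 658
    mito_rate: float = 0.01  # subs/site/MY per lineage
    mito_base_freqs: tuple[float, float, float, float] = (0.35, 0.15, 0.15, 0.35)
    kappa: float = 4.0
    nuclear_rate_multiplier: float = 0.1
    nuclear_base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    insertion_rate: float = 0.02  # events/lineage/MY
    duplication_rate: float = 0.005  # events/numt-lineage/MY
    indel_rate: float = 2e-5  # events/site/MY, nuclear regime only
    indel_length_mean: float = 3.0  # geometric mean indel length
    retention_prob: float = 0.9  # per daughter lineage at each speciation
    clones_per_sample: int = 50
    ortholog_clone_weight: float = 0.6
    pcr_error_rate: float = 0.00015
    outgroup_stem_factor: float = 1.5
    codon_aware_mito: bool = True
    locus: str = "COI"
    seed: int = 0
    #: extra insertions forced onto the root-to-taxon path at given ages:
    #: tuples of (age MY, taxon label)
    planted_insertions: tuple[tuple[float, str], ...] = ()

    def __post_init__(self) -> None:
        for freqs in (self.mito_base_freqs, self.nuclear_base_freqs):
            if abs(sum(freqs) - 1.0) > 1e-9:
                raise ValueError("base frequencies must sum to 1")
        for name in (
            "mito_rate",
            "nuclear_rate_multiplier",
            "insertion_rate",
            "duplication_rate",
            "indel_rate",
            "pcr_error_rate",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class NumtCopy:
    """One numt copy surviving to the present in one taxon's genome."""

    taxon: str
    copy_id: str
    origin_id: str  # shared by all copies descending from one insertion
    insertion_age: float
    insertion_branch: str  # label of the node below the insertion point
    insertion_on_terminal: bool
    sequence: str


@dataclass
class SimulationResult:
    config: SimulationConfig
    species_tree: dendropy.Tree
    orthologs: dict[str, str]
    outgroup: str
    numts: list[NumtCopy]
    clones: list[SequenceRecord]
    truth: pd.DataFrame

    def clone_records(self) -> list[SequenceRecord]:
        return list(self.clones)

    def ortholog_records(self, include_outgroup: bool = True) -> list[SequenceRecord]:
        locus = Locus.parse(self.config.locus)
        records = [
            SequenceRecord(
                id=f"mt_{taxon}", taxon=taxon, locus=locus, role=Role.ORTHOLOG,
                residues=seq,
            )
            for taxon, seq in sorted(self.orthologs.items())
        ]
        if include_outgroup:
            records.append(
                SequenceRecord(
                    id="mt_outgroup", taxon="Outgroup", locus=locus,
                    role=Role.OUTGROUP, residues=self.outgroup,
                )
            )
        return records

    def numt_records(self, taxa: Sequence[str] | None = None) -> list[SequenceRecord]:
        """One record per surviving numt copy (no PCR noise)."""
        locus = Locus.parse(self.config.locus)
        return [
            SequenceRecord(
                id=c.copy_id, taxon=c.taxon, locus=locus, role=Role.CLONE,
                residues=c.sequence,
            )
            for c in self.numts
            if taxa is None or c.taxon in taxa
        ]

    def write(self, outdir: str | Path) -> None:
        """Write clones FASTA, orthologs FASTA, truth TSV, species tree."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.clones, outdir / "clones.fasta")
        write_fasta(self.ortholog_records(), outdir / "orthologs.fasta")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        write_newick(self.species_tree, outdir / "species_tree.nwk")


# ---------------------------------------------------------------------------
# species tree


def simulate_species_tree(
    n_taxa: int,
    root_age: float,
    seed: int | np.random.Generator = 0,
) -> dendropy.Tree:
    """Pure-birth (Yule) tree on ``n_taxa`` tips rescaled to ``root_age``.

    Ultrametric; every node carries an ``age`` attribute in MY before
    present (tips at 0, root at ``root_age``).
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # forward simulation in arbitrary time units
    split_times = []
    t = 0.0
    for k in range(1, n_taxa):
        t += rng.exponential(1.0 / k)
        split_times.append(t)
    t_end = split_times[-1] + rng.exponential(1.0 / n_taxa)
    scale = root_age / (t_end - split_times[0])
    node_ages = [(t_end - s) * scale for s in split_times]  # ages before present

    taxa = dendropy.TaxonNamespace([f"tax{i + 1}" for i in range(n_taxa)])
    return _build_yule(n_taxa, node_ages, rng, taxa)


def _build_yule(
    n_taxa: int,
    node_ages: list[float],
    rng: np.random.Generator,
    taxa: dendropy.TaxonNamespace,
) -> dendropy.Tree:
    def split(parent: dendropy.Node) -> list[dendropy.Node]:
        children = [dendropy.Node(), dendropy.Node()]
        for child in children:
            parent.add_child(child)
        return children

    root = dendropy.Node()
    root.age = node_ages[0]
    active = split(root)  # the first split IS the root
    for age in node_ages[1:]:
        idx = int(rng.integers(len(active)))
        node = active.pop(idx)
        node.age = age
        active.extend(split(node))
    tip_idx = 0
    for node in root.preorder_iter():
        if node.num_child_nodes() == 0:
            node.age = 0.0
            node.taxon = taxa.get_taxon(f"tax{tip_idx + 1}")
            tip_idx += 1
    for node in root.preorder_iter():
        if node.parent_node is not None:
            node.edge.length = node.parent_node.age - node.age
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# HKY machinery


def hky_rate_matrix(
    base_freqs: Sequence[float], kappa: float
) -> np.ndarray:
    """HKY85 instantaneous rate matrix scaled to one expected
    substitution per site per unit distance (order A, C, G, T)."""
    pi = np.asarray(base_freqs, dtype=float)
    q = np.zeros((4, 4))
    transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            q[i, j] = pi[j] * (kappa if (i, j) in transitions else 1.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    mu = -float(np.dot(pi, np.diag(q)))
    return q / mu


def hky_transition_matrix(
    distance: float, base_freqs: Sequence[float], kappa: float
) -> np.ndarray:
    """P(d) = exp(Q d) for a branch of ``distance`` substitutions/site."""
    return expm(hky_rate_matrix(base_freqs, kappa) * distance)


def _draw_stationary(
    length: int, base_freqs: Sequence[float], rng: np.random.Generator
) -> np.ndarray:
    return rng.choice(4, size=length, p=np.asarray(base_freqs, float))


def _substitute(
    codes: np.ndarray, p_matrix: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    cum = np.cumsum(p_matrix, axis=1)
    u = rng.random(codes.shape[0])
    return (u[:, None] > cum[codes]).sum(axis=1).astype(codes.dtype)


def _mask_stops(child: np.ndarray, parent: np.ndarray) -> np.ndarray:
    """Revert codons that became in-frame stops to the parent codon —
    a rejection stand-in for purifying selection on the ortholog."""
    out = child.copy()
    for start in range(0, 3 * (len(out) // 3), 3):
        codon = "".join(BASES[b] for b in out[start : start + 3])
        if codon in _STOPS_T5:
            out[start : start + 3] = parent[start : start + 3]
    return out


def evolve_sequence(
    seq: str | np.ndarray,
    duration: float,
    rate: float,
    base_freqs: Sequence[float],
    kappa: float,
    rng: np.random.Generator,
    *,
    codon_mask: bool = False,
) -> str | np.ndarray:
    """Evolve a sequence for ``duration`` MY at ``rate`` subs/site/MY
    under HKY, using exact per-branch transition probabilities.

    With ``codon_mask`` any codon that would become an in-frame stop
    (invertebrate mitochondrial code) reverts to its parental state.
    Accepts and returns either a string or an internal code array.
    """
    as_str = isinstance(seq, str)
    codes = (
        np.frombuffer(seq.encode(), dtype=np.uint8) if as_str else seq
    )
    if as_str:
        lut = np.zeros(256, dtype=np.uint8)
        for i, b in enumerate(BASES):
            lut[ord(b)] = i
        codes = lut[codes]
    d = rate * duration
    if d == 0:
        out = codes.copy()
    else:
        out = _substitute(codes, hky_transition_matrix(d, base_freqs, kappa), rng)
        if codon_mask:
            out = _mask_stops(out, codes)
    if as_str:
        return "".join(BASES[b] for b in out)
    return out


def _apply_indels(
    codes: np.ndarray,
    duration: float,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    lam = config.indel_rate * len(codes) * duration
    if lam <= 0:
        return codes
    n_events = rng.poisson(lam)
    for _ in range(n_events):
        length = int(rng.geometric(1.0 / config.indel_length_mean))
        if rng.random() < 0.5 and len(codes) > length:  # deletion
            pos = int(rng.integers(0, len(codes) - length + 1))
            codes = np.concatenate([codes[:pos], codes[pos + length :]])
        else:  # insertion
            pos = int(rng.integers(0, len(codes) + 1))
            novel = _draw_stationary(length, config.nuclear_base_freqs, rng)
            codes = np.concatenate([codes[:pos], novel, codes[pos:]])
    return codes


# ---------------------------------------------------------------------------
# the full generator


def _codes_to_str(codes: np.ndarray) -> str:
    return "".join(BASES[b] for b in codes)


@dataclass
class _NumtLineage:
    origin_id: str
    insertion_age: float
    insertion_branch: str
    insertion_on_terminal: bool
    lineage_id: str
    codes: np.ndarray


def _evolve_numt_segment(
    lineage: _NumtLineage,
    duration: float,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[_NumtLineage]:
    """Evolve one numt lineage over ``duration`` MY, spawning duplicates."""
    out = []
    n_dup = rng.poisson(config.duplication_rate * duration) if duration > 0 else 0
    # duplication times, processed oldest first
    dup_times = sorted(rng.random(n_dup) * duration, reverse=True) if n_dup else []
    nuc_rate = config.nuclear_rate_multiplier * config.mito_rate
    remaining = duration
    current = lineage
    branch_queue: list[tuple[_NumtLineage, float]] = []
    for i, t in enumerate(dup_times):
        step = remaining - t
        codes = evolve_sequence(
            current.codes, step, nuc_rate, config.nuclear_base_freqs,
            config.kappa, rng,
        )
        codes = _apply_indels(codes, step, config, rng)
        current = replace(current, codes=codes)
        dup = replace(current, lineage_id=f"{current.lineage_id}.d{i + 1}")
        branch_queue.append((dup, t))
        remaining = t
    codes = evolve_sequence(
        current.codes, remaining, nuc_rate, config.nuclear_base_freqs,
        config.kappa, rng,
    )
    codes = _apply_indels(codes, remaining, config, rng)
    out.append(replace(current, codes=codes))
    for dup, t in branch_queue:
        out.extend(_evolve_numt_segment(dup, t, config, rng))
    return out


def simulate(config: SimulationConfig) -> SimulationResult:
    """Run one full survey simulation.

    Traverses the species tree root-to-tips simulating the
    mitochondrial sequence, drops numt insertions as a Poisson process
    on each branch (plus any planted insertions), evolves each numt
    under the nuclear regime with duplication and per-speciation
    retention, and finally samples PCR clones per taxon.
    """
    rng = np.random.default_rng(config.seed)
    tree = simulate_species_tree(config.n_taxa, config.root_age, rng)

    # node labels for branch identification
    for i, node in enumerate(tree.preorder_node_iter()):
        node.branch_label = (
            node.taxon.label if node.is_leaf() else f"node{i}"
        )

    # planted insertions -> (node-below, age) on the root-to-taxon path
    planted: dict[str, list[float]] = {}
    for age, taxon in config.planted_insertions:
        leaf = next(
            x for x in tree.leaf_node_iter() if x.taxon.label == taxon
        )
        node = leaf
        while node.parent_node is not None and node.parent_node.age < age:
            node = node.parent_node
        if age >= tree.seed_node.age:
            raise ValueError(
                f"planted insertion at {age} MY predates the root "
                f"({tree.seed_node.age:.3f} MY)"
            )
        planted.setdefault(node.branch_label, []).append(age)

    # root and outgroup mitochondrial sequences
    stem_age = config.outgroup_stem_factor * config.root_age
    ancestor = _draw_stationary(config.seq_length, config.mito_base_freqs, rng)
    if config.codon_aware_mito:
        for start in range(0, 3 * (len(ancestor) // 3), 3):
            while _codes_to_str(ancestor[start : start + 3]) in _STOPS_T5:
                ancestor[start : start + 3] = _draw_stationary(
                    3, config.mito_base_freqs, rng
                )

    def mito_step(codes: np.ndarray, duration: float) -> np.ndarray:
        return evolve_sequence(
            codes, duration, config.mito_rate, config.mito_base_freqs,
            config.kappa, rng, codon_mask=config.codon_aware_mito,
        )

    outgroup_codes = mito_step(ancestor, stem_age)
    root_codes = mito_step(ancestor, stem_age - tree.seed_node.age)

    orthologs: dict[str, str] = {}
    numts: list[NumtCopy] = []
    insertion_counter = 0

    def surviving_species(origin_id: str) -> set[str]:
        return {c.taxon for c in numts if c.origin_id == origin_id}

    def descend(node: dendropy.Node, mito: np.ndarray,
                inherited: list[_NumtLineage]) -> None:
        nonlocal insertion_counter
        if node.is_leaf():
            taxon = node.taxon.label
            orthologs[taxon] = _codes_to_str(mito)
            for k, lin in enumerate(inherited):
                numts.append(
                    NumtCopy(
                        taxon=taxon,
                        copy_id=f"{lin.lineage_id}@{taxon}",
                        origin_id=lin.origin_id,
                        insertion_age=lin.insertion_age,
                        insertion_branch=lin.insertion_branch,
                        insertion_on_terminal=lin.insertion_on_terminal,
                        sequence=_codes_to_str(lin.codes),
                    )
                )
            return
        for child in node.child_nodes():
            top, bottom = node.age, child.age
            duration = top - bottom
            # retention of inherited numts into this daughter lineage
            carried = [
                lin for lin in inherited
                if rng.random() < config.retention_prob
            ]
            # insertion events on this branch, oldest first
            n_ins = rng.poisson(config.insertion_rate * duration)
            ages = list(top - rng.random(n_ins) * duration)
            ages += planted.get(child.branch_label, [])
            ages = sorted([a for a in ages if bottom <= a <= top], reverse=True)
            # evolve mito piecewise through the insertion times
            segment_mito = mito
            cursor = top
            born: list[_NumtLineage] = []
            for age in ages:
                segment_mito = mito_step(segment_mito, cursor - age)
                cursor = age
                insertion_counter += 1
                origin = f"numt{insertion_counter}"
                born.append(
                    _NumtLineage(
                        origin_id=origin,
                        insertion_age=age,
                        insertion_branch=child.branch_label,
                        insertion_on_terminal=child.is_leaf(),
                        lineage_id=origin,
                        codes=segment_mito.copy(),
                    )
                )
            child_mito = mito_step(segment_mito, cursor - bottom)
            # evolve carried numts over the whole branch, born ones from
            # their insertion age
            evolved: list[_NumtLineage] = []
            for lin in carried:
                evolved.extend(_evolve_numt_segment(lin, duration, config, rng))
            for lin in born:
                evolved.extend(
                    _evolve_numt_segment(lin, lin.insertion_age - bottom,
                                         config, rng)
                )
            descend(child, child_mito, evolved)

    descend(tree.seed_node, root_codes, [])

    # clone sampling
    locus = Locus.parse(config.locus)
    clones: list[SequenceRecord] = []
    truth_rows: list[dict] = []
    for taxon in sorted(orthologs):
        taxon_numts = [c for c in numts if c.taxon == taxon]
        for k in range(config.clones_per_sample):
            clone_id = f"{taxon}_C{k + 1:03d}"
            if taxon_numts and rng.random() >= config.ortholog_clone_weight:
                src = taxon_numts[int(rng.integers(len(taxon_numts)))]
                template = src.sequence
                origin = "numt"
            else:
                src = None
                template = orthologs[taxon]
                origin = "mtDNA"
            seq, n_err = _pcr_copy(template, config.pcr_error_rate, rng)
            clones.append(
                SequenceRecord(
                    id=clone_id, taxon=taxon, locus=locus, role=Role.CLONE,
                    residues=seq,
                )
            )
            if src is None:
                true_class = "none"
            elif len(surviving_species(src.origin_id)) >= 2:
                true_class = "synaponumt-member"
            elif src.insertion_on_terminal:
                true_class = "neonumt"
            else:
                true_class = "paleonumt"
            truth_rows.append(
                dict(
                    clone_id=clone_id,
                    taxon=taxon,
                    origin=origin,
                    source_copy=src.copy_id if src else "",
                    origin_id=src.origin_id if src else "",
                    insertion_age=src.insertion_age if src else np.nan,
                    insertion_branch=src.insertion_branch if src else "",
                    true_class=true_class,
                    n_pcr_errors=n_err,
                )
            )

    truth = pd.DataFrame(truth_rows)
    return SimulationResult(
        config=config,
        species_tree=tree,
        orthologs=orthologs,
        outgroup=_codes_to_str(outgroup_codes),
        numts=numts,
        clones=clones,
        truth=truth,
    )


def _pcr_copy(
    template: str, error_rate: float, rng: np.random.Generator
) -> tuple[str, int]:
    """One cloned copy of ``template`` with Binomial(L, rate) errors."""
    n_err = rng.binomial(len(template), error_rate) if error_rate > 0 else 0
    if n_err == 0:
        return template, 0
    positions = rng.choice(len(template), size=n_err, replace=False)
    seq = list(template)
    for pos in positions:
        alternatives = [b for b in BASES if b != seq[pos]]
        seq[pos] = alternatives[int(rng.integers(3))]
    return "".join(seq), int(n_err)


def numt_truth_class(copy: NumtCopy, all_copies: Sequence[NumtCopy]) -> str:
    """Ground-truth class of a numt copy: synaponumt-member if its origin
    survives in >= 2 species, else neonumt (terminal-branch insertion)
    or paleonumt (older)."""
    species = {c.taxon for c in all_copies if c.origin_id == copy.origin_id}
    if len(species) >= 2:
        return "synaponumt-member"
    return "neonumt" if copy.insertion_on_terminal else "paleonumt"
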