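"""End-to-end orchestration: characterize -> tree -> classify -> report.

Ties the stages together for a clones+orthologs FASTA pair: per-clone
characterization against the matching ortholog, deduplication of numts,
distance-tree inference with outgroup rooting, paleonumt/neonumt
classification, synaponumt detection, and the survey summary tables.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import dendropy
import pandas as pd

from .characterize import CloneProfile, characterize_clone, dedupe_numts
from .classify import (
    DEFAULT_DELTA,
    DEFAULT_EPSILON,
    DEFAULT_SUPPORT_MIN,
    FossilCalibration,
    classify_numts,
    date_insertion,
    detect_synaponumts,
    tally_classes,
)
from .core import Role, SequenceRecord, read_fasta
from .phylo import (
    build_distance_matrix,
    bootstrap_support,
    neighbor_joining,
    pairwise_distance_matrix,
    root_on_outgroup,
    write_newick,
)
from .report import divergence_report, summarize_families

__all__ = ["PipelineResult", "characterize_dataset", "infer_tree", "run_pipeline"]


@dataclass
class PipelineResult:
    profiles: list[CloneProfile]
    family_summaries: list
    trees: dict[tuple[str, str], dendropy.Tree]
    classifications: pd.DataFrame
    synaponumts: list
    dated: list


def characterize_dataset(
    clones: list[SequenceRecord],
    orthologs: list[SequenceRecord],
    **kwargs,
) -> list[CloneProfile]:
    """Characterize every clone against the ortholog of its taxon+locus."""
    by_key = {}
    for rec in orthologs:
        if rec.role is Role.ORTHOLOG:
            key = (rec.taxon, rec.locus)
            if key in by_key:
                raise ValueError(f"multiple orthologs for {key}")
            by_key[key] = rec
    references = [r for r in orthologs if r.role in (Role.ORTHOLOG, Role.OUTGROUP)]
    profiles = []
    for clone in clones:
        ortholog = by_key.get((clone.taxon, clone.locus))
        if ortholog is None:
            raise ValueError(
                f"no ortholog for clone {clone.id} ({clone.taxon}, "
                f"{clone.locus.value})"
            )
        profiles.append(
            characterize_clone(clone, ortholog, references, **kwargs)
        )
    return profiles


def infer_tree(
    records: list[SequenceRecord],
    *,
    model: str = "p",
    bootstrap: int = 0,
    seed: int = 0,
) -> dendropy.Tree:
    """NJ tree for a record set, rooted on the outgroup record.

    Uses the common alignment when all sequences share one length,
    otherwise per-pair alignments (bootstrap requires the former).
    """
    lengths = {len(r.residues) for r in records}
    aligned = len(lengths) == 1
    if bootstrap > 0:
        if not aligned:
            raise ValueError(
                "bootstrap requires equal-length (aligned) sequences"
            )
        tree = bootstrap_support(records, n_replicates=bootstrap, seed=seed,
                                 model=model)
    else:
        dm = (
            build_distance_matrix(records, model)
            if aligned
            else pairwise_distance_matrix(records, model)
        )
        tree = neighbor_joining(dm)
    outgroups = [r for r in records if r.role is Role.OUTGROUP]
    if outgroups:
        tree = root_on_outgroup(tree, outgroups[0].label())
    return tree


def run_pipeline(
    clones_fasta: str | Path,
    orthologs_fasta: str | Path,
    outdir: str | Path,
    *,
    calibration: FossilCalibration | None = None,
    bootstrap: int = 0,
    seed: int = 0,
    epsilon: float = DEFAULT_EPSILON,
    delta: float = DEFAULT_DELTA,
    support_min: int = DEFAULT_SUPPORT_MIN,
) -> PipelineResult:
    """Run the full analysis on clone and ortholog FASTA files.

    Writes per-clone profiles, family summary rows, per-taxon trees, the
    classification table, synaponumt clades (with fossil dates when a
    calibration covers them) and the divergence report under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    clones = read_fasta(clones_fasta)
    orthologs = read_fasta(orthologs_fasta)
    profiles = characterize_dataset(clones, orthologs)

    profile_frame = pd.DataFrame([asdict(p) for p in profiles])
    profile_frame.to_csv(outdir / "clone_profiles.tsv", sep="\t", index=False)

    summaries = summarize_families(profiles, clones)
    pd.DataFrame([asdict(s) for s in summaries]).to_csv(
        outdir / "family_summary.tsv", sep="\t", index=False
    )
    counts, table = divergence_report(profiles)
    counts.to_csv(outdir / "divergence_counts.tsv", sep="\t", index=False)
    table.to_csv(outdir / "divergence.tsv", sep="\t", index=False)

    clones_by_id = {c.id: c for c in clones}
    trees: dict[tuple[str, str], dendropy.Tree] = {}
    verdicts: list[tuple[str, str, str]] = []
    rows = []
    keys = sorted({(p.taxon, p.locus) for p in profiles})
    for taxon, locus in keys:
        group = [p for p in profiles if p.taxon == taxon and p.locus == locus]
        unique = dedupe_numts(group, clones)
        numt_records = [clones_by_id[rep.clone_id] for rep, _ in unique]
        if not numt_records:
            continue
        locus_orthologs = [
            r for r in orthologs if r.locus.value == locus or r.role is Role.OUTGROUP
        ]
        records = locus_orthologs + numt_records
        tree = infer_tree(records, bootstrap=bootstrap, seed=seed)
        trees[(taxon, locus)] = tree
        write_newick(tree, outdir / f"tree_{taxon}_{locus}.nwk")
        for cls in classify_numts(
            tree, taxon, epsilon=epsilon, delta=delta, support_min=support_min
        ):
            verdicts.append((taxon, locus, cls.verdict))
            rows.append(dict(taxon=taxon, locus=locus, **asdict(cls)))

    classifications = pd.DataFrame(rows)
    classifications.to_csv(outdir / "classifications.tsv", sep="\t", index=False)
    tally_classes(verdicts).to_csv(
        outdir / "class_tally.tsv", sep="\t", index=False
    )

    # synaponumt detection needs numts of all taxa in one tree per locus
    synaponumts = []
    dated = []
    for locus in sorted({loc for _, loc in keys}):
        group = [p for p in profiles if p.locus == locus]
        numt_records = []
        for taxon in sorted({p.taxon for p in group}):
            sub = [p for p in group if p.taxon == taxon]
            numt_records.extend(
                clones_by_id[rep.clone_id] for rep, _ in dedupe_numts(sub, clones)
            )
        if not numt_records:
            continue
        locus_orthologs = [
            r for r in orthologs if r.locus.value == locus or r.role is Role.OUTGROUP
        ]
        tree = infer_tree(locus_orthologs + numt_records, bootstrap=bootstrap,
                          seed=seed)
        trees[("__all__", locus)] = tree
        write_newick(tree, outdir / f"tree_all_{locus}.nwk")
        for clade in detect_synaponumts(tree, support_min=support_min):
            synaponumts.append(clade)
            if calibration is not None:
                dated.append((clade, date_insertion(clade, calibration)))
    with open(outdir / "synaponumts.json", "w") as handle:
        json.dump(
            [
                dict(
                    members=c.member_clone_ids,
                    species=sorted(c.member_species),
                    support=c.support,
                    mrca=c.mrca_label,
                )
                for c in synaponumts
            ],
            handle,
            indent=2,
        )
    return PipelineResult(
        profiles=profiles,
        family_summaries=summaries,
        trees=trees,
        classifications=classifications,
        synaponumts=synaponumts,
        dated=dated,
    )
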