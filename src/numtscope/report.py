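"""Aggregation of per-clone results into survey-level summary tables.

The survey's unit of observation is a (family, locus) cell: how many
clones were sequenced, how many were identical to the mitochondrial
ortholog, how many distinct numt sequences were recovered, and how many
of those carry a stop codon or indel.  Cross-taxon summaries are
unweighted means of per-family ratios (mean of ratios, not ratio of
sums): each family counts equally regardless of how many clones it
contributed, which is the convention that makes per-gene comparisons
insensitive to uneven cloning depth.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import pandas as pd

from .characterize import CloneProfile, CloneStatus, dedupe_numts
from .core import SequenceRecord

__all__ = [
    "FamilyLocusSummary",
    "CrossTaxonSummary",
    "summarize_families",
    "summarize_across",
    "divergence_report",
    "round_pct",
]


def round_pct(fraction: float, digits: int = 2) -> float:
    """Percentage with half-up rounding to ``digits`` decimals."""
    q = Decimal(10) ** -digits
    return float(Decimal(repr(fraction * 100)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class FamilyLocusSummary:
    """Survey counts for one (taxon, locus) cell."""

    taxon: str
    locus: str
    n_total_clones: int
    n_identical: int
    n_unique_numts: int
    n_numts_with_stop_or_indel: int
    n_total_raw: int | None = None  # including cloning errors, if known

    def __post_init__(self) -> None:
        if self.n_identical + self.n_unique_numts > self.n_total_clones:
            raise ValueError(
                "identical + unique numts cannot exceed total clones"
            )
        if self.n_numts_with_stop_or_indel > self.n_unique_numts:
            raise ValueError("stop/indel numts cannot exceed unique numts")


@dataclass(frozen=True)
class CrossTaxonSummary:
    locus: str
    n_families: int
    mean_identical_fraction: float
    mean_stop_or_indel_fraction: float
    sum_total_clones: int
    sum_identical: int
    sum_unique_numts: int
    sum_stop_or_indel: int


def summarize_families(
    profiles: Sequence[CloneProfile],
    records: Sequence[SequenceRecord],
) -> list[FamilyLocusSummary]:
    """Aggregate clone profiles into per-(taxon, locus) survey rows.

    Cloning errors are excluded from all counts except the raw total.
    Unique numts are counted after collapsing byte-identical sequences;
    a unique numt contributes to the stop/indel column when its
    representative has an in-frame stop, insertion or deletion.
    """
    groups: dict[tuple[str, str], list[CloneProfile]] = {}
    for prof in profiles:
        groups.setdefault((prof.taxon, prof.locus), []).append(prof)
    out = []
    for (taxon, locus), members in sorted(groups.items()):
        screened = [p for p in members if p.status is not CloneStatus.CLONING_ERROR]
        unique = dedupe_numts(members, records)
        n_stop = sum(
            1
            for rep, _ in unique
            if (rep.n_inframe_stops or 0) > 0
            or (rep.n_insertions or 0) > 0
            or (rep.n_deletions or 0) > 0
        )
        out.append(
            FamilyLocusSummary(
                taxon=taxon,
                locus=locus,
                n_total_clones=len(screened),
                n_identical=sum(
                    1 for p in screened if p.status is CloneStatus.IDENTICAL
                ),
                n_unique_numts=len(unique),
                n_numts_with_stop_or_indel=n_stop,
                n_total_raw=len(members),
            )
        )
    return out


def summarize_across(
    rows: Sequence[FamilyLocusSummary],
    locus: str | None = None,
) -> CrossTaxonSummary:
    """Unweighted cross-family summary for one locus.

    Means are over per-family ratios; a family with a zero denominator
    (no clones, or no unique numts) is excluded from that mean only.
    """
    if locus is not None:
        rows = [r for r in rows if r.locus == locus]
    if not rows:
        raise ValueError("no rows to summarize")
    loci = {r.locus for r in rows}
    if len(loci) > 1:
        raise ValueError(f"rows span multiple loci: {sorted(loci)}; pass locus=")
    ident = [
        r.n_identical / r.n_total_clones for r in rows if r.n_total_clones > 0
    ]
    stop = [
        r.n_numts_with_stop_or_indel / r.n_unique_numts
        for r in rows
        if r.n_unique_numts > 0
    ]
    return CrossTaxonSummary(
        locus=next(iter(loci)),
        n_families=len(rows),
        mean_identical_fraction=sum(ident) / len(ident),
        mean_stop_or_indel_fraction=sum(stop) / len(stop) if stop else 0.0,
        sum_total_clones=sum(r.n_total_clones for r in rows),
        sum_identical=sum(r.n_identical for r in rows),
        sum_unique_numts=sum(r.n_unique_numts for r in rows),
        sum_stop_or_indel=sum(r.n_numts_with_stop_or_indel for r in rows),
    )


def divergence_report(
    profiles: Iterable[CloneProfile],
    *,
    p_threshold: float = 0.01,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Divergence and base-composition summary of numt profiles.

    Returns ``(counts, table)``: per-locus counts of numts below the
    p-distance threshold and of numts whose base composition differs
    significantly from the ortholog by the matched-pairs symmetry test,
    plus a per-numt table of (AT% clone, AT% ortholog, p-distance,
    Bowker p).
    """
    numts = [p for p in profiles if p.status is CloneStatus.NUMT]
    table = pd.DataFrame(
        [
            dict(
                clone_id=p.clone_id,
                taxon=p.taxon,
                locus=p.locus,
                at_fraction_clone=p.at_fraction_clone,
                at_fraction_ortholog=p.at_fraction_ortholog,
                p_distance=p.p_distance,
                bowker_p=p.bowker_p,
            )
            for p in numts
        ]
    )
    if table.empty:
        counts = pd.DataFrame(
            columns=["locus", "n_numts", "n_below_p_threshold", "n_bowker_significant"]
        )
        return counts, table
    counts = (
        table.groupby("locus")
        .apply(
            lambda g: pd.Series(
                dict(
                    n_numts=len(g),
                    n_below_p_threshold=int((g.p_distance < p_threshold).sum()),
                    n_bowker_significant=int((g.bowker_p < alpha).sum()),
                )
            ),
            include_groups=False,
        )
        .reset_index()
    )
    return counts, table
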