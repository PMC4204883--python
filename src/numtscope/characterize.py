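"""Stage 1: per-clone characterization against the mitochondrial ortholog.

Each cloned PCR product is screened for cloning errors (no credible
similarity to any mitochondrial reference), globally aligned to the
ortholog of its taxon and locus with free end gaps on the clone (clones
are sub-fragments of the gene), and then classified as *identical* or
*numt* over the aligned overlap.  For numts the module counts the
pseudogene-diagnostic mutations (in-frame stop codons, insertions,
deletions, frameshifts, point mutations), computes uncorrected
p-distance and AT content, and runs the matched-pairs Bowker test for
symmetry of the 4x4 site-pattern divergence matrix, which detects
directional base-composition change of the numt away from the
mitochondrial stationary composition.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio import Align
from scipy import stats

from .core import (
    INVERTEBRATE_MITO_TABLE,
    UNAMBIGUOUS,
    CodonTranslationTable,
    SequenceRecord,
    translate,
)

__all__ = [
    "PairwiseAlignment",
    "CloneStatus",
    "CloneProfile",
    "MutationCounts",
    "BowkerResult",
    "align_pair",
    "p_distance",
    "identity_fraction",
    "count_mutations",
    "bowker_symmetry_test",
    "screen_cloning_error",
    "characterize_clone",
    "dedupe_numts",
    "pcr_error_expectation",
]

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global pairwise alignment of reference (ortholog) and query (clone).

    ``ref_frame_offset`` is the reading-frame phase of the first reference
    column (0 means the alignment starts at a codon start of the ortholog).
    """

    ref_aligned: str
    query_aligned: str
    ref_frame_offset: int = 0

    def __post_init__(self) -> None:
        if len(self.ref_aligned) != len(self.query_aligned):
            raise ValueError("aligned strings differ in length")
        for r, q in zip(self.ref_aligned, self.query_aligned):
            if r == "-" and q == "-":
                raise ValueError("gap-in-both column")

    def columns(self) -> Iterable[tuple[str, str]]:
        return zip(self.ref_aligned, self.query_aligned)

    def overlap_slice(self) -> slice:
        """Columns between the first and last non-gap query position."""
        q = self.query_aligned
        first = len(q) - len(q.lstrip("-"))
        last = len(q.rstrip("-"))
        return slice(first, last)


class CloneStatus(str, enum.Enum):
    CLONING_ERROR = "cloning_error"
    IDENTICAL = "identical"
    NUMT = "numt"


@dataclass(frozen=True)
class MutationCounts:
    n_point: int
    n_insertions: int
    n_deletions: int
    n_inframe_stops: int
    has_frameshift: bool

    @property
    def has_stop_or_indel(self) -> bool:
        return self.n_inframe_stops > 0 or self.n_insertions > 0 or self.n_deletions > 0


@dataclass(frozen=True)
class BowkerResult:
    S: float
    df: int
    p: float


@dataclass
class CloneProfile:
    """Per-clone characterization record (one row of the per-clone table)."""

    clone_id: str
    taxon: str
    locus: str
    status: CloneStatus
    n_point_mutations: int | None = None
    n_insertions: int | None = None
    n_deletions: int | None = None
    n_inframe_stops: int | None = None
    has_frameshift: bool | None = None
    p_distance: float | None = None
    at_fraction_clone: float | None = None
    at_fraction_ortholog: float | None = None
    bowker_S: float | None = None
    bowker_df: int | None = None
    bowker_p: float | None = None
    screen_reason: str | None = None


def _make_aligner(
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -4.0,
    gap_extend: float = -1.0,
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    # clones are sub-fragments of the gene: query end gaps are free
    aligner.end_deletion_score = 0.0
    return aligner


def align_pair(
    ref: SequenceRecord | str,
    query: SequenceRecord | str,
    *,
    ref_frame_offset: int = 0,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -4.0,
    gap_extend: float = -1.0,
) -> PairwiseAlignment:
    """Optimal global alignment with free end gaps on the query.

    Scoring defaults: match +1, mismatch -1, gap open -4, gap extend -1.
    The first optimal alignment in Biopython's deterministic enumeration
    order is returned (leftmost gap placement).
    """
    ref_seq = ref.residues if isinstance(ref, SequenceRecord) else ref
    query_seq = query.residues if isinstance(query, SequenceRecord) else query
    if not ref_seq or not query_seq:
        raise ValueError("cannot align an empty sequence")
    if "-" in ref_seq or "-" in query_seq:
        raise ValueError("input sequences must be gap-free")
    aligner = _make_aligner(match, mismatch, gap_open, gap_extend)
    aln = aligner.align(ref_seq, query_seq)[0]
    return PairwiseAlignment(
        ref_aligned=str(aln[0]),
        query_aligned=str(aln[1]),
        ref_frame_offset=ref_frame_offset,
    )


def _comparable(r: str, q: str) -> bool:
    return r in UNAMBIGUOUS and q in UNAMBIGUOUS


def p_distance(aln: PairwiseAlignment) -> float:
    """Uncorrected p-distance with pairwise deletion of gap/N columns."""
    comparable = diffs = 0
    for r, q in aln.columns():
        if _comparable(r, q):
            comparable += 1
            if r != q:
                diffs += 1
    if comparable == 0:
        raise ValueError("no comparable column: p-distance undefined")
    return diffs / comparable


def identity_fraction(aln: PairwiseAlignment) -> float:
    """Gap-excluded identity over comparable columns."""
    return 1.0 - p_distance(aln)


def count_mutations(
    aln: PairwiseAlignment,
    table: CodonTranslationTable = INVERTEBRATE_MITO_TABLE,
) -> MutationCounts:
    """Count pseudogene-diagnostic mutations over the aligned overlap.

    Point mutations are differing unambiguous base pairs in ungapped
    columns.  Each maximal gap run in the reference is one insertion
    event; each maximal run in the query is one deletion event (end gaps
    of the query, where the clone simply does not cover the gene, are not
    events).  A frameshift is recorded when the running net indel length
    after any indel event is not a multiple of three.  Stop codons are
    counted in the query read in the frame induced by the reference at
    the start of the overlap; after an indel the query is read
    contiguously, i.e. codons downstream of a frameshifting indel are
    scored in the shifted frame.
    """
    window = aln.overlap_slice()
    ref = aln.ref_aligned[window]
    query = aln.query_aligned[window]

    n_point = 0
    insertions: list[int] = []
    deletions: list[int] = []
    has_frameshift = False
    run_char: str | None = None  # "ins" (gap in ref) or "del" (gap in query)
    run_len = 0
    net = 0

    def close_run() -> None:
        nonlocal run_char, run_len, net, has_frameshift
        if run_char is None:
            return
        if run_char == "ins":
            insertions.append(run_len)
            net += run_len
        else:
            deletions.append(run_len)
            net -= run_len
        if net % 3 != 0:
            has_frameshift = True
        run_char = None
        run_len = 0

    for r, q in zip(ref, query):
        if r == "-" or q == "-":
            kind = "ins" if r == "-" else "del"
            if run_char != kind:
                close_run()
                run_char = kind
            run_len += 1
        else:
            close_run()
            if _comparable(r, q) and r != q:
                n_point += 1
    close_run()

    # reading-frame phase of the first overlap column, in ref coordinates
    ref_start = len(aln.ref_aligned[: window.start].replace("-", ""))
    phase = (aln.ref_frame_offset + ref_start) % 3
    skip = (3 - phase) % 3
    query_bases = query.replace("-", "")
    n_stops = 0
    if len(query_bases) > skip:
        aa = translate(query_bases[skip:], 0, table)
        n_stops = aa.count("*")

    return MutationCounts(
        n_point=n_point,
        n_insertions=len(insertions),
        n_deletions=len(deletions),
        n_inframe_stops=n_stops,
        has_frameshift=has_frameshift,
    )


def divergence_matrix(aln: PairwiseAlignment) -> np.ndarray:
    """4x4 site-pattern matrix N with N[i,j] = #columns (ref=i, query=j)."""
    n = np.zeros((4, 4), dtype=int)
    for r, q in aln.columns():
        if _comparable(r, q):
            n[BASE_INDEX[r], BASE_INDEX[q]] += 1
    return n


def bowker_symmetry_test(aln: PairwiseAlignment) -> BowkerResult:
    """Matched-pairs Bowker test for symmetry of the divergence matrix.

    S = sum over unordered base pairs {i,j} with n_ij + n_ji > 0 of
    (n_ij - n_ji)^2 / (n_ij + n_ji); df counts those pairs; p is the
    chi-square upper tail.  df = 0 (no off-diagonal substitutions)
    gives S = 0, p = 1 by convention.
    """
    n = divergence_matrix(aln)
    if n.sum() == 0:
        raise ValueError("no comparable column: Bowker test undefined")
    S = 0.0
    df = 0
    for i in range(4):
        for j in range(i + 1, 4):
            tot = n[i, j] + n[j, i]
            if tot > 0:
                S += (n[i, j] - n[j, i]) ** 2 / tot
                df += 1
    p = 1.0 if df == 0 else float(stats.chi2.sf(S, df))
    return BowkerResult(S=S, df=df, p=p)


def screen_cloning_error(
    clone: SequenceRecord,
    references: Sequence[SequenceRecord],
    min_identity: float = 0.60,
    min_overlap: int = 50,
) -> tuple[bool, str | None]:
    """Return ``(keep, reason)``: keep is True iff the clone shows credible
    similarity (gap-excluded identity >= ``min_identity`` over >=
    ``min_overlap`` comparable columns) to at least one reference.
    """
    if not references:
        raise ValueError("at least one reference required")
    if not 0.0 < min_identity < 1.0:
        raise ValueError("min_identity must be in (0, 1)")
    best = 0.0
    had_overlap = False
    for ref in references:
        aln = align_pair(ref, clone)
        comparable = sum(1 for r, q in aln.columns() if _comparable(r, q))
        if comparable < min_overlap:
            continue
        had_overlap = True
        best = max(best, identity_fraction(aln))
    if not had_overlap:
        return False, "insufficient overlap"
    if best < min_identity:
        return False, f"best identity {best:.3f} < {min_identity}"
    return True, None


def characterize_clone(
    clone: SequenceRecord,
    ortholog: SequenceRecord,
    references: Sequence[SequenceRecord] | None = None,
    *,
    min_identity: float = 0.60,
    min_overlap: int = 50,
    ortholog_frame: int = 0,
    table: CodonTranslationTable = INVERTEBRATE_MITO_TABLE,
) -> CloneProfile:
    """Screen, align and classify one clone against its ortholog.

    Status is *identical* iff there are no point mutations and no indel
    events over the aligned overlap; otherwise *numt*.  Clones failing
    the similarity screen are *cloning_error* with no divergence stats.
    """
    from .core import at_fraction

    refs = list(references) if references else [ortholog]
    keep, reason = screen_cloning_error(clone, refs, min_identity, min_overlap)
    base = dict(clone_id=clone.id, taxon=clone.taxon, locus=clone.locus.value)
    if not keep:
        return CloneProfile(
            status=CloneStatus.CLONING_ERROR, screen_reason=reason, **base
        )
    aln = align_pair(ortholog, clone, ref_frame_offset=ortholog_frame)
    muts = count_mutations(aln, table)
    dist = p_distance(aln)
    bowker = bowker_symmetry_test(aln)
    identical = muts.n_point == 0 and muts.n_insertions == 0 and muts.n_deletions == 0
    return CloneProfile(
        status=CloneStatus.IDENTICAL if identical else CloneStatus.NUMT,
        n_point_mutations=muts.n_point,
        n_insertions=muts.n_insertions,
        n_deletions=muts.n_deletions,
        n_inframe_stops=muts.n_inframe_stops,
        has_frameshift=muts.has_frameshift,
        p_distance=dist,
        at_fraction_clone=at_fraction(clone.residues),
        at_fraction_ortholog=at_fraction(ortholog.residues),
        bowker_S=bowker.S,
        bowker_df=bowker.df,
        bowker_p=bowker.p,
        **base,
    )


def dedupe_numts(
    profiles: Sequence[CloneProfile],
    records: Sequence[SequenceRecord],
) -> list[tuple[CloneProfile, int]]:
    """Collapse byte-identical numt clones of one taxon+locus.

    Returns one ``(representative profile, multiplicity)`` pair per unique
    numt sequence; the representative is the clone with the
    lexicographically smallest id.  Identical-to-ortholog and
    cloning-error profiles are not part of the output.
    """
    keys = {(p.taxon, p.locus) for p in profiles}
    if len(keys) > 1:
        raise ValueError(f"profiles span multiple taxon/locus groups: {sorted(keys)}")
    by_id = {r.id: r for r in records}
    groups: dict[str, list[CloneProfile]] = {}
    for prof in profiles:
        if prof.status is not CloneStatus.NUMT:
            continue
        residues = by_id[prof.clone_id].residues
        groups.setdefault(residues, []).append(prof)
    out = []
    for members in groups.values():
        rep = min(members, key=lambda p: p.clone_id)
        out.append((rep, len(members)))
    out.sort(key=lambda pair: pair[0].clone_id)
    return out


def pcr_error_expectation(product_length: int, per_bp_error_rate: float) -> float:
    """Expected polymerase errors per PCR product: length x per-bp rate.

    At the 0.015% per-bp fidelity of a proofreading enzyme mix this gives
    0.0987 expected errors for a 658-bp COI barcode fragment.
    """
    if product_length <= 0:
        raise ValueError("product_length must be positive")
    if not 0.0 <= per_bp_error_rate <= 1.0:
        raise ValueError("per_bp_error_rate must be in [0, 1]")
    return product_length * per_bp_error_rate
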