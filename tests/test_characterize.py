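"""Clone-vs-ortholog characterization: alignment, distances, mutation
counts, the Bowker symmetry test, screening and deduplication."""

import numpy as np
import pytest
from scipy import stats

from numtscope.characterize import (
    CloneStatus,
    PairwiseAlignment,
    align_pair,
    bowker_symmetry_test,
    characterize_clone,
    count_mutations,
    dedupe_numts,
    p_distance,
    pcr_error_expectation,
    screen_cloning_error,
)
from numtscope.core import Locus, Role
from conftest import make_record


class TestAlignPair:
    def test_identical_sequences_align_without_gaps(self):
        aln = align_pair("ACGT", "ACGT")
        assert aln.ref_aligned == aln.query_aligned == "ACGT"

    def test_single_gap_in_query(self):
        aln = align_pair("ACGGT", "ACGT")
        assert aln.ref_aligned == "ACGGT"
        assert aln.query_aligned.count("-") == 1

    def test_free_end_gaps_leave_core_matched(self):
        aln = align_pair("AACGTAA", "CGT")
        assert aln.ref_aligned == "AACGTAA"
        assert aln.query_aligned == "--CGT--"

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_pair("", "ACGT")

    def test_deterministic(self):
        a1 = align_pair("ACGTACGTAA", "ACGTCGTA")
        a2 = align_pair("ACGTACGTAA", "ACGTCGTA")
        assert a1 == a2


class TestPDistance:
    @pytest.mark.parametrize(
        "ref,query,expected",
        [
            ("ACGT", "ACGA", 0.25),
            ("ACGT", "ACGT", 0.0),
            ("AC-T", "ACGT", 0.0),  # gap column excluded, 3 comparable
            ("ACNT", "ACGT", 0.0),  # N column excluded
        ],
    )
    def test_examples(self, ref, query, expected):
        assert p_distance(PairwiseAlignment(ref, query)) == pytest.approx(expected)

    def test_symmetric_in_rows(self):
        a = PairwiseAlignment("ACGTAC", "ACCTAG")
        b = PairwiseAlignment("ACCTAG", "ACGTAC")
        assert p_distance(a) == p_distance(b)

    def test_invariant_under_column_permutation(self, rng):
        ref, query = "ACGTACGTAA", "ACCTACGAAA"
        perm = rng.permutation(len(ref))
        shuffled = PairwiseAlignment(
            "".join(ref[i] for i in perm), "".join(query[i] for i in perm)
        )
        assert p_distance(PairwiseAlignment(ref, query)) == p_distance(shuffled)

    def test_no_comparable_columns_is_an_error(self):
        with pytest.raises(ValueError):
            p_distance(PairwiseAlignment("A-", "-T"))

    def test_adding_a_substitution_never_decreases_distance(self):
        ref = "ACGTACGTACGT"
        query = list(ref)
        last = 0.0
        for pos in range(len(ref)):
            query[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[query[pos]]
            d = p_distance(PairwiseAlignment(ref, "".join(query)))
            assert d >= last
            last = d


def oracle_count_mutations(aln: PairwiseAlignment):
    """Independent column-walk reimplementation used as a test oracle."""
    q = aln.query_aligned
    start = len(q) - len(q.lstrip("-"))
    stop = len(q.rstrip("-"))
    ref = aln.ref_aligned[start:stop]
    query = q[start:stop]

    n_point = sum(
        1
        for r, c in zip(ref, query)
        if r in "ACGT" and c in "ACGT" and r != c
    )
    import re

    ins_runs = [m.group() for m in re.finditer(r"-+", ref)]
    del_runs = [m.group() for m in re.finditer(r"-+", query)]
    # frameshift: net indel length after each event, scanning columns
    events = []
    for m in re.finditer(r"-+", ref):
        events.append((m.start(), len(m.group())))
    for m in re.finditer(r"-+", query):
        events.append((m.start(), -len(m.group())))
    events.sort()
    net = 0
    frameshift = False
    for _, delta in events:
        net += delta
        if net % 3 != 0:
            frameshift = True
    # stops: query read contiguously from the codon start induced by the
    # reference at the first overlap column
    ref_before = aln.ref_aligned[:start].replace("-", "")
    phase = (aln.ref_frame_offset + len(ref_before)) % 3
    skip = (3 - phase) % 3
    bases = query.replace("-", "")[skip:]
    stops = 0
    for i in range(0, len(bases) - 2, 3):
        if bases[i : i + 3] in ("TAA", "TAG"):
            stops += 1
    return n_point, len(ins_runs), len(del_runs), stops, frameshift


def random_alignment(rng, max_cols=30):
    n = int(rng.integers(3, max_cols + 1))
    cols = []
    for _ in range(n):
        kind = rng.random()
        r = "ACGTN"[int(rng.integers(5))]
        q = "ACGTN"[int(rng.integers(5))]
        if kind < 0.15:
            cols.append(("-", q))
        elif kind < 0.3:
            cols.append((r, "-"))
        else:
            cols.append((r, q))
    ref = "".join(c[0] for c in cols)
    query = "".join(c[1] for c in cols)
    if set(ref) == {"-"} or set(query) == {"-"}:
        return random_alignment(rng, max_cols)
    return PairwiseAlignment(ref, query, ref_frame_offset=int(rng.integers(3)))


class TestCountMutations:
    def test_identical_pair_all_zero(self):
        m = count_mutations(PairwiseAlignment("ACGATG", "ACGATG"))
        assert (m.n_point, m.n_insertions, m.n_deletions, m.n_inframe_stops) == (
            0, 0, 0, 0,
        )
        assert not m.has_frameshift

    def test_inframe_stop_detected(self):
        # ortholog ATG GCA ATA; query gains TAA at the second codon
        m = count_mutations(PairwiseAlignment("ATGGCAATA", "ATGTAAATA"))
        assert m.n_inframe_stops == 1
        assert m.n_point == 2  # GCA -> TAA differs at two sites

    def test_two_bp_deletion_is_one_event_and_frameshift(self):
        m = count_mutations(PairwiseAlignment("ACGTAC", "AC--AC"))
        assert m.n_deletions == 1
        assert m.n_insertions == 0
        assert m.has_frameshift

    def test_three_bp_deletion_is_not_a_frameshift(self):
        m = count_mutations(PairwiseAlignment("ACGTACG", "AC---CG"))
        assert m.n_deletions == 1
        assert not m.has_frameshift

    def test_query_end_gaps_are_not_deletion_events(self):
        m = count_mutations(PairwiseAlignment("AACGTAA", "--CGT--"))
        assert m.n_deletions == 0 and m.n_insertions == 0

    def test_matches_column_walk_oracle_on_random_alignments(self, rng):
        for _ in range(500):
            aln = random_alignment(rng)
            m = count_mutations(aln)
            got = (m.n_point, m.n_insertions, m.n_deletions,
                   m.n_inframe_stops, m.has_frameshift)
            assert got == oracle_count_mutations(aln), aln


class TestBowker:
    def test_symmetric_matrix_gives_zero(self):
        # A<->G both directions twice: fully symmetric
        aln = PairwiseAlignment("AGAGCC", "GAGACC")
        res = bowker_symmetry_test(aln)
        assert res.S == 0.0
        assert res.p == 1.0

    def test_three_to_one_asymmetry(self):
        # n_AG=3, n_GA=1, everything else diagonal
        aln = PairwiseAlignment("AAAGCCCC", "GGGACCCC")
        res = bowker_symmetry_test(aln)
        assert res.S == pytest.approx(1.0)
        assert res.df == 1
        assert res.p == pytest.approx(stats.chi2.sf(1.0, 1))
        assert res.p == pytest.approx(0.3173, abs=1e-4)

    def test_identical_sequences_df_zero(self):
        res = bowker_symmetry_test(PairwiseAlignment("ACGT", "ACGT"))
        assert (res.S, res.df, res.p) == (0.0, 0, 1.0)

    def test_no_comparable_columns_is_an_error(self):
        with pytest.raises(ValueError):
            bowker_symmetry_test(PairwiseAlignment("NN", "NN"))


class TestScreen:
    def test_clone_equal_to_reference_kept(self, rng):
        ref = make_record("ref", "ACGT" * 30, role=Role.ORTHOLOG)
        keep, reason = screen_cloning_error(
            make_record("c", ref.residues), [ref]
        )
        assert keep and reason is None

    def test_ninety_percent_identity_kept_at_060(self, rng):
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 600))
        mutated = list(seq)
        for pos in rng.choice(600, 60, replace=False):
            mutated[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[pos]]
        ref = make_record("ref", seq, role=Role.ORTHOLOG)
        keep, _ = screen_cloning_error(make_record("c", "".join(mutated)), [ref])
        assert keep

    def test_random_clones_nearly_always_dropped(self, rng):
        ref = make_record(
            "ref", "".join("ACGT"[i] for i in rng.integers(0, 4, 600)),
            role=Role.ORTHOLOG,
        )
        kept = 0
        n = 200
        for _ in range(n):
            clone = make_record(
                "c", "".join("ACGT"[i] for i in rng.integers(0, 4, 600))
            )
            keep, _ = screen_cloning_error(clone, [ref])
            kept += keep
        assert kept / n < 0.05

    def test_short_clone_flagged_insufficient_overlap(self):
        ref = make_record("ref", "ACGT" * 30, role=Role.ORTHOLOG)
        keep, reason = screen_cloning_error(make_record("c", "ACGTACGT"), [ref])
        assert not keep
        assert reason == "insufficient overlap"


class TestCharacterizeClone:
    def setup_method(self):
        self.ortholog = make_record(
            "mt", "ATGGCAATACCTGGAACAATT" * 10, role=Role.ORTHOLOG
        )

    def test_exact_subfragment_is_identical(self):
        clone = make_record("c1", self.ortholog.residues[30:150])
        prof = characterize_clone(clone, self.ortholog)
        assert prof.status is CloneStatus.IDENTICAL
        assert prof.p_distance == 0.0
        assert prof.n_point_mutations == 0

    def test_single_substitution_is_numt_with_matching_p_distance(self):
        residues = list(self.ortholog.residues[:120])
        residues[50] = "A" if residues[50] != "A" else "C"
        prof = characterize_clone(make_record("c2", "".join(residues)),
                                  self.ortholog)
        assert prof.status is CloneStatus.NUMT
        assert prof.p_distance == pytest.approx(1 / 120)

    def test_unrelated_clone_is_cloning_error_without_stats(self, rng):
        clone = make_record(
            "c3", "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
        )
        prof = characterize_clone(clone, self.ortholog)
        assert prof.status is CloneStatus.CLONING_ERROR
        assert prof.p_distance is None
        assert prof.bowker_p is None


class TestDedupe:
    def test_multiplicities(self):
        ortholog = make_record("mt", "ATGGCAATACCTGGAACAATT" * 5,
                               role=Role.ORTHOLOG)
        variant1 = ortholog.residues[:90].replace("ATG", "TTG", 1)
        variant2 = ortholog.residues[:90].replace("GGA", "GGG", 1)
        clones = [
            make_record("c1", variant1),
            make_record("c2", variant1),
            make_record("c3", variant1),
            make_record("c4", variant2),
            make_record("c5", ortholog.residues[:90]),
        ]
        profiles = [characterize_clone(c, ortholog) for c in clones]
        unique = dedupe_numts(profiles, clones)
        assert [(rep.clone_id, mult) for rep, mult in unique] == [
            ("c1", 3), ("c4", 1),
        ]

    def test_all_identical_yields_no_numts(self):
        ortholog = make_record("mt", "ATGGCAATACCTGGAACAATT" * 5,
                               role=Role.ORTHOLOG)
        clones = [make_record(f"c{i}", ortholog.residues[:80]) for i in range(4)]
        profiles = [characterize_clone(c, ortholog) for c in clones]
        assert dedupe_numts(profiles, clones) == []


class TestPcrErrorExpectation:
    @pytest.mark.parametrize(
        "length,rate,expected",
        [(658, 0.00015, 0.0987), (60, 0.00015, 0.009),
         (1882, 0.00015, 0.2823), (500, 0.0, 0.0)],
    )
    def test_examples(self, length, rate, expected):
        assert pcr_error_expectation(length, rate) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            pcr_error_expectation(0, 0.1)
        with pytest.raises(ValueError):
            pcr_error_expectation(100, 1.5)
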