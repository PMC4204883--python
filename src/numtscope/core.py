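"""Sequence containers, FASTA I/O and mitochondrial genetic codes.

Cloned PCR products and their mitochondrial reference sequences are carried
as :class:`SequenceRecord` objects.  Metadata (taxon, locus, role) is encoded
in the FASTA description line using the pipe dialect ``id|taxon|locus|role``,
e.g. ``>OR295_C020|Lentulidae|COII|clone``.

The invertebrate mitochondrial genetic code (NCBI translation table 5) is the
default for pseudogene scoring: under it TGA encodes Trp, AGA/AGG encode Ser,
and only TAA/TAG are stops, so an in-frame TAA in a clone is diagnostic of a
non-functional nuclear copy rather than a sequencing quirk.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Locus",
    "Role",
    "SequenceRecord",
    "CodonTranslationTable",
    "INVERTEBRATE_MITO_TABLE",
    "FastaError",
    "read_fasta",
    "write_fasta",
    "translate",
    "at_fraction",
    "gc_fraction",
]

ALLOWED_RESIDUES = frozenset("ACGTN-")
UNAMBIGUOUS = frozenset("ACGT")


class Locus(str, enum.Enum):
    """Mitochondrial locus of a sequence."""

    COI = "COI"
    COII = "COII"
    ND5 = "ND5"
    OTHER = "other"

    @classmethod
    def parse(cls, text: str) -> "Locus":
        for member in cls:
            if member.value.lower() == text.strip().lower():
                return member
        return cls.OTHER


class Role(str, enum.Enum):
    """Role of a sequence in the analysis."""

    ORTHOLOG = "ortholog"
    CLONE = "clone"
    OUTGROUP = "outgroup"

    @classmethod
    def parse(cls, text: str) -> "Role":
        try:
            return cls(text.strip().lower())
        except ValueError as exc:
            raise FastaError(f"unknown sequence role {text!r}") from exc


class FastaError(ValueError):
    """Raised on malformed FASTA input or invalid residues."""


@dataclass(frozen=True)
class SequenceRecord:
    """One nucleotide sequence with its analysis metadata.

    Parameters
    ----------
    id:
        Unique identifier within a dataset (clone or accession id).
    taxon:
        Taxon name, typically a family for survey data.
    locus:
        Mitochondrial locus (:class:`Locus`).
    role:
        Whether the record is a mitochondrial ortholog, a cloned PCR
        product, or the outgroup reference.
    residues:
        Upper-case nucleotide string over ``A C G T N -``.
    """

    id: str
    taxon: str
    locus: Locus
    role: Role
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise FastaError(f"record {self.id!r}: empty sequence")
        for pos, ch in enumerate(self.residues):
            if ch not in ALLOWED_RESIDUES:
                raise FastaError(
                    f"record {self.id!r}: disallowed symbol {ch!r} at position {pos}"
                )

    @property
    def degapped(self) -> str:
        return self.residues.replace("-", "")

    def label(self) -> str:
        """Pipe-dialect label used in FASTA headers and tree tips."""
        return f"{self.id}|{self.taxon}|{self.locus.value}|{self.role.value}"


def _normalize_residues(raw: str, record_id: str) -> str:
    seq = raw.upper().replace("U", "T")
    for pos, ch in enumerate(seq):
        if ch not in ALLOWED_RESIDUES:
            raise FastaError(
                f"record {record_id!r}: disallowed symbol {ch!r} at position {pos}"
            )
    return seq


def parse_label(label: str) -> tuple[str, str, Locus, Role]:
    """Split an ``id|taxon|locus|role`` label into its fields."""
    parts = label.split("|")
    if len(parts) != 4:
        raise FastaError(
            f"header {label!r} does not follow the id|taxon|locus|role convention"
        )
    rid, taxon, locus, role = (p.strip() for p in parts)
    return rid, taxon, Locus.parse(locus), Role.parse(role)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file whose headers follow ``id|taxon|locus|role``.

    Residues are upper-cased and U is mapped to T.  Raises
    :class:`FastaError` on an empty file, malformed headers, duplicate ids
    or disallowed residues.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        rid, taxon, locus, role = parse_label(entry.description)
        if rid in seen:
            raise FastaError(f"duplicate record id {rid!r} in {path}")
        seen.add(rid)
        records.append(
            SequenceRecord(
                id=rid,
                taxon=taxon,
                locus=locus,
                role=role,
                residues=_normalize_residues(str(entry.seq), rid),
            )
        )
    if not records:
        raise FastaError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records with pipe-dialect headers, one unwrapped line each."""
    entries = [
        SeqRecord(Seq(r.residues), id=r.label(), description="") for r in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=None)
        writer.write_file(entries)


@dataclass(frozen=True)
class CodonTranslationTable:
    """A genetic-code table mapping all 64 codons to amino-acid symbols.

    ``codon_to_aa`` maps every codon (including stops, as ``*``);
    ``stop_codons`` is the set of codons mapping to ``*``.
    """

    table_id: int
    codon_to_aa: dict[str, str] = field(repr=False)
    stop_codons: frozenset[str]

    @classmethod
    def from_ncbi(cls, table_id: int = 5) -> "CodonTranslationTable":
        ncbi = CodonTable.unambiguous_dna_by_id[table_id]
        mapping = dict(ncbi.forward_table)
        for codon in ncbi.stop_codons:
            mapping[codon] = "*"
        assert len(mapping) == 64
        return cls(
            table_id=table_id,
            codon_to_aa=mapping,
            stop_codons=frozenset(ncbi.stop_codons),
        )


#: NCBI translation table 5 — the biologically forced choice for
#: invertebrate mitochondrial protein-coding loci.
INVERTEBRATE_MITO_TABLE = CodonTranslationTable.from_ncbi(5)


def translate(
    seq: str,
    frame: int = 0,
    table: CodonTranslationTable = INVERTEBRATE_MITO_TABLE,
) -> str:
    """Translate a gap-free nucleotide sequence in the given frame.

    One amino-acid symbol per complete codon starting at ``frame``; a
    trailing partial codon is ignored; codons containing N translate to X.
    Stops are rendered as ``*``.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    if "-" in seq:
        raise ValueError("sequence contains gaps; degap before translating")
    seq = seq.upper()
    out = []
    for i in range(frame, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        out.append("X" if "N" in codon else table.codon_to_aa[codon])
    return "".join(out)


def at_fraction(seq: str) -> float:
    """AT fraction over unambiguous bases; gaps and N are excluded entirely."""
    seq = seq.upper()
    counted = sum(1 for ch in seq if ch in UNAMBIGUOUS)
    if counted == 0:
        raise ValueError("no unambiguous base: AT fraction undefined")
    at = sum(1 for ch in seq if ch in "AT")
    return at / counted


def gc_fraction(seq: str) -> float:
    """GC fraction over unambiguous bases; complements :func:`at_fraction`."""
    return 1.0 - at_fraction(seq)
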