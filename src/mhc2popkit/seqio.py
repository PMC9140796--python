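"""Sequence and clone-table I/O for the MHC class II exon-2 toolkit.

The unit of analysis throughout the package is an in-frame codon alignment:
equal-length nucleotide haplotypes whose length is a multiple of three.  The
amplicon this package was written for is the 198-bp exon 2 of the MHC class II
beta chain (66 codons, the beta-1 / peptide-binding domain), but nothing here
is hard-wired to that length.

Clone libraries -- the raw product of cloning + Sanger sequencing of PCR
products -- are read from a plain TSV mapping (individual, PCR replicate,
clone) to a sequence.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DEFAULT_LENGTH = 198
VALID_BASES = frozenset("ACGT")
VALID_BASES_WITH_N = frozenset("ACGTN")


class AlignmentLengthError(ValueError):
    """A record's length violates the expected in-frame alignment length."""


class CloneTableError(ValueError):
    """The clone TSV is malformed (schema or duplicate keys)."""


@dataclass(frozen=True)
class CodonAlignment:
    """Equal-length, in-frame nucleotide haplotypes.

    Attributes
    ----------
    records : tuple of (id, seq)
        Sequences uppercased, order preserved from the source.
    length : int
        Alignment length in nucleotide sites; divisible by 3.
    """

    records: tuple[tuple[str, str], ...]
    length: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("alignment must contain at least one record")
        L = len(self.records[0][1])
        object.__setattr__(self, "length", L)

    @property
    def codon_count(self) -> int:
        return self.length // 3

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.records]

    @property
    def seqs(self) -> list[str]:
        return [seq for _, seq in self.records]

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, ids: Iterable[str]) -> "CodonAlignment":
        """Alignment restricted to ``ids``, keeping the original order."""
        wanted = set(ids)
        kept = tuple((rid, s) for rid, s in self.records if rid in wanted)
        missing = wanted - {rid for rid, _ in kept}
        if missing:
            raise KeyError(f"ids not in alignment: {sorted(missing)}")
        return CodonAlignment(kept)


def make_alignment(
    records: Sequence[tuple[str, str]],
    expected_length: int | None = None,
    allow_n: bool = False,
) -> CodonAlignment:
    """Validate and build a :class:`CodonAlignment` from (id, seq) pairs.

    Sequences are uppercased.  Gaps are rejected: the amplicon is
    length-invariant, so a ``-`` signals an upstream curation problem rather
    than something to be handled silently.
    """
    seen: set[str] = set()
    alphabet = VALID_BASES_WITH_N if allow_n else VALID_BASES
    cleaned: list[tuple[str, str]] = []
    for rid, seq in records:
        if rid in seen:
            raise ValueError(f"duplicate sequence ID: {rid!r}")
        seen.add(rid)
        s = seq.upper()
        if expected_length is not None and len(s) != expected_length:
            raise AlignmentLengthError(
                f"record {rid!r} has length {len(s)}, expected {expected_length}"
            )
        if "-" in s:
            raise ValueError(f"record {rid!r} contains gap characters ('-')")
        bad = set(s) - alphabet
        if bad:
            raise ValueError(f"record {rid!r} has invalid characters {sorted(bad)}")
        cleaned.append((rid, s))
    if not cleaned:
        raise ValueError("no records supplied")
    L = len(cleaned[0][1])
    for rid, s in cleaned:
        if len(s) != L:
            raise AlignmentLengthError(
                f"record {rid!r} has length {len(s)}, expected {L} (ragged alignment)"
            )
    if L % 3 != 0:
        raise AlignmentLengthError(f"alignment length {L} is not a multiple of 3")
    return CodonAlignment(tuple(cleaned))


def read_fasta(
    path: str | Path,
    expected_length: int | None = DEFAULT_LENGTH,
    allow_n: bool = False,
) -> CodonAlignment:
    """Read an aligned FASTA into a :class:`CodonAlignment`.

    IDs are taken verbatim from the FASTA headers (first whitespace-separated
    token); records keep file order.
    """
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return make_alignment(records, expected_length=expected_length, allow_n=allow_n)


def write_fasta(aln: CodonAlignment, path: str | Path) -> None:
    """Write the alignment back out; round-trips byte-exactly via read_fasta."""
    recs = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in aln.records]
    SeqIO.write(recs, str(path), "fasta-2line")


@dataclass(frozen=True)
class CloneRecord:
    """One sequenced clone: (individual, PCR replicate, clone) -> sequence."""

    individual_id: str
    pcr_id: str
    clone_id: str
    seq: str

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.individual_id, self.pcr_id, self.clone_id)


CLONE_COLUMNS = ("individual_id", "pcr_id", "clone_id", "sequence")


def read_clone_table(path: str | Path) -> list[CloneRecord]:
    """Read a tab-delimited clone table.

    Expected header: individual_id, pcr_id, clone_id, sequence.  Lines whose
    first non-blank character is '#' are ignored.  Row order is preserved and
    (individual, pcr, clone) keys must be unique.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        rows = [
            line for line in fh
            if line.strip() and not line.lstrip().startswith("#")
        ]
    reader = csv.DictReader(rows, delimiter="\t")
    if reader.fieldnames is None:
        return []
    missing = [c for c in CLONE_COLUMNS if c not in reader.fieldnames]
    if missing:
        raise CloneTableError(f"clone table missing column(s): {missing}")
    clones: list[CloneRecord] = []
    seen: set[tuple[str, str, str]] = set()
    for row in reader:
        rec = CloneRecord(
            individual_id=row["individual_id"],
            pcr_id=row["pcr_id"],
            clone_id=row["clone_id"],
            seq=row["sequence"].upper(),
        )
        if rec.key in seen:
            raise CloneTableError(f"duplicate clone key: {rec.key}")
        seen.add(rec.key)
        clones.append(rec)
    return clones


def write_clone_table(clones: Sequence[CloneRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(CLONE_COLUMNS)
        for c in clones:
            writer.writerow([c.individual_id, c.pcr_id, c.clone_id, c.seq])


@dataclass(frozen=True)
class PeptideSequence:
    """Translation of one haplotype, with internal stop codons flagged."""

    id: str
    aa: str
    stop_positions: tuple[int, ...]  # 1-based codon indices

    @property
    def has_internal_stop(self) -> bool:
        return bool(self.stop_positions)


def translate(aln: CodonAlignment, code: int = 1) -> list[PeptideSequence]:
    """Translate every record codon-by-codon (frame 0, standard code).

    Stop codons anywhere in the frame are translated as '*' and their 1-based
    codon positions recorded.  Codons containing N translate to 'X'.
    """
    table = unambiguous_dna_by_id[code]
    stops = set(table.stop_codons)
    fwd = table.forward_table
    out: list[PeptideSequence] = []
    for rid, seq in aln.records:
        aa_chars: list[str] = []
        stop_pos: list[int] = []
        for i in range(0, len(seq), 3):
            codon = seq[i : i + 3]
            if "N" in codon:
                aa_chars.append("X")
            elif codon in stops:
                aa_chars.append("*")
                stop_pos.append(i // 3 + 1)
            else:
                aa_chars.append(fwd[codon])
        out.append(PeptideSequence(id=rid, aa="".join(aa_chars), stop_positions=tuple(stop_pos)))
    return out


def has_internal_stop(seq: str, code: int = 1) -> bool:
    """True if the in-frame nucleotide sequence contains a stop codon."""
    aln = CodonAlignment((("_", seq.upper()),))
    return translate(aln, code=code)[0].has_internal_stop
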