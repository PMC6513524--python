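"""Sequence containers, FASTA I/O and translation.

Conventions shared by the whole package:

* nucleotide sequences are stored as DNA (``U`` is normalised to ``T`` on
  ingest) over the alphabet ``ACGTN``; other ambiguity codes are rejected,
* protein sequences use the 20 standard residues plus ``X``,
* all coordinates are 0-based, half-open ``[start, end)``; conversion to
  1-based happens only at I/O boundaries (e.g. GFF3 export),
* translation uses the bacterial/plastid genetic code (NCBI table 11),
  because every known ssRNA phage host is a bacterium.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

NUCLEOTIDE_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: NCBI translation table 11 (bacterial, archaeal and plant plastid code).
CODON_TABLE = CodonTable.unambiguous_dna_by_id[11]


class FastaParseError(ValueError):
    """Raised for malformed FASTA input or alphabet/id violations."""


@dataclass(frozen=True)
class NucleotideSequence:
    """A DNA-alphabet nucleotide sequence (RNA inputs are normalised)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if len(self.seq) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.seq) - NUCLEOTIDE_ALPHABET
        if bad:
            raise FastaParseError(
                f"record {self.id!r}: characters outside nucleotide alphabet: "
                f"{sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.seq)

    def as_rna(self) -> str:
        """The sequence with ``T`` rendered as ``U``."""
        return self.seq.replace("T", "U")


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence over the 20 standard residues plus ``X``."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if len(self.seq) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.seq) - PROTEIN_ALPHABET
        if bad:
            raise FastaParseError(
                f"record {self.id!r}: characters outside protein alphabet: "
                f"{sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.seq)


def _normalise_nt(raw: str) -> str:
    return raw.upper().replace("U", "T")


def read_fasta(
    path: str | Path,
    alphabet: Literal["nucleotide", "protein"],
) -> list[NucleotideSequence] | list[ProteinSequence]:
    """Read a FASTA file into validated sequence records.

    Records are returned in file order.  Lowercase is uppercased and, for
    nucleotide input, ``U`` is normalised to ``T``.  Duplicate ids, characters
    outside the declared alphabet and malformed entries raise
    :class:`FastaParseError`.
    """
    path = Path(path)
    if alphabet not in ("nucleotide", "protein"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    records = []
    seen: dict[str, int] = {}
    with open(path) as handle:
        first = handle.read(1)
        if first and first != ">":
            raise FastaParseError(
                f"{path}: line 1 does not start a FASTA record ('>' expected)"
            )
        handle.seek(0)
        for rec in SeqIO.parse(handle, "fasta"):
            seen[rec.id] = seen.get(rec.id, 0) + 1
            raw = str(rec.seq).upper()
            if alphabet == "nucleotide":
                records.append(NucleotideSequence(rec.id, _normalise_nt(raw)))
            else:
                records.append(ProteinSequence(rec.id, raw))
    duplicates = sorted(i for i, n in seen.items() if n > 1)
    if duplicates:
        raise FastaParseError(f"{path}: duplicate sequence ids: {duplicates}")
    if not records:
        logger.warning("%s: no FASTA records found", path)
    return records


def write_fasta(
    records: Iterable[NucleotideSequence | ProteinSequence],
    path: str | Path,
    width: int = 80,
) -> None:
    """Write records as multi-FASTA, wrapped at ``width`` columns.

    Round-trip property: ``read_fasta(write_fasta(x)) == x``.
    """
    seqrecords = [
        SeqRecord(Seq(r.seq), id=r.id, description="") for r in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(seqrecords)


def translate(nt: NucleotideSequence, frame_start: int = 0) -> ProteinSequence:
    """Translate codon-by-codon under NCBI table 11.

    Translation starts at ``frame_start`` (0-based) and proceeds until the
    first in-frame stop codon (not included in the output) or the sequence
    end; a trailing partial codon is ignored.  A codon containing ``N``
    translates to ``X``.  Note: start codons are *not* remapped to M here —
    that convention belongs to the ORF caller.
    """
    if not 0 <= frame_start < nt.length:
        raise ValueError(
            f"frame_start {frame_start} out of range for {nt.id!r} "
            f"(length {nt.length})"
        )
    residues = []
    for i in range(frame_start, nt.length - 2, 3):
        codon = nt.seq[i : i + 3]
        if codon in CODON_TABLE.stop_codons:
            break
        aa = CODON_TABLE.forward_table.get(codon)
        if aa is None:
            # only N-containing codons reach here (alphabet is ACGTN)
            aa = "X"
        residues.append(aa)
    if not residues:
        raise ValueError(
            f"translation of {nt.id!r} at offset {frame_start} is empty"
        )
    return ProteinSequence(nt.id, "".join(residues))
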