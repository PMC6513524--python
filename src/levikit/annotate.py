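"""ORF finding and maturation/CP/replicase layout assignment.

ssRNA phage genomes carry three core genes in a fixed order —
maturation, coat protein (CP), replicase — and in partial metagenomic
assemblies the coat protein is identified positionally: it is the ORF
immediately following the maturation gene.  This module finds forward-strand
ORFs, applies that layout rule given hints locating the maturation and
replicase genes, and extracts the window around the replicase start codon
used for translational-operator (TR) hairpin prediction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

from .io import CODON_TABLE, NucleotideSequence, ProteinSequence, translate

logger = logging.getLogger(__name__)

#: Start codons accepted by the ORF caller.  GTG is common in phage and
#: bacterial genes; TTG is deliberately excluded (configurable).
DEFAULT_START_CODONS = ("ATG", "GTG")

#: ORFs may overlap the maturation stop / replicase start by up to this many
#: nucleotides and still count as lying "between" the two genes.
DEFAULT_OVERLAP_TOLERANCE = 30

Role = Literal["maturation", "cp_candidate", "replicase", "other", "unassigned"]


@dataclass(frozen=True)
class OrfAnnotation:
    """A forward-strand ORF with 0-based half-open coordinates.

    ``end`` includes the stop codon when one is present (``partial`` is set
    when the ORF runs off the contig end without a stop).
    """

    start: int
    end: int
    frame: int
    protein: ProteinSequence
    partial: bool = False
    role: Role = "unassigned"
    primary: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("ORF end must exceed start")


@dataclass
class GenomeRecord:
    """A genome sequence with its ORF annotations and layout state."""

    sequence: NucleotideSequence
    orfs: list[OrfAnnotation] = field(default_factory=list)
    layout_complete: bool = False

    @property
    def maturation(self) -> OrfAnnotation | None:
        return next((o for o in self.orfs if o.role == "maturation"), None)

    @property
    def replicase(self) -> OrfAnnotation | None:
        return next((o for o in self.orfs if o.role == "replicase"), None)

    @property
    def cp_candidates(self) -> list[OrfAnnotation]:
        return [o for o in self.orfs if o.role == "cp_candidate"]

    @property
    def primary_cp(self) -> OrfAnnotation | None:
        return next((o for o in self.orfs if o.primary), None)


def find_orfs(
    genome: NucleotideSequence,
    min_protein_length: int = 30,
    start_codons: Sequence[str] = DEFAULT_START_CODONS,
) -> list[OrfAnnotation]:
    """Find all forward-strand ORFs in the three reading frames.

    An ORF begins at a start codon (ATG/GTG by default) and ends at the end
    of the first in-frame stop codon, or at the last complete codon of the
    contig (flagged ``partial``).  Nested ORFs sharing a stop are all
    reported (one per start codon).  The first codon is translated as M.
    ORFs whose protein is shorter than ``min_protein_length`` are discarded;
    results are sorted by start coordinate.
    """
    if min_protein_length < 1:
        raise ValueError("min_protein_length must be >= 1")
    seq = genome.seq
    n = len(seq)
    stops = set(CODON_TABLE.stop_codons)
    orfs: list[OrfAnnotation] = []
    for frame in range(3):
        i = frame
        while i <= n - 3:
            codon = seq[i : i + 3]
            if codon in start_codons:
                j = i + 3
                stop_found = False
                while j <= n - 3:
                    if seq[j : j + 3] in stops:
                        stop_found = True
                        break
                    j += 3
                end = j + 3 if stop_found else frame + 3 * ((n - frame) // 3)
                # protein spans [i, stop) or [i, end) when partial
                coding_end = j if stop_found else end
                if coding_end - i >= 3:
                    body = _translate_orf(genome, i, coding_end)
                    if len(body) >= min_protein_length:
                        orfs.append(
                            OrfAnnotation(
                                start=i,
                                end=end,
                                frame=frame,
                                protein=ProteinSequence(
                                    f"{genome.id}|orf_{i}", body
                                ),
                                partial=not stop_found,
                            )
                        )
            i += 3
    orfs.sort(key=lambda o: (o.start, o.end))
    return orfs


def _translate_orf(genome: NucleotideSequence, start: int, coding_end: int) -> str:
    """Translate ``[start, coding_end)`` with the first codon forced to M."""
    prot = translate(
        NucleotideSequence(genome.id, genome.seq[start:coding_end] + "TAA"),
        0,
    )
    return "M" + prot.seq[1:]


def _resolve_hint(
    orfs: Sequence[OrfAnnotation], hint: int | tuple[int, int] | None
) -> OrfAnnotation | None:
    """Resolve a locator hint (a start offset or a (start, end) pair)."""
    if hint is None:
        return None
    if isinstance(hint, tuple):
        start, end = hint
        for o in orfs:
            if o.start == start and o.end == end:
                return o
        return None
    for o in orfs:
        if o.start == hint:
            return o
    return None


def assign_layout(
    genome: GenomeRecord,
    maturation_hint: int | tuple[int, int] | None,
    replicase_hint: int | tuple[int, int] | None,
    overlap_tolerance: int = DEFAULT_OVERLAP_TOLERANCE,
) -> GenomeRecord:
    """Apply the positional coat-protein rule to an annotated genome.

    Hints locate the maturation and replicase ORFs by start coordinate (or
    ``(start, end)`` pair).  Every ORF whose interval lies between the
    maturation end and the replicase start — allowing ``overlap_tolerance``
    nucleotides of overlap on either side — is labelled ``cp_candidate``;
    the candidate with the smallest start (the ORF immediately following the
    maturation gene) is flagged primary.  If either hint fails to resolve,
    ``layout_complete`` stays False and no candidate labels are assigned.
    """
    orfs = [replace(o, role="unassigned", primary=False) for o in genome.orfs]
    mat = _resolve_hint(orfs, maturation_hint)
    rep = _resolve_hint(orfs, replicase_hint)
    if mat is None or rep is None or mat is rep:
        logger.warning(
            "%s: maturation/replicase hints unresolved; layout incomplete",
            genome.sequence.id,
        )
        return GenomeRecord(genome.sequence, orfs, layout_complete=False)
    out: list[OrfAnnotation] = []
    lo = mat.end - overlap_tolerance
    hi = rep.start + overlap_tolerance
    for o in orfs:
        if o is mat:
            out.append(replace(o, role="maturation"))
        elif o is rep:
            out.append(replace(o, role="replicase"))
        elif o.start >= lo and o.end <= hi:
            out.append(replace(o, role="cp_candidate"))
        else:
            out.append(replace(o, role="other"))
    candidates = [o for o in out if o.role == "cp_candidate"]
    if candidates:
        first = min(candidates, key=lambda o: (o.start, o.end))
        out = [
            replace(o, primary=True) if o is first else o for o in out
        ]
    return GenomeRecord(genome.sequence, out, layout_complete=True)


@dataclass(frozen=True)
class ReplicaseWindow:
    """The RNA window around a replicase start used for hairpin folding."""

    id: str
    rna: str
    start_offset: int  # offset of the replicase first nucleotide in the window
    truncated: bool

    @property
    def length(self) -> int:
        return len(self.rna)


def extract_replicase_window(
    genome: GenomeRecord, flank: int = 20
) -> ReplicaseWindow:
    """Extract ``flank`` nt either side of the replicase first nucleotide.

    Returns the window ``[start-flank, start+flank+1)`` as RNA letters
    (length ``2*flank + 1`` unless truncated at a contig boundary, in which
    case ``truncated`` is set).
    """
    rep = genome.replicase
    if rep is None:
        raise ValueError(
            f"{genome.sequence.id}: replicase role not assigned; "
            "run assign_layout first"
        )
    if flank < 0:
        raise ValueError("flank must be >= 0")
    n = genome.sequence.length
    lo = max(0, rep.start - flank)
    hi = min(n, rep.start + flank + 1)
    window = NucleotideSequence(genome.sequence.id, genome.sequence.seq[lo:hi])
    return ReplicaseWindow(
        id=genome.sequence.id,
        rna=window.as_rna(),
        start_offset=rep.start - lo,
        truncated=(hi - lo) < 2 * flank + 1,
    )


def orf_table(genome: GenomeRecord) -> str:
    """Render ORF annotations as a TSV string (0-based half-open coords)."""
    lines = ["id\tstart\tend\tframe\trole\tprimary\tpartial\tprotein_length"]
    for o in genome.orfs:
        lines.append(
            f"{genome.sequence.id}\t{o.start}\t{o.end}\t{o.frame}\t{o.role}\t"
            f"{int(o.primary)}\t{int(o.partial)}\t{o.protein.length}"
        )
    return "\n".join(lines) + "\n"


def write_gff3(genomes: Sequence[GenomeRecord], path: str | Path) -> None:
    """Write ORF annotations as GFF3 (conversion to 1-based inclusive here)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genomes:
            for o in g.orfs:
                attrs = f"ID={g.sequence.id}_orf{o.start};role={o.role}"
                if o.primary:
                    attrs += ";primary_cp=true"
                fh.write(
                    f"{g.sequence.id}\tlevikit\tCDS\t{o.start + 1}\t{o.end}\t"
                    f".\t+\t0\t{attrs}\n"
                )
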