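"""Synthetic coat-protein families and phage genomes with planted structure.

Every pipeline stage is testable offline against generated data whose
ground truth is known by construction:

* protein families are derived from independent random ancestors by point
  substitutions to a target identity (planted clusters for the BSR/UPGMA
  stage),
* genomes carry the canonical maturation → CP → replicase layout at known
  coordinates, sized like real ssRNA phage genomes (~3.5–4.2 kb), with an
  optional translational-operator hairpin of configurable geometry planted
  over the replicase start codon.

All generators are bit-reproducible under a fixed seed.  Realism is
deliberately limited: substitutions are uniform over the 19 alternative
residues, reverse translation picks synonymous codons uniformly, and the
intergenic spacers are poly-A so that no spurious start codon can arise
between the maturation and replicase genes (and nothing in a fold window
outside a planted hairpin can base-pair with its stem).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import CODON_TABLE, NucleotideSequence, ProteinSequence

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Sense codons per amino acid under NCBI table 11.
_CODONS_BY_AA: dict[str, list[str]] = {}
for _codon, _aa in CODON_TABLE.forward_table.items():
    _CODONS_BY_AA.setdefault(_aa, []).append(_codon)
for _aa in _CODONS_BY_AA:
    _CODONS_BY_AA[_aa].sort()

_RC = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def mutate_to_identity(
    seq: ProteinSequence, identity: float, seed: int
) -> ProteinSequence:
    """Substitute exactly ``round((1 - identity) * length)`` positions.

    Positions are chosen uniformly without replacement; each substituted
    residue is replaced by one of the 19 alternatives uniformly.
    """
    if not 0 < identity <= 1:
        raise ValueError("identity must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    n_sub = round((1.0 - identity) * seq.length)
    if n_sub == 0:
        return seq
    positions = rng.choice(seq.length, size=n_sub, replace=False)
    residues = list(seq.seq)
    for pos in positions:
        alternatives = AMINO_ACIDS.replace(residues[pos], "")
        residues[pos] = alternatives[rng.integers(len(alternatives))]
    return ProteinSequence(seq.id, "".join(residues))


@dataclass(frozen=True)
class FamilySpec:
    """Planted protein-family design.

    Defaults give three well-separated families of five 130-residue members
    at 80% identity to their ancestor — the planted-recovery benchmark for
    the clustering stage.
    """

    n_families: int = 3
    members_per_family: int = 5
    ancestor_length: int = 130
    within_identity: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1 or self.members_per_family < 1:
            raise ValueError("family counts must be >= 1")
        if not 0 < self.within_identity <= 1:
            raise ValueError("within_identity must lie in (0, 1]")
        if round((1 - self.within_identity) * self.ancestor_length) > (
            self.ancestor_length
        ):
            raise ValueError("target identity unreachable at this length")


def _random_protein(rng: np.random.Generator, name: str, length: int) -> ProteinSequence:
    letters = rng.integers(0, len(AMINO_ACIDS), size=length)
    return ProteinSequence(name, "".join(AMINO_ACIDS[i] for i in letters))


def generate_families(
    spec: FamilySpec,
) -> tuple[list[ProteinSequence], dict[str, str]]:
    """Generate planted families plus the id → family truth table."""
    rng = np.random.default_rng(spec.seed)
    records: list[ProteinSequence] = []
    truth: dict[str, str] = {}
    for f in range(1, spec.n_families + 1):
        ancestor = _random_protein(rng, f"fam{f}_anc", spec.ancestor_length)
        for m in range(1, spec.members_per_family + 1):
            name = f"fam{f}_m{m}"
            member = mutate_to_identity(
                ProteinSequence(name, ancestor.seq),
                spec.within_identity,
                seed=int(rng.integers(2**31)),
            )
            records.append(member)
            truth[name] = f"fam{f}"
    return records, truth


@dataclass(frozen=True)
class TrGeometry:
    """Planted hairpin geometry: stem pairs, loop sequence (must start with
    the AUG of the replicase), and the bulged-A position along the 5' arm."""

    stem_bp: int = 8
    loop_seq: str = "AUGC"
    bulge_after: int = 4

    def __post_init__(self) -> None:
        if self.stem_bp < 2:
            raise ValueError("stem must have at least 2 base pairs")
        if not 0 < self.bulge_after < self.stem_bp:
            raise ValueError("bulge must sit strictly inside the stem")
        if not self.loop_seq.startswith("AUG"):
            raise ValueError("loop must start with the replicase AUG")
        if len(self.loop_seq) < 3:
            raise ValueError("loop too short")


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Planted genome design (lengths in residues for ORFs, nt otherwise).

    Defaults produce ~3.65 kb genomes, inside the 3.5–4.2 kb range typical
    of ssRNA phage genomes.
    """

    n_genomes: int = 5
    maturation_length: int = 400
    cp_length: int = 135
    replicase_length: int = 620
    intergenic_length: int = 30
    utr_length: int = 60
    plant_tr: bool = True
    tr_geometry: TrGeometry = field(default_factory=TrGeometry)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.maturation_length, self.cp_length, self.replicase_length) < 2:
            raise ValueError("ORF lengths must be >= 2 residues")
        if self.intergenic_length < 0 or self.utr_length < 0:
            raise ValueError("spacer lengths must be >= 0")
        if self.plant_tr:
            geom = self.tr_geometry
            if geom.stem_bp + 1 + len(geom.loop_seq) > 21:
                raise ValueError(
                    "hairpin 5' side + loop exceeds the 21 nt available "
                    "before/at the replicase start in a 41 nt window"
                )
            if self.intergenic_length < geom.stem_bp + 1:
                raise ValueError("intergenic spacer too short for the hairpin")


@dataclass(frozen=True)
class GenomeTruth:
    """Planted coordinates (0-based half-open, stop codon included)."""

    id: str
    maturation: tuple[int, int]
    cp: tuple[int, int]
    replicase: tuple[int, int]
    tr_span: tuple[int, int] | None


def _reverse_translate(rng: np.random.Generator, protein: str) -> str:
    codons = ["ATG"]  # planted ORFs always start ATG
    for aa in protein[1:]:
        options = _CODONS_BY_AA[aa]
        codons.append(options[rng.integers(len(options))])
    codons.append("TAA")  # fixed stop
    return "".join(codons)


def _inert_spacer(length: int) -> str:
    """A poly-A spacer.

    Poly-A cannot contain or create ATG/GTG or stop codons in any frame,
    and inside a fold window it can pair with nothing but U — so planted
    hairpin geometry stays the unique maximum-pairing structure.
    """
    return "A" * length


def _random_nt(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def _plant_hairpin(
    genome: list[str], replicase_start: int, geom: TrGeometry
) -> tuple[int, int]:
    """Overwrite the region around the replicase start with a TR hairpin.

    Layout (5'→3'): stem arm (bulge_after nt) · bulged A · stem arm
    (remaining nt) · loop (starts with AUG = replicase start codon) ·
    3' arm (reverse complement of the two 5' arm pieces).
    """
    arm = ("GC" * geom.stem_bp)[: geom.stem_bp]
    loop_dna = geom.loop_seq.replace("U", "T")
    five_prime = arm[: geom.bulge_after] + "A" + arm[geom.bulge_after :]
    # pad the coding side with poly-A (lysine codons) out to the default
    # 20 nt window flank: nothing there can pair, start or stop a codon
    coding = loop_dna + _revcomp(arm)
    pad_to = 21  # replicase-start offset .. +20 inclusive
    if len(coding) < pad_to:
        coding += "A" * (pad_to - len(coding))
    hairpin = five_prime + coding
    start = replicase_start - len(five_prime)
    if start < 0 or start + len(hairpin) > len(genome):
        raise ValueError("hairpin geometry does not fit the genome")
    for k in range(0, len(coding) - 2, 3):
        if coding[k : k + 3] in CODON_TABLE.stop_codons:
            raise ValueError(
                "hairpin geometry writes a stop codon into the replicase"
            )
    genome[start : start + len(hairpin)] = list(hairpin)
    return start, replicase_start + len(loop_dna) + geom.stem_bp


def _spurious_candidate_before_cp(
    seq: str, mat_end: int, cp_start: int, rep_start: int
) -> bool:
    """True if an ORF other than the planted CP could become the first
    coat-protein candidate (start codon in the maturation tail running into
    the inter-gene region).

    Checked at a stricter minimum length (15 residues) than any default the
    annotator uses, so cleanliness holds for downstream choices too.
    """
    from .annotate import DEFAULT_OVERLAP_TOLERANCE, find_orfs

    lo = mat_end - DEFAULT_OVERLAP_TOLERANCE
    hi = rep_start + DEFAULT_OVERLAP_TOLERANCE
    orfs = find_orfs(NucleotideSequence("chk", seq), min_protein_length=15)
    return any(
        o.start >= lo and o.end <= hi and o.start < cp_start for o in orfs
    )


def generate_genomes(
    spec: SyntheticGenomeSpec,
) -> tuple[list[NucleotideSequence], list[GenomeTruth]]:
    """Generate planted genomes plus their coordinate truth tables.

    Each genome is resampled (deterministically) until no spurious ORF can
    precede the planted coat protein between the maturation and replicase
    genes, so the positional CP rule recovers the planted CP by
    construction.
    """
    rng = np.random.default_rng(spec.seed)
    genomes: list[NucleotideSequence] = []
    truths: list[GenomeTruth] = []
    for g in range(1, spec.n_genomes + 1):
        name = f"genome{g}"
        for _attempt in range(100):
            mat = _random_protein(rng, "m", spec.maturation_length).seq
            cp = _random_protein(rng, "c", spec.cp_length).seq
            rep = _random_protein(rng, "r", spec.replicase_length).seq
            parts: list[str] = []
            parts.append(_random_nt(rng, spec.utr_length))
            mat_start = len("".join(parts))
            parts.append(_reverse_translate(rng, mat))
            mat_end = mat_start + 3 * (spec.maturation_length + 1)
            parts.append(_inert_spacer(spec.intergenic_length))
            cp_start = mat_end + spec.intergenic_length
            parts.append(_reverse_translate(rng, cp))
            cp_end = cp_start + 3 * (spec.cp_length + 1)
            parts.append(_inert_spacer(spec.intergenic_length))
            rep_start = cp_end + spec.intergenic_length
            parts.append(_reverse_translate(rng, rep))
            rep_end = rep_start + 3 * (spec.replicase_length + 1)
            parts.append(_random_nt(rng, spec.utr_length))
            genome = list("".join(parts))
            tr_span = None
            if spec.plant_tr:
                tr_span = _plant_hairpin(genome, rep_start, spec.tr_geometry)
            seq = "".join(genome)
            if not _spurious_candidate_before_cp(
                seq, mat_end, cp_start, rep_start
            ):
                break
        else:  # pragma: no cover - vanishingly unlikely
            raise RuntimeError(f"{name}: could not generate a clean layout")
        genomes.append(NucleotideSequence(name, seq))
        truths.append(
            GenomeTruth(
                id=name,
                maturation=(mat_start, mat_end),
                cp=(cp_start, cp_end),
                replicase=(rep_start, rep_end),
                tr_span=tr_span,
            )
        )
    return genomes, truths


def shuffle_window(window: str, seed: int) -> str:
    """Uniformly shuffle a window's nucleotides (null model for TR scans)."""
    rng = np.random.default_rng(seed)
    letters = list(window)
    rng.shuffle(letters)
    return "".join(letters)


def truth_table_tsv(truths: Sequence[GenomeTruth]) -> str:
    """Render genome truth coordinates as TSV."""
    lines = ["id\tmat_start\tmat_end\tcp_start\tcp_end\trep_start\trep_end\ttr_start\ttr_end"]
    for t in truths:
        tr = t.tr_span if t.tr_span is not None else ("", "")
        lines.append(
            f"{t.id}\t{t.maturation[0]}\t{t.maturation[1]}\t{t.cp[0]}\t{t.cp[1]}"
            f"\t{t.replicase[0]}\t{t.replicase[1]}\t{tr[0]}\t{tr[1]}"
        )
    return "\n".join(lines) + "\n"
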