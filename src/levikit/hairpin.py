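"""Replicase-start window folding and translational-operator classification.

The coat protein of several ssRNA phages binds a stem-loop (the
translational operator, TR) spanning the replicase start codon.  The
archetypal TR has an ~8 bp stem interrupted by a single unpaired adenosine
and a 3–6 nt loop; in one conserved cluster the loop carries the
tetranucleotide AUGC.

Folding here is maximum base pairing (a Nussinov dynamic program with a
minimum hairpin loop, AU/GC/GU pairs) — a self-contained, exactly testable
proxy for thermodynamic folding that is adequate for 41-nt windows.  A hook
(:func:`structure_from_dotbracket`) accepts externally computed dot-bracket
strings (e.g. from a thermodynamic folder) so that route stays usable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

RNA_ALPHABET = frozenset("ACGUN")
WC_PAIRS = frozenset({("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")})
#: Watson–Crick plus wobble pairs (the default).
CANONICAL_PAIRS = WC_PAIRS | {("G", "U"), ("U", "G")}


def can_pair(a: str, b: str, allow_gu: bool = True) -> bool:
    return (a, b) in (CANONICAL_PAIRS if allow_gu else WC_PAIRS)


@dataclass
class HairpinStructure:
    """A folded window with stem/loop/bulge features.

    ``stem_length`` counts base pairs in the longest helix, where a helix
    tolerates single-nucleotide interruptions (bulges) on either strand;
    ``loop_length``/``loop_seq`` describe the unpaired run enclosed by the
    innermost pair of that helix; ``bulged_adenosines`` counts the
    single-nucleotide interruptions inside the helix that are adenosines.
    """

    window: str
    dotbracket: str
    pairs: list[tuple[int, int]]
    mfe_proxy: int
    start_codon_offset: int | None = None
    stem_length: int = 0
    loop_length: int = 0
    loop_seq: str = ""
    bulged_adenosines: int = 0
    start_codon_in_hairpin: bool = False
    helix_pairs: list[tuple[int, int]] = field(default_factory=list)


def fold_window(
    window: str,
    min_loop: int = 3,
    start_codon_offset: int | None = None,
    allow_gu: bool = True,
) -> HairpinStructure:
    """Maximum base pairing fold of an RNA window (Nussinov DP).

    Pairs (i, j) require ``j - i > min_loop`` and an AU/GC/GU pairing
    (AU/GC only with ``allow_gu=False``; note wobble pairs break
    reverse-complement symmetry of the pair count).  Among co-optimal
    structures the traceback is deterministic: at each interval the 5' base
    is paired to the outermost (largest j) co-optimal partner, in
    preference to leaving it unpaired.
    """
    window = window.upper().replace("T", "U")
    bad = set(window) - RNA_ALPHABET
    if bad:
        raise ValueError(f"characters outside RNA alphabet: {sorted(bad)}")
    if len(window) < min_loop + 2:
        raise ValueError(
            f"window length {len(window)} < min_loop + 2 = {min_loop + 2}"
        )
    n = len(window)
    best = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            value = best[i + 1][j]  # i unpaired
            for k in range(i + min_loop + 1, j + 1):
                if can_pair(window[i], window[k], allow_gu):
                    inner = best[i + 1][k - 1] if k - i > 1 else 0
                    rest = best[k + 1][j] if k < j else 0
                    value = max(value, inner + 1 + rest)
            best[i][j] = value

    pairs: list[tuple[int, int]] = []

    def traceback(i: int, j: int) -> None:
        while i < j:
            target = best[i][j]
            if target == 0:
                return
            paired = False
            # prefer pairing i, with the largest co-optimal partner k
            for k in range(j, i + min_loop, -1):
                if can_pair(window[i], window[k], allow_gu):
                    inner = best[i + 1][k - 1] if k - i > 1 else 0
                    rest = best[k + 1][j] if k < j else 0
                    if inner + 1 + rest == target:
                        pairs.append((i, k))
                        traceback(i + 1, k - 1)
                        i = k + 1
                        paired = True
                        break
            if not paired:
                i += 1

    traceback(0, n - 1)
    pairs.sort()
    dot = ["."] * n
    for i, j in pairs:
        dot[i], dot[j] = "(", ")"
    structure = HairpinStructure(
        window=window,
        dotbracket="".join(dot),
        pairs=pairs,
        mfe_proxy=best[0][n - 1],
        start_codon_offset=start_codon_offset,
    )
    return extract_features(structure)


def structure_from_dotbracket(
    window: str,
    dotbracket: str,
    start_codon_offset: int | None = None,
) -> HairpinStructure:
    """Build a structure from an externally computed dot-bracket string."""
    window = window.upper().replace("T", "U")
    if len(window) != len(dotbracket):
        raise ValueError("window and dot-bracket lengths differ")
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i, c in enumerate(dotbracket):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            pairs.append((stack.pop(), i))
        elif c != ".":
            raise ValueError(f"unexpected dot-bracket character {c!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    pairs.sort()
    structure = HairpinStructure(
        window=window,
        dotbracket=dotbracket,
        pairs=pairs,
        mfe_proxy=len(pairs),
        start_codon_offset=start_codon_offset,
    )
    return extract_features(structure)


def _helices(
    pairs: Sequence[tuple[int, int]],
) -> list[list[tuple[int, int]]]:
    """Split a nested pair list into helices allowing 1-nt interruptions.

    Consecutive pairs (i, j), (i', j') belong to the same helix when the
    gap on each strand is at most one unpaired nucleotide
    (``i' - i <= 2`` and ``j - j' <= 2``).
    """
    if not pairs:
        return []
    ordered = sorted(pairs)
    helices: list[list[tuple[int, int]]] = []
    current = [ordered[0]]
    for prev, cur in zip(ordered, ordered[1:]):
        (pi, pj), (ci, cj) = prev, cur
        if ci > pi and cj < pj and ci - pi <= 2 and pj - cj <= 2:
            current.append(cur)
        else:
            helices.append(current)
            current = [cur]
    helices.append(current)
    return helices


def extract_features(structure: HairpinStructure) -> HairpinStructure:
    """Populate stem/loop/bulge features from the pair list."""
    helices = _helices(structure.pairs)
    if not helices:
        return replace(
            structure,
            stem_length=0,
            loop_length=0,
            loop_seq="",
            bulged_adenosines=0,
            start_codon_in_hairpin=False,
            helix_pairs=[],
        )
    # longest helix; ties broken toward the 5'-most helix
    helix = max(helices, key=lambda h: (len(h), -h[0][0]))
    inner_i, inner_j = helix[-1]
    outer_i, outer_j = helix[0]
    paired = {i for p in structure.pairs for i in p}
    # terminal loop: the run enclosed by the innermost pair of the helix
    enclosed = list(range(inner_i + 1, inner_j))
    if enclosed and not any(k in paired for k in enclosed):
        loop_seq = structure.window[inner_i + 1 : inner_j]
    else:
        loop_seq = ""
    bulged_a = 0
    for (pi, pj), (ci, cj) in zip(helix, helix[1:]):
        if ci - pi == 2 and pi + 1 not in paired and structure.window[pi + 1] == "A":
            bulged_a += 1
        if pj - cj == 2 and cj + 1 not in paired and structure.window[cj + 1] == "A":
            bulged_a += 1
    in_hairpin = False
    off = structure.start_codon_offset
    if off is not None and structure.window[off : off + 3] == "AUG":
        in_hairpin = not (off + 2 < outer_i or off > outer_j)
    return replace(
        structure,
        stem_length=len(helix),
        loop_length=len(loop_seq),
        loop_seq=loop_seq,
        bulged_adenosines=bulged_a,
        start_codon_in_hairpin=in_hairpin,
        helix_pairs=list(helix),
    )


@dataclass(frozen=True)
class TrCriteria:
    """Thresholds for TR-likeness (the archetype is 8 bp / bulged A / 3–6 nt
    loop over the replicase start; all values configurable)."""

    stem_min: int = 5
    stem_max: int = 12
    loop_min: int = 3
    loop_max: int = 6
    loop_motif: str = "AUGC"
    weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    cutoff: float = 0.75


DEFAULT_CRITERIA = TrCriteria()


@dataclass(frozen=True)
class TrVerdict:
    """Scored TR-likeness with its component feature flags."""

    is_tr_like: bool
    score: float
    stem_ok: bool
    loop_ok: bool
    bulged_a: bool
    start_codon_in_hairpin: bool
    loop_motif: bool
    loop_motif_seq: str


def classify_tr(
    structure: HairpinStructure,
    criteria: TrCriteria = DEFAULT_CRITERIA,
) -> TrVerdict:
    """Score the four TR features and apply the verdict cutoff.

    The score is the weighted mean of {stem_ok, loop_ok, bulged_a,
    start_codon_in_hairpin}; the AUGC loop motif is reported as a separate
    flag and does not enter the score.
    """
    stem_ok = criteria.stem_min <= structure.stem_length <= criteria.stem_max
    loop_ok = criteria.loop_min <= structure.loop_length <= criteria.loop_max
    bulged = structure.bulged_adenosines >= 1
    start_in = structure.start_codon_in_hairpin
    flags = (stem_ok, loop_ok, bulged, start_in)
    weights = criteria.weights
    score = sum(w * f for w, f in zip(weights, flags)) / sum(weights)
    motif = structure.loop_seq == criteria.loop_motif
    return TrVerdict(
        is_tr_like=score >= criteria.cutoff,
        score=score,
        stem_ok=stem_ok,
        loop_ok=loop_ok,
        bulged_a=bulged,
        start_codon_in_hairpin=start_in,
        loop_motif=motif,
        loop_motif_seq=structure.loop_seq if motif else "",
    )
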