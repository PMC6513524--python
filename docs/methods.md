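# Methods

This note records what each stage of levikit computes, the defaults and
why, what the synthetic benchmarks do and do not demonstrate, and the
numerical conventions that make runs reproducible.

## Sequence conventions

Sequences are held as DNA internally (RNA input is normalised U→T on
ingest and rendered back as RNA only in hairpin windows); the nucleotide
alphabet is ACGTN and ambiguity codes other than N are rejected outright —
metagenomic assemblies are dirty, and failing loudly beats silently
translating a B or Y. Translation uses the bacterial/plastid genetic code
(NCBI table 11), since every known ssRNA phage host is a bacterium;
N-containing codons translate to X, and start-codon remapping to M is
applied only by the ORF caller, never by plain translation. Coordinates
are 0-based half-open everywhere except at I/O boundaries (GFF3 export is
1-based inclusive).

## Similarity engine

All-vs-all similarity is Smith–Waterman local alignment with affine gaps,
computed by Biopython's `PairwiseAligner` (BLOSUM62, gap open 11, extend
1; a gap of length L costs 11 + (L−1)·1). Raw scores become bit scores via
the Karlin–Altschul rescaling with the published gapped-BLOSUM62 constants
λ = 0.267, K = 0.041. This is a deliberate approximation of blastp
scoring: it reproduces the scoring model but not BLAST's heuristics
(seeding, X-drop, composition-based statistics), so bit-for-bit agreement
with an actual BLAST run is out of scope. Where fidelity to a real blastp
run matters, its tabular output (outfmt 6 or 10) is ingested instead; the
best (maximum) bit score is kept per ordered query/subject pair (no HSP
summing — the simplest reading of "the bit score of the hit"), every id
must have a self-hit, and absent pairs get bit score 0 so that "no
similarity" maps to distance ≈ 1.

The BSR is asymmetric (different self-score denominators), while UPGMA
needs a symmetric dissimilarity; the distance is therefore
1 − (BSR(q,s)+BSR(s,q))/2, clamped to [0, 1] with an exact zero diagonal.
The symmetrisation choice is recorded in run metadata. The distance is a
valid dissimilarity but not a metric — BSR distances can violate the
triangle inequality, which UPGMA does not require.

## UPGMA clustering

UPGMA is implemented directly (O(n³), size-weighted average-linkage
updates) because the dendrogram is the analysis' central artefact and its
conventions need to be pinned down exactly:

* node heights are half the merge distance, so the tree is ultrametric by
  construction and branch lengths (parent height − child height) are
  non-negative;
* ties on the minimal inter-cluster distance are broken by the smallest
  original leaf index in either cluster, then the smallest index in the
  other — merges are deterministic under input permutation;
* group extraction cuts at cophenetic distance ≤ threshold (node height ≤
  threshold/2), labelling groups g1…gk in dendrogram leaf order.

The default cut threshold of 0.7 (BSR ≈ 0.3) is an operational choice —
similarity groups in this kind of analysis are traditionally read off the
dendrogram by eye, so no published numeric criterion exists; the
`threshold_sweep` report (group count vs threshold, 0 to 1 in steps of
0.05) makes the sensitivity of the group count explicit, and the group
count at any single threshold should be quoted together with it.
scipy's average-linkage clustering serves as an independent reference in
the tests (cophenetic matrices compared to 1e-9), never as the
implementation.

## Genome annotation

The ORF caller reports every forward-strand ORF starting ATG or GTG (GTG
is common in phage and bacterial genes; TTG is excluded by default but the
start-codon set is a parameter) and ending at the first in-frame stop, or
the contig end (flagged partial). Only the forward strand is modelled:
ssRNA phage genomes are positive-sense, and a reverse-complemented contig
should be reoriented, not annotated both ways.

Maturation and replicase genes are located by hints (coordinates or
planted truth labels), not by homology — profile-based gene detection is a
separate problem and deliberately out of scope. Between them, every ORF
whose interval fits with up to 30 nt of overlap tolerance on either side
is a coat-protein candidate; the earliest-starting candidate is primary.
The 30 nt tolerance covers the small gene overlaps known in these genomes
(e.g. lysis genes); it is configurable because "immediately following" has
no published definition when ORFs overlap.

The replicase-start window is genome[start−flank, start+flank+1) with
flank 20 (41 nt when not truncated), rendered as RNA; truncation at contig
edges is flagged rather than padded.

## Hairpin prediction

Folding is maximum base pairing — a Nussinov dynamic program with minimum
loop 3 and AU/GC/GU pairs — rather than thermodynamic minimum free
energy. For 41-nt windows this proxy is adequate to detect the presence
and geometry of a single stem-loop, it is exactly checkable against
brute-force enumeration of all non-crossing pairings (the tests do this
for every window length ≤ 14), and it keeps the package self-contained. A
hook accepts externally computed dot-bracket strings so a thermodynamic
folder can replace the proxy without touching feature extraction.
Caveats worth knowing:

* co-optimal structures are common; the traceback is deterministic
  (pairing preferred over bifurcation, outermost partner preferred), so
  reported structures are reproducible but not unique;
* with wobble pairs enabled the maximum pair count is *not* invariant
  under reverse complementation (G·U maps to the unpairable C·A); the
  invariance holds in Watson–Crick-only mode (`allow_gu=False`), which is
  how the symmetry test runs;
* maximum pairing is promiscuous: an arbitrary uniform-random 41-nt
  window with a centred AUG folds into something TR-like roughly two
  times out of three. TR verdicts are meaningful relative to a
  composition-matched null (see the shuffled-window rate below), not as
  absolute evidence.

Feature extraction takes the longest helix, where a helix tolerates
single-nucleotide interruptions on either strand (larger internal loops
terminate it — this matches the single-bulged-A archetype); the terminal
loop is the unpaired run under the innermost pair of that helix, bulged
adenosines are counted over the helix's single-nt interruptions, and the
start codon must overlap the helix's outermost pair span. The TR score is
the equal-weighted mean of {stem 5–12 bp, loop 3–6 nt, ≥1 bulged A, start
codon inside}; ≥ 0.75 (three of four) is TR-like. The weights and cutoff
are operational constructs — published TR calls were made by visual
inspection — and all of them are configurable; the AUGC loop motif seen in
one conserved phage cluster is reported as a separate flag and does not
enter the score.

## Property table and aggregates

`data/table1.tsv` transcribes the published property table of the 110
experimentally studied coat proteins plus six reference phages;
`data/table1_errata.md` documents every reconstruction decision forced by
the mangled source rendering, the rules used to resolve them (chiefly:
15 °C solubility was only recorded for proteins completely insoluble at
37 °C), and the aggregate counts the transcription implies. Aggregates are
computed over non-reference rows only. "Soluble" means any category above
completely-insoluble, matching the study's "at least partially soluble"
usage; the rescue percentage uses as denominator the insoluble-at-37 °C
proteins with a recorded 15 °C outcome (43 of 44 — one unexpressed protein
has none), giving 86% against the published 85%, whose exact denominator
is not recoverable from the table. The Tm histogram statistic likewise
computes 78% in [50, 70] °C against the published "~77%". Percentages are
rounded half away from zero to match the table's presentation style.

The disulfide screen asks only whether cysteine placement is *consistent
with* the confirmed inter-subunit disulfide pattern (≥ 2 cysteines, ≤ 8
residues apart, both in the central 60% of the chain — defaults read off
the confirmed examples, e.g. positions 61/66 in a 118-residue protein); it
predicts nothing about whether bonds actually form.

## Synthetic data: what passing tests show

The family generator derives each family from an independent random
ancestor by substituting exactly round((1−identity)·length) positions,
uniformly over the 19 alternative residues. Defaults (3 families × 5
members, 130 residues, 80% identity to the ancestor, hence ~64% expected
pairwise identity between members) give within-family pairwise 1−BSR
distances around 0.4–0.5, versus 0.92–0.96 between families — a
well-separated regime in which the 0.7 cut recovers the planted partition
in every seeded replicate. This
demonstrates correctness of the pipeline's plumbing, not clustering power
on hard instances: real coat-protein groups have indels, length variation
and substitution-matrix structure the generator deliberately omits.

The genome generator emits ~3.65 kb genomes (inside the 3.5–4.2 kb range
of real ssRNA phage genomes) with maturation (400 aa), CP (135 aa) and
replicase (620 aa) genes separated by 30 nt spacers and 60 nt UTRs.
Spacers are poly-A: no start or stop codon can arise in or across them in
any frame, and within a fold window poly-A is inert, so the planted
hairpin is the unique maximum-pairing structure. Each genome is
deterministically resampled until no spurious ORF in another frame could
precede the planted CP between maturation and replicase, so positional CP
recovery is 100% by construction — the corresponding test checks the
machinery, not a statistical property. The planted TR (8 bp GC stem,
bulged A after 4 pairs, AUGC loop over the start codon, poly-A-padded
coding side) is recovered with exactly stem 8 / loop AUGC / one bulged A
in all seeds; shuffling the extracted window gives ≤ 10% TR-like calls
(measured 0–2%), which bounds the false-positive rate for windows of that
(A-rich) composition only.

## Problem sizes and determinism

The shipped verification (`scripts/acceptance.py`, seconds of runtime)
uses: 200 random dissimilarity matrices up to n = 12 for UPGMA-vs-scipy
agreement; 120 random pairs of length ≤ 8 over a reduced residue alphabet
for alignment-vs-enumeration agreement (the enumeration oracle walks all
alignment skeletons, C(16,8) ≈ 1.3·10⁴ per pair at the maximum); 500
random windows of length ≤ 14 for folding-vs-enumeration agreement; 50
seeded family replicates and 50 planted genomes for the recovery rates.
All randomness flows from the single `--seed` through child seeds below
2³¹. Pipeline runs with identical inputs and configuration produce
byte-identical primary outputs, and every output file carries a short
configuration hash in its header.

## Known limitations

* Alignment scores approximate the BLAST scoring model, not BLAST itself;
  group boundaries obtained from internal scores can differ from those
  obtained from real blastp output (the CSV route exists for this).
* No E-values, HSP chaining, indel modelling in the generator, readthrough
  or frameshift genes (e.g. the Qβ A1 extension), reverse-strand models,
  or thermodynamic folding ensembles.
* The cluster count at any threshold is threshold-dependent by nature;
  only the sweep is meaningful for comparing datasets.
* TR classification encodes one archetype; operators with materially
  different geometry would need their own criteria.
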