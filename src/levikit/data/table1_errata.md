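# table1.tsv — transcription notes

`table1.tsv` transcribes the published property table of the 110
experimentally studied metagenomic ssRNA phage coat proteins plus six
previously studied reference phages (rows with `reference = 1`: MS2, Qβ,
PRR1, PP7, AP205, Cb5).  The available text rendering of the table
concatenates the symbol columns (`TR`, `Production`, `Solubility 37/15 °C`,
`EM`) without separators, so some cell boundaries had to be reconstructed.
The rules used, and the individually resolved cells, are listed here.

## Reconstruction rules

1. Solubility at 15 °C carries a value only for proteins completely
   insoluble at 37 °C ("the proteins were produced at 15 °C only if they
   were completely insoluble at 37 °C"); soluble-at-37 rows have `n.d.`
   there.  This anchors the split of every `+` run.
2. `n/a` in the morphology/diameter/Tm columns implies no VLPs (EM `-` or
   `n.d.`), and conversely.
3. Within a run of `+` signs the EM and 37 °C-solubility cells were filled
   right-to-left (up to `+++` each), then production, then TR.  The TR and
   production cells of such rows are therefore approximate; neither enters
   any aggregate statistic.
4. `±` is written `+/-` (very low). It occurs as a 37 °C solubility value
   for Beihai3, Wenzhou2, EMS007 and ESE001; such proteins were not re-grown
   at 15 °C, so they are counted as partially soluble at 37 °C.

## Individually resolved cells

* **ESE007** — S–S cell extracted as `M`, not a legend code; set to `N`
  following the running text ("none of the newly characterized VLPs with
  the highest melting temperatures (… ESE007, 90 °C …) have disulfide
  bonds").
* **Beihai33** — the row is a single 12-symbol `+` run with no `n.d.`
  marker; set sol37 `+++` / sol15 `n.d.` per rule 1 and TR `+` per the
  running text (prominent AUGC-loop hairpin).
* **Wenzhou1** — EM extracted as `++` followed by `n/a n/a n/a`; EM `++`
  kept (required by the text's own counts: 80 VLP formers overall, VLP
  formation "for less than a half" of the 21 Cb5-group proteins = 10) and
  morphology/diameter/Tm recorded as not determined.
* **EMS011** — cysteine cell `64.68` read as positions 64, 68 (decimal
  point for comma), matching EMS017/EMS002 paralogues.
* **AVE007** — cysteine cell `46.134` read as positions 46, 134.
* **EMS017** — production `-` (not detected); the two `n.d.` cells are
  taken as sol15/EM.  Its 37 °C insolubility has no recorded 15 °C
  follow-up, so it is excluded from the rescue denominator.
* **GALQ01040378** — `- - -` + `n.d.` transcribed literally (production
  not detected, insoluble at both temperatures); this is the sixth row
  insoluble at 15 °C, matching "only six remained in inclusion bodies".
* **ESE046** — Tm extracted as `36` (not a 5 °C multiple; possibly 35);
  kept as printed.  It lies outside [50, 70] either way.

## Aggregates implied by this transcription

110 constructs; 80 VLP formers; 44 proteins completely insoluble at 37 °C,
of which 43 have a recorded 15 °C outcome: 37 rescued (86%; the original
study prints 85%, whose exact denominator is not recoverable from the
table) and 6 still insoluble; 64 numeric Tm values of which 50 lie in
[50, 70] °C (78%, printed as "~ 77%"); 5 pentamer+hexamer disulfide VLPs; Tm
extremes 35/95 °C; length extremes 105/208 residues.
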