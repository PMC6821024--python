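# Methods

This document describes the scientific model implemented by
`dmnlkit`, its parameter defaults, and the numerical choices behind
each detector. Data structures are order-level unless stated
otherwise; sequence coordinates are 0-based, half-open, on the
forward (heavy) strand of a circular molecule.

## 1. The gene-order model

A mitogenome is a circular, ordered list of stranded features
(`GenomeArrangement`): 13 protein genes, 2 rRNAs, 22 tRNAs
(`S1` = Ser(UCN), `S2` = Ser(AGY), `L1` = Leu(UUR), `L2` = Leu(CUN)),
one or two control regions (CR, or CR1/CR2 when both survive), the
light-strand replication origin O_L, and — after degeneration —
spacer features that carry the name of the gene they derive from.
Strand `H`/`L` denotes transcriptional polarity (serialized `+`/`−`).

The ancestral (canonical teleost) order anchors at tRNA-F:

```
F 12S V 16S L1 ND1 I Q M ND2 W A N OL C Y COI S1 D COII K ATP8 ATP6
COIII G ND3 R ND4L ND4 H S2 L2 ND5 ND6 E CytB T P CR
```

with the nine L-strand genes {Q, A, N, C, Y, S1, ND6, E, P}.

Equality of arrangements (`arrangements_equal`) is rotation-invariant
(circularity) and ignores spacers by default; dimer comparisons also
compare copy tags. Mixing a monomer with a dimer is an error, not
`False`.

Thirteen bothid species fixtures are bundled, keyed by abbreviation
(C.az, C.ko, C.va — Type I; B.my, A.po, C.lu — Type II; G.p, A.t,
L.g, L.l, P.i — Type III; B.pa, A.in — Type IV; A.in additionally
carries the tRNA-V shuffle 12S-16S-V-L1).

## 2. The DMNL engine

`run_dmnl(start, config)` executes:

1. **Dimerize** — concatenate a `plain` and a `prime` copy of the
   monomer head-to-tail: 74 genes, 2 CRs, 2 O_L loci.
2. **Transcribe** — four promoters (HSP/LSP per CR). An H-strand unit
   runs forward from its CR to the TAS of the *next* CR; an L-strand
   unit runs backward to the first tRNA-L1 it meets. Every gene is
   covered by at least one unit while all promoters work.
3. **Non-random loss** — the promoter pair named in
   `config.lost_promoters` (default `{HSP, LSP}` of one CR) stops
   functioning. Genes covered only by the dead units are no longer
   transcribed and degenerate in place into spacer features that
   remember their source (`provenance`). Two exceptions:
   * **tRNA-N retention**: the surviving tRNA-N is the copy upstream
     of the surviving COI (with its adjacent O_L), not the copy the
     transcription bookkeeping would predict — the O_L stem-loop
     must re-form between tRNA-N and COI, which fixes the retained
     copy positionally.
   * **CR survival** (`cr_mode`): `retain_both` keeps both CRs
     (Type III; relabeled CR1/CR2 such that CR1 is the copy whose
     next surviving gene is tRNA-Q); `retain_one` keeps the CR that
     does *not* follow the cluster-terminal tRNA-P (Types I/II);
     `retain_one_full_loss` keeps the P-adjacent CR and degenerates
     the other one entirely into a CR-provenance spacer (Type IV).
4. **tRNA-D translocation** — `d_timing="after"` moves D to
   `d_target` after the loss (Type I: between T and the CR;
   Types II–IV: between S1 and ND6, splitting the 8-gene cluster
   5 + 3). `d_timing="before"` applies one pre-dimerization move
   instead and lets the geometry carry D through. Both timings reach
   the same final order.
5. **tRNA-V shuffle** — optional local move of V from 12S-V-16S to
   12S-16S-V (Type IV only; observed in one species).

The result exposes `final` (genes + CRs + O_L), `final_with_spacers`
(including every degenerated remnant), the degeneration list, and a
line-oriented event log.

For every fixture there is a config whose `run_dmnl` output equals
the fixture, and `classify(run_dmnl(config).final) == config.type_label`
for all legal configs (tested exhaustively).

## 3. Type classification

`classify` inspects only gene/CR topology. The span between tRNA-T
and tRNA-F (circularly) is matched against four templates:

| type | tail between T and F |
|------|----------------------|
| I    | D, CR, Q A C Y S1 ND6 E P |
| II   | CR, Q A C Y S1, D, ND6 E P |
| III  | CR1, Q A C Y S1, D, ND6 E P, CR2 |
| IV   | Q A C Y S1, D, ND6 E P, CR |

The canonical order maps to `ancestral`; anything else is
`unclassified` — never forced into the nearest type. Missing genes
are an error that names them. The V-shuffle is reported orthogonally
(`v_shuffled`), as is whether D's gene neighbors both belong to the
cluster (`d_inside_cluster`).

## 4. Translocation-timing parsimony

For an observed order and its type config, `scenario_search` counts
the minimal number of tRNA-D translocations needed under each timing:

* **after** — run the engine with no D move, then breadth-first
  search over single-gene D translocations (depth ≤ `max_events`,
  default 3);
* **before** — move D to some monomer adjacency first, run the
  engine, then complete with post-loss moves; minimized over all
  pre-move targets by iterative deepening on the total event count.

Only D translocations count as events; the loss step itself is the
given. `parsimony_verdict` returns `after`, `before`, `tie`, or
`unresolved` (nothing reaches the observed order within the budget).
Across the 13 fixtures this yields 10 × `after` (Types II–IV: 1 move
after vs 2 before) and 3 × `tie` (Type I: 1 vs 1).

## 5. Spacer provenance tracing

Because degeneration happens in place, each intergenic spacer should
sit exactly where the model predicts a degenerated gene.
`predict_spacer_loci(config)` runs the engine and merges consecutive
degenerated genes between the same surviving neighbors into one locus
whose `candidate_sources` lists all of them — ambiguity is preserved,
never resolved by guessing. Loci carry identifiers from a bundled
14-entry numbering (1–12 plus the repeated loci 6′ and 10′), keyed on
CR-normalized neighbor pairs; loci outside the table get fresh `x1…`
labels.

`match_observed` fills in per-genome gap lengths: a locus counts as
observed when the annotated genome shows a gap ≥ 2 bp between the
same neighbors. Gaps with no DMNL signal (the V-shuffle region, the
H/S2 doublet, gaps present in non-rearranged teleosts) are excluded
by a fixed list. `census` aggregates a cohort into a tidy table with
per-species unique-spacer counts and per-locus length ranges.

## 6. Sequence-level detectors

**Hairpin search** (`find_hairpin`) is exhaustive over (position,
stem, loop): stem 8–15 bp, loop 3–15 nt, at most 1 mismatch, G·T
wobbles allowed and counted separately. Best = longest stem, then
fewest mismatches, then leftmost. No thermodynamics: the targets are
short canonical stems, and a base-pairing heuristic keeps the search
exact and fast. Note that with a 1-mismatch budget any planted stem
can legitimately be reported one pair longer (the detector absorbs a
flank or loop position); tests therefore assert overlap with the
planted structure, not identity.

**O_L detection** (`detect_ol`) runs a three-step cascade between
tRNA-N and COI, mirroring how the origin re-forms after the WANCY
region is disrupted: (1) the spacer alone; (2) the spacer extended by
3, then 4, then 5 bases of tRNA-N; (3) a centered 26-nt window inside
tRNA-N for genomes whose spacer is too short to fold. Conserved flank
motifs (5′ GGTGG/GGGGG/GCCGG, 3′ TAGA) are sought within 8 nt of the
stem, overlapping 3 nt into it because the mismatch-tolerant search
may absorb a motif edge.

**Control regions**: `scan_tas` reports every match of the TAS core
ACAT-n-TGTA (overlaps included); `find_tandem_repeats` finds maximal
exact tandem arrays by period autocorrelation (period ≥ 10, ≥ 3
copies, fractional final copies reported to one decimal), keeping a
non-overlapping longest-first subset.

## 7. Synthetic genomes

`synth_sequence(arrangement, params)` realizes any arrangement as an
annotated circular sequence. Defaults (the study conditions):

| parameter | default |
|-----------|---------|
| gene lengths | canonical vertebrate table (monomer ≈ 16.5 kb); tRNAs uniform 65–75 bp |
| GC fraction | 0.45 |
| CR | ≈ 900 bp: pad + TAS core + pad + 35 × 22 bp tandem array at the 3′ end |
| O_L | planted stem-loop, default mode `spacer_plus_trnaN_3prime` with 4 recruited tRNA-N bases, flank motifs GGTGG/TAGA |
| spacer remnants | uniform 2–88 bp; degenerated CRs 155–511 bp with probability 0.75; full disappearance with probability 0.15 |

All randomness flows through `numpy.random.default_rng([seed, k])`
with the user seed reduced mod 2³¹; identical seeds give identical
output. For rearranged monomers the generator verifies with
`detect_ol` that the planted structure is recoverable *in the planted
mode*, resampling locally (hairpin arms and padding) and then
globally a bounded number of times. Two structural constraints make
the overlap mode verifiable: the planted stem equals the detector
minimum (8 bp — dropping one recruited pair leaves it unrecognizable)
and the loop is capped at min_loop + 1 (4 nt — otherwise the mismatch
budget would let a truncated stem regrow through the loop).

`evolve_degeneration(dimer_seq, config, params)` degenerates a
realized canonical dimer at sequence level: surviving genes keep
their sequence; every degenerated gene (and, for Type IV, the whole
lost CR) is truncated to a random contiguous slice of its own
sequence, so remnants are homologous to their sources in principle —
though tracing, like the underlying analysis, uses position only.
`ground_truth` maps every locus to its true source and remnant
length; across 20 seeded cohorts, spacer tracing attributes ≥ 95 % of
nonzero remnants to a candidate set containing the true source
(tested).

## 8. Scope and limitations

* Fixtures are order-level; per-species base coordinates come only
  from synthetic genomes or user-supplied GenBank records.
* The "functional loss by mutation" step is instantaneous; no
  substitution process or degeneration-rate model is simulated.
* Hairpin scoring is combinatorial, not thermodynamic; no CSB
  consensus detection; no tRNA cloverleaf validation.
* Parsimony counts only tRNA-D translocations, with a small event
  budget (default 3) — the analysis question is a 1-vs-2 comparison,
  so deeper searches are out of scope.
* The real-data spacer census (121 spacers at 14 loci) requires
  downloaded records; the package validates the machinery on
  synthetic cohorts with known ground truth instead.
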