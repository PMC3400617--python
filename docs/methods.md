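# Methods

This note documents the models, rules and numerical choices behind the
toolkit, the parameters that matter, and what the test suite does and
does not establish.

## Hairpin architecture

A design is `passenger + loop + guide`, all RNA, 5′→3′:

- **guide** — the mature miRNA\* the user wants expressed, placed in the
  3′ arm. Accepted length 18–26 nt (warning outside 20–24; typical
  mature miRNAs are 20–24 nt).
- **passenger** — the exact reverse complement of the guide, placed in
  the 5′ arm, optionally carrying recorded substitutions. Unlike natural
  precursors, whose stems contain mismatches and internal loops, the
  engineered stem is fully base-paired apart from the deliberate
  mutations; this removes any dependence on precursor-specific
  processing determinants.
- **loop** — default `UUCAAGAGA`, the widely used 9-nt shRNA loop.
  Alternative loops are accepted down to a 4-nt minimum (below which a
  hairpin cannot close).

All coordinates throughout the toolkit are 1-based from the 5′ end of
the strand under discussion. Every design object enforces the central
invariant that reverting its recorded mutations reproduces the exact
reverse complement of the guide, so the mutation record is always a
complete diff against the canonical passenger.

## Seed-collision detection

The passenger resembles the counterpart miRNA transcribed from the other
arm of the natural precursor. The collision check compares the passenger
and counterpart base-by-base over a window, default **sites 3–8**, the
window in which the prototype anti-146b-3p passenger and hsa-miR-146b-5p
are identical. A collision is called when *all* window positions match;
a softer threshold (e.g. 5 of 6) is configurable but off by default,
since there is no principled basis for a partial-identity cutoff. The
canonical 2–8 seed heptamer is used by the off-target scanner (below),
not by the collision check — the two windows answer different questions
and are configured independently.

## Mutation engine

When a collision is detected, substitutions are chosen deterministically
under a policy. The default policy reconstructs the prototype design's
choices from first principles:

1. **Candidates** are window positions identical to the counterpart.
2. **Substitution preference**: a transition that converts the
   Watson–Crick pair with the guide into a G·U wobble (A→G opposite U,
   C→U opposite G; possible exactly when the passenger base is A or C).
   Wobbles keep the stem geometrically closed, so Dicer processing of
   the hairpin is minimally perturbed. Fallback tiers — other
   transitions, then transversions in alphabetical order — keep the
   engine total on arbitrary inputs.
3. **5′-end protection**: positions within the passenger's 5′-terminal
   4 nt (the thermodynamic-asymmetry window) are deprioritized.
   Mismatching the passenger's own 5′ end would *lower* its 5′-duplex
   stability and bias RISC loading toward the passenger — the opposite
   of the construct's goal.
4. **Placement**: lowest acceptable position first, skipping positions
   adjacent to an already chosen one (spreading mutations maximizes
   seed disruption per substitution); at least 2 substitutions, at most
   4, and the collision must be destroyed on re-check.
5. **Guards**: a substitution is rejected if it creates a U/T run of
   ≥ 4 *touching the substituted position* in the transcript context
   (`CCC` flank + passenger + loop) — an internal Pol III terminator.
   Runs that pre-exist elsewhere in a user's guide are not blamed on
   the mutation; they surface as emission-time warnings instead.
   Optionally, a set of reference seed windows (e.g. all human miRNA
   seeds) can be supplied and the mutated window must match none.

On the prototype pair this policy yields exactly A→G at site 5 and C→U
at site 7. The policy is a reconstruction: the original construct
documents only this single worked example, and steps 2–4 are the
package's own rationalization, chosen once and fixed.

## Strand-selection scoring

RISC loads the duplex strand whose 5′ end is less tightly paired. Each
terminal window (default **4 bp**) is scored as the sum of Watson–Crick
RNA nearest-neighbor stack free energies (ΔG°37, Xia et al. 1998,
embedded as constants); a stack contributes only when both flanking
pairs are Watson–Crick, so mismatches and G·U wobbles contribute 0 — a
conservative simplification that avoids importing mismatch/wobble
parameter sets for what is an advisory score. The report gives
`asymmetry = guide_5p_dG − passenger_5p_dG`; above +0.5 kcal/mol the
guide is called, below −0.5 the passenger, otherwise ambiguous. The
0.5 kcal/mol tolerance is config-exposed; no quantitative loading
threshold is established in the literature, so predictions are emitted
as warnings, never errors.

The optional 3′-end pass (`destabilize_passenger_3prime`) exhaustively
searches single substitutions in the passenger's last four positions
(which pair the guide's 5′ end), greedily applying the strictly best
improvement of the asymmetry score up to *n* times, with the same
T-run guard; ties break to the lowest position, then alphabetical base.
If nothing improves the score the design is returned unchanged with a
warning.

## Oligo emission

A vector profile is a set of verbatim strings: single-stranded sticky
ends (`top_prefix`, `bottom_prefix`, `bottom_suffix`) and
double-stranded core flanks (`core_prefix`, `core_suffix`). Emission is
pure string assembly; in strict mode the bottom strand is the exact
reverse complement of the core, so an emitted pair anneals perfectly by
construction and `verify_duplex` (an independent antiparallel alignment
check) reports zero mismatches. Enzyme names are documentation only.

The bundled reference set retains one historical irregularity: the
published bottom oligo of `plvx-hs-146b-3p` repeats the forward arm
sequences instead of the exact complement, leaving four mismatched
positions after annealing (top-strand positions 12, 14, 54, 56).
Whether that was a typesetting artifact or deliberate mismatch-tolerant
annealing is unknown; the toolkit emits the exact complement and keeps
the verbatim pair as a regression fixture whose discrepancy
`verify_duplex` demonstrates. Whitespace inside published oligo listings
is treated as typesetting and stripped.

## Sensor design

Sensor inserts carry **two tandem copies** of one site in the fixed
layout `C · ACC site GGTCAACAATC ACC site GGC` (the leading `C` and the
spacer/linker strings are layout constants taken verbatim from the
validated inserts; no functional significance is claimed for the
linker). Site position *p* lies opposite miRNA position *L − p + 1*.

- *Perfect* site: DNA reverse complement of the mature miRNA.
- *Bulged* site: substitutions opposite miRNA positions 10–12 (all
  three), which must not overlap the seed (2–8).
- *Seed-mutant* site: derived from a bulged parent; substitutions
  opposite the first, upper-median and last positions of the seed
  window (default 2–7, hence miRNA positions 2, 5, 7).

Substituted site bases are the DNA copy of the opposing miRNA base —
identical bases can never pair, so non-complementarity is guaranteed
without creating G·T wobbles. This deterministic rule regenerates both
validated pMIR sites exactly; for other miRNAs it is the package's own
generalization of those two examples.

## Synthetic data generators

`generate_fixtures(seed, n, seed_overlap)` emulates guide/counterpart
pairs from a shared precursor: random 22-nt guides with counterparts
constructed to match the passenger at *exactly* `seed_overlap` positions
of the collision window (defaults: window 3–8, length 22 nt — the
prototype's conditions). It does **not** emulate real miRNA base
composition, arm covariation, or 3′ overhangs; passing tests therefore
establish the combinatorial correctness of the detection/mutation
machinery, not its behavior on any particular genome's miRNA
complement. `plant_seed_sites` builds random 3′UTRs containing an exact,
verified number of seed-match sites (non-overlapping planting on a
background re-drawn until the overlap-counted total equals the target),
giving the off-target scanner construction-time truth to recover.

## Off-target scanning

The scanner counts occurrences — overlapping occurrences all count — of
the reverse complement of the passenger's seed window (default 2–8) on
the supplied sense strand of each target, plus full-length perfect
reverse-complement matches (siRNA-like potential). Only the supplied
strand is scanned, matching how miRNA target recognition reads the
transcript. Counts are reported without a disqualification threshold;
what burden is acceptable is a judgment left to the user.
`check_seed_novelty` is exact string equality of seed windows against a
known-miRNA set.

## Numerical and degenerate-input choices

- Design is fully deterministic; randomness exists only in the synthetic
  generators and always behind an explicit seed.
- Empty sequences are legal at the primitive level; mature miRNAs are
  length-bounded (18–26 hard, 20–24 typical).
- T in RNA context (or U in DNA) is an error, never a silent
  conversion; IUPAC ambiguity codes are rejected with the offending
  position named.
- Floating-point end energies are plain sums of table constants;
  the destabilization pass requires *strict* improvement, so ties
  cannot cause oscillation.

## Problem sizes used in the test suite

The randomized batteries use 1,000 round-trip sequences, 500 synthetic
collision pairs for the mutation engine, 40–50 pairs for emission and
thermodynamic properties, and planted-site counts k ∈ {0, 1, 3, 7}; the
full suite runs in a few seconds on one CPU.

## Known limitations

- No secondary-structure folding of the full precursor is performed;
  the stem-integrity argument is combinatorial (wobble preservation),
  not thermodynamic. Users wanting a folding sanity check can run the
  emitted precursor through an external folder.
- The strand-selection score ignores dangling ends, terminal mismatch
  stabilization and wobble stacks; it ranks alternatives within one
  design family reliably but is not a quantitative loading predictor.
- Drosha/Dicer cleavage registers are not modeled; the design assumes
  shRNA-like processing of a fully paired stem.
- The off-target scan is seed-count only — no accessibility, context or
  conservation scoring.
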