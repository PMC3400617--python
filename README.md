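# starmir

Reagent-design toolkit for **vector-based overexpression of star-strand
microRNAs (miRNA\*)**.

Every miRNA precursor yields two mature species; the lowly expressed one
(the star strand, `-5p` or `-3p`) is hard to overexpress from a plasmid
because cloning the natural precursor recapitulates the biased maturation
that suppresses it in the first place. The strategy implemented here
sidesteps biogenesis: an artificial shRNA-style hairpin places the mature
miRNA\* in the **3′ arm** (the guide to be expressed), its full
complement in the **5′ arm** (the passenger), and a 9-nt loop
(`UUCAAGAGA`) between them. Dicer processing of the Pol III transcript
yields a duplex whose 3′-arm strand is exactly the desired miRNA\*.

Because the passenger is the perfect complement of the star strand it can
share a **seed** with the counterpart miRNA from the same precursor — the
passenger would then phenocopy the counterpart if loaded into RISC. The
toolkit therefore:

- detects **seed collisions** between the passenger and the counterpart
  (position-wise identity over sites 3–8, 1-based from the 5′ end) and
  proposes disruptive substitutions that destroy the shared seed while
  keeping the hairpin stem closed (G·U-wobble-preserving transitions) and
  never creating an internal Pol III terminator (T-run ≥ 4);
- emits **annealing-ready cloning oligos** with vector-specific flanks
  and sticky ends (built-in profiles: `plvx-shRNA2` BamHI/EcoRI,
  `psiCHECK` XhoI/NotI, `pMIR-Report` MluI/SacI);
- designs the matching **luciferase sensor inserts** — two tandem target
  sites per insert, as a *perfect* site (exact reverse complement), a
  centrally *bulged* site (non-complementary opposite miRNA positions
  10–12, forcing miRNA-like repression), or a *seed-mutant* negative
  control (additionally disrupted opposite the seed);
- screens designs for **strand-loading bias** — nearest-neighbor
  (Xia–Turner ΔG°37) end stabilities of the duplex, RISC loading the
  strand with the weaker 5′ end — and for **passenger off-target seed
  effects** against user-supplied 3′UTRs.

The bundled reference set contains the sequencing-verified prototype
constructs (`plvx-hs-146b-3p`, `plvx-hs-127-3p`, `plvx-hs-142-3p` and the
four 146b sensor inserts); the toolkit regenerates all of them
byte-for-byte from their mature miRNA inputs.

## Worked example

Design the prototype hairpin for hsa-miR-146b-3p, screening against its
counterpart hsa-miR-146b-5p:

```bash
starmir design --guide hsa-miR-146b-3p --counterpart hsa-miR-146b-5p \
    --name plvx-hs-146b-3p --out-dir demo
```

The design bundle (`demo/plvx-hs-146b-3p.design.json`) reports:

```text
passenger  = CCAGGAUUGAGUCCACAGGGCA
precursor  = CCAGGAUUGAGUCCACAGGGCAUUCAAGAGAUGCCCUGUGGACUCAGUUCUGG
mutations  = ["5A>G", "7C>U"]
collision  pre  6/6 at sites 3-8 (collision)   post 4/6 (resolved)
oligos.top = GATCCCCCCAGGATTGAGTCCACAGGGCATTCAAGAGATGCCCTGTGGACTCAGTTCTGGTTTTTA
thermo     = guide_5p_dG -8.79, passenger_5p_dG -7.45 kcal/mol,
             asymmetry -1.34, predicted_loaded "passenger"
```

Reading: the unmodified passenger (`CCAGAACUGAGUCCACAGGGCA`) shares all
six bases of the counterpart's seed at sites 3–8, so the engine
substitutes A→G at site 5 and C→U at site 7; the 4/6 residual identity no
longer constitutes a seed match. The top oligo is the 66-nt synthesis
strand — BamHI sticky end `GATC`, `CCC` flank, mutated passenger, loop,
guide, and the `TTTTTA` Pol III terminator. The end-stability report
flags this particular duplex as passenger-favoring (the guide's 5′ end is
GC-rich); `--destabilize 1` would add one passenger 3′-end substitution
to shift loading toward the guide. Matching sensors come from
`starmir sensor --mirna hsa-miR-146b-3p --kind perfect|bulged|seed-mutant`.

Library use mirrors the CLI:

```python
from starmir import design_hairpin, emit_overexpression_oligos
from starmir.reference import MATURE_MIRNAS

result = design_hairpin(MATURE_MIRNAS["hsa-miR-146b-3p"],
                        MATURE_MIRNAS["hsa-miR-146b-5p"])
pair = emit_overexpression_oligos(result.design, "plvx-shRNA2")
print(pair.top)   # the 66-nt top strand shown above
```

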