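"""Bundled reference constructs: the validated prototype designs.

This module carries the mature miRNA sequences and the synthesis oligos
of the original, sequencing-verified constructs that established the
star-strand overexpression strategy: the plvx-shRNA2 hairpin inserts for
hsa-miR-146b-3p, hsa-miR-127-3p and hsa-miR-142-3p, and the four
luciferase sensor inserts for the 146b pair.  They serve three roles:

* worked examples — the toolkit must regenerate every construct from its
  mature miRNA input;
* regression fixtures — the verbatim oligo strings (whitespace stripped
  from the published listings) are kept for byte-level comparison;
* name resolution — the CLI resolves miRNA names against this set when
  no FASTA is supplied.

Note on ``plvx-hs-146b-3p``: its published *bottom* oligo repeats the
forward arm sequences instead of the exact complement of the top strand,
leaving mismatches at the four positions affected by the two seed
mutations.  The toolkit emits the exact complement by default (strict
mode); the verbatim pair is retained here so that
:func:`starmir.oligos.verify_duplex` can demonstrate the discrepancy.
"""

from __future__ import annotations

from .hairpin import (
    DEFAULT_LOOP,
    HairpinDesign,
    MutationSpec,
    assemble_hairpin,
)
from .oligos import OligoPair, get_profile
from .sequences import MatureMiRNA, rna

#: Mature miRNA sequences as encoded in the validated constructs
#: (recoverable verbatim from the 3' arms of the hairpin-insert oligos).
MATURE_MIRNAS: dict[str, MatureMiRNA] = {
    "hsa-miR-146b-3p": MatureMiRNA(
        rna("UGCCCUGUGGACUCAGUUCUGG", "hsa-miR-146b-3p"), "3p", "builtin"
    ),
    "hsa-miR-146b-5p": MatureMiRNA(
        rna("UGAGAACUGAAUUCCAUAGGCU", "hsa-miR-146b-5p"), "5p", "builtin"
    ),
    "hsa-miR-127-3p": MatureMiRNA(
        rna("UCGGAUCCGUCUGAGCUUGGCU", "hsa-miR-127-3p"), "3p", "builtin"
    ),
    "hsa-miR-142-3p": MatureMiRNA(
        rna("UGUAGUGUUUCCUACUUUAUGGA", "hsa-miR-142-3p"), "3p", "builtin"
    ),
}

#: Seed-disruption mutations of the prototype anti-146b-3p passenger:
#: A->G at site 5 and C->U at site 7 (1-based from the passenger 5' end).
ANTI_146B_3P_MUTATIONS: tuple[MutationSpec, ...] = (
    MutationSpec(5, "A", "G"),
    MutationSpec(7, "C", "U"),
)

#: Verbatim synthesis oligos of the validated constructs, keyed by
#: construct name; each value is (top, bottom), both 5'->3', whitespace
#: stripped from the published listings.
PRINTED_OLIGOS: dict[str, tuple[str, str]] = {
    "plvx-hs-146b-3p": (
        "GATCCCCCCAGGATTGAGTCCACAGGGCATTCAAGAGATGCCCTGTGGACTCAGTTCTGGTTTTTA",
        "AATTTAAAAACCAGGATTGAGTCCACAGGGCATCTCTTGAATGCCCTGTGGACTCAGTTCTGGGGG",
    ),
    "plvx-hs-127-3p": (
        "GATCCCCAGCCAAGCTCAGACGGATCCGATTCAAGAGATCGGATCCGTCTGAGCTTGGCTTTTTTA",
        "AATTTAAAAAAGCCAAGCTCAGACGGATCCGATCTCTTGAATCGGATCCGTCTGAGCTTGGCTGGG",
    ),
    "plvx-hs-142-3p": (
        "GATCCCCTCCATAAAGTAGGAAACACTACATTCAAGAGATGTAGTGTTTCCTACTTTATGGATTTTTA",
        "AATTTAAAAATCCATAAAGTAGGAAACACTACATCTCTTGAATGTAGTGTTTCCTACTTTATGGAGGG",
    ),
    "psicheck-hs-146b-3p": (
        "TCGACACCCCAGAACTGAGTCCACAGGGCAGGTCAACAATCACCCCAGAACTGAGTCCACAGGGCAGGC",
        "GGCCGCCTGCCCTGTGGACTCAGTTCTGGGGTGATTGTTGACCTGCCCTGTGGACTCAGTTCTGGGGTG",
    ),
    "psicheck-hs-146b-5p": (
        "TCGACACCAGCCTATGGAATTCAGTTCTCAGGTCAACAATCACCAGCCTATGGAATTCAGTTCTCAGGC",
        "GGCCGCCTGAGAACTGAATTCCATAGGCTGGTGATTGTTGACCTGAGAACTGAATTCCATAGGCTGGTG",
    ),
    "pMIR-hs-146b-3p": (
        "CACCCCAGAACTGACAGCACAGGGCAGGTCAACAATCACCCCAGAACTGACAGCACAGGGCAGGC",
        "CGCGGCCTGCCCTGTGCTGTCAGTTCTGGGGTGATTGTTGACCTGCCCTGTGCTGTCAGTTCTGGGG"
        "TGAGCT",
    ),
    "pMIR-hs-146b-3p-mut": (
        "CACCCCAGAACTGACAGCAGACGGGAGGTCAACAATCACCCCAGAACTGACAGCAGACGGGAGGC",
        "CGCGGCCTCCCGTCTGCTGTCAGTTCTGGGGTGATTGTTGACCTCCCGTCTGCTGTCAGTTCTGGGG"
        "TGAGCT",
    ),
}

#: Which vector profile each printed construct belongs to.
PRINTED_PROFILE: dict[str, str] = {
    "plvx-hs-146b-3p": "plvx-shRNA2",
    "plvx-hs-127-3p": "plvx-shRNA2",
    "plvx-hs-142-3p": "plvx-shRNA2",
    "psicheck-hs-146b-3p": "psiCHECK",
    "psicheck-hs-146b-5p": "psiCHECK",
    "pMIR-hs-146b-3p": "pMIR-Report",
    "pMIR-hs-146b-3p-mut": "pMIR-Report",
}


def get_mirna(name: str) -> MatureMiRNA:
    """Look up a bundled mature miRNA by name (case-insensitive)."""
    if name in MATURE_MIRNAS:
        return MATURE_MIRNAS[name]
    for key, value in MATURE_MIRNAS.items():
        if key.lower() == name.lower():
            return value
    raise KeyError(
        f"no bundled miRNA named {name!r}; bundled: "
        + ", ".join(sorted(MATURE_MIRNAS))
    )


def printed_oligo_pair(construct: str) -> OligoPair:
    """The verbatim oligo pair of a validated construct, with the
    overhang annotations of its vector profile."""
    top, bottom = PRINTED_OLIGOS[construct]
    profile = get_profile(PRINTED_PROFILE[construct])
    return OligoPair(
        name=construct,
        top=top,
        bottom=bottom,
        top_overhang_5p=profile.top_prefix,
        top_overhang_3p=profile.top_suffix,
        bottom_overhang_5p=profile.bottom_prefix,
        bottom_overhang_3p=profile.bottom_suffix,
    )


def prototype_146b_design() -> HairpinDesign:
    """The validated hsa-miR-146b-3p hairpin design (mutated passenger)."""
    return assemble_hairpin(
        MATURE_MIRNAS["hsa-miR-146b-3p"],
        loop=DEFAULT_LOOP,
        mutations=ANTI_146B_3P_MUTATIONS,
        counterpart=MATURE_MIRNAS["hsa-miR-146b-5p"],
    )
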