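"""Alphabet-safe nucleotide sequence primitives.

All coordinates in the toolkit are 1-based and counted from the 5' end of
the strand under discussion, matching the convention used when talking
about small-RNA "sites" (seed site 3-8, a substitution "at site 5", ...).

Sequences are strict: RNA may contain only A/C/G/U and DNA only A/C/G/T,
uppercase after ingest.  A ``T`` in an RNA context (or ``U`` in DNA) is an
error rather than a silent conversion — :func:`transcribe` and
:func:`reverse_transcribe` exist precisely to make that step explicit.
IUPAC ambiguity codes are rejected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal

from Bio import SeqIO

from .errors import AlphabetError, BoundsError

Alphabet = Literal["RNA", "DNA"]

_ALPHABETS: dict[str, frozenset[str]] = {
    "RNA": frozenset("ACGU"),
    "DNA": frozenset("ACGT"),
}

_COMPLEMENT = {
    "RNA": {"A": "U", "U": "A", "C": "G", "G": "C"},
    "DNA": {"A": "T", "T": "A", "C": "G", "G": "C"},
}

#: Mature-miRNA length bounds: hard limits and the typical range outside of
#: which a warning is raised (most animal mature miRNAs are 20-24 nt).
MIRNA_LENGTH_HARD = (18, 26)
MIRNA_LENGTH_TYPICAL = (20, 24)


class MiRNALengthWarning(UserWarning):
    """Mature miRNA length is legal but outside the typical 20-24 nt range."""


@dataclass(frozen=True)
class NucleotideSequence:
    """An immutable single-stranded nucleotide sequence.

    Parameters
    ----------
    residues:
        The bases, 5'->3'.  Mixed case is uppercased on ingest.
    alphabet:
        ``"RNA"`` or ``"DNA"``.
    name:
        Free-text label carried through design reports.
    """

    residues: str
    alphabet: Alphabet
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        if self.alphabet not in _ALPHABETS:
            raise AlphabetError(f"unknown alphabet {self.alphabet!r}")
        allowed = _ALPHABETS[self.alphabet]
        for pos, base in enumerate(self.residues, start=1):
            if base not in allowed:
                raise AlphabetError(
                    f"invalid {self.alphabet} symbol {base!r} at position "
                    f"{pos} in {self.name or 'sequence'!r}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues

    def base(self, position: int) -> str:
        """Return the base at a 1-based position from the 5' end."""
        if not 1 <= position <= len(self.residues):
            raise BoundsError(
                f"position {position} outside sequence of length "
                f"{len(self.residues)}"
            )
        return self.residues[position - 1]

    def window(self, start: int, end: int) -> str:
        """Residues at 1-based positions ``start..end`` inclusive."""
        if start < 1 or end > len(self.residues) or start > end:
            raise BoundsError(
                f"window {start}..{end} out of range for length "
                f"{len(self.residues)}"
            )
        return self.residues[start - 1 : end]

    def with_name(self, name: str) -> "NucleotideSequence":
        return NucleotideSequence(self.residues, self.alphabet, name)


def rna(residues: str, name: str = "") -> NucleotideSequence:
    """Shorthand constructor for an RNA sequence."""
    return NucleotideSequence(residues, "RNA", name)


def dna(residues: str, name: str = "") -> NucleotideSequence:
    """Shorthand constructor for a DNA sequence."""
    return NucleotideSequence(residues, "DNA", name)


@dataclass(frozen=True)
class MatureMiRNA:
    """A named mature miRNA (RNA) with arm-of-origin annotation.

    The ``arm`` records which precursor arm the mature species derives
    from (``5p``/``3p``); star strands are frequently the 3p species but
    either arm can be the design target.
    """

    sequence: NucleotideSequence
    arm: Literal["5p", "3p", "unknown"] = "unknown"
    source: str = ""

    def __post_init__(self) -> None:
        if self.sequence.alphabet != "RNA":
            raise AlphabetError(
                f"mature miRNA {self.name!r} must be RNA, got "
                f"{self.sequence.alphabet}"
            )
        n = len(self.sequence)
        lo, hi = MIRNA_LENGTH_HARD
        if not lo <= n <= hi:
            raise ValueError(
                f"mature miRNA {self.name!r} length {n} outside {lo}-{hi} nt"
            )
        tlo, thi = MIRNA_LENGTH_TYPICAL
        if not tlo <= n <= thi:
            warnings.warn(
                f"mature miRNA {self.name!r} length {n} outside the typical "
                f"{tlo}-{thi} nt range",
                MiRNALengthWarning,
                stacklevel=2,
            )

    @property
    def name(self) -> str:
        return self.sequence.name

    def __len__(self) -> int:
        return len(self.sequence)


def infer_arm(name: str) -> Literal["5p", "3p", "unknown"]:
    """Infer the precursor arm from a miRBase-style name suffix."""
    low = name.lower()
    if low.endswith("-5p"):
        return "5p"
    if low.endswith("-3p"):
        return "3p"
    return "unknown"


def reverse_complement(seq: NucleotideSequence) -> NucleotideSequence:
    """Watson-Crick reverse complement in the same alphabet."""
    comp = _COMPLEMENT[seq.alphabet]
    return NucleotideSequence(
        "".join(comp[b] for b in reversed(seq.residues)),
        seq.alphabet,
        f"revcomp({seq.name})" if seq.name else "",
    )


def transcribe(seq: NucleotideSequence) -> NucleotideSequence:
    """DNA -> RNA: swap T for U (the coding-strand convention)."""
    if seq.alphabet != "DNA":
        raise AlphabetError("transcribe expects a DNA sequence")
    return NucleotideSequence(seq.residues.replace("T", "U"), "RNA", seq.name)


def reverse_transcribe(seq: NucleotideSequence) -> NucleotideSequence:
    """RNA -> DNA: swap U for T."""
    if seq.alphabet != "RNA":
        raise AlphabetError("reverse_transcribe expects an RNA sequence")
    return NucleotideSequence(seq.residues.replace("U", "T"), "DNA", seq.name)


def positional_identity(
    a: NucleotideSequence,
    b: NucleotideSequence,
    window: tuple[int, int],
) -> int:
    """Count positions within ``window`` (1-based, inclusive) where the two
    sequences carry the identical base.

    Both sequences must share an alphabet and be at least as long as the
    window end.  This is the primitive behind seed-collision detection.
    """
    if a.alphabet != b.alphabet:
        raise AlphabetError(
            f"cannot compare {a.alphabet} with {b.alphabet} positions"
        )
    start, end = window
    wa = a.window(start, end)
    wb = b.window(start, end)
    return sum(1 for x, y in zip(wa, wb) if x == y)


def watson_crick_pair(a: str, b: str, alphabet: Alphabet = "RNA") -> bool:
    """True if single bases ``a`` and ``b`` form a Watson-Crick pair."""
    return _COMPLEMENT[alphabet].get(a) == b


def read_mature_fasta(
    path: str | Path,
    alphabet: Alphabet = "RNA",
) -> list[MatureMiRNA]:
    """Read mature miRNAs from FASTA.

    Tolerates miRBase ``mature.fa`` headers such as
    ``>hsa-miR-146b-3p MIMAT0004766 Homo sapiens miR-146b-3p`` — only the
    first whitespace-delimited token is used as the name.  DNA-encoded
    records are transcribed to RNA when ``alphabet="DNA"``.
    """
    out: list[MatureMiRNA] = []
    for record in SeqIO.parse(str(path), "fasta"):
        name = record.id.split()[0]
        seq = NucleotideSequence(str(record.seq), alphabet, name)
        if alphabet == "DNA":
            seq = transcribe(seq)
        out.append(MatureMiRNA(seq, arm=infer_arm(name), source=str(path)))
    return out


def read_fasta_sequences(
    path: str | Path,
    alphabet: Alphabet = "DNA",
) -> Iterator[NucleotideSequence]:
    """Yield plain named sequences (e.g. 3'UTRs) from a FASTA file."""
    for record in SeqIO.parse(str(path), "fasta"):
        yield NucleotideSequence(str(record.seq), alphabet, record.id.split()[0])
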