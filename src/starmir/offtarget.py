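"""Off-target screening of the engineered passenger strand.

The passenger (the "anti-miRNA*" strand) is itself a small RNA that can
load into RISC; even after seed-disruption mutations it carries a seed of
its own.  This module screens that seed against user-supplied transcript
sequences (typically 3'UTRs): it counts seed-match sites — occurrences of
the reverse complement of the passenger's seed window on the supplied
(sense) strand — and full-length perfect reverse-complement matches,
which would support siRNA-like slicing.  It also checks whether the
passenger's seed coincides exactly with the seed of any known miRNA, in
which case the passenger would phenocopy that miRNA.

The tool reports counts only; how much seed-match burden is acceptable
is a judgment left to the user.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

from .sequences import MatureMiRNA, NucleotideSequence, reverse_complement

logger = logging.getLogger(__name__)

#: Canonical 7-mer seed window used for off-target scanning (this is the
#: miRNA-field default and is distinct from the 3-8 collision window used
#: by the hairpin design check).
DEFAULT_SEED_WINDOW = (2, 8)

_DNA_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class OfftargetReport:
    """Seed-match burden of a passenger strand against a target set."""

    seed_used: str  # RNA bases of the passenger's seed window
    seed_window: tuple[int, int]
    match_site: str  # DNA motif searched on the sense strand
    per_target: tuple[tuple[str, int], ...]
    perfect_match_hits: int
    skipped_records: int

    @property
    def total_hits(self) -> int:
        return sum(count for _, count in self.per_target)


def _count_overlapping(haystack: str, needle: str) -> int:
    """Occurrences of ``needle`` in ``haystack``, overlaps included."""
    if not needle:
        return 0
    count = 0
    start = haystack.find(needle)
    while start != -1:
        count += 1
        start = haystack.find(needle, start + 1)
    return count


def _normalize_target(
    target: NucleotideSequence | str, index: int
) -> tuple[str, str] | None:
    """Return (name, DNA residues) or None for a malformed record."""
    if isinstance(target, NucleotideSequence):
        name = target.name or f"target_{index}"
        residues = target.residues
    else:
        name = f"target_{index}"
        residues = target.upper()
    residues = residues.replace("U", "T")
    if any(b not in "ACGT" for b in residues):
        logger.warning(
            "skipping malformed target record %r (non-ACGT/U symbols)", name
        )
        return None
    return name, residues


def scan_seed_matches(
    passenger: NucleotideSequence,
    targets: Iterable[NucleotideSequence | str],
    seed_window: tuple[int, int] = DEFAULT_SEED_WINDOW,
) -> OfftargetReport:
    """Count passenger seed-match sites in each target sequence.

    A seed-match site is an occurrence, on the supplied (sense) strand,
    of the DNA reverse complement of the passenger's seed window;
    overlapping occurrences all count.  Targets may be DNA or RNA, as
    sequences or bare strings; the antisense strand is *not* scanned
    (miRNA target recognition reads the transcript's sense strand).
    Malformed records are skipped with a logged warning and tallied.
    """
    start, end = seed_window
    seed_rna = passenger.window(start, end)
    seed_dna = seed_rna.replace("U", "T")
    match_site = "".join(_DNA_COMPLEMENT[b] for b in reversed(seed_dna))
    full_dna = passenger.residues.replace("U", "T")
    full_site = "".join(_DNA_COMPLEMENT[b] for b in reversed(full_dna))

    per_target: list[tuple[str, int]] = []
    perfect = 0
    skipped = 0
    for i, target in enumerate(targets):
        norm = _normalize_target(target, i)
        if norm is None:
            skipped += 1
            continue
        name, residues = norm
        per_target.append((name, _count_overlapping(residues, match_site)))
        perfect += _count_overlapping(residues, full_site)
    return OfftargetReport(
        seed_used=seed_rna,
        seed_window=seed_window,
        match_site=match_site,
        per_target=tuple(per_target),
        perfect_match_hits=perfect,
        skipped_records=skipped,
    )


def check_seed_novelty(
    passenger: NucleotideSequence,
    known_mirnas: Iterable[MatureMiRNA],
    window: tuple[int, int] = DEFAULT_SEED_WINDOW,
) -> list[str]:
    """Names of known miRNAs whose seed window equals the passenger's.

    An empty list means the passenger's seed is novel with respect to the
    supplied set.  Comparison is exact string equality on the window.
    """
    start, end = window
    seed = passenger.window(start, end)
    hits = []
    for mirna in known_mirnas:
        if len(mirna.sequence) < end:
            continue
        if mirna.sequence.window(start, end) == seed:
            hits.append(mirna.name)
    return hits
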