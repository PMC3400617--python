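"""Synthetic test-data generators.

Two generators support property testing of the design machinery:

* :func:`generate_fixtures` builds guide/counterpart miRNA pairs with a
  *controlled* number of identical positions in the collision window, so
  the seed-collision detector and the mutation engine can be checked
  against construction-time truth.
* :func:`plant_seed_sites` builds a synthetic 3'UTR carrying an exact,
  known number of seed-match sites for the off-target scanner.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .errors import ConfigError
from .hairpin import DEFAULT_COLLISION_WINDOW, build_passenger
from .sequences import MatureMiRNA, NucleotideSequence, dna, rna

_RNA = "ACGU"
_DNA = "ACGT"


@dataclass(frozen=True)
class FixturePair:
    """A synthetic guide/counterpart pair with its true window overlap."""

    guide: MatureMiRNA
    counterpart: MatureMiRNA
    seed_overlap: int
    window: tuple[int, int]


def _random_rna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(_RNA) for _ in range(length))


def generate_fixtures(
    seed: int,
    n: int,
    seed_overlap: int,
    window: tuple[int, int] = DEFAULT_COLLISION_WINDOW,
    length: int = 22,
) -> list[FixturePair]:
    """Generate guide/counterpart pairs with controlled seed overlap.

    For each pair, the counterpart is constructed so that exactly
    ``seed_overlap`` positions of the collision window are identical to
    the guide's passenger (the guide's reverse complement) and the rest
    differ.  ``seed_overlap`` equal to the window length therefore
    guarantees a collision under the strict policy; 0 guarantees none.
    """
    start, end = window
    wlen = end - start + 1
    if not 0 <= seed_overlap <= wlen:
        raise ConfigError(
            f"seed_overlap must be in 0..{wlen} for window {start}..{end}"
        )
    if end > length:
        raise ConfigError("window end beyond sequence length")
    rng = random.Random(seed)
    pairs: list[FixturePair] = []
    for i in range(n):
        guide = MatureMiRNA(
            rna(_random_rna(rng, length), f"synth-guide-{i}"),
            "3p",
            "synthetic",
        )
        passenger = build_passenger(guide)
        counterpart_bases = list(_random_rna(rng, length))
        matched = set(rng.sample(range(start, end + 1), seed_overlap))
        for pos in range(start, end + 1):
            pbase = passenger.base(pos)
            if pos in matched:
                counterpart_bases[pos - 1] = pbase
            else:
                counterpart_bases[pos - 1] = rng.choice(
                    [b for b in _RNA if b != pbase]
                )
        counterpart = MatureMiRNA(
            rna("".join(counterpart_bases), f"synth-counterpart-{i}"),
            "5p",
            "synthetic",
        )
        pairs.append(FixturePair(guide, counterpart, seed_overlap, window))
    return pairs


def plant_seed_sites(
    site: str,
    k: int,
    seed: int,
    length: int = 300,
    name: str = "synthetic-utr",
    max_attempts: int = 200,
) -> NucleotideSequence:
    """A synthetic DNA 3'UTR containing exactly ``k`` copies of ``site``.

    Sites are planted non-overlapping at random positions on a random
    background; the construction is re-drawn until the final sequence
    contains exactly ``k`` (overlap-counted) occurrences, so accidental
    background matches cannot inflate the truth.
    """
    site = site.upper().replace("U", "T")
    if any(b not in _DNA for b in site):
        raise ConfigError("site must be DNA/RNA bases only")
    m = len(site)
    if k * m > length:
        raise ConfigError("too many sites for the requested length")
    rng = random.Random(seed)
    for _ in range(max_attempts):
        residues = [rng.choice(_DNA) for _ in range(length)]
        placed: list[int] = []
        tries = 0
        while len(placed) < k and tries < 1000:
            pos = rng.randrange(0, length - m + 1)
            if all(pos + m <= q or q + m <= pos for q in placed):
                placed.append(pos)
            tries += 1
        if len(placed) < k:
            continue
        for pos in placed:
            residues[pos : pos + m] = site
        candidate = "".join(residues)
        count = 0
        idx = candidate.find(site)
        while idx != -1:
            count += 1
            idx = candidate.find(site, idx + 1)
        if count == k:
            return dna(candidate, name)
    raise RuntimeError(
        "could not construct a sequence with the exact planted-site count"
    )
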