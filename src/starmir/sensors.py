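"""Luciferase 3'UTR sensor inserts for mature miRNAs.

A sensor places two tandem copies of a target site in the 3'UTR of a
luciferase reporter, so that activity of the cognate miRNA represses the
luciferase signal.  Three site kinds are supported:

* ``perfect`` — the exact DNA reverse complement of the mature miRNA;
  slicing-competent, maximally sensitive (Renilla/psiCHECK backbone).
* ``bulged`` — complementary except opposite the miRNA's central
  positions, forcing miRNA-like (non-slicing) repression (pMIR backbone).
* ``seed_mutant`` — a bulged site additionally disrupted opposite the
  miRNA seed; the specificity control that should abolish repression.

Bulge and seed substitutions replace the site base with the DNA copy of
the opposing miRNA base itself — identical bases never pair, so
non-complementarity is guaranteed without risking a G·U-style wobble.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .errors import BoundsError, ConfigError
from .oligos import OligoPair, VectorProfile, emit_duplex, get_profile
from .sequences import MatureMiRNA, reverse_complement, reverse_transcribe

#: Fixed layout constants of the tandem-site insert body:
#: ACC + site + linker + ACC + site + GGC.
SITE_PREFIX = "ACC"
INTER_SITE_LINKER = "GGTCAACAATC"
TERMINAL = "GGC"

#: miRNA positions left unpaired in a bulged site (the central bulge).
DEFAULT_BULGE_POSITIONS = (10, 11, 12)

#: miRNA seed window disrupted in a seed-mutant site.
DEFAULT_SEED_WINDOW = (2, 7)

SiteKind = Literal["perfect", "bulged", "seed_mutant"]


@dataclass(frozen=True)
class SensorSite:
    """One miRNA target site (DNA, 5'->3').

    ``edits`` lists substitutions relative to this site's parent (the
    perfect site for a bulged site; the bulged site for a seed mutant) as
    ``(site_position, from_base, to_base)`` with 1-based positions from
    the site's 5' end.  Site position ``p`` lies opposite miRNA position
    ``L - p + 1`` (antiparallel pairing).
    """

    kind: SiteKind
    sequence: str
    edits: tuple[tuple[int, str, str], ...] = ()
    mirna_name: str = ""


@dataclass(frozen=True)
class SensorInsert:
    """Two tandem identical sites dressed as a clonable duplex."""

    sites: tuple[SensorSite, SensorSite]
    body: str
    profile: VectorProfile
    oligos: OligoPair

    def __post_init__(self) -> None:
        a, b = self.sites
        if a.sequence != b.sequence:
            raise ConfigError("both sensor sites must be identical")
        expected = (
            SITE_PREFIX
            + a.sequence
            + INTER_SITE_LINKER
            + SITE_PREFIX
            + a.sequence
            + TERMINAL
        )
        if self.body != expected:
            raise ConfigError("sensor body does not follow the fixed layout")


def _site_to_mirna_position(site_pos: int, mirna_len: int) -> int:
    return mirna_len - site_pos + 1


def _mirna_to_site_position(mirna_pos: int, mirna_len: int) -> int:
    return mirna_len - mirna_pos + 1


def make_perfect_site(mirna: MatureMiRNA) -> SensorSite:
    """Perfect site: DNA reverse complement of the mature miRNA."""
    site = reverse_transcribe(reverse_complement(mirna.sequence)).residues
    return SensorSite("perfect", site, (), mirna.name)


def _substitute_opposite(
    site: str,
    mirna: MatureMiRNA,
    mirna_positions: tuple[int, ...],
) -> tuple[str, tuple[tuple[int, str, str], ...]]:
    """Replace site bases opposite the given miRNA positions with the DNA
    copy of the miRNA base (guaranteed non-pairing)."""
    L = len(mirna)
    residues = list(site)
    edits = []
    for mpos in mirna_positions:
        spos = _mirna_to_site_position(mpos, L)
        from_base = residues[spos - 1]
        to_base = mirna.sequence.base(mpos).replace("U", "T")
        residues[spos - 1] = to_base
        edits.append((spos, from_base, to_base))
    return "".join(residues), tuple(sorted(edits))


def make_bulged_site(
    mirna: MatureMiRNA,
    bulge_positions: tuple[int, ...] = DEFAULT_BULGE_POSITIONS,
) -> SensorSite:
    """Bulged site: non-complementary opposite the miRNA's central bases.

    The bulge must lie inside the miRNA and clear of the seed (positions
    2-8), which must remain paired for the site to report seed-dependent
    miRNA activity.
    """
    L = len(mirna)
    for p in bulge_positions:
        if not 1 <= p <= L:
            raise BoundsError(f"bulge position {p} outside miRNA length {L}")
        if 2 <= p <= 8:
            raise ConfigError(
                f"bulge position {p} overlaps the seed (2-8); a bulged "
                "sensor must keep seed pairing intact"
            )
    perfect = make_perfect_site(mirna)
    seq, edits = _substitute_opposite(perfect.sequence, mirna, bulge_positions)
    return SensorSite("bulged", seq, edits, mirna.name)


def make_seed_mutant_site(
    parent: SensorSite,
    mirna: MatureMiRNA,
    seed_window: tuple[int, int] = DEFAULT_SEED_WINDOW,
) -> SensorSite:
    """Seed-mutant control: disrupt pairing opposite the miRNA seed.

    Three positions of the seed window are substituted — its first,
    upper-median and last positions (for the default 2-7 window: miRNA
    positions 2, 5 and 7) — enough to abolish seed pairing while leaving
    the rest of the site untouched.
    """
    if parent.kind != "bulged":
        raise ConfigError(
            "seed-mutant sites are derived from a bulged parent "
            f"(got {parent.kind!r})"
        )
    start, end = seed_window
    if start < 1 or end > len(mirna) or start > end:
        raise BoundsError(f"seed window {start}..{end} outside miRNA")
    targets = tuple(sorted({start, (start + end + 1) // 2, end}))
    seq, edits = _substitute_opposite(parent.sequence, mirna, targets)
    return SensorSite("seed_mutant", seq, edits, mirna.name)


def seed_complementarity(
    site: SensorSite, mirna: MatureMiRNA, window: tuple[int, int] = (2, 7)
) -> int:
    """Count site bases Watson-Crick complementary to the miRNA seed."""
    L = len(mirna)
    pairs = {"A": "U", "T": "A", "C": "G", "G": "C"}
    count = 0
    for mpos in range(window[0], window[1] + 1):
        spos = _mirna_to_site_position(mpos, L)
        if pairs.get(site.sequence[spos - 1]) == mirna.sequence.base(mpos):
            count += 1
    return count


def assemble_sensor_insert(
    site: SensorSite,
    profile: VectorProfile | str,
    name: str | None = None,
) -> SensorInsert:
    """Two tandem copies of ``site`` dressed for a sensor backbone."""
    if isinstance(profile, str):
        profile = get_profile(profile)
    if profile.insert_kind != "sensor":
        raise ConfigError(
            f"profile {profile.name!r} is a {profile.insert_kind} backbone, "
            "not a sensor backbone"
        )
    body = (
        SITE_PREFIX
        + site.sequence
        + INTER_SITE_LINKER
        + SITE_PREFIX
        + site.sequence
        + TERMINAL
    )
    if name is None:
        name = f"{profile.name}:{site.mirna_name or 'sensor'}:{site.kind}"
    oligos = emit_duplex(body, profile, name)
    return SensorInsert((site, site), body, profile, oligos)
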