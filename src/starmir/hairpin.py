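"""Design of artificial miRNA* hairpin precursors.

The construct places the mature star strand (the *guide* the user wants
expressed) in the 3' arm of a short hairpin, its engineered full
complement (the *passenger*) in the 5' arm, and a short loop between the
two.  Transcribed from a Pol III shRNA vector, Dicer processing of the
hairpin yields a duplex whose 3'-arm strand is the desired miRNA*.

Because the passenger is the perfect complement of the star strand it can
resemble the natural counterpart miRNA from the same precursor — in
particular the two may share a seed window — so the passenger would then
act as a surrogate of the counterpart if loaded into RISC.  This module
detects such seed collisions and proposes disruptive substitutions that
destroy the shared seed while keeping the hairpin stem intact.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

from .errors import BoundsError, ConfigError, DesignFailure
from .sequences import (
    MatureMiRNA,
    NucleotideSequence,
    positional_identity,
    reverse_complement,
    reverse_transcribe,
    rna,
)

#: Widely used 9-nt shRNA loop (the pSUPER-style loop).
DEFAULT_LOOP = rna("UUCAAGAGA", "loop")

#: Seed window used for the collision check, 1-based inclusive.  The
#: collision concept concerns the counterpart miRNA's functional seed;
#: sites 3-8 is the window used for the prototype constructs.
DEFAULT_COLLISION_WINDOW = (3, 8)

#: Length of a U/T homopolymer that acts as a Pol III terminator; runs of
#: this length or more inside the transcribed insert are forbidden.
POL3_T_RUN = 4

_TRANSITION = {"A": "G", "G": "A", "C": "U", "U": "C"}


class DesignWarning(UserWarning):
    """Advisory emitted when a design is legal but potentially suboptimal."""


@dataclass(frozen=True)
class MutationSpec:
    """One substitution on the passenger strand.

    ``position`` is 1-based from the passenger's 5' end; ``from_base`` is
    the base of the unmutated passenger (the exact complement of the
    guide) and ``to_base`` the engineered replacement.
    """

    position: int
    from_base: str
    to_base: str

    def __post_init__(self) -> None:
        if self.from_base == self.to_base:
            raise ValueError("mutation must change the base")
        for b in (self.from_base, self.to_base):
            if b not in "ACGU":
                raise ValueError(f"mutation bases must be RNA, got {b!r}")
        if self.position < 1:
            raise ValueError("mutation position must be >= 1")

    def __str__(self) -> str:
        return f"{self.position}{self.from_base}>{self.to_base}"


@dataclass(frozen=True)
class SeedCollisionReport:
    """Outcome of comparing the passenger seed window with a counterpart."""

    window: tuple[int, int]
    identical_count: int
    collision: bool
    passenger_window_bases: str
    counterpart_window_bases: str
    threshold: int

    @property
    def window_length(self) -> int:
        return self.window[1] - self.window[0] + 1


@dataclass(frozen=True)
class MutationPolicy:
    """Rules governing seed-disruption mutation selection.

    The default ("paper") policy reconstructs the choices made for the
    prototype hsa-miR-146b-3p construct:

    * only positions inside the collision window that are identical to
      the counterpart are candidates;
    * substitutions preferring transitions that convert the Watson-Crick
      pair with the guide into a G·U wobble (A→G opposite U, C→U
      opposite G), so the hairpin stem stays closed;
    * positions inside the passenger's 5'-terminal thermodynamic-
      asymmetry window are avoided — weakening the passenger's 5' duplex
      end would bias RISC loading toward the passenger;
    * lowest acceptable positions first, skipping positions adjacent to
      an already chosen one;
    * at least ``min_mutations`` substitutions, and the collision must be
      destroyed.

    ``collision_threshold``: identical positions required to call a
    collision; ``None`` means the full window must match (the strict
    default).  A softer threshold (e.g. 5 of 6) can be configured.
    """

    window: tuple[int, int] = DEFAULT_COLLISION_WINDOW
    collision_threshold: int | None = None
    min_mutations: int = 2
    max_mutations: int = 4
    prefer_transitions: bool = True
    prefer_stem_wobble: bool = True
    protect_passenger_5p: int = 4
    skip_adjacent: bool = True

    def threshold_for(self, window: tuple[int, int]) -> int:
        if self.collision_threshold is not None:
            return self.collision_threshold
        return window[1] - window[0] + 1


PAPER_POLICY = MutationPolicy()


@dataclass(frozen=True)
class HairpinDesign:
    """A complete hairpin precursor design (all RNA, 5'->3').

    Invariants (checked on construction): reverting every recorded
    mutation on the passenger reproduces the exact reverse complement of
    the guide, and each mutation's ``from_base`` matches that unmutated
    passenger.
    """

    guide: MatureMiRNA
    passenger: NucleotideSequence
    loop: NucleotideSequence
    mutations: tuple[MutationSpec, ...] = ()
    counterpart: MatureMiRNA | None = None

    def __post_init__(self) -> None:
        if self.passenger.alphabet != "RNA" or self.loop.alphabet != "RNA":
            raise ConfigError("passenger and loop must be RNA")
        expected = reverse_complement(self.guide.sequence).residues
        reverted = list(self.passenger.residues)
        seen: set[int] = set()
        for m in self.mutations:
            if m.position > len(reverted):
                raise BoundsError(
                    f"mutation {m} beyond passenger length {len(reverted)}"
                )
            if m.position in seen:
                raise ValueError(f"duplicate mutation at position {m.position}")
            seen.add(m.position)
            if reverted[m.position - 1] != m.to_base:
                raise ValueError(
                    f"mutation {m} inconsistent with passenger base "
                    f"{reverted[m.position - 1]!r}"
                )
            reverted[m.position - 1] = m.from_base
        if "".join(reverted) != expected:
            raise ValueError(
                "passenger with mutations reverted does not equal the "
                "reverse complement of the guide"
            )

    @property
    def precursor(self) -> NucleotideSequence:
        """Passenger + loop + guide, 5'->3'."""
        return rna(
            self.passenger.residues
            + self.loop.residues
            + self.guide.sequence.residues,
            f"{self.guide.name or 'design'}-precursor",
        )

    @property
    def unmutated_passenger(self) -> NucleotideSequence:
        return reverse_complement(self.guide.sequence)


def has_t_run(dna_or_rna: str, k: int = POL3_T_RUN) -> bool:
    """True if the sequence contains a run of >= ``k`` consecutive T/U."""
    return re.search(rf"[TU]{{{k},}}", dna_or_rna.upper()) is not None


def t_run_touches(dna_or_rna: str, index0: int, k: int = POL3_T_RUN) -> bool:
    """True if a T/U run of >= ``k`` covers the 0-based position ``index0``.

    Used to reject a substitution that creates or extends a Pol III
    terminator run, without penalizing runs that pre-exist elsewhere in
    the transcript (those are reported at emission time instead).
    """
    for match in re.finditer(rf"[TU]{{{k},}}", dna_or_rna.upper()):
        if match.start() <= index0 < match.end():
            return True
    return False


def build_passenger(guide: MatureMiRNA) -> NucleotideSequence:
    """The unmutated passenger: exact reverse complement of the guide.

    Unlike natural precursors, whose stems carry mismatches and internal
    loops, the engineered 5' arm is fully complementary to the star
    strand; any seed-disruption mutations are layered on afterwards.
    """
    out = reverse_complement(guide.sequence)
    name = f"anti-{guide.name}" if guide.name else "passenger"
    return out.with_name(name)


def apply_mutations(
    passenger: NucleotideSequence, mutations: Iterable[MutationSpec]
) -> NucleotideSequence:
    """Apply substitutions to a passenger strand (1-based positions)."""
    residues = list(passenger.residues)
    for m in mutations:
        if m.position > len(residues):
            raise BoundsError(
                f"mutation {m} beyond passenger length {len(residues)}"
            )
        if residues[m.position - 1] != m.from_base:
            raise ValueError(
                f"mutation {m} does not match passenger base "
                f"{residues[m.position - 1]!r} at position {m.position}"
            )
        residues[m.position - 1] = m.to_base
    return NucleotideSequence("".join(residues), "RNA", passenger.name)


def detect_seed_collision(
    passenger: NucleotideSequence,
    counterpart: MatureMiRNA | None,
    window: tuple[int, int] = DEFAULT_COLLISION_WINDOW,
    threshold: int | None = None,
) -> SeedCollisionReport:
    """Compare the passenger and counterpart seed windows position-wise.

    A collision means the engineered passenger carries the counterpart
    miRNA's seed and could phenocopy it.  Under the strict default the
    collision flag is raised only when every window position is
    identical; ``threshold`` lowers that bar.
    """
    if counterpart is None:
        raise ConfigError(
            "no counterpart miRNA supplied for the seed-collision check; "
            "re-run with --no-counterpart to design without it"
        )
    start, end = window
    if start < 1 or start > end:
        raise BoundsError(f"bad window {start}..{end}")
    wlen = end - start + 1
    need = wlen if threshold is None else threshold
    count = positional_identity(passenger, counterpart.sequence, window)
    return SeedCollisionReport(
        window=window,
        identical_count=count,
        collision=count >= need,
        passenger_window_bases=passenger.window(start, end),
        counterpart_window_bases=counterpart.sequence.window(start, end),
        threshold=need,
    )


def _substitution_candidates(
    base: str, policy: MutationPolicy
) -> list[tuple[int, str]]:
    """Ordered (tier, to_base) substitution candidates for one position.

    Tier 1: transition that leaves a G·U wobble with the guide (possible
    only when the passenger base is A or C).  Tier 2: other transition.
    Tier 3: transversions in alphabetical order.
    """
    transition = _TRANSITION[base]
    others = [b for b in "ACGU" if b not in (base, transition)]
    tiers: list[tuple[int, str]] = []
    if policy.prefer_transitions:
        wobble = policy.prefer_stem_wobble and base in "AC"
        tiers.append((1 if wobble else 2, transition))
        tiers.extend((3, b) for b in others)
    else:
        for b in sorted(others + [transition]):
            tiers.append((3, b))
    return tiers


def propose_seed_mutations(
    passenger: NucleotideSequence,
    counterpart: MatureMiRNA,
    policy: MutationPolicy = PAPER_POLICY,
    reference_seeds: Iterable[str] = (),
) -> list[MutationSpec]:
    """Choose substitutions that destroy a passenger/counterpart seed collision.

    Returns an empty list when no collision is detected.  Otherwise
    returns at least ``policy.min_mutations`` substitutions, all inside
    the collision window, such that

    * re-running :func:`detect_seed_collision` on the mutated passenger
      reports no collision,
    * no substitution creates a U/T run of >= 4 in the transcribed insert
      (which would terminate Pol III early), and
    * if ``reference_seeds`` (RNA window strings of known miRNAs) is
      supplied, the mutated window matches none of them exactly.

    Selection is deterministic given the inputs and policy.
    """
    report = detect_seed_collision(
        passenger, counterpart, policy.window, policy.collision_threshold
    )
    if not report.collision:
        return []

    start, end = policy.window
    identical = [
        p
        for p in range(start, end + 1)
        if passenger.base(p) == counterpart.sequence.base(p)
    ]
    reference = {s.upper() for s in reference_seeds}

    # Rank candidate positions: protected 5'-end positions last, then by
    # best substitution tier, then ascending position.
    ranked = sorted(
        identical,
        key=lambda p: (
            p <= policy.protect_passenger_5p,
            _substitution_candidates(passenger.base(p), policy)[0][0],
            p,
        ),
    )

    def violates_t_run(candidate: NucleotideSequence, pos: int) -> bool:
        # Transcript context: the vector's fixed CCC flank precedes the
        # passenger and the loop follows it.  Only a run touching the
        # substituted position counts against this mutation.
        context = "CCC" + candidate.residues + DEFAULT_LOOP.residues
        return t_run_touches(context, 3 + pos - 1)

    chosen: list[MutationSpec] = []
    current = passenger

    def collision_destroyed(seq: NucleotideSequence) -> bool:
        rep = detect_seed_collision(
            seq, counterpart, policy.window, policy.collision_threshold
        )
        return not rep.collision

    def seed_is_novel(seq: NucleotideSequence) -> bool:
        if not reference:
            return True
        return seq.window(start, end) not in reference

    for pos in ranked:
        if len(chosen) >= policy.max_mutations:
            break
        if policy.skip_adjacent and any(
            abs(pos - m.position) == 1 for m in chosen
        ):
            continue
        base = current.base(pos)
        for _tier, to_base in _substitution_candidates(base, policy):
            if to_base == counterpart.sequence.base(pos):
                continue  # would re-create identity at this position
            spec = MutationSpec(pos, base, to_base)
            candidate = apply_mutations(current, [spec])
            if violates_t_run(candidate, pos):
                continue
            chosen.append(spec)
            current = candidate
            break
        if (
            len(chosen) >= policy.min_mutations
            and collision_destroyed(current)
            and seed_is_novel(current)
        ):
            return sorted(chosen, key=lambda m: m.position)

    violated = []
    if len(chosen) < policy.min_mutations:
        violated.append(
            f"fewer than {policy.min_mutations} acceptable substitutions "
            "found in the collision window"
        )
    if not collision_destroyed(current):
        violated.append("collision not destroyed within the mutation budget")
    if not seed_is_novel(current):
        violated.append("mutated seed window matches a reference miRNA seed")
    raise DesignFailure(
        "no seed-disruption mutation set satisfies the policy constraints",
        violated=violated,
    )


def assemble_hairpin(
    guide: MatureMiRNA,
    passenger: NucleotideSequence | None = None,
    loop: NucleotideSequence = DEFAULT_LOOP,
    mutations: Sequence[MutationSpec] = (),
    counterpart: MatureMiRNA | None = None,
) -> HairpinDesign:
    """Assemble passenger + loop + guide into a validated design.

    When ``passenger`` is omitted it is built as the guide's reverse
    complement with ``mutations`` applied.  A loop shorter than 4 nt is
    rejected — the hairpin cannot close.
    """
    if len(loop) < 4:
        raise ConfigError(
            f"loop {loop.residues!r} shorter than 4 nt: hairpin cannot close"
        )
    if loop.alphabet != "RNA":
        raise ConfigError("loop must be RNA")
    if passenger is None:
        passenger = apply_mutations(build_passenger(guide), mutations)
    return HairpinDesign(
        guide=guide,
        passenger=passenger,
        loop=loop,
        mutations=tuple(sorted(mutations, key=lambda m: m.position)),
        counterpart=counterpart,
    )


def destabilize_passenger_3prime(
    design: HairpinDesign, n_mutations: int = 1
) -> HairpinDesign:
    """Optionally weaken the passenger's 3'-terminal pairing.

    The passenger's 3'-terminal bases pair the guide's 5' end; mismatches
    there lower the internal stability of the guide's 5' duplex end,
    which favors loading of the guide into RISC.  Up to ``n_mutations``
    substitutions are introduced in the passenger's last four positions,
    each chosen by exhaustive search as the strictly best single
    improvement of the thermodynamic asymmetry score.  If no substitution
    improves the score the design is returned unchanged with a warning.
    """
    from .thermo import duplex_end_stability  # local import: avoid cycle

    def asymmetry(d: HairpinDesign) -> float:
        return duplex_end_stability(d.guide.sequence, d.passenger).asymmetry

    current = design
    applied = 0
    for _ in range(n_mutations):
        base_score = asymmetry(current)
        plen = len(current.passenger)
        window_start = max(1, plen - 3)
        mutated_positions = {m.position for m in current.mutations}
        best: tuple[float, int, str, HairpinDesign] | None = None
        for pos in range(window_start, plen + 1):
            if pos in mutated_positions:
                continue
            from_base = current.passenger.base(pos)
            for to_base in "ACGU":
                if to_base == from_base:
                    continue
                spec = MutationSpec(pos, from_base, to_base)
                candidate_passenger = apply_mutations(
                    current.passenger, [spec]
                )
                core = (
                    "CCC"
                    + candidate_passenger.residues
                    + current.loop.residues
                    + current.guide.sequence.residues
                )
                if t_run_touches(core, 3 + pos - 1):
                    continue
                candidate = replace(
                    current,
                    passenger=candidate_passenger,
                    mutations=tuple(
                        sorted(
                            current.mutations + (spec,),
                            key=lambda m: m.position,
                        )
                    ),
                )
                score = asymmetry(candidate)
                # maximize score; tie-break lowest position then base order
                if (
                    best is None
                    or score > best[0]
                    or (score == best[0] and (pos, to_base) < (best[1], best[2]))
                ):
                    best = (score, pos, to_base, candidate)
        if best is None or best[0] <= base_score:
            break
        current = best[3]
        applied += 1
    if applied == 0:
        warnings.warn(
            "no 3'-end substitution improves guide-loading asymmetry; "
            "design returned unchanged",
            DesignWarning,
            stacklevel=2,
        )
    return current


@dataclass
class DesignResult:
    """A hairpin design together with its screening reports."""

    design: HairpinDesign
    collision_pre: SeedCollisionReport | None
    collision_post: SeedCollisionReport | None
    warnings: list[str] = field(default_factory=list)


def design_hairpin(
    guide: MatureMiRNA,
    counterpart: MatureMiRNA | None = None,
    loop: NucleotideSequence = DEFAULT_LOOP,
    policy: MutationPolicy = PAPER_POLICY,
    reference_seeds: Iterable[str] = (),
) -> DesignResult:
    """End-to-end hairpin design: complement, collision check, mutations.

    Without a counterpart the passenger is emitted as the pure complement
    and a warning notes that no collision screen was possible.
    """
    passenger = build_passenger(guide)
    notes: list[str] = []
    if counterpart is None:
        design = assemble_hairpin(guide, passenger, loop)
        notes.append(
            "no counterpart miRNA supplied: seed-collision screen skipped; "
            "passenger emitted as the unmodified complement"
        )
        return DesignResult(design, None, None, notes)

    pre = detect_seed_collision(
        passenger, counterpart, policy.window, policy.collision_threshold
    )
    mutations: list[MutationSpec] = []
    if pre.collision:
        mutations = propose_seed_mutations(
            passenger, counterpart, policy, reference_seeds
        )
        notes.append(
            "seed collision with "
            f"{counterpart.name or 'counterpart'} at sites "
            f"{pre.window[0]}-{pre.window[1]} "
            f"({pre.identical_count}/{pre.window_length}); mutations "
            + ", ".join(str(m) for m in mutations)
        )
    mutated = apply_mutations(passenger, mutations)
    post = detect_seed_collision(
        mutated, counterpart, policy.window, policy.collision_threshold
    )
    design = assemble_hairpin(
        guide, mutated, loop, mutations, counterpart=counterpart
    )
    return DesignResult(design, pre, post, notes)
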