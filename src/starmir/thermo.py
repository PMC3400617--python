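"""Nearest-neighbor duplex end stability and RISC strand-selection bias.

RISC preferentially loads the duplex strand whose 5' end is less tightly
paired (lower internal stability).  This module scores the two terminal
windows of the designed guide/passenger duplex with the published
Watson-Crick RNA nearest-neighbor free energies and reports which strand
is expected to load.  The prediction is advisory: there is no published
quantitative loading threshold, so near-symmetric duplexes are called
ambiguous rather than forced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING, Literal

from .errors import BoundsError, ConfigError
from .sequences import NucleotideSequence, watson_crick_pair

if TYPE_CHECKING:  # pragma: no cover
    from .hairpin import HairpinDesign

#: Watson-Crick RNA nearest-neighbor stack free energies, Delta-G at 37 C
#: in kcal/mol (Xia et al. 1998, Biochemistry 37:14719).  Keyed by the
#: 5'->3' dinucleotide on the strand being read; the opposite strand is
#: its Watson-Crick complement.  The 10 unique parameters are expanded to
#: all 16 dinucleotides via strand symmetry (e.g. AG/CU == CU/AG).
XIA_TURNER_DG37: dict[str, float] = {
    "AA": -0.93, "UU": -0.93,
    "AU": -1.10,
    "UA": -1.33,
    "CU": -2.08, "AG": -2.08,
    "CA": -2.11, "UG": -2.11,
    "GU": -2.24, "AC": -2.24,
    "GA": -2.35, "UC": -2.35,
    "CG": -2.36,
    "GG": -3.26, "CC": -3.26,
    "GC": -3.42,
}

#: Terminal window width (base pairs) scored at each duplex end.
DEFAULT_WINDOW_BP = 4

#: |asymmetry| below this (kcal/mol) is called ambiguous.
DEFAULT_TOLERANCE = 0.5

End = Literal["guide_5p", "passenger_5p"]


class LoadingBiasWarning(UserWarning):
    """The duplex is not predicted to load the intended guide strand."""


@dataclass(frozen=True)
class DuplexEndStability:
    """End stabilities of a guide/passenger duplex and the loading call.

    ``asymmetry = guide_5p_dG - passenger_5p_dG``: positive means the
    guide's 5' end is the weaker (less negative) one, predicting guide
    loading.
    """

    guide_5p_dG: float
    passenger_5p_dG: float
    window_bp: int
    tolerance: float
    parameter_set: str = "Xia-Turner dG37 (RNA Watson-Crick)"

    @property
    def asymmetry(self) -> float:
        return self.guide_5p_dG - self.passenger_5p_dG

    @property
    def predicted_loaded(self) -> Literal["guide", "passenger", "ambiguous"]:
        if self.asymmetry > self.tolerance:
            return "guide"
        if self.asymmetry < -self.tolerance:
            return "passenger"
        return "ambiguous"


def _check_duplex(guide: NucleotideSequence, passenger: NucleotideSequence):
    if guide.alphabet != "RNA" or passenger.alphabet != "RNA":
        raise ConfigError("duplex strands must be RNA")
    if len(guide) != len(passenger):
        raise ConfigError(
            "guide and passenger must be equal length to form the designed "
            f"duplex (got {len(guide)} vs {len(passenger)})"
        )


def end_window_dG(
    guide: NucleotideSequence,
    passenger: NucleotideSequence,
    end: End,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> float:
    """Free energy (kcal/mol) of one terminal pairing window of the duplex.

    The duplex is the designed antiparallel pairing: guide position ``i``
    opposite passenger position ``L - i + 1``.  The window comprises the
    first ``window_bp`` positions at the named strand's 5' end; its score
    is the sum of nearest-neighbor stack energies over adjacent position
    pairs.  A stack contributes only when both of its base pairs are
    Watson-Crick — mismatched positions (e.g. from seed-disruption
    mutations) and G·U wobbles contribute zero, a deliberately
    conservative simplification.  Less negative means less stable.
    """
    _check_duplex(guide, passenger)
    L = len(guide)
    if not 1 <= window_bp <= L:
        raise BoundsError(
            f"window of {window_bp} bp invalid for duplex of {L} bp"
        )
    strand = guide if end == "guide_5p" else passenger
    other = passenger if end == "guide_5p" else guide

    def paired(i: int) -> bool:
        return watson_crick_pair(strand.base(i), other.base(L - i + 1))

    total = 0.0
    for i in range(1, window_bp):
        if paired(i) and paired(i + 1):
            total += XIA_TURNER_DG37[strand.base(i) + strand.base(i + 1)]
    return total


def duplex_end_stability(
    guide: NucleotideSequence,
    passenger: NucleotideSequence,
    window_bp: int = DEFAULT_WINDOW_BP,
    tolerance: float = DEFAULT_TOLERANCE,
) -> DuplexEndStability:
    """Score both duplex ends and call the preferentially loaded strand."""
    return DuplexEndStability(
        guide_5p_dG=end_window_dG(guide, passenger, "guide_5p", window_bp),
        passenger_5p_dG=end_window_dG(
            guide, passenger, "passenger_5p", window_bp
        ),
        window_bp=window_bp,
        tolerance=tolerance,
    )


def predict_loaded_strand(
    design: "HairpinDesign",
    window_bp: int = DEFAULT_WINDOW_BP,
    tolerance: float = DEFAULT_TOLERANCE,
) -> DuplexEndStability:
    """Strand-selection prediction for an assembled hairpin design.

    Emits a :class:`LoadingBiasWarning` when the prediction is not a
    clear call for the guide strand — the whole point of the construct is
    to express the star strand, so an ambiguous or passenger-favoring
    duplex deserves attention (see
    :func:`starmir.hairpin.destabilize_passenger_3prime`).
    """
    result = duplex_end_stability(
        design.guide.sequence, design.passenger, window_bp, tolerance
    )
    if result.predicted_loaded != "guide":
        warnings.warn(
            f"predicted loaded strand is {result.predicted_loaded!r} "
            f"(asymmetry {result.asymmetry:+.2f} kcal/mol); consider "
            "destabilizing the passenger 3' end",
            LoadingBiasWarning,
            stacklevel=2,
        )
    return result
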