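"""Synthesis-ready cloning oligos from hairpin designs.

A :class:`VectorProfile` describes how an insert body is dressed for one
backbone: fixed double-stranded flanks around the body plus the
single-stranded sticky ends left by the cloning enzymes.  Emission is
purely string assembly — the bottom strand is the exact reverse
complement of the double-stranded core (strict mode) — so an emitted
pair always anneals without mismatches.  :func:`verify_duplex` is the
independent check used both on emitted pairs and on externally supplied
(e.g. legacy or vendor) oligo pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .errors import ConfigError
from .hairpin import POL3_T_RUN, HairpinDesign, has_t_run
from .sequences import reverse_transcribe

_COMPLEMENT_DNA = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Annealing protocol carried on ordering sheets (documentation only).
ANNEALING_PROTOCOL_NOTE = (
    "anneal equimolar oligos: 95C 2 min, then -1C every 90 s down to 25C"
)


@dataclass(frozen=True)
class VectorProfile:
    """Verbatim flank/overhang strings for one cloning backbone.

    ``top_prefix``, ``top_suffix``, ``bottom_prefix`` and
    ``bottom_suffix`` are single-stranded after annealing;
    ``core_prefix`` + body + ``core_suffix`` is the double-stranded core.
    All strings 5'->3' on their own strand.
    """

    name: str
    insert_kind: str
    enzymes: tuple[str, str]
    top_prefix: str = ""
    core_prefix: str = ""
    core_suffix: str = ""
    top_suffix: str = ""
    bottom_prefix: str = ""
    bottom_suffix: str = ""
    notes: str = ""

    def __post_init__(self) -> None:
        for label in (
            "top_prefix",
            "core_prefix",
            "core_suffix",
            "top_suffix",
            "bottom_prefix",
            "bottom_suffix",
        ):
            value = getattr(self, label)
            if any(b not in "ACGT" for b in value):
                raise ConfigError(
                    f"profile {self.name!r}: {label} {value!r} is not DNA"
                )


@dataclass(frozen=True)
class OligoPair:
    """Two synthesis-ready DNA strands (both written 5'->3').

    The overhang fields record which terminal bases are single-stranded
    after annealing; everything between them on each strand is the
    annealed core.
    """

    name: str
    top: str
    bottom: str
    top_overhang_5p: str = ""
    top_overhang_3p: str = ""
    bottom_overhang_5p: str = ""
    bottom_overhang_3p: str = ""
    warnings: tuple[str, ...] = ()

    @property
    def top_core(self) -> str:
        end = len(self.top) - len(self.top_overhang_3p)
        return self.top[len(self.top_overhang_5p) : end]

    @property
    def bottom_core(self) -> str:
        end = len(self.bottom) - len(self.bottom_overhang_3p)
        return self.bottom[len(self.bottom_overhang_5p) : end]


@dataclass(frozen=True)
class DuplexReport:
    """Outcome of checking an oligo pair for annealing complementarity."""

    name: str
    core_length_top: int
    core_length_bottom: int
    mismatch_positions: tuple[int, ...]  # 1-based, in top-strand coords
    overhangs_expected: tuple[str, str, str, str] | None
    overhangs_ok: bool

    @property
    def length_ok(self) -> bool:
        return self.core_length_top == self.core_length_bottom

    @property
    def n_mismatches(self) -> int:
        return len(self.mismatch_positions)

    @property
    def ok(self) -> bool:
        return self.length_ok and not self.mismatch_positions and self.overhangs_ok


def _load_builtin_profiles() -> dict[str, VectorProfile]:
    raw = yaml.safe_load(
        resources.files("starmir.data").joinpath("profiles.yaml").read_text()
    )
    out: dict[str, VectorProfile] = {}
    for name, cfg in raw["profiles"].items():
        missing = {"insert_kind", "enzymes"} - set(cfg)
        if missing:
            raise ConfigError(
                f"profile {name!r} missing required fields: {sorted(missing)}"
            )
        out[name] = VectorProfile(
            name=name,
            insert_kind=cfg["insert_kind"],
            enzymes=tuple(cfg["enzymes"]),
            top_prefix=cfg.get("top_prefix", ""),
            core_prefix=cfg.get("core_prefix", ""),
            core_suffix=cfg.get("core_suffix", ""),
            top_suffix=cfg.get("top_suffix", ""),
            bottom_prefix=cfg.get("bottom_prefix", ""),
            bottom_suffix=cfg.get("bottom_suffix", ""),
            notes=cfg.get("notes", ""),
        )
    return out


BUILTIN_PROFILES: dict[str, VectorProfile] = _load_builtin_profiles()

_ALIASES = {
    "plvx": "plvx-shRNA2",
    "plvx-shrna2": "plvx-shRNA2",
    "psicheck": "psiCHECK",
    "pmir": "pMIR-Report",
    "pmir-report": "pMIR-Report",
}


def get_profile(name: str) -> VectorProfile:
    """Look up a built-in vector profile (case-insensitive, aliases ok)."""
    if name in BUILTIN_PROFILES:
        return BUILTIN_PROFILES[name]
    canonical = _ALIASES.get(name.lower())
    if canonical:
        return BUILTIN_PROFILES[canonical]
    raise ConfigError(
        f"unknown vector profile {name!r}; built-ins: "
        + ", ".join(sorted(BUILTIN_PROFILES))
    )


def _revcomp_dna(s: str) -> str:
    return "".join(_COMPLEMENT_DNA[b] for b in reversed(s))


def emit_duplex(
    body_dna: str,
    profile: VectorProfile,
    name: str,
    extra_warnings: Iterable[str] = (),
) -> OligoPair:
    """Dress an insert body with a profile's flanks and sticky ends.

    Strict mode: the bottom strand is constructed as the exact reverse
    complement of the double-stranded core, so the emitted pair anneals
    perfectly by construction.
    """
    if any(b not in "ACGT" for b in body_dna):
        raise ConfigError("insert body must be DNA (A/C/G/T)")
    core = profile.core_prefix + body_dna + profile.core_suffix
    top = profile.top_prefix + core + profile.top_suffix
    bottom = profile.bottom_prefix + _revcomp_dna(core) + profile.bottom_suffix
    return OligoPair(
        name=name,
        top=top,
        bottom=bottom,
        top_overhang_5p=profile.top_prefix,
        top_overhang_3p=profile.top_suffix,
        bottom_overhang_5p=profile.bottom_prefix,
        bottom_overhang_3p=profile.bottom_suffix,
        warnings=tuple(extra_warnings),
    )


def emit_overexpression_oligos(
    design: HairpinDesign,
    profile: VectorProfile | str = "plvx-shRNA2",
    name: str | None = None,
) -> OligoPair:
    """Cloning oligos for a hairpin design in an shRNA backbone.

    The top strand reads sticky end + 5' flank + passenger + loop + guide
    + terminator flank.  An internal U/T run of >= 4 inside the
    transcribed region would terminate Pol III prematurely; it is
    reported as a warning (the 3' terminator flank itself is exempt).
    """
    if isinstance(profile, str):
        profile = get_profile(profile)
    if profile.insert_kind != "hairpin":
        raise ConfigError(
            f"profile {profile.name!r} is a {profile.insert_kind} backbone, "
            "not an shRNA/hairpin backbone"
        )
    body = reverse_transcribe(design.precursor).residues
    warns: list[str] = []
    if has_t_run(profile.core_prefix + body):
        warns.append(
            f"internal T-run of >={POL3_T_RUN} inside the transcribed "
            "insert: Pol III may terminate early"
        )
    if name is None:
        name = f"{profile.name}:{design.guide.name or 'design'}"
    pair = emit_duplex(body, profile, name, warns)
    for w in warns:
        warnings.warn(f"{name}: {w}", UserWarning, stacklevel=2)
    return pair


def verify_duplex(
    pair: OligoPair, profile: VectorProfile | None = None
) -> DuplexReport:
    """Check that an oligo pair anneals as its overhang annotations imply.

    Aligns the two annealed cores antiparallel and reports every position
    (1-based on the top strand) where the bases are not Watson-Crick
    complementary.  With a profile, also checks that the annotated
    overhangs equal the profile's sticky-end strings.
    """
    top_core = pair.top_core
    bottom_core = pair.bottom_core
    mismatches: list[int] = []
    n = min(len(top_core), len(bottom_core))
    offset = len(pair.top_overhang_5p)
    for i in range(n):
        t = top_core[i]
        b = bottom_core[len(bottom_core) - 1 - i]
        if _COMPLEMENT_DNA.get(t) != b:
            mismatches.append(offset + i + 1)
    expected = None
    overhangs_ok = True
    if profile is not None:
        expected = (
            profile.top_prefix,
            profile.top_suffix,
            profile.bottom_prefix,
            profile.bottom_suffix,
        )
        overhangs_ok = expected == (
            pair.top_overhang_5p,
            pair.top_overhang_3p,
            pair.bottom_overhang_5p,
            pair.bottom_overhang_3p,
        ) and pair.top.startswith(profile.top_prefix) and pair.bottom.startswith(
            profile.bottom_prefix
        )
    return DuplexReport(
        name=pair.name,
        core_length_top=len(top_core),
        core_length_bottom=len(bottom_core),
        mismatch_positions=tuple(mismatches),
        overhangs_expected=expected,
        overhangs_ok=overhangs_ok,
    )


_SHEET_COLUMNS = [
    "construct",
    "strand",
    "sequence_5p_to_3p",
    "length_nt",
    "enzymes",
    "protocol",
]


def ordering_sheet_frame(
    pairs: Sequence[OligoPair],
    enzymes: dict[str, tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Tabulate oligo pairs for synthesis ordering (two rows per pair).

    ``enzymes`` optionally maps pair name -> enzyme pair for the enzymes
    column.  The annealing thermal ramp is carried as a protocol note.
    """
    rows = []
    for pair in pairs:
        enz = "/".join(enzymes.get(pair.name, ())) if enzymes else ""
        for strand, seq in (("top", pair.top), ("bottom", pair.bottom)):
            rows.append(
                {
                    "construct": pair.name,
                    "strand": strand,
                    "sequence_5p_to_3p": seq,
                    "length_nt": len(seq),
                    "enzymes": enz,
                    "protocol": ANNEALING_PROTOCOL_NOTE,
                }
            )
    return pd.DataFrame(rows, columns=_SHEET_COLUMNS)


def emit_ordering_sheet(
    pairs: Sequence[OligoPair],
    path: str | Path,
    enzymes: dict[str, tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Write the ordering sheet as TSV and return the frame."""
    frame = ordering_sheet_frame(pairs, enzymes)
    frame.to_csv(path, sep="\t", index=False)
    return frame


def read_ordering_sheet(path: str | Path) -> pd.DataFrame:
    """Re-parse an ordering sheet written by :func:`emit_ordering_sheet`."""
    return pd.read_csv(path, sep="\t", dtype=str).fillna("")
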