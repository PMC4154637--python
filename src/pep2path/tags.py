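"""Sequence tags: parsing, mass-shift conversion, expansion.

A sequence tag is the short, possibly degenerate amino-acid string read
off the mass differences between MS/MS fragment peaks.  Degenerate
positions ("T(S)", "I(L)") carry several candidate monomers because
distinct residues share a residue mass (Ile/Leu exactly; Lys/Gln at low
resolution) or because a post-translational modification makes two
genome-encoded residues indistinguishable in the spectrum.

Grammar (EBNF, documented in ``docs/tag_grammar.md``)::

    tag        = token , { [ "-" ] , token } ;
    token      = monomer , { "(" , monomer , { "/" , monomer } , ")" } ;
    monomer    = one-letter code | multi-letter name ;

A dash-separated tag may mix one-letter codes and NORINE-style names
("V-V-allothr-I(L)"); an undashed tag is read as one-letter codes with
optional parenthesized alternatives ("VHFVGWI(L)").
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, replace
from itertools import product
from pathlib import Path
from typing import Iterator, Sequence

from .alphabet import DEFAULT_ALPHABET, normalize_monomer, one_letter
from .errors import (
    ExpansionCapError,
    TagGrammarError,
    UnmatchedMassError,
)

DEFAULT_MASS_TOLERANCE = 0.02  # Da; typical high-resolution MS tag accuracy
DEFAULT_EXPANSION_CAP = 10_000


@dataclass(frozen=True)
class TagPosition:
    """One tag position: a non-empty set of candidate monomers, plus the
    observed residue mass when the tag came from a mass-shift list."""

    candidates: frozenset[str]
    source_mass: float | None = None

    def __post_init__(self) -> None:
        if not self.candidates:
            raise TagGrammarError("tag position with no candidate monomers")

    @property
    def degenerate(self) -> bool:
        return len(self.candidates) > 1


@dataclass(frozen=True)
class SequenceTag:
    positions: tuple[TagPosition, ...]
    kind: str = "nrp"  # "nrp" | "ripp"

    def __post_init__(self) -> None:
        if len(self.positions) < 1:
            raise TagGrammarError("a sequence tag needs at least one position")

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class MassConversionTable:
    """Rows mapping a monoisotopic residue mass (Da) to the monomers it
    may represent; a shift matches a row within ``tolerance`` Da."""

    rows: tuple[tuple[float, frozenset[str], str], ...]
    tolerance: float = DEFAULT_MASS_TOLERANCE

    def __post_init__(self) -> None:
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")
        for mass, cands, _ in self.rows:
            if mass <= 0:
                raise ValueError(f"non-positive mass {mass} in conversion table")
            if not cands:
                raise ValueError(f"mass {mass}: empty candidate set")

    def candidates_for(self, shift: float, tolerance: float | None = None) -> frozenset[str]:
        tol = self.tolerance if tolerance is None else tolerance
        out: set[str] = set()
        for mass, cands, _ in self.rows:
            if abs(mass - shift) <= tol:
                out |= cands
        return frozenset(out)


def load_conversion_table(
    path: str | Path, tolerance: float = DEFAULT_MASS_TOLERANCE
) -> MassConversionTable:
    """Read a tab-separated conversion table: ``mass<TAB>cand1/cand2<TAB>label``.

    Lines starting with ``#`` are comments.
    """
    rows = []
    for ln, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}:{ln}: expected mass<TAB>candidates[<TAB>label]")
        mass = float(parts[0])
        cands = frozenset(t.strip().lower() for t in parts[1].split("/") if t.strip())
        label = parts[2] if len(parts) > 2 else ""
        rows.append((mass, cands, label))
    return MassConversionTable(rows=tuple(rows), tolerance=tolerance)


# ---------------------------------------------------------------------------
# parsing

_TOKEN_RE = re.compile(r"([A-Za-z]+)((?:\([^()]*\))*)\s*")
_GROUP_RE = re.compile(r"\(([^()]*)\)")


def _parse_token(core: str, groups: str, alphabet: frozenset[str]) -> TagPosition:
    cands = {normalize_monomer(core, alphabet)}
    for g in _GROUP_RE.findall(groups):
        for alt in g.split("/"):
            cands.add(normalize_monomer(alt, alphabet))
    return TagPosition(candidates=frozenset(cands))


def _tokens_from_undashed(text: str) -> Iterator[tuple[str, str]]:
    """An undashed tag is a run of one-letter codes, each optionally
    followed by parenthesized alternatives."""
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise TagGrammarError(f"cannot parse tag at {text[pos:]!r}")
        letters, groups = m.group(1), m.group(2)
        # letters before the final one are bare single-letter positions;
        # the trailing letter owns any parenthesized alternatives
        for ch in letters[:-1]:
            yield ch, ""
        yield letters[-1], groups
        pos = m.end()


def parse_tag(
    text: str,
    kind: str = "nrp",
    alphabet: frozenset[str] = DEFAULT_ALPHABET,
) -> SequenceTag:
    """Parse a tag string like ``"V-V-T(S)-T(S)-A-I(L)-V-G"`` or
    ``"VHFVGWI(L)"`` or ``"thr-pro-pro-arg"``.

    Raises :class:`TagGrammarError` on empty input or unbalanced
    parentheses and :class:`UnknownMonomerError` on unknown tokens.
    """
    s = text.strip()
    if not s:
        raise TagGrammarError("empty tag string")
    if s.count("(") != s.count(")"):
        raise TagGrammarError(f"unbalanced parentheses in tag {text!r}")
    positions: list[TagPosition] = []
    if "-" in s:
        for raw in s.split("-"):
            raw = raw.strip()
            if not raw:
                raise TagGrammarError(f"empty token in tag {text!r}")
            m = _TOKEN_RE.fullmatch(raw)
            if m is None:
                raise TagGrammarError(f"cannot parse token {raw!r}")
            positions.append(_parse_token(m.group(1), m.group(2), alphabet))
    else:
        for core, groups in _tokens_from_undashed(s):
            positions.append(_parse_token(core, groups, alphabet))
    return SequenceTag(positions=tuple(positions), kind=kind)


def format_tag(tag: SequenceTag) -> str:
    """Canonical text form: dash-separated, alphabetically first
    candidate as the head and the rest parenthesized, one-letter codes
    where the whole tag is proteinogenic."""
    compact = all(
        all(one_letter(c) is not None for c in p.candidates) for p in tag.positions
    )
    parts = []
    for p in tag.positions:
        names = sorted(p.candidates)
        if compact:
            head = one_letter(names[0])
            alts = "".join(f"({one_letter(n)})" for n in names[1:])
        else:
            head = names[0]
            alts = "".join(f"({n})" for n in names[1:])
        parts.append(head + alts)
    return "-".join(parts)


# ---------------------------------------------------------------------------
# mass shifts

def masses_to_tag(
    shifts: Sequence[float],
    table: MassConversionTable,
    kind: str = "nrp",
    tolerance: float | None = None,
) -> SequenceTag:
    """Convert an ordered list of mass shifts (Da) into a degenerate tag.

    Each shift becomes one position whose candidates are the union of
    all conversion-table rows within tolerance; a shift matching no row
    raises :class:`UnmatchedMassError` naming the shift.
    """
    if not shifts:
        raise UnmatchedMassError("empty mass-shift list")
    positions = []
    for shift in shifts:
        if not (shift > 0) or math.isnan(shift):
            raise UnmatchedMassError(f"mass shift must be positive, got {shift}")
        cands = table.candidates_for(shift, tolerance)
        if not cands:
            raise UnmatchedMassError(
                f"mass shift {shift} Da matches no conversion-table row "
                f"(tolerance {table.tolerance if tolerance is None else tolerance} Da)"
            )
        positions.append(TagPosition(candidates=cands, source_mass=float(shift)))
    return SequenceTag(positions=tuple(positions), kind=kind)


# ---------------------------------------------------------------------------
# expansion / reversal

def expansion_size(tag: SequenceTag) -> int:
    n = 1
    for p in tag.positions:
        n *= len(p.candidates)
    return n


def expand_tag(
    tag: SequenceTag, cap: int = DEFAULT_EXPANSION_CAP
) -> list[tuple[str, ...]]:
    """All concrete monomer sequences compatible with the tag, in
    lexicographic order; size is the product of per-position candidate
    counts, guarded by ``cap``."""
    n = expansion_size(tag)
    if n > cap:
        raise ExpansionCapError(
            f"tag expands to {n} sequences, above the cap of {cap}"
        )
    choices = [sorted(p.candidates) for p in tag.positions]
    return [tuple(seq) for seq in product(*choices)]


def reverse_tag(tag: SequenceTag) -> SequenceTag:
    """The tag read in the opposite direction (MS tags do not reveal the
    N-to-C orientation)."""
    return replace(tag, positions=tuple(reversed(tag.positions)))
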