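"""RiPP precursor matching: six-frame translation plus sliding-window
degenerate search.

Ribosomal peptides (RiPPs) are genome-encoded, so a sequence tag can be
matched directly against the conceptual six-frame translation of a
(meta)genome: every window of tag length, in every frame of both
strands, is tested position-by-position against the tag's candidate
sets.  Matching is context-free — no ORF or start-codon requirement —
and windows never span stop codons or N-containing codons, since a
contiguous precursor peptide cannot contain either.

Coordinates are 0-based half-open on the forward strand in machine
output (BED convention); the human-readable table also carries 1-based
inclusive coordinates (GenBank convention).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Seq import Seq
from Bio import SeqIO

from .alphabet import one_letter
from .errors import SchemaError
from .tags import SequenceTag, reverse_tag

TRANSLATION_TABLE = 11  # bacterial/archaeal code
STOP = "*"

_VALID_NT = set("ACGTN")


@dataclass(frozen=True)
class GenomeRecord:
    record_id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        bad = set(seq) - _VALID_NT
        if bad:
            raise SchemaError(
                f"record {self.record_id!r}: non-nucleotide character(s) {sorted(bad)}"
            )
        if len(seq) < 3:
            raise SchemaError(f"record {self.record_id!r}: shorter than one codon")
        object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class FrameTranslation:
    """One of the six conceptual translations of a record.

    ``frame`` is +1/+2/+3 (forward strand, 0/1/2 nt offset) or
    −1/−2/−3 (reverse-complement strand, offset counted on that
    strand).  ``nt_interval(i)`` maps a peptide index back to its
    forward-strand codon interval.
    """

    record_id: str
    frame: int
    peptide: str
    seq_length: int

    @property
    def strand(self) -> str:
        return "+" if self.frame > 0 else "-"

    @property
    def offset(self) -> int:
        return abs(self.frame) - 1

    def nt_interval(self, i: int) -> tuple[int, int]:
        """Forward-strand 0-based half-open interval of codon ``i``."""
        if not 0 <= i < len(self.peptide):
            raise IndexError(i)
        o = self.offset
        if self.frame > 0:
            return o + 3 * i, o + 3 * i + 3
        end = self.seq_length - (o + 3 * i)
        return end - 3, end

    def window_interval(self, start: int, length: int) -> tuple[int, int]:
        """Forward-strand interval covered by ``length`` codons starting
        at peptide index ``start``."""
        a0, a1 = self.nt_interval(start)
        b0, b1 = self.nt_interval(start + length - 1)
        return min(a0, b0), max(a1, b1)


def _translate(nt: str) -> str:
    # Bio.Seq yields 'X' for N-containing codons and '*' for stops; both
    # match no tag candidate.
    return str(Seq(nt).translate(table=TRANSLATION_TABLE))


def six_frame_translate(g: GenomeRecord) -> list[FrameTranslation]:
    """The six conceptual translations, frames +1, +2, +3, −1, −2, −3."""
    out = []
    rc = str(Seq(g.sequence).reverse_complement())
    for strand_seq, sign in ((g.sequence, 1), (rc, -1)):
        for o in range(3):
            usable = len(strand_seq) - o
            usable -= usable % 3
            pep = _translate(strand_seq[o : o + usable]) if usable else ""
            out.append(
                FrameTranslation(
                    record_id=g.record_id,
                    frame=sign * (o + 1),
                    peptide=pep,
                    seq_length=len(g.sequence),
                )
            )
    return out


@dataclass(frozen=True)
class RiPPMatch:
    record_id: str
    frame: int
    strand: str
    start_nt: int            # 0-based half-open, forward strand
    end_nt: int
    matched_peptide: str     # one-letter, N-to-C in reading direction
    tag_orientation: str     # "forward" | "reversed"

    @property
    def locus(self) -> tuple[str, int, int, int]:
        return (self.record_id, self.frame, self.start_nt, self.end_nt)


def _char_sets(tag: SequenceTag) -> list[frozenset[str]]:
    """Per-position sets of acceptable one-letter residues; candidates
    without a one-letter code (nonproteinogenic monomers) can never be
    genome-encoded and are dropped."""
    sets = []
    for p in tag.positions:
        chars = {one_letter(c) for c in p.candidates}
        sets.append(frozenset(c for c in chars if c is not None))
    return sets


def find_prepeptide_matches(
    tag: SequenceTag,
    genomes: Iterable[GenomeRecord],
    orientation_mode: str = "forward",
) -> list[RiPPMatch]:
    """Slide a window of tag length over all six frames of every record
    and report each window whose residues all lie in the corresponding
    candidate sets.

    With ``orientation_mode="both"`` the reversed tag is searched too;
    a locus found by both readings is reported once, as forward.
    Matches come back in deterministic (record, frame, window) order.
    Zero matches is a valid outcome.
    """
    if orientation_mode not in ("forward", "both"):
        raise ValueError("orientation_mode must be 'forward' or 'both'")
    searches = [("forward", _char_sets(tag))]
    if orientation_mode == "both":
        searches.append(("reversed", _char_sets(reverse_tag(tag))))
    t = len(tag)
    matches: list[RiPPMatch] = []
    seen: set[tuple[str, int, int, int]] = set()
    for g in genomes:
        for ft in six_frame_translate(g):
            pep = ft.peptide
            for start in range(len(pep) - t + 1):
                window = pep[start : start + t]
                for orientation, sets in searches:
                    if all(ch in s for ch, s in zip(window, sets)):
                        start_nt, end_nt = ft.window_interval(start, t)
                        key = (g.record_id, ft.frame, start_nt, end_nt)
                        if key in seen:
                            continue
                        seen.add(key)
                        matches.append(
                            RiPPMatch(
                                record_id=g.record_id,
                                frame=ft.frame,
                                strand=ft.strand,
                                start_nt=start_nt,
                                end_nt=end_nt,
                                matched_peptide=window,
                                tag_orientation=orientation,
                            )
                        )
                        break  # at most one report per locus
    return matches


# ---------------------------------------------------------------------------
# IO

def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read a multi-record FASTA file, plain or gzip-compressed."""
    p = Path(path)
    if p.suffix == ".gz":
        with gzip.open(p, "rt") as fh:
            records = list(SeqIO.parse(fh, "fasta"))
    else:
        records = list(SeqIO.parse(str(p), "fasta"))
    return [GenomeRecord(record_id=r.id, sequence=str(r.seq)) for r in records]


def matches_to_table(matches: Sequence[RiPPMatch]) -> str:
    """Human-readable tab-separated match table (0-based half-open and
    1-based inclusive coordinates, as flagged in the header)."""
    lines = [
        "# coordinates: start0/end0 are 0-based half-open (forward strand); "
        "start1/end1 are 1-based inclusive",
        "record\tstrand\tframe\tstart0\tend0\tstart1\tend1\tpeptide\ttag_orientation",
    ]
    for m in matches:
        lines.append(
            f"{m.record_id}\t{m.strand}\t{m.frame:+d}\t{m.start_nt}\t{m.end_nt}"
            f"\t{m.start_nt + 1}\t{m.end_nt}\t{m.matched_peptide}\t{m.tag_orientation}"
        )
    return "\n".join(lines) + "\n"


def matches_to_bed(matches: Sequence[RiPPMatch]) -> str:
    """BED6: name is peptide|frame, score column is 0."""
    lines = []
    for m in matches:
        lines.append(
            f"{m.record_id}\t{m.start_nt}\t{m.end_nt}"
            f"\t{m.matched_peptide}|frame{m.frame:+d}\t0\t{m.strand}"
        )
    return "\n".join(lines) + ("\n" if lines else "")
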