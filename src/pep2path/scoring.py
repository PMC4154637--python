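"""Bayesian scoring of sequence tags against NRPS gene clusters.

For a tag position with amino acid :math:`A` and an NRPS module
:math:`M`, the posterior that the module made the residue is, by Bayes'
theorem and up to the constant module prior,

.. math:: P(M \\mid A) \\propto \\frac{P(A \\mid M)}{P(A)}.

The baseline :math:`P(A)` comes from monomer frequencies in known
nonribosomal peptides with additive smoothing,

.. math:: P(A) = \\frac{n_A + k}{N + k\\,|\\Sigma|},

except at degenerate tag positions, which use the flat value
:math:`1/|\\Sigma|` so that a rare candidate monomer cannot inflate a
match on the strength of a merely *possible* observation.

:math:`P(A \\mid M)` blends the adenylation-domain specificity evidence
:math:`\\bar I \\in [0,1]` (the mean of the Stachelhaus-code identity
channel and the tiered SVM-class channel, maximized over a position's
candidates) with the baseline,

.. math:: P(A \\mid M) = \\frac{c\\,\\bar I^{\\eta} + x\\,P(A)}{c + x},

where ``c`` weighs prediction against baseline (``c = 0`` makes every
term vanish), ``x`` is a small pseudocount that keeps the logarithm
finite at :math:`\\bar I = 0`, and ``eta`` penalizes mispredictions
exponentially in their number through log-additivity.  The cluster
score is the sum of :math:`\\ln(P(A \\mid M)/P(A))` over tag positions,
maximized over every admissible alignment: each assembly-line
configuration (permutation of the cluster's NRPS genes, module order
within a gene fixed), each contiguous window, and both tag orientations
by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import islice, permutations
from pathlib import Path
from typing import Iterable, Mapping

from .alphabet import DEFAULT_ALPHABET
from .errors import EmptyDatabaseError, UnknownMonomerError
from .model import BGCDatabase, BGCEntry, NRPSModule, TaxonQuery, filter_by_taxonomy
from .tags import SequenceTag, TagPosition

DEFAULT_ORDERING_CAP = 5040  # 7! gene orderings

#: SVM prediction tiers, most specific first.
_SVM_TIERS = (
    ("svm_single", 1.0),
    ("svm_small_class", 0.75),
    ("svm_large_class", 0.5),
    ("svm_three_class", 0.25),
)


@dataclass(frozen=True)
class MonomerFrequencyTable:
    """Background monomer counts (NORINE-style) with additive smoothing."""

    counts: Mapping[str, int]
    alphabet: frozenset[str] = DEFAULT_ALPHABET
    pseudocount: int = 1

    def __post_init__(self) -> None:
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        bad = set(self.counts) - set(self.alphabet)
        if bad:
            raise UnknownMonomerError(
                f"frequency-table monomer(s) outside the alphabet: {sorted(bad)}"
            )
        for a, n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative count for {a!r}")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def probability(self, monomer: str) -> float:
        """Smoothed P(A) = (n_A + k) / (N + k |Sigma|)."""
        if monomer not in self.alphabet:
            raise UnknownMonomerError(f"monomer {monomer!r} not in the alphabet")
        k = self.pseudocount
        return (self.counts.get(monomer, 0) + k) / (self.total + k * len(self.alphabet))


def load_frequency_table(path: str | Path) -> MonomerFrequencyTable:
    """Read a tab-separated ``monomer<TAB>count`` table.  Header comment
    lines may declare ``# alphabet: a/b/c`` and ``# pseudocount: k``;
    without a declaration the alphabet is the set of listed monomers."""
    counts: dict[str, int] = {}
    alphabet: frozenset[str] | None = None
    pseudocount = 1
    for ln, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        s = line.strip()
        if not s:
            continue
        if s.startswith("#"):
            body = s.lstrip("#").strip()
            if body.lower().startswith("alphabet:"):
                alphabet = frozenset(
                    t.strip().lower()
                    for t in body.split(":", 1)[1].split("/")
                    if t.strip()
                )
            elif body.lower().startswith("pseudocount:"):
                pseudocount = int(body.split(":", 1)[1])
            continue
        parts = s.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{ln}: expected monomer<TAB>count")
        counts[parts[0].strip().lower()] = int(parts[1])
    if alphabet is None:
        alphabet = frozenset(counts)
    return MonomerFrequencyTable(
        counts=counts, alphabet=alphabet, pseudocount=pseudocount
    )


def save_frequency_table(f: MonomerFrequencyTable, path: str | Path) -> None:
    lines = [
        "# alphabet: " + "/".join(sorted(f.alphabet)),
        f"# pseudocount: {f.pseudocount}",
    ]
    lines += [f"{a}\t{f.counts.get(a, 0)}" for a in sorted(f.alphabet)]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


@dataclass(frozen=True)
class ScoringParams:
    """Tunable scorer parameters; the defaults are the method's stated
    defaults (c = 1, x = 0.01, eta = 2, both orientations)."""

    c: float = 1.0
    x: float = 0.01
    eta: float = 2.0
    orientation_mode: str = "both"  # "forward" | "both"
    max_orderings: int = DEFAULT_ORDERING_CAP
    tie_break: str = "ci_then_id"

    def __post_init__(self) -> None:
        if self.c < 0:
            raise ValueError("c must be >= 0")
        if not 0 < self.x <= 1:
            raise ValueError("x must be in (0, 1]")
        if self.eta < 1:
            raise ValueError("eta must be >= 1")
        if self.orientation_mode not in ("forward", "both"):
            raise ValueError("orientation_mode must be 'forward' or 'both'")
        if self.max_orderings < 1:
            raise ValueError("max_orderings must be >= 1")


@dataclass(frozen=True)
class Alignment:
    """One placement of a tag along one assembly-line configuration.

    ``pairs`` lists, in tag order, each tag position with the module it
    is matched to; for a reversed-orientation alignment the modules run
    backwards along the concatenated assembly line.
    """

    ordering: tuple[str, ...]          # gene ids, assembly-line order
    offset: int                        # window start along the concatenation
    orientation: str                   # "forward" | "reversed"
    pairs: tuple[tuple[TagPosition, NRPSModule], ...]

    def describe(self) -> str:
        return ",".join(f"{m.gene_id}/{m.index_in_gene}" for _, m in self.pairs)


@dataclass(frozen=True)
class BGCScore:
    cluster_id: str
    S: float
    colinearity: float
    best_alignment: Alignment | None
    capped: bool = False
    rank: int | None = None

    @property
    def admissible(self) -> bool:
        return self.best_alignment is not None


# ---------------------------------------------------------------------------
# per-position terms

def baseline_probability(
    a: str | TagPosition, f: MonomerFrequencyTable
) -> float:
    """P(A) for a monomer or a tag position.

    Singleton positions use the smoothed background frequency; a
    degenerate position uses the flat ``1/|alphabet|`` baseline.
    """
    if isinstance(a, TagPosition):
        for cand in a.candidates:
            if cand not in f.alphabet:
                raise UnknownMonomerError(f"monomer {cand!r} not in the alphabet")
        if a.degenerate:
            return 1.0 / len(f.alphabet)
        a = next(iter(a.candidates))
    return f.probability(a)


def _svm_tier(pred, monomer: str) -> float:
    for fieldname, tier in _SVM_TIERS:
        s = getattr(pred, fieldname)
        if s and monomer in s:
            return tier
    return 0.0


def match_value(p: TagPosition | str, m: NRPSModule) -> float:
    """The prediction support Ī in [0, 1] for a tag position against a
    module: per candidate, the mean of the Stachelhaus-identity channel
    (identity if the candidate is the nearest-code substrate, else 0)
    and the tiered SVM channel; a position takes the best candidate.
    An absent channel leaves Ī to the remaining one alone.
    """
    if isinstance(p, str):
        candidates: Iterable[str] = (p,)
    else:
        candidates = p.candidates
    pred = m.prediction
    best = 0.0
    for a in candidates:
        channels = []
        if pred.has_stachelhaus:
            channels.append(
                pred.stachelhaus_identity if a in pred.stachelhaus_best_match else 0.0
            )
        if pred.has_svm:
            channels.append(_svm_tier(pred, a))
        value = sum(channels) / len(channels) if channels else 0.0
        if value > best:
            best = value
    return best


def position_score(i_bar: float, p_a: float, params: ScoringParams) -> float:
    """ln(P(A|M)/P(A)) for one aligned position."""
    if not 0.0 <= i_bar <= 1.0:
        raise ValueError(f"match value must be in [0, 1], got {i_bar}")
    if not 0.0 < p_a < 1.0:
        raise ValueError(f"baseline probability must be in (0, 1), got {p_a}")
    if params.c == 0.0:
        return 0.0  # prediction evidence switched off: baseline-neutral
    p_am = (params.c * i_bar**params.eta + params.x * p_a) / (params.c + params.x)
    return math.log(p_am / p_a)


# ---------------------------------------------------------------------------
# assembly-line enumeration and alignment search

def enumerate_orderings(
    bgc: BGCEntry, cap: int = DEFAULT_ORDERING_CAP
) -> tuple[list[list[NRPSModule]], bool]:
    """All assembly-line configurations of a cluster: permutations of
    its genes (native module order within each gene), each concatenated
    into one module sequence.  Generation order is deterministic
    (permutations of the native gene order); if the count exceeds
    ``cap`` the list is truncated there and flagged."""
    if cap < 1:
        raise ValueError("cap must be >= 1")
    total = math.factorial(len(bgc.genes))
    perms = islice(permutations(bgc.genes), cap)
    orderings = [[m for g in perm for m in g.modules] for perm in perms]
    return orderings, total > cap


def colinearity_index(al: Alignment) -> float:
    """Fraction of adjacent tag-position pairs whose matched modules are
    consecutive in the natively encoded order (same gene, ascending
    ordinals).  Length-1 alignments return 1.0 by convention."""
    if len(al.pairs) < 2:
        return 1.0
    hits = 0
    for (_, m1), (_, m2) in zip(al.pairs, al.pairs[1:]):
        if m1.gene_id == m2.gene_id and m2.index_in_gene == m1.index_in_gene + 1:
            hits += 1
    return hits / (len(al.pairs) - 1)


def score_tag_against_bgc(
    tag: SequenceTag,
    bgc: BGCEntry,
    f: MonomerFrequencyTable,
    params: ScoringParams = ScoringParams(),
) -> BGCScore:
    """Maximum summed log-likelihood over every admissible alignment of
    the tag with the cluster, with the argmax alignment and its
    colinearity index.

    A tag longer than the cluster's module chain has no admissible
    alignment and yields a sentinel score that always ranks last.
    """
    t = len(tag)
    n_modules = bgc.module_count()
    if t > n_modules:
        return BGCScore(
            cluster_id=bgc.cluster_id,
            S=float("-inf"),
            colinearity=0.0,
            best_alignment=None,
        )

    p_a = [baseline_probability(p, f) for p in tag.positions]
    # terms are per (tag position, module); modules are shared across
    # orderings so cache by module identity
    term: list[dict[int, float]] = [{} for _ in range(t)]

    def term_for(i: int, m: NRPSModule) -> float:
        key = id(m)
        cached = term[i].get(key)
        if cached is None:
            cached = position_score(match_value(tag.positions[i], m), p_a[i], params)
            term[i][key] = cached
        return cached

    orientations = ["forward"]
    if params.orientation_mode == "both":
        orientations.append("reversed")

    orderings, capped = enumerate_orderings(bgc, params.max_orderings)
    best: tuple[float, Alignment] | None = None
    for perm_modules, perm in zip(
        orderings, islice(permutations(bgc.genes), params.max_orderings)
    ):
        gene_order = tuple(g.gene_id for g in perm)
        for orientation in orientations:
            for offset in range(n_modules - t + 1):
                window = perm_modules[offset : offset + t]
                if orientation == "reversed":
                    # tag position i meets the window back-to-front
                    matched = list(reversed(window))
                else:
                    matched = window
                s = 0.0
                for i in range(t):
                    s += term_for(i, matched[i])
                if best is None or s > best[0]:
                    al = Alignment(
                        ordering=gene_order,
                        offset=offset,
                        orientation=orientation,
                        pairs=tuple(zip(tag.positions, matched)),
                    )
                    best = (s, al)
    assert best is not None
    s, al = best
    return BGCScore(
        cluster_id=bgc.cluster_id,
        S=s,
        colinearity=colinearity_index(al),
        best_alignment=al,
        capped=capped,
    )


def rank_bgcs(
    tag: SequenceTag,
    db: BGCDatabase,
    f: MonomerFrequencyTable,
    params: ScoringParams = ScoringParams(),
    taxon: TaxonQuery | None = None,
) -> list[BGCScore]:
    """Score every cluster in the (optionally taxon-filtered) database
    and sort descending by S, ties broken by higher colinearity then
    cluster_id; entries with equal (S, CI) share a rank."""
    if taxon is not None:
        db = filter_by_taxonomy(db, taxon)
    if len(db) == 0:
        raise EmptyDatabaseError(
            "no clusters to score (database empty after taxonomic filtering)"
        )
    scores = [score_tag_against_bgc(tag, e, f, params) for e in db.entries]
    scores.sort(key=lambda sc: (-sc.S, -sc.colinearity, sc.cluster_id))
    ranked: list[BGCScore] = []
    rank = 0
    prev_key: tuple[float, float] | None = None
    for i, sc in enumerate(scores):
        key = (sc.S, sc.colinearity)
        if key != prev_key:
            rank = i + 1
            prev_key = key
        ranked.append(
            BGCScore(
                cluster_id=sc.cluster_id,
                S=sc.S,
                colinearity=sc.colinearity,
                best_alignment=sc.best_alignment,
                capped=sc.capped,
                rank=rank,
            )
        )
    return ranked
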