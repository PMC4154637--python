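"""Independent reference implementations used as test oracles.

These deliberately re-derive everything from first principles with
plain loops and ``itertools.permutations`` — no caching, no shared code
with the package's search — so that agreement is meaningful.
"""

from __future__ import annotations

import math
from itertools import permutations

_TIERS = (
    ("svm_single", 1.0),
    ("svm_small_class", 0.75),
    ("svm_large_class", 0.5),
    ("svm_three_class", 0.25),
)


def ref_candidate_support(pred, monomer: str) -> float:
    channels = []
    if pred.stachelhaus_identity is not None:
        channels.append(
            pred.stachelhaus_identity if monomer in pred.stachelhaus_best_match else 0.0
        )
    svm_sets = [getattr(pred, f) for f, _ in _TIERS]
    if any(s is not None for s in svm_sets):
        tier = 0.0
        for (_, value), s in zip(_TIERS, svm_sets):
            if s and monomer in s:
                tier = value
                break
        channels.append(tier)
    return sum(channels) / len(channels) if channels else 0.0


def ref_baseline(position, freq) -> float:
    if len(position.candidates) > 1:
        return 1.0 / len(freq.alphabet)
    (a,) = position.candidates
    k = freq.pseudocount
    total = sum(freq.counts.values())
    return (freq.counts.get(a, 0) + k) / (total + k * len(freq.alphabet))


def ref_term(position, module, p_a: float, c: float, x: float, eta: float) -> float:
    i_bar = max(ref_candidate_support(module.prediction, a) for a in position.candidates)
    if c == 0:
        return 0.0
    return math.log(((c * i_bar**eta + x * p_a) / (c + x)) / p_a)


def ref_best_score(tag, bgc, freq, c=1.0, x=0.01, eta=2.0, both_orientations=True):
    """Exhaustive maximum over gene permutations, contiguous offsets and
    orientations; -inf when the tag does not fit."""
    t = len(tag.positions)
    p_a = [ref_baseline(p, freq) for p in tag.positions]
    best = float("-inf")
    for perm in permutations(bgc.genes):
        chain = [m for g in perm for m in g.modules]
        if t > len(chain):
            continue
        for offset in range(len(chain) - t + 1):
            window = chain[offset : offset + t]
            readings = [window]
            if both_orientations:
                readings.append(list(reversed(window)))
            for matched in readings:
                s = sum(
                    ref_term(tag.positions[i], matched[i], p_a[i], c, x, eta)
                    for i in range(t)
                )
                best = max(best, s)
    return best


def ref_window_matches(tag, record, translator, orientation_mode="forward"):
    """Naive sliding-window matcher over the six frames: test candidate
    membership at every window, no early exits, no deduplication logic
    beyond a set of loci."""
    from pep2path.alphabet import one_letter

    def sets_for(positions):
        return [
            frozenset(c for c in (one_letter(m) for m in p.candidates) if c)
            for p in positions
        ]

    searches = [sets_for(tag.positions)]
    if orientation_mode == "both":
        searches.append(sets_for(tuple(reversed(tag.positions))))
    t = len(tag.positions)
    loci = set()
    for ft in translator(record):
        for start in range(len(ft.peptide) - t + 1):
            window = ft.peptide[start : start + t]
            for sets in searches:
                if all(ch in s for ch, s in zip(window, sets)):
                    loci.add((record.record_id, ft.frame) + ft.window_interval(start, t))
    return loci
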