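"""Synthetic fixtures with planted ground truth.

Benchmarks of tag-to-cluster matching need databases where the right
answer is known.  The generators here plant one cluster (or genome
locus) that encodes a given tag and surround it with decoys whose
specificity predictions are drawn from the background monomer
frequencies — so decoys are realistically confusable rather than
uniformly random, which would overstate recovery.  Prediction noise is
modelled as in misprediction benchmarks: at a chosen number of planted
positions the prediction is replaced by one supporting none of the
tag's candidates, which forces the prediction support Ī to 0 there.

All randomness flows through one seeded numpy Generator; identical
(inputs, seed) give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.Seq import Seq

from .errors import InfeasibleSimulationError
from .model import BGCDatabase, BGCEntry, Gene, NRPSModule, SpecificityPrediction
from .ripp import GenomeRecord, six_frame_translate
from .scoring import MonomerFrequencyTable, ScoringParams, rank_bgcs
from .tags import SequenceTag, TagPosition, parse_tag

_STACH_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SyntheticTruth:
    """Everything needed to score recovery of a planted answer."""

    seed: int
    tag: SequenceTag | None = None
    planted_cluster_id: str | None = None
    misprediction_count: int = 0
    planted_locus: tuple[str, str, int, int] | None = None  # (record, strand, start, end)
    planted_frame: int | None = None
    planted_peptide: str | None = None


def _weighted_monomer(rng: np.random.Generator, f: MonomerFrequencyTable) -> str:
    names = sorted(f.alphabet)
    k = f.pseudocount
    w = np.array([f.counts.get(a, 0) + k for a in names], dtype=float)
    return names[int(rng.choice(len(names), p=w / w.sum()))]


def _random_code(rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(_STACH_RESIDUES), size=10))


def _nested_sets(
    rng: np.random.Generator, core: str, alphabet: frozenset[str]
) -> tuple[frozenset[str], ...]:
    """Nested SVM-style class predictions single ⊆ small ⊆ large ⊆ three
    around a core monomer."""
    others = sorted(alphabet - {core})
    rng.shuffle(others)
    single = {core}
    small = single | set(others[:2])
    large = small | set(others[2:6])
    three = large | set(others[6:12])
    return frozenset(single), frozenset(small), frozenset(large), frozenset(three)


def _supporting_prediction(
    rng: np.random.Generator, monomer: str, alphabet: frozenset[str],
    identity: float = 1.0,
) -> SpecificityPrediction:
    single, small, large, three = _nested_sets(rng, monomer, alphabet)
    return SpecificityPrediction(
        stachelhaus_code=_random_code(rng),
        stachelhaus_best_match=frozenset({monomer}),
        stachelhaus_identity=identity,
        svm_single=single,
        svm_small_class=small,
        svm_large_class=large,
        svm_three_class=three,
    )


def _zero_support_prediction(
    rng: np.random.Generator, avoid: frozenset[str], alphabet: frozenset[str]
) -> SpecificityPrediction:
    """A prediction giving Ī = 0 for every monomer in ``avoid``: empty
    SVM calls (explicit no-call) and a nearest-code substrate outside
    the avoided set."""
    pool = sorted(alphabet - avoid)
    if not pool:
        raise InfeasibleSimulationError(
            "cannot build a zero-support prediction: the avoided set covers the alphabet"
        )
    wrong = pool[int(rng.integers(len(pool)))]
    return SpecificityPrediction(
        stachelhaus_code=_random_code(rng),
        stachelhaus_best_match=frozenset({wrong}),
        stachelhaus_identity=float(rng.uniform(0.6, 1.0)),
        svm_single=frozenset(),
        svm_small_class=frozenset(),
        svm_large_class=frozenset(),
        svm_three_class=frozenset(),
    )


def _split_into_genes(
    rng: np.random.Generator, cluster_id: str, preds: Sequence[SpecificityPrediction]
) -> tuple[Gene, ...]:
    """Partition a module chain into 1-3 genes at random boundaries."""
    n = len(preds)
    max_genes = min(3, n)
    n_genes = int(rng.integers(1, max_genes + 1))
    cuts = sorted(rng.choice(np.arange(1, n), size=n_genes - 1, replace=False)) if n_genes > 1 else []
    bounds = [0, *map(int, cuts), n]
    genes = []
    for gi in range(len(bounds) - 1):
        gid = f"{cluster_id}_g{gi + 1}"
        genes.append(
            Gene(
                gene_id=gid,
                modules=tuple(
                    NRPSModule(gene_id=gid, index_in_gene=j, prediction=pred)
                    for j, pred in enumerate(preds[bounds[gi] : bounds[gi + 1]])
                ),
            )
        )
    return tuple(genes)


_GENERA = ("streptomyces", "bacillus", "pseudomonas", "lysobacter", "collimonas")


def _lineage(genus: str, idx: int) -> tuple[str, ...]:
    return ("bacteria", "synthphylum", "synthclass", "synthorder",
            "synthfamily", genus, f"{genus} synthetica", f"strain{idx}")


def generate_nrp_database(
    n_bgcs: int,
    tag: SequenceTag | str,
    mispredictions: int,
    seed: int,
    f: MonomerFrequencyTable | None = None,
) -> tuple[BGCDatabase, SyntheticTruth]:
    """A database with one planted cluster encoding ``tag`` and
    ``n_bgcs - 1`` frequency-sampled decoys.

    The planted cluster's modules predict a concrete reading of the tag
    exactly (Stachelhaus identity 1.0 and a single-residue SVM call),
    except at ``mispredictions`` randomly chosen positions whose
    predictions support none of the tag's candidates there (Ī = 0).
    """
    from .data import default_frequency_table  # deferred: data loads a file

    if f is None:
        f = default_frequency_table()
    if isinstance(tag, str):
        tag = parse_tag(tag, alphabet=f.alphabet)
    if n_bgcs < 1:
        raise InfeasibleSimulationError("n_bgcs must be >= 1")
    if not 0 <= mispredictions <= len(tag):
        raise InfeasibleSimulationError(
            f"mispredictions must lie in [0, {len(tag)}], got {mispredictions}"
        )
    rng = np.random.default_rng(seed)
    alphabet = f.alphabet

    # planted cluster
    truth_reading = [
        sorted(p.candidates)[int(rng.integers(len(p.candidates)))]
        for p in tag.positions
    ]
    wrong_at = set(
        int(i) for i in rng.choice(len(tag), size=mispredictions, replace=False)
    )
    planted_preds = [
        _zero_support_prediction(rng, tag.positions[i].candidates, alphabet)
        if i in wrong_at
        else _supporting_prediction(rng, truth_reading[i], alphabet)
        for i in range(len(tag))
    ]
    planted_id = "planted"
    entries = [
        BGCEntry(
            cluster_id=planted_id,
            source_accession="SYN000001",
            lineage=_lineage("streptomyces", 0),
            genes=_split_into_genes(rng, planted_id, planted_preds),
        )
    ]

    # decoys: module counts in a realistic cluster-size range, always
    # long enough to admit the tag
    lo, hi = max(2, len(tag)), max(len(tag) + 4, 8)
    for i in range(1, n_bgcs):
        cid = f"decoy{i:05d}"
        n_mod = int(rng.integers(lo, hi + 1))
        preds = [
            _supporting_prediction(
                rng, _weighted_monomer(rng, f), alphabet,
                identity=float(rng.uniform(0.5, 1.0)),
            )
            for _ in range(n_mod)
        ]
        genus = _GENERA[int(rng.integers(len(_GENERA)))]
        entries.append(
            BGCEntry(
                cluster_id=cid,
                source_accession=f"SYN{i + 1:06d}",
                lineage=_lineage(genus, i),
                genes=_split_into_genes(rng, cid, preds),
            )
        )
    db = BGCDatabase(
        entries=tuple(entries),
        alphabet=alphabet,
        provenance=f"synthetic (seed={seed}, mispredictions={mispredictions})",
    )
    truth = SyntheticTruth(
        seed=seed,
        tag=tag,
        planted_cluster_id=planted_id,
        misprediction_count=mispredictions,
    )
    return db, truth


# ---------------------------------------------------------------------------
# RiPP genome fixture

_CODONS: dict[str, list[str]] = {}


def _codon_table() -> dict[str, list[str]]:
    if not _CODONS:
        from Bio.Data.CodonTable import unambiguous_dna_by_id

        fwd = unambiguous_dna_by_id[11].forward_table
        for codon, aa in sorted(fwd.items()):
            _CODONS.setdefault(aa, []).append(codon)
    return _CODONS


def _exact_peptide_loci(g: GenomeRecord, peptide: str) -> list[tuple[int, int, int]]:
    """(frame, start_nt, end_nt) of every exact occurrence of ``peptide``
    across the six frames."""
    out = []
    for ft in six_frame_translate(g):
        start = ft.peptide.find(peptide)
        while start != -1:
            a, b = ft.window_interval(start, len(peptide))
            out.append((ft.frame, a, b))
            start = ft.peptide.find(peptide, start + 1)
    return out


def generate_ripp_genome(
    length_nt: int,
    peptide: str,
    strand: str,
    seed: int,
    record_id: str = "synthetic_contig",
    max_attempts: int = 200,
) -> tuple[GenomeRecord, SyntheticTruth]:
    """Random background DNA with ``peptide``'s codons planted once.

    The peptide (one-letter, proteinogenic, no stops) is reverse-
    translated with random synonymous codons and inserted at a random
    position; backgrounds containing any additional exact occurrence of
    the peptide in any frame are rejected and redrawn.
    """
    peptide = peptide.upper()
    if strand not in ("+", "-"):
        raise InfeasibleSimulationError("strand must be '+' or '-'")
    if not peptide or any(aa not in _codon_table() for aa in peptide):
        raise InfeasibleSimulationError(
            f"peptide must be non-empty proteinogenic one-letter residues, got {peptide!r}"
        )
    if 3 * len(peptide) > length_nt:
        raise InfeasibleSimulationError(
            f"peptide needs {3 * len(peptide)} nt but genome length is {length_nt}"
        )
    rng = np.random.default_rng(seed)
    table = _codon_table()
    for _ in range(max_attempts):
        insert = "".join(
            table[aa][int(rng.integers(len(table[aa])))] for aa in peptide
        )
        if strand == "-":
            insert = str(Seq(insert).reverse_complement())
        pos = int(rng.integers(0, length_nt - len(insert) + 1))
        background = rng.choice(list("ACGT"), size=length_nt)
        seq = "".join(background[:pos]) + insert + "".join(background[pos + len(insert):])
        g = GenomeRecord(record_id=record_id, sequence=seq)
        start, end = pos, pos + len(insert)
        loci = _exact_peptide_loci(g, peptide)
        planted = [(fr, a, b) for fr, a, b in loci if (a, b) == (start, end)]
        if len(loci) == 1 and planted:
            truth = SyntheticTruth(
                seed=seed,
                planted_locus=(record_id, strand, start, end),
                planted_frame=planted[0][0],
                planted_peptide=peptide,
            )
            return g, truth
    raise InfeasibleSimulationError(
        f"could not plant a unique locus for {peptide!r} in {length_nt} nt "
        f"after {max_attempts} attempts"
    )


def genome_to_fasta(g: GenomeRecord, path: str | Path, width: int = 70) -> None:
    lines = [f">{g.record_id}"]
    lines += [g.sequence[i : i + width] for i in range(0, len(g.sequence), width)]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# recovery benchmark

def _random_tag(
    rng: np.random.Generator, length: int, f: MonomerFrequencyTable
) -> SequenceTag:
    return SequenceTag(
        positions=tuple(
            TagPosition(candidates=frozenset({_weighted_monomer(rng, f)}))
            for _ in range(length)
        )
    )


def recovery_curve(
    tag_lengths: Sequence[int],
    db_sizes: Sequence[int],
    replicates: int,
    seed: int,
    mispredictions: int = 0,
    f: MonomerFrequencyTable | None = None,
    params: ScoringParams = ScoringParams(),
) -> dict[tuple[int, int], float]:
    """Fraction of replicates in which the planted cluster is the
    (shared) best hit, for every (tag length, database size) pair.

    Each replicate draws a fresh random singleton tag from the
    background frequencies and a fresh database; shared best hits count
    as successes, mirroring the presence of orthologous clusters in
    real searches.
    """
    from .data import default_frequency_table

    if f is None:
        f = default_frequency_table()
    if replicates < 1:
        raise InfeasibleSimulationError("replicates must be >= 1")
    out: dict[tuple[int, int], float] = {}
    for t in tag_lengths:
        for n in db_sizes:
            hits = 0
            for r in range(replicates):
                child = np.random.SeedSequence(
                    entropy=seed, spawn_key=(t, n, r)
                )
                rng = np.random.default_rng(child)
                tag = _random_tag(rng, t, f)
                db_seed = int(child.generate_state(1)[0] % (2**31))
                db, truth = generate_nrp_database(
                    n, tag, mispredictions, db_seed, f=f
                )
                ranked = rank_bgcs(tag, db, f, params)
                planted = next(
                    sc for sc in ranked if sc.cluster_id == truth.planted_cluster_id
                )
                if planted.rank == 1:
                    hits += 1
            out[(t, n)] = hits / replicates
    return out
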