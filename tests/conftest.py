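from __future__ import annotations

import numpy as np
import pytest

from pep2path.data import default_frequency_table
from pep2path.model import (
    BGCDatabase,
    BGCEntry,
    Gene,
    NRPSModule,
    SpecificityPrediction,
)
from pep2path.scoring import MonomerFrequencyTable
from pep2path.tags import SequenceTag, TagPosition

PROTEINOGENIC_20 = frozenset(
    "ala arg asn asp cys gln glu gly his ile leu lys met phe pro ser thr trp tyr val".split()
)


def make_prediction(
    target: str | set[str],
    identity: float = 1.0,
    tier: str = "svm_single",
    alphabet: frozenset[str] = PROTEINOGENIC_20,
) -> SpecificityPrediction:
    """A prediction whose SVM call at ``tier`` and Stachelhaus nearest
    code both point at ``target``."""
    targets = frozenset({target} if isinstance(target, str) else target)
    sets = {
        "svm_single": frozenset(),
        "svm_small_class": frozenset(),
        "svm_large_class": frozenset(),
        "svm_three_class": frozenset(),
    }
    order = list(sets)
    for name in order[order.index(tier):]:
        sets[name] = targets
    return SpecificityPrediction(
        stachelhaus_code="DAWTIAAICK",
        stachelhaus_best_match=targets,
        stachelhaus_identity=identity,
        **sets,
    )


def make_entry(
    cluster_id: str,
    gene_monomers: list[list[str]],
    lineage: tuple[str, ...] = ("bacteria", "actinomycetota", "actinomycetes",
                               "kitasatosporales", "streptomycetaceae",
                               "streptomyces", "streptomyces testus", "strain0"),
    accession: str = "TEST000001",
) -> BGCEntry:
    """An entry whose module predictions perfectly support the given
    monomers, one inner list per gene."""
    genes = []
    for gi, monomers in enumerate(gene_monomers):
        gid = f"{cluster_id}_g{gi + 1}"
        genes.append(
            Gene(
                gene_id=gid,
                modules=tuple(
                    NRPSModule(
                        gene_id=gid, index_in_gene=j,
                        prediction=make_prediction(m),
                    )
                    for j, m in enumerate(monomers)
                ),
            )
        )
    return BGCEntry(
        cluster_id=cluster_id, source_accession=accession,
        lineage=lineage, genes=tuple(genes),
    )


def singleton_tag(monomers: list[str], kind: str = "nrp") -> SequenceTag:
    return SequenceTag(
        positions=tuple(TagPosition(candidates=frozenset({m})) for m in monomers),
        kind=kind,
    )


def random_small_bgc(rng: np.random.Generator, cluster_id: str,
                     alphabet=PROTEINOGENIC_20) -> BGCEntry:
    """A random cluster with <=3 genes and <=8 modules, random channel
    availability and identities — the adversarial shape for the
    exhaustive-search oracle."""
    names = sorted(alphabet)
    n_modules = int(rng.integers(2, 9))
    n_genes = int(rng.integers(1, min(3, n_modules) + 1))
    cuts = sorted(rng.choice(np.arange(1, n_modules), size=n_genes - 1, replace=False))
    bounds = [0, *map(int, cuts), n_modules]
    genes = []
    for gi in range(n_genes):
        gid = f"{cluster_id}_g{gi}"
        mods = []
        for j in range(bounds[gi + 1] - bounds[gi]):
            core = names[int(rng.integers(len(names)))]
            has_stach = bool(rng.integers(2))
            has_svm = bool(rng.integers(2)) or not has_stach
            extras = [names[int(rng.integers(len(names)))] for _ in range(3)]
            single = frozenset({core})
            small = single | {extras[0]}
            large = small | {extras[1]}
            three = large | {extras[2]}
            mods.append(
                NRPSModule(
                    gene_id=gid, index_in_gene=j,
                    prediction=SpecificityPrediction(
                        stachelhaus_code=None,
                        stachelhaus_best_match=(
                            frozenset({names[int(rng.integers(len(names)))]})
                            if has_stach else frozenset()
                        ),
                        stachelhaus_identity=(
                            float(rng.uniform(0, 1)) if has_stach else None
                        ),
                        svm_single=single if has_svm else None,
                        svm_small_class=small if has_svm else None,
                        svm_large_class=large if has_svm else None,
                        svm_three_class=three if has_svm else None,
                    ),
                )
            )
        genes.append(Gene(gene_id=gid, modules=tuple(mods)))
    return BGCEntry(
        cluster_id=cluster_id, source_accession="RND000001",
        lineage=("bacteria", "testphylum"), genes=tuple(genes),
    )


def random_tag(rng: np.random.Generator, length: int,
               alphabet=PROTEINOGENIC_20, p_degenerate: float = 0.3) -> SequenceTag:
    names = sorted(alphabet)
    positions = []
    for _ in range(length):
        cands = {names[int(rng.integers(len(names)))]}
        if rng.random() < p_degenerate:
            cands.add(names[int(rng.integers(len(names)))])
        positions.append(TagPosition(candidates=frozenset(cands)))
    return SequenceTag(positions=tuple(positions))


@pytest.fixture(scope="session")
def freq() -> MonomerFrequencyTable:
    return default_frequency_table()


@pytest.fixture()
def small_freq() -> MonomerFrequencyTable:
    """Four-monomer table: P(ala) = (3+1)/(4+4) = 0.5, P(ser) = 1/8."""
    return MonomerFrequencyTable(
        counts={"ala": 3, "gly": 1, "ser": 0, "val": 0},
        alphabet=frozenset({"ala", "gly", "ser", "val"}),
        pseudocount=1,
    )


@pytest.fixture()
def uniform20_freq() -> MonomerFrequencyTable:
    """All-zero counts over the 20 proteinogenic monomers: every
    baseline, singleton or degenerate, is exactly 1/20."""
    return MonomerFrequencyTable(
        counts={}, alphabet=PROTEINOGENIC_20, pseudocount=1
    )


@pytest.fixture()
def two_entry_db() -> BGCDatabase:
    strep = make_entry("strepA", [["val", "val", "thr"], ["ala", "leu"]])
    pseudo = make_entry(
        "pseuB", [["ser", "gly", "orn"]],
        lineage=("bacteria", "pseudomonadota", "gammaproteobacteria",
                 "pseudomonadales", "pseudomonadaceae", "pseudomonas",
                 "pseudomonas testa", "strain1"),
        accession="TEST000002",
    )
    return BGCDatabase(entries=(strep, pseudo))
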