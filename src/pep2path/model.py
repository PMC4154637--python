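"""Gene-cluster domain model and database IO.

A :class:`BGCDatabase` holds biosynthetic gene clusters (BGCs) whose
NRPS modules carry adenylation-domain substrate-specificity predictions
of the NRPSPredictor2 kind: a 10-residue Stachelhaus-code identity to
the nearest known module, and four nested support-vector-machine class
predictions (single residue / small class / large class / three-class).

The on-disk format is a single self-describing JSON document with an
embedded schema version (documented in ``docs/db_schema.md``), produced
either programmatically, by :func:`read_prediction_table` from a
tab-separated per-module prediction table, or by the ``pep2path makedb``
command.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from .alphabet import DEFAULT_ALPHABET
from .errors import MergeConflictError, SchemaError

SCHEMA_VERSION = 1
DB_FORMAT_NAME = "pep2path-bgc-db"

#: Canonical rank order used to interpret rank keywords against an
#: ordered lineage list (GenBank-style lineages vary in depth, so ranks
#: index positions rather than keys).
RANK_ORDER: tuple[str, ...] = (
    "domain", "phylum", "class", "order", "family", "genus", "species", "strain",
)

_SVM_FIELDS = ("svm_single", "svm_small_class", "svm_large_class", "svm_three_class")


@dataclass(frozen=True)
class SpecificityPrediction:
    """Substrate-specificity prediction for one adenylation domain.

    ``None`` for an SVM field means that channel was not predicted at
    all; an empty set is an explicit no-call ("nrp") which scores tier
    0.  The Stachelhaus channel is present iff ``stachelhaus_identity``
    is not None.
    """

    stachelhaus_code: str | None = None
    stachelhaus_best_match: frozenset[str] = frozenset()
    stachelhaus_identity: float | None = None
    svm_single: frozenset[str] | None = None
    svm_small_class: frozenset[str] | None = None
    svm_large_class: frozenset[str] | None = None
    svm_three_class: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.stachelhaus_identity is not None and not (
            0.0 <= self.stachelhaus_identity <= 1.0
        ):
            raise SchemaError(
                f"stachelhaus_identity must lie in [0, 1], got {self.stachelhaus_identity}"
            )
        if not self.has_stachelhaus and not self.has_svm:
            raise SchemaError("prediction has neither a Stachelhaus nor an SVM channel")
        # SVM class predictions are nested by construction of the
        # classifier; enforce subset ordering between non-empty tiers.
        tiers = [getattr(self, f) for f in _SVM_FIELDS]
        present = [t for t in tiers if t]
        for lower, upper in zip(present, present[1:]):
            if not lower <= upper:
                raise SchemaError(
                    "SVM class predictions must be nested "
                    f"(got {sorted(lower)} not within {sorted(upper)})"
                )

    @property
    def has_stachelhaus(self) -> bool:
        return self.stachelhaus_identity is not None

    @property
    def has_svm(self) -> bool:
        return any(getattr(self, f) is not None for f in _SVM_FIELDS)

    def monomers(self) -> frozenset[str]:
        """Every monomer named anywhere in the prediction."""
        out = set(self.stachelhaus_best_match)
        for f in _SVM_FIELDS:
            out |= getattr(self, f) or frozenset()
        return frozenset(out)


@dataclass(frozen=True)
class NRPSModule:
    gene_id: str
    index_in_gene: int
    prediction: SpecificityPrediction


@dataclass(frozen=True)
class Gene:
    gene_id: str
    modules: tuple[NRPSModule, ...]

    def __post_init__(self) -> None:
        for i, m in enumerate(self.modules):
            if m.gene_id != self.gene_id:
                raise SchemaError(
                    f"module gene_id {m.gene_id!r} disagrees with gene {self.gene_id!r}"
                )
            if m.index_in_gene != i:
                raise SchemaError(
                    f"gene {self.gene_id!r}: module ordinals must be consecutive "
                    f"from 0 (found {m.index_in_gene} at position {i})"
                )


@dataclass(frozen=True)
class BGCEntry:
    """One biosynthetic gene cluster: ordered genes, each an ordered run
    of NRPS modules, plus provenance (accession) and taxonomy."""

    cluster_id: str
    source_accession: str
    lineage: tuple[str, ...]
    genes: tuple[Gene, ...]

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise SchemaError(
                f"entry {self.cluster_id!r}: duplicate gene_id(s) {dup}"
            )
        if self.module_count() < 1:
            raise SchemaError(f"entry {self.cluster_id!r}: no NRPS modules")

    def module_count(self) -> int:
        return sum(len(g.modules) for g in self.genes)

    def all_modules(self) -> list[NRPSModule]:
        return [m for g in self.genes for m in g.modules]


@dataclass(frozen=True)
class BGCDatabase:
    entries: tuple[BGCEntry, ...]
    alphabet: frozenset[str] = DEFAULT_ALPHABET
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [e.cluster_id for e in self.entries]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise SchemaError(f"duplicate cluster_id(s) {dup}")
        for e in self.entries:
            for m in e.all_modules():
                bad = m.prediction.monomers() - self.alphabet
                if bad:
                    raise SchemaError(
                        f"entry {e.cluster_id!r}, gene {m.gene_id!r}, module "
                        f"{m.index_in_gene}: monomer(s) {sorted(bad)} outside the alphabet"
                    )

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, cluster_id: str) -> BGCEntry:
        for e in self.entries:
            if e.cluster_id == cluster_id:
                return e
        raise KeyError(cluster_id)


@dataclass(frozen=True)
class TaxonQuery:
    """A taxonomic restriction: ``rank`` is one of the canonical rank
    keywords (or None / an unknown keyword to match at any lineage
    position) and ``value`` the taxon name, matched case-insensitively."""

    value: str
    rank: str | None = None

    def __post_init__(self) -> None:
        if not self.value:
            raise SchemaError("TaxonQuery value must be non-empty")

    def matches(self, lineage: Sequence[str]) -> bool:
        names = [x.lower() for x in lineage]
        want = self.value.lower()
        if self.rank is not None and self.rank.lower() in RANK_ORDER:
            i = RANK_ORDER.index(self.rank.lower())
            return i < len(names) and names[i] == want
        return want in names


# ---------------------------------------------------------------------------
# serialization

def _set_or_none(v: frozenset[str] | None) -> list[str] | None:
    return None if v is None else sorted(v)


def _prediction_to_json(p: SpecificityPrediction) -> dict:
    return {
        "stachelhaus_code": p.stachelhaus_code,
        "stachelhaus_best_match": sorted(p.stachelhaus_best_match),
        "stachelhaus_identity": p.stachelhaus_identity,
        "svm_single": _set_or_none(p.svm_single),
        "svm_small_class": _set_or_none(p.svm_small_class),
        "svm_large_class": _set_or_none(p.svm_large_class),
        "svm_three_class": _set_or_none(p.svm_three_class),
    }


def database_to_json(db: BGCDatabase) -> dict:
    return {
        "format": DB_FORMAT_NAME,
        "schema_version": SCHEMA_VERSION,
        "alphabet": sorted(db.alphabet),
        "provenance": db.provenance,
        "entries": [
            {
                "cluster_id": e.cluster_id,
                "source_accession": e.source_accession,
                "lineage": list(e.lineage),
                "genes": [
                    {
                        "gene_id": g.gene_id,
                        "modules": [
                            {"index": m.index_in_gene,
                             **_prediction_to_json(m.prediction)}
                            for m in g.modules
                        ],
                    }
                    for g in e.genes
                ],
            }
            for e in db.entries
        ],
    }


def save_database(db: BGCDatabase, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(database_to_json(db), indent=1, sort_keys=False) + "\n",
        encoding="utf-8",
    )


def _require(obj: dict, key: str, where: str):
    if key not in obj:
        raise SchemaError(f"{where}: missing field {key!r}")
    return obj[key]


def _parse_identity(raw, where: str) -> float | None:
    """Stachelhaus identity is stored as a fraction; percent input
    (values in (1, 100]) is normalized on load."""
    if raw is None:
        return None
    try:
        v = float(raw)
    except (TypeError, ValueError):
        raise SchemaError(f"{where}: stachelhaus_identity {raw!r} is not a number")
    if 1.0 < v <= 100.0:
        v /= 100.0
    if not 0.0 <= v <= 1.0:
        raise SchemaError(f"{where}: stachelhaus_identity {raw!r} outside [0, 100]")
    return v


def _parse_set(raw, where: str, fieldname: str) -> frozenset[str] | None:
    if raw is None:
        return None
    if not isinstance(raw, list):
        raise SchemaError(f"{where}: field {fieldname!r} must be a list or null")
    return frozenset(str(x).lower() for x in raw)


def _prediction_from_json(obj: dict, where: str) -> SpecificityPrediction:
    try:
        return SpecificityPrediction(
            stachelhaus_code=obj.get("stachelhaus_code"),
            stachelhaus_best_match=_parse_set(
                obj.get("stachelhaus_best_match", []), where, "stachelhaus_best_match"
            ) or frozenset(),
            stachelhaus_identity=_parse_identity(obj.get("stachelhaus_identity"), where),
            svm_single=_parse_set(obj.get("svm_single"), where, "svm_single"),
            svm_small_class=_parse_set(obj.get("svm_small_class"), where, "svm_small_class"),
            svm_large_class=_parse_set(obj.get("svm_large_class"), where, "svm_large_class"),
            svm_three_class=_parse_set(obj.get("svm_three_class"), where, "svm_three_class"),
        )
    except SchemaError as err:
        raise SchemaError(f"{where}: {err}") from None


def database_from_json(doc: dict) -> BGCDatabase:
    if not isinstance(doc, dict):
        raise SchemaError("database document must be a JSON object")
    fmt = doc.get("format", DB_FORMAT_NAME)
    if fmt != DB_FORMAT_NAME:
        raise SchemaError(f"unrecognized database format {fmt!r}")
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise SchemaError(f"unsupported schema_version {version!r}")
    alphabet = frozenset(str(x).lower() for x in _require(doc, "alphabet", "document"))
    entries = []
    for eobj in _require(doc, "entries", "document"):
        cid = str(_require(eobj, "cluster_id", "entry"))
        where = f"entry {cid!r}"
        genes = []
        for gobj in _require(eobj, "genes", where):
            gid = str(_require(gobj, "gene_id", where))
            gwhere = f"{where}, gene {gid!r}"
            modules = []
            for mobj in _require(gobj, "modules", gwhere):
                idx = int(_require(mobj, "index", gwhere))
                modules.append(
                    NRPSModule(
                        gene_id=gid,
                        index_in_gene=idx,
                        prediction=_prediction_from_json(
                            mobj, f"{gwhere}, module {idx}"
                        ),
                    )
                )
            genes.append(Gene(gene_id=gid, modules=tuple(modules)))
        entries.append(
            BGCEntry(
                cluster_id=cid,
                source_accession=str(eobj.get("source_accession", "")),
                lineage=tuple(str(x) for x in eobj.get("lineage", [])),
                genes=tuple(genes),
            )
        )
    return BGCDatabase(
        entries=tuple(entries),
        alphabet=alphabet,
        provenance=str(doc.get("provenance", "")),
    )


def load_database(path: str | Path) -> BGCDatabase:
    """Load and validate a database document; any violation raises
    :class:`SchemaError` naming the failing entry/field."""
    p = Path(path)
    try:
        doc = json.loads(p.read_text(encoding="utf-8"))
    except json.JSONDecodeError as err:
        raise SchemaError(f"{p}: not valid JSON ({err})") from None
    return database_from_json(doc)


# ---------------------------------------------------------------------------
# merge and taxonomy filtering

def merge_databases(a: BGCDatabase, b: BGCDatabase) -> BGCDatabase:
    """Union of two databases.

    Alphabets must be identical or one a superset of the other; the
    result uses the union.  Entries sharing a cluster_id must be
    identical (deduplicated), otherwise a :class:`MergeConflictError`
    is raised naming the conflicting id.
    """
    if not (a.alphabet <= b.alphabet or b.alphabet <= a.alphabet):
        raise MergeConflictError(
            "incompatible alphabets: neither database's alphabet contains the other's"
        )
    by_id = {e.cluster_id: e for e in a.entries}
    merged = list(a.entries)
    for e in b.entries:
        prev = by_id.get(e.cluster_id)
        if prev is None:
            merged.append(e)
            by_id[e.cluster_id] = e
        elif prev != e:
            raise MergeConflictError(
                f"cluster_id {e.cluster_id!r} present in both databases with different content"
            )
    prov = "; ".join(x for x in (a.provenance, b.provenance) if x)
    return BGCDatabase(
        entries=tuple(merged), alphabet=a.alphabet | b.alphabet, provenance=prov
    )


def filter_by_taxonomy(db: BGCDatabase, q: TaxonQuery) -> BGCDatabase:
    """Entries whose lineage matches the query, original order preserved."""
    kept = tuple(e for e in db.entries if q.matches(e.lineage))
    return replace(db, entries=kept)


# ---------------------------------------------------------------------------
# prediction-table importer (the `makedb` input format)

_TABLE_COLUMNS = (
    "cluster_id", "accession", "lineage", "gene_id", "module_index",
    "stachelhaus_code", "stachelhaus_identity",
    "svm_single", "svm_small", "svm_large", "svm_three",
)
# optional trailing column: the monomer(s) of the nearest known
# Stachelhaus code; when omitted it defaults to the single-residue SVM
# call, which is the nearest-neighbour substrate in the common case
_OPTIONAL_COLUMN = "stachelhaus_best_match"

_NO_CALL = {"", "nrp", "n/a", "none"}


def _cell_set(cell: str) -> frozenset[str]:
    cell = cell.strip()
    if cell.lower() in _NO_CALL:
        return frozenset()
    return frozenset(t.strip().lower() for t in cell.split("/") if t.strip())


def read_prediction_table(
    path: str | Path,
    alphabet: Iterable[str] = DEFAULT_ALPHABET,
    provenance: str = "",
) -> BGCDatabase:
    """Build a database from a tab-separated per-module prediction table.

    One row per module with columns ``cluster_id, accession, lineage
    (semicolon-separated), gene_id, module_index, stachelhaus_code,
    stachelhaus_identity, svm_single, svm_small, svm_large, svm_three``;
    set-valued cells are "/"-separated, "nrp" or an empty cell is a
    no-call, "-" means the Stachelhaus channel is absent.  A header row
    naming the columns is accepted and skipped.
    """
    p = Path(path)
    rows: list[dict[str, str]] = []
    for ln, line in enumerate(p.read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cells = line.rstrip("\n").split("\t")
        if cells[0].strip().lower() == "cluster_id":
            continue
        if len(cells) not in (len(_TABLE_COLUMNS), len(_TABLE_COLUMNS) + 1):
            raise SchemaError(
                f"{p}:{ln}: expected {len(_TABLE_COLUMNS)} (or "
                f"{len(_TABLE_COLUMNS) + 1}) tab-separated columns, got {len(cells)}"
            )
        rows.append(dict(zip(_TABLE_COLUMNS + (_OPTIONAL_COLUMN,), cells)))

    clusters: dict[str, dict] = {}
    for row in rows:
        cid = row["cluster_id"].strip()
        c = clusters.setdefault(
            cid,
            {"accession": row["accession"].strip(),
             "lineage": tuple(t.strip() for t in row["lineage"].split(";") if t.strip()),
             "genes": {}, "gene_order": []},
        )
        gid = row["gene_id"].strip()
        if gid not in c["genes"]:
            c["genes"][gid] = []
            c["gene_order"].append(gid)
        code = row["stachelhaus_code"].strip()
        code = None if code in ("", "-") else code
        ident_cell = row["stachelhaus_identity"].strip()
        identity = None if ident_cell in ("", "-") else _parse_identity(
            ident_cell, f"cluster {cid!r} gene {gid!r}"
        )
        try:
            idx = int(row["module_index"])
        except ValueError:
            raise SchemaError(
                f"cluster {cid!r} gene {gid!r}: module_index "
                f"{row['module_index']!r} is not an integer"
            ) from None
        if _OPTIONAL_COLUMN in row:
            best_match = _cell_set(row[_OPTIONAL_COLUMN])
        else:
            best_match = _cell_set(row["svm_single"]) if identity is not None else frozenset()
        pred = SpecificityPrediction(
            stachelhaus_code=code,
            stachelhaus_best_match=best_match,
            stachelhaus_identity=identity,
            svm_single=_cell_set(row["svm_single"]),
            svm_small_class=_cell_set(row["svm_small"]),
            svm_large_class=_cell_set(row["svm_large"]),
            svm_three_class=_cell_set(row["svm_three"]),
        )
        c["genes"][gid].append((idx, pred))

    entries = []
    for cid, c in clusters.items():
        genes = []
        for gid in c["gene_order"]:
            mods = sorted(c["genes"][gid], key=lambda t: t[0])
            genes.append(
                Gene(
                    gene_id=gid,
                    modules=tuple(
                        NRPSModule(gene_id=gid, index_in_gene=i, prediction=pred)
                        for i, (_, pred) in enumerate(mods)
                    ),
                )
            )
        entries.append(
            BGCEntry(
                cluster_id=cid,
                source_accession=c["accession"],
                lineage=c["lineage"],
                genes=tuple(genes),
            )
        )
    return BGCDatabase(
        entries=tuple(entries), alphabet=frozenset(alphabet), provenance=provenance
    )
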