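# Cluster database format

A database is a single self-describing UTF-8 JSON document:

```json
{
 "format": "pep2path-bgc-db",
 "schema_version": 1,
 "alphabet": ["ala", "arg", "..."],
 "provenance": "free text",
 "entries": [
  {
   "cluster_id": "unique-id",
   "source_accession": "nucleotide record the cluster came from",
   "lineage": ["bacteria", "...", "genus", "species", "strain"],
   "genes": [
    {
     "gene_id": "unique within the entry",
     "modules": [
      {
       "index": 0,
       "stachelhaus_code": "DAWTIAAICK",
       "stachelhaus_best_match": ["val"],
       "stachelhaus_identity": 0.9,
       "svm_single": ["val"],
       "svm_small_class": ["val", "ile"],
       "svm_large_class": ["val", "ile", "leu"],
       "svm_three_class": ["val", "ile", "leu", "ala"]
      }
     ]
    }
   ]
  }
 ]
}
```

Field semantics and invariants (violations raise a schema error naming
the failing entry/field):

* `alphabet` — the monomer alphabet Σ; every monomer named in any
  prediction must be a member. Lower-case names.
* `cluster_id` unique across entries; `gene_id` unique within an
  entry; `index` values consecutive from 0 within a gene. Gene order
  and module order are meaningful (native encoded order).
* `lineage` — ordered, domain first, as deep as known. Rank keywords
  (`domain`, `phylum`, `class`, `order`, `family`, `genus`, `species`,
  `strain`) index positions in this list.
* `stachelhaus_identity` — fraction in [0, 1]; percent values in
  (1, 100] are normalized on load (predictors report percent of the
  10-residue code). `null` means the Stachelhaus channel is absent;
  then `stachelhaus_best_match` is ignored.
* SVM fields — `null` means the channel was not predicted; an empty
  list is an explicit no-call ("nrp"), which scores tier 0. Non-empty
  tiers must nest: single ⊆ small ⊆ large ⊆ three-class.
* At least one channel (Stachelhaus or SVM) must be present per
  module.

## Prediction-table import (`pep2path makedb`)

Tab-separated, one row per module, optional header row, `#` comments:

```
cluster_id  accession  lineage  gene_id  module_index  stachelhaus_code
stachelhaus_identity  svm_single  svm_small  svm_large  svm_three
[stachelhaus_best_match]
```

* `lineage` is `;`-separated; set-valued cells are `/`-separated.
* `nrp` or an empty cell is an SVM no-call (empty set); `-` means the
  Stachelhaus channel is absent.
* The optional 12th column names the monomer(s) of the nearest known
  code; without it, the best match defaults to the single-residue SVM
  call (the common case for the predictors this table mirrors).
* `module_index` orders modules within a gene; rows may appear in any
  order.

## Merging

`pep2path mergedb A B --out C` unions entries. Alphabets must be equal
or one a superset of the other (result: union). Entries sharing a
`cluster_id` must be byte-equal in content (deduplicated); otherwise
the merge fails with a conflict error naming the id.
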