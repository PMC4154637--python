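# Methods

`pep2path` matches short, possibly degenerate peptide sequence tags —
the strings of residue masses read off MS/MS fragment spectra — to
their genomic origin. Nonribosomal peptides (NRPs) and ribosomal
peptides (RiPPs) need fundamentally different treatments, and the
package implements one component for each.

## The NRP scoring model

### Problem

An NRPS assembly line is a chain of modules, each of whose adenylation
(A) domains selects one monomer. Substrate-specificity predictors give,
per module, two kinds of evidence: the identity of the module's
~10-residue active-site fingerprint (Stachelhaus code) to the nearest
experimentally characterized code, and nested support-vector-machine
class predictions at four granularities (single residue ⊆ small class
⊆ large class ⊆ three-class). Given a tag `T = A₁…Aₜ` and a cluster
`C`, we want the likelihood that `C` encodes the peptide the tag came
from.

### Per-position posterior

By Bayes' theorem, for one tag residue `A` and one module `M`,

    P(M | A) ∝ P(A | M) / P(A),

dropping the module prior `P(M)`, which is constant when all clusters
under consideration are equally plausible a priori. (For metagenomic
mixtures one would want to weight it by organism abundance; that is out
of scope here.)

**Baseline `P(A)`.** Monomer background frequencies with additive
(Laplace) smoothing over the monomer alphabet Σ:

    P(A) = (n_A + k) / (N + k·|Σ|),        k = 1 by default.

At *degenerate* tag positions (several candidate residues compatible
with the observed mass) the flat value `1/|Σ|` is used instead.
Rationale: a degenerate position only says the residue *might* be a
rare monomer; using the rare monomer's tiny background frequency would
reward the match for an observation that was never actually made.

**Prediction support `Ī`.** For each candidate monomer `a` at a
position, the SVM channel contributes a tier — 1.0 (single-residue
call), 0.75 (small class), 0.5 (large class), 0.25 (three-class), 0.0
(none, including an explicit "nrp" no-call) — and the Stachelhaus
channel contributes the code identity if `a` is the nearest-code
substrate, else 0. `I(a)` is the mean of the channels present (a
module may lack either channel entirely, in which case the other
stands alone). A degenerate position takes the best candidate:
`Ī = max_a I(a)` — the tag is compatible with its best-supported
reading.

**Likelihood.** `P(A|M)` blends prediction support with the baseline:

    P(A|M) = (c·Ī^η + x·P(A)) / (c + x)

with defaults `c = 1` (confidence in the predictor vs the baseline),
`x = 0.01` (pseudocount keeping the log finite at `Ī = 0`), `η = 2`
(the exponent makes multi-position misprediction penalties exponential
in the number of mispredictions, via additivity of the log terms).
The published equations for this model are not recoverable from our
source text (they survive only as figure placeholders), so this
functional form is a reconstruction constrained to satisfy every
property the prose states; tests lock all four limits:

* `c = 0` ⇒ every term is exactly 0 (baseline-neutral);
* `Ī = 0` ⇒ term = ln(x/(c+x)) independent of `P(A)` and `η`;
* `Ī = 1` ⇒ term ≈ ln(1/P(A)), independent of `η`;
* strictly increasing in `Ī`, non-increasing in `η` for `Ī < 1`.

Because the reconstruction may differ from the original in constants,
absolute scores from other implementations are not comparable; ranks
and the locked limits are.

### Cluster score

The cluster score is

    S(C|T) = max over alignments  Σᵢ ln( P(Aᵢ|Mᵢ) / P(Aᵢ) ),

where the maximum ranges over

* **assembly-line configurations**: permutations of the cluster's NRPS
  genes, concatenated; module order *within* a gene is fixed, because
  colinearity operates at the protein level (and module-level
  permutation would be combinatorially absurd). The enumeration is
  capped at 5,040 orderings (7 genes); beyond that it truncates
  deterministically in generation order and flags the score as capped.
* **contiguous windows** (no gaps) along the concatenated module chain;
* **both tag orientations** by default, since MS/MS fragment series do
  not reveal the N→C reading direction (`orientation_mode=forward`
  restricts this).

A tag longer than the module chain has no admissible alignment and
receives a sentinel score that always ranks last. Ties in `S` are
broken by the colinearity index, then lexicographic cluster id; entries
equal on both share a rank ("shared best hits", which is the right
accounting when orthologous clusters encode the same molecule).

**Colinearity index.** The fraction of adjacent tag-position pairs
whose matched modules are natively consecutive (same gene, ascending
ordinals). A perfectly colinear forward alignment scores 1.0, a
reversed one 0.0; length-1 alignments are 1.0 by convention. It is a
tie-breaking interpretability aid, not part of `S`.

### Numerical choices

Natural logarithms throughout; scores are reported to 2 decimals in
human-readable output and at full precision in JSON. The search keeps
the first-encountered maximum (deterministic enumeration order:
permutations of the native gene order, forward orientation before
reversed, offsets ascending), so equal-scoring alignments resolve
deterministically.

## RiPP matching

RiPP precursor peptides are genome-encoded, so matching is exact: the
genome's six conceptual translation frames (bacterial code, table 11)
are scanned with a sliding window of tag length, testing membership of
each translated residue in the position's candidate set. Stop codons
translate to `*` and N-containing codons to `X`, neither of which
matches any candidate — windows therefore never span them, as a
contiguous precursor cannot either. Matching is deliberately
context-free (no ORF or start-codon requirement, no cluster-context
check). Candidate monomers without a one-letter code (nonproteinogenic)
can never be genome-encoded and simply never match.

Tag orientation defaults to forward-only — the conservative reading,
since published per-genome match counts are orientation-sensitive —
with `both` available; a locus found by both readings is reported once.
Machine coordinates are 0-based half-open on the forward strand
(BED-style); the human-readable table adds 1-based inclusive columns.

## Synthetic data

The generators exist because the real benchmark databases (a
GenBank-wide cluster database; curated prediction sets) cannot be
shipped or rebuilt here.

* `generate_nrp_database` plants one cluster whose modules support a
  concrete reading of the query tag exactly (Stachelhaus identity 1.0
  and a single-residue SVM call), split over 1–3 genes, among decoys
  whose per-module predictions are drawn from the background monomer
  frequencies — frequency-sampled decoys are realistically confusable,
  where uniform decoys would overstate recovery. Decoy module counts
  are drawn from max(2, t)…max(t+4, 8), a realistic cluster-size range
  that always admits the tag. Misprediction noise replaces a planted
  position's prediction with one supporting none of the tag's
  candidates there (prediction support exactly 0), the standard way to
  simulate a substrate misprediction.
* `generate_ripp_genome` reverse-translates a peptide with random
  synonymous codons, plants it once at a random position/strand in
  random background DNA, and rejects backgrounds containing any
  additional exact occurrence in any frame.
* `recovery_curve` reports, per (tag length, database size), the
  fraction of replicates in which the planted cluster is the (shared)
  best hit, with fresh frequency-drawn singleton tags per replicate.

All randomness flows through one seeded numpy `Generator`
(`SeedSequence` children keyed by grid cell and replicate), so equal
seeds give byte-identical outputs.

**What passing these benchmarks does and does not show.** The planted
generator controls prediction quality exactly, so noise-free recovery
of 100% and monotone degradation under mispredictions validate the
*scorer's* behavior, not the accuracy of any real-world predictor;
real A-domain predictions (especially for fungi or unusual taxa) are
noisier than the zero-or-perfect channels simulated here, and real
decoy clusters have correlated, phylogenetically structured
predictions rather than i.i.d. frequency draws.

The shipped background frequency table is likewise a synthetic
stand-in (hand-set counts shaped like NRP monomer abundances; file
`monomer_frequencies.synthetic.tsv`), and the two mass-conversion
tables are best-effort reconstructions from standard monoisotopic
residue masses. All three are ordinary data files the user can
replace; scores depend on the frequency table only through smoothed
ratios, so ranking behavior is robust to moderate count changes.

## Benchmark problem sizes

The shipped acceptance checks use 200 random clusters for the
exhaustive-search cross-check (≤3 genes, ≤8 modules — small enough
that the brute-force enumerator is itself trustworthy), 50 replicates
per cell for recovery grids over database sizes 5–100, 30 replicates
for the misprediction series, and 1,000 (tests) / 300 (acceptance
script) planted-genome round trips at 600 nt. These sizes give stable
percentages while keeping the whole suite fast on a single CPU.

## Known limitations

* The scoring equations are a property-constrained reconstruction (see
  above); absolute score values are implementation-specific.
* Whole-gene permutation covers standard assembly-line biology but not
  module skipping or iterative module use.
* The published per-genome RiPP match counts can only be checked
  against the actual multi-megabyte genome sequences, which must be
  fetched separately (`scripts/fetch_genomes.py`); the orientation
  policy behind those published counts is not documented, so the check
  accepts either forward-only or both-orientations agreement and
  reports both.
* Mass-to-residue conversion is table-driven; residues missing from
  the table (or outside the monomer alphabet) are reported as errors,
  not guessed.
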