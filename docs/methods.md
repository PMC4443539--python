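# Methods

This note records the model underlying `partialdom`, the parameters that
matter, what the synthetic data generator does and does not emulate, and the
design decisions taken where the problem left genuine freedom.

## Data model and filters

Input mirrors a Pfam-style relational dump: families (`model_length` in match
states, optional clan), sequences (length plus `is_fragment`, `is_eukaryote`,
`reviewed`, `has_gene_model` flags), and domain annotations with 1-based
inclusive coordinates in both the sequence (`seq_start/seq_end`, residues)
and the model (`model_start/model_end`, match states). Coordinates are
validated at load; unknown columns are ignored with a warning.

Two filters precede all analysis: only annotations with the `in_full` flag
(the curated full-significance set), and only sequences not flagged as
fragments — a fragment record is incomplete by construction, so a partial
domain on it carries no information. Both filters are idempotent.

## Partial detection and classification

Coverage is `model_end − model_start + 1` match states; an annotation is a
partial when coverage is strictly below `partial_threshold × model_length`.
The threshold is a parameter (default 0.5) so coverage sweeps can reuse the
same code; the cumulative coverage-distribution report bins fractions into
right-closed bins of configurable width at both domain level and sequence
level (a sequence enters at the minimum fraction over its domains — the
conservative attribution, since a single broken domain yields several short
annotations on one protein).

Classification proceeds in two stages, split first:

1. **Chains.** Annotations on one sequence are grouped by homology (same
   family, or two families sharing a clan — clans mark homology too diverse
   for one model, so clan mates are treated as the same domain throughout).
   Within a group ordered by `seq_start`, consecutive annotations chain when
   the downstream member does not step backwards in the model
   (`model_start` non-decreasing) and the model intervals overlap by at most
   `chain_overlap_tolerance` match states (default 10 — alignment boundaries
   are fuzzy, and pieces of one broken domain commonly re-align a few states
   twice). Chains are maximal and independent of input row order. Every
   <50% member of a multi-member chain is **split**; a short piece chained
   to a ≥50% piece is still split, but only <50% members are tallied as
   partials. Annotations of unrelated families between chain members do not
   break a chain.

2. **Free span.** For each remaining partial the full model is projected
   around the annotation (`model_start − 1` residues upstream,
   `model_length − model_end` downstream, clipped to the sequence). The free
   span is the maximal interval around the partial delimited by the sequence
   termini and the nearest non-homologous annotations (different family and
   clan), allowing `neighbor_overlap_tolerance` residues of overlap (default
   10). The partial is **unbounded** when the free span holds at least
   `(1 − slack) × model_length` residues, else **bounded**, with the
   delimiting features (terminus and/or neighbor annotations) recorded as
   machine-checkable evidence.

`slack` defaults to 0.1: requiring ~90% of the model length of room is the
single rule that reproduces both canonical bounded geometries — a 141-residue
protein against a 292-state model (no room for even half the model) and a
partial walled in by a non-homologous domain that leaves no room for the
missing states. The exact bounded/unbounded frontier is this package's
decision and is therefore surfaced in the run metadata; increasing `slack`
weakens the requirement and can only move bounded calls to unbounded.

## Homology search and E-values

Unbounded partials are re-examined by sequence search: the projected region
(optionally padded) is cut from the protein and compared to the protein
database with Smith–Waterman under BLOSUM62. Gap costs follow the
BLAST/FASTA convention for "−11/−1": a gap of length *k* costs 11 + *k*
(implemented as open −12 for the first gap residue, −1 for each further
one). The aligner is exact (no banding or heuristics); scores are checked
against an independent quadratic-space Gotoh DP in the test suite.

E-values are calibrated per query from that query's own database score
distribution, the same strategy search programs use. Procedure:

1. regress score on log subject length over the lower 75% of scores (true
   homologs must not leverage the slope) and subtract the fitted trend;
2. obtain robust initial Gumbel parameters from the 25th/50th percentiles;
3. iteratively trim every score the current fit deems a credible homolog
   (E < 0.01) and refit the Gumbel to the remainder by **right-truncated**
   maximum likelihood, until the trimmed set is stable. When nothing is
   trimmed the fit is plain MLE on the full sample.

Truncation, not censoring, is essential: censoring would force the null to
account for the trimmed mass, and on a database rich in true homologs (in
the synthetic setting a single family can be most of the database) that
inflates the fitted scale by an order of magnitude and suppresses every hit.
A fixed trim fraction fails the same way; the data-driven trim handles both
the pure-null and the homolog-rich regimes, and on pure-decoy databases the
expected count of chance hits at E ≤ 1 is ~1 per search (verified in the
acceptance suite). At least 50 database scores are required; the pipeline
search stage pads small databases with shuffled decoys (same composition, no
homology, deterministic seed) and excludes them from reported hits.

`E(s) = db_size × P(S ≥ s)` is monotone non-increasing in the score, linear
in database size, and approaches `db_size` for vanishing scores. Absolute
E-values from this desk-scale calibration are not expected to match any
particular search program's statistics; only threshold behavior is promised
(clear homologs at E ≤ 10⁻⁶, decoys nowhere near it).

A query's homologs are summarized by `n_significant` (hits at E ≤ 10⁻⁶,
self-hits excluded by sequence accession only — duplicate sequences under
different accessions are retained) and `n_short` (significant hits whose
alignment is shorter than half the model). Alignment length is counted as
aligned residue pairs, i.e. columns excluding gaps (query-span and
subject-span conventions are available as options). The partial is
**putative** when `n_significant ≥ 10` and `n_short / n_significant ≥ 0.25`,
both boundaries inclusive.

## Enrichment

Per family with at least `min_bounded` (default 10) bounded partial domains,
the 2×2 table contrasts the family's bounded-partial-containing sequences
against sequences annotated with the family that carry no <50% partial of
any kind (the cleanest partial-free comparison group), split by the
eukaryote flag. Fisher's exact test is two-sided by probability ordering
(sum of all tables with the observed margins no more probable than the
observed one); the odds ratio is the sample value `ad/bc` with zero
denominators reported as infinity and degenerate margins as p = 1.
FDR adjustment is Benjamini–Hochberg by default — no tuning parameter,
conservative; Storey-style q-values (π₀ estimated at λ = 0.5) are available
behind a flag because they are less conservative when many families are
truly enriched. The reviewed and reviewed-with-gene-model contrasts are
built from the sequence flags over the same two groups, optionally
restricted by a caller-supplied taxon predicate.

## Synthetic data generator

The generator emulates the structure of a curated HMM annotation set:
families with models of 200–500 match states (the regime where partials are
reliably detectable), member proteins assembled as linker + domain + linker
with linkers of uniform length 20–200 (enough flanking sequence to create
realistic projection geometry), and a pool of shorter decoy families
(100–200 states) for multi-domain architectures.

Member domains are copies of a family consensus with position-independent
substitutions, uniform over the 19 alternative residues, at a per-position
rate solved from the target *pairwise* identity
(`t = (1 − p)² + p²/19`); consensus and linker residues are drawn from
BLOSUM62-compatible background frequencies. Short indels (rate
0.005/position split between single-state deletions and geometric mean-2
insertions) are tracked exactly so every planted coordinate remains exact.
This substitution model carries no rate heterogeneity, conserved motifs, or
realistic indel placement — adequate here because only the rank/threshold
behavior of the search stage is asserted, never absolute scores. Passing
tests on these data show the pipeline's logic is correct under its own
assumptions; they do not certify recall on real HMM alignments, whose
boundary noise is structured rather than random.

Planted artifacts per family (counts configurable): split domains (model cut
at 2/3 for two pieces — an even cut would leave both halves at exactly 50%,
which the strict threshold does not call partial — evenly for more, with a
few states of model overlap between pieces); bounded-by-terminus (a <50%
model tail on a host truncated to at most 85% of the model length);
bounded-by-neighbor (the tail hemmed in between two decoy domains with
5–15-residue gaps); unbounded (full domain residues present but only a
`keep_fraction` = 0.45 window annotated); and degraded-half putative
candidates (like unbounded, but the unannotated complement replaced by
random residues, so homolog alignments stop at the annotated part). On
noiseless plants the classifier recovers every planted label exactly, and
the search stage flags exactly the degraded members as putative.

Eukaryote flags are assigned at a configurable base rate, with
bounded-partial sequences of the designated enriched families at
`enrichment_odds_ratio` times the base odds (infinite odds ratio forces the
flag). Reviewed/gene-model flags follow class-dependent rates that mirror
the annotation-artifact story (bounded-partial sequences rarely reviewed).
The enrichment power simulation plants 40 bounded sequences per 400-member
family: at odds ratio 5 this gives each family's Fisher test ~95% power, so
the expected recovery (≥ 80% of enriched families at q < 0.05) is a property
of the method rather than of sampling luck; 20 bounded per family would put
the design underpowered at ~70%.

Identical config and seed reproduce byte-identical tables and FASTA; all
randomness flows from explicit seeds (no wall-clock seeding anywhere).

## Numerical and scale choices

* Degenerate inputs: empty annotation tables, empty coverage collections and
  degenerate contingency margins return empty/flagged results, not errors;
  coordinate violations and dangling references fail loudly with row
  numbers.
* Ties in chain building are broken by a fixed sort key
  (`seq_start`, `seq_end`, family, model coordinates), which is what makes
  chaining order-independent.
* Test and acceptance problem sizes (30–100 planted datasets, 60–100 decoy
  replicates, 50 families × 400 sequences for enrichment) were chosen as the
  smallest scales at which the asserted statistical properties are stable
  across seeds; everything runs in well under a minute on one CPU.
* The pipeline's default of 200 shuffled decoys in the search stage keeps
  per-query calibration above the 50-score minimum even for tiny datasets.

## Known limitations

* The classifier sees only annotation geometry; it cannot distinguish a
  genuinely absent domain half from one the HMM failed to align unless the
  search stage has residues to work with.
* The free-span rule uses total room around the partial, not side-specific
  room relative to the projection; a partial at a terminus with ample room
  on the wrong side is still called unbounded.
* E-value calibration needs a score bulk that is mostly non-homologous;
  with fewer than ~50 non-homolog scores even decoy padding leaves the
  Gumbel tail poorly constrained.
* Structural validation of putative partials (against structure databases)
  is out of scope; the putative flag is a sequence-level candidate list.
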