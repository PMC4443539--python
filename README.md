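# partialdom

Detection, classification and enrichment analysis of **partial protein-domain
annotations** in Pfam-style data.

Profile-HMM domain databases annotate each domain occurrence with its mapping
onto the family model (`model_start`, `model_end`, in match states) and onto
the protein (`seq_start`, `seq_end`, in residues). A sizable fraction of these
annotations cover less than half of the family model, which — if taken at face
value — would mean that more than half of a supposedly indivisible structural
unit is missing. `partialdom` implements the analysis that resolves what these
apparent partials really are:

* **split domains** — one biological domain broken into several consecutive
  annotations by the local HMM alignment (the pieces progress through the
  model in order, overlapping by at most a few match states);
* **bounded partials** — annotations that *cannot* be extended to near full
  model length because the protein ends or a non-homologous domain is in the
  way (often a symptom of truncated gene models or mis-assembled proteins);
* **unbounded partials** — annotations with enough unannotated flanking
  sequence to hold the whole projected model, i.e. likely alignment
  artifacts; and among these,
* **putative partials** — unbounded partials whose extended-region query
  finds many significant homologs (≥ 10 at *E* ≤ 10⁻⁶) of which a substantial
  share (≥ 25%) align over less than half the model: candidates for genuinely
  mobile sub-domains.

## The core quantities

An annotation's coverage of its family model is

```
covered_states = model_end − model_start + 1
fraction       = covered_states / model_length
```

and it is a **<50% partial** when `covered_states < 0.5 × model_length`
(strict). Projecting the full model around an annotation on a sequence of
length `n` gives the interval

```
proj_start = max(1, seq_start − (model_start − 1))
proj_end   = min(n, seq_end + (model_length − model_end))
```

A non-split partial is **unbounded** when its *free span* — the maximal
interval around it delimited by the sequence termini and the nearest
non-homologous annotations (different family *and* different clan), allowing
a small overlap tolerance — is at least `(1 − slack) × model_length` residues
(default `slack = 0.1`); otherwise it is **bounded** and the blocking feature
is recorded.

Extended-region queries are searched with Smith–Waterman (BLOSUM62, affine
gaps: a gap of length *k* costs 11 + *k*). E-values come from a Gumbel
(extreme-value) fit to the query's own database score distribution, with a
log-length correction and iterative exclusion of credible homologs from the
null fit; shuffled decoys anchor the null when the database is small.

Per family with ≥ 10 bounded partials, a 2×2 table contrasts
bounded-partial-containing sequences against partial-free sequences of the
family, split by the eukaryote flag; Fisher's exact test (two-sided,
probability ordering) with Benjamini–Hochberg FDR (Storey q-values optional)
summarizes which families are enriched.

## Worked example

Generate a synthetic dataset with planted artifacts, classify it and print a
category summary:

```sh
partialdom simulate --seed 11 --out-dir demo --n-families 2 --members-per-family 20
partialdom classify --families demo/families.tsv --annotations demo/annotations.tsv \
    --sequences demo/sequences.tsv --out demo/classification.tsv
partialdom report --families demo/families.tsv --annotations demo/annotations.tsv \
    --sequences demo/sequences.tsv
```

which prints

```
Category             Sequences       %     Domains       %
Total                       40  100.00          52  100.00
50% partials                16   40.00          16   30.77
Split                        4   10.00           4    7.69
Bounded                      8   20.00           8   15.38
Unbounded                    4   10.00           4    7.69
Putative partial             0    0.00           0    0.00
```

Each of the two simulated families planted 2 split, 4 bounded (2 cut off by
the sequence end, 2 walled in by decoy domains) and 2 unbounded partials, and
the classifier recovers exactly those 16 <50% partials with their planted
categories. The 52 domains include the decoy-family annotations used as
non-homologous walls. Per-annotation calls land in `demo/classification.tsv`:

```
seq_id      family_id  ... covered_states  fraction  category  putative  evidence
F000_M0003  FAM00000   ... 94              0.344322  split     0         chain:F000_M0003:FAM00000:0
F000_M0004  FAM00000   ... 109             0.399267  bounded   0         free_span=1-122(122);left=terminus;right=terminus
```

The full pipeline (simulate/load → classify → search → enrich → report) runs
from a flat config file with `partialdom run --config run.cfg --out-dir out`;
see `partialdom run --help` and `tests/test_cli.py` for config keys.

Real Pfam data can be analyzed by exporting the `pfamA` (family accession,
model length, clan), `pfamA_reg_full_significant` (domain regions with
`in_full`) and sequence tables from the Pfam MySQL dump into the three
tab-separated schemas documented in `partialdom.annotation_core`, with
booleans as 0/1.

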