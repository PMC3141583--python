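# Methods

## Model

A citation corpus is a sequence of records, each a record identifier with a
finite *set* of descriptor terms (duplicates and whitespace variation are
normalized away on ingest; case is preserved because controlled vocabularies
distinguish, e.g., gene symbols by case). A record with k descriptors emits
the k(k−1)/2 unordered pairs of distinct terms; the frequency of a pair is
the number of records emitting it. This is raw co-occurrence counting: no
tf-idf, PMI or other weighting, which is deliberate — the slicing calculus is
defined on counts of records.

Pair canonicalization orders the two normalized terms lexicographically on
code points; ties are impossible because self-pairs are excluded. A
historical pseudocode variant of the enumeration (a double loop producing k²
ordered tuples including self-pairs) is retained as
`enumerate_pairs_literal`, used nowhere in the pipeline; the worked example's
printed 28-pair output fixes the unordered i<j semantics as the intended one.

## The slicing calculus

With `k` the maximum frequency in a table:

- `slice_i` (i ≥ 1) is the set of pairs at frequency ≥ i. Slices nest and may
  be empty (real corpora exhibit blank levels).
- `ld_i = slice_i − slice_{i+1}` is the set of pairs at frequency exactly i.
  It is computed both by the slice difference and by direct lookup, and the
  implementation asserts the two routes agree on every call.
- The discrete derivative differences adjacent levels by **set** difference:
  the proof of constancy manipulates sets, not counts, so the set semantics is
  the only one under which the statement is meaningful. Order m is defined on
  levels 1..k−m: each differencing step drops the top index because the
  derivative at the last point has no successor to difference against. An
  absent level (above k−m) is *undefined*, represented as a missing key, and
  is distinct from an empty level (defined, no pairs).

Because pairs at distinct exact frequencies are disjoint,
`ld_i − ld_{i+1} = ld_i`, hence every order of derivative equals the level
distribution on its shared range. `verify_constant_derivative(table, m)`
checks this for every order 1..m and every surviving level, and is both a
library function and a pipeline gate (a failing verdict makes the `run`
command exit nonzero — it would indicate a counting bug, since the property
is a theorem).

Slices are materialized lazily from the frequency table rather than stored
per level; per-level TSVs are written only on explicit export
(`<label>_freq_<i>.tsv`).

## Cross-corpus operations

- **Intersection**: keys are the pair-set intersection. The frequency of a
  retained pair is combined per policy; the default `min` means a pair
  reaches slice level f of the intersection iff it reaches f in both corpora
  — the conservative choice when no combination rule is given. `sum`, `left`
  and `right` are provided for sensitivity analysis.
- **Lexicon filter**: exact-term, case-insensitive matching (substring
  matching on short herb names produces uncontrolled false positives).
  `both` keeps item–item pairs, `either` keeps item–concept links.
- **Ranking**: lexicon terms ordered by the number of records mentioning
  them (record-level occurrence, not keyword-field multiplicity), ties
  broken lexicographically. Output is meant for human review, not
  auto-curation.
- **Seed query**: pairs with at least one endpoint among the seed terms at
  frequency ≥ a threshold — the cross-verification step that carries items
  selected in one corpus back into the other.

## Graphs and motifs

A pair set becomes an undirected `networkx` graph with `frequency` as an edge
attribute. A **wheel** is formalized as a star: any node of degree ≥
`min_rim` with its neighborhood as rim. Rim–rim connectivity is not
required — observed wheels are defined pictorially by their hub, and
requiring rim independence or rim closure would be an invention. `min_rim`
defaults to 5, the smallest rim size at which the structure is discussed as
a wheel. The **hub intersection** of two centers is the subgraph on the
centers plus their common neighbors, keeping only center-incident edges
(plus the center–center edge when present); shared-node-to-shared-node edges
are not part of the motif.

Exports (SIF, GraphML, edge TSV) use a canonical sort (descending frequency,
then pair order), so repeated exports are byte-identical. No layout
coordinates are computed or stored.

## Synthetic data

The generator emulates the statistical shape of keyword co-occurrence
corpora, not their semantics:

- `n_records` (default 300) records draw between 2 and 8 descriptors
  (uniform count, with-replacement sampling then set collapse) from a
  vocabulary of `vocab_size` (default 150) terms with power-law rank weights
  `rank^(−s)`, `s = vocabulary_skew` (default 1.2). The skew gives the
  heavy-tailed pair-frequency spectrum of real data — most pairs occur once,
  a few occur tens of times — so slice occupancy thins as the threshold
  rises, matching the qualitative simplification trend the method relies on.
  Defaults were chosen so that a default corpus spans pair frequencies from
  1 into the tens.
- **Planting** gives exact ground truth: each planted pair (or star edge)
  receives its own records — allocated disjointly across structures from a
  seed-shuffled pool — containing only that structure's two terms, and
  background records that would accidentally complete a planted edge are
  redrawn (bounded retries, then an error). Realized frequencies are
  post-checked by a direct scan at generation time. Planted records
  therefore carry exactly two descriptors; this is a modelling
  simplification that trades record realism for an exact oracle, which the
  recovery tests require.
- All randomness flows from a single integer seed through one `random.Random`
  instance; identical configs produce byte-identical corpora.

What passing tests on synthetic corpora do **not** show: anything about the
semantic plausibility of real MeSH co-occurrence (term hierarchies,
qualifier structure, topical correlation between records), nor about the
specific networks any historical database snapshot would yield. They show
that the counting, slicing, derivative, intersection, filtering and motif
operations are correct on data with the right frequency shape.

## Problem sizes and numerical choices

- The test suite's property sweep uses 100 seeded corpora cycling through
  50–500 records and 20–200 vocabulary terms; the brute-force counting
  oracle is compared on the 50-record / 20-term members. These sizes give
  pair tables up to a few thousand entries, ample to exercise every code
  path while keeping the whole suite in seconds.
- The acceptance script repeats the sweep with seeds derived from its
  `--seed` argument (`(seed·100003 + i) mod 2³¹`), so the properties are
  checked on fresh corpora every run rather than on memorized cases.
- Planted-recovery conditions (a pair at frequency 17, an 8-rim star at
  per-edge frequency 19, in 300 records over a 300-term vocabulary at skew
  0.8) were chosen so that background co-occurrence stays safely below the
  planted frequencies, making exact recovery the correct expectation rather
  than a statistical hope.
- Degenerate inputs: empty corpora give empty tables; empty tables have max
  frequency 0, no levels, and pass the derivative verification vacuously; a
  table whose maximum frequency is 1 has an empty (and warned-about)
  derivative series.

## Limitations

- Live database querying and any historical snapshot reproduction are out of
  scope; corpora enter as files.
- "Specific" vs "abstract" concept judgments on wheel rims are manual
  curation steps with no stated rule and are not implemented.
- Numeric-valued derivatives (assigning coordinates to descriptors in a
  continuous space) are speculative and not implemented.
- The lexicon filter is exact-term; morphological variants of item names
  must be expanded in the lexicon itself.
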