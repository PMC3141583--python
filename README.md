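# ddslice

Frequency-sliced literature co-occurrence networks and discrete set
derivatives.

## The problem

When two diseases respond to the same therapy — the motivating case is
rheumatoid arthritis (RA) and coronary heart disease (CHD), both treated with
the same herbal formulas in traditional Chinese medicine — a natural question
is whether the biomedical literature already encodes a shared biological
basis. Citation databases index every paper with controlled-vocabulary
descriptors (MeSH headings in PubMed, keywords in SinoMed), so the literature
of a disease induces an undirected co-occurrence network: descriptors are
nodes, and an edge joins two descriptors indexed on the same paper, weighted
by the number of papers in which they co-occur.

These networks are far too dense to read. `ddslice` implements the
*data-slicing* approach: stratify the pair table by co-occurrence frequency
and inspect the strata, where clean hub-and-spoke ("wheel") structures
emerge — a central descriptor with its associated concepts as the rim.

## The method

Let `frequency(e)` be the number of records in which pair `e` co-occurs and
`k = max frequency` (the hierarchical parameter). Then for `i = 1..k`:

- **slice**: `slice_i = { e : frequency(e) ≥ i }`, so slices nest
  (`slice_{i+1} ⊆ slice_i`) and `slice_1` is the whole table;
- **level distribution**: `ld_i = slice_i − slice_{i+1}`, the pairs at
  frequency exactly `i`; the levels partition the pair set;
- **discrete derivative**: `ld′_i = ld_i − ld_{i+1}` (set difference), with
  higher orders `ld^(m) = (ld^(m−1))′`, each order dropping the top level
  (differencing the last point is undefined).

Because levels at distinct frequencies are disjoint, `ld_i − ld_{i+1} = ld_i`:
**discrete derivatives of every order are constant**, equal to the level
distribution on the shared level range. `verify_constant_derivative` is the
executable form of this statement and the pipeline checks it on every run.

Around the calculus sit the workflow steps: building pair tables from
MEDLINE XML or plain record tables, intersecting two disease tables (the
RA ∩ CHD construction, `min` frequency policy by default), filtering by a
term lexicon (e.g. a table of herb names), ranking lexicon terms by record
occurrence, pulling the pair star around chosen seed terms, detecting wheel
motifs and hub-intersection subnetworks, and exporting SIF / GraphML /
edge-TSV for Cytoscape.

## Worked example

The method's printed worked example is a single citation (PMID 20464912)
carrying eight heading terms; it ships as a fixture:

```python
from ddslice import enumerate_pairs, count_frequencies, max_frequency
from ddslice.synthetic import table3_fixture

corpus = table3_fixture()
pairs = enumerate_pairs(corpus.records[0])
print(len(pairs))                      # 28  (= C(8,2), all unordered pairs)

table = count_frequencies(corpus)
print(len(table), max_frequency(table))  # 28 1  (single record: every pair once)
```

A synthetic two-corpus run from the shell:

```bash
ddslice synth --seed 1 --out A.tsv
ddslice synth --seed 2 --out B.tsv
ddslice run --left A.tsv --right B.tsv --out-dir out
```

prints the run report, including (for one such run)

```
"intersection": {"policy": "min", "pairs_left": 1028, "pairs_right": 906, "pairs_kept": 426}
"theorem_constant_derivative": {..., "passed": true}
```

i.e. 426 descriptor pairs survive in both corpora, each at the smaller of
its two frequencies, and the constant-derivative property holds on the
intersected table. `out/` contains the pair tables, the sliced graph export
and `run_report.json`.

## Layout

- `ddslice.corpus_io` — MEDLINE XML / record-table / lexicon I/O
- `ddslice.cooc` — pair enumeration and frequency tables
- `ddslice.slicing` — slices, level distributions, discrete derivatives
- `ddslice.crosscorpus` — intersection, lexicon filter, ranking, seed queries
- `ddslice.graphs` — wheel motifs, hub intersections, Cytoscape export
- `ddslice.synthetic` — seeded corpora with planted ground truth
- `ddslice.pipeline` / `ddslice.cli` — orchestration and the `ddslice` command

See `docs/methods.md` for the model, parameter choices and limitations.
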