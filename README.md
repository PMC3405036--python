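# primereval

In-silico evaluation of degenerate PCR primers against aligned marker-gene
databases: IUPAC-aware fuzzy matching with mismatch budgets, sequence-depth-
normalized coverage statistics stratified by phylogenetic group and
environment, primer-pair amplicon prediction, degeneracy and melting-
temperature characterization.  A registry of 51 universal and 35
group-specific nifH primers (paired into 42 + 19 primer sets) is bundled,
together with a synthetic aligned-database generator that provides exact
ground truth for every pipeline stage.

## Concepts

* **Aligned database** — an aligned FASTA (gaps `-`/`.` allowed) plus a
  metadata TSV (`id`, `group`, `environments` semicolon-separated).  One
  record is the designated reference and defines 1-based coordinates.
* **Coverage** — hit events of a primer within its own binding window,
  divided by the number of records with nucleotide representation spanning
  that window, as a half-up-rounded integer percent.  Highly degenerate
  primers can bind multiple positions, so event-based coverage can exceed
  100%.  A zero denominator reports NA, not 0.
* **Matching** — Hamming-style against gap-stripped sequences; inosine is a
  universal base for matching but contributes multiplicity 1 to degeneracy;
  ambiguous database bases match by base-set intersection (a `strict` policy
  is available).  Reverse primers are scanned as their reverse complement
  on the sense strand.
* **Tm** — unified nearest-neighbor parameters (data file, swappable) with
  a monovalent-equivalent Mg correction by default (0.25 µM oligo, 50 mM
  Na+, 1.5 mM Mg++, 0 mM dNTPs); min–max ranges over all expansions of a
  degenerate primer, by exhaustive enumeration or an exact
  fractional-programming optimizer.

## CLI

```sh
primereval simulate --n-records 300 --seed 42 --out-dir sim/
primereval evaluate --db sim/synthetic.fasta --metadata sim/synthetic.metadata.tsv \
    --reference-id REF --primers universal --mismatches 0,1,2 --out coverage.tsv
primereval pairs --db sim/synthetic.fasta --metadata sim/synthetic.metadata.tsv \
    --reference-id REF --pairs all --out pairs.tsv
primereval tm --name F2 --name R6         # melting-temperature ranges
primereval depth --db sim/synthetic.fasta --reference-id REF --out depth.tsv
primereval map --out primer_map.tsv       # binding windows along the reference
primereval all --out-dir report/          # full bundle on the synthetic fixture
```

Output tables are TSV with `#`-prefixed metadata headers recording every
policy choice, the seed and a config hash; identical configs produce
byte-identical reports.

## Layout

```
src/primereval/
  registry.py   primers, pairs, degeneracy/expansion, packaged fixtures
  aligned.py    aligned FASTA IO, reference map, depth profile, denominators
  matching.py   mismatch-tolerant degenerate scanning (+ expansion oracle)
  coverage.py   stratified percentage tables
  pairpcr.py    primer-pair amplicon prediction and pair coverage
  thermo.py     nearest-neighbor Tm and Tm ranges
  synth.py      synthetic database generator with ground-truth manifests
  cli.py        click-based command-line interface
  runconfig.py  run configuration and the full report bundle
  data/         primer/pair fixtures (TSV) and NN parameter tables
```
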