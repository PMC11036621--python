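# syngenes

Standardize mitochondrial and chloroplast gene-name variants, and build
synonym-aware Entrez search queries for GenBank and PubMedCentral.

## The problem

Gene nomenclature in deposited organelle genomes is not standardized: the
same marker appears as *COI*, *COX1*, "cytochrome oxidase subunit I",
"cytochrome c oxidase subunit 1", hyphenated, re-cased, and occasionally
misspelled ("cytchrome", "cutochrome"). This hurts two everyday tasks in
phylogenetics and molecular evolution:

* **database searches** — a query for one spelling misses records annotated
  under any other;
* **automated analysis input preparation** — gene-order and comparative
  tools treat "cytochrome oxidase subunit I" and "cytochrome c oxidase
  subunit 1" as different genes unless both are first mapped to one symbol.

`syngenes` maintains a many-to-one **synonym table**
`(variant, organelle) → canonical short name`, where the canonical symbols
follow HUGO-style conventions (*COI*, *CYTB*, *ND1–ND6*, *rbcL*, *matK*, ...)
and the two organelle namespaces (`mt` / `cp`) are fully isolated (*16S* is
mitochondrial; the chloroplast ribosomal RNA is *rrn16S*). On top of the
table it provides:

* `fix_gene_name(name, table, organelle)` — exact lookup on a normalized key
  (lower-case, hyphen/underscore folded to space, whitespace collapsed);
  misses return a falsy `NotFound` sentinel and are appended to a log for
  curation. Deliberately no fuzzy matching: real typos are harvested into
  the table as first-class variants.
* `build_query(spec, table)` — renders the advanced search string
  `("<organism>"[Organism]) AND ("v1"[field] OR "v2"[field] OR ...)`
  that OR-joins every known synonym of a marker, plus the fixed clade-level
  genome-retrieval query templates.
* `build_from_files(paths, organelle, canonical_map)` — scans GenBank flat
  files (CDS, rRNA and control-region/D-loop features only; tRNAs are out of
  scope), deduplicates on the normalized product name, and grows a draft
  synonym table with full accounting (new entries, duplicates, unmapped
  queue for manual curation).
* `generate_corpus(n, organelle, seed, params)` — synthetic GenBank genomes
  with controlled annotation noise (case flips, hyphen/space swaps,
  character typos) and an exact ground-truth variant map, so the whole
  pipeline is testable offline.
* CSV/JSON persistence with a versioned file format and an atomic remote
  refresh (`update_table`).

A curated seed table ships with the package: 77 mitochondrial and 311
chloroplast variant entries over 16 mt and 98 cp canonical markers.

## Worked example

```python
from syngenes import QuerySpec, build_query, fix_gene_name, load_seed_table

table = load_seed_table()
fix_gene_name("COX1", table, "mt", verbose=False)
# -> 'COI'
fix_gene_name("CYTOCHROME-B", table, "mt", verbose=False)
# -> 'CYTB'

spec = QuerySpec("COI", organelle="mt", organism="Carcharodon Carcharias")
print(build_query(spec, table))
```

prints

```
("Carcharodon Carcharias"[Organism]) AND ("COI"[All Fields] OR "cytochrome oxidase subunit I"[All Fields] OR "cytochrome c oxidase subunit 1"[All Fields] OR "cytochrome c oxidase subunit I"[All Fields] OR "COX1"[All Fields] OR "CO1"[All Fields])
```

— one search that covers every spelling of *COI* the table knows for the
white shark. Building a database from scanned genomes:

```bash
syngenes generate-fixtures --n 20 --type mt --seed 7 --out example_corpus
syngenes build-db --type mt --out draft.csv --input example_corpus/SYNMT00000.gb ...
```

reports (via the library, `examples/build_database_from_genomes.py`):

```
scanned 20 genomes, 320 features: 119 new product names, 201 duplicates
skipped, 15 gene-symbol spellings added, 0 unmapped
draft map equals planted ground truth: True
```

i.e. each of the 320 harvested features either introduced a new product
spelling or was skipped as a known duplicate, and the rebuilt
variant→canonical map matches the generator's ground truth exactly.

The same operations are available from the shell: `syngenes fix`,
`syngenes query`, `syngenes retrieval-query`, `syngenes build-db`,
`syngenes export-json`, `syngenes generate-fixtures`, `syngenes update`,
`syngenes version`. `fix` and `query` print only their payload on stdout
(diagnostics go to stderr); `fix` exits 1 when the name is unknown.
See `examples/` for narrative scripts covering each capability.

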