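# Methods

## The synonym model

The database is a finite map `(normalized variant, organelle) → canonical
short name`. Three structural rules are enforced everywhere, at load time
and on every insertion:

* **Uniqueness** — within one organelle a normalized variant resolves to at
  most one short name. An ambiguous file (same key, two targets) is a hard
  load error naming both mappings, never a warning: a lookup that could
  return two symbols would silently corrupt downstream gene-order input.
  A benign duplicate (same key, same target, e.g. "ATP synthase" and
  "ATP-synthase") is collapsed to the first-registered spelling.
* **Closure** — every short name referenced by an entry is a canonical gene
  of the same organelle; the canonical-gene registry (symbol, organelle,
  functional category) is derived from the entries themselves.
* **Self-maps** — every canonical symbol is a variant of itself. Missing
  self-maps are materialized when a table is constructed or loaded, which
  makes lookup total over canonical names without special-casing. A draft
  being grown by the builder only contains what was actually harvested;
  its self-maps appear on the save→load round trip.

The two organelle namespaces are disjoint by construction. The same string
may appear in both with different targets ("16S ribosomal RNA" is *16S*
under `mt` and *rrn16S* under `cp`), which is why the organelle is an
explicit argument throughout rather than something inferred per record.

## Name normalization

All matching happens on a normalized key: trim; strip *paired* surrounding
quotes (straight and typographic — a lone apostrophe is kept, so the RNA
polymerase subunits beta′/beta′′ stay distinct); fold `-` and `_` to
spaces; collapse whitespace runs; lower-case. Digits and dots pass through
(`rrn4.5S`). The transform is idempotent, and a non-blank input never
yields an empty key (an input that folds away entirely, like `"-"`, falls
back to its trimmed lower-case form).

Matching is **exact on the normalized key**. Fuzzy/edit-distance matching
is excluded by design: observed misspellings are enumerated as database
variants harvested from genomes, which keeps resolution deterministic and
auditable. Unresolved names are appended (never overwritten) to a plain
text log — one tab-separated line of timestamp, organelle, raw name — as
the curation queue for future variants; the default log is
`SynGenes_unfound.log` in the working directory.

## Database construction from genome scans

`build_from_files` folds two steps over every record of every input file
(GenBank flat files, gzip accepted by extension), in file order:

1. **Scan** — harvest `(gene, product)` qualifier pairs from `CDS` and
   `rRNA` features. tRNAs and all other feature kinds are ignored: the
   database covers coding and ribosomal genes only. Additionally, `D-loop`
   features and `misc_feature`s whose note/product mentions a control
   region are harvested as `control_region`, because the control region is
   a standardized mitochondrial marker that no CDS or rRNA feature would
   otherwise reach. A feature with neither qualifier is skipped and
   counted.
2. **Accumulate** — the *product* name is checked against the draft (the
   dedup key); if new, it is inserted mapped to the canonical symbol
   resolved through the reference table — gene qualifier first (closer to
   a symbol), product as fallback. The gene-qualifier spelling is also
   recorded as a variant of the same symbol, so `COX1` stays findable even
   when its product name was already known. An extraction resolving to
   nothing goes to the unmapped queue; a resolution contradicting an
   existing draft mapping is recorded as a conflict and the draft is left
   untouched.

The report counts features at the product-name check (`new_entries` +
`duplicates_skipped` + unmapped + conflicts = `features_seen`), with
gene-qualifier insertions tracked separately (`gene_variants_added`);
draft growth is exactly `new_entries + gene_variants_added`. Two
consequences tested as properties: reordering input genomes never changes
the final variant→symbol map (only provenance of first sighting), and
rebuilding over a duplicated corpus yields the identical map while
`duplicates_skipped` grows by exactly one per re-seen feature.

## Query rendering

`build_query` renders every variant of a marker exactly once as
`"<variant>"[<field>]`, canonical name first and the remainder in table
registration order, OR-joined, with an optional
`("<organism>"[Organism]) AND (...)` wrapper. Registration order (rather
than, say, alphabetical) is used because it is equally stable under
rebuilds and preserves the conventional presentation of well-known
synonym lists. Output uses plain ASCII double quotes, which the search
engines accept; variants containing a double quote are rejected at load
because no escaping dialect is defined for the query syntax. Rendering is
invertible: `parse_query` recovers the organism and the exact term set,
which the property tests use to show no synonym is lost or invented.
The clade-level genome-retrieval templates (mitochondrial and chloroplast)
are fixed strings parameterized only by the clade name.

## Synthetic corpus generator

The generator stands in for a real harvest of thousands of deposited
genomes. Each synthetic genome carries one feature per canonical marker of
its organelle (CDS for protein-coding, rRNA for ribosomal, a D-loop on
mitochondrial genomes, plus one decoy tRNA that must stay excluded), with
the product name drawn from the packaged long-name lexicon and perturbed
by three noise processes modeled on real annotation variation:

* whole-name re-casing (upper/title/lower), default rate 0.1 per name;
* hyphen↔space swaps, default rate 0.1 per separator;
* character typos (substitution/deletion/insertion), default rate 0.02 per
  alphabetic character — the order of magnitude that leaves a handful of
  misspellings in a 50-genome corpus, matching how rare genuine typos are
  in curated records.

Every planted spelling is recorded in a ground-truth map keyed by the raw
string; generation is byte-deterministic given (n, organelle, seed, rates).
Two guards keep the truth single-valued: D-loop notes receive no typos
(a D-loop feature has no gene qualifier to resolve through, so a typo
there would be unresolvable by design rather than by data), and a
perturbation that would collide with a different marker's name falls back
to the unperturbed spelling. What the generator does *not* emulate:
biologically meaningful sequences, missing or partial annotations, genomes
with absent markers, and ambiguous products shared between genes — so a
perfect rebuild score shows the pipeline's bookkeeping is exact, not that
real corpora are free of curation work (the unmapped queue exists for
that).

## Numerical and interface choices

* Canonical on-disk form is UTF-8 CSV with header
  `variant,short_name,organelle,category` and the version in a
  `# version=...` comment line (survives renames); JSON export mirrors the
  fields plus a top-level version. Load validation is total: a file either
  yields an invariant-satisfying table or raises a typed error with no
  partial state.
* Remote refresh downloads to a temporary file, validates by loading, and
  replaces the destination atomically; any failure leaves the local file
  byte-identical.
* The CLI maps each library operation to one subcommand; `fix`/`query`
  print only their payload on stdout. Exit codes: 0 success, 1 unknown
  name from `fix`, 2 usage error.
* Problem sizes in the test suite and acceptance script: 50-genome
  mitochondrial corpus (800 harvested features) for the build round trip,
  100 randomized tables for the persistence and query properties — large
  enough that every code path (dedup, typo harvesting, gene-qualifier
  variants, control region) is exercised, while the full suite runs in
  seconds.

## Known limitations

* The seed lexicon's long forms beyond the documented synonyms follow
  common INSDC annotation styles but are a curated starting set, not a
  census of GenBank; real deployments should grow the table with
  `build-db` over genuine genome downloads.
* Resolution of never-seen product names requires a human pass over the
  unmapped queue; the package does not guess.
* tRNA genes are out of scope by design; the tool is not suitable for
  tRNA-based analyses.
* Queries are rendered, not executed: no live search, counting, or rate
  limiting.
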