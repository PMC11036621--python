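"""Standardize assorted gene-name spellings to canonical short symbols.

Annotations for the same gene vary wildly between deposited genomes; every
spelling below resolves to one canonical symbol, and unknown names come
back as a falsy NotFound sentinel (logged, not raised).
"""

from syngenes import fix_gene_name, load_seed_table

table = load_seed_table()

names = [
    ("cytochrome c oxidase subunit 1", "mt"),
    ("COX1", "mt"),
    ("CYTOCHROME-B", "mt"),
    ("rrn16S", "cp"),
    ("ribulose-1,5-bisphosphate carboxylase/oxygenase large subunit", "cp"),
    ("totally unknown gene", "mt"),
]

for name, organelle in names:
    result = fix_gene_name(name, table, organelle,
                           log_path="unfound.log", verbose=False)
    print(f"{organelle}  {name!r:65s} -> {result if result else 'NOT FOUND'}")

# Each line maps one observed spelling to the symbol every downstream tool
# (gene-order analysis, alignment input preparation) should use; the miss
# was appended to unfound.log for later curation.
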