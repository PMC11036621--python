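"""Render synonym-aware advanced search queries for GenBank/PubMedCentral.

A plain search for "COI" misses records annotated under any long form; the
rendered query OR-joins every known synonym of the marker, so one search
covers them all.
"""

from syngenes import QuerySpec, build_query, esearch_url, genome_retrieval_query, load_seed_table

table = load_seed_table()

spec = QuerySpec("COI", organelle="mt", search_field="All Fields",
                 organism="Carcharodon Carcharias")
query = build_query(spec, table)
print("marker query for the white shark:")
print(" ", query)
print("as an E-utilities URL:")
print(" ", esearch_url(query, "genbank"))

# the fixed clade-level templates used to harvest whole organelle genomes:
print("\ngenome-retrieval templates:")
print(" ", genome_retrieval_query("Chordata", "mt"))
print(" ", genome_retrieval_query("Embryophyta", "cp"))

# The OR-joined string is pasted into (or sent to) the Entrez search; each
# quoted term is one known spelling of the marker, tagged with the search
# field it should match in.
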