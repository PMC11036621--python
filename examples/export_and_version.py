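"""Persist the synonym database: CSV save, JSON export, version string.

The JSON export mirrors the CSV content plus the version, so non-Python
consumers (e.g. a NodeJS web form) can use the same database.
"""

from syngenes import export_json, load_seed_table, load_table, save_csv, version_info

table = load_seed_table()
print("database version:", version_info(table))
print("entries:", len(table))

csv_path = save_csv(table, "SynGenes_copy.csv")
json_path = export_json(table)  # SynGenes/SynGenes.js by default
print("CSV written to:", csv_path)
print("JSON written to:", json_path)

reloaded = load_table(json_path, format="json")
print("JSON round trip preserves the table:", reloaded == table)

# Both files reload to the identical table (entry multiset and version),
# so either format can serve as the canonical on-disk form.
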