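"""Data model and persistence for the gene-name synonym database.

The database is a many-to-one map from observed name variants (long forms,
abbreviations, harvested typos) to canonical short names, partitioned into
two disjoint namespaces: mitochondrial (``mt``) and chloroplast (``cp``).
The canonical on-disk form is a UTF-8 CSV with header
``variant,short_name,organelle,category`` preceded by a ``# version=...``
comment line; a JSON export carries the same fields plus the version as a
top-level key.  A curated seed table covering the standard organelle marker
sets ships with the package.
"""

from __future__ import annotations

import datetime as _dt
import json
import os
import tempfile
import urllib.request
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple, Union

import pandas as pd

from .normalize import ORGANELLES, canonicalize_text

__all__ = [
    "CanonicalGene",
    "SynonymEntry",
    "SynonymTable",
    "SynGenesError",
    "SchemaError",
    "AmbiguityError",
    "UpdateError",
    "load_table",
    "save_csv",
    "export_json",
    "update_table",
    "version_info",
    "load_seed_table",
    "ORGANELLES",
]

#: Version string assigned to tables built in memory without one.
UNVERSIONED = "unreleased"


class SynGenesError(Exception):
    """Base class for synonym-database errors."""


class SchemaError(SynGenesError):
    """A file does not conform to the CSV/JSON synonym-table schema."""


class AmbiguityError(SynGenesError):
    """One normalized variant maps to two different short names."""


class UpdateError(SynGenesError):
    """A remote refresh failed; the local table is untouched (retryable)."""


@dataclass(frozen=True)
class CanonicalGene:
    """One standardized short gene symbol, e.g. ``COI`` or ``rbcL``."""

    short_name: str
    organelle: str
    category: str = ""


@dataclass(frozen=True)
class SynonymEntry:
    """One variant -> short-name mapping within an organelle namespace."""

    variant: str
    short_name: str
    organelle: str
    category: str = ""


class SynonymTable:
    """In-memory synonym database with a unique-lookup guarantee.

    Invariants enforced at construction and on every :meth:`add`:

    * within one organelle each *normalized* variant key maps to exactly
      one short name (ambiguity is a hard error, never a warning);
    * every referenced short name exists as a :class:`CanonicalGene`
      of the same organelle (the registry is derived from the entries);
    * every canonical short name is present as a variant of itself
      (self-maps are materialized on construction if absent);
    * variants never contain double quotes (no escaping dialect exists
      for the Entrez query syntax they end up in).
    """

    def __init__(
        self,
        entries: Iterable[SynonymEntry] = (),
        version: str = UNVERSIONED,
        built_at: Optional[str] = None,
    ) -> None:
        self.version = version
        self.built_at = built_at or _dt.datetime.now(
            _dt.timezone.utc
        ).isoformat(timespec="seconds")
        self._entries: List[SynonymEntry] = []
        self._index: Dict[Tuple[str, str], SynonymEntry] = {}
        for entry in entries:
            self.add(entry)
        self._materialize_self_maps()

    # -- construction ---------------------------------------------------

    def add(self, entry: SynonymEntry) -> bool:
        """Insert one entry; return True if it changed the table.

        A duplicate of an existing mapping (same normalized variant, same
        short name) is collapsed silently; a conflicting mapping raises
        :class:`AmbiguityError` naming both sides.
        """
        if entry.organelle not in ORGANELLES:
            raise SchemaError(
                f"unknown organelle code {entry.organelle!r} "
                f"(expected one of {ORGANELLES})"
            )
        if not entry.variant or not entry.variant.strip():
            raise SchemaError("empty variant name")
        if '"' in entry.variant:
            raise SchemaError(
                f"variant {entry.variant!r} contains a double quote, which "
                "cannot be rendered in an Entrez query term"
            )
        key = (entry.organelle, canonicalize_text(entry.variant))
        present = self._index.get(key)
        if present is not None:
            if present.short_name != entry.short_name:
                raise AmbiguityError(
                    f"variant {entry.variant!r} ({entry.organelle}) maps to "
                    f"both {present.short_name!r} and {entry.short_name!r}"
                )
            return False
        self._index[key] = entry
        self._entries.append(entry)
        return True

    def _materialize_self_maps(self) -> None:
        for gene in self.canonical_genes():
            self.add(
                SynonymEntry(
                    gene.short_name, gene.short_name, gene.organelle, gene.category
                )
            )

    # -- queries --------------------------------------------------------

    @property
    def entries(self) -> Tuple[SynonymEntry, ...]:
        return tuple(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SynonymTable):
            return NotImplemented
        return self.version == other.version and sorted(
            (e.variant, e.short_name, e.organelle) for e in self._entries
        ) == sorted((e.variant, e.short_name, e.organelle) for e in other._entries)

    def lookup(self, name: str, organelle: str) -> Optional[str]:
        """Return the short name for *name* in *organelle*, or None."""
        entry = self._index.get((organelle, canonicalize_text(name)))
        return entry.short_name if entry is not None else None

    def canonical_genes(self, organelle: Optional[str] = None) -> List[CanonicalGene]:
        """The distinct canonical genes referenced by the entries.

        The category of a gene is taken from the first entry that names it.
        """
        seen: Dict[Tuple[str, str], CanonicalGene] = {}
        for e in self._entries:
            key = (e.organelle, e.short_name)
            if key not in seen:
                seen[key] = CanonicalGene(e.short_name, e.organelle, e.category)
        genes = list(seen.values())
        if organelle is not None:
            genes = [g for g in genes if g.organelle == organelle]
        return genes

    def variants_of(self, short_name: str, organelle: str) -> List[str]:
        """All variants of a marker, canonical name first, then in the
        order they were registered."""
        canon_key = canonicalize_text(short_name)
        rest = [
            e.variant
            for e in self._entries
            if e.organelle == organelle
            and e.short_name == short_name
            and canonicalize_text(e.variant) != canon_key
        ]
        return [short_name] + rest

    def as_mapping(self, organelle: Optional[str] = None) -> Dict[str, str]:
        """Normalized-variant -> short-name dict, optionally one organelle."""
        return {
            key[1]: e.short_name
            for key, e in self._index.items()
            if organelle is None or key[0] == organelle
        }

    def copy(self) -> "SynonymTable":
        return SynonymTable(self._entries, version=self.version, built_at=self.built_at)


# -- persistence --------------------------------------------------------

_CSV_COLUMNS = ["variant", "short_name", "organelle", "category"]


def _read_csv_version(path: Path) -> str:
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                body = stripped.lstrip("#").strip()
                if body.startswith("version="):
                    return body[len("version=") :].strip()
                continue
            break
    return UNVERSIONED


def _load_csv(path: Path) -> SynonymTable:
    version = _read_csv_version(path)
    try:
        frame = pd.read_csv(
            path, comment="#", dtype=str, keep_default_na=False
        )
    except Exception as exc:  # pandas raises several parser error types
        raise SchemaError(f"cannot parse {path} as a synonym-table CSV: {exc}")
    missing = [c for c in _CSV_COLUMNS[:3] if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    if "category" not in frame.columns:
        frame["category"] = ""
    entries = [
        SynonymEntry(r.variant, r.short_name, r.organelle, r.category)
        for r in frame.itertuples(index=False)
    ]
    return SynonymTable(entries, version=version)


def _load_json(path: Path) -> SynonymTable:
    try:
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"cannot parse {path} as JSON: {exc}")
    if not isinstance(doc, dict) or "entries" not in doc:
        raise SchemaError(f"{path}: expected an object with an 'entries' list")
    entries = []
    for item in doc["entries"]:
        try:
            entries.append(
                SynonymEntry(
                    item["variant"],
                    item["short_name"],
                    item["organelle"],
                    item.get("category", ""),
                )
            )
        except (TypeError, KeyError) as exc:
            raise SchemaError(f"{path}: malformed entry {item!r} ({exc})")
    return SynonymTable(entries, version=str(doc.get("version", UNVERSIONED)))


def load_table(
    path: Union[str, Path], format: Optional[str] = None
) -> SynonymTable:
    """Load a synonym table from CSV or JSON.

    *format* is ``"csv"`` or ``"json"``; when omitted it is inferred from
    the file suffix (``.json``/``.js`` mean JSON, anything else CSV).
    Validation is total: the file either yields a table satisfying every
    invariant or a typed error is raised and no partial state escapes.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"synonym table not found: {path}")
    if format is None:
        format = "json" if path.suffix.lower() in (".json", ".js") else "csv"
    if format == "csv":
        return _load_csv(path)
    if format == "json":
        return _load_json(path)
    raise ValueError(f"unknown format {format!r} (expected 'csv' or 'json')")


def save_csv(table: SynonymTable, path: Union[str, Path]) -> Path:
    """Write *table* to CSV in the canonical schema; returns the path."""
    path = Path(path)
    if path.parent != Path(""):
        path.parent.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame(
        [(e.variant, e.short_name, e.organelle, e.category) for e in table.entries],
        columns=_CSV_COLUMNS,
    )
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# version={table.version}\n")
        frame.to_csv(fh, index=False)
    return path


def export_json(
    table: SynonymTable,
    file_name: str = "SynGenes.js",
    out_dir: Union[str, Path] = "SynGenes",
) -> Path:
    """Export the database as a JSON document (for non-Python consumers).

    By default the file is named ``SynGenes.js`` inside a ``SynGenes``
    folder under the current working directory.  ``load_table`` on the
    output reproduces the input table exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / file_name
    doc = {
        "version": table.version,
        "entries": [
            {
                "variant": e.variant,
                "short_name": e.short_name,
                "organelle": e.organelle,
                "category": e.category,
            }
            for e in table.entries
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, ensure_ascii=False, indent=1)
        fh.write("\n")
    return path


def update_table(
    source_url: str, destination: Union[str, Path], timeout: float = 30.0
) -> SynonymTable:
    """Refresh the local database from *source_url* (atomic replace).

    The download is written to a temporary file, validated by loading it,
    and only then moved over *destination*; on any failure — network or
    validation — the pre-existing local file is left untouched and a
    typed error is raised.  Every other operation in this package works
    offline; only this one needs the network.
    """
    destination = Path(destination)
    destination.parent.mkdir(parents=True, exist_ok=True)
    fmt = "json" if destination.suffix.lower() in (".json", ".js") else "csv"
    tmp_fd, tmp_name = tempfile.mkstemp(
        dir=destination.parent, suffix=destination.suffix
    )
    tmp_path = Path(tmp_name)
    try:
        try:
            with urllib.request.urlopen(source_url, timeout=timeout) as resp:
                payload = resp.read()
        except OSError as exc:
            raise UpdateError(f"download from {source_url} failed: {exc}")
        with os.fdopen(tmp_fd, "wb") as fh:
            fh.write(payload)
            tmp_fd = None
        table = load_table(tmp_path, format=fmt)  # SchemaError/AmbiguityError
        os.replace(tmp_path, destination)
        return table
    finally:
        if tmp_path.exists():
            try:
                tmp_path.unlink()
            except OSError:
                pass


def version_info(table: SynonymTable) -> str:
    """The stored database version string (pure accessor)."""
    return table.version


def seed_table_path() -> Path:
    """Filesystem path of the packaged seed table CSV."""
    return Path(str(resources.files("syngenes.data") / "seed_table.csv"))


def load_seed_table() -> SynonymTable:
    """Load the curated seed table shipped with the package.

    It covers the standard mitochondrial marker set (rRNAs, complex I/III/
    IV/V subunits and the control region) and the chloroplast set (rRNAs,
    ATP synthase, cytochrome b6/f, RNA polymerase, ribosomal proteins,
    NDH, photosystems, Rubisco and accessory genes), each with curated
    long-name variants.
    """
    return load_table(seed_table_path(), format="csv")


def with_version(table: SynonymTable, version: str) -> SynonymTable:
    """Copy of *table* carrying a new version string."""
    new = table.copy()
    new.version = version
    return new
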