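"""Build a synonym-table draft by scanning annotated organelle genomes.

The construction loop mirrors how name variants accumulate in public
databases: walk every genome record, pull the ``gene`` and ``product``
qualifiers of coding (CDS) and ribosomal (rRNA) features — plus control
region / D-loop features, which carry a standardized marker of their own —
and insert each previously unseen product name into the draft together
with its canonical short name.  Deduplication is keyed on the normalized
product name, so the same spelling is recorded once no matter how many
genomes carry it, while every new spelling (including genuine typos) is
harvested as a variant.

tRNA features are deliberately ignored: the synonym database covers coding
and ribosomal genes only.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import IO, Iterable, List, Optional, Sequence, Tuple, Union

from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

from .normalize import ORGANELLES, canonicalize_text
from .store import SynGenesError, SynonymEntry, SynonymTable

__all__ = [
    "RawExtraction",
    "BuildReport",
    "BuildError",
    "scan_genome",
    "accumulate",
    "build_from_files",
]

#: Feature kinds the builder harvests.
FEATURE_KINDS = ("CDS", "rRNA", "control_region")

_CONTROL_HINTS = ("control region", "d loop")


class BuildError(SynGenesError):
    """A genome file or record could not be processed."""


@dataclass(frozen=True)
class RawExtraction:
    """One (gene, product) qualifier pair pulled from a genome feature."""

    gene: Optional[str]
    product: Optional[str]
    kind: str  # one of FEATURE_KINDS
    accession: str = ""

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"kind must be one of {FEATURE_KINDS}")
        if self.gene is None and self.product is None:
            raise ValueError("extraction needs a gene or a product qualifier")

    @property
    def primary_name(self) -> str:
        """The name the dedup check keys on: product, else gene."""
        return self.product if self.product is not None else self.gene  # type: ignore[return-value]


@dataclass
class BuildReport:
    """Accounting for one build run.

    ``features_seen`` counts harvested extractions; each one ends up in
    exactly one of ``new_entries`` (its product name was new),
    ``duplicates_skipped`` (already present), ``unmapped`` (no canonical
    resolution) or ``conflicts``.  ``gene_variants_added`` counts the extra
    entries created when a gene qualifier spelling was recorded alongside
    an already-known product name.
    """

    genomes_scanned: int = 0
    features_seen: int = 0
    skipped_featureless: int = 0
    new_entries: int = 0
    duplicates_skipped: int = 0
    gene_variants_added: int = 0
    unmapped: List[RawExtraction] = dc_field(default_factory=list)
    conflicts: List[str] = dc_field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "genomes_scanned": self.genomes_scanned,
            "features_seen": self.features_seen,
            "skipped_featureless": self.skipped_featureless,
            "new_entries": self.new_entries,
            "duplicates_skipped": self.duplicates_skipped,
            "gene_variants_added": self.gene_variants_added,
            "unmapped": [
                {"gene": x.gene, "product": x.product, "kind": x.kind,
                 "accession": x.accession}
                for x in self.unmapped
            ],
            "conflicts": list(self.conflicts),
        }


def _first(qualifiers: dict, key: str) -> Optional[str]:
    values = qualifiers.get(key)
    return values[0] if values else None


def _is_control_region(text: Optional[str]) -> bool:
    if not text:
        return False
    return any(hint in canonicalize_text(text) for hint in _CONTROL_HINTS)


def _harvest(record: SeqRecord) -> Tuple[List[RawExtraction], int]:
    """Extract (gene, product) pairs; returns (extractions, n_skipped)."""
    out: List[RawExtraction] = []
    skipped = 0
    accession = record.id or record.name or ""
    for feature in record.features:
        kind: Optional[str] = None
        gene = _first(feature.qualifiers, "gene")
        product = _first(feature.qualifiers, "product")
        if feature.type in ("CDS", "rRNA"):
            kind = feature.type
        elif feature.type == "D-loop":
            kind = "control_region"
            product = product or _first(feature.qualifiers, "note") or "D-loop"
        elif feature.type == "misc_feature":
            note = product or _first(feature.qualifiers, "note")
            if _is_control_region(note):
                kind = "control_region"
                product = note
        if kind is None:
            continue  # tRNA, source, anything else: not harvested
        if gene is None and product is None:
            skipped += 1
            continue
        out.append(RawExtraction(gene, product, kind, accession))
    return out, skipped


def scan_genome(record: SeqRecord) -> List[RawExtraction]:
    """One :class:`RawExtraction` per CDS/rRNA/control-region feature.

    Order follows feature order in the record.  Features lacking both a
    ``gene`` and a ``product`` qualifier are skipped (they are counted in
    the report when scanning goes through :func:`build_from_files`).
    """
    extractions, _ = _harvest(record)
    return extractions


def _resolve(
    extraction: RawExtraction, canonical_map: SynonymTable, organelle: str
) -> Optional[Tuple[str, str]]:
    """(short_name, category) via the gene qualifier first, then product."""
    for name in (extraction.gene, extraction.product):
        if name is None:
            continue
        short = canonical_map.lookup(name, organelle)
        if short is not None:
            category = ""
            for g in canonical_map.canonical_genes(organelle):
                if g.short_name == short:
                    category = g.category
                    break
            return short, category
    return None


def accumulate(
    draft: SynonymTable,
    extraction: RawExtraction,
    canonical_map: SynonymTable,
    organelle: str,
    report: Optional[BuildReport] = None,
) -> bool:
    """Fold one extraction into the draft; True if anything was inserted.

    The product name is checked against the draft first (the dedup step);
    if absent it is inserted mapped to the canonical short name resolved
    from the gene qualifier (falling back to the product itself).  The
    gene qualifier spelling is additionally recorded as a variant so that
    symbols like ``COX1`` stay findable even when their product name was
    already known.  An extraction that resolves to nothing goes to the
    report's unmapped queue; a resolution that contradicts an existing
    draft mapping is recorded as a conflict and the draft is left alone.
    """
    if organelle not in ORGANELLES:
        raise ValueError(f"organelle must be one of {ORGANELLES}")
    report = report if report is not None else BuildReport()
    resolved = _resolve(extraction, canonical_map, organelle)
    if resolved is None:
        report.unmapped.append(extraction)
        return False
    short, category = resolved
    primary = extraction.primary_name
    existing = draft.lookup(primary, organelle)
    if existing is not None and existing != short:
        report.conflicts.append(
            f"{primary!r} ({organelle}) already maps to {existing!r}, "
            f"but {extraction.accession or 'a record'} resolves it to {short!r}"
        )
        return False
    delta = False
    if existing is None:
        draft.add(SynonymEntry(primary, short, organelle, category))
        report.new_entries += 1
        delta = True
    else:
        report.duplicates_skipped += 1
    if (
        extraction.gene is not None
        and extraction.product is not None
        and draft.lookup(extraction.gene, organelle) is None
    ):
        draft.add(SynonymEntry(extraction.gene, short, organelle, category))
        report.gene_variants_added += 1
        delta = True
    return delta


def _open_maybe_gzip(path: Path) -> IO[str]:
    if path.suffix == ".gz":
        return gzip.open(path, "rt", encoding="utf-8")
    return open(path, encoding="utf-8")


def _iter_records(path: Path, skip_bad: bool, report: BuildReport) -> Iterable[SeqRecord]:
    with _open_maybe_gzip(path) as handle:
        iterator = SeqIO.parse(handle, "genbank")
        while True:
            try:
                record = next(iterator)
            except StopIteration:
                return
            except ValueError as exc:
                if skip_bad:
                    report.conflicts.append(f"bad record in {path}: {exc}")
                    return  # parser state is unreliable past a bad record
                raise BuildError(f"unparseable record in {path}: {exc}")
            yield record


def build_from_files(
    paths: Sequence[Union[str, Path]],
    organelle: str,
    canonical_map: SynonymTable,
    draft: Optional[SynonymTable] = None,
    skip_bad: bool = False,
) -> Tuple[SynonymTable, BuildReport]:
    """Scan GenBank flat files (optionally gzipped) into a draft table.

    Equivalent to folding :func:`scan_genome` + :func:`accumulate` over
    all records in all files, in file order; deterministic for a fixed
    input order, and idempotent — rebuilding over the same corpus adds
    nothing and only grows ``duplicates_skipped``.
    """
    if organelle not in ORGANELLES:
        raise ValueError(f"organelle must be one of {ORGANELLES}")
    resolved_paths = [Path(p) for p in paths]
    missing = [str(p) for p in resolved_paths if not p.exists()]
    if missing:
        raise BuildError(f"unreadable input file(s): {', '.join(missing)}")
    draft = draft if draft is not None else SynonymTable()
    report = BuildReport()
    for path in resolved_paths:
        for record in _iter_records(path, skip_bad, report):
            report.genomes_scanned += 1
            extractions, skipped = _harvest(record)
            report.skipped_featureless += skipped
            report.features_seen += len(extractions)
            for extraction in extractions:
                accumulate(draft, extraction, canonical_map, organelle, report)
    return draft, report
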