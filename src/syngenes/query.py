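"""Render Entrez-style advanced search queries from the synonym table.

A conventional GenBank or PubMedCentral search for, say, *COI* misses every
record annotated under "cytochrome oxidase subunit I" or any other spelling.
The remedy is an advanced query that OR-joins all known synonyms of the
marker, each with an Entrez field tag::

    ("Carcharodon Carcharias"[Organism]) AND ("COI"[All Fields] OR
     "cytochrome oxidase subunit I"[All Fields] OR
     "cytochrome c oxidase subunit 1"[All Fields])

This module renders such strings from a :class:`~syngenes.store.SynonymTable`
and also carries the fixed genome-retrieval query templates used to harvest
organelle genomes by clade.  It builds strings only; it never talks to NCBI.
"""

from __future__ import annotations

import re
import urllib.parse
from dataclasses import dataclass
from typing import List, Optional, Tuple

from .normalize import ORGANELLES
from .store import SynonymTable

__all__ = [
    "QuerySpec",
    "QueryError",
    "SEARCH_FIELDS",
    "TARGET_DBS",
    "build_query",
    "genome_retrieval_query",
    "parse_query",
    "balanced",
    "esearch_url",
]

#: The supported Entrez search-field tags; "All Fields" is the default.
SEARCH_FIELDS = ("Title", "Abstract", "All Fields", "MeSH Terms")

#: Target databases the rendered query is intended for.
TARGET_DBS = ("genbank", "pmc")

#: Entrez database names for :func:`esearch_url`.
_ESEARCH_DB = {"genbank": "nucleotide", "pmc": "pmc"}

_ESEARCH_BASE = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/esearch.fcgi"


class QueryError(ValueError):
    """Raised when a query cannot be rendered from the given inputs."""


@dataclass(frozen=True)
class QuerySpec:
    """What to search for: a marker plus rendering options.

    ``short_name`` must already be in canonical form — callers standardize
    free-text names with :func:`syngenes.normalize.fix_gene_name` first.
    """

    short_name: str
    organelle: str = "mt"
    search_field: str = "All Fields"
    target_db: str = "genbank"
    organism: Optional[str] = None

    def __post_init__(self) -> None:
        if self.organelle not in ORGANELLES:
            raise QueryError(f"organelle must be one of {ORGANELLES}")
        if self.search_field not in SEARCH_FIELDS:
            raise QueryError(
                f"search_field must be one of {SEARCH_FIELDS}, "
                f"got {self.search_field!r}"
            )
        if self.target_db not in TARGET_DBS:
            raise QueryError(f"target_db must be one of {TARGET_DBS}")


def build_query(spec: QuerySpec, table: SynonymTable) -> str:
    """Render the OR-joined synonym query for one marker.

    Every variant the table knows for the marker appears exactly once as
    ``"<variant>"[<search_field>]``, canonical name first and the rest in
    table order, joined by `` OR ``.  With an organism the whole term group
    is AND-ed to ``("<organism>"[Organism])``.  Output uses plain ASCII
    double quotes, which Entrez accepts.
    """
    canonical = table.lookup(spec.short_name, spec.organelle)
    if canonical is None:
        raise QueryError(
            f"{spec.short_name!r} does not resolve for organelle "
            f"{spec.organelle!r}; standardize it first with fix_gene_name()"
        )
    variants = table.variants_of(canonical, spec.organelle)
    terms = " OR ".join(f'"{v}"[{spec.search_field}]' for v in variants)
    if spec.organism:
        return f'("{spec.organism}"[Organism]) AND ({terms})'
    return f"({terms})"


def genome_retrieval_query(clade: str, organelle: str = "mt") -> str:
    """The fixed Entrez query template for harvesting organelle genomes.

    These are the templates used to collect complete mitochondrial
    (``mt``) or chloroplast (``cp``) genome records for a clade, e.g.
    Chordata mitogenomes or Embryophyta plastomes.
    """
    if not clade or not clade.strip():
        raise QueryError("clade must be a non-empty string")
    if organelle == "mt":
        return (
            f'("{clade}"[Organism] OR "{clade}"[All Fields]) AND '
            f'("Genome"[Title]) AND '
            f'("mitochondrial"[Title] OR "mitochondrion"[Title]) AND '
            f"mitochondrion[filter]"
        )
    if organelle == "cp":
        return (
            f'("{clade}"[Organism] OR "{clade}"[All Fields]) AND '
            f'("Genome"[Title]) AND chloroplast[filter]'
        )
    raise QueryError(f"organelle must be one of {ORGANELLES}")


_TERM_RE = re.compile(r'"([^"]*)"\[([^\]]+)\]')


def parse_query(query: str) -> Tuple[Optional[str], List[Tuple[str, str]]]:
    """Parse a rendered query back into (organism, [(term, field), ...]).

    Inverse of :func:`build_query` for well-formed output; used to verify
    that rendering loses no synonym and invents none.
    """
    organism: Optional[str] = None
    terms: List[Tuple[str, str]] = []
    for text, fld in _TERM_RE.findall(query):
        if fld == "Organism":
            organism = text
        else:
            terms.append((text, fld))
    return organism, terms


def balanced(query: str) -> bool:
    """True when parentheses pair up and double quotes come in pairs."""
    depth = 0
    in_quote = False
    for ch in query:
        if ch == '"':
            in_quote = not in_quote
        elif not in_quote:
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
                if depth < 0:
                    return False
    return depth == 0 and not in_quote


def esearch_url(query: str, target_db: str = "genbank") -> str:
    """Percent-encoded E-utilities esearch URL for a rendered query."""
    if target_db not in TARGET_DBS:
        raise QueryError(f"target_db must be one of {TARGET_DBS}")
    params = urllib.parse.urlencode(
        {"db": _ESEARCH_DB[target_db], "term": query}
    )
    return f"{_ESEARCH_BASE}?{params}"
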