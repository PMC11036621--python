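"""Canonicalization of raw gene-name strings and lookup against a synonym table.

Gene names harvested from annotated organelle genomes differ in case,
hyphenation and spacing far more often than in substance ("ATP-synthase",
"ATP synthase", "atp_synthase").  All lookups therefore go through a single
normalized key: lower-cased, surrounding quotes removed, hyphens and
underscores folded to spaces, whitespace runs collapsed.  Matching is exact
on that key — deliberately no fuzzy or edit-distance matching, because real
typos ("cytchrome", "cutochrome") are treated as first-class variants to be
harvested into the database, not spellings to be guessed at.
"""

from __future__ import annotations

import datetime as _dt
import re
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Union

if TYPE_CHECKING:  # pragma: no cover
    from .store import SynonymTable

__all__ = [
    "canonicalize_text",
    "fix_gene_name",
    "NotFound",
    "NOT_FOUND",
    "ORGANELLES",
    "DEFAULT_LOG_PATH",
]

#: The two gene namespaces: mitochondrial and chloroplast.
ORGANELLES = ("mt", "cp")

#: Default append-only log of failed lookups, in the working directory.
DEFAULT_LOG_PATH = "SynGenes_unfound.log"

_WS_RE = re.compile(r"\s+")
# Opening quote -> the closing quote that must pair with it.  Lone
# apostrophes are left alone so symbols like beta' survive.
_QUOTE_PAIRS = {'"': '"', "'": "'", "“": "”", "‘": "’"}


@dataclass(frozen=True)
class NotFound:
    """Sentinel returned by :func:`fix_gene_name` for a failed lookup.

    Falsy, so callers can write ``if not result: ...``.
    """

    raw_name: str = ""
    organelle: str = "mt"

    def __bool__(self) -> bool:  # pragma: no cover - trivial
        return False


#: Generic instance for identity checks (``result is NOT_FOUND`` is wrong —
#: compare with ``isinstance(result, NotFound)`` or truthiness instead).
NOT_FOUND = NotFound()


def canonicalize_text(raw: str) -> str:
    """Return the normalized lookup key for *raw*.

    The transform is deterministic and idempotent: trim, strip paired
    surrounding quotes, fold ``-`` and ``_`` to spaces, collapse internal
    whitespace, lower-case.  Digits, dots and Roman-numeral letters pass
    through unchanged, so "rrn4.5S" and "COIII" keep their identity.
    An input that folds away entirely (e.g. ``"-"``) falls back to its
    trimmed lower-case form so that non-blank input never yields an empty
    key.
    """
    s = raw.strip()
    while len(s) >= 2 and s[0] in _QUOTE_PAIRS and s[-1] == _QUOTE_PAIRS[s[0]]:
        s = s[1:-1].strip()
    folded = s.replace("-", " ").replace("_", " ")
    folded = _WS_RE.sub(" ", folded).strip().lower()
    if not folded and raw.strip():
        return raw.strip().lower()
    return folded


def _append_unfound(log_path: Union[str, Path], name: str, organelle: str) -> None:
    """Append one tab-separated miss record: timestamp, organelle, raw name."""
    stamp = _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds")
    path = Path(log_path)
    if path.parent != Path(""):
        path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "a", encoding="utf-8") as fh:
        fh.write(f"{stamp}\t{organelle}\t{name}\n")


def fix_gene_name(
    name: str,
    table: "SynonymTable",
    organelle: str = "mt",
    log_path: Union[str, Path] = DEFAULT_LOG_PATH,
    verbose: bool = True,
) -> Union[str, NotFound]:
    """Resolve *name* to its canonical short name within one organelle.

    Parameters
    ----------
    name:
        The gene name to standardize, in any spelling the table knows.
    table:
        A loaded :class:`~syngenes.store.SynonymTable`.
    organelle:
        ``"mt"`` (mitochondrial, the default) or ``"cp"`` (chloroplast).
        The two namespaces are fully isolated: "16S" is a mitochondrial
        marker while the chloroplast equivalent is "rrn16S".
    log_path:
        File that accumulates one line per failed lookup.
    verbose:
        Print a human-readable message to stderr; never changes the
        return value.

    Returns
    -------
    The canonical short name on a hit, or a falsy :class:`NotFound`
    sentinel on a miss.  A miss is an expected outcome, not an error:
    it is logged to *log_path* and the sentinel is returned.
    """
    if not isinstance(name, str) or not name.strip():
        raise ValueError("gene name must be a non-empty string")
    if organelle not in ORGANELLES:
        raise ValueError(f"organelle must be one of {ORGANELLES}, got {organelle!r}")
    short = table.lookup(name, organelle)
    if short is not None:
        if verbose:
            print(f"[syngenes] {name!r} ({organelle}) -> {short}", file=sys.stderr)
        return short
    _append_unfound(log_path, name, organelle)
    if verbose:
        print(
            f"[syngenes] {name!r} not found for organelle {organelle!r}; "
            f"logged to {log_path}",
            file=sys.stderr,
        )
    return NotFound(raw_name=name, organelle=organelle)
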