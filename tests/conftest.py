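import string

import pytest
from hypothesis import strategies as st

from syngenes.store import (
    AmbiguityError,
    SynonymEntry,
    SynonymTable,
    load_seed_table,
)

CANONICAL_POOL = ["COI", "CYTB", "ND1", "ATP6", "16S", "rbcL", "matK", "atpA"]

_VARIANT_ALPHABET = string.ascii_letters + string.digits + " -_./,'"


@pytest.fixture(scope="session")
def seed_table() -> SynonymTable:
    return load_seed_table()


@pytest.fixture()
def tiny_table() -> SynonymTable:
    """COI with the two long-form synonyms from the worked example."""
    return SynonymTable(
        [
            SynonymEntry("COI", "COI", "mt", "Mitochondrial Complex IV"),
            SynonymEntry("cytochrome oxidase subunit I", "COI", "mt"),
            SynonymEntry("cytochrome c oxidase subunit 1", "COI", "mt"),
        ]
    )


def variant_text() -> st.SearchStrategy[str]:
    return st.text(alphabet=_VARIANT_ALPHABET, min_size=1, max_size=40).filter(
        lambda s: s.strip()
    )


@st.composite
def synonym_tables(draw) -> SynonymTable:
    """Random valid tables: consistent, quote-free, 1-30 raw entries."""
    raw = draw(
        st.lists(
            st.tuples(
                variant_text(),
                st.sampled_from(CANONICAL_POOL),
                st.sampled_from(["mt", "cp"]),
                st.text(alphabet=string.ascii_letters + " ", max_size=15),
            ),
            min_size=1,
            max_size=30,
        )
    )
    probe = SynonymTable()
    entries = []
    for variant, short, organelle, category in raw:
        try:
            if probe.add(SynonymEntry(variant, short, organelle, category)):
                entries.append(SynonymEntry(variant, short, organelle, category))
        except AmbiguityError:
            continue
    version = draw(
        st.text(alphabet=string.ascii_lowercase + string.digits + ".-", min_size=1, max_size=12)
    )
    return SynonymTable(entries, version=version)
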