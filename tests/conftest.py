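import datetime as dt

import numpy as np
import pytest

from patmine.corpus import FilterCriteria, PatentDocument
from patmine.concepts import Lexicon, MappingBundle


def make_doc(doc_id="US0000001", year=2000, month=6, day=1, title="A device",
             abstract="", claims="", uspc=None, cpc=None):
    return PatentDocument(
        doc_id=doc_id,
        grant_date=dt.date(year, month, day),
        title=title,
        abstract=abstract,
        claims=claims,
        uspc_codes=uspc or [],
        cpc_codes=cpc or ["A61K31/00"],
    )


@pytest.fixture
def criteria():
    return FilterCriteria(
        date_start=dt.date(1995, 1, 1),
        date_end=dt.date(2017, 12, 31),
        uspc_allowlist=frozenset({"424", "514"}),
        cpc_allowlist=frozenset({"A61K", "A61B"}),
        match_mode="prefix",
    )


@pytest.fixture
def diabetes_lexicon():
    lex = Lexicon()
    lex.add("type 2 diabetes", "C0011860")
    lex.add("diabetes mellitus", "C0011849")
    lex.add("type 2 diabetes mellitus", "C0011860")
    lex.add("obesity", "C0028754")
    return lex


@pytest.fixture
def simple_bundle():
    """C0011849/C0011860 -> root 250 (definitive); C0028754 -> {278, 279}
    (ambiguous); C0999999 unmapped."""
    bundle = MappingBundle(
        cui_to_icd9={
            "C0011849": {"250.00"},
            "C0011860": {"250.00", "250.02"},
            "C0028754": {"278.0", "279.0"},
        },
        icd9_to_phecode={
            "250.00": {"250.2"},
            "250.02": {"250.2"},
            "278.0": {"278.1"},
            "279.0": {"279.1"},
        },
        phecode_to_root={
            "250.2": "250",
            "250": "250",
            "278.1": "278",
            "278": "278",
            "279.1": "279",
            "279": "279",
        },
    )
    bundle.validate()
    return bundle


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
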