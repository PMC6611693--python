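"""Patent corpus I/O and biomedical filtering.

Reads granted-patent records from two dialects — a simplified patent XML
(one ``<patent>`` element per document) and a JSON-lines record dialect —
and filters them to a biomedical subcorpus by grant-date window and
USPC/CPC classification allowlists.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from lxml import etree

logger = logging.getLogger(__name__)

__all__ = [
    "PatentDocument",
    "FilterCriteria",
    "FilterReport",
    "EmptyCorpusError",
    "read_corpus",
    "write_corpus",
    "is_biomedical",
    "filter_corpus",
]


class EmptyCorpusError(ValueError):
    """Raised when a corpus file yields zero parseable documents."""


@dataclass
class PatentDocument:
    """One granted patent: identifier, grant date, text sections, class codes."""

    doc_id: str
    grant_date: dt.date
    title: str = ""
    abstract: str = ""
    claims: str = ""
    uspc_codes: list[str] = field(default_factory=list)
    cpc_codes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")
        if not (self.title or self.abstract or self.claims):
            raise ValueError(f"document {self.doc_id}: all text sections empty")

    @property
    def year(self) -> int:
        return self.grant_date.year

    def sections(self) -> dict[str, str]:
        return {"title": self.title, "abstract": self.abstract, "claims": self.claims}


@dataclass(frozen=True)
class FilterCriteria:
    """Inclusion criteria: grant-date window plus USPC/CPC allowlists.

    A document passes when its grant date lies in ``[date_start, date_end]``
    (inclusive) and at least one of its USPC or CPC codes matches the union
    of the two allowlists.  ``match_mode="prefix"`` matches a code whose
    string begins with an allowlist pattern; ``"exact"`` requires equality.
    """

    date_start: dt.date
    date_end: dt.date
    uspc_allowlist: frozenset[str] = frozenset()
    cpc_allowlist: frozenset[str] = frozenset()
    match_mode: str = "prefix"

    def __post_init__(self) -> None:
        if self.date_start > self.date_end:
            raise ValueError("date_start must be <= date_end")
        if not (self.uspc_allowlist or self.cpc_allowlist):
            raise ValueError("allowlists must not both be empty")
        if self.match_mode not in ("exact", "prefix"):
            raise ValueError(f"unknown match_mode {self.match_mode!r}")
        object.__setattr__(self, "uspc_allowlist", frozenset(self.uspc_allowlist))
        object.__setattr__(self, "cpc_allowlist", frozenset(self.cpc_allowlist))


@dataclass
class FilterReport:
    """Bookkeeping for one filtering pass."""

    n_total: int = 0
    n_pass_date: int = 0
    n_pass_code: int = 0
    n_biomedical: int = 0
    per_year_counts: dict[int, tuple[int, int]] = field(default_factory=dict)

    def add(self, year: int, biomedical: bool) -> None:
        total, bio = self.per_year_counts.get(year, (0, 0))
        self.per_year_counts[year] = (total + 1, bio + int(biomedical))

    def per_year_csv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("year,total,biomedical,fraction\n")
            for year in sorted(self.per_year_counts):
                total, bio = self.per_year_counts[year]
                frac = bio / total if total else 0.0
                fh.write(f"{year},{total},{bio},{frac:.6f}\n")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_total": self.n_total,
            "n_pass_date": self.n_pass_date,
            "n_pass_code": self.n_pass_code,
            "n_biomedical": self.n_biomedical,
            "per_year_counts": {
                str(y): list(v) for y, v in sorted(self.per_year_counts.items())
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def _parse_date(raw: str) -> dt.date:
    raw = raw.strip()
    if len(raw) == 8 and raw.isdigit():
        return dt.date(int(raw[:4]), int(raw[4:6]), int(raw[6:8]))
    return dt.date.fromisoformat(raw)


_FIELDS = ("doc_number", "date", "title", "abstract", "claims")


def _doc_from_record(rec: dict) -> PatentDocument:
    return PatentDocument(
        doc_id=str(rec["doc_number"]),
        grant_date=_parse_date(str(rec["date"])),
        title=rec.get("title", "") or "",
        abstract=rec.get("abstract", "") or "",
        claims=rec.get("claims", "") or "",
        uspc_codes=[str(c) for c in rec.get("uspc", [])],
        cpc_codes=[str(c) for c in rec.get("cpc", [])],
    )


def _iter_xml(path: Path, skipped: list[str]) -> Iterator[PatentDocument]:
    for _, elem in etree.iterparse(str(path), tag="patent"):
        rec: dict = {"uspc": [], "cpc": []}
        for child in elem:
            tag = child.tag.replace("-", "_")
            text = child.text or ""
            if tag in ("uspc", "cpc"):
                rec[tag].append(text.strip())
            elif tag in _FIELDS:
                rec[tag] = text
        try:
            yield _doc_from_record(rec)
        except (KeyError, ValueError) as exc:
            skipped.append(str(exc))
            logger.warning("skipping malformed patent element: %s", exc)
        elem.clear(keep_tail=True)


def _iter_records(path: Path, skipped: list[str]) -> Iterator[PatentDocument]:
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                yield _doc_from_record(json.loads(line))
            except (json.JSONDecodeError, KeyError, ValueError) as exc:
                skipped.append(f"line {lineno}: {exc}")
                logger.warning("skipping malformed record at line %d: %s", lineno, exc)


def read_corpus(
    path: str | Path,
    dialect: str = "records",
    skipped: list[str] | None = None,
) -> Iterator[PatentDocument]:
    """Stream documents from ``path`` in file order.

    Malformed records are skipped with a logged warning (and appended to
    ``skipped`` if a list is supplied), never fatal.  Raises
    :class:`EmptyCorpusError` if the file yields no parseable document.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sink = skipped if skipped is not None else []
    if dialect in ("xml", "patent-xml"):
        it = _iter_xml(path, sink)
    elif dialect == "records":
        it = _iter_records(path, sink)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    n = 0
    for doc in it:
        n += 1
        yield doc
    if n == 0:
        raise EmptyCorpusError(f"no parseable records in {path}")


def write_corpus(
    docs: Iterable[PatentDocument], path: str | Path, dialect: str = "records"
) -> int:
    """Write documents to ``path``; returns the number written."""
    path = Path(path)
    n = 0
    if dialect in ("xml", "patent-xml"):
        root = etree.Element("patents")
        for doc in docs:
            el = etree.SubElement(root, "patent")
            etree.SubElement(el, "doc-number").text = doc.doc_id
            etree.SubElement(el, "date").text = doc.grant_date.strftime("%Y%m%d")
            etree.SubElement(el, "title").text = doc.title
            etree.SubElement(el, "abstract").text = doc.abstract
            etree.SubElement(el, "claims").text = doc.claims
            for c in doc.uspc_codes:
                etree.SubElement(el, "uspc").text = c
            for c in doc.cpc_codes:
                etree.SubElement(el, "cpc").text = c
            n += 1
        etree.ElementTree(root).write(
            str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8"
        )
    elif dialect == "records":
        with open(path, "w", encoding="utf-8") as fh:
            for doc in docs:
                rec = {
                    "doc_number": doc.doc_id,
                    "date": doc.grant_date.strftime("%Y%m%d"),
                    "title": doc.title,
                    "abstract": doc.abstract,
                    "claims": doc.claims,
                    "uspc": doc.uspc_codes,
                    "cpc": doc.cpc_codes,
                }
                fh.write(json.dumps(rec, sort_keys=True) + "\n")
                n += 1
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return n


def _code_matches(codes: Sequence[str], allow: frozenset[str], mode: str) -> bool:
    if not allow:
        return False
    if mode == "exact":
        return any(c in allow for c in codes)
    return any(c.startswith(p) for c in codes for p in allow)


def is_biomedical(doc: PatentDocument, criteria: FilterCriteria) -> bool:
    """True iff the grant date is inside the window and a class code matches."""
    if doc.grant_date is None:  # defensive: parse layer normally rejects these
        logger.warning("document %s has no parseable grant date; rejected", doc.doc_id)
        return False
    if not (criteria.date_start <= doc.grant_date <= criteria.date_end):
        return False
    return _code_matches(
        doc.uspc_codes, criteria.uspc_allowlist, criteria.match_mode
    ) or _code_matches(doc.cpc_codes, criteria.cpc_allowlist, criteria.match_mode)


def filter_corpus(
    docs: Iterable[PatentDocument], criteria: FilterCriteria
) -> tuple[list[PatentDocument], FilterReport]:
    """Apply :func:`is_biomedical` to a stream, preserving order.

    Returns the passing documents and a :class:`FilterReport` whose counts
    reconcile with the output length.
    """
    report = FilterReport()
    out: list[PatentDocument] = []
    for doc in docs:
        report.n_total += 1
        in_date = criteria.date_start <= doc.grant_date <= criteria.date_end
        has_code = _code_matches(
            doc.uspc_codes, criteria.uspc_allowlist, criteria.match_mode
        ) or _code_matches(doc.cpc_codes, criteria.cpc_allowlist, criteria.match_mode)
        report.n_pass_date += int(in_date)
        report.n_pass_code += int(has_code)
        ok = in_date and has_code
        report.add(doc.year, ok)
        if ok:
            report.n_biomedical += 1
            out.append(doc)
    return out, report
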