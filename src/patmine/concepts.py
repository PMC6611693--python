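"""Disease concept recognition and PheCode rollup.

A dictionary recognizer (greedy longest match, left to right, token
boundaries, case-insensitive) finds disease mentions in patent text and a
mapping bundle rolls each concept identifier (CUI) up to root PheCodes
through CUI -> ICD-9-CM -> PheCode -> root PheCode tables.  A rollup is
*definitive* when it lands on exactly one root PheCode (one-to-one or
many-to-one) and *ambiguous* when several roots remain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .corpus import PatentDocument
from .preprocess import tokenize

logger = logging.getLogger(__name__)

__all__ = [
    "Lexicon",
    "MappingBundle",
    "ConceptMention",
    "DiseaseAnnotation",
    "MappingAudit",
    "recognize",
    "match_tokens",
    "rollup",
    "annotate_corpus",
    "mapping_audit",
]


@dataclass
class Lexicon:
    """Surface term -> CUI dictionary; multiword terms stored token-split."""

    entries: dict[tuple[str, ...], str] = field(default_factory=dict)
    case_insensitive: bool = True

    def add(self, term: str, cui: str) -> None:
        key = tuple(
            t.lower() if self.case_insensitive else t for t in tokenize(term)
        )
        if not key:
            raise ValueError(f"empty lexicon term for CUI {cui}")
        existing = self.entries.get(key)
        if existing is not None and existing != cui:
            raise ValueError(f"term {term!r} maps to both {existing} and {cui}")
        self.entries[key] = cui

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def cuis(self) -> set[str]:
        return set(self.entries.values())

    @property
    def max_term_tokens(self) -> int:
        return max((len(k) for k in self.entries), default=0)

    @classmethod
    def from_tsv(cls, path: str | Path, case_insensitive: bool = True) -> "Lexicon":
        """Tab-separated columns (term, cui); '#' comment lines ignored."""
        lex = cls(case_insensitive=case_insensitive)
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            term, cui = line.split("\t")[:2]
            lex.add(term, cui.strip())
        return lex

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("# term\tcui\n")
            for key in sorted(self.entries):
                fh.write(f"{' '.join(key)}\t{self.entries[key]}\n")


def _read_pairs(path: str | Path) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        src, dst = line.split("\t")[:2]
        out.setdefault(src.strip(), set()).add(dst.strip())
    return out


@dataclass
class MappingBundle:
    """CUI -> ICD-9 -> PheCode -> root PheCode tables, with an optional
    ICD-10 -> ICD-9 bridge for claims-derived inputs."""

    cui_to_icd9: dict[str, set[str]] = field(default_factory=dict)
    icd9_to_phecode: dict[str, set[str]] = field(default_factory=dict)
    phecode_to_root: dict[str, str] = field(default_factory=dict)
    icd10_to_icd9: dict[str, set[str]] = field(default_factory=dict)

    def validate(self) -> None:
        for icd9, phecodes in self.icd9_to_phecode.items():
            for p in phecodes:
                if p not in self.phecode_to_root:
                    raise ValueError(
                        f"PheCode {p} (from ICD-9 {icd9}) has no root PheCode"
                    )
        for p, r in self.phecode_to_root.items():
            if r in self.phecode_to_root and self.phecode_to_root[r] != r:
                raise ValueError(f"root PheCode {r} does not map to itself")

    @classmethod
    def from_files(
        cls,
        cui2icd9: str | Path,
        icd92phe: str | Path,
        phe2root: str | Path,
        icd102icd9: str | Path | None = None,
    ) -> "MappingBundle":
        phe2root_pairs = _read_pairs(phe2root)
        roots: dict[str, str] = {}
        for p, targets in phe2root_pairs.items():
            if len(targets) != 1:
                raise ValueError(f"PheCode {p} maps to multiple roots: {targets}")
            roots[p] = next(iter(targets))
        bundle = cls(
            cui_to_icd9=_read_pairs(cui2icd9),
            icd9_to_phecode=_read_pairs(icd92phe),
            phecode_to_root=roots,
            icd10_to_icd9=_read_pairs(icd102icd9) if icd102icd9 else {},
        )
        bundle.validate()
        return bundle

    def icd10_to_root(self, icd10: str) -> frozenset[str]:
        """Bridge an ICD-10-CM code to root PheCodes via ICD-9-CM."""
        roots: set[str] = set()
        for icd9 in self.icd10_to_icd9.get(icd10, ()):  # absent -> empty
            for phe in self.icd9_to_phecode.get(icd9, ()):
                roots.add(self.phecode_to_root[phe])
        return frozenset(roots)


@dataclass(frozen=True)
class ConceptMention:
    doc_id: str
    section: str
    surface: str
    cui: str
    token_span: tuple[int, int]  # 0-based, half-open


@dataclass
class DiseaseAnnotation:
    doc_id: str
    root_phecodes: frozenset[str]
    ambiguous: bool  # any contributing mention had an ambiguous rollup


def match_tokens(
    tokens: list[str], lexicon: Lexicon
) -> list[tuple[int, int, str]]:
    """Greedy longest-match over a token sequence.

    Returns (start, end, cui) triples, non-overlapping, left to right.
    Shorter matches inside an accepted longer match are suppressed.
    """
    if lexicon.case_insensitive:
        probe = [t.lower() for t in tokens]
    else:
        probe = tokens
    out: list[tuple[int, int, str]] = []
    n = len(probe)
    max_len = lexicon.max_term_tokens
    i = 0
    while i < n:
        hit = None
        for length in range(min(max_len, n - i), 0, -1):
            cui = lexicon.entries.get(tuple(probe[i : i + length]))
            if cui is not None:
                hit = (i, i + length, cui)
                break
        if hit is not None:
            out.append(hit)
            i = hit[1]
        else:
            i += 1
    return out


def recognize(doc: PatentDocument, lexicon: Lexicon) -> list[ConceptMention]:
    """Find lexicon mentions in title, abstract, and claims."""
    if len(lexicon) == 0:
        raise ValueError("lexicon is empty")
    mentions: list[ConceptMention] = []
    for section, text in doc.sections().items():
        tokens = tokenize(text)
        for start, end, cui in match_tokens(tokens, lexicon):
            mentions.append(
                ConceptMention(
                    doc_id=doc.doc_id,
                    section=section,
                    surface=" ".join(tokens[start:end]),
                    cui=cui,
                    token_span=(start, end),
                )
            )
    return mentions


def rollup(cui: str, bundle: MappingBundle) -> tuple[frozenset[str], bool]:
    """Compose CUI -> ICD-9 set -> PheCode set -> root PheCode set.

    Returns the root set and whether the mapping is definitive (exactly one
    root).  CUIs absent from the bundle return ``(frozenset(), False)``.
    """
    icd9s = bundle.cui_to_icd9.get(cui)
    if not icd9s:
        return frozenset(), False
    roots: set[str] = set()
    for icd9 in sorted(icd9s):
        for phe in sorted(bundle.icd9_to_phecode.get(icd9, ())):
            root = bundle.phecode_to_root.get(phe)
            if root is None:
                raise ValueError(f"PheCode {phe} has no root PheCode in bundle")
            roots.add(root)
    return frozenset(roots), len(roots) == 1


def annotate_corpus(
    docs: Iterable[PatentDocument],
    lexicon: Lexicon,
    bundle: MappingBundle,
    ambiguity_policy: str = "all",
) -> Iterator[DiseaseAnnotation]:
    """Per document, union root PheCodes over all mentions.

    ``ambiguity_policy="all"`` keeps every candidate root of an ambiguous
    rollup; ``"drop"`` discards ambiguous mentions entirely.  Documents
    without any disease mention yield an annotation with an empty set.
    """
    if ambiguity_policy not in ("all", "drop"):
        raise ValueError(f"unknown ambiguity_policy {ambiguity_policy!r}")
    for doc in docs:
        roots: set[str] = set()
        any_ambiguous = False
        for mention in recognize(doc, lexicon):
            mention_roots, definitive = rollup(mention.cui, bundle)
            if not mention_roots:
                continue
            if not definitive:
                any_ambiguous = True
                if ambiguity_policy == "drop":
                    continue
            roots.update(mention_roots)
        yield DiseaseAnnotation(
            doc_id=doc.doc_id, root_phecodes=frozenset(roots), ambiguous=any_ambiguous
        )


def write_annotations(
    annotations: Iterable[DiseaseAnnotation], path: str | Path
) -> None:
    """Tab-separated (doc_id, root_phecode) rows, one row per pair; documents
    with no roots emit a single row with an empty phecode column."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("doc_id\troot_phecode\n")
        for ann in annotations:
            if ann.root_phecodes:
                for root in sorted(ann.root_phecodes):
                    fh.write(f"{ann.doc_id}\t{root}\n")
            else:
                fh.write(f"{ann.doc_id}\t\n")


def read_annotations(path: str | Path) -> list[DiseaseAnnotation]:
    per_doc: dict[str, set[str]] = {}
    order: list[str] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("doc_id"):
            raise ValueError(f"{path}: missing annotation header")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            doc_id, _, root = line.partition("\t")
            if doc_id not in per_doc:
                per_doc[doc_id] = set()
                order.append(doc_id)
            if root:
                per_doc[doc_id].add(root)
    return [
        DiseaseAnnotation(doc_id=d, root_phecodes=frozenset(per_doc[d]), ambiguous=False)
        for d in order
    ]


@dataclass
class MappingAudit:
    n_total: int
    n_mapped: int
    n_definitive: int
    n_ambiguous: int
    n_unmapped: int

    @property
    def definitive_pct(self) -> float | None:
        """Percentage of mapped CUIs whose rollup is definitive; None when no
        CUI maps at all (undefined)."""
        if self.n_mapped == 0:
            return None
        return 100.0 * self.n_definitive / self.n_mapped

    @property
    def ambiguous_pct(self) -> float | None:
        if self.n_mapped == 0:
            return None
        return 100.0 * self.n_ambiguous / self.n_mapped


def mapping_audit(bundle: MappingBundle, cuis: Iterable[str]) -> MappingAudit:
    """Classify each CUI's rollup as definitive, ambiguous, or unmapped."""
    cuis = set(cuis)
    if not cuis:
        raise ValueError("mapping_audit requires a non-empty CUI set")
    n_def = n_amb = n_unmapped = 0
    for cui in cuis:
        roots, definitive = rollup(cui, bundle)
        if not roots:
            n_unmapped += 1
        elif definitive:
            n_def += 1
        else:
            n_amb += 1
    return MappingAudit(
        n_total=len(cuis),
        n_mapped=n_def + n_amb,
        n_definitive=n_def,
        n_ambiguous=n_amb,
        n_unmapped=n_unmapped,
    )
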