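"""Text preprocessing for topic modeling.

Fixed order of operations: (1) multiword concept recognition and CUI
substitution, (2) tokenization on non-alphanumeric boundaries,
(3) lowercasing, (4) stop-word removal, (5) rule-based suffix
lemmatization.  Everything is deterministic; CUI tokens are atomic and
exempt from lowercasing/lemmatization so compound concepts such as
"type 2 diabetes" survive the bag-of-words conversion intact.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Sequence, TYPE_CHECKING

if TYPE_CHECKING:
    from .concepts import Lexicon
    from .corpus import PatentDocument

logger = logging.getLogger(__name__)

__all__ = [
    "TokenizedDoc",
    "tokenize",
    "default_stopwords",
    "load_stopwords",
    "LemmaRules",
    "default_lemma_rules",
    "load_lemma_rules",
    "preprocess_docs",
]

_TOKEN_RE = re.compile(r"[A-Za-z0-9]+")
_CUI_RE = re.compile(r"^C\d{7}$")


def tokenize(text: str) -> list[str]:
    """Split on non-alphanumeric boundaries; keeps original case."""
    return _TOKEN_RE.findall(text)


def is_cui_token(token: str) -> bool:
    return bool(_CUI_RE.match(token))


@dataclass
class TokenizedDoc:
    doc_id: str
    year: int
    tokens: list[str]


def load_stopwords(path: str | Path) -> frozenset[str]:
    """One term per line; blank lines and '#' comments ignored."""
    words = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            words.add(line.lower())
    return frozenset(words)


def default_stopwords() -> frozenset[str]:
    with resources.as_file(
        resources.files("patmine.data").joinpath("stopwords.txt")
    ) as p:
        return load_stopwords(p)


@dataclass
class LemmaRules:
    """Ordered suffix-rewrite rules: first matching rule wins.

    A rule (suffix, replacement) applies only when the remaining stem has at
    least ``min_stem`` characters, which keeps short function words intact
    ("was" is not stemmed to "wa" ... it is, unless stoplisted; the guard
    protects genuinely short stems like "is").
    """

    rules: list[tuple[str, str]] = field(default_factory=list)
    min_stem: int = 3

    def apply(self, token: str) -> str:
        for suffix, repl in self.rules:
            if token.endswith(suffix) and len(token) - len(suffix) >= self.min_stem:
                return token[: len(token) - len(suffix)] + repl
        return token


def load_lemma_rules(path: str | Path) -> LemmaRules:
    """Tab-separated (suffix, replacement) pairs, ordered; '#' comments."""
    rules = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        suffix = parts[0]
        repl = parts[1] if len(parts) > 1 else ""
        rules.append((suffix, repl))
    return LemmaRules(rules=rules)


def default_lemma_rules() -> LemmaRules:
    with resources.as_file(
        resources.files("patmine.data").joinpath("lemma_rules.tsv")
    ) as p:
        return load_lemma_rules(p)


def _encode_section(text: str, lexicon: "Lexicon | None") -> list[str]:
    """Tokenize one section, replacing recognized concept spans by CUI tokens."""
    tokens = tokenize(text)
    if lexicon is None or not tokens:
        return tokens
    from .concepts import match_tokens

    out: list[str] = []
    i = 0
    matches = {m[0]: m for m in match_tokens(tokens, lexicon)}
    while i < len(tokens):
        if i in matches:
            start, end, cui = matches[i]
            out.append(cui)
            i = end
        else:
            out.append(tokens[i])
            i += 1
    return out


def preprocess_doc(
    doc: "PatentDocument",
    lexicon: "Lexicon | None" = None,
    stopwords: frozenset[str] | None = None,
    lemma_rules: LemmaRules | None = None,
) -> TokenizedDoc:
    if stopwords is None:
        stopwords = default_stopwords()
    if lemma_rules is None:
        lemma_rules = default_lemma_rules()
    tokens: list[str] = []
    for section_text in doc.sections().values():
        for tok in _encode_section(section_text, lexicon):
            if is_cui_token(tok):
                tokens.append(tok)
                continue
            low = tok.lower()
            if low in stopwords:
                continue
            tokens.append(lemma_rules.apply(low))
    return TokenizedDoc(doc_id=doc.doc_id, year=doc.year, tokens=tokens)


def preprocess_docs(
    docs: Iterable["PatentDocument"],
    lexicon: "Lexicon | None" = None,
    stopwords: frozenset[str] | None = None,
    lemma_rules: LemmaRules | None = None,
) -> Iterator[TokenizedDoc]:
    """Preprocess a document stream; empty token lists are yielded (the
    matrix builder drops and logs them)."""
    if stopwords is None:
        stopwords = default_stopwords()
    if lemma_rules is None:
        lemma_rules = default_lemma_rules()
    for doc in docs:
        yield preprocess_doc(doc, lexicon, stopwords, lemma_rules)
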