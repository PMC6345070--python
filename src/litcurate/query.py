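"""Boolean query language: parsing, per-portal translation and evaluation.

One query syntax covers every portal: case-insensitive terms, exact phrases
in double quotes, uppercase AND/OR/NOT operators, and parentheses for
priority, e.g.::

    (morphology OR "neuromorpho.org") AND "neuronal reconstruction"

Precedence is NOT > AND > OR with left associativity; adjacent atoms with
no operator between them are joined by an implicit AND.  Lowercase "and",
"or" and "not" are ordinary search terms.  The parsed tree is translated
into each portal's dialect (word joiners, phrase delimiters, capability
checks such as portals that lack NOT) and can be evaluated directly against
full text, which is how the mock portal answers queries.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence, Union

__all__ = [
    "Term",
    "Phrase",
    "Not",
    "And",
    "Or",
    "QueryNode",
    "PortalDialect",
    "DEFAULT_DIALECT",
    "ParseError",
    "CapabilityError",
    "parse_query",
    "validate_for_portal",
    "translate",
    "evaluate",
    "expand_lemma",
]


class ParseError(ValueError):
    """Malformed query text; ``position`` is the 0-based character offset."""

    def __init__(self, message: str, position: int):
        self.position = position
        super().__init__(f"{message} (at position {position})")


class CapabilityError(ValueError):
    """Query uses a construct the portal's dialect cannot express."""


@dataclass(frozen=True)
class Term:
    text: str

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError("empty term")


@dataclass(frozen=True)
class Phrase:
    text: str

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError("empty phrase")


@dataclass(frozen=True)
class Not:
    child: "QueryNode"


@dataclass(frozen=True)
class And:
    children: tuple["QueryNode", ...]

    def __post_init__(self) -> None:
        if len(self.children) < 2:
            raise ValueError("AND needs >= 2 children")


@dataclass(frozen=True)
class Or:
    children: tuple["QueryNode", ...]

    def __post_init__(self) -> None:
        if len(self.children) < 2:
            raise ValueError("OR needs >= 2 children")


QueryNode = Union[Term, Phrase, Not, And, Or]


@dataclass(frozen=True)
class PortalDialect:
    """Per-portal capabilities and serialization rules.

    ``word_joiner`` replaces the spaces inside multi-word phrases (Nature,
    for instance, wants '+' between words); ``supports_not`` is False for
    portals like Google Scholar; ``html_scrape`` dialects only run when
    scraping is explicitly enabled (off by default).
    """

    name: str
    supports_not: bool = True
    word_joiner: str = " "
    phrase_delimiters: tuple[str, str] = ('"', '"')
    date_granularity: str = "year_month_day"  # year | year_month | year_month_day
    payload_format: str = "json"  # xml | json | html_scrape
    scraping_enabled: bool = False
    api_root: str = ""
    page_size: int = 100
    active: bool = True
    access_token_ref: Optional[str] = None
    target_collection: str = "default"

    def __post_init__(self) -> None:
        if self.payload_format not in ("xml", "json", "html_scrape"):
            raise ValueError(f"unknown payload_format {self.payload_format!r}")
        if self.date_granularity not in ("year", "year_month", "year_month_day"):
            raise ValueError(f"unknown date_granularity {self.date_granularity!r}")


DEFAULT_DIALECT = PortalDialect(name="default")


# ---------------------------------------------------------------------------
# tokenizer + recursive-descent parser
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r'\s*(?:(?P<lparen>\()|(?P<rparen>\))|(?P<quote>")|(?P<word>[^\s()"]+))')


@dataclass(frozen=True)
class _Tok:
    kind: str  # LPAREN RPAREN PHRASE WORD AND OR NOT
    text: str
    pos: int


def _tokenize(text: str) -> list[_Tok]:
    toks: list[_Tok] = []
    i = 0
    n = len(text)
    while i < n:
        m = _TOKEN_RE.match(text, i)
        if m is None:  # only trailing whitespace remains
            break
        if m.end() == i and not m.group(0):
            break
        start = m.start(m.lastgroup) if m.lastgroup else m.start()
        if m.group("lparen"):
            toks.append(_Tok("LPAREN", "(", start))
            i = m.end()
        elif m.group("rparen"):
            toks.append(_Tok("RPAREN", ")", start))
            i = m.end()
        elif m.group("quote"):
            close = text.find('"', m.end())
            if close == -1:
                raise ParseError("unbalanced quote", start)
            payload = text[m.end() : close]
            if not payload.strip():
                raise ParseError("empty phrase", start)
            toks.append(_Tok("PHRASE", " ".join(payload.split()), start))
            i = close + 1
        else:
            w = m.group("word")
            if w in ("AND", "OR", "NOT"):
                toks.append(_Tok(w, w, start))
            else:
                toks.append(_Tok("WORD", w, start))
            i = m.end()
    return toks


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.toks = _tokenize(text)
        self.i = 0

    def peek(self) -> Optional[_Tok]:
        return self.toks[self.i] if self.i < len(self.toks) else None

    def next(self) -> Optional[_Tok]:
        t = self.peek()
        if t is not None:
            self.i += 1
        return t

    def parse(self) -> QueryNode:
        if not self.toks:
            raise ParseError("empty query", 0)
        node = self.or_expr()
        leftover = self.peek()
        if leftover is not None:
            raise ParseError(f"unexpected {leftover.text!r}", leftover.pos)
        return node

    def or_expr(self) -> QueryNode:
        parts = [self.and_expr()]
        while (t := self.peek()) is not None and t.kind == "OR":
            self.next()
            parts.append(self.and_expr())
        return parts[0] if len(parts) == 1 else _flat_or(parts)

    def and_expr(self) -> QueryNode:
        parts = [self.not_expr()]
        while (t := self.peek()) is not None:
            if t.kind == "AND":
                self.next()
                parts.append(self.not_expr())
            elif t.kind in ("WORD", "PHRASE", "LPAREN", "NOT"):
                # implicit AND between adjacent atoms
                parts.append(self.not_expr())
            else:
                break
        return parts[0] if len(parts) == 1 else _flat_and(parts)

    def not_expr(self) -> QueryNode:
        t = self.peek()
        if t is not None and t.kind == "NOT":
            self.next()
            return Not(self.not_expr())
        return self.atom()

    def atom(self) -> QueryNode:
        t = self.next()
        if t is None:
            prev = self.toks[self.i - 2] if self.i >= 2 else None
            pos = (prev.pos + len(prev.text)) if prev else len(self.text)
            raise ParseError("dangling operator", pos)
        if t.kind == "WORD":
            return Term(t.text)
        if t.kind == "PHRASE":
            return Phrase(t.text)
        if t.kind == "LPAREN":
            node = self.or_expr()
            close = self.next()
            if close is None or close.kind != "RPAREN":
                raise ParseError("unbalanced parenthesis", t.pos)
            return node
        if t.kind in ("AND", "OR"):
            raise ParseError(f"dangling operator {t.text!r}", t.pos)
        raise ParseError(f"unexpected {t.text!r}", t.pos)


def _flat_and(parts: Sequence[QueryNode]) -> And:
    out: list[QueryNode] = []
    for p in parts:
        out.extend(p.children) if isinstance(p, And) else out.append(p)
    return And(tuple(out))


def _flat_or(parts: Sequence[QueryNode]) -> Or:
    out: list[QueryNode] = []
    for p in parts:
        out.extend(p.children) if isinstance(p, Or) else out.append(p)
    return Or(tuple(out))


def parse_query(text: str) -> QueryNode:
    """Parse query text into an AST (NOT > AND > OR, parentheses override)."""
    if not text or not text.strip():
        raise ParseError("empty query", 0)
    return _Parser(text).parse()


# ---------------------------------------------------------------------------
# dialect validation + translation
# ---------------------------------------------------------------------------


def validate_for_portal(ast: QueryNode, dialect: PortalDialect) -> None:
    """Raise CapabilityError if the AST uses a construct the portal lacks."""
    if isinstance(ast, Not):
        if not dialect.supports_not:
            raise CapabilityError(f"portal {dialect.name!r} does not support NOT")
        validate_for_portal(ast.child, dialect)
    elif isinstance(ast, (And, Or)):
        for c in ast.children:
            validate_for_portal(c, dialect)


def _serialize(node: QueryNode, dialect: PortalDialect, *, top: bool) -> str:
    if isinstance(node, Term):
        return node.text
    if isinstance(node, Phrase):
        open_, close = dialect.phrase_delimiters
        payload = node.text
        if dialect.word_joiner != " ":
            payload = payload.replace(" ", dialect.word_joiner)
        return f"{open_}{payload}{close}"
    if isinstance(node, Not):
        return "NOT " + _serialize(node.child, dialect, top=False)
    op = " AND " if isinstance(node, And) else " OR "
    inner = op.join(_serialize(c, dialect, top=False) for c in node.children)
    return inner if top else f"({inner})"


def translate(ast: QueryNode, dialect: PortalDialect = DEFAULT_DIALECT) -> str:
    """Serialize an AST into the portal's query string.

    Deterministic; with the default dialect, ``parse_query(translate(ast))``
    reproduces the AST structurally.
    """
    validate_for_portal(ast, dialect)
    return _serialize(ast, dialect, top=True)


# ---------------------------------------------------------------------------
# lemma expansion + evaluation
# ---------------------------------------------------------------------------

_SIBILANT = ("s", "x", "z", "ch", "sh")


def expand_lemma(term: str) -> set[str]:
    """Singular/plural variants of a single token by English suffix rules.

    The rules only fire on recognised suffixes (-ies/-es/-s and their
    inverses); a word like "sheep" expands to itself alone.  Real portals do
    richer lemmatization (and PubMed adds MeSH synonyms) server-side; this
    table is what the mock portal's evaluator applies.
    """
    t = term.casefold()
    out = {t}
    if t.endswith("ies") and len(t) > 3:
        out.add(t[:-3] + "y")
    elif t.endswith("es") and len(t) > 2 and t[:-2].endswith(_SIBILANT):
        out.add(t[:-2])
    elif t.endswith("s") and not t.endswith("ss") and len(t) > 1:
        out.add(t[:-1])
    if t.endswith("y") and len(t) > 1 and t[-2] not in "aeiou":
        out.add(t[:-1] + "ies")
    elif t.endswith(_SIBILANT) and not t.endswith("s"):
        out.add(t + "es")
    return out


def _normalize_text(document: str) -> str:
    return " ".join(document.casefold().split())


def _occurs(needle: str, haystack: str) -> bool:
    """Whole-token occurrence: the needle must not abut word characters."""
    pattern = r"(?<!\w)" + re.escape(needle) + r"(?!\w)"
    return re.search(pattern, haystack) is not None


def evaluate(ast: QueryNode, document: str, lemma_expansion: bool = False) -> bool:
    """Evaluate a query against plain full text.

    Case-insensitive; phrases require a contiguous match on
    whitespace-normalized text (punctuation inside a phrase must match
    literally); with ``lemma_expansion`` a term matches any of its
    singular/plural variants.  Pure function of its inputs.
    """
    text = _normalize_text(document)

    def ev(node: QueryNode) -> bool:
        if isinstance(node, Term):
            variants = expand_lemma(node.text) if lemma_expansion else {node.text.casefold()}
            return any(_occurs(v, text) for v in variants)
        if isinstance(node, Phrase):
            return _occurs(_normalize_text(node.text), text)
        if isinstance(node, Not):
            return not ev(node.child)
        if isinstance(node, And):
            return all(ev(c) for c in node.children)
        return any(ev(c) for c in node.children)

    return ev(ast)
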