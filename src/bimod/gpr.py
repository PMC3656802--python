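"""Gene-protein-reaction (GPR) rules.

A GPR rule is a boolean expression over gene identifiers that states which
gene products are needed to catalyse a reaction.  ``and`` joins subunits of
an enzyme complex, ``or`` joins alternative enzymes (isozymes).  Internally
every rule is normalised to disjunctive normal form: a set of complexes,
each complex a non-empty frozenset of gene IDs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable

__all__ = ["GPRRule", "parse_gpr", "GPRParseError"]


class GPRParseError(ValueError):
    """Raised when a gene-association string cannot be parsed."""


@dataclass(frozen=True)
class GPRRule:
    """OR-of-ANDs gene association: ``disjuncts`` is a frozenset of complexes,
    each complex a non-empty frozenset of gene IDs (matched case-sensitively).
    """

    disjuncts: frozenset[frozenset[str]]

    def __post_init__(self) -> None:
        if not self.disjuncts:
            raise ValueError("GPRRule needs at least one complex")
        if any(len(c) == 0 for c in self.disjuncts):
            raise ValueError("GPRRule complexes must be non-empty")

    @classmethod
    def from_complexes(cls, complexes: Iterable[Iterable[str]]) -> "GPRRule":
        return cls(frozenset(frozenset(c) for c in complexes))

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(g for c in self.disjuncts for g in c)

    def evaluate(self, present: set[str]) -> bool:
        """Truth value of the rule when exactly ``present`` genes are on."""
        return any(c <= present for c in self.disjuncts)

    def render(self) -> str:
        """Canonical string form, re-parseable by :func:`parse_gpr`."""
        parts = []
        for c in sorted(self.disjuncts, key=lambda c: sorted(c)):
            inner = " and ".join(sorted(c))
            parts.append(f"({inner})" if len(c) > 1 else inner)
        return " or ".join(parts)


_TOKEN = re.compile(r"\s*(\(|\)|and\b|AND\b|And\b|or\b|OR\b|Or\b|[^\s()]+)")


def _tokenize(text: str) -> list[str]:
    tokens, pos = [], 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            break
        tok = m.group(1)
        low = tok.lower()
        tokens.append(low if low in ("and", "or") else tok)
        pos = m.end()
    if text[pos:].strip():
        raise GPRParseError(f"unparseable trailing text in GPR: {text[pos:]!r}")
    return tokens


def parse_gpr(text: str) -> GPRRule | None:
    """Parse a boolean gene-association string into a :class:`GPRRule`.

    Grammar: ``expr := term (or term)*; term := factor (and factor)*;
    factor := gene | ( expr )``.  Gene IDs are any whitespace-free token that
    is not a keyword or parenthesis; matching is case-sensitive for genes but
    not for the ``and`` / ``or`` keywords.  Returns ``None`` for an empty or
    whitespace-only string.
    """
    tokens = _tokenize(text)
    if not tokens:
        return None
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take(expected: str | None = None) -> str:
        nonlocal pos
        if pos >= len(tokens):
            raise GPRParseError(f"unexpected end of GPR string: {text!r}")
        tok = tokens[pos]
        if expected is not None and tok != expected:
            raise GPRParseError(f"expected {expected!r} but found {tok!r} in {text!r}")
        pos += 1
        return tok

    def expr() -> frozenset[frozenset[str]]:
        result = term()
        while peek() == "or":
            take("or")
            result = result | term()
        return result

    def term() -> frozenset[frozenset[str]]:
        # AND distributes over the OR-of-ANDs of both operands
        result = factor()
        while peek() == "and":
            take("and")
            rhs = factor()
            result = frozenset(a | b for a in result for b in rhs)
        return result

    def factor() -> frozenset[frozenset[str]]:
        tok = peek()
        if tok == "(":
            take("(")
            inner = expr()
            take(")")
            return inner
        if tok in (")", "and", "or", None):
            raise GPRParseError(f"unexpected token {tok!r} in GPR {text!r}")
        take()
        return frozenset({frozenset({tok})})

    disjuncts = expr()
    if pos != len(tokens):
        raise GPRParseError(f"unconsumed tokens {tokens[pos:]!r} in GPR {text!r}")
    return GPRRule(disjuncts)
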