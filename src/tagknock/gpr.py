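"""Gene-protein-reaction (GPR) rule parsing and evaluation.

A GPR rule is a boolean expression over gene identifiers using ``and`` /
``or`` (case-insensitive) and parentheses.  ``or`` joins isozymes — any one
gene suffices; ``and`` joins complex subunits — all are required.  ``and``
binds tighter than ``or``, following the convention of genome-scale model
exchange formats.
"""

from __future__ import annotations

from typing import Iterable

__all__ = ["GPRParseError", "parse_gpr", "evaluate_gpr", "gpr_genes", "gpr_to_string"]


class GPRParseError(ValueError):
    """Raised for a malformed GPR expression; carries the token position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


# AST nodes are tuples: ("gene", id) | ("and", [nodes]) | ("or", [nodes])


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        if ch == "(":
            tokens.append(("LPAREN", ch, i))
            i += 1
        elif ch == ")":
            tokens.append(("RPAREN", ch, i))
            i += 1
        else:
            j = i
            while j < n and not text[j].isspace() and text[j] not in "()":
                j += 1
            word = text[i:j]
            low = word.lower()
            if low == "and":
                tokens.append(("AND", word, i))
            elif low == "or":
                tokens.append(("OR", word, i))
            else:
                tokens.append(("ID", word, i))
            i = j
    return tokens


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.pos = 0

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self):
        tok = self.peek()
        if tok is None:
            raise GPRParseError("unexpected end of expression", len(self.text))
        self.pos += 1
        return tok

    def parse(self):
        node = self.expr()
        tok = self.peek()
        if tok is not None:
            raise GPRParseError(f"unexpected token {tok[1]!r}", tok[2])
        return node

    def expr(self):
        terms = [self.term()]
        while self.peek() is not None and self.peek()[0] == "OR":
            self.next()
            terms.append(self.term())
        return terms[0] if len(terms) == 1 else ("or", terms)

    def term(self):
        factors = [self.factor()]
        while self.peek() is not None and self.peek()[0] == "AND":
            self.next()
            factors.append(self.factor())
        return factors[0] if len(factors) == 1 else ("and", factors)

    def factor(self):
        tok = self.next()
        kind, word, pos = tok
        if kind == "LPAREN":
            node = self.expr()
            closing = self.next()
            if closing[0] != "RPAREN":
                raise GPRParseError("expected ')'", closing[2])
            return node
        if kind == "ID":
            return ("gene", word)
        raise GPRParseError(f"unexpected token {word!r}", pos)


def parse_gpr(text: str | None):
    """Parse a GPR rule into an AST; ``None``/blank input parses to ``None``."""
    if text is None or not text.strip():
        return None
    return _Parser(text).parse()


def _eval(node, deleted: set) -> bool:
    kind = node[0]
    if kind == "gene":
        return node[1] not in deleted
    values = (_eval(child, deleted) for child in node[1])
    return all(values) if kind == "and" else any(values)


def evaluate_gpr(association: str | None, deleted_genes: Iterable[str]) -> bool:
    """True iff the reaction can still be catalyzed after deleting the genes.

    Each gene leaf evaluates true iff the gene is *not* deleted.  An absent
    or empty association means the reaction needs no gene and is always
    catalyzable.
    """
    node = parse_gpr(association)
    if node is None:
        return True
    return _eval(node, set(deleted_genes))


def gpr_genes(association: str | None) -> list[str]:
    """Gene ids in the rule, first-occurrence order, deduplicated."""
    node = parse_gpr(association)
    seen: dict[str, None] = {}

    def walk(n):
        if n[0] == "gene":
            seen.setdefault(n[1])
        else:
            for child in n[1]:
                walk(child)

    if node is not None:
        walk(node)
    return list(seen)


def gpr_to_string(node) -> str:
    """Canonical text form of a GPR AST (full parenthesization of groups)."""
    if node is None:
        return ""
    kind = node[0]
    if kind == "gene":
        return node[1]
    sep = f" {kind} "
    parts = []
    for child in node[1]:
        text = gpr_to_string(child)
        # 'and' binds tighter than 'or', so only 'or' groups under an 'and'
        # need explicit parentheses
        if kind == "and" and child[0] == "or":
            text = f"({text})"
        parts.append(text)
    return sep.join(parts)


def normalize_gpr(text: str | None) -> str | None:
    """Canonical string form of a rule, or None for an empty rule."""
    node = parse_gpr(text)
    return gpr_to_string(node) if node is not None else None
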