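"""Gene-protein-reaction (GPR) rules.

A GPR rule is a Boolean expression over gene identifiers that states which
gene products are needed for a reaction to be catalysed, e.g.
``(g1 and g2) or g3`` for an isoenzyme of a two-subunit complex.  Besides
Boolean evaluation, the same tree is evaluated over continuous expression
values with the usual convention AND = min (a complex is limited by its
scarcest subunit) and OR = max (isoenzymes add alternatives).

Grammar: identifiers plus case-insensitive ``and`` / ``or`` with
parentheses.  ``or`` binds weaker than ``and``.  Identifiers are any run of
characters that is not whitespace, a parenthesis, or a bare and/or keyword.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional

__all__ = ["GPR", "parse_gpr", "GPRParseError"]


class GPRParseError(ValueError):
    """Raised when a GPR rule string cannot be parsed."""


class GPR:
    """Node of a GPR expression tree.

    ``op`` is one of ``"gene"``, ``"and"``, ``"or"``.  Leaf nodes carry the
    gene identifier in ``gene``; internal nodes carry ≥ 2 ``children``.
    """

    __slots__ = ("op", "gene", "children")

    def __init__(self, op: str, gene: Optional[str] = None,
                 children: Optional[Iterable["GPR"]] = None):
        if op not in ("gene", "and", "or"):
            raise ValueError(f"invalid GPR op {op!r}")
        self.op = op
        self.gene = gene
        self.children: tuple[GPR, ...] = tuple(children or ())
        if op == "gene":
            if not gene:
                raise ValueError("gene node requires a gene identifier")
        elif len(self.children) < 2:
            raise ValueError(f"{op} node requires at least two children")

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def gene_(name: str) -> "GPR":
        return GPR("gene", gene=name)

    @staticmethod
    def and_(*children: "GPR") -> "GPR":
        return GPR("and", children=children)

    @staticmethod
    def or_(*children: "GPR") -> "GPR":
        return GPR("or", children=children)

    # -- queries --------------------------------------------------------------
    def genes(self) -> frozenset[str]:
        if self.op == "gene":
            return frozenset((self.gene,))
        out: set[str] = set()
        for c in self.children:
            out |= c.genes()
        return frozenset(out)

    def value(self, values: Mapping[str, float]) -> Optional[float]:
        """Evaluate the tree over per-gene values.

        AND = min of child values, OR = max.  A gene absent from ``values``
        (or mapped to None) is dropped from OR nodes and makes the enclosing
        AND node evaluate to None (no data): a complex with an unmeasured
        subunit cannot be scored, an isoenzyme set can.
        """
        if self.op == "gene":
            v = values.get(self.gene)
            return None if v is None else v
        child = [c.value(values) for c in self.children]
        if self.op == "and":
            if any(v is None for v in child):
                return None
            return min(child)
        present = [v for v in child if v is not None]
        return max(present) if present else None

    def __eq__(self, other) -> bool:
        if not isinstance(other, GPR):
            return NotImplemented
        return (self.op == other.op and self.gene == other.gene
                and self.children == other.children)

    def __hash__(self):
        return hash((self.op, self.gene, self.children))

    def to_string(self) -> str:
        if self.op == "gene":
            return self.gene
        sep = f" {self.op} "
        parts = []
        for c in self.children:
            s = c.to_string()
            # parenthesise an OR child under AND to keep precedence explicit
            if c.op != "gene" and c.op != self.op:
                s = f"({s})"
            parts.append(s)
        return sep.join(parts)

    def __repr__(self):
        return f"GPR<{self.to_string()}>"


def _tokenize(rule: str) -> list[str]:
    tokens: list[str] = []
    cur = []
    for ch in rule:
        if ch in "()":
            if cur:
                tokens.append("".join(cur))
                cur = []
            tokens.append(ch)
        elif ch.isspace():
            if cur:
                tokens.append("".join(cur))
                cur = []
        else:
            cur.append(ch)
    if cur:
        tokens.append("".join(cur))
    return tokens


def parse_gpr(rule: Optional[str]) -> Optional[GPR]:
    """Parse a GPR rule string into a :class:`GPR` tree.

    Returns None for an empty/whitespace rule (reaction with no gene
    association).  Raises :class:`GPRParseError` on malformed input.
    """
    if rule is None:
        return None
    tokens = _tokenize(rule)
    if not tokens:
        return None
    pos = 0

    def peek() -> Optional[str]:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> GPR:
        terms = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            take()
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else GPR("or", children=terms)

    def parse_and() -> GPR:
        factors = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            take()
            factors.append(parse_atom())
        return factors[0] if len(factors) == 1 else GPR("and", children=factors)

    def parse_atom() -> GPR:
        tok = peek()
        if tok is None:
            raise GPRParseError(f"unexpected end of rule in {rule!r}")
        if tok == "(":
            take()
            node = parse_or()
            if peek() != ")":
                raise GPRParseError(f"unbalanced parenthesis in {rule!r}")
            take()
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GPRParseError(f"unexpected token {tok!r} in {rule!r}")
        return GPR.gene_(take())

    node = parse_or()
    if pos != len(tokens):
        raise GPRParseError(f"trailing tokens {tokens[pos:]!r} in {rule!r}")
    return node
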