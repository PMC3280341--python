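"""Class expressions, axioms and the in-memory ontology model.

The model is a deliberately small algebra over OWL class expressions:
named classes, quantified object restrictions (``some``, ``only``,
``exactly/min/max n``), negation, intersection and disjunction.  It is
rich enough to express every construct discussed in the audit — the
all-some translation of an OBO relationship, value-restriction
substitutes, negated parthood/participation, and nested restrictions
such as ``has_realization only (has_input some X)``.

Expressions serialize to (and parse back from) a compact Manchester-like
syntax, e.g. ``part_of some Hindlimb`` or
``not (participant_of some Post-translational protein modification)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Optional, Union

__all__ = [
    "Quantifier",
    "ClassExpression",
    "Named",
    "Restriction",
    "Not",
    "And",
    "Or",
    "SubClassOfAxiom",
    "OboTerm",
    "Ontology",
    "serialize_expression",
    "serialize_axiom",
    "parse_expression",
    "ExpressionParseError",
]

CURIE_RE = re.compile(r"^[A-Za-z_]+:[A-Za-z0-9_.-]+$")


class Quantifier(Enum):
    """Quantifier of an object restriction."""

    SOME = "some"
    ONLY = "only"
    EXACTLY = "exactly"
    MIN = "min"
    MAX = "max"


@dataclass(frozen=True)
class Named:
    """A named class, identified by CURIE when present, else by label.

    Equality follows that identification rule: two named classes are
    equal when their CURIEs match (if both have one) or, failing that,
    when their labels match.
    """

    curie: Optional[str] = None
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.curie is None and self.label is None:
            raise ValueError("Named class needs a CURIE or a label")

    @property
    def key(self) -> str:
        return self.curie if self.curie is not None else self.label  # type: ignore[return-value]

    @property
    def display(self) -> str:
        return self.label if self.label is not None else self.curie  # type: ignore[return-value]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Named):
            return NotImplemented
        if self.curie is not None and other.curie is not None:
            return self.curie == other.curie
        return self.key == other.key

    def __hash__(self) -> int:
        return hash(self.key)


@dataclass(frozen=True)
class Restriction:
    relation: str
    quantifier: Quantifier
    filler: "ClassExpression"
    cardinality: Optional[int] = None

    def __post_init__(self) -> None:
        needs_n = self.quantifier in (Quantifier.EXACTLY, Quantifier.MIN, Quantifier.MAX)
        if needs_n and (self.cardinality is None or self.cardinality < 0):
            raise ValueError(f"{self.quantifier.value} restriction needs cardinality n >= 0")
        if not needs_n and self.cardinality is not None:
            raise ValueError(f"{self.quantifier.value} restriction takes no cardinality")


@dataclass(frozen=True)
class Not:
    expr: "ClassExpression"


@dataclass(frozen=True)
class And:
    operands: tuple["ClassExpression", ...]

    def __post_init__(self) -> None:
        if len(self.operands) < 2:
            raise ValueError("And needs >= 2 operands")


@dataclass(frozen=True)
class Or:
    operands: tuple["ClassExpression", ...]

    def __post_init__(self) -> None:
        if len(self.operands) < 2:
            raise ValueError("Or needs >= 2 operands")


ClassExpression = Union[Named, Restriction, Not, And, Or]


@dataclass(frozen=True)
class SubClassOfAxiom:
    """``subject SubClassOf superclass`` with a named subject."""

    subject: Named
    superclass: ClassExpression
    source_ontology: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.subject, Named):
            raise ValueError("axiom subject must be a named class")


@dataclass
class OboTerm:
    id: str
    name: Optional[str] = None
    parents: list[str] = field(default_factory=list)
    relationships: list[tuple[str, str]] = field(default_factory=list)
    obsolete: bool = False

    def __post_init__(self) -> None:
        if not CURIE_RE.match(self.id):
            raise ValueError(f"term id is not a CURIE: {self.id!r}")


@dataclass
class Ontology:
    ontology_id: str = ""
    terms: dict[str, OboTerm] = field(default_factory=dict)
    axioms: list[SubClassOfAxiom] = field(default_factory=list)
    relations: set[str] = field(default_factory=set)
    inverses: dict[str, str] = field(default_factory=dict)

    def add_term(self, term: OboTerm) -> None:
        if term.id in self.terms:
            raise ValueError(f"duplicate term id {term.id}")
        self.terms[term.id] = term

    def add_axiom(self, axiom: SubClassOfAxiom) -> None:
        self.axioms.append(axiom)
        for rel in iter_relations(axiom.superclass):
            self.relations.add(rel)

    def label_of(self, curie: str) -> Optional[str]:
        term = self.terms.get(curie)
        return term.name if term is not None else None


def iter_subexpressions(expr: ClassExpression) -> Iterator[ClassExpression]:
    """Depth-first pre-order walk of an expression tree."""
    yield expr
    if isinstance(expr, Restriction):
        yield from iter_subexpressions(expr.filler)
    elif isinstance(expr, Not):
        yield from iter_subexpressions(expr.expr)
    elif isinstance(expr, (And, Or)):
        for op in expr.operands:
            yield from iter_subexpressions(op)


def iter_asserted_existentials(expr: ClassExpression) -> Iterator[Restriction]:
    """SOME restrictions in dependence-asserting positions only.

    A ``some`` clause under a negation or inside the filler of an
    ``only``/``max`` restriction makes no existence claim for instances
    of the subject class, so those contexts are not entered.  This is
    the scan behind the "asserts no ontological dependence" checks.
    """
    if isinstance(expr, Restriction):
        if expr.quantifier is Quantifier.SOME:
            yield expr
        if expr.quantifier in (Quantifier.SOME, Quantifier.EXACTLY, Quantifier.MIN):
            yield from iter_asserted_existentials(expr.filler)
    elif isinstance(expr, (And, Or)):
        for op in expr.operands:
            yield from iter_asserted_existentials(op)
    # Not(...) and only/max fillers: no existence claim, do not descend


def iter_relations(expr: ClassExpression) -> Iterator[str]:
    for sub in iter_subexpressions(expr):
        if isinstance(sub, Restriction):
            yield sub.relation


# ---------------------------------------------------------------------------
# Compact Manchester-style serialization
# ---------------------------------------------------------------------------

def _is_compound(expr: ClassExpression) -> bool:
    return not isinstance(expr, Named)


def _paren_operand(expr: ClassExpression) -> str:
    """Render an And/Or operand: compound members are parenthesized,
    except ``not (...)`` which delimits itself."""
    s = serialize_expression(expr)
    if isinstance(expr, (Restriction, And, Or)):
        return f"({s})"
    return s


def _paren_filler(expr: ClassExpression) -> str:
    """Render a restriction filler. Named classes and ``not X`` forms are
    self-delimiting; everything else is parenthesized."""
    s = serialize_expression(expr)
    if isinstance(expr, (Restriction, And, Or)):
        return f"({s})"
    return s


def serialize_expression(expr: ClassExpression) -> str:
    """Deterministic compact-syntax rendering of a class expression.

    ``Restriction(part_of, SOME, Hindlimb)`` -> ``"part_of some Hindlimb"``;
    ``Not(Restriction(has_part, SOME, Tail))`` -> ``"not (has_part some Tail)"``.
    """
    if isinstance(expr, Named):
        return expr.display
    if isinstance(expr, Restriction):
        if expr.quantifier in (Quantifier.EXACTLY, Quantifier.MIN, Quantifier.MAX):
            head = f"{expr.relation} {expr.quantifier.value} {expr.cardinality}"
        else:
            head = f"{expr.relation} {expr.quantifier.value}"
        return f"{head} {_paren_filler(expr.filler)}"
    if isinstance(expr, Not):
        inner = expr.expr
        if isinstance(inner, Named):
            return f"not {serialize_expression(inner)}"
        return f"not ({serialize_expression(inner)})"
    if isinstance(expr, And):
        return " and ".join(_paren_operand(op) for op in expr.operands)
    if isinstance(expr, Or):
        return " or ".join(_paren_operand(op) for op in expr.operands)
    raise TypeError(f"not a class expression: {expr!r}")


def serialize_axiom(axiom: SubClassOfAxiom) -> str:
    return f"{axiom.subject.display} subClassOf {serialize_expression(axiom.superclass)}"


# ---------------------------------------------------------------------------
# Compact-syntax parser (round-trip checks, report ingestion)
# ---------------------------------------------------------------------------

class ExpressionParseError(ValueError):
    pass


_KEYWORDS = {"some", "only", "exactly", "min", "max", "and", "or", "not"}
_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def _tokenize(text: str) -> list[str]:
    return _TOKEN_RE.findall(text)


class _Parser:
    """Recursive-descent parser for the compact syntax.

    Class names may contain spaces (``Anti-ulcer drug``); a run of plain
    words is read greedily until a keyword, parenthesis or end of input.
    A word run immediately followed by a quantifier keyword is a relation
    name, otherwise it is a named-class label.
    """

    def __init__(self, tokens: list[str]):
        self.tokens = tokens
        self.pos = 0

    def peek(self) -> Optional[str]:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise ExpressionParseError("unexpected end of expression")
        self.pos += 1
        return tok

    def parse(self) -> ClassExpression:
        expr = self.parse_or()
        if self.peek() is not None:
            raise ExpressionParseError(f"trailing tokens at {self.peek()!r}")
        return expr

    def parse_or(self) -> ClassExpression:
        ops = [self.parse_and()]
        while self.peek() == "or":
            self.take()
            ops.append(self.parse_and())
        return ops[0] if len(ops) == 1 else Or(tuple(ops))

    def parse_and(self) -> ClassExpression:
        ops = [self.parse_unary()]
        while self.peek() == "and":
            self.take()
            ops.append(self.parse_unary())
        return ops[0] if len(ops) == 1 else And(tuple(ops))

    def parse_unary(self) -> ClassExpression:
        if self.peek() == "not":
            self.take()
            return Not(self.parse_unary())
        return self.parse_primary()

    def parse_primary(self) -> ClassExpression:
        tok = self.peek()
        if tok == "(":
            self.take()
            expr = self.parse_or()
            if self.take() != ")":
                raise ExpressionParseError("expected ')'")
            return expr
        words: list[str] = []
        while (tok := self.peek()) is not None and tok not in _KEYWORDS and tok not in "()":
            words.append(self.take())
        if not words:
            raise ExpressionParseError(f"expected a name at {self.peek()!r}")
        name = " ".join(words)
        nxt = self.peek()
        if nxt in ("some", "only"):
            quant = Quantifier(self.take())
            filler = self.parse_unary()
            return Restriction(name, quant, filler)
        if nxt in ("exactly", "min", "max"):
            quant = Quantifier(self.take())
            n_tok = self.take()
            if not n_tok.isdigit():
                raise ExpressionParseError(f"cardinality must be an integer, got {n_tok!r}")
            filler = self.parse_unary()
            return Restriction(name, quant, filler, cardinality=int(n_tok))
        if CURIE_RE.match(name) and " " not in name:
            return Named(curie=name)
        return Named(label=name)


def parse_expression(text: str) -> ClassExpression:
    """Parse compact-syntax text back into an expression tree.

    Inverse of :func:`serialize_expression` on expressions whose names
    contain no syntax keywords; a single-token CURIE-shaped name parses
    as a CURIE, any other name as a label.
    """
    tokens = _tokenize(text)
    if not tokens:
        raise ExpressionParseError("empty expression")
    return _Parser(tokens).parse()
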