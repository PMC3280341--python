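"""OWL 2 functional-syntax subset reader and writer.

The audit only needs ``SubClassOf`` axioms whose subject is a named
class and whose superclass is built from ``ObjectSomeValuesFrom``,
``ObjectAllValuesFrom``, ``ObjectExactCardinality`` /
``ObjectMinCardinality`` / ``ObjectMaxCardinality``,
``ObjectComplementOf``, ``ObjectIntersectionOf`` and ``ObjectUnionOf``
over named classes.  Any other axiom kind (EquivalentClasses, property
axioms, ...) is counted in a skip report rather than silently dropped.
``AnnotationAssertion(rdfs:label ...)`` is consumed to attach labels so
a write/read cycle preserves class identity.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Optional

from .expressions import (
    And,
    ClassExpression,
    Named,
    Not,
    Ontology,
    Or,
    Quantifier,
    Restriction,
    SubClassOfAxiom,
    iter_subexpressions,
)

__all__ = ["read_owl_axioms", "write_owl_functional", "SkipReport", "OwlParseError"]

log = logging.getLogger(__name__)


class OwlParseError(ValueError):
    pass


@dataclass
class SkipReport:
    """Axioms encountered but outside the supported subset, by kind."""

    skipped: dict[str, int] = field(default_factory=dict)

    def note(self, kind: str) -> None:
        self.skipped[kind] = self.skipped.get(kind, 0) + 1

    @property
    def total(self) -> int:
        return sum(self.skipped.values())


_TOKEN_RE = re.compile(r"\(|\)|\"(?:[^\"\\]|\\.)*\"|[^\s()]+")

_QUANT_FUNCTORS = {
    "ObjectSomeValuesFrom": Quantifier.SOME,
    "ObjectAllValuesFrom": Quantifier.ONLY,
}
_CARD_FUNCTORS = {
    "ObjectExactCardinality": Quantifier.EXACTLY,
    "ObjectMinCardinality": Quantifier.MIN,
    "ObjectMaxCardinality": Quantifier.MAX,
}


def _strip_entity(tok: str) -> str:
    """Normalize ``<iri>`` / ``:name`` / ``prefix:name`` tokens to a bare name."""
    if tok.startswith("<") and tok.endswith(">"):
        iri = tok[1:-1]
        frag = iri.rsplit("#", 1)[-1].rsplit("/", 1)[-1].replace("%20", " ")
        # OBO-style IRI tails (MA_0000043) are CURIEs with '_' for ':'
        m = re.match(r"^([A-Za-z]+)_([A-Za-z0-9_.-]+)$", frag)
        if m and m.group(2)[0].isdigit():
            return f"{m.group(1)}:{m.group(2)}"
        return frag
    if tok.startswith(":"):
        return tok[1:]
    return tok


class _Tokens:
    def __init__(self, text: str):
        self.toks = _TOKEN_RE.findall(text)
        self.pos = 0

    def peek(self) -> Optional[str]:
        return self.toks[self.pos] if self.pos < len(self.toks) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise OwlParseError("unexpected end of input")
        self.pos += 1
        return tok

    def expect(self, tok: str) -> None:
        got = self.take()
        if got != tok:
            raise OwlParseError(f"expected {tok!r}, got {got!r}")

    def skip_balanced(self) -> None:
        """Consume a parenthesized argument list, assuming '(' is next."""
        self.expect("(")
        depth = 1
        while depth:
            tok = self.take()
            if tok == "(":
                depth += 1
            elif tok == ")":
                depth -= 1


def _parse_class_expression(ts: _Tokens) -> ClassExpression:
    tok = ts.take()
    if tok in _QUANT_FUNCTORS:
        ts.expect("(")
        relation = _strip_entity(ts.take())
        filler = _parse_class_expression(ts)
        ts.expect(")")
        return Restriction(relation, _QUANT_FUNCTORS[tok], filler)
    if tok in _CARD_FUNCTORS:
        ts.expect("(")
        n_tok = ts.take()
        if not n_tok.isdigit():
            raise OwlParseError(f"cardinality must be an integer, got {n_tok!r}")
        relation = _strip_entity(ts.take())
        filler = _parse_class_expression(ts)
        ts.expect(")")
        return Restriction(relation, _CARD_FUNCTORS[tok], filler, cardinality=int(n_tok))
    if tok == "ObjectComplementOf":
        ts.expect("(")
        inner = _parse_class_expression(ts)
        ts.expect(")")
        return Not(inner)
    if tok in ("ObjectIntersectionOf", "ObjectUnionOf"):
        ts.expect("(")
        ops: list[ClassExpression] = []
        while ts.peek() != ")":
            ops.append(_parse_class_expression(ts))
        ts.expect(")")
        cls = And if tok == "ObjectIntersectionOf" else Or
        return cls(tuple(ops))
    if tok in ("(", ")"):
        raise OwlParseError(f"unexpected {tok!r} in class expression")
    name = _strip_entity(tok)
    from .expressions import CURIE_RE

    if CURIE_RE.match(name):
        return Named(curie=name)
    return Named(label=name)


def read_owl_axioms(
    text: str, ontology_id: str = ""
) -> tuple[Ontology, SkipReport]:
    """Read supported ``SubClassOf`` axioms from functional-syntax text.

    Returns the ontology together with a :class:`SkipReport` counting
    every axiom that used a constructor outside the subset.
    """
    ts = _Tokens(text)
    onto = Ontology(ontology_id=ontology_id)
    report = SkipReport()
    labels: dict[str, str] = {}
    axioms: list[SubClassOfAxiom] = []

    while (tok := ts.peek()) is not None:
        if tok in ("Prefix", "Declaration", "Annotation"):
            ts.take()
            ts.skip_balanced()
            continue
        if tok == "Ontology":
            ts.take()
            ts.expect("(")
            nxt = ts.peek()
            if nxt is not None and nxt.startswith("<"):
                onto.ontology_id = onto.ontology_id or _strip_entity(ts.take())
            continue
        if tok == ")":
            ts.take()
            continue
        if tok == "AnnotationAssertion":
            ts.take()
            ts.expect("(")
            prop = ts.take()
            subject = _strip_entity(ts.take())
            value = ts.take()
            ts.expect(")")
            if prop in ("rdfs:label", "label") and value.startswith('"'):
                labels[subject] = value[1:-1].replace('\\"', '"')
            else:
                report.note("AnnotationAssertion")
            continue
        if tok == "SubClassOf":
            ts.take()
            ts.expect("(")
            start = ts.pos
            try:
                subject_expr = _parse_class_expression(ts)
                superclass = _parse_class_expression(ts)
                ts.expect(")")
            except OwlParseError:
                ts.pos = start
                depth = 1
                while depth:
                    t = ts.take()
                    depth += t == "("
                    depth -= t == ")"
                report.note("SubClassOf(unsupported)")
                continue
            if not isinstance(subject_expr, Named):
                report.note("SubClassOf(anonymous-subject)")
                continue
            axioms.append(
                SubClassOfAxiom(subject_expr, superclass, source_ontology=ontology_id)
            )
            continue
        # any other functor with an argument list is an unsupported axiom
        ts.take()
        if ts.peek() == "(":
            ts.skip_balanced()
            report.note(tok)
        # bare tokens (stray IRIs) are ignored

    def relabel(expr: ClassExpression) -> None:
        for sub in iter_subexpressions(expr):
            if isinstance(sub, Named) and sub.curie in labels and sub.label is None:
                object.__setattr__(sub, "label", labels[sub.curie])

    for ax in axioms:
        if ax.subject.curie in labels and ax.subject.label is None:
            object.__setattr__(ax.subject, "label", labels[ax.subject.curie])
        relabel(ax.superclass)
        onto.add_axiom(ax)

    if report.total:
        log.info("skipped %d unsupported OWL axioms: %s", report.total, report.skipped)
    return onto, report


def _fs_entity(named: Named) -> str:
    name = named.curie if named.curie is not None else named.label
    assert name is not None
    if re.match(r"^[A-Za-z_][A-Za-z0-9_.:-]*$", name):
        return f":{name}" if ":" not in name else name
    return f"<http://example.org/{name.replace(' ', '%20')}>"


def _fs_expression(expr: ClassExpression) -> str:
    if isinstance(expr, Named):
        return _fs_entity(expr)
    if isinstance(expr, Restriction):
        filler = _fs_expression(expr.filler)
        if expr.quantifier is Quantifier.SOME:
            return f"ObjectSomeValuesFrom(:{expr.relation} {filler})"
        if expr.quantifier is Quantifier.ONLY:
            return f"ObjectAllValuesFrom(:{expr.relation} {filler})"
        functor = {
            Quantifier.EXACTLY: "ObjectExactCardinality",
            Quantifier.MIN: "ObjectMinCardinality",
            Quantifier.MAX: "ObjectMaxCardinality",
        }[expr.quantifier]
        return f"{functor}({expr.cardinality} :{expr.relation} {filler})"
    if isinstance(expr, Not):
        return f"ObjectComplementOf({_fs_expression(expr.expr)})"
    if isinstance(expr, And):
        return f"ObjectIntersectionOf({' '.join(_fs_expression(o) for o in expr.operands)})"
    if isinstance(expr, Or):
        return f"ObjectUnionOf({' '.join(_fs_expression(o) for o in expr.operands)})"
    raise TypeError(f"not a class expression: {expr!r}")


def write_owl_functional(onto: Ontology) -> str:
    """Serialize SubClassOf axioms (plus labels) to functional syntax."""
    lines = [
        "Prefix(:=<http://example.org/onto#>)",
        "Prefix(rdfs:=<http://www.w3.org/2000/01/rdf-schema#>)",
        f"Ontology(<http://example.org/{onto.ontology_id or 'onto'}>",
    ]
    emitted_labels: set[str] = set()

    def note_labels(expr: ClassExpression) -> None:
        for sub in iter_subexpressions(expr):
            if isinstance(sub, Named) and sub.curie and sub.label:
                if sub.curie not in emitted_labels:
                    emitted_labels.add(sub.curie)
                    lines.append(
                        f'AnnotationAssertion(rdfs:label {sub.curie} "{sub.label}")'
                    )

    for ax in onto.axioms:
        note_labels(ax.subject)
        note_labels(ax.superclass)
    for ax in onto.axioms:
        lines.append(f"SubClassOf({_fs_entity(ax.subject)} {_fs_expression(ax.superclass)})")
    lines.append(")")
    return "\n".join(lines) + "\n"
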