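"""OBO relationship -> OWL axiom translation under configurable patterns.

The canonical OBO-to-OWL conversion renders every relationship line as
an existential restriction (the *all-some* pattern): ``A rel B`` becomes
``A subClassOf rel some B``.  That reading asserts generic ontological
dependence of A-instances on B-instances, which is exactly what goes
wrong for relations like ``lacks_part`` whose intended meaning is the
antithesis of dependence.  A :class:`PatternTable` lets individual
relations opt out of the all-some default into one of the alternative
patterns:

==================== ==============================================
ALL_SOME             ``rel some T``           (default)
VALUE_ONLY           ``rel only T``
CARDINALITY_EXACT(n) ``rel exactly n T``
NEGATED_HAS_PART     ``not (has_part some T)``
NEGATED_PARTICIPATION ``not (carrier some T)``
REALIZED_ONLY        ``carrier-or-rel only T``
==================== ==============================================

Only ALL_SOME and the cardinality variant keep an existential claim over
the original relation; every other pattern avoids asserting ontological
dependence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from .expressions import (
    ClassExpression,
    Named,
    Not,
    OboTerm,
    Ontology,
    Quantifier,
    Restriction,
    SubClassOfAxiom,
)

__all__ = [
    "PatternKind",
    "TranslationPattern",
    "PatternTable",
    "resolve_pattern",
    "translate_relationship",
    "translate_ontology",
    "PatternConfigError",
    "ALL_SOME",
    "hoehndorf_overrides",
]


class PatternKind(Enum):
    ALL_SOME = "ALL_SOME"
    VALUE_ONLY = "VALUE_ONLY"
    CARDINALITY_EXACT = "CARDINALITY_EXACT"
    NEGATED_HAS_PART = "NEGATED_HAS_PART"
    NEGATED_PARTICIPATION = "NEGATED_PARTICIPATION"
    REALIZED_ONLY = "REALIZED_ONLY"


_CARRIER_PATTERNS = {PatternKind.NEGATED_PARTICIPATION}
# REALIZED_ONLY may name a carrier (has_realization style) but defaults to
# the relation itself, yielding "rel only T".


class PatternConfigError(ValueError):
    pass


@dataclass(frozen=True)
class TranslationPattern:
    kind: PatternKind
    cardinality: Optional[int] = None
    carrier: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind is PatternKind.CARDINALITY_EXACT:
            if self.cardinality is None or self.cardinality < 1:
                raise PatternConfigError("CARDINALITY_EXACT requires n >= 1")
        elif self.cardinality is not None:
            raise PatternConfigError(f"{self.kind.value} takes no cardinality")
        if self.carrier is not None and self.kind not in (
            PatternKind.NEGATED_PARTICIPATION,
            PatternKind.NEGATED_HAS_PART,
            PatternKind.REALIZED_ONLY,
        ):
            raise PatternConfigError(f"{self.kind.value} takes no carrier relation")


ALL_SOME = TranslationPattern(PatternKind.ALL_SOME)


@dataclass
class PatternTable:
    """Relation -> pattern overrides with an all-some fallback."""

    overrides: dict[str, TranslationPattern] = field(default_factory=dict)
    default: TranslationPattern = ALL_SOME


def hoehndorf_overrides() -> PatternTable:
    """The two published alternative mappings: ``realized_by only Y``
    and ``not (has_part some Y)`` for lacks_part."""
    return PatternTable(
        overrides={
            "realized_by": TranslationPattern(PatternKind.REALIZED_ONLY),
            "lacks_part": TranslationPattern(PatternKind.NEGATED_HAS_PART),
        }
    )


def resolve_pattern(relation_id: str, table: PatternTable) -> TranslationPattern:
    """Override if present, else the table's default (all-some)."""
    return table.overrides.get(relation_id, table.default)


def _named_target(target: str, onto: Optional[Ontology]) -> Named:
    label = onto.label_of(target) if onto is not None else None
    return Named(curie=target, label=label)


def translate_relationship(
    subject: OboTerm,
    relationship: tuple[str, str],
    table: PatternTable,
    onto: Optional[Ontology] = None,
    source_ontology: str = "",
) -> SubClassOfAxiom:
    """Build the ``subject subClassOf <pattern>(rel, target)`` axiom.

    Unresolved targets become ``Named(curie, curie)``-style classes with
    the CURIE standing in for the label.
    """
    relation, target = relationship
    pattern = resolve_pattern(relation, table)
    filler = _named_target(target, onto)
    superclass: ClassExpression
    if pattern.kind is PatternKind.ALL_SOME:
        superclass = Restriction(relation, Quantifier.SOME, filler)
    elif pattern.kind is PatternKind.VALUE_ONLY:
        superclass = Restriction(relation, Quantifier.ONLY, filler)
    elif pattern.kind is PatternKind.CARDINALITY_EXACT:
        superclass = Restriction(
            relation, Quantifier.EXACTLY, filler, cardinality=pattern.cardinality
        )
    elif pattern.kind is PatternKind.NEGATED_HAS_PART:
        carrier = pattern.carrier or "has_part"
        superclass = Not(Restriction(carrier, Quantifier.SOME, filler))
    elif pattern.kind is PatternKind.NEGATED_PARTICIPATION:
        if pattern.carrier is None:
            raise PatternConfigError(
                f"NEGATED_PARTICIPATION for {relation!r} needs a carrier relation"
            )
        superclass = Not(Restriction(pattern.carrier, Quantifier.SOME, filler))
    elif pattern.kind is PatternKind.REALIZED_ONLY:
        superclass = Restriction(pattern.carrier or relation, Quantifier.ONLY, filler)
    else:  # pragma: no cover
        raise PatternConfigError(f"unknown pattern kind {pattern.kind!r}")
    subj = Named(curie=subject.id, label=subject.name)
    return SubClassOfAxiom(subj, superclass, source_ontology=source_ontology)


def translate_ontology(onto: Ontology, table: PatternTable) -> Ontology:
    """Translate every relationship of every non-obsolete term.

    Returns a new ontology sharing the term table; axiom count equals
    the total relationship count over non-obsolete terms.
    """
    out = Ontology(
        ontology_id=onto.ontology_id,
        terms=onto.terms,
        inverses=dict(onto.inverses),
    )
    for term_id in sorted(onto.terms):
        term = onto.terms[term_id]
        if term.obsolete:
            continue
        for relationship in term.relationships:
            out.add_axiom(
                translate_relationship(
                    term, relationship, table, onto=onto,
                    source_ontology=onto.ontology_id,
                )
            )
    return out
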