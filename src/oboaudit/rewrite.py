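"""Corrective rewrites for suspicious existential restrictions.

Each error category has a design-pattern template that removes the
unintended ontological-dependence claim while keeping the information
the modeler meant to convey:

* INVERTED_PART_OF — invert: the filler becomes the subject and the
  configured inverse relation carries an existential claim the other way
  (``B subClassOf has_part some A``).
* CHEMICAL_STRUCTURE / TIME_DEPENDENCY — substitute the value
  restriction: ``rel some T`` becomes ``rel only T``.
* MISSING_ENTITY — negate participation:
  ``lacks_x some T`` becomes ``not (participant_of some T)``.
* ROLE_REALIZABLE — ``has_role some T`` becomes ``has_role only T``
  (the filler may be a user-supplied disjunction for multi-role
  classes); for ``has_input``/``has_output`` on a function class the
  realization is made conditional:
  ``has_realization only (has_input some T)``.

Every ``only`` rewrite logs a closed-world caveat: a value restriction
enumerates the admissible fillers, so it is only correct if all of them
are known in advance.  Rewrites are emitted alongside the source axiom,
never destructively.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .audit import RestrictionRecord
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
    serialize_axiom,
)
from .taxonomy import ErrorCategory

__all__ = [
    "Carriers",
    "RewriteError",
    "rewrite_axiom",
    "rewrite_report",
    "RewriteReport",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Carriers:
    """Carrier relations used by the negated-participation and
    realization templates."""

    participation: str = "participant_of"
    realization: str = "has_realization"


class RewriteError(ValueError):
    pass


def _warn_closed_world(axiom: SubClassOfAxiom) -> None:
    log.warning(
        "value-restriction rewrite of %s is closed-world: all admissible "
        "fillers must be known in advance",
        serialize_axiom(axiom),
    )


def _substitute(
    expr: ClassExpression,
    relation: str,
    make: "callable",
) -> tuple[ClassExpression, int]:
    """Replace every dependence-asserting SOME restriction over
    ``relation`` via ``make``; sibling conjuncts/disjuncts survive
    unchanged.  Occurrences under a negation or inside an ``only``/
    ``max`` filler assert nothing and are left alone — which also makes
    re-applying a template a no-op."""
    if isinstance(expr, Restriction):
        if expr.quantifier is Quantifier.SOME and expr.relation == relation:
            return make(expr), 1
        if expr.quantifier in (Quantifier.SOME, Quantifier.EXACTLY, Quantifier.MIN):
            inner, n = _substitute(expr.filler, relation, make)
            if n:
                return (
                    Restriction(expr.relation, expr.quantifier, inner, expr.cardinality),
                    n,
                )
        return expr, 0
    if isinstance(expr, (And, Or)):
        total = 0
        ops = []
        for op in expr.operands:
            new, n = _substitute(op, relation, make)
            ops.append(new)
            total += n
        if total:
            cls = And if isinstance(expr, And) else Or
            return cls(tuple(ops)), total
        return expr, 0
    return expr, 0


def rewrite_axiom(
    axiom: SubClassOfAxiom,
    category: ErrorCategory,
    relation: Optional[str] = None,
    inverse_map: Optional[Mapping[str, str]] = None,
    carriers: Carriers = Carriers(),
) -> list[SubClassOfAxiom]:
    """Apply the category's corrective template to the axiom.

    ``relation`` names the flagged relation (defaults to the first SOME
    restriction's relation); an axiom already rewritten under the same
    category no longer contains a flagged SOME restriction and comes
    back unchanged, making the operation idempotent.  OTHER proposes no
    rewrite and returns an empty list.
    """
    if category is ErrorCategory.OTHER:
        return []

    from .expressions import iter_asserted_existentials

    some = list(iter_asserted_existentials(axiom.superclass))
    if relation is None:
        matching = some
    else:
        matching = [r for r in some if r.relation == relation]
    if not matching:
        return [axiom]  # already rewritten (or nothing to do): idempotent
    target_relation = relation if relation is not None else matching[0].relation

    if category is ErrorCategory.INVERTED_PART_OF:
        inverse_map = inverse_map or {}
        if target_relation not in inverse_map:
            raise RewriteError(
                f"no inverse configured for relation {target_relation!r}"
            )
        restriction = matching[0]
        if not isinstance(restriction.filler, Named):
            raise RewriteError("inversion needs a named filler")
        inverted = SubClassOfAxiom(
            subject=restriction.filler,
            superclass=Restriction(
                inverse_map[target_relation], Quantifier.SOME, axiom.subject
            ),
            source_ontology=axiom.source_ontology,
        )
        return [inverted]

    if category in (ErrorCategory.CHEMICAL_STRUCTURE, ErrorCategory.TIME_DEPENDENCY):
        def to_only(r: Restriction) -> ClassExpression:
            return Restriction(r.relation, Quantifier.ONLY, r.filler)

        new, _ = _substitute(axiom.superclass, target_relation, to_only)
        out = SubClassOfAxiom(axiom.subject, new, axiom.source_ontology)
        _warn_closed_world(out)
        return [out]

    if category is ErrorCategory.MISSING_ENTITY:
        def negate_participation(r: Restriction) -> ClassExpression:
            return Not(Restriction(carriers.participation, Quantifier.SOME, r.filler))

        new, _ = _substitute(axiom.superclass, target_relation, negate_participation)
        return [SubClassOfAxiom(axiom.subject, new, axiom.source_ontology)]

    if category is ErrorCategory.ROLE_REALIZABLE:
        if target_relation in ("has_input", "has_output"):
            def realize(r: Restriction) -> ClassExpression:
                return Restriction(
                    carriers.realization,
                    Quantifier.ONLY,
                    Restriction(r.relation, Quantifier.SOME, r.filler),
                )

            new, _ = _substitute(axiom.superclass, target_relation, realize)
        else:
            def to_only(r: Restriction) -> ClassExpression:
                return Restriction(r.relation, Quantifier.ONLY, r.filler)

            new, _ = _substitute(axiom.superclass, target_relation, to_only)
        out = SubClassOfAxiom(axiom.subject, new, axiom.source_ontology)
        _warn_closed_world(out)
        return [out]

    raise RewriteError(f"no template for category {category!r}")  # pragma: no cover


@dataclass
class RewriteReport:
    by_category: dict[ErrorCategory, int] = field(default_factory=dict)
    by_relation: dict[str, int] = field(default_factory=dict)
    pairs: list[tuple[str, str]] = field(default_factory=list)  # (before, after)
    n_no_rewrite: int = 0

    def to_text(self) -> str:
        lines = ["Rewrite report", "==============", "", "Per category:"]
        if any(self.by_category.values()):
            for cat in ErrorCategory:
                if self.by_category.get(cat):
                    lines.append(f"  {cat.value}: {self.by_category[cat]}")
        else:
            lines.append("  no rewrites proposed")
        lines.append("")
        lines.append("Per relation:")
        for rel in sorted(self.by_relation):
            lines.append(f"  {rel}: {self.by_relation[rel]}")
        lines.append("")
        lines.append("Before / after:")
        if not self.pairs:
            lines.append("  (none)")
        for before, after in self.pairs:
            lines.append(f"  - {before}")
            lines.append(f"    -> {after}")
        return "\n".join(lines) + "\n"


def rewrite_report(
    flagged: Sequence[tuple[RestrictionRecord, ErrorCategory]],
    onto: Ontology,
    inverse_map: Optional[Mapping[str, str]] = None,
    carriers: Carriers = Carriers(),
) -> RewriteReport:
    """Rewrite every flagged record's axiom and summarize the outcome:
    per-category and per-relation counts plus the before/after axiom
    listing in compact syntax."""
    report = RewriteReport()
    for record, category in flagged:
        if record.axiom_index is None:
            raise RewriteError(f"record {record.record_id} carries no axiom index")
        axiom = onto.axioms[record.axiom_index]
        rewritten = rewrite_axiom(
            axiom,
            category,
            relation=record.relation,
            inverse_map=inverse_map,
            carriers=carriers,
        )
        if category is ErrorCategory.OTHER or not rewritten:
            report.n_no_rewrite += 1
            continue
        report.by_category[category] = report.by_category.get(category, 0) + 1
        report.by_relation[record.relation] = (
            report.by_relation.get(record.relation, 0) + 1
        )
        for new_axiom in rewritten:
            report.pairs.append((serialize_axiom(axiom), serialize_axiom(new_axiom)))
    return report
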