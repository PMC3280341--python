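"""Synthetic ontologies with planted errors and simulated raters.

Real audit campaigns depend on downloaded ontology releases and human
expert judgment; neither is available to a test suite.  The generator
emulates the *shape* of such a campaign instead: an ontology with
several relation types, a skewed per-relation axiom count, and a planted
proportion of each relation's restrictions marked as unjustified
(ground truth).  Simulated raters with configurable sensitivity (the
probability of calling a truly false restriction "no") and specificity
(calling a true one "yes") stand in for the experts.

What the fixtures do *not* emulate: the semantic content of real class
names, correlated rater errors, consensus discussion, and the long-tail
relation inventory of a full ontology collection.  A green test on a
fixture therefore establishes the pipeline's arithmetic and invariants,
not the plausibility of any particular ontology.

One global seed fans out to per-component seeds through
:func:`spawn_seeds`, so each stage is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .audit import RaterAssignment, RestrictionRecord, extract_existential_records
from .expressions import OboTerm, Ontology
from .stats import RatingSet
from .taxonomy import ErrorCategory
from .translate import PatternTable, translate_ontology

__all__ = [
    "RelationSpec",
    "FixtureSpec",
    "SimulatedRater",
    "generate_fixture",
    "simulate_ratings",
    "spawn_seeds",
]

# relation ids typical of each planted category (defaults; overridable
# per RelationSpec)
_CATEGORY_RELATIONS = {
    ErrorCategory.CHEMICAL_STRUCTURE: "has_parent_hydride",
    ErrorCategory.MISSING_ENTITY: "lacks_part",
    ErrorCategory.ROLE_REALIZABLE: "has_role",
    ErrorCategory.TIME_DEPENDENCY: "end",
    ErrorCategory.INVERTED_PART_OF: "part_of",
    ErrorCategory.OTHER: "part_of",
}

_NAME_TEMPLATES = {
    ErrorCategory.CHEMICAL_STRUCTURE: ("nitroso compound", "benzene derivative"),
    ErrorCategory.MISSING_ENTITY: ("unmodified isoform", "protein modification"),
    ErrorCategory.ROLE_REALIZABLE: ("methylbromide salt", "drug role"),
    ErrorCategory.TIME_DEPENDENCY: ("pharyngeal structure", "developmental stage"),
    ErrorCategory.INVERTED_PART_OF: ("migration process", "proliferation process"),
    ErrorCategory.OTHER: ("anatomical entity", "anatomical whole"),
}


def spawn_seeds(master_seed: int, n: int) -> list[int]:
    """Fan a global seed out into ``n`` independent component seeds
    (all below 2**31) via numpy's SeedSequence."""
    state = np.random.SeedSequence(master_seed).generate_state(n, np.uint32)
    return [int(s) % (2**31) for s in state]


@dataclass(frozen=True)
class RelationSpec:
    relation_id: str
    n_axioms: int
    planted_category: ErrorCategory = ErrorCategory.OTHER
    planted_false_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_axioms < 0:
            raise ValueError("n_axioms must be >= 0")
        if not 0.0 <= self.planted_false_rate <= 1.0:
            raise ValueError("planted_false_rate must be in [0, 1]")


@dataclass(frozen=True)
class FixtureSpec:
    relations: tuple[RelationSpec, ...]
    seed: int = 0
    ontology_id: str = "SYN"
    n_targets: int = 10  # distinct target classes per relation
    function_suffix_share: float = 0.0  # share of subjects named "... activity"

    @property
    def total_axioms(self) -> int:
        return sum(r.n_axioms for r in self.relations)


@dataclass(frozen=True)
class SimulatedRater:
    rater_id: str
    sensitivity: float = 1.0  # P(verdict "no" | truly false)
    specificity: float = 1.0  # P(verdict "yes" | truly true)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.sensitivity <= 1.0 and 0.0 <= self.specificity <= 1.0):
            raise ValueError("sensitivity and specificity must be in [0, 1]")


def generate_fixture(
    spec: FixtureSpec,
    table: Optional[PatternTable] = None,
) -> tuple[Ontology, dict[str, bool]]:
    """Build a synthetic translated ontology plus ground truth.

    Returns ``(ontology, ground_truth)`` where ``ground_truth`` maps
    each extracted record id to its dependence-justified flag (``False``
    for the planted share of unjustified restrictions).  The ontology's
    :func:`extract_existential_records` output has exactly the planted
    per-relation axiom counts under the default all-some table.
    Deterministic for a fixed spec.
    """
    rng = np.random.default_rng(spec.seed)
    obo = Ontology(ontology_id=spec.ontology_id)
    counter = 0

    def new_term(name: str) -> OboTerm:
        nonlocal counter
        counter += 1
        term = OboTerm(id=f"{spec.ontology_id}:{counter:07d}", name=name)
        obo.add_term(term)
        return term

    for rel_spec in spec.relations:
        src_tpl, tgt_tpl = _NAME_TEMPLATES.get(
            rel_spec.planted_category, _NAME_TEMPLATES[ErrorCategory.OTHER]
        )
        targets = [
            new_term(f"{tgt_tpl} {rel_spec.relation_id} T{j}")
            for j in range(spec.n_targets)
        ]
        for i in range(rel_spec.n_axioms):
            name = f"{src_tpl} {rel_spec.relation_id} S{i}"
            if rng.random() < spec.function_suffix_share:
                name += " activity"
            subject = new_term(name)
            target = targets[rng.integers(len(targets))]
            subject.relationships.append((rel_spec.relation_id, target.id))
            obo.relations.add(rel_spec.relation_id)

    translated = translate_ontology(obo, table if table is not None else PatternTable())
    records = extract_existential_records(translated)

    ground_truth: dict[str, bool] = {}
    by_relation: dict[str, list[RestrictionRecord]] = {}
    for rec in records:
        by_relation.setdefault(rec.relation, []).append(rec)
    for rel_spec in spec.relations:
        recs = by_relation.get(rel_spec.relation_id, [])
        n_false = round(rel_spec.planted_false_rate * len(recs))
        false_idx = set(
            rng.choice(len(recs), size=n_false, replace=False).tolist()
        ) if recs else set()
        for i, rec in enumerate(recs):
            ground_truth[rec.record_id] = i not in false_idx
    return translated, ground_truth


def simulate_ratings(
    ground_truth: dict[str, bool],
    assignment: RaterAssignment,
    raters: Sequence[SimulatedRater],
) -> RatingSet:
    """Draw a verdict for every (record, rater) task.

    A rater answers "no" with probability ``sensitivity`` on a truly
    false restriction, "yes" with probability ``specificity`` on a true
    one.  Each rater consumes an independent stream seeded from their
    own seed, so verdicts are deterministic per (spec, seeds) and
    independent across raters.
    """
    profiles = {r.rater_id: r for r in raters}
    for record_id, assigned in assignment.mapping.items():
        for rater_id in assigned:
            if rater_id not in profiles:
                raise ValueError(f"no SimulatedRater profile for {rater_id!r}")
    rngs = {r.rater_id: np.random.default_rng(r.seed) for r in raters}
    ratings: list[tuple[str, str, str]] = []
    for record_id in sorted(assignment.mapping):
        truly_justified = ground_truth[record_id]
        for rater_id in assignment.mapping[record_id]:
            profile = profiles[rater_id]
            u = rngs[rater_id].random()
            if truly_justified:
                verdict = "yes" if u < profile.specificity else "no"
            else:
                verdict = "no" if u < profile.sensitivity else "yes"
            ratings.append((record_id, rater_id, verdict))
    return RatingSet(ratings=ratings)
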