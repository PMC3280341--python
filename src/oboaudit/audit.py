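"""Flatten existential restrictions into rating records, stratify,
sample and assign raters.

The rating unit is one ``someValuesFrom`` clause flattened to
(ontology, source class, relation, target class) — the tabular format
shown to the raters.  Restrictions are harvested from anywhere in an
axiom's superclass tree, with the nesting depth recorded, so that a
conjunct-embedded clause like ``... and lacks_modification some
Post-translational protein modification`` is rated just like a
top-level one.

Sampling is stratified by (ontology, relation) with a per-stratum cap
(study default 20, chosen because of the rating effort per statement),
drawn uniformly without replacement.  A configurable share of sampled
statements (study default one quarter) is assigned to two raters to
support agreement statistics.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np

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
    serialize_expression,
)

__all__ = [
    "RestrictionRecord",
    "SamplePlan",
    "RaterAssignment",
    "Stratum",
    "extract_existential_records",
    "build_strata",
    "draw_sample",
    "assign_raters",
    "write_rating_sheet",
    "read_rating_responses",
    "SHEET_COLUMNS",
]

SHEET_COLUMNS = [
    "record_id",
    "rater_id",
    "Source_Ontology",
    "Class_Source",
    "Relation",
    "Class_Target",
    "verdict",
]


@dataclass(frozen=True)
class RestrictionRecord:
    """One existential restriction flattened for rating."""

    record_id: str
    source_ontology: str
    class_source: str
    relation: str
    class_target: str
    nesting_depth: int = 0
    source_curie: Optional[str] = None
    target_curie: Optional[str] = None
    axiom_index: Optional[int] = None

    @property
    def stratum_key(self) -> tuple[str, str]:
        return (self.source_ontology, self.relation)


@dataclass(frozen=True)
class SamplePlan:
    cap_per_stratum: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cap_per_stratum < 1:
            raise ValueError("cap_per_stratum must be >= 1")


@dataclass
class Stratum:
    records: list[RestrictionRecord]

    @property
    def population_size(self) -> int:
        return len(self.records)


@dataclass
class RaterAssignment:
    raters: list[str]
    double_fraction: float
    mapping: dict[str, tuple[str, ...]]  # record_id -> 1 or 2 rater ids

    @property
    def n_tasks(self) -> int:
        return sum(len(rs) for rs in self.mapping.values())


def _walk_some(expr: ClassExpression, depth: int) -> Iterable[tuple[Restriction, int]]:
    """Depth-first yield of every SOME restriction with its nesting depth."""
    if isinstance(expr, Restriction):
        if expr.quantifier is Quantifier.SOME:
            yield expr, depth
        yield from _walk_some(expr.filler, depth + 1)
    elif isinstance(expr, Not):
        yield from _walk_some(expr.expr, depth + 1)
    elif isinstance(expr, (And, Or)):
        for op in expr.operands:
            yield from _walk_some(op, depth + 1)


def extract_existential_records(onto: Ontology) -> list[RestrictionRecord]:
    """One record per SOME restriction anywhere in an axiom superclass.

    An axiom whose superclass is exactly one existential restriction
    yields a single depth-0 record; nested occurrences carry their
    depth.  Axioms without any SOME restriction contribute nothing.
    """
    records: list[RestrictionRecord] = []
    counter = 0
    for idx, axiom in enumerate(onto.axioms):
        for restriction, depth in _walk_some(axiom.superclass, 0):
            filler = restriction.filler
            if isinstance(filler, Named):
                target_label = filler.display
                target_curie = filler.curie
            else:
                target_label = serialize_expression(filler)
                target_curie = None
            records.append(
                RestrictionRecord(
                    record_id=f"{onto.ontology_id or 'onto'}-{counter:06d}",
                    source_ontology=axiom.source_ontology or onto.ontology_id,
                    class_source=axiom.subject.display,
                    relation=restriction.relation,
                    class_target=target_label,
                    nesting_depth=depth,
                    source_curie=axiom.subject.curie,
                    target_curie=target_curie,
                    axiom_index=idx,
                )
            )
            counter += 1
    return records


def build_strata(
    records: Iterable[RestrictionRecord],
) -> dict[tuple[str, str], Stratum]:
    """Partition records by (ontology, relation); population sizes sum
    to the record count."""
    strata: dict[tuple[str, str], Stratum] = {}
    for rec in records:
        strata.setdefault(rec.stratum_key, Stratum(records=[])).records.append(rec)
    return strata


def draw_sample(
    strata: Mapping[tuple[str, str], Stratum], plan: SamplePlan
) -> list[RestrictionRecord]:
    """Per stratum, min(cap, population) records uniformly without
    replacement; deterministic for a fixed seed."""
    rng = np.random.default_rng(plan.seed)
    sampled: list[RestrictionRecord] = []
    for key in sorted(strata):
        stratum = strata[key]
        n = min(plan.cap_per_stratum, stratum.population_size)
        idx = rng.choice(stratum.population_size, size=n, replace=False)
        sampled.extend(stratum.records[i] for i in sorted(idx))
    return sampled


def assign_raters(
    sample: list[RestrictionRecord],
    raters: list[str],
    double_fraction: float = 0.25,
    seed: int = 0,
) -> RaterAssignment:
    """Assign each sampled record to one rater, a random
    ``round(double_fraction * N)`` of them to two distinct raters.

    Task loads are balanced across raters within +/-1 where achievable:
    each slot goes to a least-loaded eligible rater, ties broken at
    random.
    """
    if not 0.0 <= double_fraction <= 1.0:
        raise ValueError("double_fraction must be in [0, 1]")
    if double_fraction > 0 and len(raters) < 2:
        raise ValueError("double rating needs at least 2 raters")
    if not raters:
        raise ValueError("need at least one rater")
    rng = np.random.default_rng(seed)
    n = len(sample)
    n_double = round(double_fraction * n)
    double_idx = set(rng.choice(n, size=n_double, replace=False).tolist())

    loads = {r: 0 for r in raters}
    mapping: dict[str, tuple[str, ...]] = {}
    order = rng.permutation(n)
    for i in order:
        rec = sample[i]
        k = 2 if i in double_idx else 1
        chosen: list[str] = []
        for _ in range(k):
            eligible = [r for r in raters if r not in chosen]
            low = min(loads[r] for r in eligible)
            pool = [r for r in eligible if loads[r] == low]
            pick = pool[rng.integers(len(pool))]
            chosen.append(pick)
            loads[pick] += 1
        mapping[rec.record_id] = tuple(chosen)
    return RaterAssignment(raters=list(raters), double_fraction=double_fraction, mapping=mapping)


def write_rating_sheet(
    assignment: RaterAssignment,
    records: list[RestrictionRecord],
    path_or_buffer,
) -> None:
    """Write the rating sheet CSV: one row per (record, rater) task,
    verdict column left empty for the rater to fill."""
    by_id = {rec.record_id: rec for rec in records}
    rows = []
    for record_id in sorted(assignment.mapping):
        rec = by_id[record_id]
        for rater in assignment.mapping[record_id]:
            rows.append(
                [
                    rec.record_id,
                    rater,
                    rec.source_ontology,
                    rec.class_source,
                    rec.relation,
                    rec.class_target,
                    "",
                ]
            )

    def _dump(handle) -> None:
        writer = csv.writer(handle)
        writer.writerow(SHEET_COLUMNS)
        writer.writerows(rows)

    if isinstance(path_or_buffer, io.TextIOBase):
        _dump(path_or_buffer)
    else:
        with open(path_or_buffer, "w", newline="", encoding="utf-8") as handle:
            _dump(handle)


def read_rating_responses(path_or_buffer) -> list[tuple[str, str, str]]:
    """Read a filled rating sheet back as (record_id, rater_id, verdict)
    triples; verdicts must be 'yes' or 'no'."""
    def _load(handle) -> list[tuple[str, str, str]]:
        reader = csv.DictReader(handle)
        out = []
        for i, row in enumerate(reader, start=2):
            verdict = (row.get("verdict") or "").strip().lower()
            if verdict not in ("yes", "no"):
                raise ValueError(
                    f"row {i}: verdict must be 'yes' or 'no', got {row.get('verdict')!r}"
                )
            out.append((row["record_id"], row["rater_id"], verdict))
        return out

    if isinstance(path_or_buffer, io.TextIOBase):
        return _load(path_or_buffer)
    with open(path_or_buffer, newline="", encoding="utf-8") as handle:
        return _load(handle)
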