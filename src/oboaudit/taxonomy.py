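"""Error taxonomy for suspicious existential restrictions.

Five recurrent failure modes of the all-some translation, plus OTHER:

* INVERTED_PART_OF — ``A part_of some B`` asserted where only
  ``B has_part some A`` is true; detectable only by expert judgment,
  never lexically.
* CHEMICAL_STRUCTURE — structural relations between molecule classes
  (tautomer/enantiomer/conjugate pairs, parent hydrides, functional
  parents) misread as existential dependence between molecules.
* MISSING_ENTITY — ``lacks_*`` relations whose intended meaning
  (absence) is the antithesis of the existential claim made for them.
* ROLE_REALIZABLE — roles and functions that may never be realized;
  ``has_role some`` and function-class ``has_input/has_output some``
  wrongly imply a realization exists.
* TIME_DEPENDENCY — developmental ``start``/``end`` stage links that do
  not make the stage ontologically necessary for the structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional

from .audit import RestrictionRecord

__all__ = ["ErrorCategory", "RelationLexicon", "default_lexicon", "categorize_record"]


class ErrorCategory(Enum):
    INVERTED_PART_OF = "INVERTED_PART_OF"
    CHEMICAL_STRUCTURE = "CHEMICAL_STRUCTURE"
    MISSING_ENTITY = "MISSING_ENTITY"
    ROLE_REALIZABLE = "ROLE_REALIZABLE"
    TIME_DEPENDENCY = "TIME_DEPENDENCY"
    OTHER = "OTHER"


@dataclass
class RelationLexicon:
    """Relation -> category rules: exact match beats prefix match beats
    the function-class conditional; everything else is OTHER."""

    exact: dict[str, ErrorCategory] = field(default_factory=dict)
    prefixes: dict[str, ErrorCategory] = field(default_factory=dict)
    function_conditional: dict[str, ErrorCategory] = field(default_factory=dict)
    function_suffix: str = "activity"


CHEMICAL_RELATIONS = (
    "is_tautomer_of",
    "is_enantiomer_of",
    "is_conjugate_base_of",
    "is_conjugate_acid_of",
    "has_functional_parent",
    "has_parent_hydride",
)


def default_lexicon() -> RelationLexicon:
    """The shipped defaults mirroring the relations implicated per
    category in the audited ontologies."""
    exact = {rel: ErrorCategory.CHEMICAL_STRUCTURE for rel in CHEMICAL_RELATIONS}
    exact["has_role"] = ErrorCategory.ROLE_REALIZABLE
    exact["start"] = ErrorCategory.TIME_DEPENDENCY
    exact["end"] = ErrorCategory.TIME_DEPENDENCY
    return RelationLexicon(
        exact=exact,
        prefixes={"lacks_": ErrorCategory.MISSING_ENTITY},
        function_conditional={
            "has_input": ErrorCategory.ROLE_REALIZABLE,
            "has_output": ErrorCategory.ROLE_REALIZABLE,
        },
    )


def _is_function_class(
    record: RestrictionRecord,
    function_classes: Iterable[str],
    suffix: Optional[str],
) -> bool:
    keys = set(function_classes)
    if record.source_curie in keys or record.class_source in keys:
        return True
    return bool(suffix) and record.class_source.endswith(suffix)


def categorize_record(
    record: RestrictionRecord,
    lexicon: Optional[RelationLexicon] = None,
    function_classes: Iterable[str] = (),
) -> ErrorCategory:
    """Map a restriction record to its error category.

    Precedence: exact relation match > relation prefix match >
    function-class conditional (``has_input``/``has_output`` on a class
    flagged — or suffix-named — as a function) > OTHER.  Inverted
    part-of use cannot be detected lexically and always falls through
    to OTHER here; it is asserted via rating metadata instead.
    """
    lex = lexicon if lexicon is not None else default_lexicon()
    if record.relation in lex.exact:
        return lex.exact[record.relation]
    for prefix, category in lex.prefixes.items():
        if record.relation.startswith(prefix):
            return category
    if record.relation in lex.function_conditional:
        if _is_function_class(record, function_classes, lex.function_suffix):
            return lex.function_conditional[record.relation]
    return ErrorCategory.OTHER
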