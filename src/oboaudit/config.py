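"""TOML configuration: translation patterns, inverses, taxonomy lexicon.

Example::

    [patterns]
    realized_by = "REALIZED_ONLY"
    lacks_part = "NEGATED_HAS_PART"
    has_part_count = { kind = "CARDINALITY_EXACT", n = 1 }
    lacks_participation = { kind = "NEGATED_PARTICIPATION", carrier = "participant_of" }

    [inverses]
    part_of = "has_part"

    [lexicon.exact]
    has_role = "ROLE_REALIZABLE"

    [lexicon.prefixes]
    "lacks_" = "MISSING_ENTITY"

    [carriers]
    participation = "participant_of"
    realization = "has_realization"

    [options]
    function_suffix = "activity"
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from typing import Any

from .rewrite import Carriers
from .taxonomy import ErrorCategory, RelationLexicon, default_lexicon
from .translate import PatternKind, PatternTable, TranslationPattern

__all__ = ["AuditConfig", "load_config", "parse_config"]


@dataclass
class AuditConfig:
    patterns: PatternTable = field(default_factory=PatternTable)
    inverses: dict[str, str] = field(default_factory=dict)
    lexicon: RelationLexicon = field(default_factory=default_lexicon)
    carriers: Carriers = field(default_factory=Carriers)


def _pattern_from_value(relation: str, value: Any) -> TranslationPattern:
    if isinstance(value, str):
        return TranslationPattern(PatternKind(value))
    if isinstance(value, dict):
        kind = PatternKind(value["kind"])
        return TranslationPattern(
            kind, cardinality=value.get("n"), carrier=value.get("carrier")
        )
    raise ValueError(f"bad pattern for relation {relation!r}: {value!r}")


def parse_config(data: dict) -> AuditConfig:
    patterns = PatternTable(
        overrides={
            rel: _pattern_from_value(rel, val)
            for rel, val in data.get("patterns", {}).items()
        }
    )
    inverses = dict(data.get("inverses", {}))
    # symmetric closure: declaring one direction declares both
    for a, b in list(inverses.items()):
        inverses.setdefault(b, a)

    lexicon = default_lexicon()
    lex_data = data.get("lexicon", {})
    for rel, cat in lex_data.get("exact", {}).items():
        lexicon.exact[rel] = ErrorCategory(cat)
    for prefix, cat in lex_data.get("prefixes", {}).items():
        lexicon.prefixes[prefix] = ErrorCategory(cat)
    for rel, cat in lex_data.get("function_conditional", {}).items():
        lexicon.function_conditional[rel] = ErrorCategory(cat)

    options = data.get("options", {})
    if "function_suffix" in options:
        lexicon.function_suffix = options["function_suffix"]

    carriers_data = data.get("carriers", {})
    carriers = Carriers(
        participation=carriers_data.get("participation", "participant_of"),
        realization=carriers_data.get("realization", "has_realization"),
    )
    return AuditConfig(
        patterns=patterns, inverses=inverses, lexicon=lexicon, carriers=carriers
    )


def load_config(path) -> AuditConfig:
    with open(path, "rb") as handle:
        return parse_config(tomllib.load(handle))
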