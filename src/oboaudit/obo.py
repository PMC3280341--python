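"""OBO flatfile (1.2-style) reading and writing.

Only the tags the audit needs are interpreted: ``id``, ``name``,
``is_a``, ``relationship`` and ``is_obsolete``.  Everything else —
``def``, ``synonym``, ``xref``, header tags, ``[Typedef]`` stanzas — is
ignored with a logged note, never silently.  Trailing ``! comment`` text
is stripped from tag values, as in::

    [Term]
    id: MA:0000043
    name: ankle
    relationship: part_of MA:0000026 ! hindlimb
"""

from __future__ import annotations

import logging
import re
from typing import Optional

from .expressions import CURIE_RE, OboTerm, Ontology

__all__ = ["parse_obo", "write_obo", "OboParseError"]

log = logging.getLogger(__name__)

_SUPPORTED_TAGS = {"id", "name", "is_a", "relationship", "is_obsolete"}
_STANZA_RE = re.compile(r"^\[([A-Za-z_-]+)\]\s*$")


class OboParseError(ValueError):
    """Malformed OBO input; message names the offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


def _strip_comment(value: str) -> str:
    # OBO comments start at an unescaped '!'
    out = []
    i = 0
    while i < len(value):
        c = value[i]
        if c == "\\" and i + 1 < len(value):
            out.append(value[i : i + 2])
            i += 2
            continue
        if c == "!":
            break
        out.append(c)
        i += 1
    return "".join(out).strip()


def parse_obo(text: str, ontology_id: str = "") -> Ontology:
    """Parse an OBO flatfile document into an :class:`Ontology`.

    One :class:`OboTerm` per ``[Term]`` stanza; ``is_a`` and
    ``relationship`` lines are captured, unsupported tags are counted and
    logged.  No axioms are built here — translation to OWL axioms is a
    separate, pattern-driven step.
    """
    onto = Ontology(ontology_id=ontology_id)
    current: Optional[dict] = None
    in_term = False
    ignored: dict[str, int] = {}

    def flush(line_no: int) -> None:
        nonlocal current
        if current is None:
            return
        if "id" not in current:
            raise OboParseError("[Term] stanza without an id tag", line_no)
        term = OboTerm(
            id=current["id"],
            name=current.get("name"),
            parents=current.get("is_a", []),
            relationships=current.get("relationship", []),
            obsolete=current.get("is_obsolete", False),
        )
        onto.add_term(term)
        for rel, _target in term.relationships:
            onto.relations.add(rel)
        current = None

    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("!"):
            continue
        m = _STANZA_RE.match(line)
        if m:
            flush(line_no)
            in_term = m.group(1) == "Term"
            if in_term:
                current = {}
            else:
                log.info("ignoring [%s] stanza at line %d", m.group(1), line_no)
            continue
        if ":" not in line:
            if line.startswith("["):
                raise OboParseError(f"malformed stanza header {line!r}", line_no)
            raise OboParseError(f"expected 'tag: value', got {line!r}", line_no)
        if not in_term or current is None:
            continue  # header or non-Term stanza content
        tag, _, value = line.partition(":")
        tag = tag.strip()
        value = _strip_comment(value)
        if tag not in _SUPPORTED_TAGS:
            ignored[tag] = ignored.get(tag, 0) + 1
            continue
        if tag == "id":
            if not CURIE_RE.match(value):
                raise OboParseError(f"term id is not a CURIE: {value!r}", line_no)
            current["id"] = value
        elif tag == "name":
            current["name"] = value
        elif tag == "is_a":
            if not CURIE_RE.match(value):
                raise OboParseError(f"is_a target is not a CURIE: {value!r}", line_no)
            current.setdefault("is_a", []).append(value)
        elif tag == "relationship":
            parts = value.split()
            if len(parts) < 2:
                raise OboParseError(
                    f"relationship line without a target CURIE: {value!r}", line_no
                )
            rel = parts[0]
            target = parts[1]
            if not CURIE_RE.match(target):
                raise OboParseError(
                    f"relationship target is not a CURIE: {target!r}", line_no
                )
            current.setdefault("relationship", []).append((rel, target))
        elif tag == "is_obsolete":
            current["is_obsolete"] = value.lower() == "true"
    flush(len(text.splitlines()) + 1)

    for tag, count in sorted(ignored.items()):
        log.info("ignored unsupported OBO tag %r on %d lines", tag, count)
    return onto


def write_obo(onto: Ontology) -> str:
    """Serialize the supported term subset back to OBO flatfile text.

    ``parse_obo(write_obo(parse_obo(doc)))`` is a fixed point on the
    supported tag subset.
    """
    chunks: list[str] = []
    for term_id in sorted(onto.terms):
        term = onto.terms[term_id]
        lines = ["[Term]", f"id: {term.id}"]
        if term.name is not None:
            lines.append(f"name: {term.name}")
        for parent in term.parents:
            lines.append(f"is_a: {parent}")
        for rel, target in term.relationships:
            label = onto.label_of(target)
            comment = f" ! {label}" if label else ""
            lines.append(f"relationship: {rel} {target}{comment}")
        if term.obsolete:
            lines.append("is_obsolete: true")
        chunks.append("\n".join(lines))
    return "\n\n".join(chunks) + ("\n" if chunks else "")
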