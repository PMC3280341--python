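"""Translate OBO relationships to OWL axioms under different patterns.

Parses a small mouse-anatomy-style OBO document, translates it with the
default all-some pattern, and then re-translates a 'lacks_part'
statement under the dependence-free alternative mapping.
"""

from oboaudit import (
    PatternTable,
    hoehndorf_overrides,
    parse_obo,
    serialize_axiom,
    translate_ontology,
)

DOC = """\
[Term]
id: MA:0000043
name: ankle
relationship: part_of MA:0000026 ! hindlimb

[Term]
id: MA:0000026
name: hindlimb

[Term]
id: MA:0000008
name: tailless mouse
relationship: lacks_part MA:0000009 ! tail

[Term]
id: MA:0000009
name: tail
"""


def main() -> None:
    onto = parse_obo(DOC, ontology_id="MA")
    print(f"parsed {len(onto.terms)} terms, relations: {sorted(onto.relations)}\n")

    print("default all-some translation (every relationship -> 'some'):")
    for ax in translate_ontology(onto, PatternTable()).axioms:
        print(f"  {serialize_axiom(ax)}")
    print(
        "\n  -> each 'some' axiom claims every instance of the subject"
        "\n     depends on an instance of the target; for lacks_part that"
        "\n     claim is the opposite of the intended meaning.\n"
    )

    print("alternative mapping (lacks_part -> negated parthood):")
    for ax in translate_ontology(onto, hoehndorf_overrides()).axioms:
        print(f"  {serialize_axiom(ax)}")
    print(
        "\n  -> 'not (has_part some tail)' asserts the absence directly"
        "\n     and no longer implies any tail must exist."
    )


if __name__ == "__main__":
    main()
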