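"""Classify suspicious statements and apply corrective design patterns.

Shows the five error categories on their canonical examples: an
inverted parthood claim, a chemical-structure relation, a reference to
a missing entity, an unrealized role/function, and a developmental time
dependency.
"""

import logging

from oboaudit import (
    And,
    ErrorCategory,
    Named,
    Quantifier,
    Restriction,
    SubClassOfAxiom,
    rewrite_axiom,
    serialize_axiom,
)

logging.basicConfig(level=logging.ERROR)  # silence per-rewrite caveats here


def some(rel, filler):
    return Restriction(rel, Quantifier.SOME, Named(label=filler))


CASES = [
    (
        SubClassOfAxiom(
            Named(label="Interkinetic nuclear migration"),
            some("part_of", "Cell proliferation in forebrain"),
        ),
        ErrorCategory.INVERTED_PART_OF,
        "part_of",
        "inversion via the inverse relation",
    ),
    (
        SubClassOfAxiom(Named(label="Nitrosobenzene"), some("has_parent_hydride", "Benzene")),
        ErrorCategory.CHEMICAL_STRUCTURE,
        "has_parent_hydride",
        "value restriction instead of existential",
    ),
    (
        SubClassOfAxiom(
            Named(label="Chordin isoform 1 unmodified form"),
            And((
                Named(label="Chordin isoform 1"),
                some("lacks_modification", "Post-translational protein modification"),
            )),
        ),
        ErrorCategory.MISSING_ENTITY,
        "lacks_modification",
        "negated participation",
    ),
    (
        SubClassOfAxiom(
            Named(label="tRNA sulfurtransferase"), some("has_input", "Transfer RNA")
        ),
        ErrorCategory.ROLE_REALIZABLE,
        "has_input",
        "realization made conditional",
    ),
    (
        SubClassOfAxiom(
            Named(label="Pharyngeal endoderm"), some("end", "Pharyngula:Prim-15")
        ),
        ErrorCategory.TIME_DEPENDENCY,
        "end",
        "value restriction on the stage",
    ),
]


def main() -> None:
    for axiom, category, relation, note in CASES:
        out = rewrite_axiom(
            axiom, category, relation=relation, inverse_map={"part_of": "has_part"}
        )
        print(f"[{category.value}] {note}")
        print(f"  before: {serialize_axiom(axiom)}")
        for new in out:
            print(f"  after : {serialize_axiom(new)}")
        print()
    print(
        "Each corrected axiom no longer asserts that instances of the\n"
        "subject class require an instance of the target class to exist."
    )


if __name__ == "__main__":
    main()
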