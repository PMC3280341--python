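import pytest

from oboaudit import (
    And,
    ErrorCategory,
    FixtureSpec,
    Named,
    Not,
    Ontology,
    Or,
    PatternTable,
    Quantifier,
    RelationSpec,
    Restriction,
    SubClassOfAxiom,
    generate_fixture,
    parse_obo,
)

ANKLE_OBO = """\
[Term]
id: MA:0000043
name: ankle
relationship: part_of MA:0000026 ! hindlimb

[Term]
id: MA:0000026
name: hindlimb
"""


@pytest.fixture
def ankle_ontology() -> Ontology:
    return parse_obo(ANKLE_OBO, ontology_id="MA")


@pytest.fixture
def ankle_axiom() -> SubClassOfAxiom:
    return SubClassOfAxiom(
        subject=Named("MA:0000043", "ankle"),
        superclass=Restriction(
            "part_of", Quantifier.SOME, Named("MA:0000026", "hindlimb")
        ),
        source_ontology="MA",
    )


@pytest.fixture
def mixed_fixture():
    """Multi-relation synthetic ontology with planted error categories,
    skewed per-relation counts and known ground truth."""
    spec = FixtureSpec(
        relations=(
            RelationSpec("part_of", 60, ErrorCategory.OTHER, 0.0),
            RelationSpec("has_parent_hydride", 25, ErrorCategory.CHEMICAL_STRUCTURE, 1.0),
            RelationSpec("lacks_part", 15, ErrorCategory.MISSING_ENTITY, 1.0),
            RelationSpec("has_role", 40, ErrorCategory.ROLE_REALIZABLE, 0.5),
            RelationSpec("end", 10, ErrorCategory.TIME_DEPENDENCY, 0.8),
            RelationSpec("derives_from", 5, ErrorCategory.OTHER, 0.2),
        ),
        seed=42,
        ontology_id="SYN",
    )
    return generate_fixture(spec)


@pytest.fixture
def fifty_axiom_ontology() -> Ontology:
    """50 axioms exercising every supported OWL constructor."""
    onto = Ontology(ontology_id="RT")
    named = [Named(f"RT:{i:07d}", f"class {i}") for i in range(60)]
    builders = [
        lambda a, b: Restriction("part_of", Quantifier.SOME, b),
        lambda a, b: Restriction("located_in", Quantifier.ONLY, b),
        lambda a, b: Restriction("has_part", Quantifier.EXACTLY, b, cardinality=2),
        lambda a, b: Restriction("has_part", Quantifier.MIN, b, cardinality=1),
        lambda a, b: Restriction("has_part", Quantifier.MAX, b, cardinality=3),
        lambda a, b: Not(Restriction("has_part", Quantifier.SOME, b)),
        lambda a, b: And((b, Restriction("lacks_part", Quantifier.SOME, a))),
        lambda a, b: Or((a, b)),
        lambda a, b: Restriction(
            "has_realization",
            Quantifier.ONLY,
            Restriction("has_input", Quantifier.SOME, b),
        ),
        lambda a, b: And((a, Not(Restriction("participant_of", Quantifier.SOME, b)))),
    ]
    for i in range(50):
        build = builders[i % len(builders)]
        onto.add_axiom(
            SubClassOfAxiom(
                subject=named[i],
                superclass=build(named[(i + 7) % 60], named[(i + 13) % 60]),
                source_ontology="RT",
            )
        )
    return onto
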