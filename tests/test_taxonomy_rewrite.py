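"""Error taxonomy classification and corrective rewrites."""

import pytest

from oboaudit import (
    And,
    Carriers,
    ErrorCategory,
    Named,
    Not,
    Ontology,
    Quantifier,
    RelationLexicon,
    Restriction,
    RestrictionRecord,
    RewriteError,
    SubClassOfAxiom,
    categorize_record,
    extract_existential_records,
    parse_expression,
    rewrite_axiom,
    rewrite_report,
    serialize_axiom,
    serialize_expression,
)


def record(relation, class_source="X", **kw):
    return RestrictionRecord(
        record_id="r0", source_ontology="O", class_source=class_source,
        relation=relation, class_target="T", **kw,
    )


class TestCategorize:
    @pytest.mark.parametrize(
        "relation,expected",
        [
            ("lacks_modification", ErrorCategory.MISSING_ENTITY),
            ("lacks_part", ErrorCategory.MISSING_ENTITY),
            ("has_parent_hydride", ErrorCategory.CHEMICAL_STRUCTURE),
            ("is_tautomer_of", ErrorCategory.CHEMICAL_STRUCTURE),
            ("is_enantiomer_of", ErrorCategory.CHEMICAL_STRUCTURE),
            ("is_conjugate_base_of", ErrorCategory.CHEMICAL_STRUCTURE),
            ("is_conjugate_acid_of", ErrorCategory.CHEMICAL_STRUCTURE),
            ("has_functional_parent", ErrorCategory.CHEMICAL_STRUCTURE),
            ("has_role", ErrorCategory.ROLE_REALIZABLE),
            ("start", ErrorCategory.TIME_DEPENDENCY),
            ("end", ErrorCategory.TIME_DEPENDENCY),
            ("part_of", ErrorCategory.OTHER),  # inversion is not lexical
            ("derives_from", ErrorCategory.OTHER),
        ],
    )
    def test_default_lexicon(self, relation, expected):
        assert categorize_record(record(relation)) is expected

    def test_has_input_only_on_function_classes(self):
        plain = record("has_input", class_source="Some complex")
        assert categorize_record(plain) is ErrorCategory.OTHER
        suffixed = record("has_input", class_source="tRNA sulfurtransferase activity")
        assert categorize_record(suffixed) is ErrorCategory.ROLE_REALIZABLE
        flagged = record("has_output", class_source="tRNA sulfurtransferase")
        assert (
            categorize_record(flagged, function_classes={"tRNA sulfurtransferase"})
            is ErrorCategory.ROLE_REALIZABLE
        )

    def test_exact_match_beats_prefix(self):
        lex = RelationLexicon(
            exact={"lacks_part": ErrorCategory.OTHER},
            prefixes={"lacks_": ErrorCategory.MISSING_ENTITY},
        )
        assert categorize_record(record("lacks_part"), lex) is ErrorCategory.OTHER
        assert categorize_record(record("lacks_limb"), lex) is ErrorCategory.MISSING_ENTITY


def axiom(subject, superclass):
    return SubClassOfAxiom(Named(label=subject), superclass, source_ontology="O")


def some(rel, filler):
    return Restriction(rel, Quantifier.SOME, Named(label=filler))


class TestRewriteTemplates:
    def test_inversion(self):
        ax = axiom(
            "Interkinetic nuclear migration",
            some("part_of", "Cell proliferation in forebrain"),
        )
        out = rewrite_axiom(
            ax, ErrorCategory.INVERTED_PART_OF, relation="part_of",
            inverse_map={"part_of": "has_part"},
        )
        assert len(out) == 1
        assert serialize_axiom(out[0]) == (
            "Cell proliferation in forebrain subClassOf "
            "has_part some Interkinetic nuclear migration"
        )

    def test_inversion_without_inverse_names_the_relation(self):
        ax = axiom("A", some("part_of", "B"))
        with pytest.raises(RewriteError, match="part_of"):
            rewrite_axiom(ax, ErrorCategory.INVERTED_PART_OF, relation="part_of")

    def test_chemical_structure_value_substitution(self):
        ax = axiom("Nitrosobenzene", some("has_parent_hydride", "Benzene"))
        out = rewrite_axiom(ax, ErrorCategory.CHEMICAL_STRUCTURE)
        assert serialize_axiom(out[0]) == (
            "Nitrosobenzene subClassOf has_parent_hydride only Benzene"
        )

    def test_missing_entity_negated_participation_preserves_conjuncts(self):
        ax = axiom(
            "Chordin isoform 1 unmodified form",
            And((Named(label="Chordin isoform 1"),
                 some("lacks_modification", "Post-translational protein modification"))),
        )
        out = rewrite_axiom(ax, ErrorCategory.MISSING_ENTITY,
                            relation="lacks_modification")
        assert serialize_expression(out[0].superclass) == (
            "Chordin isoform 1 and "
            "not (participant_of some Post-translational protein modification)"
        )

    def test_role_only_substitution(self):
        ax = axiom("Anisotropine methylbromide", some("has_role", "Anti-ulcer drug"))
        out = rewrite_axiom(ax, ErrorCategory.ROLE_REALIZABLE)
        assert serialize_axiom(out[0]) == (
            "Anisotropine methylbromide subClassOf has_role only Anti-ulcer drug"
        )

    def test_function_input_realization(self):
        ax = axiom("tRNA sulfurtransferase", some("has_input", "Transfer RNA"))
        out = rewrite_axiom(ax, ErrorCategory.ROLE_REALIZABLE, relation="has_input")
        assert serialize_axiom(out[0]) == (
            "tRNA sulfurtransferase subClassOf "
            "has_realization only (has_input some Transfer RNA)"
        )

    def test_time_dependency_only_substitution(self):
        ax = axiom("Pharyngeal endoderm", some("end", "Pharyngula:Prim-15"))
        out = rewrite_axiom(ax, ErrorCategory.TIME_DEPENDENCY)
        assert serialize_axiom(out[0]) == (
            "Pharyngeal endoderm subClassOf end only Pharyngula:Prim-15"
        )

    def test_other_proposes_nothing(self):
        ax = axiom("A", some("part_of", "B"))
        assert rewrite_axiom(ax, ErrorCategory.OTHER) == []

    def test_custom_carriers(self):
        ax = axiom("A", some("lacks_part", "B"))
        out = rewrite_axiom(
            ax, ErrorCategory.MISSING_ENTITY,
            carriers=Carriers(participation="has_part"),
        )
        assert serialize_expression(out[0].superclass) == "not (has_part some B)"


class TestRewriteProperties:
    CASES = [
        (ErrorCategory.CHEMICAL_STRUCTURE, "has_parent_hydride"),
        (ErrorCategory.MISSING_ENTITY, "lacks_modification"),
        (ErrorCategory.ROLE_REALIZABLE, "has_role"),
        (ErrorCategory.ROLE_REALIZABLE, "has_input"),
        (ErrorCategory.TIME_DEPENDENCY, "end"),
    ]

    @staticmethod
    def asserted_some_pairs(expr):
        """Independent tree scan: (relation, filler) of every SOME clause
        in an existence-asserting position — conjuncts, disjuncts and the
        fillers of some/exactly/min, but not negations or only/max
        fillers, which claim no instances exist."""
        out = []
        if isinstance(expr, Restriction):
            if expr.quantifier is Quantifier.SOME:
                out.append((expr.relation, expr.filler))
                out.extend(TestRewriteProperties.asserted_some_pairs(expr.filler))
            elif expr.quantifier in (Quantifier.EXACTLY, Quantifier.MIN):
                out.extend(TestRewriteProperties.asserted_some_pairs(expr.filler))
        elif isinstance(expr, And):
            for op in expr.operands:
                out.extend(TestRewriteProperties.asserted_some_pairs(op))
        elif hasattr(expr, "operands"):  # Or
            for op in expr.operands:
                out.extend(TestRewriteProperties.asserted_some_pairs(op))
        return out

    @pytest.mark.parametrize("category,relation", CASES)
    def test_dependence_removal(self, category, relation):
        """No non-inversion rewrite leaves a dependence-asserting SOME
        restriction over the original (relation, filler) pair in its
        output."""
        filler = Named(label="T")
        ax = axiom("A", And((Named(label="B"), some(relation, "T"))))
        for out in rewrite_axiom(ax, category, relation=relation):
            assert (relation, filler) not in self.asserted_some_pairs(out.superclass)

    @pytest.mark.parametrize("category,relation", CASES)
    def test_idempotence(self, category, relation):
        ax = axiom("A", some(relation, "T"))
        once = rewrite_axiom(ax, category, relation=relation)
        twice = rewrite_axiom(once[0], category, relation=relation)
        assert twice in ([once[0]], [])

    def test_inversion_property(self):
        ax = axiom("A", some("part_of", "B"))
        inv = {"part_of": "has_part"}
        out = rewrite_axiom(ax, ErrorCategory.INVERTED_PART_OF, relation="part_of",
                            inverse_map=inv)[0]
        assert out.subject == Named(label="B")
        assert out.superclass == Restriction("has_part", Quantifier.SOME,
                                             Named(label="A"))
        # a second pass finds no flagged relation left and changes nothing
        again = rewrite_axiom(out, ErrorCategory.INVERTED_PART_OF,
                              relation="part_of", inverse_map=inv)
        assert again == [out]

    def test_sibling_conjuncts_survive(self):
        ax = axiom("A", And((Named(label="B"), Named(label="C"),
                             some("has_role", "R"))))
        out = rewrite_axiom(ax, ErrorCategory.ROLE_REALIZABLE, relation="has_role")[0]
        assert isinstance(out.superclass, And)
        assert out.superclass.operands[0] == Named(label="B")
        assert out.superclass.operands[1] == Named(label="C")


class TestRewriteReport:
    def _flagged_ontology(self):
        onto = Ontology(ontology_id="O")
        cases = [
            ("Nitrosobenzene", some("has_parent_hydride", "Benzene"),
             ErrorCategory.CHEMICAL_STRUCTURE),
            ("Unmodified form", And((Named(label="Isoform"),
                                     some("lacks_modification", "PTM"))),
             ErrorCategory.MISSING_ENTITY),
            ("Methylbromide", some("has_role", "Anti-ulcer drug"),
             ErrorCategory.ROLE_REALIZABLE),
            ("Endoderm", some("end", "Prim-15"), ErrorCategory.TIME_DEPENDENCY),
            ("Migration", some("part_of", "Proliferation"),
             ErrorCategory.INVERTED_PART_OF),
        ]
        for subject, superclass, _ in cases:
            onto.add_axiom(axiom(subject, superclass))
        records = extract_existential_records(onto)
        flagged = [(rec, cases[rec.axiom_index][2]) for rec in records]
        return onto, flagged

    def test_five_planted_categories_give_five_rows(self):
        onto, flagged = self._flagged_ontology()
        report = rewrite_report(flagged, onto,
                                inverse_map={"part_of": "has_part"})
        assert sum(report.by_category.values()) == 5
        assert len(report.by_category) == 5
        assert len(report.pairs) == 5
        text = report.to_text()
        assert "INVERTED_PART_OF: 1" in text

    def test_all_other_yields_no_rewrites(self):
        onto = Ontology(ontology_id="O")
        onto.add_axiom(axiom("A", some("part_of", "B")))
        records = extract_existential_records(onto)
        report = rewrite_report([(records[0], ErrorCategory.OTHER)], onto)
        assert report.pairs == [] and report.n_no_rewrite == 1
        assert "no rewrites proposed" in report.to_text()

    def test_listing_roundtrips_through_compact_syntax(self):
        onto, flagged = self._flagged_ontology()
        report = rewrite_report(flagged, onto,
                                inverse_map={"part_of": "has_part"})
        for before, after in report.pairs:
            for rendered in (before, after):
                _, _, expr_text = rendered.partition(" subClassOf ")
                reparsed = parse_expression(expr_text)
                assert serialize_expression(reparsed) == expr_text
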