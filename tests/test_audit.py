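"""Record extraction, stratification, sampling and rater assignment."""

import io
from math import comb

import numpy as np
import pytest

from oboaudit import (
    And,
    Named,
    Not,
    Ontology,
    Quantifier,
    RaterAssignment,
    Restriction,
    SamplePlan,
    SubClassOfAxiom,
    assign_raters,
    build_strata,
    draw_sample,
    extract_existential_records,
    read_rating_responses,
    write_rating_sheet,
)


class TestExtraction:
    def test_single_top_level_restriction(self, ankle_axiom):
        onto = Ontology(ontology_id="MA")
        onto.add_axiom(ankle_axiom)
        recs = extract_existential_records(onto)
        assert len(recs) == 1
        rec = recs[0]
        assert (rec.source_ontology, rec.class_source, rec.relation, rec.class_target) \
            == ("MA", "ankle", "part_of", "hindlimb")
        assert rec.nesting_depth == 0

    def test_conjunct_embedded_restriction_has_depth_one(self):
        # unmodified-isoform shape: Named and (lacks_modification some PTM)
        onto = Ontology(ontology_id="PR")
        onto.add_axiom(
            SubClassOfAxiom(
                subject=Named(label="Chordin isoform 1 unmodified form"),
                superclass=And(
                    (
                        Named(label="Chordin isoform 1"),
                        Restriction(
                            "lacks_modification",
                            Quantifier.SOME,
                            Named(label="Post-translational protein modification"),
                        ),
                    )
                ),
                source_ontology="PR",
            )
        )
        recs = extract_existential_records(onto)
        assert len(recs) == 1
        assert recs[0].relation == "lacks_modification"
        assert recs[0].nesting_depth == 1

    def test_only_quantifiers_yield_no_records(self):
        onto = Ontology()
        onto.add_axiom(
            SubClassOfAxiom(
                subject=Named(label="A"),
                superclass=Restriction("r", Quantifier.ONLY, Named(label="B")),
            )
        )
        assert extract_existential_records(onto) == []

    def test_anonymous_filler_serialized_as_target(self):
        onto = Ontology()
        onto.add_axiom(
            SubClassOfAxiom(
                subject=Named(label="A"),
                superclass=Restriction(
                    "r",
                    Quantifier.SOME,
                    Not(Restriction("s", Quantifier.ONLY, Named(label="B"))),
                ),
            )
        )
        recs = extract_existential_records(onto)
        assert recs[0].class_target == "not (s only B)"

    def test_count_invariant_under_axiom_permutation(self, mixed_fixture):
        onto, _ = mixed_fixture
        shuffled = Ontology(ontology_id=onto.ontology_id, terms=onto.terms)
        rng = np.random.default_rng(7)
        for i in rng.permutation(len(onto.axioms)):
            shuffled.add_axiom(onto.axioms[i])
        a = extract_existential_records(onto)
        b = extract_existential_records(shuffled)
        assert len(a) == len(b) == 155
        key = lambda r: (r.class_source, r.relation, r.class_target)
        assert sorted(map(key, a)) == sorted(map(key, b))


class TestStrata:
    def test_partition_sums_to_total(self, mixed_fixture):
        onto, _ = mixed_fixture
        recs = extract_existential_records(onto)
        strata = build_strata(recs)
        assert len(strata) == 6
        assert sum(s.population_size for s in strata.values()) == len(recs)

    def test_single_record_single_stratum(self, ankle_axiom):
        onto = Ontology(ontology_id="MA")
        onto.add_axiom(ankle_axiom)
        strata = build_strata(extract_existential_records(onto))
        assert list(strata) == [("MA", "part_of")]
        assert strata[("MA", "part_of")].population_size == 1


class TestSampling:
    def test_cap_rule_holds_for_every_stratum(self, mixed_fixture):
        """Sampled size is exactly min(cap, population), checked
        exhaustively across strata and several caps."""
        onto, _ = mixed_fixture
        strata = build_strata(extract_existential_records(onto))
        for cap in (1, 5, 20, 100):
            sample = draw_sample(strata, SamplePlan(cap_per_stratum=cap, seed=3))
            per = {}
            for rec in sample:
                per[rec.stratum_key] = per.get(rec.stratum_key, 0) + 1
            for key, stratum in strata.items():
                assert per.get(key, 0) == min(cap, stratum.population_size)
            assert len({r.record_id for r in sample}) == len(sample)  # no duplicates

    def test_small_stratum_taken_whole(self, mixed_fixture):
        onto, _ = mixed_fixture
        strata = build_strata(extract_existential_records(onto))
        sample = draw_sample(strata, SamplePlan(cap_per_stratum=20, seed=1))
        n_small = sum(1 for r in sample if r.relation == "derives_from")
        assert n_small == 5  # population 5 < cap

    def test_deterministic_per_seed_and_sensitive_to_seed(self, mixed_fixture):
        """Same seed -> identical sample; different seeds on a 60-choose-20
        stratum coincide with probability 1/C(60,20) ~ 2e-16."""
        onto, _ = mixed_fixture
        strata = build_strata(extract_existential_records(onto))
        s1 = draw_sample(strata, SamplePlan(20, seed=11))
        s2 = draw_sample(strata, SamplePlan(20, seed=11))
        s3 = draw_sample(strata, SamplePlan(20, seed=12))
        ids = lambda s: [r.record_id for r in s]
        assert ids(s1) == ids(s2)
        assert ids(s1) != ids(s3)
        assert comb(60, 20) > 10**15  # collision chance negligible

    def test_cap_must_be_positive(self):
        with pytest.raises(ValueError):
            SamplePlan(cap_per_stratum=0)


def _records(n):
    onto = Ontology(ontology_id="S")
    for i in range(n):
        onto.add_axiom(
            SubClassOfAxiom(
                subject=Named(label=f"c{i}"),
                superclass=Restriction("part_of", Quantifier.SOME, Named(label="w")),
                source_ontology="S",
            )
        )
    return extract_existential_records(onto)


class TestAssignment:
    def test_quarter_double_rated_arithmetic(self):
        sample = _records(40)
        a = assign_raters(sample, ["r1", "r2", "r3", "r4"], 0.25, seed=5)
        n_double = sum(1 for rs in a.mapping.values() if len(rs) == 2)
        assert n_double == 10
        assert a.n_tasks == 50
        loads = {}
        for rs in a.mapping.values():
            for r in rs:
                loads[r] = loads.get(r, 0) + 1
        assert sorted(loads.values()) in ([12, 12, 13, 13], [12, 13, 12, 13])
        assert all(12 <= v <= 13 for v in loads.values())

    def test_zero_double_fraction(self):
        a = assign_raters(_records(40), ["r1", "r2"], 0.0, seed=1)
        assert all(len(rs) == 1 for rs in a.mapping.values())
        assert a.n_tasks == 40

    def test_two_raters_half_double(self):
        a = assign_raters(_records(8), ["r1", "r2"], 0.5, seed=2)
        doubles = [rs for rs in a.mapping.values() if len(rs) == 2]
        assert len(doubles) == 4
        assert all(set(rs) == {"r1", "r2"} for rs in doubles)

    def test_never_same_rater_twice(self):
        a = assign_raters(_records(100), ["r1", "r2", "r3"], 0.5, seed=9)
        assert all(len(set(rs)) == len(rs) for rs in a.mapping.values())

    def test_double_rating_needs_two_raters(self):
        with pytest.raises(ValueError):
            assign_raters(_records(4), ["solo"], 0.25, seed=0)

    def test_deterministic(self):
        sample = _records(30)
        a1 = assign_raters(sample, ["a", "b", "c"], 0.25, seed=4)
        a2 = assign_raters(sample, ["a", "b", "c"], 0.25, seed=4)
        assert a1.mapping == a2.mapping


class TestRatingSheet:
    def test_sheet_rows_and_roundtrip(self):
        sample = _records(40)
        assignment = assign_raters(sample, ["r1", "r2", "r3", "r4"], 0.25, seed=5)
        buf = io.StringIO()
        write_rating_sheet(assignment, sample, buf)
        lines = buf.getvalue().strip().splitlines()
        assert lines[0].split(",")[:6] == [
            "record_id", "rater_id", "Source_Ontology", "Class_Source",
            "Relation", "Class_Target",
        ]
        assert len(lines) == 1 + assignment.n_tasks

        # fill verdicts and read back: all (record, rater) tasks preserved
        filled = lines[0] + "\n" + "\n".join(line + "yes" for line in lines[1:])
        responses = read_rating_responses(io.StringIO(filled))
        assert {(rid, rater) for rid, rater, _ in responses} == {
            (rid, rater)
            for rid, rs in assignment.mapping.items()
            for rater in rs
        }

    def test_sheet_contains_rating_columns(self, ankle_axiom):
        onto = Ontology(ontology_id="MA")
        onto.add_axiom(ankle_axiom)
        recs = extract_existential_records(onto)
        assignment = RaterAssignment(
            raters=["r1"], double_fraction=0.0,
            mapping={recs[0].record_id: ("r1",)},
        )
        buf = io.StringIO()
        write_rating_sheet(assignment, recs, buf)
        row = buf.getvalue().strip().splitlines()[1]
        assert "part_of" in row and "hindlimb" in row

    def test_bad_verdict_rejected(self):
        text = "record_id,rater_id,Source_Ontology,Class_Source,Relation,Class_Target,verdict\nr0,a,O,S,part_of,T,maybe\n"
        with pytest.raises(ValueError, match="verdict"):
            read_rating_responses(io.StringIO(text))
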