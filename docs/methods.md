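# Methods

## The problem

Biomedical ontologies maintained in the OBO flatfile format state typed
relationships between terms (`ankle part_of hindlimb`) without logical
quantification.  The standard conversion to OWL renders every such
relationship as an existential restriction — the *all-some* pattern,
`Ankle subClassOf part_of some Hindlimb` — which asserts *generic
ontological dependence*: every instance of the subject class requires
some instance of the target class to exist.  For parthood that claim is
usually right; for relations like `lacks_part`, `has_role`,
`has_parent_hydride` or developmental `start`/`end` links it is wrong
or highly questionable, and a reasoner will happily propagate the
unintended entailments.

`oboaudit` implements an audit pipeline for this failure mode:
translation under configurable patterns, extraction and stratified
sampling of existential restrictions for expert (or simulated) rating,
agreement and prevalence statistics, an error taxonomy, and corrective
axiom rewrites.

## Ontology model and I/O

Class expressions are a small algebra: named classes, object
restrictions (`some`, `only`, `exactly/min/max n`), negation,
intersection, disjunction.  Named classes are identified by CURIE when
one is present, otherwise by label.  The audited unit is the
`SubClassOf` axiom with a named subject.

Two readers are provided: an OBO 1.2-style flatfile parser (tags `id`,
`name`, `is_a`, `relationship`, `is_obsolete`; everything else ignored
with a log note, trailing `! comments` stripped) and an OWL
functional-syntax reader restricted to `SubClassOf` over the
constructors above plus `rdfs:label` annotation assertions.  Axiom
kinds outside the subset are counted in a skip report, never silently
dropped.  Both directions round-trip: `parse → write → parse` is a
fixed point on the supported subset, verified by tests.  Expressions
serialize to a compact Manchester-like syntax (`part_of some
Hindlimb`, `not (has_part some Tail)`) and parse back, which the
reports rely on.

## Translation patterns

`PatternTable` maps relation ids to translation patterns with an
all-some default.  Alternatives: value restriction (`rel only T`),
exact cardinality, negated parthood (`not (has_part some T)`), negated
participation (`not (carrier some T)`), and realization-scoped value
restriction (`rel only T` or `has_realization only T` when a carrier is
configured; the carrier defaults to the relation itself because both
published variants exist).  Only the all-some and cardinality patterns
keep an existential claim over the original relation — a property the
tests assert by tree scan.  Inverse relations (`part_of`/`has_part`)
live in configuration because OBO inputs often do not declare them; the
config loader closes the map symmetrically.

## Sampling and rating design

Every `someValuesFrom` clause anywhere in a superclass tree becomes a
rating record carrying (ontology, source class, relation, target class)
and its nesting depth — nested clauses are included because
conjunct-embedded restrictions (an unmodified protein isoform defined
as `isoform and lacks_modification some PTM`) are exactly where the
worst errors hide.  Records are stratified by (ontology, relation); a
per-stratum cap (default 20, reflecting the per-statement effort of a
real expert audit) is drawn uniformly **without replacement** — the
study design says only "at random"; without replacement is the natural
reading for a finite stratum.  A configurable fraction of sampled
statements (default 0.25) is assigned to two distinct raters, slots
filled by least-loaded raters with random tie-breaks so workloads
balance within ±1.  The published campaign's own task counts are not
exactly consistent with any single scheme, so the fraction stays a
parameter rather than hard-coding a guess.

Verdicts answer: *is the ontological dependence of the source class on
the target class justified?* — `yes`/`no`.

## Statistics

**Effective false weight.**  A record's weight is the mean of its
verdict indicators, so single-rated records contribute 0 or 1 and
double-rated disagreements contribute 0.5.  This is the only reading
under which a campaign can report a fractional false count (e.g. 83.5
of 1650), and it is used consistently for prevalence, stratum rates and
estimation.  Disagreements are *not* consensus-resolved; an optional
override of verdicts can be applied upstream by editing the response
sheet.

**Cohen's kappa.**  Double-rated records are pooled across rater
identities into one 2×2 table, each record's two slots ordered by
rater id (the campaign design does not fix rater roles; the ordering
only fixes which margin is which and is deterministic).
κ = (p_o − p_e)/(1 − p_e).  Degenerate case: if both raters are
constant and identical, p_e = 1 and κ is defined as 1 with a degenerate
CI and a log note.  The default CI is a seeded percentile bootstrap
over records (B = 2000, 2.5/97.5); an asymptotic option uses
SE = √(p_o(1−p_o)/(n(1−p_e)²)).  Kappa's prevalence dependence — near-
perfect raw agreement with κ near 0 at extreme class imbalance — is
exercised in the tests because it matters for interpreting
low-prevalence strata.

**Population estimate.**  Stratified expansion: total false count
= Σ_h N_h · p̂_h over strata, with N_h the stratum's full population of
restrictions and p̂_h the mean sampled false weight.  The 95% CI is a
stratified percentile bootstrap (resample weights within stratum,
B = 2000 default, seeded).  The originally published totals do not
document their estimator, so this estimator is this package's own
documented choice; the published totals are context, not test targets.
The bootstrap resamples with replacement and therefore ignores the
finite-population correction; with sampling fractions around 10% this
overstates the CI slightly (conservative).  Coverage is measured in the
test suite: over 200 seeded replicates of a 10-stratum fixture the 95%
CI covers the planted total in 90–99% of replicates.

**Heat-map table.**  Per-(ontology, relation) error rates with sample
size binned `<20` / `20–39` / `40+`, the table behind the usual
campaign heat-map figure; rendering is out of scope.

## Taxonomy and rewrites

The lexicon maps relations to five categories (chemical-structure
relations, `lacks_*`, `has_role`, `start`/`end`, and
`has_input`/`has_output` conditional on the subject being a function
class) with precedence exact > prefix > function-conditional > OTHER.
Function classes are detected by an explicit set or a configurable
label suffix (default `"activity"`, the naming convention of molecular
function terms).  Inverted parthood is deliberately *not* lexical: only
expert judgment can distinguish a correct `part_of` from an inverted
one, so that category must be asserted via rating metadata.

Rewrite templates per category are listed in the module docstring.  Two
numerical/structural choices deserve note:

- **Asserting positions.**  Both the rewrite matcher and the
  dependence-removal check operate on *dependence-asserting* SOME
  clauses only — conjuncts, disjuncts and fillers of
  `some`/`exactly`/`min`, but not inside a negation or an `only`/`max`
  filler, where no existence claim is made.  This is what makes the
  realization template (`has_realization only (has_input some T)`)
  dependence-free despite containing a nested `some`, and it makes
  every template idempotent: re-applying a rewrite finds no asserting
  occurrence and returns the axiom unchanged.
- **Closed-world caveat.**  Every `only` rewrite is logged with a
  warning: a value restriction enumerates admissible fillers and is
  only correct if all of them are known in advance.  The `only`
  substitution for chemical-structure relations is the best available
  pattern but remains imperfect (it still relates molecules that never
  interact); it is shipped as specified.  `start`/`end` rewrites keep
  the relation name.

Rewrites are emitted alongside source axioms; the report pairs
before/after in compact syntax.

## Synthetic fixtures and simulated raters

`generate_fixture` builds an ontology from a per-relation spec
(relation id, axiom count, planted category, planted false rate),
translates it and marks `round(rate × n)` of each relation's records as
unjustified, deterministically per seed.  Term names come from
category-flavoured templates purely for report readability; nothing
linguistic depends on them except the optional `"activity"` suffix the
generator can plant.  `SimulatedRater` answers `no` on truly false
records with probability *sensitivity* and `yes` on true ones with
probability *specificity*, each rater on an independent seeded stream.
A single master seed fans out to component seeds via
`spawn_seeds` (numpy `SeedSequence.generate_state`, reduced mod 2³¹).

What a green fixture test establishes: the pipeline's arithmetic,
determinism and invariants.  What it does not: anything about the error
rate of any real ontology — fixtures have no semantic content,
independent rater errors, and a much smaller relation inventory than a
real collection.

## Known limitations

- OBO 1.4 constructs, imports, annotation properties and property
  axioms are out of scope; the OWL reader accepts only the functional-
  syntax subset described above.
- No DL reasoning: rewritten ontologies are not checked for
  consistency.
- Kappa is two-rater only (by design of the double-rating scheme);
  multi-rater generalizations are not provided.
- The compact-syntax parser assumes class names do not contain the
  syntax keywords (`some`, `and`, ...); real labels violating this
  would need quoting, which is not implemented.
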