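# oboaudit

Audit the existential restrictions of OBO/OWL biomedical ontologies.

The standard OBO-to-OWL conversion turns every relationship line into
an existential restriction (the *all-some* pattern):

    Ankle subClassOf part_of some Hindlimb

Formally this asserts **generic ontological dependence** — every
instance of `Ankle` requires some instance of `Hindlimb` to exist.
That reading is fine for canonical parthood but wrong for many relation
types found in real ontologies: `lacks_part` means precisely the
*absence* of the target, a `has_role` may never be realized, chemical
relations like `has_parent_hydride` describe structure rather than
dependence, and developmental `start`/`end` stages are not necessary
for the structures they date.  Once such ontologies are used for
machine reasoning these axioms yield unintended entailments.

`oboaudit` is a library for quality-assurance campaigns over this axiom
class, aimed at ontology engineers and curators.  It provides:

- **I/O** — an OBO flatfile (1.2-style) parser/writer, an OWL
  functional-syntax subset reader/writer, and a compact Manchester-like
  serializer/parser for class expressions.
- **Translation** — the all-some default plus dependence-free
  alternative patterns (`only`, `exactly n`, `not (has_part some …)`,
  `not (participant_of some …)`, `has_realization only …`) selected
  per relation via a TOML-configurable pattern table.
- **Sampling** — flattening of every `someValuesFrom` clause (at any
  nesting depth) into rating records, stratification by
  (ontology, relation), capped uniform sampling (default ≤20 per
  stratum), and rater assignment with partial double-rating
  (default: one quarter of statements rated twice).
- **Statistics** — Cohen's κ with bootstrap or asymptotic CI, marginal
  prevalence with fractional weights for disagreeing double ratings,
  per-stratum error rates, stratified-expansion population estimates
  (Σ_h N_h·p̂_h) with stratified-bootstrap 95% CIs, and the binned
  heat-map table.
- **Taxonomy & rewrites** — classification of suspicious statements
  into five error categories and corrective design-pattern rewrites
  (inversion, value-restriction substitution, negated participation,
  realization-scoped restriction).
- **Simulation** — synthetic ontologies with planted per-relation error
  rates and simulated raters with configurable sensitivity/specificity,
  so every stage is testable without downloads or human raters.

## Worked example

`examples/audit_campaign.py` runs a full simulated campaign — plant
known error rates, sample, rate with four imperfect simulated experts,
and estimate.  Its output:

```
545 restrictions in 5 strata; sampled 100
125 rating tasks across 4 raters

Cohen's kappa = 0.68 [0.36, 0.92] (25 double-rated statements)
  -> chance-corrected agreement between the two verdicts per statement
marginal prevalence = 50.0/100 = 0.50
  -> share of sampled statements judged false (disagreements count 1/2)
population estimate = 174 [126, 228] false restrictions (planted: 186)
  -> stratified expansion of sampled rates to all 545 restrictions

heat-map table (rate of false restrictions per relation):
  end                  n=20  rate=0.20  bin=20-39
  has_parent_hydride   n=20  rate=0.82  bin=20-39
  has_role             n=20  rate=0.47  bin=20-39
  lacks_part           n=20  rate=0.88  bin=20-39
  part_of              n=20  rate=0.12  bin=20-39
```

The planted total (186 false restrictions) falls inside the 95%
stratified-bootstrap interval, and the per-relation rates track the
planted rates at the sampled precision.  The other examples show the
translation patterns (`examples/translate_patterns.py`) and the five
corrective rewrites on their canonical axioms
(`examples/rewrite_corrections.py`), e.g.:

```
before: Nitrosobenzene subClassOf has_parent_hydride some Benzene
after : Nitrosobenzene subClassOf has_parent_hydride only Benzene
```

See `docs/methods.md` for the statistical model, design choices and
limitations.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the whole pipeline from scratch on a seeded synthetic
campaign — generation, translation, extraction, sampling, simulated
rating, κ, prevalence, population estimate, heat-map table and rewrite
report — printing a summary and writing the results JSON to `--out`.
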