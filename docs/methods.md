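# Methods

## The model

The toolkit represents a clinical ontology network as a set of ontology
modules — each a namespace with classes, object/data/annotation
properties, individuals and annotations — plus a network-level namespace
(`red#`) that owns (i) the *meta-relations*, object properties whose
domain and range classes live in different modules, and (ii) the
Prescription Dose class, which deliberately belongs to no single domain
(a dose ties clinical-information content to drug content). Every
meta-relation carries a provenance stage: `design` for the nine relations
chosen during meta-relation design and `extraction` for the five added by
non-ontological resource integration (`presentsDisease`,
`presentsSymptom`, `hasSideEffect`, `hasContraindication`, `hasCaution`).

Assertions are a set of (subject, predicate, object) triples over named
individuals and typed literals (`string`, `integer`, `float`, ISO-8601
`date` — the only datatypes the clinical contract uses). "Anonymous"
nodes (prescription doses, ingredient mappers, restriction nodes) are
skolemized under reserved `_bn*` local names with deterministic counters,
which makes serialization reproducible and round trips trivially lossless;
no RDF blank nodes are emitted.

### Naming

The deployed network mixes Spanish and English property names, and the
toolkit preserves that deliberately: properties that appear in the
executable SPARQL of the competency registry are canonical in Spanish
(`tienePeso`, `tieneExpedienteClinico`, `resideEn`), properties only ever
named in English stay English (`presentsDisease`, `hasAge`). An alias map
resolves the English synonyms (`hasWeight` → `tienePeso`, including the
catalog spelling `hasActivePharmacueticalIngredientPerPortion`), and the
English names are attached as `rdfs:label`s. The lint pass reports the
mixture — faithfully, as the pitfall scanner did — without failing it.

## Rules

Rules are DL-safe Horn clauses (every head variable occurs in the body,
no negation) with swrlb-style builtins; arithmetic builtins unify their
first argument with the result, comparison builtins require bound
arguments. Application is monotone, so the fixpoint exists and is
order-independent; the test suite checks confluence under seeded shuffles
of rule and fact order.

Clinical constants, with units:

| quantity | value | unit |
|---|---|---|
| Overweight band, lower (inclusive) | 25 | kg/m² |
| Overweight band, upper (exclusive) | 30 | kg/m² |
| BMR slope (women ≥ 61) | 10.5 | kcal per kg |
| BMR intercept (women ≥ 61) | 596 | kcal |
| BMR age threshold (inclusive) | 61 | years |

Unit conventions (inferred from the formula magnitudes and documented as
a package convention): weight kg, height m, waist/hip cm (their ratio is
unitless), age integer years. Only the Overweight band and the
female-over-60 BMR variant ship enabled; other bands (Underweight,
Normal, Obese) and BMR variants are configuration extension slots
(`BiotypeBand`, `BMRFormula`) left empty so the specified behaviour is
the default observable behaviour. Builtin comparisons are exact IEEE
double comparisons, as SWRL's are; tests compare derived values at 1e-9
absolute tolerance.

The contraindication alert is a conjunctive join — note → dose →
ingredient → drug (through the mapper) → contraindicated entity ∩ same
note's diagnoses — materialized as a network-namespace property on the
note (`hasContraindicationAlert`) and checked in tests against an O(n²)
nested-loop oracle. Drug-catalog and Control-Plan twins of the same
ingredient are `owl:sameAs`-linked; equivalence is handled in the query
layer (the graph builder materializes the symmetric closure over subject
and object positions), not by OWL reasoning, which keeps checking cheap
and decidable.

## Cardinality checking

The checker evaluates each individual of a restricted class against the
class's restriction conjuncts (`exactly n` / `min n` / `some`), reporting
observed counts. One deliberate deviation from a strict reading: the
medical-note contract includes `exactly 1` conjuncts on BMI, waist-hip
index and BMR and a `some` conjunct on the biotype — values that only
exist *after* rules fire, and the shipped rule set is intentionally
partial (only the Overweight band, only the female-over-60 BMR). Under a
strict reading every note outside those cases would be a violation of the
schema rather than of the data. The default checker therefore treats
conjuncts on the four derived properties as upper bounds; passing
`derived_optional=frozenset()` restores the strict contract, and a test
demonstrates what the strict reading flags.

Similarly, a Clinical History individual is only created for records that
carry at least one disability, because the history class requires
`hasDisability some Discapacidad`; other history content stays on the
clinical record.

## The synthetic corpus

The generator emulates the reference corpus profile: 171 records, 90
male / 81 female; 729 diagnosis entries of which 143 insulin-dependent DM,
149 non-insulin-dependent DM and 437 spread over a ten-disease fixture
list; 1626 prescriptions of which Insulin Glargine 131, Metformin 61,
Diosmin-with-Hesperidin 58 and the remainder spread near-evenly over
twelve further fixture ingredients (the spread is capped well below 131,
so the most-prescribed drug is stable at every seed). Allocation is
deal-from-deck: decks of diagnosis and prescription cards are shuffled
with the seeded RNG and dealt so every note receives at least one of
each; totals are therefore exact for every seed, and the seed only
permutes assignments. Sign values use plausible adult ranges (weight
45–120 kg, height 1.40–1.95 m, post-prandial glucose 70–300 mg/dl, waist
drawn as 0.70–1.05 of hip). Notes per record is uniform on 1..4 — the
reference material does not constrain it, and this keeps the
one-diagnosis-per-note floor feasible (at most 684 notes against 729
diagnoses); it is exposed as a profile parameter. Ten doctors cover the
notes round-robin-then-randomly so the Doctor contract
(`writesMedicalNote some`) holds.

What the generator does **not** emulate: disease co-occurrence structure,
longitudinal sign trajectories, free-text variability beyond templated
Spanish sentences, missing data, or coding errors. Passing tests on this
corpus therefore show that the machinery (allocation, population, rules,
queries, checking) is correct, not that extraction or rules would perform
at any particular accuracy on real clinical notes. For the same reason
the per-relation extraction counts of the original study are not
reproduction targets: they depend on licensed gazetteers and real notes;
the shipped gazetteers are small synthetic fixtures and are labelled as
such.

Education levels are a 13-item fixture (the level count is documented,
the names are ours), grouped under four subclasses so the education
competency query (individuals of subclasses of `Escolaridad`) returns
exactly the 13. The 32 Mexican states are the real state list. The ATC
slice, drug products and drug-catalog texts are synthetic fixtures
(`*_FIXTURE` constants) shaped like the real resources.

## Numerical and design choices

* IRIs split at the last `#`, else the last `/`; the split is reversible
  and namespace membership decides which module owns a resource.
* Serialization is sorted N-Triples lines per module file (a valid Turtle
  subset): deterministic bytes, subjects routed to their namespace's
  file, everything else to `network.ttl`.
* Restriction conjuncts are canonically sorted before skolem naming so
  write → read → write is byte-stable.
* Meta-relation selection is rule-based (explicit selected/rejected flags
  with recorded reasons) rather than graph-theoretic redundancy search:
  the design argument is case-by-case (e.g. Patient–hasMedicalNote is
  rejected because the clinical record already reaches the note;
  treatment and diagnosis live on the note so they stay date-anchored).
* Candidates present in the candidate table but absent from the final
  relation set (attends / isAttendedBy / isIndicatedFor) are marked
  rejected with reason "absent from the final meta-relation set".
* Extraction-created object properties always take the network IRI; data
  properties the Clinical Information Administration IRI. New individuals
  go to the owning module's configured master class. Sign values parse as
  float when numeric, else string. The interactive review screen is
  replaced by a TSV review-file round trip with identical
  register/skip/edit semantics; in the automated pipeline only
  vocabulary-anchored candidates are auto-registered, free NP-V-NP
  proposals stay pending for a human.
* Semantic verification of integration name-matches is a pluggable
  predicate; the default confirms a match only when both sides share an
  external code (ATC key, ICD-10, SCTID) and otherwise leaves it for
  manual review.
* Inverse-property lint findings are informational by design: the network
  omits inverses to avoid unnecessary reasoning cost.
* The SPARQL layer supports whatever rdflib supports; the registry
  guarantees only basic graph patterns, `DISTINCT` and literal filters,
  which is all the default queries use.

## Problem sizes

The default end-to-end run (171 records, ≈420 notes, ≈30k triples)
completes in well under a minute; the test suite runs one shared pipeline
fixture plus small constructed networks, and the acceptance script's
sweeps (40k-point BMI grid, 121-age sweep) are sub-second. These sizes
were chosen to exercise every stage at the full corpus profile while
keeping iteration fast.

## Known limitations

* No OWL-DL reasoning: consistency is the cardinality contract plus the
  satisfiability scan, not a tableau check; property chains, negation and
  nominals beyond the contract are out of scope.
* Shallow Spanish NLP: no dependency parsing, negation detection ("niega
  poliuria" still tags the symptom), or word-sense disambiguation.
* `sameAs` equivalence is query-layer only and does not interact with the
  cardinality checker.
* The full content of the original deployed network (its reused SNOMED
  CT / full ICD-10 / complete drug catalog, 1367 classes and 4268
  individuals) is not reconstructable from fixtures and is not attempted.
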