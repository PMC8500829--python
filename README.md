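# ontonet

A toolkit for building, populating and evaluating a **modular clinical
ontology network** for Diabetes Mellitus care in Mexico.

Clinical knowledge about a chronic disease is scattered across vocabularies
(ICD-10, SNOMED CT, ATC), drug catalogs, epidemiological bulletins and
free-text medical records. An *ontology network* organizes that knowledge
as a set of small, independently maintainable domain ontologies — here
Person, Clinical Entity, Control Plan, Education Level, Geographic
Location and Clinical Information Administration, plus a reused Drug-ATC
ontology — joined by **meta-relations**: object properties whose domain
and range classes live in different modules and which carry the network's
own IRI (`http://www.diabetes-mexico.org/red#`). The toolkit is aimed at
ontology engineers and clinical-informatics researchers who want to apply
the same design methodology to their own domains, with every stage
testable on synthetic data.

## What it implements

* **Schema construction** (`ontonet.schema`) — the six domain modules with
  their published IRIs, the candidate/selected meta-relation workflow
  (9 design-stage + 5 extraction-stage relations), and the non-primitive
  class definitions, e.g. for Patient:

  `Paciente ≡ (resideEn exactly 1 Estado) ⊓ (hasEducationLevel exactly 1
  Escolaridad) ⊓ (tieneExpedienteClinico exactly 1 Expediente_Clinico) ⊓
  (tieneFechaNacimiento exactly 1 xsd:date) ⊓ (tieneSexo exactly 1 xsd:string)`

* **Ontology integration** (`ontonet.integrate`) — the six-stage merge of a
  drug-catalog ontology with an ATC classification slice: name matching,
  semantic verification, class-to-instance demotion of the lowest ATC
  levels (the code moves into a unique-key data property), ingredient
  *mapper* nodes for combination drugs, and SCTID/ICD-10 external
  references as annotation-only cross-links.

* **Rule engine** (`ontonet.rules`) — forward chaining with swrlb-style
  builtins over the network:

  - BMI = *w* / *t*², asserted on the medical note (`tieneIMC`);
  - waist–hip index = *ci* / *ca* (`tieneICC`);
  - human biotype band: Overweight ⇔ 25 ≤ BMI < 30;
  - basal metabolic rate for women aged ≥ 61: BMR = 10.5·*w* + 596 kcal;
  - contraindication alerts joining prescriptions with same-note diagnoses.

* **Extraction** (`ontonet.extract`) — gazetteer tagging of Spanish
  clinical text (longest match, accent-insensitive), shallow nominal
  phrases, candidate triple formation (`presentsDisease`,
  `presentsSymptom`, sign-value data properties, drug-section relations)
  and a register/skip/edit review-file round trip.

* **Population** (`ontonet.populate`) — structured JSON-lines clinical
  records become Patient / Clinical Record / Medical Note / Prescription
  Dose individuals with deterministic names.

* **Synthetic corpus** (`ontonet.synth`) — a seeded generator whose
  default profile reproduces the reference corpus margins exactly at any
  seed: 171 records (90 male / 81 female), 729 diagnoses (143 + 149 + 437),
  1626 prescriptions (Insulin Glargine 131, Metformin 61,
  Diosmin-with-Hesperidin 58).

* **Evaluation** (`ontonet.evaluate`) — a SPARQL competency-question
  registry, a cardinality-consistency checker against the non-primitive
  definitions, and an OOPS-style lint pass.

## Worked example

```python
from ontonet import run_pipeline
from ontonet.synth import corpus_counts

result = run_pipeline(seed=1)     # schema -> integrate -> synth -> populate
counts = corpus_counts(result.records)      # -> extract -> derive -> evaluate
print(counts["n_records"], counts["diagnoses_total"], counts["prescriptions_total"])
print(result.report["satisfiable"], len(result.report["cardinality_violations"]))
print(len(result.network.derivations), len(result.alerts))
```

prints

```
records: 171  (male 90 / female 81)
diagnoses: 729   prescriptions: 1626
satisfiable: True   cardinality violations: 0
competency questions passed: 9/9
derived triples: 985   contraindication alerts: 22
example alert: Nota_0006_3 prescribes MetforminaTableta850Mg, contraindicated for Gastritis
```

The corpus margins are exact for every seed; `satisfiable` means every
module holds at least one individual after population; the 985 derived
triples are BMI / waist-hip / biotype / BMR assertions, each traceable to
its producing rule via `result.network.derivations`; the alerts pair a
note's prescription with a contraindicated same-note diagnosis.

The same workflow is available as a CLI:

```bash
ontonet synth --seed 1 --out records.jsonl
ontonet build-schema --out schema/
ontonet integrate --network schema/ --out integrated/
ontonet populate --network integrated/ --records records.jsonl --out populated/
ontonet derive --network populated/ --out derived/
ontonet evaluate --network derived/ --report report.json
```

Networks are written as one deterministic Turtle file per module plus
`network.ttl`; two writes of the same network are byte-identical.

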