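# Default competency-question registry.  Prefixes are merged over the
# toolkit namespace table; each query states its expected result shape.
prefixes:
  dato: "http://www.modelo.org/datos#"
  red: "http://www.diabetes-mexico.org/red#"
  enf: "http://www.padecimientos-mexico.org/enfermedades#"
  medi: "http://www.medicamentos-mexico.org/medicamento#"
  edu: "http://www.niveleseducativos-mexico.org/niveles#"
  per: "http://www.personas-mexico.org/persona#"
  rdfs: "http://www.w3.org/2000/01/rdf-schema#"

queries:
  - id: patient_weight
    question: "What is the weight of a patient?"
    sparql: |
      SELECT ?patient ?weight ?date
      WHERE { ?patient red:tieneExpedienteClinico ?record .
              ?record dato:tieneNotaMedica ?note .
              ?note dato:tienePeso ?weight .
              ?note dato:tieneFecha ?date }
    expect: {non_empty: true, columns: [patient, weight, date]}

  - id: icd10_t2dm
    question: "What is the ICD-10 code for T2DM?"
    sparql: |
      SELECT ?icd10
      WHERE { enf:DiabetesMellitusTipo2 red:ICD10 ?icd10 }
    expect: {non_empty: true, columns: [icd10]}

  - id: lispro_presentations
    question: "What are the presentations of Insulin Lispro?"
    sparql: |
      SELECT DISTINCT ?form
      WHERE { ?x medi:tienePrincipioActivo medi:InsulinaLispro .
              ?y medi:tienePrincipioActivoPorPorcion ?x .
              ?y medi:tieneFormaFarmaceutica ?form }
    expect: {non_empty: true, columns: [form], min_rows: 2}

  - id: patient_residence
    question: "Where is patient X living?"
    sparql: |
      SELECT ?patient ?place
      WHERE { ?patient red:resideEn ?place }
    expect: {non_empty: true, columns: [patient, place]}

  - id: side_effects_of_treatment
    question: "Which side effects may a patient have from the drugs in a note?"
    sparql: |
      SELECT DISTINCT ?patient ?drug ?effect
      WHERE { ?patient red:tieneExpedienteClinico ?record .
              ?record dato:tieneNotaMedica ?note .
              ?note red:hasTreatment ?dose .
              ?dose red:hasAPIInPrescription ?api .
              ?mapper medi:tienePrincipioActivo ?api .
              ?drug medi:tienePrincipioActivoPorPorcion ?mapper .
              ?drug red:hasSideEffect ?effect }
    expect: {non_empty: true, columns: [patient, drug, effect]}

  - id: education_levels
    question: "What are the main education levels?"
    sparql: |
      SELECT ?x
      WHERE { ?ec rdfs:subClassOf edu:Escolaridad .
              ?x a ?ec }
    expect: {non_empty: true, columns: [x]}

  - id: person_categories
    question: "What are the main categories a person may belong to?"
    sparql: |
      SELECT ?category
      WHERE { ?category rdfs:subClassOf per:Persona }
    expect: {non_empty: true, columns: [category]}

  - id: note_data_types
    question: "What types of data are collected during clinical consultation?"
    sparql: |
      SELECT ?data ?range
      WHERE { ?data rdfs:domain dato:Nota_Medica .
              ?data rdfs:range ?range }
    expect: {non_empty: true, columns: [data, range]}

  - id: diagnosis_types
    question: "What are the types of diagnosis?"
    sparql: |
      SELECT ?diagnosis
      WHERE { ?diagnosis rdfs:subClassOf enf:Entidad_Clinica }
    expect: {non_empty: true, columns: [diagnosis]}
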