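# Default semantic rule set for the clinical network.
# Atoms: [prop, <property>, <subject>, <object>] | [class, <class>, <ind>]
#        [builtin, <name>, <result-or-arg>, <args...>]
# Builtins follow the swrlb vocabulary; the first argument of an arithmetic
# builtin unifies with the result.  Property names may use the Spanish
# canonical local names or their English aliases.
rules:
  - name: body_mass_index
    body:
      - [prop, "datos:tienePeso", "?n", "?p"]
      - [prop, "datos:tieneTalla", "?n", "?t"]
      - [builtin, multiply, "?t2", "?t", "?t"]
      - [builtin, divide, "?imc", "?p", "?t2"]
    head:
      - [prop, "datos:tieneIMC", "?n", "?imc"]

  - name: waist_hip_index
    body:
      - [prop, "datos:hasWaistMeasure", "?n", "?ci"]
      - [prop, "datos:hasHipMeasure", "?n", "?ca"]
      - [builtin, divide, "?icc", "?ci", "?ca"]
    head:
      - [prop, "datos:tieneICC", "?n", "?icc"]

  - name: overweight_biotype
    body:
      - [prop, "datos:tieneIMC", "?n", "?imc"]
      - [builtin, greaterThanOrEqual, "?imc", 25]
      - [builtin, lessThan, "?imc", 30]
    head:
      - [prop, "datos:hasHumanBiotype", "?n", "datos:Overweight"]

  - name: bmr_female_over_60
    body:
      - [prop, "persona:tieneSexo", "?pa", "?sx"]
      - [builtin, stringEqualIgnoreCase, "?sx", Female]
      - [prop, "red:tieneExpedienteClinico", "?pa", "?ec"]
      - [prop, "datos:tieneNotaMedica", "?ec", "?nm"]
      - [prop, "datos:hasAge", "?nm", "?e"]
      - [builtin, greaterThanOrEqual, "?e", 61]
      - [prop, "datos:tienePeso", "?nm", "?p"]
      - [builtin, multiply, "?aux", 10.5, "?p"]
      - [builtin, add, "?tasa", "?aux", 596]
    head:
      - [prop, "datos:tieneTMB", "?nm", "?tasa"]
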