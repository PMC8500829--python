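"""Rule engine: closed forms, boundaries, fixpoint behaviour, alerts."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ontonet import namespaces as NS
from ontonet.model import IRIRef, LiteralValue
from ontonet.rules import (
    Atom,
    Rule,
    RuleError,
    apply_rules,
    classify_biotype,
    compute_bmi,
    compute_bmr,
    compute_whi,
    contraindication_alerts,
    load_default_rules,
)
from ontonet.schema import build_default_network

TOL = 1e-9


class TestComputeBmi:
    @pytest.mark.parametrize(
        "weight,height,expected",
        [(80.0, 1.6, 31.25), (0.0, 1.7, 0.0), (55.0, 1.0, 55.0), (123.4, 1.0, 123.4)],
    )
    def test_weight_over_height_squared(self, weight, height, expected):
        assert compute_bmi(weight, height) == pytest.approx(expected, abs=TOL)

    def test_non_positive_height_is_a_domain_error(self):
        with pytest.raises(ValueError):
            compute_bmi(80.0, 0.0)
        with pytest.raises(ValueError):
            compute_bmi(80.0, -1.5)


class TestComputeWhi:
    @pytest.mark.parametrize(
        "waist,hip,expected", [(80.0, 100.0, 0.8), (93.0, 93.0, 1.0), (0.0, 90.0, 0.0)]
    )
    def test_waist_over_hip(self, waist, hip, expected):
        assert compute_whi(waist, hip) == pytest.approx(expected, abs=TOL)

    def test_non_positive_hip_is_a_domain_error(self):
        with pytest.raises(ValueError):
            compute_whi(80.0, 0.0)


class TestBiotypeBand:
    @pytest.mark.parametrize(
        "bmi,expected",
        [
            (25.0, "Overweight"),   # lower bound inclusive
            (29.999, "Overweight"),
            (30.0, None),           # upper bound exclusive
            (24.999, None),
            (18.0, None),
            (45.0, None),
        ],
    )
    def test_overweight_band_boundaries(self, bmi, expected):
        assert classify_biotype(bmi) == expected

    def test_band_edges_by_fine_sweep(self):
        """Grid sweep recovers the [25, 30) band exactly."""
        grid = [round(10 + 0.001 * i, 3) for i in range(40001)]
        inside = [x for x in grid if classify_biotype(x) == "Overweight"]
        assert min(inside) == 25.0
        above = [x for x in grid if x > min(inside) and classify_biotype(x) is None]
        assert min(above) == 30.0

    def test_non_finite_bmi_maps_to_none(self):
        assert classify_biotype(float("nan")) is None
        assert classify_biotype(float("inf")) is None


class TestComputeBmr:
    def test_female_over_sixty_affine_form(self):
        assert compute_bmr("Female", 65, 60.0) == pytest.approx(1226.0, abs=TOL)

    def test_age_threshold_is_sixty_one_inclusive(self):
        assert compute_bmr("Female", 61, 60.0) is not None
        assert compute_bmr("Female", 60, 60.0) is None

    def test_sex_match_is_case_insensitive_and_exclusive(self):
        assert compute_bmr("female", 70, 60.0) is not None
        assert compute_bmr("Male", 70, 60.0) is None

    @settings(max_examples=50, derandomize=True)
    @given(w1=st.integers(0, 400), w2=st.integers(0, 400))
    def test_linearity_in_weight(self, w1, w2):
        """f(w2) - f(w1) = 10.5 * (w2 - w1) exactly for integer weights."""
        f1, f2 = compute_bmr("Female", 65, float(w1)), compute_bmr("Female", 65, float(w2))
        assert f2 - f1 == 10.5 * (w2 - w1)


def _note_network(weight=80.0, height=1.6, sex=None, age=None, waist=None, hip=None):
    net = build_default_network()
    datos = net.module_for_namespace(NS.DATOS)
    persona = net.module_for_namespace(NS.PERSONA)
    note = datos.add_individual("Nota_1", datos.iri("Nota_Medica")).iri
    if weight is not None:
        net.add_assertion(note, datos.iri("tienePeso"), LiteralValue(weight))
    if height is not None:
        net.add_assertion(note, datos.iri("tieneTalla"), LiteralValue(height))
    if waist is not None:
        net.add_assertion(note, datos.iri("hasWaistMeasure"), LiteralValue(waist))
    if hip is not None:
        net.add_assertion(note, datos.iri("hasHipMeasure"), LiteralValue(hip))
    if sex is not None:
        patient = persona.add_individual("Paciente_1", persona.iri("Paciente")).iri
        record = datos.add_individual("Expediente_1", datos.iri("Expediente_Clinico")).iri
        net.add_assertion(patient, persona.iri("tieneSexo"), LiteralValue(sex))
        net.add_assertion(patient, IRIRef(net.network_iri, "tieneExpedienteClinico"), record)
        net.add_assertion(record, datos.iri("tieneNotaMedica"), note)
        net.add_assertion(note, datos.iri("hasAge"), LiteralValue(age))
    return net, note, datos


class TestApplyRules:
    def test_bmi_is_derived_on_the_note(self):
        net, note, datos = _note_network()
        apply_rules(net, load_default_rules())
        [imc] = net.objects(note, datos.iri("tieneIMC"))
        assert imc.value == pytest.approx(31.25, abs=TOL)

    def test_derived_triples_record_their_rule(self):
        net, note, datos = _note_network()
        apply_rules(net, load_default_rules())
        [imc] = net.objects(note, datos.iri("tieneIMC"))
        assert net.derivations[(note, datos.iri("tieneIMC"), imc)] == "body_mass_index"

    def test_overweight_biotype_from_chained_bmi(self):
        net, note, datos = _note_network(weight=70.0, height=1.6)  # BMI 27.34
        apply_rules(net, load_default_rules())
        assert net.objects(note, datos.iri("hasHumanBiotype")) == [datos.iri("Overweight")]

    def test_bmr_for_female_over_sixty(self):
        net, note, datos = _note_network(weight=60.0, sex="Female", age=65)
        apply_rules(net, load_default_rules())
        [tmb] = net.objects(note, datos.iri("tieneTMB"))
        assert tmb.value == pytest.approx(1226.0, abs=TOL)

    def test_no_bmr_for_male_or_younger_patients(self):
        for sex, age in (("Male", 70), ("Female", 60)):
            net, note, datos = _note_network(weight=60.0, sex=sex, age=age)
            apply_rules(net, load_default_rules())
            assert net.objects(note, datos.iri("tieneTMB")) == []

    def test_schema_only_network_is_unchanged(self):
        net = build_default_network()
        before = set(net.assertions)
        apply_rules(net, load_default_rules())
        assert net.assertions == before

    def test_monotonicity(self):
        net, _, _ = _note_network(sex="Female", age=65, waist=80.0, hip=100.0)
        before = set(net.assertions)
        apply_rules(net, load_default_rules())
        assert before <= net.assertions

    def test_non_dl_safe_rule_is_rejected_naming_the_variable(self):
        with pytest.raises(RuleError, match=r"\?ghost"):
            Rule(
                "bad",
                (Atom("prop", NS.DATOS + "tienePeso", ("?n", "?p")),),
                (Atom("prop", NS.DATOS + "tieneIMC", ("?n", "?ghost")),),
            )

    def test_fixpoint_is_confluent_under_shuffling(self):
        """Seeded shuffles of rule order and fact order reach the same
        fixpoint triple set."""
        reference = None
        for seed in range(5):
            rng = random.Random(seed)
            net, _, _ = _note_network(weight=70.0, height=1.6, sex="Female", age=65,
                                      waist=80.0, hip=100.0)
            rules = load_default_rules()
            rng.shuffle(rules)
            facts = list(net.assertions)
            rng.shuffle(facts)
            net.assertions = set(facts)
            apply_rules(net, rules)
            final = {(s.full, p.full, getattr(o, "full", o)) for s, p, o in net.assertions}
            if reference is None:
                reference = final
            assert final == reference

    def test_pipeline_derivations_match_closed_forms(self, pipeline_result):
        """On every populated note: derived BMI equals weight/height^2 and
        derived BMR matches the female-over-60 closed form, to 1e-9."""
        net = pipeline_result.network
        datos = net.module_for_namespace(NS.DATOS)
        checked = 0
        for note, imc in net.by_predicate(datos.iri("tieneIMC")):
            [w] = net.objects(note, datos.iri("tienePeso"))
            [h] = net.objects(note, datos.iri("tieneTalla"))
            assert imc.value == pytest.approx(compute_bmi(w.value, h.value), abs=TOL)
            checked += 1
        assert checked > 100
        for note, tmb in net.by_predicate(datos.iri("tieneTMB")):
            [w] = net.objects(note, datos.iri("tienePeso"))
            [age] = net.objects(note, datos.iri("hasAge"))
            assert tmb.value == pytest.approx(
                compute_bmr("Female", age.value, w.value), abs=TOL
            )


class TestContraindicationAlerts:
    def _fixture(self, rng=None, n_notes=6):
        """Small seeded network with known drug/diagnosis collisions."""
        rng = rng or random.Random(0)
        net = build_default_network()
        datos = net.module_for_namespace(NS.DATOS)
        enf = net.module_for_namespace(NS.ENF)
        medi = net.module_for_namespace(NS.MEDI)
        redns = net.network_iri
        diseases = [enf.add_individual(f"D{i}", enf.iri("Enfermedad")).iri for i in range(4)]
        apis = [medi.add_individual(f"Api{i}", medi.iri("Clasificacion_ATC")).iri for i in range(3)]
        drugs = []
        for i in range(3):
            d = medi.add_individual(f"Drug{i}", medi.iri("Medicamento")).iri
            m = medi.add_individual(f"_bnMap_Drug{i}_1", medi.iri("Mapeador_Principio_Activo")).iri
            net.add_assertion(d, medi.iri("tienePrincipioActivoPorPorcion"), m)
            net.add_assertion(m, medi.iri("tienePrincipioActivo"), apis[i])
            for dis in diseases:
                if rng.random() < 0.5:
                    net.add_assertion(d, IRIRef(redns, "hasContraindication"), dis)
            drugs.append(d)
        notes = []
        for i in range(n_notes):
            note = datos.add_individual(f"Nota_{i}", datos.iri("Nota_Medica")).iri
            for dis in diseases:
                if rng.random() < 0.5:
                    net.add_assertion(note, IRIRef(redns, "hasDiagnosis"), dis)
            for j, api in enumerate(apis):
                if rng.random() < 0.5:
                    dose = net.network_module.add_individual(
                        f"_bnDosis_{i}_{j}", net.network_module.iri("Dosis_En_Receta")
                    ).iri
                    net.add_assertion(note, IRIRef(redns, "hasTreatment"), dose)
                    net.add_assertion(dose, IRIRef(redns, "hasAPIInPrescription"), api)
            notes.append(note)
        return net, notes, drugs, diseases, apis

    def _brute_force(self, net, notes, drugs, diseases, apis):
        """O(n^2) nested-loop join oracle."""
        redns = net.network_iri
        medi = net.module_for_namespace(NS.MEDI)
        out = set()
        for note in notes:
            for dose in net.objects(note, IRIRef(redns, "hasTreatment")):
                for api in net.objects(dose, IRIRef(redns, "hasAPIInPrescription")):
                    for drug in drugs:
                        for mapper in net.objects(drug, medi.iri("tienePrincipioActivoPorPorcion")):
                            if api in net.objects(mapper, medi.iri("tienePrincipioActivo")):
                                for dis in net.objects(drug, IRIRef(redns, "hasContraindication")):
                                    if dis in net.objects(note, IRIRef(redns, "hasDiagnosis")):
                                        out.add((note, drug, dis))
        return out

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_alert_set_matches_nested_loop_join(self, seed):
        net, notes, drugs, diseases, apis = self._fixture(random.Random(seed))
        alerts = set(contraindication_alerts(net))
        assert alerts == self._brute_force(net, notes, drugs, diseases, apis)

    def test_alert_is_materialized_on_the_note(self):
        net, notes, drugs, *_ = self._fixture()
        alerts = contraindication_alerts(net)
        assert alerts, "fixture should produce at least one alert"
        note, drug, _ = alerts[0]
        prop = IRIRef(net.network_iri, "hasContraindicationAlert")
        assert drug in net.objects(note, prop)

    def test_contraindication_for_undiagnosed_disease_gives_no_alert(self):
        net = build_default_network()
        datos = net.module_for_namespace(NS.DATOS)
        enf = net.module_for_namespace(NS.ENF)
        medi = net.module_for_namespace(NS.MEDI)
        redns = net.network_iri
        d1 = enf.add_individual("D1", enf.iri("Enfermedad")).iri
        d2 = enf.add_individual("D2", enf.iri("Enfermedad")).iri
        api = medi.add_individual("ApiX", medi.iri("Clasificacion_ATC")).iri
        drug = medi.add_individual("DrugX", medi.iri("Medicamento")).iri
        mapper = medi.add_individual("_bnMap_DrugX_1", medi.iri("Mapeador_Principio_Activo")).iri
        net.add_assertion(drug, medi.iri("tienePrincipioActivoPorPorcion"), mapper)
        net.add_assertion(mapper, medi.iri("tienePrincipioActivo"), api)
        net.add_assertion(drug, IRIRef(redns, "hasContraindication"), d2)
        note = datos.add_individual("Nota_1", datos.iri("Nota_Medica")).iri
        dose = net.network_module.add_individual("_bnDosis_1", net.network_module.iri("Dosis_En_Receta")).iri
        net.add_assertion(note, IRIRef(redns, "hasDiagnosis"), d1)
        net.add_assertion(note, IRIRef(redns, "hasTreatment"), dose)
        net.add_assertion(dose, IRIRef(redns, "hasAPIInPrescription"), api)
        assert contraindication_alerts(net) == []
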