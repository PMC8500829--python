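"""Ontology integration: name matches, demotion, mappers, external refs."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ontonet import namespaces as NS
from ontonet.integrate import (
    ExternalRef,
    annotate_external_refs,
    build_incoming_atc_module,
    create_api_mappers,
    demote_classes_to_instances,
    find_name_matches,
    integrate_drug_atc,
    verify_matches,
)
from ontonet.model import ConflictError, IRIRef, NetworkSpec, OntologyModule, ResolutionError
from ontonet.schema import build_default_network
from ontonet.ttl import network_to_graph, serialize_bytes


@pytest.fixture(scope="module")
def integrated_network():
    net = build_default_network()
    return integrate_drug_atc(net)


class TestFindNameMatches:
    def test_atc_leaf_class_matches_drug_ingredient_individual(self):
        from ontonet.integrate import build_drug_base_module

        net = build_default_network()
        medi = build_drug_base_module(net)
        atc = build_incoming_atc_module()
        matches = find_name_matches(medi, atc)
        kinds = {
            (m.element_a.local_name, m.kind_a, m.kind_b)
            for m in matches
            if m.element_a.local_name == "Metformina"
        }
        assert ("Metformina", "individual", "class") in kinds
        assert all(not m.verified for m in matches)

    def test_disjoint_vocabularies_yield_no_matches(self):
        a = OntologyModule("http://t.org/a#", "A")
        a.add_class("Uno")
        b = OntologyModule("http://t.org/b#", "B")
        b.add_class("Dos")
        assert find_name_matches(a, b) == []

    def test_lexicon_mediated_synonym_match(self):
        a = OntologyModule("http://t.org/a#", "A")
        a.add_individual("Paracetamol")
        b = OntologyModule("http://t.org/b#", "B")
        b.add_individual("Acetaminofen")
        matches = find_name_matches(a, b, {"acetaminofen": "paracetamol"})
        assert len(matches) == 1
        assert matches[0].match_basis == "synonym"

    def test_brute_force_join_oracle(self):
        """Synonym matching equals a brute-force join of the two name sets
        through the lexicon."""
        from ontonet.extract import fold

        a = OntologyModule("http://t.org/a#", "A")
        b = OntologyModule("http://t.org/b#", "B")
        names_a = ["alfa", "beta", "gama"]
        names_b = ["uno", "dos", "beta"]
        lexicon = {"uno": "alfa", "tres": "gama"}
        for n in names_a:
            a.add_individual(n.capitalize())
        for n in names_b:
            b.add_individual(n.capitalize())
        expected = set()
        for nb in names_b:
            for na in names_a:
                if fold(na) == fold(nb):
                    expected.add((na, nb, "exact_name"))
                if lexicon.get(fold(nb)) == fold(na):
                    expected.add((na, nb, "synonym"))
        got = {
            (m.element_a.local_name.lower(), m.element_b.local_name.lower(), m.match_basis)
            for m in find_name_matches(a, b, lexicon)
        }
        assert got == expected


def _toy_atc_network():
    net = NetworkSpec()
    m = net.add_module(OntologyModule("http://t.org/atc#", "ATC"))
    root = m.add_class("Root")
    branch = m.add_class("A10BA", root.iri)
    leaf = m.add_class("A10BA02", branch.iri)
    m.label(leaf.iri, "Metformina")
    return net, m


class TestDemotion:
    def test_leaf_becomes_individual_with_key_property(self):
        net, m = _toy_atc_network()
        demote_classes_to_instances(net, m, ["A10BA02"])
        assert "A10BA02" not in m.classes
        ind = m.individuals["Metformina"]
        assert m.iri("A10BA") in ind.classes
        keys = net.objects(ind.iri, m.iri("tieneClaveATC"))
        assert [k.value for k in keys] == ["A10BA02"]

    def test_no_leaves_selected_is_a_no_op(self):
        net, m = _toy_atc_network()
        before = (dict(m.classes), dict(m.individuals))
        demote_classes_to_instances(net, m, [])
        assert (m.classes, m.individuals) == before

    def test_non_leaf_selection_is_refused_with_the_iri(self):
        net, m = _toy_atc_network()
        with pytest.raises(ResolutionError, match="A10BA"):
            demote_classes_to_instances(net, m, ["A10BA"])

    @settings(max_examples=30, derandomize=True)
    @given(n_leaves=st.integers(min_value=0, max_value=8))
    def test_count_conservation(self, n_leaves):
        """classes + individuals is conserved by demotion on any input."""
        net = NetworkSpec()
        m = net.add_module(OntologyModule("http://t.org/atc#", "ATC"))
        parent = m.add_class("P")
        for i in range(n_leaves):
            m.add_class(f"L{i:02d}", parent.iri)
        before = len(m.classes) + len(m.individuals)
        demote_classes_to_instances(net, m, [f"L{i:02d}" for i in range(n_leaves)])
        assert len(m.classes) + len(m.individuals) == before


class TestMappers:
    def test_two_ingredient_drug_gets_two_nodes_each_with_one_amount(self, integrated_network):
        net = integrated_network
        medi = net.module_for_namespace(NS.MEDI)
        drug = medi.iri("DiosminaConHesperidinaTableta500Mg")
        mappers = net.objects(drug, medi.iri("tienePrincipioActivoPorPorcion"))
        assert len(mappers) == 2
        for node in mappers:
            amounts = net.objects(node, medi.iri("tieneCantidadDePrincipioActivo"))
            assert len(amounts) == 1

    def test_single_ingredient_degenerate_case(self, integrated_network):
        net = integrated_network
        medi = net.module_for_namespace(NS.MEDI)
        drug = medi.iri("MetforminaTableta850Mg")
        assert len(net.objects(drug, medi.iri("tienePrincipioActivoPorPorcion"))) == 1

    @settings(max_examples=25, derandomize=True)
    @given(n=st.integers(min_value=0, max_value=6))
    def test_node_count_equals_portion_count(self, n):
        net = build_default_network()
        medi = net.module_for_namespace(NS.MEDI)
        drug = medi.add_individual("DrogaX", medi.iri("Medicamento")).iri
        apis = []
        for i in range(n):
            apis.append(medi.add_individual(f"Api{i}", medi.iri("Clasificacion_ATC")).iri)
        nodes = create_api_mappers(net, drug, [(a, 10.0 * (i + 1), "mg") for i, a in enumerate(apis)])
        assert len(nodes) == n

    def test_non_positive_amount_is_refused(self):
        net = build_default_network()
        medi = net.module_for_namespace(NS.MEDI)
        drug = medi.add_individual("DrogaX", medi.iri("Medicamento")).iri
        api = medi.add_individual("ApiX", medi.iri("Clasificacion_ATC")).iri
        with pytest.raises(ValueError, match="positive"):
            create_api_mappers(net, drug, [(api, 0.0, "mg")])

    def test_obsolete_flat_ingredient_class_is_eliminated(self, integrated_network):
        medi = integrated_network.module_for_namespace(NS.MEDI)
        assert "Principio_Activo" not in medi.classes
        assert not any(
            medi.iri("Principio_Activo") in ind.classes for ind in medi.individuals.values()
        )


class TestExternalRefs:
    def test_icd10_annotation_is_queryable(self, pipeline_result):
        g = network_to_graph(pipeline_result.network)
        rows = list(
            g.query(
                "SELECT ?icd10 WHERE { <%s> <%s> ?icd10 }"
                % (NS.ENF + "DiabetesMellitusTipo2", NS.RED + "ICD10")
            )
        )
        assert [str(r[0]) for r in rows] == ["E11"]

    def test_empty_ref_list_changes_nothing(self, default_network):
        before = serialize_bytes(default_network)
        annotate_external_refs(default_network, [])
        assert serialize_bytes(default_network) == before

    def test_conflicting_code_for_same_scheme_is_refused(self):
        net = build_default_network()
        enf = net.module_for_namespace(NS.ENF)
        d = enf.add_individual("X", enf.iri("Enfermedad")).iri
        annotate_external_refs(net, [ExternalRef(d.full, "ICD10", "E11")])
        annotate_external_refs(net, [ExternalRef(d.full, "ICD10", "E11")])  # same: fine
        with pytest.raises(ConflictError):
            annotate_external_refs(net, [ExternalRef(d.full, "ICD10", "E10")])

    def test_annotation_adds_no_class_or_property_axioms(self):
        """Only annotation triples change: the definitional partition of the
        graph is untouched by external referencing."""
        from rdflib.namespace import OWL, RDF

        net = build_default_network()
        enf = net.module_for_namespace(NS.ENF)
        d = enf.add_individual("X", enf.iri("Enfermedad")).iri

        def axioms(n):
            g = network_to_graph(n)
            return {
                t for t in g
                if t[1] == RDF.type or str(t[1]).startswith(str(OWL))
            }

        before = axioms(net)
        annotate_external_refs(net, [ExternalRef(d.full, "SCTID", "44054006")])
        assert axioms(net) == before


class TestResultingOntology:
    def test_ingredient_presentation_competency_still_answered(self, integrated_network):
        """After integration the drug ontology's original purpose holds: the
        pharmaceutical forms of a given ingredient are retrievable."""
        g = network_to_graph(integrated_network)
        q = """
        SELECT DISTINCT ?form WHERE {
          ?x <%(medi)stienePrincipioActivo> <%(medi)sInsulinaLispro> .
          ?y <%(medi)stienePrincipioActivoPorPorcion> ?x .
          ?y <%(medi)stieneFormaFarmaceutica> ?form }
        """ % {"medi": NS.MEDI}
        forms = {str(r[0]) for r in g.query(q)}
        assert forms == {"SOLUCION INYECTABLE", "SUSPENSION INYECTABLE"}

    def test_integration_is_deterministic(self):
        n1 = integrate_drug_atc(build_default_network())
        n2 = integrate_drug_atc(build_default_network())
        assert serialize_bytes(n1) == serialize_bytes(n2)

    def test_control_plan_twin_reaches_drug_assertions_via_sameas(self, integrated_network):
        g = network_to_graph(integrated_network, sameas_closure=True)
        q = "SELECT ?k WHERE { <%s> <%s> ?k }" % (
            NS.TRATAMIENTO + "Metformina",
            NS.MEDI + "tieneClaveATC",
        )
        assert {str(r[0]) for r in g.query(q)} == {"A10BA02"}

    def test_verified_matches_record_evidence(self, integrated_network):
        from ontonet.integrate import build_drug_base_module

        net = build_default_network()
        medi = build_drug_base_module(net)
        atc = build_incoming_atc_module()
        verified = verify_matches(find_name_matches(medi, atc), net)
        assert all(m.evidence for m in verified if m.verified)
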