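"""Extraction: tagging, nominal phrases, triplet formation, review flow."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ontonet import namespaces as NS
from ontonet.extract import (
    CandidateTriple,
    ExtractionError,
    find_nominal_phrases,
    form_triplets,
    integrate_candidates,
    integrate_triplet,
    load_fixture_gazetteers,
    read_review_file,
    review_candidates,
    tag_terms,
    write_review_file,
)
from ontonet.model import LiteralValue, ResolutionError
from ontonet.schema import build_default_network
from ontonet.ttl import serialize_bytes


@pytest.fixture(scope="module")
def gazetteers():
    return load_fixture_gazetteers()


def _net_with_note():
    net = build_default_network()
    datos = net.module_for_namespace(NS.DATOS)
    datos.add_individual("Nota_1", datos.iri("Nota_Medica"))
    return net


def semantic(tags):
    return [t for t in tags if t.tag_kind == "semantic"]


class TestTagTerms:
    def test_disease_term_is_tagged_from_the_icd10_gazetteer(self, gazetteers):
        tags = semantic(tag_terms("diabetes mellitus tipo 2", gazetteers))
        assert len(tags) == 1
        assert tags[0].tag == "Disease"
        assert tags[0].code == "E11"
        assert tags[0].source_vocab == "ICD-10"

    def test_text_without_hits_gets_only_syntactic_tags(self, gazetteers):
        tags = tag_terms("el clima estuvo agradable", gazetteers)
        assert semantic(tags) == []
        assert all(t.tag_kind == "syntactic" for t in tags)

    def test_longest_match_wins_over_nested_entry(self, gazetteers):
        tags = semantic(tag_terms("se administra insulina lispro diaria", gazetteers))
        assert [t.text.lower() for t in tags] == ["insulina lispro"]

    def test_matching_is_accent_and_case_insensitive(self, gazetteers):
        tags = semantic(tag_terms("HIPERTENSION ARTERIAL descontrolada", gazetteers))
        assert len(tags) == 1 and tags[0].code == "I10"

    def test_empty_text_yields_empty_list(self, gazetteers):
        assert tag_terms("", gazetteers) == []

    @settings(max_examples=25, derandomize=True)
    @given(
        a=st.sampled_from(
            ["refiere poliuria", "padece diabetes mellitus tipo 1", "sin hallazgos"]
        ),
        b=st.sampled_from(
            ["se indica metformina", "presenta gastritis", "control regular"]
        ),
    )
    def test_stability_under_concatenation(self, gazetteers, a, b):
        """Semantic tags of two fragments equal those of their separated
        concatenation (with offsets shifted)."""
        joined = a + ". " + b
        got = {(t.start, t.text.lower()) for t in semantic(tag_terms(joined, gazetteers))}
        shift = len(a) + 2
        expected = {(t.start, t.text.lower()) for t in semantic(tag_terms(a, gazetteers))} | {
            (t.start + shift, t.text.lower()) for t in semantic(tag_terms(b, gazetteers))
        }
        assert got == expected


class TestNominalPhrases:
    def test_noun_adjective_sequence_is_one_phrase(self, gazetteers):
        text = "molestia toracica"  # Noun Adj under the shallow tagger
        tags = tag_terms(text, gazetteers)
        phrases = find_nominal_phrases(tags)
        assert len(phrases) == 1
        start, end, _ = phrases[0]
        assert text[start:end] == "molestia toracica"

    def test_all_verb_fragment_has_no_phrases(self, gazetteers):
        tags = tag_terms("presenta refiere niega", gazetteers)
        assert find_nominal_phrases(tags) == []

    def test_phrase_covered_by_semantic_term_is_excluded(self, gazetteers):
        """The span of a gazetteer entity is subtracted from the phrase set."""
        tags = tag_terms("gastritis", gazetteers)
        assert find_nominal_phrases(tags) == []


class TestFormTriplets:
    def test_disease_list_becomes_presents_disease_candidate(self, gazetteers):
        net = _net_with_note()
        note = NS.DATOS + "Nota_1"
        text = "Diagnósticos: diabetes mellitus tipo 2."
        cands = form_triplets(net, note, tag_terms(text, gazetteers), text=text)
        hits = [c for c in cands if c.relation_ref == NS.RED + "presentsDisease"]
        assert len(hits) == 1
        assert hits[0].domain_ref == note
        assert hits[0].range_ref == NS.ENF + "DiabetesMellitusTipo2"

    def test_symptom_becomes_presents_symptom_candidate(self, gazetteers):
        net = _net_with_note()
        text = "refiere poliuria"
        cands = form_triplets(net, NS.DATOS + "Nota_1", tag_terms(text, gazetteers), text=text)
        assert any(
            c.relation_ref == NS.RED + "presentsSymptom"
            and c.range_ref == NS.ENF + "Poliuria"
            for c in cands
        )

    def test_sign_with_value_becomes_float_data_candidate(self, gazetteers):
        net = _net_with_note()
        text = "glucosa 140"
        cands = form_triplets(net, NS.DATOS + "Nota_1", tag_terms(text, gazetteers), text=text)
        sign = [c for c in cands if c.pattern == "sign-literal"]
        assert len(sign) == 1
        assert sign[0].relation_ref == NS.DATOS + "hasGlucosa"
        assert sign[0].range_ref == LiteralValue(140.0)

    def test_contraindication_section_links_drug_to_disease(self, gazetteers):
        net = build_default_network()
        medi = net.module_for_namespace(NS.MEDI)
        medi.add_individual("MetforminaTableta", medi.iri("Medicamento"))
        text = "Contraindicado en insuficiencia renal crónica."
        cands = form_triplets(
            net, NS.MEDI + "MetforminaTableta", tag_terms(text, gazetteers),
            text=text, section="contraindicaciones",
        )
        assert [
            (c.relation_ref, c.range_ref) for c in cands
        ] == [(NS.RED + "hasContraindication", NS.ENF + "InsuficienciaRenalCronica")]

    def test_unresolvable_context_raises_before_any_candidate(self, gazetteers):
        net = build_default_network()
        with pytest.raises(ResolutionError):
            form_triplets(net, NS.DATOS + "Nota_Fantasma", [], text="")


class TestReview:
    def _cands(self):
        return [
            CandidateTriple("c0001", NS.DATOS + "Nota_1", NS.RED + "presentsDisease",
                            NS.ENF + "Gastritis", "bare-list"),
            CandidateTriple("c0002", NS.DATOS + "Nota_1", NS.RED + "presentsSymptom",
                            NS.ENF + "Poliuria", "bare-list"),
        ]

    def test_register_all_round_trip(self):
        cands = self._cands()
        reviewed = review_candidates(cands, read_review_file(write_review_file(cands)))
        assert [c.status for c in reviewed] == ["registered", "registered"]

    def test_edited_range_is_retained_with_edited_status(self):
        cands = self._cands()
        records = read_review_file(write_review_file(cands))
        records[1]["range"] = NS.ENF + "Polidipsia"
        reviewed = review_candidates(cands, records)
        assert reviewed[1].status == "edited"
        assert reviewed[1].range_ref == NS.ENF + "Polidipsia"

    def test_unknown_candidate_id_lists_the_ids(self):
        with pytest.raises(ExtractionError, match="c9999"):
            review_candidates(self._cands(), [{"id": "c9999", "domain": "", "relation": "", "range": "", "action": "register"}])

    def test_skip_all_makes_integration_a_no_op(self):
        net = _net_with_note()
        cands = self._cands()
        records = read_review_file(write_review_file(cands))
        for r in records:
            r["action"] = "skip"
        reviewed = review_candidates(cands, records)
        before = serialize_bytes(net)
        integrate_candidates(net, reviewed)
        assert serialize_bytes(net) == before


class TestIntegrateTriplet:
    def test_absent_disease_is_created_under_the_master_class(self):
        net = _net_with_note()
        c = CandidateTriple("c0001", NS.DATOS + "Nota_1", NS.RED + "presentsDisease",
                            NS.ENF + "MalRaro", "bare-list", status="registered")
        integrate_triplet(net, c)
        enf = net.module_for_namespace(NS.ENF)
        assert enf.iri("Entidad_Clinica") in enf.individuals["MalRaro"].classes

    def test_fully_resolvable_candidate_adds_exactly_one_triple(self):
        net = _net_with_note()
        enf = net.module_for_namespace(NS.ENF)
        enf.add_individual("Gastritis", enf.iri("Enfermedad"))
        before = len(net.assertions)
        c = CandidateTriple("c0001", NS.DATOS + "Nota_1", NS.RED + "presentsDisease",
                            NS.ENF + "Gastritis", "bare-list", status="registered")
        integrate_triplet(net, c)
        assert len(net.assertions) == before + 1

    def test_running_the_flow_twice_is_idempotent(self):
        net = _net_with_note()
        cands = [
            CandidateTriple("c0001", NS.DATOS + "Nota_1", NS.RED + "presentsDisease",
                            NS.ENF + "MalRaro", "bare-list", status="registered"),
            CandidateTriple("c0002", NS.DATOS + "Nota_1", NS.DATOS + "hasGlucosa",
                            LiteralValue(140.0), "sign-literal", status="registered"),
        ]
        integrate_candidates(net, cands)
        once = serialize_bytes(net)
        integrate_candidates(net, cands)
        assert serialize_bytes(net) == once

    def test_property_namespace_routing(self):
        """Created object properties live in the network namespace; created
        data properties in the Clinical Information Administration one."""
        net = _net_with_note()
        obj = CandidateTriple("c0001", NS.DATOS + "Nota_1", NS.RED + "sugiereEstudio",
                              NS.ENF + "MalRaro", "NP-V-NP", status="registered")
        dat = CandidateTriple("c0002", NS.DATOS + "Nota_1", NS.DATOS + "hasGlucosa",
                              LiteralValue(140.0), "sign-literal", status="registered")
        integrate_candidates(net, [obj, dat])
        assert "sugiereEstudio" in net.network_module.object_properties
        assert "hasGlucosa" in net.module_for_namespace(NS.DATOS).data_properties

    def test_unroutable_namespace_is_an_error(self):
        net = _net_with_note()
        c = CandidateTriple("c0001", "http://nadie.invalid/x#A", NS.RED + "presentsDisease",
                            NS.ENF + "Gastritis", "bare-list", status="registered")
        with pytest.raises(ResolutionError, match="unroutable"):
            integrate_triplet(net, c)

    def test_pending_candidate_is_refused(self):
        net = _net_with_note()
        c = CandidateTriple("c0001", NS.DATOS + "Nota_1", NS.RED + "presentsDisease",
                            NS.ENF + "Gastritis", "bare-list")
        with pytest.raises(ExtractionError, match="not registered"):
            integrate_triplet(net, c)
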