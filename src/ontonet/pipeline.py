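"""End-to-end orchestration: schema -> integration -> corpus -> population
-> extraction -> rules -> evaluation.

This is the full workflow the individual modules implement piecewise; it is
what the command-line subcommands chain together and what the acceptance
checks drive.  Everything is seeded and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from . import extract, integrate, populate as pop, rules as rl, synth
from . import namespaces as NS
from .evaluate import evaluation_report
from .model import IRIRef, NetworkSpec
from .schema import build_default_network, slug

#: SNOMED CT concept ids for the two DM types (standard published codes).
SCTID_FIXTURE = {
    "DiabetesMellitusTipo1": "46635009",
    "DiabetesMellitusTipo2": "44054006",
}


def seed_clinical_entities(network: NetworkSpec) -> NetworkSpec:
    """Pre-populate the Clinical Entity module from the fixture gazetteers:
    diseases (with ICD-10 annotation codes) and symptoms, plus SCTID
    external references for the two DM types."""
    enf = network.module_for_namespace(NS.ENF)
    gazetteers = extract.load_fixture_gazetteers()
    refs = []
    for g in gazetteers:
        for e in g.entries:
            if e.tag == "Disease":
                ind = enf.add_individual(slug(e.term), enf.iri("Enfermedad"))
                enf.label(ind.iri, e.term)
                if e.code:
                    refs.append(integrate.ExternalRef(ind.iri.full, "ICD10", e.code))
            elif e.tag == "Symptom":
                ind = enf.add_individual(slug(e.term), enf.iri("Sintoma"))
                enf.label(ind.iri, e.term)
    integrate.annotate_external_refs(network, refs)
    integrate.annotate_external_refs(
        network,
        [
            integrate.ExternalRef(NS.ENF + local, "SCTID", code)
            for local, code in SCTID_FIXTURE.items()
        ],
    )
    return network


@dataclass
class PipelineResult:
    network: NetworkSpec
    records: list = field(default_factory=list)
    fragments: dict = field(default_factory=dict)
    candidates: list = field(default_factory=list)
    alerts: list = field(default_factory=list)
    report: dict = field(default_factory=dict)


def run_pipeline(
    seed: int = 0,
    profile: Optional[synth.CorpusProfile] = None,
    evaluate: bool = True,
) -> PipelineResult:
    """Build, integrate, generate, populate, extract, derive, evaluate."""
    network = build_default_network()
    integrate.integrate_drug_atc(network)
    seed_clinical_entities(network)

    records, fragments = synth.generate_corpus(profile, seed=seed)
    pop.populate(network, records)

    gazetteers = extract.load_fixture_gazetteers()
    datos_ns = NS.DATOS
    candidates: list[extract.CandidateTriple] = []
    counter = [0]
    for frag in fragments["note_fragments"]:
        note_iri = f"{datos_ns}Nota_{frag['record_id']}_{frag['note_index']}"
        tagged = extract.tag_terms(frag["text"], gazetteers)
        phrases = extract.find_nominal_phrases(tagged)
        candidates.extend(
            extract.form_triplets(
                network, note_iri, tagged, phrases, text=frag["text"], _counter=counter
            )
        )
    medi_ns = NS.MEDI
    for dt in fragments["drug_texts"]:
        drug_iri = medi_ns + slug(dt["drug"])
        tagged = extract.tag_terms(dt["text"], gazetteers)
        candidates.extend(
            extract.form_triplets(
                network, drug_iri, tagged, (), text=dt["text"],
                section=dt["section"], _counter=counter,
            )
        )
    # the deterministic stand-in for interactive review: vocabulary-anchored
    # candidates are registered, free NP-V-NP proposals stay pending
    auto = [c for c in candidates if c.pattern in ("bare-list", "individual-anchored")]
    reviewed = extract.review_candidates(auto, extract.read_review_file(extract.write_review_file(auto)))
    extract.integrate_candidates(network, reviewed)

    rl.apply_rules(network, rl.load_default_rules())
    alerts = rl.contraindication_alerts(network)

    report = evaluation_report(network) if evaluate else {}
    return PipelineResult(network, records, fragments, candidates, alerts, report)
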