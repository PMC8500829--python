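"""Namespace table and the Spanish/English property alias map.

The network mixes naming conventions on purpose: properties that appear in
the executable SPARQL of the competency-question registry carry Spanish
local names (``tienePeso``, ``resideEn``), while properties only ever named
in English (``presentsDisease``, ``hasSideEffect``) keep the English form.
English synonyms of the Spanish-canonical properties are resolved through
``ALIASES`` and attached as ``rdfs:label`` annotations, so either spelling
works in rule files and configuration.
"""

from __future__ import annotations

RED = "http://www.diabetes-mexico.org/red#"
PERSONA = "http://www.personas-mexico.org/persona#"
DATOS = "http://www.modelo.org/datos#"
ENF = "http://www.padecimientos-mexico.org/enfermedades#"
EDU = "http://www.niveleseducativos-mexico.org/niveles#"
ESTADOS = "http://www.estados-mexico.org/estados#"
TRATAMIENTO = "http://www.medida-control.com/tratamiento#"
MEDI = "http://www.medicamentos-mexico.org/medicamento#"

RDF = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
RDFS = "http://www.w3.org/2000/01/rdf-schema#"
OWL = "http://www.w3.org/2002/07/owl#"
XSD = "http://www.w3.org/2001/XMLSchema#"

RDF_TYPE = RDF + "type"
RDFS_LABEL = RDFS + "label"
RDFS_COMMENT = RDFS + "comment"
OWL_SAMEAS = OWL + "sameAs"

#: prefix -> namespace, used by config files, rule files and the query
#: registry.  ``dato`` mirrors the prefix spelling used in the published
#: competency queries.
PREFIXES: dict[str, str] = {
    "red": RED,
    "persona": PERSONA,
    "dato": DATOS,
    "datos": DATOS,
    "enf": ENF,
    "edu": EDU,
    "estados": ESTADOS,
    "trat": TRATAMIENTO,
    "medi": MEDI,
    "rdf": RDF,
    "rdfs": RDFS,
    "owl": OWL,
    "xsd": XSD,
}


def expand_curie(curie: str) -> str:
    """Expand ``prefix:Local`` using :data:`PREFIXES`; full IRIs pass through."""
    if curie.startswith("http://") or curie.startswith("https://"):
        return curie
    prefix, _, local = curie.partition(":")
    if not local or prefix not in PREFIXES:
        raise KeyError(f"unknown prefix in CURIE: {curie!r}")
    return PREFIXES[prefix] + local


# English alias -> canonical full IRI.  Keys are full IRIs built with the
# alias local name in the namespace where the canonical property lives.
_ALIAS_SPEC: list[tuple[str, str, str, str]] = [
    # (alias namespace, alias local, canonical namespace, canonical local)
    (RED, "hasClinicalRecord", RED, "tieneExpedienteClinico"),
    (RED, "livesIn", RED, "resideEn"),
    (RED, "hasAPIPrescription", RED, "hasAPIInPrescription"),
    (RED, "hasTreatmento", RED, "hasTreatment"),
    (DATOS, "hasMedicalNote", DATOS, "tieneNotaMedica"),
    (DATOS, "hasWeight", DATOS, "tienePeso"),
    (DATOS, "hasHeight", DATOS, "tieneTalla"),
    (DATOS, "hasBMI", DATOS, "tieneIMC"),
    (DATOS, "hasWHI", DATOS, "tieneICC"),
    (DATOS, "hasBMR", DATOS, "tieneTMB"),
    (DATOS, "hasDate", DATOS, "tieneFecha"),
    (PERSONA, "hasGender", PERSONA, "tieneSexo"),
    (PERSONA, "hasSex", PERSONA, "tieneSexo"),
    (MEDI, "hasActivePharmaceuticalIngredient", MEDI, "tienePrincipioActivo"),
    # catalog spelling kept verbatim as an alias
    (MEDI, "hasActivePharmacueticalIngredientPerPortion", MEDI, "tienePrincipioActivoPorPorcion"),
    (MEDI, "hasActivePharmaceuticalIngredientPerPortion", MEDI, "tienePrincipioActivoPorPorcion"),
    (MEDI, "hasAmountOfActivePharmaceuticalIngredient", MEDI, "tieneCantidadDePrincipioActivo"),
    (MEDI, "hasPharmaceuticalForm", MEDI, "tieneFormaFarmaceutica"),
]

ALIASES: dict[str, str] = {
    a_ns + a_local: c_ns + c_local for a_ns, a_local, c_ns, c_local in _ALIAS_SPEC
}

#: canonical full IRI -> preferred English label (used for rdfs:label).
ENGLISH_LABELS: dict[str, str] = {
    c_ns + c_local: a_local
    for _, a_local, c_ns, c_local in _ALIAS_SPEC
    if not a_local.startswith("hasActivePharmacuetical")
}


def canonical_iri(iri: str) -> str:
    """Map an aliased (English) property IRI onto its canonical form."""
    return ALIASES.get(iri, iri)


def resolve_name(name: str) -> str:
    """Expand a CURIE or IRI and fold aliases onto canonical IRIs."""
    return canonical_iri(expand_curie(name))
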