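"""Construction of the six domain ontology modules and the meta-relation set.

The default configuration reproduces the published network skeleton: six
domain ontologies (Control Plan, Clinical Entity, Education Level, Clinical
Information Administration, Geographic Location, Person), fourteen
meta-relations in the network namespace (nine from the design stage, five
from the non-ontological integration stage), and the non-primitive class
definitions (cardinality-restriction conjunctions) for Patient, Medical
Note, Doctor, Prescription Dose and Clinical History.

The Geographic Location module ships the 32 Mexican states.  The 13
education-level individuals are a fixture: the source material states the
count but not the names.
"""

from __future__ import annotations

from typing import Iterable, Optional

from . import namespaces as NS
from .model import (
    CardinalityRestriction,
    ConfigError,
    IRIRef,
    MetaRelation,
    NetworkSpec,
    OntologyModule,
    ResolutionError,
)

# ---------------------------------------------------------------------------
# fixtures

MEXICAN_STATES = [
    "Aguascalientes", "Baja California", "Baja California Sur", "Campeche",
    "Chiapas", "Chihuahua", "Ciudad de México", "Coahuila", "Colima",
    "Durango", "Guanajuato", "Guerrero", "Hidalgo", "Jalisco", "México",
    "Michoacán", "Morelos", "Nayarit", "Nuevo León", "Oaxaca", "Puebla",
    "Querétaro", "Quintana Roo", "San Luis Potosí", "Sinaloa", "Sonora",
    "Tabasco", "Tamaulipas", "Tlaxcala", "Veracruz", "Yucatán", "Zacatecas",
]
assert len(MEXICAN_STATES) == 32

#: fixture 13-level scale (the count is documented, the names are ours),
#: grouped so the education competency query walks subclasses.
EDUCATION_LEVELS: dict[str, list[str]] = {
    "Sin_Escolaridad": ["Ninguna", "No Especificada"],
    "Educacion_Basica": ["Preescolar", "Primaria", "Secundaria"],
    "Educacion_Media_Superior": ["Bachillerato", "Carrera Técnica", "Normal Básica"],
    "Educacion_Superior": [
        "Técnico Superior", "Licenciatura", "Especialidad", "Maestría", "Doctorado",
    ],
}
assert sum(len(v) for v in EDUCATION_LEVELS.values()) == 13


def slug(name: str) -> str:
    """Individual naming: accent-folded CamelCase (``DiabetesMellitusTipo2``)."""
    import unicodedata

    folded = "".join(
        c for c in unicodedata.normalize("NFD", name) if unicodedata.category(c) != "Mn"
    )
    parts = [p for p in folded.replace("-", " ").replace("/", " ").split() if p]
    return "".join(p[:1].upper() + p[1:] for p in parts)


# ---------------------------------------------------------------------------
# declarative default configuration

REQUIRED_DOMAINS = [
    "Control Plan",
    "Clinical Entity",
    "Education Level",
    "Clinical Information Administration",
    "Geographic Location",
    "Person",
]

MODULE_NAMESPACES = {
    "Control Plan": NS.TRATAMIENTO,
    "Clinical Entity": NS.ENF,
    "Education Level": NS.EDU,
    "Clinical Information Administration": NS.DATOS,
    "Geographic Location": NS.ESTADOS,
    "Person": NS.PERSONA,
}

#: master class per module: the class into which extraction-created
#: individuals are asserted when a proposed IRI does not resolve.
MASTER_CLASSES = {
    "Clinical Entity": "Entidad_Clinica",
    "Control Plan": "Tratamiento_Farmacologico",
    "Person": "Persona",
    "Clinical Information Administration": "Nota_Medica",
    "Education Level": "Escolaridad",
    "Geographic Location": "Estado",
    "Drug-ATC": "Medicamento",
}


def default_schema_config() -> dict:
    """The declarative configuration the builder consumes (YAML-compatible)."""
    modules = [
        {
            "domain": "Person",
            "iri": NS.PERSONA,
            "classes": [
                {"name": "Persona", "label": "Person"},
                {"name": "Paciente", "parent": "Persona", "label": "Patient"},
                {"name": "Medico", "parent": "Persona", "label": "Doctor"},
            ],
            "data_properties": [
                {"name": "tieneSexo", "domain": "Persona", "range": "string"},
                {"name": "tieneFechaNacimiento", "domain": "Persona", "range": "date"},
            ],
        },
        {
            "domain": "Clinical Entity",
            "iri": NS.ENF,
            "classes": [
                {"name": "Entidad_Clinica", "label": "Clinical Entity"},
                {"name": "Enfermedad", "parent": "Entidad_Clinica", "label": "Disease"},
                {"name": "Sintoma", "parent": "Entidad_Clinica", "label": "Symptom"},
                {"name": "Discapacidad", "parent": "Entidad_Clinica", "label": "Disability"},
                {"name": "Comorbilidad", "parent": "Entidad_Clinica", "label": "Comorbidity"},
            ],
        },
        {
            "domain": "Education Level",
            "iri": NS.EDU,
            "classes": [{"name": "Escolaridad", "label": "Education Level"}]
            + [
                {"name": group, "parent": "Escolaridad"}
                for group in EDUCATION_LEVELS
            ],
            "individuals": [
                {"name": slug(level), "class": group, "label": level}
                for group, levels in EDUCATION_LEVELS.items()
                for level in levels
            ],
        },
        {
            "domain": "Clinical Information Administration",
            "iri": NS.DATOS,
            "classes": [
                {"name": "Expediente_Clinico", "label": "Clinical Record"},
                {"name": "Nota_Medica", "label": "Medical Note"},
                {"name": "Historia_Clinica", "label": "Clinical History"},
                {"name": "Biotipo_Humano", "label": "Human Biotype"},
            ],
            "individuals": [
                {"name": "Overweight", "class": "Biotipo_Humano", "label": "Overweight"}
            ],
            "object_properties": [
                {"name": "tieneNotaMedica", "domain": "Expediente_Clinico",
                 "range": "Nota_Medica", "label": "hasMedicalNote"},
                {"name": "tieneHistoriaClinica", "domain": "Expediente_Clinico",
                 "range": "Historia_Clinica", "label": "hasClinicalHistory"},
                {"name": "hasHumanBiotype", "domain": "Nota_Medica",
                 "range": "Biotipo_Humano", "label": "hasHumanBiotype"},
            ],
            "data_properties": [
                {"name": "tienePeso", "domain": "Nota_Medica", "range": "float",
                 "label": "hasWeight"},
                {"name": "tieneTalla", "domain": "Nota_Medica", "range": "float",
                 "label": "hasHeight"},
                {"name": "tieneIMC", "domain": "Nota_Medica", "range": "float",
                 "label": "hasBMI"},
                {"name": "tieneICC", "domain": "Nota_Medica", "range": "float",
                 "label": "hasWHI"},
                {"name": "tieneTMB", "domain": "Nota_Medica", "range": "float",
                 "label": "hasBMR"},
                {"name": "tieneFecha", "domain": "Nota_Medica", "range": "date",
                 "label": "hasDate"},
                {"name": "tieneFrecuenciaCardiaca", "domain": "Nota_Medica",
                 "range": "integer"},
                {"name": "tieneFrecuenciaRespiratoria", "domain": "Nota_Medica",
                 "range": "integer"},
                {"name": "tieneTemperaturaCorporal", "domain": "Nota_Medica",
                 "range": "float"},
                {"name": "tieneGlucosaPostPrandial", "domain": "Nota_Medica",
                 "range": "integer"},
                {"name": "tieneAnalisis", "domain": "Nota_Medica", "range": "string"},
                {"name": "tieneExploracionFisica", "domain": "Nota_Medica",
                 "range": "string"},
                {"name": "tienePadecimientoActual", "domain": "Nota_Medica",
                 "range": "string"},
                {"name": "hasAge", "domain": "Nota_Medica", "range": "integer"},
                {"name": "hasWaistMeasure", "domain": "Nota_Medica", "range": "float"},
                {"name": "hasHipMeasure", "domain": "Nota_Medica", "range": "float"},
                {"name": "tieneCantidadIndicadaEnReceta", "range": "float"},
                {"name": "tieneFrecuenciaIndicadaEnReceta", "range": "float"},
                {"name": "tieneMedidaIndicadaEnReceta", "range": "string"},
            ],
        },
        {
            "domain": "Geographic Location",
            "iri": NS.ESTADOS,
            "classes": [{"name": "Estado", "label": "Geographic Location"}],
            "individuals": [
                {"name": slug(state), "class": "Estado", "label": state}
                for state in MEXICAN_STATES
            ],
        },
        {
            "domain": "Control Plan",
            "iri": NS.TRATAMIENTO,
            "classes": [
                {"name": "Plan_de_Control", "label": "Control Plan"},
                {"name": "Tratamiento_Farmacologico", "parent": "Plan_de_Control",
                 "label": "Pharmaceutical Treatment"},
                {"name": "Dieta", "parent": "Plan_de_Control", "label": "Diet"},
                {"name": "Ejercicio", "parent": "Plan_de_Control", "label": "Exercise"},
            ],
        },
    ]

    candidates = [
        {"name": "hasClinicalRecord", "domain": "persona:Paciente",
         "range": "dato:Expediente_Clinico", "selected": True},
        {"name": "hasMedicalNote", "domain": "persona:Paciente",
         "range": "dato:Nota_Medica", "selected": False,
         "rejection_reason": "redundant: Clinical Record already reaches Medical "
                             "Note via dato:tieneNotaMedica; a patient with a "
                             "clinical record also has its notes"},
        {"name": "hasTreatment", "domain": "persona:Paciente",
         "range": "red:Dosis_En_Receta", "selected": False,
         "rejection_reason": "treatment varies over time; handled on the medical "
                             "note so the assertion stays anchored to a date"},
        {"name": "livesIn", "domain": "persona:Paciente",
         "range": "estados:Estado", "selected": True},
        {"name": "hasEducationLevel", "domain": "persona:Paciente",
         "range": "edu:Escolaridad", "selected": True},
        {"name": "hasDiagnosis", "domain": "persona:Paciente",
         "range": "enf:Enfermedad", "selected": False,
         "rejection_reason": "diagnoses vary over time; handled on the medical "
                             "note so the assertion stays anchored to a date"},
        {"name": "hasTreatment", "domain": "dato:Nota_Medica",
         "range": "red:Dosis_En_Receta", "selected": True},
        {"name": "hasDiagnosis", "domain": "dato:Nota_Medica",
         "range": "enf:Enfermedad", "selected": True},
        {"name": "isIndicatedFor", "domain": "medi:Medicamento",
         "range": "enf:Enfermedad", "selected": False,
         "rejection_reason": "absent from the final meta-relation set"},
        {"name": "isWrittenBy", "domain": "dato:Nota_Medica",
         "range": "persona:Medico", "selected": True},
        {"name": "writesMedicalNote", "domain": "persona:Medico",
         "range": "dato:Nota_Medica", "selected": True},
        {"name": "attends", "domain": "persona:Medico",
         "range": "persona:Paciente", "selected": False,
         "rejection_reason": "absent from the final meta-relation set"},
        {"name": "isAttendedBy", "domain": "persona:Paciente",
         "range": "persona:Medico", "selected": False,
         "rejection_reason": "absent from the final meta-relation set"},
    ]

    meta_relations = [
        {"name": "isWrittenBy", "domain": "dato:Nota_Medica",
         "range": "persona:Medico", "stage": "design"},
        {"name": "presentsDisease", "domain": "dato:Nota_Medica",
         "range": "enf:Enfermedad", "stage": "extraction"},
        {"name": "presentsSymptom", "domain": "dato:Nota_Medica",
         "range": "enf:Sintoma", "stage": "extraction"},
        {"name": "writesMedicalNote", "domain": "persona:Medico",
         "range": "dato:Nota_Medica", "stage": "design"},
        {"name": "resideEn", "domain": "persona:Paciente",
         "range": "estados:Estado", "stage": "design"},
        {"name": "hasAPIInPrescription", "domain": "red:Dosis_En_Receta",
         "range": "medi:Clasificacion_ATC", "stage": "design"},
        {"name": "hasContraindication", "domain": "medi:Medicamento",
         "range": "enf:Entidad_Clinica", "stage": "extraction"},
        {"name": "hasDiagnosis", "domain": "dato:Nota_Medica",
         "range": "enf:Enfermedad", "stage": "design"},
        {"name": "hasDisability", "domain": "dato:Historia_Clinica",
         "range": "enf:Discapacidad", "stage": "design"},
        {"name": "hasSideEffect", "domain": "medi:Medicamento",
         "range": "enf:Entidad_Clinica", "stage": "extraction"},
        {"name": "hasEducationLevel", "domain": "persona:Paciente",
         "range": "edu:Escolaridad", "stage": "design"},
        {"name": "tieneExpedienteClinico", "domain": "persona:Paciente",
         "range": "dato:Expediente_Clinico", "stage": "design"},
        {"name": "hasCaution", "domain": "medi:Medicamento",
         "range": "enf:Entidad_Clinica", "stage": "extraction"},
        {"name": "hasTreatment", "domain": "dato:Nota_Medica",
         "range": "red:Dosis_En_Receta", "stage": "design"},
    ]

    nonprimitive = [
        {"class": "persona:Paciente", "restrictions": [
            {"property": "red:resideEn", "kind": "exactly", "n": 1,
             "filler": "estados:Estado"},
            {"property": "red:hasEducationLevel", "kind": "exactly", "n": 1,
             "filler": "edu:Escolaridad"},
            {"property": "red:tieneExpedienteClinico", "kind": "exactly", "n": 1,
             "filler": "dato:Expediente_Clinico"},
            {"property": "persona:tieneFechaNacimiento", "kind": "exactly", "n": 1,
             "filler": "date"},
            {"property": "persona:tieneSexo", "kind": "exactly", "n": 1,
             "filler": "string"},
        ]},
        {"class": "dato:Nota_Medica", "restrictions": [
            {"property": "red:hasTreatment", "kind": "some",
             "filler": "red:Dosis_En_Receta"},
            {"property": "dato:hasHumanBiotype", "kind": "some",
             "filler": "dato:Biotipo_Humano"},
            {"property": "red:hasDiagnosis", "kind": "min", "n": 1,
             "filler": "enf:Entidad_Clinica"},
            {"property": "red:isWrittenBy", "kind": "exactly", "n": 1,
             "filler": "persona:Medico"},
            {"property": "dato:tieneGlucosaPostPrandial", "kind": "some",
             "filler": "integer"},
            {"property": "dato:tieneAnalisis", "kind": "exactly", "n": 1,
             "filler": "string"},
            {"property": "dato:tieneExploracionFisica", "kind": "exactly", "n": 1,
             "filler": "string"},
            {"property": "dato:tieneFecha", "kind": "exactly", "n": 1,
             "filler": "date"},
            {"property": "dato:tieneFrecuenciaCardiaca", "kind": "exactly", "n": 1,
             "filler": "integer"},
            {"property": "dato:tieneFrecuenciaRespiratoria", "kind": "exactly",
             "n": 1, "filler": "integer"},
            {"property": "dato:tieneICC", "kind": "exactly", "n": 1,
             "filler": "float"},
            {"property": "dato:tieneIMC", "kind": "exactly", "n": 1,
             "filler": "float"},
            {"property": "dato:tienePadecimientoActual", "kind": "exactly", "n": 1,
             "filler": "string"},
            {"property": "dato:tienePeso", "kind": "exactly", "n": 1,
             "filler": "float"},
            {"property": "dato:tieneTMB", "kind": "exactly", "n": 1,
             "filler": "float"},
            {"property": "dato:tieneTalla", "kind": "exactly", "n": 1,
             "filler": "float"},
            {"property": "dato:tieneTemperaturaCorporal", "kind": "exactly", "n": 1,
             "filler": "float"},
        ]},
        {"class": "persona:Medico", "restrictions": [
            {"property": "red:writesMedicalNote", "kind": "some",
             "filler": "dato:Nota_Medica"},
        ]},
        {"class": "red:Dosis_En_Receta", "restrictions": [
            {"property": "red:hasAPIInPrescription", "kind": "some",
             "filler": "medi:Clasificacion_ATC"},
            {"property": "dato:tieneCantidadIndicadaEnReceta", "kind": "some",
             "filler": "float"},
            {"property": "dato:tieneFrecuenciaIndicadaEnReceta", "kind": "some",
             "filler": "float"},
            {"property": "dato:tieneMedidaIndicadaEnReceta", "kind": "some",
             "filler": "string"},
        ]},
        {"class": "dato:Historia_Clinica", "restrictions": [
            {"property": "red:hasDisability", "kind": "some",
             "filler": "enf:Discapacidad"},
        ]},
    ]

    return {
        "network_iri": NS.RED,
        "network_name": "Red de Ontologias DM",
        "modules": modules,
        "candidates": candidates,
        "meta_relations": meta_relations,
        "nonprimitive": nonprimitive,
    }


# ---------------------------------------------------------------------------
# operations


def build_module_schemas(config: Optional[dict] = None) -> NetworkSpec:
    """Build the six empty-but-typed domain modules from a configuration.

    Geographic Location is pre-populated with the 32 Mexican states and
    Education Level with the 13-level fixture.  Raises :class:`ConfigError`
    naming the absent domain if the configuration is incomplete, and on
    duplicate module IRIs.
    """
    cfg = config or default_schema_config()
    network = NetworkSpec(cfg.get("network_iri", NS.RED), cfg.get("network_name", "Red"))
    domains = [m["domain"] for m in cfg["modules"]]
    for required in REQUIRED_DOMAINS:
        if required not in domains:
            raise ConfigError(f"schema configuration is missing the domain: {required}")
    for mc in cfg["modules"]:
        ns = mc["iri"]
        if not ns.endswith(("#", "/")):
            ns = ns + "#"
        module = network.add_module(OntologyModule(ns, mc["domain"]))
        for cc in mc.get("classes", []):
            parent = module.iri(cc["parent"]) if cc.get("parent") else None
            cd = module.add_class(cc["name"], parent)
            module.label(cd.iri, cc.get("label", cc["name"]))
        def _cls_iri(name: Optional[str]) -> Optional[IRIRef]:
            if not name:
                return None
            if ":" in name:
                return IRIRef.parse(NS.expand_curie(name))
            return module.iri(name)

        for oc in mc.get("object_properties", []):
            pd = module.add_object_property(
                oc["name"], _cls_iri(oc.get("domain")), _cls_iri(oc.get("range"))
            )
            module.label(pd.iri, oc.get("label", oc["name"]))
        for dc in mc.get("data_properties", []):
            pd = module.add_data_property(
                dc["name"], _cls_iri(dc.get("domain")), dc.get("range", "string")
            )
            module.label(pd.iri, dc.get("label", dc["name"]))
        for ic in mc.get("individuals", []):
            ind = module.add_individual(ic["name"], module.iri(ic["class"]))
            module.label(ind.iri, ic.get("label", ic["name"]))
    # the network-level prescription-dose class (no module of its own)
    net = network.network_module
    dose = net.add_class("Dosis_En_Receta")
    net.label(dose.iri, "Prescription Dose")
    for ann in ("ICD10", "SCTID", "stage"):
        net.add_annotation_property(ann)
    return network


def ensure_drug_atc_stub(network: NetworkSpec) -> OntologyModule:
    """Declare the reused Drug-ATC module skeleton (classes and properties
    only; content arrives through the integration workflow)."""
    existing = network.modules.get("Drug-ATC")
    if existing is not None:
        return existing
    m = network.add_module(OntologyModule(NS.MEDI, "Drug-ATC"))
    med = m.add_class("Medicamento")
    m.label(med.iri, "Drug")
    atc = m.add_class("Clasificacion_ATC")
    m.label(atc.iri, "ATC_Classification")
    mapper = m.add_class("Mapeador_Principio_Activo")
    m.label(mapper.iri, "Active Pharmaceutical Ingredient Mapper")
    api = m.add_class("Principio_Activo")
    m.label(api.iri, "Active_Pharmaceutical_Ingredient")
    p = m.add_object_property("tienePrincipioActivoPorPorcion", med.iri, mapper.iri)
    m.label(p.iri, "hasActivePharmaceuticalIngredientPerPortion")
    p = m.add_object_property("tienePrincipioActivo", mapper.iri, atc.iri)
    m.label(p.iri, "hasActivePharmaceuticalIngredient")
    m.add_data_property("tieneFormaFarmaceutica", med.iri, "string")
    m.label(m.data_properties["tieneFormaFarmaceutica"].iri, "hasPharmaceuticalForm")
    m.add_data_property("tieneCantidadDePrincipioActivo", mapper.iri, "float")
    m.label(
        m.data_properties["tieneCantidadDePrincipioActivo"].iri,
        "hasAmountOfActivePharmaceuticalIngredient",
    )
    m.add_data_property("tieneMedidaDePrincipioActivo", mapper.iri, "string")
    m.add_data_property("tieneClaveATC", None, "string")
    return m


def select_meta_relations(candidates: Iterable[dict], network: NetworkSpec) -> list[dict]:
    """Filter candidate meta-relations by the configured selection flags.

    The redundancy argument is case-by-case (e.g. Patient-hasMedicalNote is
    subsumed by Patient-hasClinicalRecord composed with the record-internal
    hasMedicalNote property), so selection is rule-based: every candidate is
    either selected or carries an explicit rejection reason.
    """
    selected = []
    for cand in candidates:
        for key in ("domain", "range"):
            iri = NS.expand_curie(cand[key])
            res = network.resolve(iri)
            if res.found_as == "absent" and res.owner_module is None and not iri.startswith(network.network_iri):
                raise ResolutionError(f"candidate {cand['name']} references unknown class {iri}")
        if cand.get("selected"):
            selected.append(cand)
        elif not cand.get("rejection_reason"):
            raise ConfigError(
                f"candidate {cand['name']} is neither selected nor carries a rejection reason"
            )
    return selected


def attach_meta_relations(
    network: NetworkSpec, relations: Iterable[dict], stages: Optional[set[str]] = None
) -> NetworkSpec:
    """Materialize meta-relations as network-namespace object properties.

    ``stages`` optionally restricts attachment to a provenance subset
    ({"design"} gives the nine design-stage relations, {"extraction"} the
    five from non-ontological integration).
    """
    net = network.network_module
    for rc in relations:
        if stages is not None and rc["stage"] not in stages:
            continue
        name = rc["name"]
        canonical = NS.canonical_iri(network.network_iri + name)
        local = IRIRef.parse(canonical).local_name
        dom = IRIRef.parse(NS.expand_curie(rc["domain"]))
        rng = IRIRef.parse(NS.expand_curie(rc["range"]))
        for cls in (dom, rng):
            if network.find_class(cls) is None:
                raise ResolutionError(
                    f"meta-relation {name} names an absent class: {cls.full}"
                )
        pd = net.add_object_property(local, dom, rng)
        network.meta_relations.append(MetaRelation(pd.iri, dom, rng, rc["stage"]))
        label = NS.ENGLISH_LABELS.get(pd.iri.full, rc.get("label", local))
        net.label(pd.iri, label)
    return network


def attach_nonprimitive_defs(network: NetworkSpec, defs: Iterable[dict]) -> NetworkSpec:
    """Attach the restriction conjunctions defining the non-primitive classes."""
    for dc in defs:
        cls_iri = IRIRef.parse(NS.expand_curie(dc["class"]))
        cd = network.find_class(cls_iri)
        if cd is None:
            raise ResolutionError(f"non-primitive definition for unknown class {cls_iri.full}")
        conjuncts = []
        for rc in dc["restrictions"]:
            prop = IRIRef.parse(NS.resolve_name(rc["property"]))
            res = network.resolve(prop.full)
            if res.found_as not in ("object_property", "data_property"):
                raise ResolutionError(
                    f"restriction on undeclared property {prop.full} (class {cls_iri.full})"
                )
            filler_txt = rc["filler"]
            filler: "IRIRef | str"
            if filler_txt in ("string", "integer", "float", "date"):
                filler = filler_txt
            else:
                filler = IRIRef.parse(NS.expand_curie(filler_txt))
            conjuncts.append(
                CardinalityRestriction(prop, rc["kind"], filler, rc.get("n"))
            )
        cd.restrictions = conjuncts
    return network


def meta_relation_counts(network: NetworkSpec) -> dict[str, int]:
    counts = {"design": 0, "extraction": 0}
    for mr in network.meta_relations:
        counts[mr.stage] += 1
    counts["total"] = len(network.meta_relations)
    return counts


def build_default_network(with_drug_module: bool = True) -> NetworkSpec:
    """Six modules + Drug-ATC stub + meta-relations + non-primitive defs."""
    cfg = default_schema_config()
    network = build_module_schemas(cfg)
    if with_drug_module:
        ensure_drug_atc_stub(network)
    select_meta_relations(cfg["candidates"], network)
    attach_meta_relations(network, cfg["meta_relations"])
    attach_nonprimitive_defs(network, cfg["nonprimitive"])
    return network
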