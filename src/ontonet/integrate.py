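"""Ontology integration and external referencing.

Two methods live here.  The six-stage integration methodology merges an
incoming classification ontology into a base ontology: (1) pick the base,
(2) find same-name elements (plus lexicon synonyms), (3) verify the matches
semantically, (4) choose a representation -- the lowest classification
levels are demoted to individuals of their immediate superclass, the class
key moving into a unique-key data property, (5) settle the final structure,
creating ingredient *mapper* nodes (one anonymous node per active
pharmaceutical ingredient portion, carrying the amount) so drugs that
combine several ingredients are representable, and (6) re-check the base
ontology's original competency.  The worked case is the Mexican drug
catalog ontology against a (synthetic fixture) slice of the WHO ATC
classification.

The external-reference method attaches SNOMED CT / ICD-10 codes as
annotation properties only -- no foreign class structure is imported, which
keeps querying cheap and reasoning unaffected.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Optional, Sequence

from . import namespaces as NS
from .model import (
    ConflictError,
    IRIRef,
    LiteralValue,
    NetworkSpec,
    OntologyModule,
    ResolutionError,
)
from .schema import ensure_drug_atc_stub, slug


# ---------------------------------------------------------------------------
# name matching (stage 2) and semantic verification (stage 3)


@dataclass(frozen=True)
class NameMatch:
    element_a: IRIRef
    kind_a: str  # class | individual
    element_b: IRIRef
    kind_b: str
    match_basis: str  # exact_name | synonym
    verified: bool = False
    evidence: str = ""


def _name_table(module: OntologyModule) -> list[tuple[str, IRIRef, str]]:
    from .extract import fold

    out = []
    for cd in module.classes.values():
        out.append((fold(cd.iri.local_name.replace("_", " ")), cd.iri, "class"))
    for ind in module.individuals.values():
        out.append((fold(ind.iri.local_name.replace("_", " ")), ind.iri, "individual"))
    # labels also count as names
    for s, p, v in module.annotations:
        if p.full == NS.RDFS_LABEL:
            kind = "class" if s.local_name in module.classes else (
                "individual" if s.local_name in module.individuals else ""
            )
            if kind:
                out.append((fold(str(v.value)), s, kind))
    return out


def find_name_matches(
    base: OntologyModule,
    incoming: OntologyModule,
    synonym_lexicon: Optional[dict[str, str]] = None,
) -> list[NameMatch]:
    """Case-insensitive exact-name matches plus lexicon-mediated synonym
    matches between two modules; all returned unverified."""
    from .extract import fold

    lex = {fold(k): fold(v) for k, v in (synonym_lexicon or {}).items()}
    base_names = _name_table(base)
    inc_names = _name_table(incoming)
    by_name: dict[str, list[tuple[IRIRef, str]]] = {}
    for name, iri, kind in base_names:
        by_name.setdefault(name, []).append((iri, kind))
    seen = set()
    matches = []
    for name, iri_b, kind_b in inc_names:
        for target_name, basis in ((name, "exact_name"), (lex.get(name), "synonym")):
            if not target_name:
                continue
            for iri_a, kind_a in by_name.get(target_name, []):
                key = (iri_a, iri_b, basis)
                if key not in seen and iri_a != iri_b:
                    seen.add(key)
                    matches.append(NameMatch(iri_a, kind_a, iri_b, kind_b, basis))
    return matches


def verify_matches(
    matches: Sequence[NameMatch],
    network: NetworkSpec,
    predicate: Optional[Callable[[NameMatch], Optional[str]]] = None,
) -> list[NameMatch]:
    """Semantic verification is pluggable: the default predicate confirms a
    match when both elements carry the same external code (ATC key, ICD-10
    or SCTID annotation); matches it cannot decide stay unverified and are
    left for manual review."""

    def default_predicate(m: NameMatch) -> Optional[str]:
        codes = {}
        for side in (m.element_a, m.element_b):
            vals = set()
            for p, v in network.annotations_of(side):
                if p.local_name in ("ICD10", "SCTID"):
                    vals.add(str(v.value))
            for o in network.objects(side, IRIRef.parse(NS.MEDI + "tieneClaveATC")):
                vals.add(str(o.value))
            codes[side] = vals
        common = codes[m.element_a] & codes[m.element_b]
        return f"shared external code {sorted(common)[0]}" if common else None

    pred = predicate or default_predicate
    out = []
    for m in matches:
        evidence = pred(m)
        out.append(replace(m, verified=evidence is not None, evidence=evidence or ""))
    return out


# ---------------------------------------------------------------------------
# stage 4: class-to-instance demotion


def demote_classes_to_instances(
    network: NetworkSpec,
    module: OntologyModule,
    leaf_locals: Iterable[str],
    key_property: str = "tieneClaveATC",
) -> OntologyModule:
    """Convert selected leaf classes into individuals of their parent.

    The class key (its local name, e.g. an ATC code) moves into the
    ``key_property`` data value; the displayed name (label) becomes the
    individual's identifier.  Classes + individuals count is conserved.
    Selecting a non-leaf class is refused, naming the offending IRI.
    """
    children = {c.parent.local_name for c in module.classes.values() if c.parent is not None and c.parent.namespace == module.namespace}
    if key_property not in module.data_properties:
        module.add_data_property(key_property, None, "string")
    for local in list(leaf_locals):
        cd = module.classes.get(local)
        if cd is None:
            raise ResolutionError(f"no such class to demote: {module.namespace}{local}")
        if local in children:
            raise ResolutionError(f"refusing to demote non-leaf class {cd.iri.full}")
        label = next(
            (str(v.value) for s, p, v in module.annotations
             if s == cd.iri and p.full == NS.RDFS_LABEL),
            local,
        )
        ind_local = slug(label)
        del module.classes[local]
        module.annotations = {a for a in module.annotations if a[0] != cd.iri}
        ind = module.add_individual(ind_local, cd.parent)
        module.label(ind.iri, label)
        network.add_assertion(ind.iri, module.iri(key_property), LiteralValue(local))
    return module


# ---------------------------------------------------------------------------
# stage 5: ingredient mapper nodes


def create_api_mappers(
    network: NetworkSpec,
    drug: IRIRef,
    portions: Sequence[tuple[IRIRef, float, str]],
) -> list[IRIRef]:
    """One anonymous mapper node per (ingredient, amount, unit) portion.

    Each node carries exactly one amount and links the drug (per-portion
    property) to the ATC-classified ingredient individual.  Units are free
    text; non-positive amounts are refused.
    """
    medi = network.module_for_namespace(NS.MEDI)
    if network.find_individual(drug) is None:
        raise ResolutionError(f"unknown drug individual: {drug.full}")
    nodes = []
    for i, (api, amount, unit) in enumerate(portions, start=1):
        if amount <= 0:
            raise ValueError(f"ingredient amount must be positive, got {amount}")
        if network.find_individual(api) is None:
            raise ResolutionError(f"unknown ingredient individual: {api.full}")
        node = medi.add_individual(
            f"_bnMap_{drug.local_name}_{i}", medi.iri("Mapeador_Principio_Activo")
        )
        network.add_assertion(drug, medi.iri("tienePrincipioActivoPorPorcion"), node.iri)
        network.add_assertion(node.iri, medi.iri("tienePrincipioActivo"), api)
        network.add_assertion(
            node.iri, medi.iri("tieneCantidadDePrincipioActivo"), LiteralValue(float(amount))
        )
        network.add_assertion(
            node.iri, medi.iri("tieneMedidaDePrincipioActivo"), LiteralValue(unit)
        )
        nodes.append(node.iri)
    return nodes


# ---------------------------------------------------------------------------
# external references


@dataclass(frozen=True)
class ExternalRef:
    subject: str  # full IRI
    scheme: str  # ICD10 | SCTID
    code: str


def annotate_external_refs(network: NetworkSpec, refs: Iterable[ExternalRef]) -> NetworkSpec:
    """Attach vocabulary codes as annotations only; class/property axioms
    are untouched.  A second, different code for the same (subject, scheme)
    is a conflict."""
    for ref in refs:
        if ref.scheme not in ("ICD10", "SCTID"):
            raise ConflictError(f"unknown reference scheme: {ref.scheme}")
        subject = IRIRef.parse(ref.subject)
        prop = IRIRef(network.network_iri, ref.scheme)
        existing = [
            str(v.value) for p, v in network.annotations_of(subject) if p == prop
        ]
        if existing and ref.code not in existing:
            raise ConflictError(
                f"{subject.full} already carries {ref.scheme}={existing[0]}, refusing {ref.code}"
            )
        network.annotate(subject, prop, ref.code)
    return network


def read_refs_tsv(text: str) -> list[ExternalRef]:
    import csv
    import io

    out = []
    for row in csv.reader(io.StringIO(text), delimiter="\t"):
        if not row or row[0].startswith("#") or row[0] == "subject_iri":
            continue
        out.append(ExternalRef(row[0], row[1], row[2]))
    return out


# ---------------------------------------------------------------------------
# fixture Drug / ATC content (synthetic: a small catalog slice sufficient to
# exercise the methodology; the production resources are licensed)

#: (code, display name, parent code); parent None = child of the ATC root.
ATC_TREE_FIXTURE: list[tuple[str, str, Optional[str]]] = [
    ("A", "Tracto alimentario y metabolismo", None),
    ("A02BC", "Inhibidores de la bomba de protones", "A"),
    ("A02BC01", "Omeprazol", "A02BC"),
    ("A10", "Fármacos usados en diabetes", "A"),
    ("A10A", "Insulinas y análogos", "A10"),
    ("A10AB", "Insulinas de acción rápida", "A10A"),
    ("A10AB04", "Insulina Lispro", "A10AB"),
    ("A10AE", "Insulinas de acción prolongada", "A10A"),
    ("A10AE04", "Insulina Glargina", "A10AE"),
    ("A10B", "Hipoglucemiantes orales", "A10"),
    ("A10BA", "Biguanidas", "A10B"),
    ("A10BA02", "Metformina", "A10BA"),
    ("A10BB", "Sulfonilureas", "A10B"),
    ("A10BB01", "Glibenclamida", "A10BB"),
    ("A10BB12", "Glimepirida", "A10BB"),
    ("B", "Sangre y órganos hematopoyéticos", None),
    ("B01AC", "Antiagregantes plaquetarios", "B"),
    ("B01AC06", "Ácido Acetilsalicílico", "B01AC"),
    ("C", "Sistema cardiovascular", None),
    ("C03AA", "Tiazidas", "C"),
    ("C03AA03", "Hidroclorotiazida", "C03AA"),
    ("C05CA", "Bioflavonoides", "C"),
    ("C05CA03", "Diosmina", "C05CA"),
    ("C05CA05", "Hesperidina", "C05CA"),
    ("C05CA53", "Diosmina con Hesperidina", "C05CA"),
    ("C09AA", "Inhibidores de la ECA", "C"),
    ("C09AA01", "Captopril", "C09AA"),
    ("C09AA02", "Enalapril", "C09AA"),
    ("C09CA", "Antagonistas de angiotensina II", "C"),
    ("C09CA01", "Losartán", "C09CA"),
    ("C10AA", "Estatinas", "C"),
    ("C10AA05", "Atorvastatina", "C10AA"),
    ("C10AB", "Fibratos", "C"),
    ("C10AB02", "Bezafibrato", "C10AB"),
    ("N", "Sistema nervioso", None),
    ("N02BE", "Anilidas", "N"),
    ("N02BE01", "Paracetamol", "N02BE"),
]

#: drug products: (product name, pharmaceutical form, [(ingredient, amount, unit)])
DRUG_PRODUCTS_FIXTURE: list[tuple[str, str, list[tuple[str, float, str]]]] = [
    ("Metformina Tableta 850 mg", "TABLETA", [("Metformina", 850.0, "mg")]),
    ("Insulina Glargina Solución 100 UI/ml", "SOLUCION INYECTABLE", [("Insulina Glargina", 100.0, "UI/ml")]),
    ("Insulina Lispro Solución 100 UI/ml", "SOLUCION INYECTABLE", [("Insulina Lispro", 100.0, "UI/ml")]),
    ("Insulina Lispro Suspensión 75/25", "SUSPENSION INYECTABLE", [("Insulina Lispro", 75.0, "UI/ml")]),
    ("Glibenclamida Tableta 5 mg", "TABLETA", [("Glibenclamida", 5.0, "mg")]),
    ("Glimepirida Tableta 2 mg", "TABLETA", [("Glimepirida", 2.0, "mg")]),
    ("Diosmina con Hesperidina Tableta 500 mg", "TABLETA",
     [("Diosmina", 450.0, "mg"), ("Hesperidina", 50.0, "mg")]),
    ("Losartán Tableta 50 mg", "TABLETA", [("Losartán", 50.0, "mg")]),
    ("Captopril Tableta 25 mg", "TABLETA", [("Captopril", 25.0, "mg")]),
    ("Enalapril Tableta 10 mg", "TABLETA", [("Enalapril", 10.0, "mg")]),
    ("Atorvastatina Tableta 20 mg", "TABLETA", [("Atorvastatina", 20.0, "mg")]),
    ("Bezafibrato Tableta 200 mg", "TABLETA", [("Bezafibrato", 200.0, "mg")]),
    ("Ácido Acetilsalicílico Tableta 100 mg", "TABLETA", [("Ácido Acetilsalicílico", 100.0, "mg")]),
    ("Omeprazol Cápsula 20 mg", "CAPSULA", [("Omeprazol", 20.0, "mg")]),
    ("Paracetamol Tableta 500 mg", "TABLETA", [("Paracetamol", 500.0, "mg")]),
    ("Hidroclorotiazida Tableta 25 mg", "TABLETA", [("Hidroclorotiazida", 25.0, "mg")]),
]

#: natural-language drug-catalog sections (synthetic), the non-ontological
#: resource the extraction pipeline mines for hasSideEffect /
#: hasContraindication / hasCaution candidates.
DRUG_TEXTS_FIXTURE: dict[str, dict[str, str]] = {
    "Metformina Tableta 850 mg": {
        "contraindicaciones": "Contraindicado en insuficiencia renal crónica y en gastritis severa.",
        "efectos_secundarios": "Puede causar náusea y mareo al inicio del tratamiento.",
        "precauciones": "Vigilar en pacientes con hipotiroidismo.",
    },
    "Glibenclamida Tableta 5 mg": {
        "contraindicaciones": "Contraindicado en hipoglucemia recurrente.",
        "efectos_secundarios": "Puede causar hipoglucemia y cefalea.",
        "precauciones": "Usar con cautela en insuficiencia renal crónica.",
    },
    "Insulina Glargina Solución 100 UI/ml": {
        "contraindicaciones": "Contraindicado en hipoglucemia.",
        "efectos_secundarios": "Puede provocar hipoglucemia y fatiga.",
        "precauciones": "Ajustar dosis en insuficiencia renal crónica.",
    },
    "Ácido Acetilsalicílico Tableta 100 mg": {
        "contraindicaciones": "Contraindicado en gastritis erosiva.",
        "efectos_secundarios": "Puede causar gastritis y náusea.",
        "precauciones": "Suspender ante datos de sangrado.",
    },
    "Losartán Tableta 50 mg": {
        "contraindicaciones": "Contraindicado en el embarazo.",
        "efectos_secundarios": "Puede causar mareo y cefalea.",
        "precauciones": "Vigilar potasio en insuficiencia renal crónica.",
    },
    "Atorvastatina Tableta 20 mg": {
        "efectos_secundarios": "Puede causar fatiga y mialgias.",
        "precauciones": "Vigilar enzimas hepáticas.",
    },
}


def build_incoming_atc_module(namespace: str = "http://www.atc-clasificacion.org/atc#") -> OntologyModule:
    """The incoming ATC fixture ontology as a pure class hierarchy."""
    m = OntologyModule(namespace, "ATC")
    root = m.add_class("Clasificacion_ATC")
    m.label(root.iri, "ATC_Classification")
    for code, name, parent in ATC_TREE_FIXTURE:
        cd = m.add_class(code, m.iri(parent) if parent else root.iri)
        m.label(cd.iri, name)
    return m


def atc_leaf_codes() -> list[str]:
    parents = {p for _, _, p in ATC_TREE_FIXTURE if p}
    return [code for code, _, _ in ATC_TREE_FIXTURE if code not in parents]


def build_drug_base_module(network: NetworkSpec) -> OntologyModule:
    """Fill the Drug-ATC stub with the base drug-catalog content: drug
    product individuals, their pharmaceutical forms, and the (soon to be
    eliminated) flat Active_Pharmaceutical_Ingredient individuals."""
    medi = ensure_drug_atc_stub(network)
    api_names = {name for _, _, portions in DRUG_PRODUCTS_FIXTURE for name, _, _ in portions}
    for name in sorted(api_names):
        ind = medi.add_individual(slug(name), medi.iri("Principio_Activo"))
        medi.label(ind.iri, name)
    for name, forma, _ in DRUG_PRODUCTS_FIXTURE:
        ind = medi.add_individual(slug(name), medi.iri("Medicamento"))
        medi.label(ind.iri, name)
        network.add_assertion(ind.iri, medi.iri("tieneFormaFarmaceutica"), LiteralValue(forma))
    return medi


def integrate_drug_atc(network: NetworkSpec) -> NetworkSpec:
    """Run the six-stage methodology on the fixture Drug and ATC content.

    Stages: the drug catalog module is the base (1); name matches are found
    between ATC leaf classes and the flat ingredient individuals (2) and
    verified (3); ATC leaves are demoted to individuals keyed by their ATC
    code (4); the hierarchy is merged into the Drug-ATC module, ingredient
    mapper nodes are created per product portion and the obsolete flat
    ingredient class is eliminated (5); the original drug competency (forms
    by ingredient) remains answerable, which the evaluation suite re-checks
    (6).  Control-Plan twins of each prescribed ingredient are linked with
    ``owl:sameAs``.
    """
    medi = build_drug_base_module(network)
    incoming = build_incoming_atc_module()
    matches = find_name_matches(medi, incoming)
    verify_matches(matches, network)

    # demotion happens on a scratch network so the incoming module object
    # handed to us is never mutated in place
    scratch = NetworkSpec("http://scratch.invalid/red#")
    work = build_incoming_atc_module()
    scratch.add_module(work)
    demote_classes_to_instances(scratch, work, atc_leaf_codes())

    # merge the worked hierarchy into the Drug-ATC module
    for local, cd in work.classes.items():
        if local == "Clasificacion_ATC":
            continue
        parent_local = cd.parent.local_name if cd.parent is not None else "Clasificacion_ATC"
        medi.add_class(local, medi.iri(parent_local))
    for s, p, v in work.annotations:
        if s.local_name in medi.classes or s.local_name in work.individuals:
            medi.annotations.add((IRIRef(medi.namespace, s.local_name), p, v))
    for local, ind in work.individuals.items():
        new = medi.add_individual(local)
        for cls in ind.classes:
            new.classes.add(IRIRef(medi.namespace, cls.local_name))
    for s, p, o in scratch.assertions:
        network.add_assertion(
            IRIRef(medi.namespace, s.local_name), medi.iri(p.local_name), o
        )

    # stage 5: mapper nodes per product; the flat ingredient class goes away
    for name, _, portions in DRUG_PRODUCTS_FIXTURE:
        drug = medi.iri(slug(name))
        create_api_mappers(
            network,
            drug,
            [(medi.iri(slug(api)), amount, unit) for api, amount, unit in portions],
        )
    obsolete = [
        local for local, ind in medi.individuals.items()
        if medi.iri("Principio_Activo") in ind.classes
    ]
    for local in obsolete:
        ind = medi.individuals[local]
        ind.classes.discard(medi.iri("Principio_Activo"))
        if not ind.classes:
            # demoted ATC twin carries the data now; drop the flat duplicate
            del medi.individuals[local]
            medi.annotations = {
                a for a in medi.annotations if a[0] != IRIRef(medi.namespace, local)
            }
    medi.classes.pop("Principio_Activo", None)
    medi.annotations = {
        a for a in medi.annotations if a[0] != medi.iri("Principio_Activo")
    }

    # Control-Plan twins linked by sameAs (query-layer equivalence)
    trat = network.modules["Control Plan"]
    sameas = IRIRef.parse(NS.OWL_SAMEAS)
    for name in sorted({n for _, _, ps in DRUG_PRODUCTS_FIXTURE for n, _, _ in ps}):
        local = slug(name)
        twin = trat.add_individual(local, trat.iri("Tratamiento_Farmacologico"))
        trat.label(twin.iri, name)
        network.assertions.add((twin.iri, sameas, medi.iri(local)))
    return network
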