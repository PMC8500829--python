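"""Turtle I/O and the rdflib query graph.

On disk the network is one ``.ttl`` file per module plus ``network.ttl``
(which ``owl:imports`` the modules and holds everything in the network
namespace).  Files are written as sorted N-Triples lines -- a valid Turtle
subset -- so two writes of the same network are byte-identical and round
trips are lossless at the triple level.  Anonymous individuals are
skolemized under reserved ``_bn`` local names, so no blank nodes appear.
"""

from __future__ import annotations

import datetime as _dt
import os
import re
from typing import Iterable, Optional

import rdflib
from rdflib import Graph, Literal, URIRef
from rdflib.namespace import OWL, RDF, RDFS, XSD

from . import namespaces as NS
from .model import (
    Assertion,
    CardinalityRestriction,
    IRIRef,
    LiteralValue,
    MetaRelation,
    NetworkSpec,
    OntologyModule,
    OntologyError,
)


class ParseError(OntologyError):
    pass


_XSD_IRI = {
    "string": XSD.string,
    "integer": XSD.integer,
    "float": XSD.float,
    "date": XSD.date,
}

STAGE_PROP = NS.RED + "stage"


def _lit(value: LiteralValue) -> Literal:
    if value.datatype == "string":
        return Literal(str(value.value))
    if value.datatype == "date":
        return Literal(value.value.isoformat(), datatype=XSD.date)
    return Literal(str(value.value), datatype=_XSD_IRI[value.datatype])


def _from_lit(lit: Literal) -> LiteralValue:
    dt = lit.datatype
    if dt in (XSD.integer, XSD.int, XSD.long):
        return LiteralValue(int(lit))
    if dt in (XSD.float, XSD.double, XSD.decimal):
        return LiteralValue(float(lit))
    if dt == XSD.date:
        return LiteralValue(_dt.date.fromisoformat(str(lit)))
    return LiteralValue(str(lit))


def _base_iri(namespace: str) -> URIRef:
    return URIRef(namespace.rstrip("#/"))


def _restriction_node(cls: IRIRef, idx: int) -> URIRef:
    return URIRef(f"{cls.namespace}_bnR_{cls.local_name}_{idx}")


def _sorted_restrictions(rs: Iterable[CardinalityRestriction]):
    def key(r: CardinalityRestriction):
        filler = r.filler.full if isinstance(r.filler, IRIRef) else str(r.filler)
        return (r.on_property.full, r.kind, r.n if r.n is not None else -1, filler)

    return sorted(rs, key=key)


def network_to_graph(network: NetworkSpec, sameas_closure: bool = False) -> Graph:
    """Materialize the network as an rdflib graph.

    With ``sameas_closure`` every assertion is replicated across
    ``owl:sameAs``-equivalent individuals (in subject and object position),
    so queries through either IRI see the union of both individuals'
    assertions.  This is the query-layer reading of ``sameAs``; no OWL
    reasoning is involved.
    """
    g = Graph()
    for prefix, ns in NS.PREFIXES.items():
        if prefix != "datos":
            g.bind(prefix, ns)

    net_base = _base_iri(network.network_iri)
    g.add((net_base, RDF.type, OWL.Ontology))
    g.add((net_base, RDFS.label, Literal(network.network_module.name)))
    for module in network.modules.values():
        base = _base_iri(module.namespace)
        g.add((base, RDF.type, OWL.Ontology))
        g.add((base, RDFS.label, Literal(module.name)))
        g.add((net_base, OWL.imports, base))

    stage_by_prop = {mr.property.full: mr.stage for mr in network.meta_relations}

    for module in network.iter_modules():
        for cd in module.classes.values():
            c = URIRef(cd.iri.full)
            g.add((c, RDF.type, OWL.Class))
            if cd.parent is not None:
                g.add((c, RDFS.subClassOf, URIRef(cd.parent.full)))
            for idx, r in enumerate(_sorted_restrictions(cd.restrictions)):
                node = _restriction_node(cd.iri, idx)
                g.add((c, RDFS.subClassOf, node))
                g.add((node, RDF.type, OWL.Restriction))
                g.add((node, OWL.onProperty, URIRef(r.on_property.full)))
                data_range = isinstance(r.filler, str)
                filler = _XSD_IRI[r.filler] if data_range else URIRef(r.filler.full)
                if r.kind == "some":
                    g.add((node, OWL.someValuesFrom, filler))
                else:
                    card = OWL.qualifiedCardinality if r.kind == "exactly" else OWL.minQualifiedCardinality
                    g.add((node, card, Literal(r.n, datatype=XSD.nonNegativeInteger)))
                    g.add((node, OWL.onDataRange if data_range else OWL.onClass, filler))
        for pd in module.object_properties.values():
            p = URIRef(pd.iri.full)
            g.add((p, RDF.type, OWL.ObjectProperty))
            if pd.domain is not None:
                g.add((p, RDFS.domain, URIRef(pd.domain.full)))
            if pd.range is not None:
                g.add((p, RDFS.range, URIRef(pd.range.full)))
            stage = stage_by_prop.get(pd.iri.full)
            if stage:
                g.add((p, URIRef(STAGE_PROP), Literal(stage)))
        for dd in module.data_properties.values():
            p = URIRef(dd.iri.full)
            g.add((p, RDF.type, OWL.DatatypeProperty))
            if dd.domain is not None:
                g.add((p, RDFS.domain, URIRef(dd.domain.full)))
            g.add((p, RDFS.range, _XSD_IRI[dd.range]))
        for ad in module.annotation_properties.values():
            g.add((URIRef(ad.iri.full), RDF.type, OWL.AnnotationProperty))
        for ind in module.individuals.values():
            i = URIRef(ind.iri.full)
            g.add((i, RDF.type, OWL.NamedIndividual))
            for cls in ind.classes:
                g.add((i, RDF.type, URIRef(cls.full)))
        for s, p, v in module.annotations:
            g.add((URIRef(s.full), URIRef(p.full), _lit(v)))

    for s, p, o in network.assertions:
        obj = URIRef(o.full) if isinstance(o, IRIRef) else _lit(o)
        g.add((URIRef(s.full), URIRef(p.full), obj))

    if sameas_closure:
        _materialize_sameas(g, network)
    return g


def _materialize_sameas(g: Graph, network: NetworkSpec) -> None:
    rep: dict[URIRef, list[URIRef]] = {}
    for group in network.sameas_groups():
        uris = [URIRef(m.full) for m in group]
        for u in uris:
            rep[u] = uris
        for a in uris:
            for b in uris:
                if a != b:
                    g.add((a, OWL.sameAs, b))
    skip = {RDF.type, OWL.sameAs}
    for s, p, o in list(g.triples((None, None, None))):
        if p in skip:
            continue
        subs = rep.get(s, [s])
        objs = rep.get(o, [o]) if isinstance(o, URIRef) else [o]
        for s2 in subs:
            for o2 in objs:
                g.add((s2, p, o2))


# ---------------------------------------------------------------------------
# writing


def _nt_lines(g: Graph) -> list[str]:
    lines = set()
    for s, p, o in g:
        lines.add(f"{s.n3()} {p.n3()} {o.n3()} .")
    return sorted(lines)


def _module_filename(module: OntologyModule) -> str:
    slug = re.sub(r"[^a-z0-9]+", "_", module.name.lower()).strip("_")
    return f"{slug}.ttl"


def write_network(network: NetworkSpec, outdir: str) -> list[str]:
    """Write one Turtle file per module plus ``network.ttl``; returns paths.

    Triples are routed by subject namespace; anything outside a module
    namespace (meta-relations, network classes, dose individuals, imports)
    lands in ``network.ttl``.  Output ordering is deterministic.
    """
    os.makedirs(outdir, exist_ok=True)
    g = network_to_graph(network)
    buckets: dict[str, set] = {_module_filename(m): set() for m in network.modules.values()}
    buckets["network.ttl"] = set()
    ns_of = {m.namespace: _module_filename(m) for m in network.modules.values()}
    for s, p, o in g:
        target = "network.ttl"
        if isinstance(s, URIRef):
            text = str(s)
            for ns, fname in ns_of.items():
                if text.startswith(ns) or text == ns.rstrip("#/"):
                    target = fname
                    break
        buckets[target].add((s, p, o))
    paths = []
    for fname in sorted(buckets):
        sub = Graph()
        for t in buckets[fname]:
            sub.add(t)
        path = os.path.join(outdir, fname)
        with open(path, "w", encoding="utf-8") as fh:
            for line in _nt_lines(sub):
                fh.write(line + "\n")
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# reading


def _parse_file(path: str) -> Graph:
    g = Graph()
    try:
        g.parse(path, format="turtle")
    except Exception as exc:  # rdflib BadSyntax carries line info
        line = getattr(exc, "lines", None)
        where = f"{path}:{line}" if line else path
        raise ParseError(f"malformed Turtle in {where}: {exc}") from exc
    return g


def read_network(path: str) -> NetworkSpec:
    """Load a network from a directory of ``.ttl`` files (or a single file)."""
    if os.path.isdir(path):
        files = sorted(
            os.path.join(path, f) for f in os.listdir(path) if f.endswith(".ttl")
        )
    else:
        files = [path]
    if not files:
        raise ParseError(f"no .ttl files under {path}")
    g = Graph()
    for f in files:
        for t in _parse_file(f):
            g.add(t)
    return graph_to_network(g)


def graph_to_network(g: Graph) -> NetworkSpec:
    """Rebuild a :class:`NetworkSpec` from a graph written by this module."""
    ontologies = sorted(set(g.subjects(RDF.type, OWL.Ontology)))
    importers = set(g.subjects(OWL.imports, None))
    net_base: Optional[URIRef] = None
    if importers:
        net_base = sorted(importers)[0]
    elif URIRef(_base_iri(NS.RED)) in ontologies:
        net_base = _base_iri(NS.RED)
    elif len(ontologies) == 1:
        net_base = ontologies[0]
    if net_base is None:
        raise ParseError("cannot identify the network ontology (no owl:imports)")

    def _name_of(base: URIRef) -> str:
        lbl = g.value(base, RDFS.label)
        return str(lbl) if lbl is not None else str(base).rsplit("/", 1)[-1]

    network = NetworkSpec(network_iri=str(net_base) + "#", name=_name_of(net_base))
    for base in ontologies:
        if base == net_base:
            continue
        network.add_module(OntologyModule(str(base) + "#", _name_of(base)))

    def owner(iri: URIRef) -> Optional[OntologyModule]:
        try:
            ref = IRIRef.parse(str(iri))
        except OntologyError:
            return None
        return network.module_for_namespace(ref.namespace)

    restriction_nodes = set(g.subjects(RDF.type, OWL.Restriction))

    # classes (restriction conjuncts re-attached in canonical sorted order)
    for c in set(g.subjects(RDF.type, OWL.Class)):
        if c in restriction_nodes:
            continue
        m = owner(c)
        if m is None:
            continue
        local = IRIRef.parse(str(c)).local_name
        cd = m.add_class(local)
        restrictions = []
        for sup in g.objects(c, RDFS.subClassOf):
            if sup in restriction_nodes:
                restrictions.append(_read_restriction(g, sup))
            else:
                cd.parent = IRIRef.parse(str(sup))
        cd.restrictions = _sorted_restrictions(restrictions)

    stages: dict[str, str] = {}
    for p in set(g.subjects(RDF.type, OWL.ObjectProperty)):
        m = owner(p)
        if m is None:
            continue
        local = IRIRef.parse(str(p)).local_name
        dom = g.value(p, RDFS.domain)
        rng = g.value(p, RDFS.range)
        m.add_object_property(
            local,
            IRIRef.parse(str(dom)) if dom is not None else None,
            IRIRef.parse(str(rng)) if rng is not None else None,
        )
        stage = g.value(p, URIRef(STAGE_PROP))
        if stage is not None:
            stages[str(p)] = str(stage)
    for p in set(g.subjects(RDF.type, OWL.DatatypeProperty)):
        m = owner(p)
        if m is None:
            continue
        local = IRIRef.parse(str(p)).local_name
        dom = g.value(p, RDFS.domain)
        rng = g.value(p, RDFS.range)
        xsd_name = str(rng).rsplit("#", 1)[-1] if rng is not None else "string"
        if xsd_name not in _XSD_IRI:
            xsd_name = "string"
        m.add_data_property(
            local, IRIRef.parse(str(dom)) if dom is not None else None, xsd_name
        )
    for p in set(g.subjects(RDF.type, OWL.AnnotationProperty)):
        m = owner(p)
        if m is not None:
            m.add_annotation_property(IRIRef.parse(str(p)).local_name)

    for i in set(g.subjects(RDF.type, OWL.NamedIndividual)):
        m = owner(i)
        if m is None:
            continue
        ind = m.add_individual(IRIRef.parse(str(i)).local_name)
        for cls in g.objects(i, RDF.type):
            if cls not in (OWL.NamedIndividual,) and owner(cls) is not None:
                ind.classes.add(IRIRef.parse(str(cls)))

    # rebuild meta-relations from stage-tagged network properties
    for local, pd in sorted(network.network_module.object_properties.items()):
        stage = stages.get(pd.iri.full)
        if stage and pd.domain is not None and pd.range is not None:
            network.meta_relations.append(MetaRelation(pd.iri, pd.domain, pd.range, stage))

    # remaining triples: assertions and annotations
    structural_preds = {
        RDF.type,
        RDFS.subClassOf,
        RDFS.domain,
        RDFS.range,
        OWL.imports,
        OWL.onProperty,
        OWL.onClass,
        OWL.onDataRange,
        OWL.someValuesFrom,
        OWL.qualifiedCardinality,
        OWL.minQualifiedCardinality,
        URIRef(STAGE_PROP),
    }
    bases = {str(o) for o in ontologies}
    for s, p, o in g:
        if p in structural_preds or not isinstance(s, URIRef) or str(s) in bases:
            continue
        s_ref = IRIRef.parse(str(s))
        p_ref = IRIRef.parse(str(p))
        if str(p) == str(OWL.sameAs):
            network.assertions.add((s_ref, p_ref, IRIRef.parse(str(o))))
            continue
        kind = network.resolve(str(p)).found_as
        if kind == "object_property":
            network.assertions.add((s_ref, p_ref, IRIRef.parse(str(o))))
        elif kind == "data_property":
            network.assertions.add((s_ref, p_ref, _from_lit(o)))
        elif kind == "annotation_property" or p in (RDFS.label, RDFS.comment):
            owner_m = network.module_for_namespace(s_ref.namespace) or network.network_module
            owner_m.annotations.add((s_ref, p_ref, _from_lit(o)))
    return network


def _read_restriction(g: Graph, node) -> CardinalityRestriction:
    prop = IRIRef.parse(str(g.value(node, OWL.onProperty)))
    some = g.value(node, OWL.someValuesFrom)
    if some is not None:
        return CardinalityRestriction(prop, "some", _filler(some))
    exact = g.value(node, OWL.qualifiedCardinality)
    if exact is not None:
        filler = g.value(node, OWL.onClass) or g.value(node, OWL.onDataRange)
        return CardinalityRestriction(prop, "exactly", _filler(filler), int(exact))
    minc = g.value(node, OWL.minQualifiedCardinality)
    filler = g.value(node, OWL.onClass) or g.value(node, OWL.onDataRange)
    return CardinalityRestriction(prop, "min", _filler(filler), int(minc))


def _filler(term) -> "IRIRef | str":
    text = str(term)
    if text.startswith(str(XSD)):
        return text.rsplit("#", 1)[-1]
    return IRIRef.parse(text)


def serialize_bytes(network: NetworkSpec) -> bytes:
    """Whole-network deterministic serialization (single buffer)."""
    return ("\n".join(_nt_lines(network_to_graph(network))) + "\n").encode("utf-8")
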