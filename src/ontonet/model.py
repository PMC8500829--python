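"""In-memory data model for ontology modules, the network and assertions.

The network is a set of :class:`OntologyModule` objects (one IRI namespace
each) plus a network-level module holding the meta-relations -- object
properties whose domain and range classes live in different modules -- and
any network-namespace classes (e.g. the prescription-dose class).  Every
other component of the toolkit reads and writes this substrate; Turtle
serialization lives in :mod:`ontonet.ttl`.

Literals are restricted to ``string``, ``integer``, ``float`` and ISO-8601
``date``: the only datatypes the clinical contract uses.
"""

from __future__ import annotations

import copy
import datetime as _dt
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Union

from . import namespaces as NS


class OntologyError(Exception):
    """Base class for toolkit errors."""


class IRIFormatError(OntologyError):
    pass


class ResolutionError(OntologyError):
    pass


class TypeMismatchError(OntologyError):
    pass


class ConflictError(OntologyError):
    pass


class ConfigError(OntologyError):
    pass


_WS = re.compile(r"\s")


@dataclass(frozen=True, order=True)
class IRIRef:
    """A full IRI split into namespace (ending in ``#`` or ``/``) and local name."""

    namespace: str
    local_name: str

    def __post_init__(self) -> None:
        if not self.namespace.endswith(("#", "/")):
            raise IRIFormatError(f"namespace must end in '#' or '/': {self.namespace!r}")
        if not self.local_name or _WS.search(self.local_name):
            raise IRIFormatError(f"bad local name: {self.local_name!r}")

    @property
    def full(self) -> str:
        return self.namespace + self.local_name

    @classmethod
    def parse(cls, full_iri: str) -> "IRIRef":
        """Split at the last ``#``, else the last ``/`` (the separator stays
        with the namespace); the split is exact and reversible."""
        if not isinstance(full_iri, str) or "://" not in full_iri:
            raise IRIFormatError(f"not an absolute IRI: {full_iri!r}")
        pos = full_iri.rfind("#")
        if pos == -1:
            pos = full_iri.rfind("/")
            if pos <= full_iri.find("://") + 2:
                raise IRIFormatError(f"IRI has no '#' or '/' separator: {full_iri!r}")
        return cls(full_iri[: pos + 1], full_iri[pos + 1 :])

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.full


LiteralPy = Union[str, int, float, _dt.date]

_XSD_OF_TYPE = {
    str: "string",
    int: "integer",
    float: "float",
    _dt.date: "date",
}

XSD_NAMES = {"string", "integer", "float", "date"}


@dataclass(frozen=True)
class LiteralValue:
    """A typed literal; ``datatype`` is one of string/integer/float/date."""

    value: LiteralPy
    datatype: str = ""

    def __post_init__(self) -> None:
        if isinstance(self.value, bool) or type(self.value) not in _XSD_OF_TYPE:
            raise TypeMismatchError(f"unsupported literal type: {self.value!r}")
        if not self.datatype:
            object.__setattr__(self, "datatype", _XSD_OF_TYPE[type(self.value)])
        elif self.datatype not in XSD_NAMES:
            raise TypeMismatchError(f"unsupported literal datatype: {self.datatype!r}")

    @property
    def xsd_iri(self) -> str:
        return NS.XSD + self.datatype


def as_literal(value: Union[LiteralValue, LiteralPy]) -> LiteralValue:
    return value if isinstance(value, LiteralValue) else LiteralValue(value)


Term = Union[IRIRef, LiteralValue]
Assertion = tuple[IRIRef, IRIRef, Term]


@dataclass(frozen=True)
class CardinalityRestriction:
    """One conjunct of a non-primitive class definition.

    ``filler`` is a class :class:`IRIRef` for object properties or an xsd
    type name (``"float"`` ...) for data properties.  ``kind`` follows the
    OWL surface syntax: ``exactly``/``min`` carry a count, ``some`` does not.
    """

    on_property: IRIRef
    kind: str
    filler: Union[IRIRef, str]
    n: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in ("exactly", "min", "some"):
            raise ConfigError(f"unknown restriction kind: {self.kind!r}")
        if self.kind == "some" and self.n is not None:
            raise ConfigError("'some' restriction carries no cardinality")
        if self.kind in ("exactly", "min") and (self.n is None or self.n < 0):
            raise ConfigError(f"restriction {self.kind!r} needs n >= 0")


@dataclass
class ClassDef:
    iri: IRIRef
    parent: Optional[IRIRef] = None
    restrictions: list[CardinalityRestriction] = field(default_factory=list)

    @property
    def primitive(self) -> bool:
        return not self.restrictions


@dataclass
class ObjectPropertyDef:
    iri: IRIRef
    domain: Optional[IRIRef] = None
    range: Optional[IRIRef] = None


@dataclass
class DataPropertyDef:
    iri: IRIRef
    domain: Optional[IRIRef] = None
    range: str = "string"  # xsd type name


@dataclass
class AnnotationPropertyDef:
    iri: IRIRef


@dataclass
class IndividualDef:
    iri: IRIRef
    classes: set[IRIRef] = field(default_factory=set)


@dataclass(frozen=True)
class MetaRelation:
    """Cross-module object property carried in the network namespace."""

    property: IRIRef
    domain_class: IRIRef
    range_class: IRIRef
    stage: str  # "design" | "extraction"

    def __post_init__(self) -> None:
        if self.stage not in ("design", "extraction"):
            raise ConfigError(f"meta-relation stage must be design|extraction: {self.stage!r}")


class OntologyModule:
    """A named collection of definitions under one IRI namespace."""

    def __init__(self, namespace: str, name: str):
        if not namespace.endswith(("#", "/")):
            raise IRIFormatError(f"module namespace must end in '#' or '/': {namespace!r}")
        self.namespace = namespace
        self.name = name
        self.classes: dict[str, ClassDef] = {}
        self.object_properties: dict[str, ObjectPropertyDef] = {}
        self.data_properties: dict[str, DataPropertyDef] = {}
        self.annotation_properties: dict[str, AnnotationPropertyDef] = {}
        self.individuals: dict[str, IndividualDef] = {}
        # (subject, annotation property, literal)
        self.annotations: set[tuple[IRIRef, IRIRef, LiteralValue]] = set()

    # -- builders ---------------------------------------------------------
    def iri(self, local: str) -> IRIRef:
        return IRIRef(self.namespace, local)

    def add_class(self, local: str, parent: Optional[IRIRef] = None) -> ClassDef:
        cd = self.classes.get(local)
        if cd is None:
            cd = ClassDef(self.iri(local), parent)
            self.classes[local] = cd
        elif parent is not None:
            cd.parent = parent
        return cd

    def add_object_property(self, local: str, domain=None, range=None) -> ObjectPropertyDef:
        pd = self.object_properties.setdefault(
            local, ObjectPropertyDef(self.iri(local), domain, range)
        )
        return pd

    def add_data_property(self, local: str, domain=None, range: str = "string") -> DataPropertyDef:
        if range not in XSD_NAMES:
            raise ConfigError(f"bad data property range {range!r}")
        return self.data_properties.setdefault(
            local, DataPropertyDef(self.iri(local), domain, range)
        )

    def add_annotation_property(self, local: str) -> AnnotationPropertyDef:
        return self.annotation_properties.setdefault(local, AnnotationPropertyDef(self.iri(local)))

    def add_individual(self, local: str, cls: Optional[IRIRef] = None) -> IndividualDef:
        ind = self.individuals.setdefault(local, IndividualDef(self.iri(local)))
        if cls is not None:
            ind.classes.add(cls)
        return ind

    def label(self, subject: IRIRef, text: str) -> None:
        self.annotations.add((subject, IRIRef.parse(NS.RDFS_LABEL), LiteralValue(text)))


@dataclass(frozen=True)
class Resolution:
    found_as: str  # class|individual|object_property|data_property|annotation_property|absent
    owner_module: Optional[str]  # module name, None when namespace matches nothing
    namespace: str
    local_name: str


class NetworkSpec:
    """The ontology network: modules, meta-relations and assertions."""

    def __init__(self, network_iri: str = NS.RED, name: str = "Red"):
        self.network_iri = network_iri
        self.modules: dict[str, OntologyModule] = {}
        self.network_module = OntologyModule(network_iri, name)
        self.meta_relations: list[MetaRelation] = []
        self.assertions: set[Assertion] = set()
        #: derived assertion -> producing rule name (explanations; not serialized)
        self.derivations: dict[Assertion, str] = {}

    # -- modules ----------------------------------------------------------
    def add_module(self, module: OntologyModule) -> OntologyModule:
        seen = {m.namespace for m in self.modules.values()} | {self.network_iri}
        if module.namespace in seen:
            raise ConfigError(f"duplicate module namespace: {module.namespace}")
        if module.name in self.modules:
            raise ConfigError(f"duplicate module name: {module.name}")
        self.modules[module.name] = module
        return module

    def iter_modules(self, include_network: bool = True) -> Iterator[OntologyModule]:
        yield from self.modules.values()
        if include_network:
            yield self.network_module

    def module_for_namespace(self, namespace: str) -> Optional[OntologyModule]:
        if namespace == self.network_iri:
            return self.network_module
        for m in self.modules.values():
            if m.namespace == namespace:
                return m
        return None

    # -- resolution -------------------------------------------------------
    def resolve(self, full_iri: str) -> Resolution:
        """Locate a full IRI among all definitions; never raises on absence
        (malformed IRIs still raise :class:`IRIFormatError`)."""
        ref = IRIRef.parse(full_iri)
        module = self.module_for_namespace(ref.namespace)
        if module is not None:
            for kind, table in (
                ("class", module.classes),
                ("individual", module.individuals),
                ("object_property", module.object_properties),
                ("data_property", module.data_properties),
                ("annotation_property", module.annotation_properties),
            ):
                if ref.local_name in table:
                    return Resolution(kind, module.name, ref.namespace, ref.local_name)
            return Resolution("absent", module.name, ref.namespace, ref.local_name)
        return Resolution("absent", None, ref.namespace, ref.local_name)

    def find_object_property(self, iri: IRIRef) -> Optional[ObjectPropertyDef]:
        m = self.module_for_namespace(iri.namespace)
        return m.object_properties.get(iri.local_name) if m else None

    def find_data_property(self, iri: IRIRef) -> Optional[DataPropertyDef]:
        m = self.module_for_namespace(iri.namespace)
        return m.data_properties.get(iri.local_name) if m else None

    def find_class(self, iri: IRIRef) -> Optional[ClassDef]:
        m = self.module_for_namespace(iri.namespace)
        return m.classes.get(iri.local_name) if m else None

    def find_individual(self, iri: IRIRef) -> Optional[IndividualDef]:
        m = self.module_for_namespace(iri.namespace)
        return m.individuals.get(iri.local_name) if m else None

    # -- assertions -------------------------------------------------------
    def add_assertion(
        self,
        subject: Union[IRIRef, str],
        predicate: Union[IRIRef, str],
        obj: Union[Term, LiteralPy],
        rule: Optional[str] = None,
    ) -> "NetworkSpec":
        """Add one triple; idempotent; validates subject and predicate before
        any mutation so errors leave the network unchanged."""
        s = subject if isinstance(subject, IRIRef) else IRIRef.parse(subject)
        p = predicate if isinstance(predicate, IRIRef) else IRIRef.parse(predicate)
        p = IRIRef.parse(NS.canonical_iri(p.full))
        if self.resolve(s.full).found_as == "absent":
            raise ResolutionError(f"unknown subject: {s.full}")
        if p.full == NS.OWL_SAMEAS:
            if not isinstance(obj, IRIRef):
                raise TypeMismatchError("owl:sameAs needs an IRI object")
            self.assertions.add((s, p, obj))
            return self
        if self.find_object_property(p) is not None:
            if not isinstance(obj, IRIRef):
                raise TypeMismatchError(f"{p.full} is an object property; got literal {obj!r}")
            o: Term = obj
        elif self.find_data_property(p) is not None:
            if isinstance(obj, IRIRef):
                raise TypeMismatchError(f"{p.full} is a data property; got IRI {obj.full}")
            o = as_literal(obj)
        else:
            raise ResolutionError(f"unknown predicate: {p.full}")
        triple = (s, p, o)
        if triple not in self.assertions:
            self.assertions.add(triple)
            if rule:
                self.derivations[triple] = rule
        return self

    def annotate(
        self,
        subject: Union[IRIRef, str],
        prop: Union[IRIRef, str],
        value: Union[LiteralValue, LiteralPy],
    ) -> None:
        """Attach an annotation literal; stored with the subject's module."""
        s = subject if isinstance(subject, IRIRef) else IRIRef.parse(subject)
        p = prop if isinstance(prop, IRIRef) else IRIRef.parse(prop)
        if self.resolve(s.full).found_as == "absent":
            raise ResolutionError(f"unknown annotation subject: {s.full}")
        builtin = p.full in (NS.RDFS_LABEL, NS.RDFS_COMMENT)
        if not builtin and self.resolve(p.full).found_as != "annotation_property":
            raise ResolutionError(f"not an annotation property: {p.full}")
        owner = self.module_for_namespace(s.namespace) or self.network_module
        owner.annotations.add((s, p, as_literal(value)))

    def annotations_of(self, subject: IRIRef) -> list[tuple[IRIRef, LiteralValue]]:
        out = []
        for m in self.iter_modules():
            for s, p, v in m.annotations:
                if s == subject:
                    out.append((p, v))
        return out

    def objects(self, subject: IRIRef, predicate: IRIRef) -> list[Term]:
        return [o for (s, p, o) in self.assertions if s == subject and p == predicate]

    def by_predicate(self, predicate: IRIRef) -> list[tuple[IRIRef, Term]]:
        return [(s, o) for (s, p, o) in self.assertions if p == predicate]

    # -- class hierarchy --------------------------------------------------
    def subclasses(self, cls: IRIRef) -> set[IRIRef]:
        """``cls`` plus all transitive subclasses across the network."""
        children: dict[IRIRef, list[IRIRef]] = {}
        for m in self.iter_modules():
            for cd in m.classes.values():
                if cd.parent is not None:
                    children.setdefault(cd.parent, []).append(cd.iri)
        out, stack = {cls}, [cls]
        while stack:
            for ch in children.get(stack.pop(), []):
                if ch not in out:
                    out.add(ch)
                    stack.append(ch)
        return out

    def superclasses(self, cls: IRIRef) -> set[IRIRef]:
        out, cur = {cls}, cls
        while True:
            cd = self.find_class(cur)
            if cd is None or cd.parent is None or cd.parent in out:
                return out
            out.add(cd.parent)
            cur = cd.parent

    def individuals_of(self, cls: IRIRef, transitive: bool = True) -> list[IndividualDef]:
        accepted = self.subclasses(cls) if transitive else {cls}
        out = []
        for m in self.iter_modules():
            for ind in m.individuals.values():
                if ind.classes & accepted:
                    out.append(ind)
        return out

    def is_instance_of(self, ind: IRIRef, cls: IRIRef) -> bool:
        d = self.find_individual(ind)
        return d is not None and bool(d.classes & self.subclasses(cls))

    # -- sameAs equivalence (query-layer, not OWL reasoning) --------------
    def sameas_groups(self) -> list[set[IRIRef]]:
        parent: dict[IRIRef, IRIRef] = {}

        def find(x: IRIRef) -> IRIRef:
            while parent.get(x, x) != x:
                parent[x] = parent.get(parent[x], parent[x])
                x = parent[x]
            return x

        sameas = IRIRef.parse(NS.OWL_SAMEAS)
        for s, p, o in self.assertions:
            if p == sameas and isinstance(o, IRIRef):
                parent.setdefault(s, s)
                parent.setdefault(o, o)
                parent[find(s)] = find(o)
        groups: dict[IRIRef, set[IRIRef]] = {}
        for x in list(parent):
            groups.setdefault(find(x), set()).add(x)
        return [g for g in groups.values() if len(g) > 1]

    # -- misc -------------------------------------------------------------
    def copy(self) -> "NetworkSpec":
        return copy.deepcopy(self)

    def individual_counts(self) -> dict[str, int]:
        return {m.name: len(m.individuals) for m in self.iter_modules()}


def resolve_iri(full_iri: str, network: NetworkSpec) -> Resolution:
    """Operation form of :meth:`NetworkSpec.resolve`."""
    return network.resolve(full_iri)


def add_assertion(network: NetworkSpec, subject, predicate, obj) -> NetworkSpec:
    return network.add_assertion(subject, predicate, obj)


def check_meta_relation_conformance(network: NetworkSpec) -> list[tuple[Assertion, str]]:
    """Exhaustively scan meta-relation assertions for domain/range conformance
    (subclass-aware).  Returns offending (assertion, reason) pairs."""
    by_prop = {mr.property: mr for mr in network.meta_relations}
    bad = []
    for triple in network.assertions:
        s, p, o = triple
        mr = by_prop.get(p)
        if mr is None:
            continue
        if not network.is_instance_of(s, mr.domain_class):
            bad.append((triple, f"subject not in domain {mr.domain_class.full}"))
        if isinstance(o, IRIRef) and not network.is_instance_of(o, mr.range_class):
            bad.append((triple, f"object not in range {mr.range_class.full}"))
    return bad
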