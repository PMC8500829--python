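"""Evaluation: competency questions, cardinality consistency, lint.

Three instruments, mirroring how the deployed network was judged:

* a SPARQL competency-question suite (registry of queries with expected
  result shapes), run over the rdflib graph with sameAs treated as a
  query-layer equivalence;
* a cardinality checker comparing every individual of a restricted class
  against the class's restriction conjunction (exactly / min / some);
* an OOPS-style lint pass flagging missing labels, mixed has*/tiene*
  naming and absent inverse properties.  Inverse findings are always
  informational: the network deliberately omits inverses to keep reasoning
  cheap.

Conjuncts over rule-derived properties (BMI, WHI, BMR, biotype) are
checked as upper bounds by default: with only the published rule variants
active (Overweight band, female-over-60 BMR) a note may legitimately lack
a derived value, and a strict exactly-1 reading would flag every such
note.  Pass ``derived_optional=frozenset()`` for the strict contract.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources as _ilres
from typing import Optional, Sequence

import yaml
from rdflib import Graph
from rdflib.plugins.sparql import prepareQuery

from . import namespaces as NS
from .model import (
    CardinalityRestriction,
    IRIRef,
    LiteralValue,
    NetworkSpec,
    OntologyError,
)
from .ttl import network_to_graph


class RegistryError(OntologyError):
    pass


@dataclass(frozen=True)
class CompetencyQuery:
    id: str
    question: str
    sparql: str
    non_empty: bool = True
    columns: tuple[str, ...] = ()
    min_rows: int = 0


def parse_registry(text: str) -> list[CompetencyQuery]:
    doc = yaml.safe_load(text)
    prefixes = {**NS.PREFIXES, **(doc.get("prefixes") or {})}
    queries = []
    for q in doc.get("queries", []):
        expect = q.get("expect") or {}
        # only the prefixes a query uses are declared (and two prefixes for
        # one namespace never coexist in a prologue)
        used = set(re.findall(r"\b([A-Za-z][\w-]*):", q["sparql"]))
        missing = used - set(prefixes) - {"http", "https"}
        if missing:
            raise RegistryError(f"query {q['id']} uses unknown prefixes: {sorted(missing)}")
        header = "".join(
            f"PREFIX {p}: <{prefixes[p]}>\n" for p in sorted(used & set(prefixes))
        )
        sparql = header + q["sparql"]
        try:
            prepareQuery(sparql)
        except Exception as exc:
            raise RegistryError(f"query {q['id']} does not parse: {exc}") from exc
        queries.append(
            CompetencyQuery(
                q["id"],
                q.get("question", ""),
                sparql,
                bool(expect.get("non_empty", True)),
                tuple(expect.get("columns", ())),
                int(expect.get("min_rows", 0)),
            )
        )
    return queries


def load_default_registry() -> list[CompetencyQuery]:
    text = _ilres.files("ontonet.resources").joinpath("registry_default.yaml").read_text("utf-8")
    return parse_registry(text)


@dataclass
class QueryResult:
    id: str
    question: str
    rows: list[dict]
    passed: bool
    reason: str = ""


def run_competency_suite(
    network: NetworkSpec,
    registry: Optional[Sequence[CompetencyQuery]] = None,
    graph: Optional[Graph] = None,
) -> dict:
    """Execute each registry query against the network; a query passes when
    its expected shape (non-empty, column names, minimum rows) holds."""
    registry = list(registry) if registry is not None else load_default_registry()
    g = graph if graph is not None else network_to_graph(network, sameas_closure=True)
    results = []
    for q in registry:
        res = g.query(q.sparql)
        cols = tuple(str(v) for v in res.vars) if res.vars else ()
        rows = [
            {str(v): str(row[v]) for v in res.vars if row[v] is not None}
            for row in res
        ]
        passed, reason = True, ""
        if q.columns and tuple(q.columns) != cols:
            passed, reason = False, f"columns {cols} != expected {tuple(q.columns)}"
        if q.non_empty and not rows:
            passed, reason = False, "empty result for non-empty expectation"
        if q.min_rows and len(rows) < q.min_rows:
            passed, reason = False, f"{len(rows)} rows < min {q.min_rows}"
        results.append(QueryResult(q.id, q.question, rows, passed, reason))
    return {
        "queries": results,
        "all_passed": all(r.passed for r in results),
        "n_queries": len(results),
    }


# ---------------------------------------------------------------------------
# cardinality / consistency


@dataclass(frozen=True)
class Violation:
    individual: str
    cls: str
    restriction: str
    observed: int


@dataclass
class ConsistencyReport:
    violations: list[Violation] = field(default_factory=list)
    lint: list[tuple[str, str]] = field(default_factory=list)

    @property
    def consistent(self) -> bool:
        return not self.violations


#: properties whose values only exist after the (partial) rule set fires
DERIVED_PROPERTIES = frozenset(
    {
        NS.DATOS + "tieneIMC",
        NS.DATOS + "tieneICC",
        NS.DATOS + "tieneTMB",
        NS.DATOS + "hasHumanBiotype",
    }
)


def check_cardinality(
    network: NetworkSpec,
    derived_optional: frozenset[str] = DERIVED_PROPERTIES,
) -> ConsistencyReport:
    """Compare every individual of a restricted class against the class's
    restriction conjunction; violations report the observed count."""
    report = ConsistencyReport()
    counts: dict[tuple[IRIRef, IRIRef], int] = {}
    for s, p, _ in network.assertions:
        counts[(s, p)] = counts.get((s, p), 0) + 1
    for module in network.iter_modules():
        for cd in module.classes.values():
            if not cd.restrictions:
                continue
            for ind in network.individuals_of(cd.iri):
                for r in cd.restrictions:
                    observed = counts.get((ind.iri, r.on_property), 0)
                    derived = r.on_property.full in derived_optional
                    ok = _restriction_holds(r, observed, derived)
                    if not ok:
                        report.violations.append(
                            Violation(
                                ind.iri.full,
                                cd.iri.full,
                                _describe(r),
                                observed,
                            )
                        )
    return report


def _restriction_holds(r: CardinalityRestriction, observed: int, derived: bool) -> bool:
    if r.kind == "some":
        return True if derived else observed >= 1
    if r.kind == "min":
        return True if derived and observed <= r.n else observed >= r.n
    # exactly: derived conjuncts are upper-bound checked
    return observed <= r.n if derived else observed == r.n


def _describe(r: CardinalityRestriction) -> str:
    filler = r.filler.full if isinstance(r.filler, IRIRef) else f"xsd:{r.filler}"
    n = "" if r.n is None else f" {r.n}"
    return f"{r.on_property.full} {r.kind}{n} {filler}"


# ---------------------------------------------------------------------------
# lint

_HAS = re.compile(r"^has[A-Z]")
_TIENE = re.compile(r"^(tiene|reside|presenta|escribe)[A-Z]")


def lint(network: NetworkSpec) -> list[tuple[str, str]]:
    """OOPS-style findings: (subject, pitfall kind).

    Kinds: ``missing-label`` for classes/properties without an rdfs:label,
    ``naming-convention`` for every has*/tiene* property when both styles
    coexist in the network, ``missing-inverse`` (informational) for object
    properties without an inverse."""
    findings: list[tuple[str, str]] = []
    labelled: set[str] = set()
    for m in network.iter_modules():
        for s, p, _ in m.annotations:
            if p.full == NS.RDFS_LABEL:
                labelled.add(s.full)
    prop_names: list[IRIRef] = []
    for m in network.iter_modules():
        for cd in m.classes.values():
            if cd.iri.full not in labelled:
                findings.append((cd.iri.full, "missing-label"))
        for table in (m.object_properties, m.data_properties):
            for pd in table.values():
                prop_names.append(pd.iri)
                if pd.iri.full not in labelled:
                    findings.append((pd.iri.full, "missing-label"))
        for pd in m.object_properties.values():
            findings.append((pd.iri.full, "missing-inverse"))
    english = [p for p in prop_names if _HAS.match(p.local_name)]
    spanish = [p for p in prop_names if _TIENE.match(p.local_name)]
    if english and spanish:
        for p in english + spanish:
            findings.append((p.full, "naming-convention"))
    return findings


def evaluation_report(network: NetworkSpec, registry=None) -> dict:
    """Aggregate report: satisfiability, cardinality, competency, lint."""
    from .populate import satisfy_check

    suite = run_competency_suite(network, registry)
    consistency = check_cardinality(network)
    consistency.lint = lint(network)
    sat = satisfy_check(network)
    return {
        "satisfiable": sat["all_nonempty"],
        "module_counts": sat["counts"],
        "cardinality_violations": [v.__dict__ for v in consistency.violations],
        "consistent": consistency.consistent,
        "competency": {
            "all_passed": suite["all_passed"],
            "per_query": {
                r.id: {"passed": r.passed, "rows": len(r.rows), "reason": r.reason}
                for r in suite["queries"]
            },
        },
        "lint_counts": _count_kinds(consistency.lint),
    }


def _count_kinds(findings: list[tuple[str, str]]) -> dict[str, int]:
    out: dict[str, int] = {}
    for _, kind in findings:
        out[kind] = out.get(kind, 0) + 1
    return out
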