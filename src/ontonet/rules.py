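"""Forward-chaining rule engine with SWRL-style builtins.

Rules are Horn clauses over class atoms, property atoms and builtin atoms
(``multiply``, ``divide``, ``add``, ``subtract``, ``greaterThanOrEqual``,
``greaterThan``, ``lessThan``, ``lessThanOrEqual``,
``stringEqualIgnoreCase``).  Heads contain property atoms only and every
head variable must occur in the body (DL-safety); there is no negation, so
application is monotone and the fixpoint is confluent: derivation order
cannot change the final triple set.

The clinical rule set mirrors the deployed network's semantic rules:

* body-mass index  BMI = weight / height^2  (kg, m)
* waist-hip index  WHI = waist / hip  (cm/cm, unitless)
* Overweight biotype band  25 <= BMI < 30 (lower bound inclusive,
  upper exclusive)
* basal metabolic rate for women aged >= 61:  BMR = 10.5 * weight + 596
  (kcal/day, weight in kg)

Only the Overweight band and the female-over-60 BMR variant are active by
default; other bands and BMR variants are configuration extension slots.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources as _ilres
from typing import Optional, Sequence, Union

import yaml

from . import namespaces as NS
from .model import (
    ConfigError,
    IRIRef,
    LiteralValue,
    NetworkSpec,
    OntologyError,
    as_literal,
)


class RuleError(OntologyError):
    pass


# ---------------------------------------------------------------------------
# rule constants (the published figures; see docs/methods.md)

OVERWEIGHT_LO = 25.0  # inclusive
OVERWEIGHT_HI = 30.0  # exclusive
BMR_FEMALE_SLOPE = 10.5  # kcal per kg
BMR_FEMALE_INTERCEPT = 596.0  # kcal
BMR_AGE_THRESHOLD = 61  # inclusive, years


@dataclass(frozen=True)
class BiotypeBand:
    label: str  # individual local name in the datos namespace
    lo: float  # inclusive
    hi: float  # exclusive

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ConfigError(f"biotype band needs lo < hi: {self}")


#: default band set: only Overweight is specified by the source rule set;
#: Underweight/Normal/Obese are extension slots left disabled.
DEFAULT_BANDS: tuple[BiotypeBand, ...] = (BiotypeBand("Overweight", OVERWEIGHT_LO, OVERWEIGHT_HI),)


@dataclass(frozen=True)
class BMRFormula:
    sex: str  # matched case-insensitively
    min_age: int  # inclusive
    slope: float
    intercept: float

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ConfigError("BMR slope must be positive")


DEFAULT_BMR: tuple[BMRFormula, ...] = (
    BMRFormula("Female", BMR_AGE_THRESHOLD, BMR_FEMALE_SLOPE, BMR_FEMALE_INTERCEPT),
)


# ---------------------------------------------------------------------------
# closed-form operations (the rule bodies as plain functions)


def compute_bmi(weight_kg: float, height_m: float) -> float:
    """weight / height^2; height must be positive."""
    if height_m <= 0:
        raise ValueError(f"height must be positive, got {height_m}")
    if weight_kg < 0:
        raise ValueError(f"weight must be non-negative, got {weight_kg}")
    return weight_kg / (height_m * height_m)


def compute_whi(waist_cm: float, hip_cm: float) -> float:
    """waist / hip; hip must be positive."""
    if hip_cm <= 0:
        raise ValueError(f"hip circumference must be positive, got {hip_cm}")
    return waist_cm / hip_cm


def classify_biotype(
    bmi: float, bands: Sequence[BiotypeBand] = DEFAULT_BANDS
) -> Optional[str]:
    """Band label for a BMI, or None when no band matches.

    Bands are half-open ``[lo, hi)``: 25.0 is Overweight, 30.0 is not.
    """
    if not math.isfinite(bmi):
        return None
    for band in bands:
        if band.lo <= bmi < band.hi:
            return band.label
    return None


def compute_bmr(
    sex: str,
    age_years: int,
    weight_kg: float,
    formulas: Sequence[BMRFormula] = DEFAULT_BMR,
) -> Optional[float]:
    """Basal metabolic rate, or None when no formula applies.

    The default rule set only covers women aged >= 61:
    ``10.5 * weight + 596`` kcal/day.
    """
    if weight_kg < 0:
        raise ValueError(f"weight must be non-negative, got {weight_kg}")
    for f in formulas:
        if sex.lower() == f.sex.lower() and age_years >= f.min_age:
            return f.slope * weight_kg + f.intercept
    return None


# ---------------------------------------------------------------------------
# rule representation


@dataclass(frozen=True)
class Atom:
    kind: str  # "class" | "prop" | "builtin"
    op: str  # class IRI, property IRI, or builtin name
    args: tuple  # variables ("?x") or constants (IRIRef / python literal)


@dataclass(frozen=True)
class Rule:
    name: str
    body: tuple[Atom, ...]
    head: tuple[Atom, ...]

    def __post_init__(self) -> None:
        body_vars = {a for atom in self.body for a in atom.args if _is_var(a)}
        for atom in self.head:
            if atom.kind != "prop":
                raise RuleError(f"rule {self.name}: head atoms must be property atoms")
            for a in atom.args:
                if _is_var(a) and a not in body_vars:
                    raise RuleError(
                        f"rule {self.name} is not DL-safe: head variable {a} "
                        f"does not occur in the body"
                    )


def _is_var(x) -> bool:
    return isinstance(x, str) and x.startswith("?")


_BUILTINS_FUNC = {
    "multiply": lambda args: math.prod(args),
    "add": lambda args: sum(args),
    "subtract": lambda args: args[0] - sum(args[1:]),
    "divide": lambda args: args[0] / args[1],
}
_BUILTINS_TEST = {
    "greaterThanOrEqual": lambda a, b: _num(a) >= _num(b),
    "greaterThan": lambda a, b: _num(a) > _num(b),
    "lessThan": lambda a, b: _num(a) < _num(b),
    "lessThanOrEqual": lambda a, b: _num(a) <= _num(b),
    "stringEqualIgnoreCase": lambda a, b: str(a).lower() == str(b).lower(),
}


def _num(x):
    if isinstance(x, (int, float)) and not isinstance(x, bool):
        return x
    raise RuleError(f"builtin needs a numeric argument, got {x!r}")


# ---------------------------------------------------------------------------
# loading


def parse_rule_file(text: str) -> list[Rule]:
    """Parse a declarative YAML rule file into :class:`Rule` objects."""
    doc = yaml.safe_load(text)
    prefixes = {**NS.PREFIXES, **(doc.get("prefixes") or {})}

    def term(tok):
        if isinstance(tok, (int, float)):
            return tok
        if _is_var(tok):
            return tok
        if isinstance(tok, str) and ":" in tok:
            prefix, _, local = tok.partition(":")
            if prefix in prefixes:
                return IRIRef.parse(NS.canonical_iri(prefixes[prefix] + local))
        return tok  # plain string constant

    rules = []
    for rc in doc.get("rules", []):
        def atoms(entries):
            out = []
            for e in entries:
                kind = e[0]
                if kind == "builtin":
                    if e[1] not in _BUILTINS_FUNC and e[1] not in _BUILTINS_TEST:
                        raise RuleError(f"unknown builtin: {e[1]}")
                    out.append(Atom("builtin", e[1], tuple(term(t) for t in e[2:])))
                elif kind in ("prop", "class"):
                    op = term(e[1])
                    if not isinstance(op, IRIRef):
                        raise RuleError(f"atom needs an IRI, got {e[1]!r}")
                    out.append(Atom(kind, op.full, tuple(term(t) for t in e[2:])))
                else:
                    raise RuleError(f"unknown atom kind: {kind!r}")
            return tuple(out)

        rules.append(Rule(rc["name"], atoms(rc["body"]), atoms(rc["head"])))
    return rules


def load_default_rules() -> list[Rule]:
    text = _ilres.files("ontonet.resources").joinpath("rules_default.yaml").read_text("utf-8")
    return parse_rule_file(text)


# ---------------------------------------------------------------------------
# evaluation


def _fact_value(term):
    if isinstance(term, LiteralValue):
        return term.value
    return term  # IRIRef


def _match_atom(network: NetworkSpec, atom: Atom, binding: dict) -> list[dict]:
    def subst(x):
        return binding.get(x, x) if _is_var(x) else x

    if atom.kind == "class":
        cls = IRIRef.parse(atom.op)
        var = subst(atom.args[0])
        out = []
        for ind in network.individuals_of(cls):
            if _is_var(var):
                out.append({**binding, var: ind.iri})
            elif var == ind.iri:
                out.append(binding)
        return out
    if atom.kind == "prop":
        pred = IRIRef.parse(atom.op)
        s_t, o_t = (subst(a) for a in atom.args)
        out = []
        for s, o in network.by_predicate(pred):
            ov = _fact_value(o)
            b = dict(binding)
            if _is_var(s_t):
                b[s_t] = s
            elif s_t != s:
                continue
            if _is_var(o_t):
                b[o_t] = ov
            elif not _const_eq(o_t, ov):
                continue
            out.append(b)
        return out
    # builtin
    args = [subst(a) for a in atom.args]
    if atom.op in _BUILTINS_TEST:
        if any(_is_var(a) for a in args):
            return []  # unbound arguments never satisfy a test builtin
        return [binding] if _BUILTINS_TEST[atom.op](*args) else []
    result_t, rest = args[0], args[1:]
    if any(_is_var(a) for a in rest):
        return []
    value = _BUILTINS_FUNC[atom.op]([_num(a) for a in rest])
    if _is_var(result_t):
        return [{**binding, result_t: value}]
    return [binding] if _const_eq(result_t, value) else []


def _const_eq(a, b) -> bool:
    if isinstance(a, IRIRef) or isinstance(b, IRIRef):
        return a == b
    if isinstance(a, (int, float)) and isinstance(b, (int, float)):
        return a == b
    return a == b


def _head_assertions(network: NetworkSpec, rule: Rule, binding: dict):
    for atom in rule.head:
        pred = IRIRef.parse(atom.op)
        s = binding.get(atom.args[0], atom.args[0])
        o = binding.get(atom.args[1], atom.args[1]) if _is_var(atom.args[1]) else atom.args[1]
        if not isinstance(s, IRIRef):
            continue
        if network.find_data_property(pred) is not None and isinstance(o, int) \
                and network.find_data_property(pred).range == "float":
            o = float(o)
        yield s, pred, o


def apply_rules(network: NetworkSpec, rules: Sequence[Rule]) -> NetworkSpec:
    """Run the rules to fixpoint, recording the producing rule per triple.

    Monotone: assertions are only ever added.  Rules are re-evaluated until
    a full pass adds nothing new.
    """
    changed = True
    while changed:
        changed = False
        for rule in rules:
            bindings = [dict()]
            for atom in rule.body:
                nxt = []
                for b in bindings:
                    nxt.extend(_match_atom(network, atom, b))
                bindings = nxt
                if not bindings:
                    break
            for b in bindings:
                for s, p, o in _head_assertions(network, rule, b):
                    obj = o if isinstance(o, IRIRef) else as_literal(o)
                    if (s, p, obj) not in network.assertions:
                        network.add_assertion(s, p, o if isinstance(o, IRIRef) else obj, rule=rule.name)
                        changed = True
    return network


# ---------------------------------------------------------------------------
# contraindication alerts

ALERT_PROP = "hasContraindicationAlert"


def contraindication_alerts(network: NetworkSpec) -> list[tuple[IRIRef, IRIRef, IRIRef]]:
    """Alerts for notes whose prescriptions carry a drug contraindicated for
    a diagnosis given in the same note.

    Join: note --hasDiagnosis--> d; note --hasTreatment--> dose
    --hasAPIInPrescription--> api; drug --tienePrincipioActivoPorPorcion-->
    mapper --tienePrincipioActivo--> api; drug --hasContraindication--> d.
    Each alert is materialized as a network-namespace property on the note.
    """
    red = network.network_iri
    medi = NS.MEDI
    diag = network.by_predicate(IRIRef.parse(red + "hasDiagnosis"))
    treat = network.by_predicate(IRIRef.parse(red + "hasTreatment"))
    dose_api = network.by_predicate(IRIRef.parse(red + "hasAPIInPrescription"))
    drug_map = network.by_predicate(IRIRef.parse(medi + "tienePrincipioActivoPorPorcion"))
    map_api = network.by_predicate(IRIRef.parse(medi + "tienePrincipioActivo"))
    contra = network.by_predicate(IRIRef.parse(red + "hasContraindication"))

    api_of_dose: dict[IRIRef, set[IRIRef]] = {}
    for dose, api in dose_api:
        api_of_dose.setdefault(dose, set()).add(api)
    drugs_of_api: dict[IRIRef, set[IRIRef]] = {}
    api_of_mapper = {m: a for m, a in map_api}
    for drug, mapper in drug_map:
        api = api_of_mapper.get(mapper)
        if api is not None:
            drugs_of_api.setdefault(api, set()).add(drug)
    contra_of_drug: dict[IRIRef, set[IRIRef]] = {}
    for drug, ent in contra:
        contra_of_drug.setdefault(drug, set()).add(ent)
    diags_of_note: dict[IRIRef, set[IRIRef]] = {}
    for note, d in diag:
        diags_of_note.setdefault(note, set()).add(d)

    # sameAs equivalence between Control-Plan and Drug-ATC ingredient twins
    canon: dict[IRIRef, IRIRef] = {}
    for group in network.sameas_groups():
        rep = sorted(group)[0]
        for m in group:
            canon[m] = rep

    def eq(x: IRIRef) -> IRIRef:
        return canon.get(x, x)

    drugs_by_canon_api: dict[IRIRef, set[IRIRef]] = {}
    for api, drugs in drugs_of_api.items():
        drugs_by_canon_api.setdefault(eq(api), set()).update(drugs)

    alerts = []
    seen = set()
    net_mod = network.network_module
    if ALERT_PROP not in net_mod.object_properties:
        pd = net_mod.add_object_property(
            ALERT_PROP,
            IRIRef.parse(NS.DATOS + "Nota_Medica"),
            IRIRef.parse(NS.MEDI + "Medicamento"),
        )
        net_mod.label(pd.iri, "hasContraindicationAlert")
    for note, doses in ((n, ds) for n, ds in _group(treat).items()):
        for dose in doses:
            for api in api_of_dose.get(dose, ()):
                for drug in drugs_by_canon_api.get(eq(api), ()):
                    hits = contra_of_drug.get(drug, set()) & diags_of_note.get(note, set())
                    for d in sorted(hits):
                        if (note, drug, d) not in seen:
                            seen.add((note, drug, d))
                            alerts.append((note, drug, d))
                            network.add_assertion(
                                note, IRIRef.parse(red + ALERT_PROP), drug,
                                rule="contraindication_alert",
                            )
    return alerts


def _group(pairs):
    out: dict = {}
    for a, b in pairs:
        out.setdefault(a, set()).add(b)
    return out
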