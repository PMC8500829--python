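"""Semi-automatic extraction of candidate triples from Spanish clinical text.

The pipeline tags terms against TSV gazetteers (diseases with ICD-10 codes,
signs, symptoms, anatomy, active pharmaceutical ingredients with ATC
codes), assigns shallow syntactic tags to the rest, finds nominal phrases
with a small configurable pattern (Noun (Adj | Prep [Det] Noun)*), forms
candidate triples, and routes reviewed candidates into the network.

Matching is case- and diacritic-insensitive (NFD fold) and longest-match:
"insulina lispro" wins over "insulina".  The interactive review screen is
replaced by a deterministic review-file round trip with the same
register / skip / edit semantics.
"""

from __future__ import annotations

import csv
import io
import re
import unicodedata
from dataclasses import dataclass, field, replace
from importlib import resources as _ilres
from typing import Iterable, Optional, Sequence, Union

from . import namespaces as NS
from .model import (
    IRIRef,
    LiteralValue,
    NetworkSpec,
    OntologyError,
    ResolutionError,
)
from .schema import MASTER_CLASSES, slug


class ExtractionError(OntologyError):
    pass


def fold(text: str) -> str:
    """Accent/case folding: NFD normalization with combining marks stripped."""
    return "".join(
        c for c in unicodedata.normalize("NFD", text.lower())
        if unicodedata.category(c) != "Mn"
    )


# ---------------------------------------------------------------------------
# gazetteers


@dataclass(frozen=True)
class GazetteerEntry:
    term: str
    tag: str  # Disease | Symptom | Sign | Anatomy | API
    code: str
    vocab: str  # gazetteer id, e.g. ICD-10, ATC


class Gazetteer:
    def __init__(self, entries: Iterable[GazetteerEntry]):
        self.entries = list(entries)
        self.by_folded = {fold(e.term): e for e in self.entries}
        self.max_words = max((len(e.term.split()) for e in self.entries), default=1)

    def __len__(self) -> int:
        return len(self.entries)


def parse_gazetteer(text: str) -> Gazetteer:
    """TSV columns: term, tag, code, vocab (header optional)."""
    entries = []
    for row in csv.reader(io.StringIO(text), delimiter="\t"):
        if not row or row[0].strip().lower() in ("", "term") or row[0].startswith("#"):
            continue
        term, tag = row[0].strip(), row[1].strip()
        code = row[2].strip() if len(row) > 2 else ""
        vocab = row[3].strip() if len(row) > 3 else ""
        entries.append(GazetteerEntry(term, tag, code, vocab))
    return Gazetteer(entries)


FIXTURE_GAZETTEERS = (
    "gaz_enfermedades.tsv",
    "gaz_sintomas.tsv",
    "gaz_signos.tsv",
    "gaz_anatomia.tsv",
    "gaz_principios_activos.tsv",
)


def load_fixture_gazetteers() -> list[Gazetteer]:
    """The synthetic fixture gazetteers shipped with the package (the real
    vocabularies used in production are licensed and much larger)."""
    out = []
    for name in FIXTURE_GAZETTEERS:
        text = _ilres.files("ontonet.resources").joinpath(name).read_text("utf-8")
        out.append(parse_gazetteer(text))
    return out


def load_gazetteer_file(path: str) -> Gazetteer:
    with open(path, encoding="utf-8") as fh:
        return parse_gazetteer(fh.read())


# ---------------------------------------------------------------------------
# tagging


@dataclass(frozen=True)
class TaggedTerm:
    start: int
    end: int
    text: str
    tag_kind: str  # "semantic" | "syntactic"
    tag: str
    source_vocab: str = ""
    code: str = ""


_TOKEN = re.compile(r"\d+(?:[.,]\d+)?|\w+|\S", re.UNICODE)

# tiny Spanish function-word lexicon; everything else falls back on suffix
# heuristics with Noun as the default.
_POS_LEXICON = {
    "Det": {"el", "la", "los", "las", "un", "una", "unos", "unas", "su", "sus"},
    "Prep": {"de", "del", "en", "con", "por", "para", "sin", "a", "al", "sobre", "tras"},
    "Conj": {"y", "e", "o", "u", "ni", "que"},
    "Verb": {
        "es", "esta", "estan", "tiene", "presenta", "refiere", "niega", "recibe",
        "puede", "causar", "causa", "produce", "producir", "provoca", "provocar",
        "administrar", "administra", "evitar", "indica", "indicado", "contraindicado",
        "usar", "vigilar", "suspender", "requiere", "manifiesta", "padece",
    },
}
_ADJ_SUFFIXES = ("osa", "oso", "ica", "ico", "ada", "ado", "able", "iva", "ivo", "al", "ar")


def _pos_tag(token: str) -> str:
    folded = fold(token)
    if re.fullmatch(r"\d+(?:[.,]\d+)?", token):
        return "Num"
    if not token[0].isalnum():
        return "Punct"
    for tag, words in _POS_LEXICON.items():
        if folded in words:
            return tag
    if folded.endswith(_ADJ_SUFFIXES) and len(folded) > 4:
        return "Adj"
    return "Noun"


def tag_terms(text: str, gazetteers: Sequence[Gazetteer]) -> list[TaggedTerm]:
    """Tag every token syntactically; gazetteer hits additionally get
    semantic tags.  Semantic matches are longest-match and non-overlapping;
    empty text yields an empty list."""
    if not text:
        return []
    tokens = [(m.start(), m.end(), m.group()) for m in _TOKEN.finditer(text)]
    tagged: list[TaggedTerm] = [
        TaggedTerm(s, e, t, "syntactic", _pos_tag(t)) for s, e, t in tokens
    ]
    max_words = max((g.max_words for g in gazetteers), default=1)
    semantic: list[TaggedTerm] = []
    i = 0
    while i < len(tokens):
        hit = None
        for n in range(min(max_words, len(tokens) - i), 0, -1):
            span = tokens[i : i + n]
            phrase = fold(" ".join(t for _, _, t in span))
            for g in gazetteers:
                entry = g.by_folded.get(phrase)
                if entry is not None:
                    hit = (n, span, entry)
                    break
            if hit:
                break
        if hit:
            n, span, entry = hit
            semantic.append(
                TaggedTerm(
                    span[0][0], span[-1][1], text[span[0][0] : span[-1][1]],
                    "semantic", entry.tag, entry.vocab, entry.code,
                )
            )
            i += n
        else:
            i += 1
    return tagged + semantic


# ---------------------------------------------------------------------------
# nominal phrases

DEFAULT_NP_PATTERN = "Noun (Adj | Prep Det? Noun)*"


def find_nominal_phrases(tagged: Sequence[TaggedTerm], pattern: str = DEFAULT_NP_PATTERN) -> list[tuple[int, int, str]]:
    """Maximal non-overlapping noun phrases over the syntactic token layer.

    The default shallow pattern is Noun (Adj | Prep [Det] Noun)*; phrase
    spans contained in a semantic term are excluded (those entities already
    have a vocabulary).  Only the default pattern is interpreted; the
    parameter exists so a different grammar can be swapped in.
    """
    if pattern != DEFAULT_NP_PATTERN:
        raise ExtractionError(f"unsupported phrase pattern: {pattern!r}")
    tokens = sorted(
        (t for t in tagged if t.tag_kind == "syntactic"), key=lambda t: t.start
    )
    semantic_spans = [(t.start, t.end) for t in tagged if t.tag_kind == "semantic"]

    def covered(s: int, e: int) -> bool:
        return any(s >= ss and e <= se for ss, se in semantic_spans)

    phrases = []
    i = 0
    while i < len(tokens):
        if tokens[i].tag != "Noun" or covered(tokens[i].start, tokens[i].end):
            i += 1
            continue
        j = i + 1
        while j < len(tokens):
            if tokens[j].tag == "Adj":
                j += 1
            elif tokens[j].tag == "Prep":
                k = j + 1
                if k < len(tokens) and tokens[k].tag == "Det":
                    k += 1
                if k < len(tokens) and tokens[k].tag == "Noun":
                    j = k + 1
                else:
                    break
            else:
                break
        start, end = tokens[i].start, tokens[j - 1].end
        if not covered(start, end):
            phrases.append((start, end, ""))
        i = j
    return phrases


# ---------------------------------------------------------------------------
# candidate triples


@dataclass
class CandidateTriple:
    id: str
    domain_ref: str  # full IRI
    relation_ref: str  # full IRI
    range_ref: Union[str, LiteralValue]  # full IRI or literal
    pattern: str  # NP-V-NP | individual-anchored | sign-literal | bare-list
    status: str = "pending"  # pending | registered | skipped | edited


_SECTION_RELATION = {
    "efectos_secundarios": "hasSideEffect",
    "generalidades": "hasSideEffect",
    "contraindicaciones": "hasContraindication",
    "precauciones": "hasCaution",
    "interacciones": "hasCaution",
}


def form_triplets(
    network: NetworkSpec,
    context_iri: str,
    tagged: Sequence[TaggedTerm],
    phrases: Sequence[tuple[int, int, str]] = (),
    text: str = "",
    section: Optional[str] = None,
    _counter: Optional[list[int]] = None,
) -> list[CandidateTriple]:
    """Propose candidate triples for one tagged fragment.

    For medical notes (``section is None``) the context must resolve to a
    Medical Note individual: disease and symptom lists become
    (note, presentsDisease/presentsSymptom, entity) candidates; a sign
    followed by a value becomes a "has"+SignName data-property candidate
    (numeric values typed float, otherwise string); NP-Verb-NP sequences
    become generic candidates.  For drug-catalog sections the context is
    the drug and the relation follows the section kind (side effects,
    contraindications, cautions)."""
    res = network.resolve(context_iri)
    if res.found_as != "individual":
        raise ResolutionError(f"context does not resolve to an individual: {context_iri}")
    counter = _counter if _counter is not None else [0]

    def new(domain, relation, rng, pattern) -> CandidateTriple:
        counter[0] += 1
        return CandidateTriple(f"c{counter[0]:04d}", domain, relation, rng, pattern)

    out: list[CandidateTriple] = []
    semantic = sorted(
        (t for t in tagged if t.tag_kind == "semantic"), key=lambda t: t.start
    )
    if section is not None:
        relation = NS.RED + _SECTION_RELATION.get(section, "hasCaution")
        for t in semantic:
            if t.tag in ("Disease", "Symptom"):
                out.append(
                    new(context_iri, relation, NS.ENF + slug(t.text), "individual-anchored")
                )
        return out

    tokens = sorted((t for t in tagged if t.tag_kind == "syntactic"), key=lambda t: t.start)
    for t in semantic:
        if t.tag == "Disease":
            out.append(
                new(context_iri, NS.RED + "presentsDisease", NS.ENF + slug(t.text), "bare-list")
            )
        elif t.tag == "Symptom":
            out.append(
                new(context_iri, NS.RED + "presentsSymptom", NS.ENF + slug(t.text), "bare-list")
            )
        elif t.tag == "Sign":
            nxt = next((tok for tok in tokens if tok.start >= t.end and tok.tag != "Punct"), None)
            if nxt is not None and nxt.tag == "Num":
                value = LiteralValue(float(nxt.text.replace(",", ".")))
            elif nxt is not None:
                value = LiteralValue(nxt.text)
            else:
                continue
            prop = NS.DATOS + "has" + slug(t.text)
            out.append(new(context_iri, prop, value, "sign-literal"))

    # NominalPhrase - Verb - NominalPhrase
    verbs = [t for t in tokens if t.tag == "Verb"]
    for v in verbs:
        left = [p for p in phrases if p[1] <= v.start]
        right = [p for p in phrases if p[0] >= v.end]
        if left and right:
            lp, rp = left[-1], right[0]
            verb_text = text[v.start : v.end] if text else "relatesTo"
            out.append(
                new(
                    NS.ENF + slug(text[lp[0] : lp[1]] if text else "X"),
                    NS.RED + "tiene" + slug(verb_text),
                    NS.ENF + slug(text[rp[0] : rp[1]] if text else "Y"),
                    "NP-V-NP",
                )
            )
    return out


# ---------------------------------------------------------------------------
# review round trip


def write_review_file(candidates: Sequence[CandidateTriple]) -> str:
    """Review file: one TSV record per candidate (id, domain, relation,
    range, action).  Default action is register; a reviewer edits fields or
    flips the action to skip."""
    buf = io.StringIO()
    w = csv.writer(buf, delimiter="\t", lineterminator="\n")
    w.writerow(["id", "domain", "relation", "range", "action"])
    for c in candidates:
        rng = c.range_ref.value if isinstance(c.range_ref, LiteralValue) else c.range_ref
        w.writerow([c.id, c.domain_ref, c.relation_ref, rng, "register"])
    return buf.getvalue()


def read_review_file(text: str) -> list[dict]:
    rows = []
    for row in csv.reader(io.StringIO(text), delimiter="\t"):
        if not row or row[0] == "id" or row[0].startswith("#"):
            continue
        rows.append(
            {"id": row[0], "domain": row[1], "relation": row[2], "range": row[3], "action": row[4]}
        )
    return rows


def review_candidates(
    candidates: Sequence[CandidateTriple], review_records: Sequence[dict]
) -> list[CandidateTriple]:
    """Apply review decisions; unknown candidate ids are an error."""
    by_id = {c.id: c for c in candidates}
    unknown = [r["id"] for r in review_records if r["id"] not in by_id]
    if unknown:
        raise ExtractionError(f"review records reference unknown candidate ids: {unknown}")
    out = {c.id: c for c in candidates}
    for r in review_records:
        c = by_id[r["id"]]
        if r["action"] == "skip":
            out[c.id] = replace(c, status="skipped")
            continue
        rng_new: Union[str, LiteralValue]
        if isinstance(c.range_ref, LiteralValue):
            raw = r["range"]
            try:
                rng_new = LiteralValue(type(c.range_ref.value)(raw))
            except (TypeError, ValueError):
                rng_new = LiteralValue(raw)
        else:
            rng_new = r["range"]
        edited = (
            r["domain"] != c.domain_ref
            or r["relation"] != c.relation_ref
            or rng_new != c.range_ref
        )
        out[c.id] = replace(
            c,
            domain_ref=r["domain"],
            relation_ref=r["relation"],
            range_ref=rng_new,
            status="edited" if edited else "registered",
        )
    return list(out.values())


# ---------------------------------------------------------------------------
# integration flow


def _route_individual(network: NetworkSpec, full_iri: str) -> IRIRef:
    """Resolve-or-create: an absent resource becomes an individual of the
    owning module's master class, then the IRI is re-verified."""
    res = network.resolve(full_iri)
    ref = IRIRef.parse(full_iri)
    if res.found_as == "individual":
        return ref
    if res.found_as not in ("absent",):
        raise ResolutionError(f"{full_iri} resolves to a {res.found_as}, not an individual")
    module = network.module_for_namespace(ref.namespace)
    if module is None:
        raise ResolutionError(f"unroutable IRI (no module owns {ref.namespace})")
    master_local = MASTER_CLASSES.get(module.name)
    if module is network.network_module:
        master_local = "Dosis_En_Receta"
    if master_local is None or master_local not in module.classes:
        raise ResolutionError(f"module {module.name} has no master class for new individuals")
    module.add_individual(ref.local_name, module.iri(master_local))
    assert network.resolve(full_iri).found_as == "individual"
    return ref


def integrate_triplet(network: NetworkSpec, triple: CandidateTriple) -> NetworkSpec:
    """Assert one registered candidate into the network.

    Absent domain/range resources are created under the owning module's
    master class.  Absent object properties are created in the network
    namespace; absent data properties in the Clinical Information
    Administration namespace.  Skipped or pending candidates are refused.
    """
    if triple.status not in ("registered", "edited"):
        raise ExtractionError(f"candidate {triple.id} is not registered (status={triple.status})")
    subject = _route_individual(network, triple.domain_ref)
    rel = IRIRef.parse(NS.canonical_iri(triple.relation_ref))
    if isinstance(triple.range_ref, LiteralValue):
        # data properties live in the Clinical Information Administration module
        datos = network.module_for_namespace(NS.DATOS)
        if rel.local_name not in datos.data_properties:
            rng = "float" if triple.range_ref.datatype == "float" else triple.range_ref.datatype
            datos.add_data_property(rel.local_name, datos.iri("Nota_Medica"), rng)
        network.add_assertion(subject, datos.iri(rel.local_name), triple.range_ref)
        return network
    obj = _route_individual(network, triple.range_ref)
    canonical = IRIRef(network.network_iri, IRIRef.parse(NS.canonical_iri(rel.full)).local_name)
    net = network.network_module
    if canonical.local_name not in net.object_properties:
        dom_cls = next(iter(network.find_individual(subject).classes), None)
        rng_cls = next(iter(network.find_individual(obj).classes), None)
        net.add_object_property(canonical.local_name, dom_cls, rng_cls)
    network.add_assertion(subject, canonical, obj)
    return network


def integrate_candidates(
    network: NetworkSpec, candidates: Sequence[CandidateTriple]
) -> NetworkSpec:
    for c in candidates:
        if c.status in ("registered", "edited"):
            integrate_triplet(network, c)
    return network
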