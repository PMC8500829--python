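"""Population: structured clinical records become individuals and assertions.

Each record yields one Patient individual (Person module), one Clinical
Record and one Medical Note per visit (Clinical Information Administration
module), and one anonymous Prescription Dose node per prescription in the
network namespace.  Module-internal links use each module's own IRI;
cross-module links (livesIn, hasClinicalRecord, hasDiagnosis, ...) use the
network IRI.  Individual names are deterministic slugs of the record ids
(``Paciente_0001``, ``Nota_0001_1``), so re-population is idempotent.

Age is stored per note (floor of the year difference between birth date
and note date): the basal-metabolic-rate rule traverses the note, not the
patient.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import asdict, dataclass, field
from typing import Iterable, Optional

from . import namespaces as NS
from .model import IRIRef, LiteralValue, NetworkSpec, OntologyError
from .schema import slug


class PopulationError(OntologyError):
    pass


@dataclass
class MedicalNoteDoc:
    date: str  # ISO-8601
    doctor_id: str
    signs: dict[str, float]
    current_condition: str = ""
    physical_exam: str = ""
    analysis: str = ""
    diagnoses: list[str] = field(default_factory=list)
    prescriptions: list[dict] = field(default_factory=list)


@dataclass
class ClinicalRecordDoc:
    record_id: str
    patient: dict  # sex, birth_date, state_of_residence, education_level
    histories: dict = field(default_factory=dict)
    notes: list[MedicalNoteDoc] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), ensure_ascii=False, sort_keys=True)

    @classmethod
    def from_json(cls, line: str) -> "ClinicalRecordDoc":
        doc = json.loads(line)
        notes = [MedicalNoteDoc(**n) for n in doc.pop("notes", [])]
        return cls(notes=notes, **doc)


def write_records_jsonl(records: Iterable[ClinicalRecordDoc]) -> str:
    return "".join(r.to_json() + "\n" for r in records)


def read_records_jsonl(text: str) -> list[ClinicalRecordDoc]:
    return [ClinicalRecordDoc.from_json(line) for line in text.splitlines() if line.strip()]


# sign key in the record -> (data property local name, python type)
SIGN_PROPERTIES = {
    "peso": ("tienePeso", float),
    "talla": ("tieneTalla", float),
    "glucosa": ("tieneGlucosaPostPrandial", int),
    "frecuencia_cardiaca": ("tieneFrecuenciaCardiaca", int),
    "frecuencia_respiratoria": ("tieneFrecuenciaRespiratoria", int),
    "temperatura": ("tieneTemperaturaCorporal", float),
    "cintura": ("hasWaistMeasure", float),
    "cadera": ("hasHipMeasure", float),
}


def _age_at(birth: _dt.date, on: _dt.date) -> int:
    return on.year - birth.year - ((on.month, on.day) < (birth.month, birth.day))


def populate(network: NetworkSpec, records: Iterable[ClinicalRecordDoc]) -> NetworkSpec:
    """Assert all records into a network whose schema and meta-relations are
    already attached.  Unknown states or education levels are refused by
    name before any assertion for that record is made."""
    persona = network.module_for_namespace(NS.PERSONA)
    datos = network.module_for_namespace(NS.DATOS)
    enf = network.module_for_namespace(NS.ENF)
    edu = network.module_for_namespace(NS.EDU)
    estados = network.module_for_namespace(NS.ESTADOS)
    medi = network.module_for_namespace(NS.MEDI)
    net = network.network_module
    red = network.network_iri

    for rec in records:
        p = rec.patient
        state_local = slug(p["state_of_residence"])
        if state_local not in estados.individuals:
            raise PopulationError(
                f"unknown state of residence: {p['state_of_residence']!r} (record {rec.record_id})"
            )
        level_local = slug(p["education_level"])
        if level_local not in edu.individuals:
            raise PopulationError(
                f"unknown education level: {p['education_level']!r} (record {rec.record_id})"
            )
        birth = _dt.date.fromisoformat(p["birth_date"])

        patient = persona.add_individual(f"Paciente_{rec.record_id}", persona.iri("Paciente"))
        network.add_assertion(patient.iri, persona.iri("tieneSexo"), LiteralValue(p["sex"]))
        network.add_assertion(
            patient.iri, persona.iri("tieneFechaNacimiento"), LiteralValue(birth)
        )
        network.add_assertion(patient.iri, IRIRef(red, "resideEn"), estados.iri(state_local))
        network.add_assertion(
            patient.iri, IRIRef(red, "hasEducationLevel"), edu.iri(level_local)
        )
        record = datos.add_individual(
            f"Expediente_{rec.record_id}", datos.iri("Expediente_Clinico")
        )
        network.add_assertion(patient.iri, IRIRef(red, "tieneExpedienteClinico"), record.iri)

        disabilities = (rec.histories or {}).get("disabilities") or []
        if disabilities:
            hist = datos.add_individual(
                f"Historia_{rec.record_id}", datos.iri("Historia_Clinica")
            )
            network.add_assertion(record.iri, datos.iri("tieneHistoriaClinica"), hist.iri)
            for dis in disabilities:
                d = enf.add_individual(slug(dis), enf.iri("Discapacidad"))
                enf.label(d.iri, dis)
                network.add_assertion(hist.iri, IRIRef(red, "hasDisability"), d.iri)

        for n_idx, note_doc in enumerate(rec.notes, start=1):
            note = datos.add_individual(
                f"Nota_{rec.record_id}_{n_idx}", datos.iri("Nota_Medica")
            )
            network.add_assertion(record.iri, datos.iri("tieneNotaMedica"), note.iri)
            note_date = _dt.date.fromisoformat(note_doc.date)
            network.add_assertion(note.iri, datos.iri("tieneFecha"), LiteralValue(note_date))
            network.add_assertion(
                note.iri, datos.iri("hasAge"), LiteralValue(_age_at(birth, note_date))
            )
            doctor = persona.add_individual(
                f"Medico_{note_doc.doctor_id}", persona.iri("Medico")
            )
            network.add_assertion(note.iri, IRIRef(red, "isWrittenBy"), doctor.iri)
            network.add_assertion(doctor.iri, IRIRef(red, "writesMedicalNote"), note.iri)
            for key, value in note_doc.signs.items():
                if key not in SIGN_PROPERTIES:
                    raise PopulationError(f"unknown sign {key!r} (record {rec.record_id})")
                local, typ = SIGN_PROPERTIES[key]
                network.add_assertion(note.iri, datos.iri(local), LiteralValue(typ(value)))
            for local, text in (
                ("tienePadecimientoActual", note_doc.current_condition),
                ("tieneExploracionFisica", note_doc.physical_exam),
                ("tieneAnalisis", note_doc.analysis),
            ):
                network.add_assertion(note.iri, datos.iri(local), LiteralValue(text or "sin datos"))
            for dx in note_doc.diagnoses:
                d = enf.add_individual(slug(dx), enf.iri("Enfermedad"))
                enf.label(d.iri, dx)
                network.add_assertion(note.iri, IRIRef(red, "hasDiagnosis"), d.iri)
            for i, rx in enumerate(note_doc.prescriptions, start=1):
                dose = net.add_individual(
                    f"_bnDosis_{rec.record_id}_{n_idx}_{i}", net.iri("Dosis_En_Receta")
                )
                network.add_assertion(note.iri, IRIRef(red, "hasTreatment"), dose.iri)
                api_local = slug(rx["api"])
                if medi is not None:
                    if api_local not in medi.individuals:
                        medi.add_individual(api_local, medi.iri("Clasificacion_ATC"))
                        medi.label(medi.iri(api_local), rx["api"])
                    api_iri = medi.iri(api_local)
                else:  # pragma: no cover - drug module should exist
                    raise PopulationError("network lacks the Drug-ATC module")
                network.add_assertion(dose.iri, IRIRef(red, "hasAPIInPrescription"), api_iri)
                network.add_assertion(
                    dose.iri, datos.iri("tieneCantidadIndicadaEnReceta"),
                    LiteralValue(float(rx["amount"])),
                )
                network.add_assertion(
                    dose.iri, datos.iri("tieneFrecuenciaIndicadaEnReceta"),
                    LiteralValue(float(rx["frequency"])),
                )
                network.add_assertion(
                    dose.iri, datos.iri("tieneMedidaIndicadaEnReceta"),
                    LiteralValue(str(rx["measure"])),
                )
    return network


def satisfy_check(network: NetworkSpec) -> dict:
    """Per-module individual counts and the all-modules-non-empty flag (the
    satisfiability reading used for the network: every participating
    ontology holds at least one instance)."""
    counts = {m.name: len(m.individuals) for m in network.modules.values()}
    counts["network"] = len(network.network_module.individuals)
    return {
        "counts": counts,
        "all_nonempty": all(len(m.individuals) > 0 for m in network.modules.values()),
    }
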