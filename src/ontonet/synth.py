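"""Seeded generator of synthetic clinical-record corpora.

The default profile reproduces the reference corpus margins exactly at
every seed: 171 records (90 male / 81 female), 729 diagnosis entries (143
insulin-dependent DM, 149 non-insulin-dependent DM, 437 other), and 1626
prescriptions (Insulin Glargine 131, Metformin 61, Diosmin-with-Hesperidin
58, the remainder spread over a fixture drug list).  Allocation is
deal-from-deck rather than i.i.d. sampling, so the totals are exact and
randomness only permutes which patient or note receives which card.

Sign values are drawn from plausible adult ranges (weight 45-120 kg,
height 1.40-1.95 m, post-prandial glucose 70-300 mg/dl).  Alongside the
structured records the generator emits free-text note fragments and the
synthetic drug-catalog sections, which exercise the extraction gazetteers.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional

from .integrate import DRUG_TEXTS_FIXTURE
from .model import ConfigError
from .populate import ClinicalRecordDoc, MedicalNoteDoc
from .schema import EDUCATION_LEVELS, MEXICAN_STATES

T1DM = "Diabetes Mellitus Tipo 1"  # insulin-dependent
T2DM = "Diabetes Mellitus Tipo 2"  # non-insulin-dependent

OTHER_DISEASES = [
    "Hipertensión Arterial", "Obesidad", "Insuficiencia Renal Crónica",
    "Retinopatía Diabética", "Neuropatía Diabética", "Pie Diabético",
    "Dislipidemia", "Hipotiroidismo", "Gastritis", "Infección de Vías Urinarias",
]

NAMED_APIS = ["Insulina Glargina", "Metformina", "Diosmina con Hesperidina"]

OTHER_APIS = [
    "Insulina Lispro", "Glibenclamida", "Glimepirida", "Losartán", "Captopril",
    "Enalapril", "Atorvastatina", "Bezafibrato", "Ácido Acetilsalicílico",
    "Omeprazol", "Paracetamol", "Hidroclorotiazida",
]

#: default (amount, measure, frequency-per-day) per prescribed ingredient
RX_DEFAULTS: dict[str, tuple[float, str, float]] = {
    "Insulina Glargina": (20.0, "UI", 1.0),
    "Metformina": (850.0, "mg", 2.0),
    "Diosmina con Hesperidina": (500.0, "mg", 1.0),
    "Insulina Lispro": (10.0, "UI", 3.0),
    "Glibenclamida": (5.0, "mg", 1.0),
    "Glimepirida": (2.0, "mg", 1.0),
    "Losartán": (50.0, "mg", 1.0),
    "Captopril": (25.0, "mg", 2.0),
    "Enalapril": (10.0, "mg", 2.0),
    "Atorvastatina": (20.0, "mg", 1.0),
    "Bezafibrato": (200.0, "mg", 2.0),
    "Ácido Acetilsalicílico": (100.0, "mg", 1.0),
    "Omeprazol": (20.0, "mg", 1.0),
    "Paracetamol": (500.0, "mg", 3.0),
    "Hidroclorotiazida": (25.0, "mg", 1.0),
}

SYMPTOMS = [
    "poliuria", "polidipsia", "polifagia", "fatiga",
    "visión borrosa", "cefalea", "mareo", "náusea",
]

DISABILITIES = ["Discapacidad Visual", "Discapacidad Motriz", "Discapacidad Auditiva"]

ALL_EDUCATION_LEVELS = [lvl for group in EDUCATION_LEVELS.values() for lvl in group]


@dataclass
class CorpusProfile:
    n_patients: int = 171
    n_male: int = 90
    n_female: int = 81
    #: diagnosis entries per category; "other" is spread over OTHER_DISEASES
    diagnosis_quota: dict[str, int] = field(
        default_factory=lambda: {T1DM: 143, T2DM: 149, "other": 437}
    )
    #: prescription entries per ingredient; "other" spread over OTHER_APIS
    prescription_quota: dict[str, int] = field(
        default_factory=lambda: {
            "Insulina Glargina": 131, "Metformina": 61,
            "Diosmina con Hesperidina": 58, "other": 1376,
        }
    )
    notes_per_record: tuple[int, int] = (1, 4)  # uniform inclusive bounds
    n_doctors: int = 10
    symptom_fraction: float = 0.10  # notes whose free text mentions a symptom
    disability_fraction: float = 0.15
    seed: int = 0

    @property
    def total_diagnoses(self) -> int:
        return sum(self.diagnosis_quota.values())

    @property
    def total_prescriptions(self) -> int:
        return sum(self.prescription_quota.values())

    def validate(self) -> None:
        if self.n_male + self.n_female != self.n_patients:
            raise ConfigError(
                f"sex split {self.n_male}+{self.n_female} != n_patients {self.n_patients}"
            )
        for name, quota in {**self.diagnosis_quota, **self.prescription_quota}.items():
            if quota < 0:
                raise ConfigError(f"negative quota for {name!r}")
        lo, hi = self.notes_per_record
        if not (1 <= lo <= hi):
            raise ConfigError(f"bad notes_per_record bounds: {self.notes_per_record}")
        if self.n_patients * lo > self.total_diagnoses:
            raise ConfigError("fewer diagnoses than notes: every note needs one")
        if self.n_patients * lo > self.total_prescriptions:
            raise ConfigError("fewer prescriptions than notes: every note needs one")
        if self.n_patients > 0 and self.n_doctors < 1:
            raise ConfigError("need at least one doctor")


def profile_from_paper() -> CorpusProfile:
    """The default profile with the reference corpus counts."""
    return CorpusProfile()


def _spread(total: int, names: list[str]) -> dict[str, int]:
    """Deterministic near-even split of a quota over a name list."""
    base, extra = divmod(total, len(names))
    return {name: base + (1 if i < extra else 0) for i, name in enumerate(names)}


def _expand_deck(quota: dict[str, int], other_names: list[str], rng: random.Random) -> list[str]:
    deck: list[str] = []
    for name, count in quota.items():
        if name == "other":
            for other, c in _spread(count, other_names).items():
                deck.extend([other] * c)
        else:
            deck.extend([name] * count)
    rng.shuffle(deck)
    return deck


def _deal(deck: list[str], n_slots: int, rng: random.Random) -> list[list[str]]:
    """Every slot gets at least one card; the remainder lands randomly,
    avoiding in-slot duplicates when possible."""
    slots: list[list[str]] = [[deck[i]] for i in range(n_slots)]
    for card in deck[n_slots:]:
        for _ in range(10):
            idx = rng.randrange(n_slots)
            if card not in slots[idx]:
                break
        slots[idx].append(card)
    return slots


def generate_corpus(
    profile: Optional[CorpusProfile] = None, seed: Optional[int] = None
) -> tuple[list[ClinicalRecordDoc], dict]:
    """Generate records plus companion free-text fragments.

    Same seed, same corpus (byte-identical through the JSON-lines writer);
    different seeds permute assignments but keep every marginal total.
    """
    profile = profile or profile_from_paper()
    profile.validate()
    rng = random.Random(profile.seed if seed is None else seed)

    sexes = ["Male"] * profile.n_male + ["Female"] * profile.n_female
    rng.shuffle(sexes)
    note_counts = [
        rng.randint(*profile.notes_per_record) for _ in range(profile.n_patients)
    ]
    n_notes = sum(note_counts)
    if n_notes > profile.total_diagnoses or n_notes > profile.total_prescriptions:
        raise ConfigError(
            f"infeasible allocation: {n_notes} notes exceed the diagnosis or "
            f"prescription quota"
        )
    dx_slots = _deal(_expand_deck(profile.diagnosis_quota, OTHER_DISEASES, rng), n_notes, rng)
    rx_slots = _deal(
        _expand_deck(profile.prescription_quota, OTHER_APIS, rng), n_notes, rng
    )

    doctor_ids = [f"{i:02d}" for i in range(1, profile.n_doctors + 1)]
    records: list[ClinicalRecordDoc] = []
    fragments: list[dict] = []
    slot = 0
    for idx in range(profile.n_patients):
        rid = f"{idx + 1:04d}"
        sex = sexes[idx]
        age = rng.randint(28, 85)
        birth = f"{2019 - age:04d}-{rng.randint(1, 12):02d}-{rng.randint(1, 28):02d}"
        height = round(rng.uniform(1.40, 1.95), 2)
        base_weight = round(rng.uniform(45.0, 120.0), 1)
        disabilities = (
            [rng.choice(DISABILITIES)]
            if rng.random() < profile.disability_fraction
            else []
        )
        notes = []
        for n in range(note_counts[idx]):
            date = (
                f"{rng.choice((2018, 2019, 2020)):04d}-"
                f"{rng.randint(1, 12):02d}-{rng.randint(1, 28):02d}"
            )
            hip = round(rng.uniform(80.0, 140.0), 1)
            signs = {
                "peso": round(min(135.0, max(40.0, base_weight + rng.uniform(-4, 4))), 1),
                "talla": height,
                "glucosa": rng.randint(70, 300),
                "frecuencia_cardiaca": rng.randint(55, 100),
                "frecuencia_respiratoria": rng.randint(12, 22),
                "temperatura": round(rng.uniform(36.0, 37.5), 1),
                "cintura": round(hip * rng.uniform(0.70, 1.05), 1),
                "cadera": hip,
            }
            diagnoses = dx_slots[slot]
            prescriptions = [
                {
                    "api": api,
                    "amount": RX_DEFAULTS[api][0],
                    "measure": RX_DEFAULTS[api][1],
                    "frequency": RX_DEFAULTS[api][2],
                }
                for api in rx_slots[slot]
            ]
            symptom = (
                rng.choice(SYMPTOMS) if rng.random() < profile.symptom_fraction else None
            )
            condition = (
                f"Paciente refiere {symptom} de varios días."
                if symptom
                else "Paciente acude a control sin molestias agudas."
            )
            note = MedicalNoteDoc(
                date=date,
                doctor_id=(
                    doctor_ids[slot % len(doctor_ids)]
                    if slot < len(doctor_ids)
                    else rng.choice(doctor_ids)
                ),
                signs=signs,
                current_condition=condition,
                physical_exam="Exploración física sin datos de alarma.",
                analysis="Se ajusta manejo según evolución.",
                diagnoses=list(diagnoses),
                prescriptions=prescriptions,
            )
            notes.append(note)
            fragments.append(
                {
                    "record_id": rid,
                    "note_index": n + 1,
                    "text": f"{condition} Diagnósticos: {'; '.join(diagnoses)}. "
                            f"Glucosa {signs['glucosa']}.",
                }
            )
            slot += 1
        records.append(
            ClinicalRecordDoc(
                record_id=rid,
                patient={
                    "sex": sex,
                    "birth_date": birth,
                    "state_of_residence": rng.choice(MEXICAN_STATES),
                    "education_level": rng.choice(ALL_EDUCATION_LEVELS),
                },
                histories={
                    "hereditary_family": ["Diabetes Mellitus Tipo 2"] if rng.random() < 0.5 else [],
                    "pathological": [],
                    "non_pathological": [],
                    "gyneco_obstetric": [],
                    "allergies": [],
                    "disabilities": disabilities,
                },
                notes=notes,
            )
        )
    drug_texts = [
        {"drug": name, "section": section, "text": text}
        for name, sections in sorted(DRUG_TEXTS_FIXTURE.items())
        for section, text in sorted(sections.items())
    ]
    return records, {"note_fragments": fragments, "drug_texts": drug_texts}


def corpus_counts(records: list[ClinicalRecordDoc]) -> dict:
    """Marginal totals of a corpus (the quantities the profile pins down)."""
    by_sex = {"Male": 0, "Female": 0}
    dx: dict[str, int] = {}
    rx: dict[str, int] = {}
    n_notes = 0
    for rec in records:
        by_sex[rec.patient["sex"]] += 1
        for note in rec.notes:
            n_notes += 1
            for d in note.diagnoses:
                dx[d] = dx.get(d, 0) + 1
            for p in note.prescriptions:
                rx[p["api"]] = rx.get(p["api"], 0) + 1
    return {
        "n_records": len(records),
        "n_male": by_sex["Male"],
        "n_female": by_sex["Female"],
        "n_notes": n_notes,
        "diagnoses_total": sum(dx.values()),
        "diagnoses_by_name": dx,
        "prescriptions_total": sum(rx.values()),
        "prescriptions_by_api": rx,
    }
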