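"""Synthetic ICSR database generator with known ground truth.

National spontaneous-reporting extracts are not public, so downstream stages
are exercised on simulated databases whose structure mirrors a pediatric
serious-ADR extract: ~2,000 serious reports over 2008-2013, 1-6 suspected
drugs per report (mean ~1.13), five pediatric age groups, six serious
outcomes, ~1% missing gender, ~9.6% indeterminate route/form.

Generative model, per case:

1. an age group is sampled, then an age in days uniform within a day range
   chosen so the anniversary-based classifier always recovers the group;
2. the event-onset date is uniform over 2008-2013 and the birth date follows
   by subtraction, so the age-derivation code path is exercised;
3. the number of suspected drugs is sampled from ``n_drugs_distribution``
   and that many catalog drugs are drawn without replacement with
   probability proportional to their marginal weights (with one drug per
   report — the dominant case — a weight equals the per-report marginal);
4. each catalog event occurs independently with probability p where
   ``odds(p) = odds(background) * lambda`` if a sampled drug forms an
   injected pair with it (multipliers of several matching pairs multiply),
   else the background odds. Because the model is odds-multiplicative, the
   expected ROR of an injected pair is ~lambda. Cases with no event get one
   event resampled from the background distribution: every report reports
   something;
5. one seriousness outcome is sampled independently of drugs and events (no
   joint model is asserted), then gender, reporter origin, pharmaceutical
   form/route and indication are drawn, with the configured missingness.

A single pseudo-random stream, seeded once, is consumed stage by stage in
the documented order (age -> dates -> drugs -> events -> seriousness ->
demographics/missingness), so identical seeds give byte-identical output.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .icsr_model import (
    SERIOUS_LEVELS,
    CaseReport,
    DrugEntry,
    EventEntry,
    normalize_name,
)
from .label_registry import LabelRecord, build_registry
from .preprocess import AgeGroup

_PROB_TOL = 1e-9

#: Day ranges per age group, chosen strictly inside each group's possible
#: anniversary span so the calendar-based classifier always agrees with the
#: sampled group regardless of leap days.
GROUP_DAY_RANGES: dict[AgeGroup, tuple[int, int]] = {
    AgeGroup.BABY: (0, 364),
    AgeGroup.TODDLER: (366, 1094),
    AgeGroup.PRESCHOOL: (1096, 1824),
    AgeGroup.PRIMARY_SCHOOL: (1827, 2919),
    AgeGroup.SECONDARY_SCHOOL: (2922, 4379),
}

STUDY_START = dt.date(2008, 1, 1)
STUDY_END = dt.date(2013, 12, 31)

#: (pharm_form, route, conditional probability given a determinate route).
#: Marginal shares renormalized among determinate entries.
PHARM_FORMS: tuple[tuple[str, str, float], ...] = (
    ("intravenous_powder_or_solution", "intravenous", 0.69 / 0.904),
    ("tablet", "oral", 0.093 / 0.904),
    ("oral_solution", "oral", 0.045 / 0.904),
    ("oral_suspension", "oral", 0.037 / 0.904),
    ("other", "other", 0.039 / 0.904),
)

P_INDICATION_REPORTED = 0.6  # share of drug entries with an ICD indication


class ConfigError(ValueError):
    """The simulation configuration is structurally invalid."""


@dataclass(frozen=True)
class DrugSpec:
    """One catalog drug: sampling weight plus its synthetic label."""

    name: str
    atc_level5: str
    marginal_probability: float
    licensed: bool = True
    min_age_days: Optional[int] = None
    max_age_days: Optional[int] = None
    labelled_event_terms: tuple[str, ...] = ()
    on_monitoring_list: bool = False
    indication_icd: Optional[str] = None


@dataclass(frozen=True)
class EventSpec:
    """One catalog adverse-event term with its background probability."""

    term: str
    soc: str
    background_probability: float
    is_ime: bool = False


@dataclass(frozen=True)
class InjectedSignal:
    """A drug-event pair whose reporting odds are multiplied by lambda."""

    drug_name: str
    event_term: str
    odds_multiplier: float


@dataclass
class SimulationConfig:
    n_reports: int
    drug_catalog: list[DrugSpec]
    event_catalog: list[EventSpec]
    injected_signals: list[InjectedSignal] = field(default_factory=list)
    n_drugs_distribution: tuple[float, ...] = (0.895, 0.09, 0.01, 0.003, 0.0015, 0.0005)
    age_group_probabilities: tuple[float, ...] = (0.2, 0.2, 0.2, 0.2, 0.2)
    p_gender_missing: float = 0.01
    p_route_indeterminate: float = 0.096
    seriousness_probabilities: tuple[float, ...] = (1 / 6,) * 6
    p_male: float = 0.545  # male share among reports with gender specified
    reporter_origin_probabilities: tuple[float, float, float] = (0.72, 0.27, 0.01)
    seed: int = 0

    def validate(self) -> None:
        if self.n_reports < 0:
            raise ConfigError("n_reports must be non-negative")
        if not self.drug_catalog:
            raise ConfigError("drug catalog is empty")
        if not self.event_catalog:
            raise ConfigError("event catalog is empty")
        for name, vec, k in (
            ("n_drugs_distribution", self.n_drugs_distribution, 6),
            ("age_group_probabilities", self.age_group_probabilities, 5),
            ("seriousness_probabilities", self.seriousness_probabilities, 6),
            ("reporter_origin_probabilities", self.reporter_origin_probabilities, 3),
        ):
            if len(vec) != k:
                raise ConfigError(f"{name} must have length {k}")
            if abs(sum(vec) - 1.0) > _PROB_TOL:
                raise ConfigError(f"{name} must sum to 1 (got {sum(vec)!r})")
            if any(p < 0 for p in vec):
                raise ConfigError(f"{name} has negative entries")
        for p, name in (
            (self.p_gender_missing, "p_gender_missing"),
            (self.p_route_indeterminate, "p_route_indeterminate"),
        ):
            if not 0 <= p <= 1:
                raise ConfigError(f"{name} must lie in [0,1]")
        for spec in self.drug_catalog:
            if not 0 < spec.marginal_probability < 1:
                raise ConfigError(
                    f"drug {spec.name}: marginal probability must be in (0,1)"
                )
        for spec in self.event_catalog:
            if not 0 < spec.background_probability < 1:
                raise ConfigError(
                    f"event {spec.term}: background probability must be in (0,1)"
                )
        drug_names = {normalize_name(d.name) for d in self.drug_catalog}
        event_terms = {normalize_name(e.term) for e in self.event_catalog}
        for sig in self.injected_signals:
            if not np.isfinite(sig.odds_multiplier) or sig.odds_multiplier <= 0:
                raise ConfigError(
                    f"signal {sig.drug_name}-{sig.event_term}: lambda must be "
                    "finite and positive"
                )
            if normalize_name(sig.drug_name) not in drug_names:
                raise ConfigError(f"injected signal names unknown drug {sig.drug_name}")
            if normalize_name(sig.event_term) not in event_terms:
                raise ConfigError(
                    f"injected signal names unknown event {sig.event_term}"
                )


@dataclass
class GroundTruth:
    """What the generator actually injected, for recovery checks."""

    injected_signals: list[InjectedSignal]
    background_odds: dict[str, float]

    def expected_ror(self, drug_name: str, event_term: str) -> float:
        key = (normalize_name(drug_name), normalize_name(event_term))
        for sig in self.injected_signals:
            if (normalize_name(sig.drug_name), normalize_name(sig.event_term)) == key:
                return sig.odds_multiplier
        return 1.0


def generate_database(
    config: SimulationConfig,
) -> tuple[list[CaseReport], GroundTruth]:
    """Sample a full synthetic database; deterministic under a fixed seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_reports

    bg_odds = {
        normalize_name(e.term): e.background_probability / (1 - e.background_probability)
        for e in config.event_catalog
    }
    truth = GroundTruth(list(config.injected_signals), bg_odds)
    if n == 0:
        return [], truth

    groups = list(GROUP_DAY_RANGES)
    # --- ages
    group_idx = rng.choice(len(groups), size=n, p=config.age_group_probabilities)
    lo = np.array([GROUP_DAY_RANGES[g][0] for g in groups])[group_idx]
    hi = np.array([GROUP_DAY_RANGES[g][1] for g in groups])[group_idx]
    age_days = rng.integers(lo, hi + 1)

    # --- dates
    start_ord = STUDY_START.toordinal()
    span = STUDY_END.toordinal() - start_ord + 1
    event_ord = start_ord + rng.integers(0, span, size=n)

    # --- drugs
    m_drugs = len(config.drug_catalog)
    weights = np.array([d.marginal_probability for d in config.drug_catalog])
    weights = weights / weights.sum()
    n_drugs = rng.choice(6, size=n, p=config.n_drugs_distribution) + 1
    n_drugs = np.minimum(n_drugs, m_drugs)  # catalog may be smaller than 6
    drug_sets: list[np.ndarray] = [np.empty(0, dtype=np.int64)] * n
    singles = np.flatnonzero(n_drugs == 1)
    if singles.size:
        picks = rng.choice(m_drugs, size=singles.size, p=weights)
        for i, pick in zip(singles, picks):
            drug_sets[i] = np.array([pick])
    for i in np.flatnonzero(n_drugs > 1):
        drug_sets[i] = rng.choice(m_drugs, size=n_drugs[i], replace=False, p=weights)

    # --- events (catalog order; odds multiplied where an injected pair matches)
    name_to_drug_idx = {
        normalize_name(d.name): j for j, d in enumerate(config.drug_catalog)
    }
    term_to_event_idx = {
        normalize_name(e.term): j for j, e in enumerate(config.event_catalog)
    }
    lambda_by_event: dict[int, list[tuple[int, float]]] = {}
    for sig in config.injected_signals:
        ev = term_to_event_idx[normalize_name(sig.event_term)]
        dr = name_to_drug_idx[normalize_name(sig.drug_name)]
        lambda_by_event.setdefault(ev, []).append((dr, sig.odds_multiplier))

    m_events = len(config.event_catalog)
    occur = np.zeros((n, m_events), dtype=bool)
    has_drug_cache: dict[int, np.ndarray] = {}

    def _has_drug(j: int) -> np.ndarray:
        if j not in has_drug_cache:
            has_drug_cache[j] = np.fromiter(
                (j in s for s in drug_sets), count=n, dtype=bool
            )
        return has_drug_cache[j]

    for ev_idx, espec in enumerate(config.event_catalog):
        odds = np.full(n, bg_odds[normalize_name(espec.term)])
        for dr_idx, lam in lambda_by_event.get(ev_idx, []):
            odds = np.where(_has_drug(dr_idx), odds * lam, odds)
        p = odds / (1 + odds)
        occur[:, ev_idx] = rng.random(n) < p

    empty_rows = np.flatnonzero(~occur.any(axis=1))
    if empty_rows.size:
        bg = np.array([e.background_probability for e in config.event_catalog])
        fills = rng.choice(m_events, size=empty_rows.size, p=bg / bg.sum())
        occur[empty_rows, fills] = True

    # --- seriousness (independent of drugs and events by design)
    seriousness_idx = rng.choice(6, size=n, p=config.seriousness_probabilities)

    # --- demographics and missingness
    is_male = rng.random(n) < config.p_male
    gender_missing = rng.random(n) < config.p_gender_missing
    reporter_idx = rng.choice(3, size=n, p=config.reporter_origin_probabilities)

    total_entries = int(n_drugs.sum())
    route_indet = rng.random(total_entries) < config.p_route_indeterminate
    form_probs = np.array([f[2] for f in PHARM_FORMS])
    form_idx = rng.choice(len(PHARM_FORMS), size=total_entries, p=form_probs / form_probs.sum())
    ind_reported = rng.random(total_entries) < P_INDICATION_REPORTED

    reporters = ("hospital", "other", "missing")
    reports: list[CaseReport] = []
    entry_ptr = 0
    for i in range(n):
        event_date = dt.date.fromordinal(int(event_ord[i]))
        birth_date = event_date - dt.timedelta(days=int(age_days[i]))
        drugs = []
        for j in drug_sets[i]:
            spec = config.drug_catalog[int(j)]
            if route_indet[entry_ptr]:
                form, route = "indeterminate", "indeterminate"
            else:
                form, route, _ = PHARM_FORMS[form_idx[entry_ptr]]
            indication = spec.indication_icd if ind_reported[entry_ptr] else None
            drugs.append(
                DrugEntry(
                    drug_name=spec.name,
                    atc_level5=spec.atc_level5,
                    pharm_form=form,
                    route=route,
                    indication_icd=indication,
                )
            )
            entry_ptr += 1
        events = [
            EventEntry(
                event_term=config.event_catalog[int(j)].term,
                soc=config.event_catalog[int(j)].soc,
                is_ime=config.event_catalog[int(j)].is_ime,
            )
            for j in np.flatnonzero(occur[i])
        ]
        reports.append(
            CaseReport(
                case_id=f"SIM{i:06d}",
                seriousness=SERIOUS_LEVELS[seriousness_idx[i]],
                gender="missing"
                if gender_missing[i]
                else ("male" if is_male[i] else "female"),
                reporter_origin=reporters[reporter_idx[i]],
                birth_date=birth_date,
                event_date=event_date,
                age_days=int(age_days[i]),
                drugs=drugs,
                events=events,
            )
        )
    return reports, truth


# ---------------------------------------------------------------------------
# Default calibration emulating a pediatric national serious-ADR extract


def expected_drugs_per_report(config: SimulationConfig) -> float:
    return float(
        sum((k + 1) * p for k, p in enumerate(config.n_drugs_distribution))
    )


_MIN_1M, _MIN_2M, _MIN_3M = 30, 61, 92
_MIN_1Y, _MIN_2Y, _MIN_3Y = 366, 731, 1096
_MIN_5Y, _MIN_6Y, _MIN_18Y = 1827, 2192, 6570


def _default_drug_catalog() -> list[DrugSpec]:
    # Weights reproduce the ATC level-1 profile of pediatric serious-ADR
    # reporting (anti-infectives ~47%, nervous system ~17%, antineoplastics
    # ~10%, ...); age bounds are synthetic labels calibrated so ~25% of drug
    # entries are off-label by age and ~0.5% unlicensed.
    d = DrugSpec
    return [
        # J - anti-infectives for systemic use (0.470)
        d("VANCOMYCIN", "J01XA01", 0.092, min_age_days=_MIN_1M, indication_icd="A41",
          labelled_event_terms=("RED MAN SYNDROME", "RASH", "PHLEBITIS", "THROMBOCYTOPENIA", "FEVER")),
        d("CEFTRIAXONE", "J01DD04", 0.059, min_age_days=_MIN_1M, indication_icd="J06",
          labelled_event_terms=("RASH", "DIARRHOEA", "URTICARIA", "FEVER")),
        d("OXACILLIN", "J01CF04", 0.057, min_age_days=0, on_monitoring_list=True,
          indication_icd="A49", labelled_event_terms=("RASH", "FEVER", "PHLEBITIS")),
        d("AMPICILLIN", "J01CA01", 0.050, min_age_days=0,
          labelled_event_terms=("RASH", "DIARRHOEA", "URTICARIA")),
        d("IMIPENEM/CILASTATIN", "J01DH51", 0.045, min_age_days=_MIN_3Y,
          on_monitoring_list=True, indication_icd="J15",
          labelled_event_terms=("VOMITING", "SEIZURE", "PHLEBITIS", "RASH")),
        d("AMPHOTERICIN B", "J02AA01", 0.040, min_age_days=_MIN_1M, indication_icd="B37",
          labelled_event_terms=("FEVER", "VOMITING", "PHLEBITIS")),
        d("MEROPENEM", "J01DH02", 0.040, min_age_days=_MIN_3M, indication_icd="A41",
          labelled_event_terms=("RASH", "DIARRHOEA", "SEIZURE")),
        d("BENZYLPENICILLIN", "J01CE01", 0.035, min_age_days=_MIN_1M,
          labelled_event_terms=("RASH", "URTICARIA", "ANAPHYLACTIC REACTION")),
        d("METRONIDAZOLE", "J01XD01", 0.027, min_age_days=0, indication_icd="A06",
          labelled_event_terms=("VOMITING", "DIARRHOEA")),
        d("CASPOFUNGIN", "J02AX04", 0.025, min_age_days=_MIN_1Y, on_monitoring_list=True,
          indication_icd="B44", labelled_event_terms=("FEVER", "RASH", "PHLEBITIS")),
        # N - nervous system (0.172)
        d("DIPYRONE", "N02BB02", 0.060, min_age_days=_MIN_1Y, indication_icd="R50",
          labelled_event_terms=("RASH", "URTICARIA", "ANAPHYLACTIC REACTION")),
        d("PARACETAMOL", "N02BE01", 0.045, min_age_days=_MIN_3M, indication_icd="R50",
          labelled_event_terms=("RASH",)),
        d("MIDAZOLAM", "N05CD08", 0.042, min_age_days=_MIN_18Y,
          labelled_event_terms=("APNOEA", "BRADYCARDIA")),
        d("PHENYTOIN", "N03AB02", 0.025, min_age_days=0, indication_icd="G40",
          labelled_event_terms=("NYSTAGMUS", "RASH")),
        # L - antineoplastic and immunomodulating agents (0.100)
        d("METHOTREXATE", "L01BA01", 0.045, min_age_days=_MIN_3Y, indication_icd="C91",
          labelled_event_terms=("VOMITING", "DIARRHOEA", "THROMBOCYTOPENIA")),
        d("CICLOSPORIN", "L04AD01", 0.030, min_age_days=_MIN_1Y, on_monitoring_list=True,
          labelled_event_terms=("VOMITING", "RASH")),
        d("RITUXIMAB", "L01XC02", 0.020, min_age_days=_MIN_18Y, indication_icd="C85",
          labelled_event_terms=("FEVER", "URTICARIA")),
        d("CLOFARABINE", "L01BB06", 0.005, licensed=False, on_monitoring_list=True,
          indication_icd="C91"),
        # A - alimentary tract and metabolism (0.069)
        d("METOCLOPRAMIDE", "A03FA01", 0.025, min_age_days=_MIN_18Y, on_monitoring_list=True,
          indication_icd="R11", labelled_event_terms=("DIARRHOEA",)),
        d("OMEPRAZOLE", "A02BC01", 0.020, min_age_days=_MIN_5Y, indication_icd="K21",
          labelled_event_terms=("DIARRHOEA", "VOMITING")),
        d("LARONIDASE", "A16AB05", 0.012, min_age_days=0, on_monitoring_list=True,
          indication_icd="E76", labelled_event_terms=("FEVER", "URTICARIA", "RASH")),
        d("MIGLUSTAT", "A16AX06", 0.012, min_age_days=_MIN_18Y, on_monitoring_list=True,
          indication_icd="E75", labelled_event_terms=("DIARRHOEA", "VOMITING")),
        # B - blood and blood-forming organs (0.045)
        d("HEPARIN", "B01AB01", 0.030, min_age_days=_MIN_1Y, indication_icd="I82",
          labelled_event_terms=("THROMBOCYTOPENIA", "PETECHIAE")),
        d("FACTOR VIII", "B02BD02", 0.015, min_age_days=0, indication_icd="D66",
          labelled_event_terms=("URTICARIA", "FEVER")),
        # remaining main groups
        d("HYDROCORTISONE", "H02AB09", 0.025, min_age_days=_MIN_1Y,
          labelled_event_terms=("RASH",)),
        d("FUROSEMIDE", "C03CA01", 0.024, min_age_days=_MIN_1Y, indication_icd="I50",
          labelled_event_terms=("HYPOKALAEMIA",)),
        d("IBUPROFEN", "M01AE01", 0.023, min_age_days=_MIN_2Y, indication_icd="R50",
          labelled_event_terms=("VOMITING", "RASH")),
        d("SALBUTAMOL", "R03AC02", 0.021, min_age_days=_MIN_2Y, indication_icd="J45",
          labelled_event_terms=("RASH",)),
        d("TROPICAMIDE", "S01FA06", 0.019, min_age_days=_MIN_6Y, on_monitoring_list=True,
          indication_icd="H52", labelled_event_terms=("BLURRED VISION",)),
        d("IOHEXOL", "V08AB02", 0.017, min_age_days=0,
          labelled_event_terms=("URTICARIA", "VOMITING", "RASH")),
        d("ALBENDAZOLE", "P02CA03", 0.010, min_age_days=_MIN_2Y, indication_icd="B76",
          labelled_event_terms=("VOMITING", "DIARRHOEA")),
        d("SILVER SULFADIAZINE", "D06BA01", 0.004, min_age_days=_MIN_2M,
          indication_icd="T30", labelled_event_terms=("RASH", "PRURITUS")),
        d("OXYBUTYNIN", "G04BD04", 0.001, min_age_days=_MIN_5Y, indication_icd="N39",
          labelled_event_terms=("BLURRED VISION",)),
    ]


def _default_event_catalog() -> list[EventSpec]:
    e = EventSpec
    return [
        e("FEVER", "General disorders", 0.09),
        e("RASH", "Skin and appendages", 0.12),
        e("URTICARIA", "Skin and appendages", 0.06),
        e("PRURITUS", "Skin and appendages", 0.05),
        e("VOMITING", "Gastro-intestinal system", 0.08),
        e("DIARRHOEA", "Gastro-intestinal system", 0.05),
        e("PHLEBITIS", "Vascular", 0.05),
        e("RED MAN SYNDROME", "Skin and appendages", 0.02),
        e("ANAPHYLACTIC REACTION", "General disorders", 0.02, is_ime=True),
        e("SEIZURE", "Central nervous system", 0.012, is_ime=True),
        e("PNEUMONIA", "Respiratory system", 0.02, is_ime=True),
        e("RESPIRATORY INSUFFICIENCY", "Respiratory system", 0.012, is_ime=True),
        e("DYSPNOEA", "Respiratory system", 0.02, is_ime=True),
        e("APNOEA", "Respiratory system", 0.006, is_ime=True),
        e("COUGH", "Respiratory system", 0.02, is_ime=True),
        e("HYPOKALAEMIA", "Metabolic and nutritional", 0.018, is_ime=True),
        e("NYSTAGMUS", "Central nervous system", 0.004, is_ime=True),
        e("PSYCHOSIS", "Psychiatric", 0.004, is_ime=True),
        e("BLURRED VISION", "Vision", 0.005, is_ime=True),
        e("ASTHENIA", "General disorders", 0.02, is_ime=True),
        e("BRADYCARDIA", "Cardiovascular", 0.01, is_ime=True),
        e("PERSISTENT CRYING", "General disorders", 0.003, is_ime=True),
        e("PETECHIAE", "Platelet and bleeding", 0.012, is_ime=True),
        e("THROMBOCYTOPENIA", "Platelet and bleeding", 0.015, is_ime=True),
    ]


def _default_injected_signals() -> list[InjectedSignal]:
    s = InjectedSignal
    return [
        s("IMIPENEM/CILASTATIN", "PNEUMONIA", 40.0),
        s("LARONIDASE", "RESPIRATORY INSUFFICIENCY", 30.0),
        s("CICLOSPORIN", "NYSTAGMUS", 45.0),
        s("CICLOSPORIN", "BLURRED VISION", 60.0),
        s("CICLOSPORIN", "PSYCHOSIS", 15.0),
        s("METOCLOPRAMIDE", "PSYCHOSIS", 15.0),
        s("TROPICAMIDE", "APNOEA", 70.0),
        s("TROPICAMIDE", "PERSISTENT CRYING", 80.0),
        s("AMPHOTERICIN B", "HYPOKALAEMIA", 50.0),
        s("OXACILLIN", "COUGH", 3.0),
        s("VANCOMYCIN", "PETECHIAE", 3.5),
    ]


def default_notivisa_like_config(seed: int) -> SimulationConfig:
    """Default configuration emulating the 2008-2013 pediatric extract.

    1977 serious reports; drugs-per-report distribution with mean 1.1275
    (expected drug-entry count ~2229); age-group marginals proportional to
    (542, 345, 281, 267, 542); seriousness marginals proportional to
    (75, 216, 263, 3, 27, 1393); 1% missing gender; 9.6% indeterminate
    route/form.
    """
    config = SimulationConfig(
        n_reports=1977,
        drug_catalog=_default_drug_catalog(),
        event_catalog=_default_event_catalog(),
        injected_signals=_default_injected_signals(),
        n_drugs_distribution=(0.895, 0.09, 0.01, 0.003, 0.0015, 0.0005),
        age_group_probabilities=tuple(
            np.array([542, 345, 281, 267, 542]) / 1977.0
        ),
        p_gender_missing=0.01,
        p_route_indeterminate=0.096,
        seriousness_probabilities=tuple(
            np.array([75, 216, 263, 3, 27, 1393]) / 1977.0
        ),
        seed=seed,
    )
    config.validate()
    return config


def registry_from_config(config: SimulationConfig) -> dict[str, LabelRecord]:
    """The label registry matching the generator's catalog."""
    records = []
    for spec in config.drug_catalog:
        records.append(
            LabelRecord(
                drug_name=spec.name,
                licensed=spec.licensed,
                min_age_days=spec.min_age_days if spec.licensed else None,
                max_age_days=spec.max_age_days if spec.licensed else None,
                labelled_event_terms=frozenset(spec.labelled_event_terms),
            )
        )
    return build_registry(r for r in records if r.licensed)


def monitoring_list_from_config(config: SimulationConfig) -> set[str]:
    return {
        normalize_name(d.name) for d in config.drug_catalog if d.on_monitoring_list
    }


def ime_list_from_config(config: SimulationConfig) -> set[str]:
    return {normalize_name(e.term) for e in config.event_catalog if e.is_ime}


def write_ground_truth(truth: GroundTruth, path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {
            "drug_name": normalize_name(s.drug_name),
            "event_term": normalize_name(s.event_term),
            "lambda": s.odds_multiplier,
        }
        for s in truth.injected_signals
    ]
    pd.DataFrame(rows, columns=["drug_name", "event_term", "lambda"]).to_csv(
        path, index=False
    )
    return path


# ---------------------------------------------------------------------------
# Config file round trip (YAML mirroring the dataclass field names)


def config_to_dict(config: SimulationConfig) -> dict:
    out = dataclasses.asdict(config)
    out["n_drugs_distribution"] = list(config.n_drugs_distribution)
    out["age_group_probabilities"] = [float(p) for p in config.age_group_probabilities]
    out["seriousness_probabilities"] = [
        float(p) for p in config.seriousness_probabilities
    ]
    out["reporter_origin_probabilities"] = list(config.reporter_origin_probabilities)
    for drug in out["drug_catalog"]:
        drug["labelled_event_terms"] = list(drug["labelled_event_terms"])
    return out


def config_from_dict(data: dict) -> SimulationConfig:
    data = dict(data)
    data["drug_catalog"] = [
        DrugSpec(**{**d, "labelled_event_terms": tuple(d.get("labelled_event_terms", ()))})
        for d in data["drug_catalog"]
    ]
    data["event_catalog"] = [EventSpec(**e) for e in data["event_catalog"]]
    data["injected_signals"] = [
        InjectedSignal(**s) for s in data.get("injected_signals", [])
    ]
    for key in (
        "n_drugs_distribution",
        "age_group_probabilities",
        "seriousness_probabilities",
        "reporter_origin_probabilities",
    ):
        if key in data:
            data[key] = tuple(data[key])
    config = SimulationConfig(**data)
    config.validate()
    return config


def save_config(config: SimulationConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False))
    return path


def load_config(path: str | Path) -> SimulationConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()))
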