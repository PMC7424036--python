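import datetime as dt

import pytest
from hypothesis import settings

from pedpv import disproportionality as dis
from pedpv import synthetic_data as sd
from pedpv.icsr_model import CaseReport, DrugEntry, EventEntry

settings.register_profile("ci", derandomize=True, max_examples=60)
settings.load_profile("ci")


def two_drug_config(seed, lam=1.0, n_reports=20000):
    """One drug of interest at per-report marginal 0.3 against a filler drug;
    the event of interest at background 0.05 among common filler events (so
    that the 'every report reports something' resampling rarely touches it)."""
    return sd.SimulationConfig(
        n_reports=n_reports,
        drug_catalog=[
            sd.DrugSpec("TARGETDRUG", "J01XX01", 0.3),
            sd.DrugSpec("OTHERDRUG", "N02XX01", 0.7),
        ],
        event_catalog=[
            sd.EventSpec("TARGETEVENT", "General disorders", 0.05, is_ime=True)
        ]
        + [sd.EventSpec(f"FILLER{i}", "General disorders", 0.6) for i in range(5)],
        injected_signals=(
            [sd.InjectedSignal("TARGETDRUG", "TARGETEVENT", lam)] if lam != 1.0 else []
        ),
        n_drugs_distribution=(1.0, 0, 0, 0, 0, 0),
        age_group_probabilities=(0.2, 0.2, 0.2, 0.2, 0.2),
        seriousness_probabilities=(1 / 6,) * 6,
        seed=seed,
    )


def pair_result(reports, drug="TARGETDRUG", event="TARGETEVENT"):
    table = dis.build_contingency(reports, drug, event)
    return dis.score_pair(drug, event, table)


def make_case(
    case_id,
    drugs,
    events,
    seriousness="medically_important",
    age_days=400,
    gender="female",
    **kwargs,
):
    """Terse constructor for hand-built fixtures: drugs/events as name lists."""
    return CaseReport(
        case_id=case_id,
        seriousness=seriousness,
        gender=gender,
        age_days=age_days,
        drugs=[d if isinstance(d, DrugEntry) else DrugEntry(d) for d in drugs],
        events=[e if isinstance(e, EventEntry) else EventEntry(e) for e in events],
        **kwargs,
    )


@pytest.fixture
def ten_cases():
    """Ten hand-built cases spanning the schema's optional fields."""
    cases = [
        make_case(
            "C01",
            [DrugEntry("Vancomycin", atc_level5="J01XA01", pharm_form="tablet", route="oral", indication_icd="A41")],
            [EventEntry("rash", soc="Skin and appendages")],
            seriousness="death",
            gender="male",
            birth_date=dt.date(2009, 5, 2),
            event_date=dt.date(2010, 6, 1),
            age_days=395,
        ),
        make_case("C02", ["CEFTRIAXONE", "OXACILLIN"], ["FEVER", "RASH"],
                  seriousness="life_threatening", age_days=50),
        make_case("C03", ["imipenem/cilastatin"], ["PNEUMONIA"],
                  seriousness="death", age_days=3000),
        make_case("C04", ["DIPYRONE"], ["URTICARIA"],
                  seriousness="prolonged_hospitalization", gender="missing",
                  reporter_origin="hospital", age_days=1200),
        make_case("C05", ["LARONIDASE"], ["RESPIRATORY INSUFFICIENCY", "FEVER"],
                  seriousness="death", age_days=2000),
        make_case("C06", ["MIDAZOLAM"], ["APNOEA"],
                  seriousness="persistent_disability", age_days=100),
        make_case("C07", ["VANCOMYCIN", "HEPARIN"], ["PETECHIAE"],
                  seriousness="medically_important", age_days=4000),
        make_case("C08", ["TROPICAMIDE"], ["BLURRED VISION"],
                  seriousness="congenital_abnormality", age_days=10),
        make_case("C09", ["METOCLOPRAMIDE"], ["PSYCHOSIS"],
                  seriousness="not_serious", age_days=3500,
                  birth_date=dt.date(2000, 1, 1), event_date=dt.date(2009, 8, 1)),
        make_case("C10", ["OXACILLIN"], ["COUGH"],
                  seriousness="medically_important", age_days=900,
                  reporter_origin="other"),
    ]
    return cases
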