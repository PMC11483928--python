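import datetime as dt

import pandas as pd
import pytest

from gpp_journey.catalog import load_catalog
from gpp_journey.config import StudyConfig
from gpp_journey.model import ClaimsBundle

WINDOW = (dt.date(2016, 1, 1), dt.date(2021, 8, 31))


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture(scope="session")
def config():
    return StudyConfig(study_window=WINDOW)


def make_bundle(patients, diagnoses, prescriptions, window=WINDOW) -> ClaimsBundle:
    """Assemble a bundle from plain tuples.

    patients: (patient_id, sex, birth_year, death_date-or-None)
    diagnoses: (patient_id, code, iso_date, confirmed)
    prescriptions: (patient_id, drug_code, iso_date, days_supply-or-None)
    """
    pt = pd.DataFrame(patients, columns=["patient_id", "sex", "birth_year", "death_date"])
    pt["death_date"] = pd.to_datetime(pt["death_date"])
    dx = pd.DataFrame(diagnoses, columns=["patient_id", "code", "date", "confirmed"])
    dx["date"] = pd.to_datetime(dx["date"])
    dx["confirmed"] = dx["confirmed"].astype(bool)
    rx = pd.DataFrame(prescriptions, columns=["patient_id", "drug_code", "date", "days_supply"])
    rx["date"] = pd.to_datetime(rx["date"])
    rx["days_supply"] = rx["days_supply"].astype("Int64")
    return ClaimsBundle(pt, dx, rx, window)


@pytest.fixture()
def small_bundle():
    """Three patients, seven prescriptions; referentially consistent."""
    return make_bundle(
        patients=[
            ("A", "female", 1970, None),
            ("B", "male", 1950, "2018-06-01"),
            ("C", "female", 1990, None),
        ],
        diagnoses=[
            ("A", "L40.1", "2017-03-01", True),
            ("A", "L40.1", "2017-06-01", True),
            ("B", "L40.1", "2016-05-01", True),
            ("B", "L40.1", "2016-05-20", True),
            ("C", "L40.0", "2018-01-01", True),
        ],
        prescriptions=[
            ("A", "etretinate", "2017-03-01", 30),
            ("A", "etretinate", "2017-04-01", 30),
            ("A", "secukinumab", "2017-08-01", 28),
            ("B", "cyclosporin", "2016-05-01", 30),
            ("B", "cyclosporin", "2016-06-01", 30),
            ("B", "topical_corticosteroid", "2016-05-01", 30),
            ("C", "antihistamine", "2018-01-05", None),
        ],
    )
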