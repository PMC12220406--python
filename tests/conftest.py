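import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def toy_facilities() -> pd.DataFrame:
    """Two regions, five obstetric facilities plus one non-obstetric."""
    return pd.DataFrame(
        {
            "facility_id": ["A1", "A2", "A3", "B1", "B2", "X1"],
            "name": [f"Facility {i}" for i in range(6)],
            "level": ["I", "II", "RPC", "I", "RPC", "I"],
            "system": ["S1", "S1", "S2", "S2", "S2", "S3"],
            "dpr": ["RA", "RA", "RA", "RB", "RB", "RA"],
            "is_obstetric": [True, True, True, True, True, False],
        }
    )


@pytest.fixture
def toy_counties() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "county_id": ["C1", "C2", "C3"],
            "rucc": [1, 5, 9],
            "dpr": ["RA", "RA", "RB"],
        }
    )


def make_records(rows: list[dict]) -> pd.DataFrame:
    """Build a minimal delivery table; unspecified covariates get defaults."""
    defaults = {
        "maternal_age": 28.0,
        "race": "White",
        "ethnicity": "NonHispanic",
        "education": "SomeCollegeOrHigher",
        "payor": "Commercial",
        "apncu": "Adequate",
        "tobacco": "No",
        "n_medical_risk_factors": "0",
        "preterm": "No",
        "plurality": "1",
        "fetal_presentation": "Cephalic",
        "delivery_method": "Vaginal",
        "infant_transfer": "No",
        "nicu_abnormal": "No",
        "wic": "No",
        "steroid_lung_maturation": "No",
        "maternal_transfusion": "No",
        "county_of_residence": "C1",
        "transported": False,
        "origin_facility": pd.NA,
        "destination_facility": "A1",
    }
    out = []
    for i, row in enumerate(rows):
        rec = {"record_id": f"D{i + 1:04d}", **defaults, **row}
        out.append(rec)
    df = pd.DataFrame(out, columns=["record_id", *defaults])
    for col in ("origin_facility", "destination_facility"):
        df[col] = df[col].astype("string")
    return df


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20250924)
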