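import numpy as np
import pandas as pd
import pytest


def make_claims(rows):
    """Build a claims frame from (patient, provider, date, type, dx_list,
    procedure, payer) tuples."""
    records = []
    for pat, prov, date, ctype, dxs, proc, payer in rows:
        rec = {
            "patient_id": pat,
            "provider_id": prov,
            "service_date": pd.Timestamp(date),
            "claim_type": ctype,
            "dx1": dxs[0] if len(dxs) > 0 else "",
            "dx2": dxs[1] if len(dxs) > 1 else "",
            "procedure_code": proc,
            "payer": payer,
        }
        records.append(rec)
    return pd.DataFrame(records)


def make_visits(entries):
    """Visit frame from (patient, provider, date) triples."""
    df = pd.DataFrame(entries, columns=["patient_id", "provider_id", "date"])
    df["date"] = pd.to_datetime(df["date"])
    df["year"] = df["date"].dt.year
    return df


@pytest.fixture
def rng():
    return np.random.default_rng(20160101)


@pytest.fixture
def providers_table():
    return pd.DataFrame({
        "provider_id": ["A", "B", "C", "D", "E"],
        "taxonomy_code": ["207R00000X", "2084P0800X", "103T00000X",
                          "1041C0700X", "207Q00000X"],
        "specialty_group": ["pcp", "psychiatrist", "psychologist",
                            "bh_specialist", "pcp"],
    })
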