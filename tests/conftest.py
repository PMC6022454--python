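from __future__ import annotations

from datetime import date, timedelta

import pandas as pd
import pytest

from painclaims.claims import SCHEMAS
from painclaims.synthetic import SimConfig, simulate


def medical_frame(rows):
    """rows: (person_id, service_date, codes, payer)"""
    return pd.DataFrame(rows, columns=SCHEMAS["medical"])


def pharmacy_frame(rows):
    """rows: (person_id, fill_date, drug_id, days_supply, payer)"""
    return pd.DataFrame(rows, columns=SCHEMAS["pharmacy"])


def fills_from_days(person_id, year, day_fills):
    """Build a pharmacy frame from (drug, start_day, days_supply) triples
    with 1-based day-of-year offsets (values outside the year allowed)."""
    jan1 = date(year, 1, 1)
    return pharmacy_frame([
        (person_id, jan1 + timedelta(days=d - 1), drug, ds, "private")
        for drug, d, ds in day_fills
    ])


@pytest.fixture(scope="session")
def small_sim():
    """A modest seeded synthetic dataset shared across tests."""
    cfg = SimConfig(n_persons=1500, seed=11)
    persons, census, medical, pharmacy, truth = simulate(cfg)
    return {"config": cfg, "persons": persons, "census": census,
            "medical": medical, "pharmacy": pharmacy, "truth": truth}
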