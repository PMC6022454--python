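"""Seeded synthetic all-payer-claims populations with planted case status.

The generator emulates the structure of a multi-year, insured state
population observed through medical and pharmacy claims: age/sex/county
marginals drawn from the 2010 Maine census profile, per-claim public/private
payer assignment (income- and age-linked by default), and — crucially —
*planted* chronic-pain case status per person-year, so that every
downstream stage can be validated against known truth.

Planted patterns satisfy the identification criteria by construction:

* ``icd_only``  — one highly-likely (338.xx) diagnosis, or two likely-code
  diagnoses at least 30 days apart, and no 90-day opioid run;
* ``opioid_only`` — a chain of opioid fills giving >= 90 consecutive covered
  days within the year, and no qualifying diagnosis pattern;
* ``both``      — both of the above.

Non-cases receive mandatory near-miss noise at configurable rates (single
likely diagnosis; likely pairs 1-29 days apart; opioid runs of 60-89 days;
excluded headache-family codes only) so the temporal boundaries of the
rules are always exercised.  Truth labels are exact under the default
(union overlap, zero grace gap, year-clipped) policy.
"""

from __future__ import annotations

from calendar import isleap
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .claims import SCHEMAS, ValidationError, write_claims

__all__ = ["SimConfig", "generate_population", "generate_claims", "simulate"]

# 2010-census-like demographic profile (shares; covariates per county:
# median household income $, % below poverty, % bachelor's or higher).
MAINE_COUNTY_PROFILE: dict[str, tuple[float, float, float, float]] = {
    "Androscoggin": (107.7, 44470, 14.2, 18.4),
    "Aroostook":    (71.9, 36574, 19.1, 15.2),
    "Cumberland":   (281.7, 56365, 11.5, 38.7),
    "Franklin":     (30.8, 41377, 15.3, 23.2),
    "Hancock":      (54.4, 47533, 13.4, 30.5),
    "Kennebec":     (122.2, 45973, 13.7, 26.0),
    "Knox":         (39.7, 45264, 13.0, 30.6),
    "Lincoln":      (34.5, 48087, 11.4, 30.1),
    "Oxford":       (57.8, 40661, 16.2, 18.8),
    "Penobscot":    (153.9, 42658, 16.8, 24.5),
    "Piscataquis":  (17.5, 34016, 19.4, 15.5),
    "Sagadahoc":    (35.3, 55486, 9.6, 30.0),
    "Somerset":     (52.2, 36647, 19.5, 14.9),
    "Waldo":        (38.8, 41312, 16.9, 26.3),
    "Washington":   (32.9, 34859, 20.0, 18.6),
    "York":         (197.1, 55008, 10.2, 29.8),
}

AGE_BANDS = ["<5"] + [f"{a}-{a + 4}" for a in range(5, 85, 5)] + ["85+"]

_AGE_BAND_WEIGHTS = {
    "<5": 5.2, "5-9": 5.5, "10-14": 5.9, "15-19": 6.5, "20-24": 5.6,
    "25-29": 5.4, "30-34": 5.3, "35-39": 5.9, "40-44": 6.9, "45-49": 8.0,
    "50-54": 8.3, "55-59": 7.7, "60-64": 6.9, "65-69": 5.2, "70-74": 4.0,
    "75-79": 3.1, "80-84": 2.4, "85+": 2.2,
}

_HIGHLY_CODES = ["338.0", "338.11", "338.19", "338.21", "338.29", "338.4"]
_LIKELY_CODES = ["724.2", "722.10", "723.1", "729.1", "719.41", "715.90", "354.0", "353.0"]
_EXCLUDED_CODES = ["346.90", "784.0", "307.81", "350.2"]
_BENIGN_CODES = ["401.9", "460", "786.2", "V70.0", "477.9"]
_OPIOID_DRUGS = ["oxycodone", "hydrocodone-acetaminophen", "morphine", "tramadol"]
_BENIGN_DRUGS = ["lisinopril", "metformin", "atorvastatin", "omeprazole"]


@dataclass
class SimConfig:
    """Configuration of one synthetic claims simulation.

    Defaults reproduce the study conditions: a planted person-year
    prevalence of 33% (female) / 26% (male), about 29.5% overall, and a
    case-route mix of 84% diagnosis-only, 13% both, 3% opioid-only.
    """

    n_persons: int = 2000
    years: tuple[int, ...] = (2010,)
    seed: int = 0

    county_marginals: dict[str, float] | None = None      # None -> Maine profile
    sex_marginals: dict[str, float] = field(
        default_factory=lambda: {"female": 0.511, "male": 0.489})
    age_band_marginals: dict[str, float] | None = None     # None -> Maine profile

    prevalence_target: float | dict[str, float] = field(
        default_factory=lambda: {"female": 0.33, "male": 0.26})
    mix_icd_only: float = 0.84
    mix_both: float = 0.13
    mix_opioid_only: float = 0.03

    payer_public_prob: float | None = None  # None -> income/age-linked per county

    # mandatory near-miss noise rates among non-case person-years
    noise_single_likely: float = 0.15
    noise_near_pair: float = 0.10
    noise_short_opioid: float = 0.05
    noise_excluded_only: float = 0.05

    benign_medical_rate: float = 1.2
    benign_pharmacy_rate: float = 0.4
    overlapping_fills: bool = False  # plant early-refill overlaps (stockpile exercise)

    def __post_init__(self) -> None:
        if self.n_persons < 0:
            raise ValidationError("n_persons must be >= 0")
        if not self.years:
            raise ValidationError("at least one simulation year is required")
        mix = self.mix_icd_only + self.mix_both + self.mix_opioid_only
        if abs(mix - 1.0) > 1e-9:
            raise ValidationError(f"case-route mix must sum to 1, got {mix}")
        for name in ("mix_icd_only", "mix_both", "mix_opioid_only",
                     "noise_single_likely", "noise_near_pair",
                     "noise_short_opioid", "noise_excluded_only"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        for sex, p in self.prevalence_by_sex.items():
            if not 0.0 <= p < 1.0:
                raise ValidationError(f"prevalence for {sex} must be in [0, 1), got {p}")
        if self.county_marginals is not None and not self.county_marginals:
            raise ValidationError("county_marginals must be non-empty")
        if self.age_band_marginals is not None and not self.age_band_marginals:
            raise ValidationError("age_band_marginals must be non-empty")

    @property
    def prevalence_by_sex(self) -> dict[str, float]:
        if isinstance(self.prevalence_target, dict):
            return dict(self.prevalence_target)
        return {s: float(self.prevalence_target) for s in self.sex_marginals}

    @property
    def census_year(self) -> int:
        """Reference year for ages and census denominators (latest sim year)."""
        return max(self.years)


def _normalized(d: dict[str, float]) -> tuple[list[str], np.ndarray]:
    keys = list(d)
    w = np.asarray([d[k] for k in keys], dtype=float)
    if w.sum() <= 0:
        raise ValidationError("marginal weights must have positive mass")
    return keys, w / w.sum()


def _band_age_range(band: str) -> tuple[int, int]:
    if band == "<5":
        return 0, 4
    if band.endswith("+"):
        return int(band[:-1]), int(band[:-1]) + 14
    lo, hi = band.split("-")
    return int(lo), int(hi)


def generate_population(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw persons i.i.d. from the marginal tables and emit a census table.

    The census table holds the *realized* counts per (county, sex, age band)
    stratum — not the target marginals — so that prevalence denominators
    are exactly self-consistent with the generated population.  County
    socioeconomic covariates are attached to every stratum row.
    """
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([config.seed, 0])))
    county_m = config.county_marginals or {
        c: p[0] for c, p in MAINE_COUNTY_PROFILE.items()}
    covars = {c: p[1:] for c, p in MAINE_COUNTY_PROFILE.items()}
    for c in county_m:
        covars.setdefault(c, (45000.0, 14.0, 25.0))
    counties, cw = _normalized(county_m)
    sexes, sw = _normalized(config.sex_marginals)
    bands, bw = _normalized(config.age_band_marginals or _AGE_BAND_WEIGHTS)

    n = config.n_persons
    county_ix = rng.choice(len(counties), size=n, p=cw)
    sex_ix = rng.choice(len(sexes), size=n, p=sw)
    band_ix = rng.choice(len(bands), size=n, p=bw)
    ages = np.empty(n, dtype=int)
    for i, b in enumerate(band_ix):
        lo, hi = _band_age_range(bands[b])
        ages[i] = rng.integers(lo, hi + 1)

    persons = pd.DataFrame({
        "person_id": [f"P{i:07d}" for i in range(n)],
        "sex": [sexes[i] for i in sex_ix],
        "birth_year": config.census_year - ages,
        "county": [counties[i] for i in county_ix],
    })

    if n:
        band_of = pd.Series([bands[i] for i in band_ix], name="age_band")
        strata = (
            pd.DataFrame({"county": persons["county"], "sex": persons["sex"],
                          "age_band": band_of})
            .groupby(["county", "sex", "age_band"], sort=True)
            .size().rename("population").reset_index()
        )
    else:
        strata = pd.DataFrame(columns=["county", "sex", "age_band", "population"])
    strata["median_income"] = [covars[c][0] for c in strata["county"]]
    strata["pct_poverty"] = [covars[c][1] for c in strata["county"]]
    strata["pct_bachelors"] = [covars[c][2] for c in strata["county"]]
    return persons, strata[SCHEMAS["census"]]


def _public_prob(config: SimConfig, county: str, age: int) -> float:
    if config.payer_public_prob is not None:
        return float(config.payer_public_prob)
    if age >= 65:
        return 0.92  # Medicare-age
    income = MAINE_COUNTY_PROFILE.get(county, (0, 45000.0))[1]
    lo, hi = 34000.0, 57000.0
    return float(np.clip(0.30 + 0.35 * (hi - income) / (hi - lo), 0.05, 0.95))


def generate_claims(
    persons: pd.DataFrame, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate medical claims, pharmacy claims and truth labels.

    Every planted pattern is wholly contained in its calendar year, so the
    labels are exact under the default year-clipping policy; likely-code
    noise for any person-year spans strictly fewer than 30 days and opioid
    noise runs are 60-89 days, so no noise pattern can qualify.
    """
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([config.seed, 1])))
    prev = config.prevalence_by_sex
    routes = ["icd_only", "both", "opioid_only"]
    route_p = np.array([config.mix_icd_only, config.mix_both, config.mix_opioid_only])

    med_rows: list[tuple] = []
    ph_rows: list[tuple] = []
    truth_rows: list[tuple] = []

    for r in persons.itertuples():
        for year in config.years:
            n_days = 366 if isleap(year) else 365
            y0 = date(year, 1, 1)
            age = year - int(r.birth_year)
            p_pub = _public_prob(config, r.county, age)

            def payer() -> str:
                return "public" if rng.random() < p_pub else "private"

            def day(d: int) -> date:
                return y0 + timedelta(days=int(d) - 1)

            is_case = rng.random() < prev.get(r.sex, 0.0)
            route = routes[rng.choice(3, p=route_p)] if is_case else "none"
            truth_rows.append((r.person_id, year, is_case, route))

            # --- qualifying diagnosis pattern -------------------------------
            if route in ("icd_only", "both"):
                if rng.random() < 0.5:
                    code = _HIGHLY_CODES[rng.integers(len(_HIGHLY_CODES))]
                    med_rows.append((r.person_id, day(rng.integers(1, n_days + 1)),
                                     code, payer()))
                else:
                    code = _LIKELY_CODES[rng.integers(len(_LIKELY_CODES))]
                    d1 = int(rng.integers(1, n_days - 30 + 1))
                    d2 = int(rng.integers(d1 + 30, n_days + 1))
                    med_rows.append((r.person_id, day(d1), code, payer()))
                    med_rows.append((r.person_id, day(d2), code, payer()))

            # --- qualifying opioid run --------------------------------------
            if route in ("opioid_only", "both"):
                run = int(rng.integers(90, 141))
                start = int(rng.integers(1, n_days - run + 2))
                drug = _OPIOID_DRUGS[rng.integers(len(_OPIOID_DRUGS))]
                ph_rows.extend(_plant_run(r.person_id, day(start), run, drug,
                                          payer, rng, config.overlapping_fills))

            # --- near-miss noise --------------------------------------------
            if is_case:
                # cases on the diagnosis route get sub-threshold opioid noise
                if route == "icd_only" and rng.random() < config.noise_short_opioid:
                    ph_rows.extend(_short_run(r.person_id, n_days, day, payer, rng))
                # opioid-route cases may carry a lone likely diagnosis
                if route == "opioid_only" and rng.random() < config.noise_single_likely:
                    code = _LIKELY_CODES[rng.integers(len(_LIKELY_CODES))]
                    med_rows.append((r.person_id, day(rng.integers(1, n_days + 1)),
                                     code, payer()))
            else:
                u = rng.random()
                if u < config.noise_single_likely:
                    code = _LIKELY_CODES[rng.integers(len(_LIKELY_CODES))]
                    med_rows.append((r.person_id, day(rng.integers(1, n_days + 1)),
                                     code, payer()))
                elif u < config.noise_single_likely + config.noise_near_pair:
                    code = _LIKELY_CODES[rng.integers(len(_LIKELY_CODES))]
                    gap = int(rng.integers(1, 30))  # 1-29 days: below threshold
                    d1 = int(rng.integers(1, n_days - gap + 1))
                    med_rows.append((r.person_id, day(d1), code, payer()))
                    med_rows.append((r.person_id, day(d1 + gap), code, payer()))
                elif u < (config.noise_single_likely + config.noise_near_pair
                          + config.noise_excluded_only):
                    code = _EXCLUDED_CODES[rng.integers(len(_EXCLUDED_CODES))]
                    for _ in range(int(rng.integers(1, 3))):
                        med_rows.append((r.person_id, day(rng.integers(1, n_days + 1)),
                                         code, payer()))
                if rng.random() < config.noise_short_opioid:
                    ph_rows.extend(_short_run(r.person_id, n_days, day, payer, rng))

            # --- benign background ------------------------------------------
            for _ in range(rng.poisson(config.benign_medical_rate)):
                code = _BENIGN_CODES[rng.integers(len(_BENIGN_CODES))]
                med_rows.append((r.person_id, day(rng.integers(1, n_days + 1)),
                                 code, payer()))
            for _ in range(rng.poisson(config.benign_pharmacy_rate)):
                drug = _BENIGN_DRUGS[rng.integers(len(_BENIGN_DRUGS))]
                ds = int(rng.choice([30, 90]))
                d0 = int(rng.integers(1, max(n_days - ds, 1) + 1))
                ph_rows.append((r.person_id, day(d0), drug, ds, payer()))

    medical = pd.DataFrame(med_rows, columns=SCHEMAS["medical"])
    pharmacy = pd.DataFrame(ph_rows, columns=SCHEMAS["pharmacy"])
    truth = pd.DataFrame(truth_rows, columns=SCHEMAS["truth"])
    return medical, pharmacy, truth


def _plant_run(pid, start: date, run: int, drug: str, payer, rng,
               overlapping: bool) -> list[tuple]:
    """Fills covering exactly [start, start+run-1] under the union policy.

    With ``overlapping`` each refill arrives 7 days early (extending the
    final supply so the union span is unchanged), exercising the stockpile
    policy without altering the planted truth under union.
    """
    rows = []
    if overlapping:
        step, ds = 23, 30
        pos = 0
        while pos + ds < run:
            rows.append((pid, start + timedelta(days=pos), drug, ds, payer()))
            pos += step
        rows.append((pid, start + timedelta(days=pos), drug, run - pos, payer()))
    else:
        pos = 0
        while pos < run:
            ds = int(min(30, run - pos))
            rows.append((pid, start + timedelta(days=pos), drug, ds, payer()))
            pos += ds
    return rows


def _short_run(pid, n_days: int, day, payer, rng) -> list[tuple]:
    """A 60-89-day opioid run, below the 90-day threshold by construction."""
    run = int(rng.integers(60, 90))
    start = int(rng.integers(1, n_days - run + 2))
    drug = _OPIOID_DRUGS[rng.integers(len(_OPIOID_DRUGS))]
    return _plant_run(pid, day(start), run, drug, payer, rng, False)


def simulate(config: SimConfig, out_dir: str | Path | None = None):
    """Run the full simulation; optionally write the five interchange CSVs.

    Returns ``(persons, census, medical, pharmacy, truth)`` DataFrames.
    Bit-reproducible for identical configs (including seed).
    """
    persons, census = generate_population(config)
    medical, pharmacy, truth = generate_claims(persons, config)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_claims(persons, out / "persons.csv", "person")
        write_claims(census, out / "census.csv", "census")
        write_claims(medical, out / "medical_claims.csv", "medical")
        write_claims(pharmacy, out / "pharmacy_claims.csv", "pharmacy")
        write_claims(truth, out / "truth.csv", "truth")
    return persons, census, medical, pharmacy, truth
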