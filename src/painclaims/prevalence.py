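"""Census-denominated stratified prevalence and payer attribution.

Prevalence is the identified cohort count in a stratum divided by the
census population of the same stratum, as a percentage.  Age is computed
as analysis year minus birth year (claims extracts rarely carry full dates
of birth) and banded in five-year increments (<5, 5-9, ..., 80-84, 85+).
Person-level insurance is attributed by majority payer type over the
person-year's claims, ties going to public.

Note that with real all-payer claims the numerator (insured persons
observed in claims) and a whole-population census denominator are not the
same universe; prevalence can exceed plausible bounds in strata (e.g. the
elderly) where the mismatch is largest.  The synthetic generator emits
denominators from the realized population, making the two consistent.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .claims import ValidationError

__all__ = [
    "assign_age_band",
    "assign_insurance",
    "attribute_insurance",
    "compute_prevalence",
    "insurance_split",
]

STRATA_FIELDS = ("year", "sex", "age_band", "county")


def assign_age_band(age: int) -> str:
    """Map an age in years to its five-year band label (<5 ... 85+)."""
    if age < 0:
        raise ValidationError(f"age must be non-negative, got {age}")
    if age < 5:
        return "<5"
    if age >= 85:
        return "85+"
    lo = (age // 5) * 5
    return f"{lo}-{lo + 4}"


def assign_insurance(person_year_claims: pd.DataFrame) -> str:
    """Person-year insurance label: payer type of the majority of claims.

    *person_year_claims* is any frame with a ``payer_type`` column covering
    one person-year (medical and pharmacy rows may be concatenated).
    Ties go to public.
    """
    if not len(person_year_claims):
        raise ValidationError("cannot attribute insurance with zero claims")
    counts = person_year_claims["payer_type"].value_counts()
    n_pub = int(counts.get("public", 0))
    n_priv = int(counts.get("private", 0))
    return "public" if n_pub >= n_priv else "private"


def attribute_insurance(
    cohort: pd.DataFrame, medical: pd.DataFrame, pharmacy: pd.DataFrame
) -> pd.DataFrame:
    """Vectorized majority-payer attribution for every cohort person-year.

    Returns the cohort frame with an ``insurance`` column.  Cohort rows
    whose person-year has no claims at all cannot occur (cohort membership
    requires claims), but are guarded with a contract error.
    """
    pieces = []
    if len(medical):
        pieces.append(pd.DataFrame({
            "person_id": medical["person_id"].astype(str),
            "year": [d.year for d in medical["service_date"]],
            "payer_type": medical["payer_type"],
        }))
    if len(pharmacy):
        pieces.append(pd.DataFrame({
            "person_id": pharmacy["person_id"].astype(str),
            "year": [d.year for d in pharmacy["fill_date"]],
            "payer_type": pharmacy["payer_type"],
        }))
    if pieces:
        allc = pd.concat(pieces, ignore_index=True)
        tab = (allc.groupby(["person_id", "year"])["payer_type"]
               .agg(lambda s: "public" if (s == "public").sum() >= (s == "private").sum()
                    else "private"))
    else:
        tab = pd.Series(dtype=object)
    out = cohort.copy()
    keys = list(zip(out["person_id"].astype(str), out["year"]))
    out["insurance"] = [tab.get(k) for k in keys]
    if out["insurance"].isna().any():
        missing = out.loc[out["insurance"].isna(), ["person_id", "year"]].iloc[0]
        raise ValidationError(
            f"no claims found for cohort person-year {tuple(missing)}"
        )
    return out


def _with_strata(cohort: pd.DataFrame, persons: pd.DataFrame | None) -> pd.DataFrame:
    out = cohort.copy()
    if persons is not None and ("sex" not in out.columns or "age_band" not in out.columns
                                or "county" not in out.columns):
        out = out.merge(
            persons[["person_id", "sex", "birth_year", "county"]],
            on="person_id", how="left", validate="many_to_one",
        )
        out["age_band"] = [
            assign_age_band(int(y) - int(b)) if pd.notna(b) else None
            for y, b in zip(out["year"], out["birth_year"])
        ]
    return out


def compute_prevalence(
    cohort: pd.DataFrame,
    census: pd.DataFrame,
    strata_spec: Sequence[str] = (),
    persons: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Stratified prevalence table: cases, population and prevalence %.

    Parameters
    ----------
    cohort
        Cohort records (``classification != 'none'`` rows are counted; an
        ``excluded_only`` row is not a case).  Must carry, or be joinable
        (via *persons*) to, the demographic fields named in *strata_spec*.
    census
        Stratified denominators (county x sex x age_band rows).  For the
        ``year`` stratum the full census population is used as denominator
        for every year.
    strata_spec
        Subset of ``{"year", "sex", "age_band", "county"}``.  Empty means
        the overall row only; otherwise one row per realized stratum plus
        an overall row labelled ``overall``.

    Returns a frame with the stratum columns, ``cases``, ``population``
    and ``prevalence_pct`` (= 100 * cases / population, full precision).
    """
    strata = list(strata_spec)
    bad = [s for s in strata if s not in STRATA_FIELDS]
    if bad:
        raise ValueError(f"unknown strata {bad}; choose from {STRATA_FIELDS}")
    cases = _with_strata(cohort[cohort["classification"] != "none"], persons)

    total_pop = int(census["population"].sum())

    def _denominator(key: dict) -> int:
        sub = census
        for s, v in key.items():
            sub = sub[sub[s] == v]
        return int(sub["population"].sum())

    rows = []
    if strata:
        for key_vals, grp in cases.groupby(strata, sort=True):
            if not isinstance(key_vals, tuple):
                key_vals = (key_vals,)
            key = dict(zip(strata, key_vals))
            denom_key = {s: v for s, v in key.items() if s != "year"}
            pop = _denominator(denom_key)
            if pop == 0:
                raise ValidationError(
                    f"cohort stratum {key} missing from census denominators")
            rows.append({**key, "cases": len(grp), "population": pop,
                         "prevalence_pct": 100.0 * len(grp) / pop})
    overall = {s: "overall" for s in strata}
    rows.append({**overall, "cases": len(cases), "population": total_pop,
                 "prevalence_pct": (100.0 * len(cases) / total_pop) if total_pop
                 else float("nan")})
    return pd.DataFrame(rows, columns=[*strata, "cases", "population", "prevalence_pct"])


def insurance_split(
    cohort_with_insurance: pd.DataFrame,
    by: str = "overall",
) -> pd.DataFrame:
    """Public vs private percentage split of the cohort.

    *by* is ``overall``, ``county``, ``sex`` or ``year``; grouped splits
    carry one row per group.  Percentages are of the group's cohort size
    and sum to 100 within rounding.
    """
    df = cohort_with_insurance
    if "insurance" not in df.columns:
        raise ValidationError("cohort must carry an 'insurance' column "
                              "(see attribute_insurance)")
    df = df[df["classification"] != "none"]

    def _split(grp: pd.DataFrame) -> dict:
        n = len(grp)
        n_pub = int((grp["insurance"] == "public").sum())
        return {"n": n,
                "public_pct": 100.0 * n_pub / n if n else float("nan"),
                "private_pct": 100.0 * (n - n_pub) / n if n else float("nan")}

    if by == "overall":
        return pd.DataFrame([{"group": "overall", **_split(df)}])
    if by not in df.columns:
        raise ValueError(f"cannot split by {by!r}: column absent")
    rows = [{"group": g, **_split(grp)} for g, grp in df.groupby(by, sort=True)]
    return pd.DataFrame(rows)
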