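"""Two-criterion chronic-pain case identification per person per calendar year.

A person-year enters the cohort if either

1. the diagnosis criterion holds — at least one claim bearing a
   highly-likely chronic-pain code (the 338.xx family, cancer pain 338.3x
   carved out), or claims bearing likely codes on two service dates at
   least ``min_separation_days`` apart within the year; or
2. the opioid criterion holds — dispensed opioid coverage (fill date +
   days' supply, closed intervals) forms a run of at least
   ``min_consecutive_days`` consecutive days within the calendar year.

Person-years carrying only headache / facial-pain / cancer-pain codes and
no include pattern are flagged ``excluded_only`` and are not cohort members
unless the opioid criterion holds independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Literal, Sequence

import pandas as pd

from .claims import CodeConfig, OpioidList, ValidationError, match_icd9

__all__ = [
    "FinderPolicy",
    "ExposureTimeline",
    "evaluate_diagnosis_criterion",
    "build_exposure_timeline",
    "evaluate_opioid_criterion",
    "identify_cohort",
    "criterion_breakdown",
]

Classification = Literal["icd_only", "opioid_only", "both", "none"]


@dataclass(frozen=True)
class FinderPolicy:
    """Tunable thresholds and policies of the identification rule.

    Parameters
    ----------
    min_separation_days
        Minimum separation (``>=``, in days) between two service dates with
        likely codes.  Default 30.
    min_consecutive_days
        Minimum length of a continuous opioid coverage run. Default 90.
    grace_gap_days
        Maximum uncovered gap still merged into one continuous run.
        Default 0 (strict "consecutive"); real dispensing often warrants a
        few days.
    overlap_policy
        ``union``: overlapping fills waste the overlap (conservative).
        ``stockpile``: an early same-drug refill is shifted to start the day
        after the prior fill's coverage ends.
    clip_to_year
        If True (default) coverage runs are clipped to the calendar year
        before the run-length test — a run straddling New Year qualifies in
        neither year unless 90 days fall within one of them.
    """

    min_separation_days: int = 30
    min_consecutive_days: int = 90
    grace_gap_days: int = 0
    overlap_policy: Literal["union", "stockpile"] = "union"
    clip_to_year: bool = True

    def __post_init__(self) -> None:
        if self.min_separation_days <= 0 or self.min_consecutive_days <= 0:
            raise ValidationError("durations must be positive")
        if self.grace_gap_days < 0:
            raise ValidationError("grace_gap_days must be >= 0")
        if self.overlap_policy not in ("union", "stockpile"):
            raise ValidationError(f"unknown overlap policy {self.overlap_policy!r}")


@dataclass
class ExposureTimeline:
    """Merged opioid-coverage intervals for one person-year.

    ``covered_intervals`` are sorted, disjoint, closed date intervals after
    overlap-policy application, grace-gap merging and (by default) clipping
    to the calendar year; ``max_consecutive_days`` is the length of the
    longest interval.
    """

    person_id: str
    year: int
    covered_intervals: list[tuple[date, date]] = field(default_factory=list)
    max_consecutive_days: int = 0


def evaluate_diagnosis_criterion(
    claims: pd.DataFrame,
    config: CodeConfig | None = None,
    policy: FinderPolicy | None = None,
) -> tuple[bool, list[str], bool]:
    """Evaluate the ICD-9 diagnosis criterion on one person-year of claims.

    Returns ``(icd_flag, evidence, excluded_only_flag)``.  ``icd_flag`` is
    True iff at least one claim bears a highly-likely code, or likely codes
    appear on two service dates separated by at least
    ``policy.min_separation_days`` (max minus min likely-code date, which is
    equivalent to the best pair).  ``excluded_only_flag`` marks person-years
    with headache/facial-pain/cancer-pain codes and no include pattern.
    """
    config = config or CodeConfig()
    policy = policy or FinderPolicy()
    if len(claims) and claims["person_id"].nunique() > 1:
        raise ValidationError("claims span multiple persons")
    years = {d.year for d in claims["service_date"]} if len(claims) else set()
    if len(years) > 1:
        raise ValidationError("claims span multiple calendar years")

    evidence: list[str] = []
    likely_dates: set[date] = set()
    has_highly = False
    has_excluded = False
    for _, row in claims.iterrows():
        codes = [c.strip() for c in str(row["icd9_codes"]).split(";") if c.strip()]
        for code, cls in zip(codes, (match_icd9(c, config) for c in codes)):
            if cls == "highly_likely":
                has_highly = True
                evidence.append(f"{row['service_date'].isoformat()}:{code.strip()}")
            elif cls == "likely":
                likely_dates.add(row["service_date"])
                evidence.append(f"{row['service_date'].isoformat()}:{code.strip()}")
            elif cls in ("excluded_headache", "cancer_pain"):
                has_excluded = True

    pair_ok = False
    if len(likely_dates) >= 2:
        span = (max(likely_dates) - min(likely_dates)).days
        pair_ok = span >= policy.min_separation_days
    icd_flag = has_highly or pair_ok
    excluded_only = has_excluded and not icd_flag
    if not icd_flag:
        evidence = []
    return icd_flag, evidence, excluded_only


def _merge(intervals: list[tuple[date, date]], grace: int) -> list[tuple[date, date]]:
    """Union of closed intervals, merging gaps of at most *grace* days."""
    if not intervals:
        return []
    intervals = sorted(intervals)
    out = [intervals[0]]
    for s, e in intervals[1:]:
        ps, pe = out[-1]
        if (s - pe).days <= 1 + grace:
            out[-1] = (ps, max(pe, e))
        else:
            out.append((s, e))
    return out


def build_exposure_timeline(
    fills: pd.DataFrame,
    opioids: OpioidList | None = None,
    policy: FinderPolicy | None = None,
    year: int | None = None,
) -> ExposureTimeline:
    """Construct the merged opioid-coverage timeline for one person-year.

    Fills outside *year* are admitted (a December fill may cover January
    days) but coverage is clipped to the year before the longest-run
    computation unless ``policy.clip_to_year`` is False, in which case a
    run merely has to intersect the year and counts its full length.
    Non-opioid fills are ignored.
    """
    opioids = opioids or OpioidList()
    policy = policy or FinderPolicy()
    if len(fills) and fills["person_id"].nunique() > 1:
        raise ValidationError("fills span multiple persons")
    person_id = str(fills["person_id"].iloc[0]) if len(fills) else ""
    if year is None:
        if not len(fills):
            raise ValidationError("year is required when no fills are given")
        year = fills["fill_date"].iloc[0].year

    raw: list[tuple[str, date, int]] = [
        (str(r.drug_id), r.fill_date, int(r.days_supply))
        for r in fills.itertuples()
        if str(r.drug_id) in opioids
    ]
    intervals: list[tuple[date, date]] = []
    if policy.overlap_policy == "stockpile":
        # early same-drug refills start the day after prior coverage ends
        by_drug: dict[str, list[tuple[date, int]]] = {}
        for drug, d, ds in raw:
            by_drug.setdefault(drug, []).append((d, ds))
        for drug, lst in by_drug.items():
            prev_end: date | None = None
            for d, ds in sorted(lst):
                start = d if prev_end is None else max(d, prev_end + timedelta(days=1))
                end = start + timedelta(days=ds - 1)
                intervals.append((start, end))
                prev_end = end
    else:
        intervals = [(d, d + timedelta(days=ds - 1)) for _, d, ds in raw]

    merged = _merge(intervals, policy.grace_gap_days)

    y0, y1 = date(year, 1, 1), date(year, 12, 31)
    covered: list[tuple[date, date]] = []
    max_days = 0
    for s, e in merged:
        if e < y0 or s > y1:
            continue
        if policy.clip_to_year:
            cs, ce = max(s, y0), min(e, y1)
        else:
            cs, ce = s, e
        covered.append((cs, ce))
        max_days = max(max_days, (ce - cs).days + 1)
    return ExposureTimeline(person_id, year, covered, max_days)


def evaluate_opioid_criterion(
    timeline: ExposureTimeline, policy: FinderPolicy | None = None
) -> bool:
    """True iff the longest coverage run reaches the consecutive-day threshold."""
    policy = policy or FinderPolicy()
    return timeline.max_consecutive_days >= policy.min_consecutive_days


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

def _code_class_series(codes: pd.Series, config: CodeConfig) -> pd.DataFrame:
    """Explode semicolon-joined code strings into (row index, code, class)."""
    exploded = codes.str.split(";").explode().str.strip()
    exploded = exploded[exploded != ""]
    uniq = {c: match_icd9(c, config) for c in exploded.unique()}
    return pd.DataFrame({"code": exploded, "cls": exploded.map(uniq)})


def identify_cohort(
    medical: pd.DataFrame,
    pharmacy: pd.DataFrame,
    persons: pd.DataFrame | None = None,
    config: CodeConfig | None = None,
    opioids: OpioidList | None = None,
    policy: FinderPolicy | None = None,
    years: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Apply both identification criteria to every person-year.

    Returns a cohort table (schema ``cohort``) with one row per person-year
    where the classification is not ``none`` or where only excluded
    (headache/facial/cancer-pain) diagnoses were found
    (``excluded_only_flag``).  A person counts once per year no matter how
    many qualifying patterns exist; ``classification`` is ``both`` when
    both criteria hold.  Persons appearing only in pharmacy claims are
    still evaluated for the opioid criterion.
    """
    config = config or CodeConfig()
    opioids = opioids or OpioidList()
    policy = policy or FinderPolicy()
    if persons is not None and persons["person_id"].duplicated().any():
        raise ValidationError("duplicate person_id in persons table")

    if years is None:
        ys: set[int] = set()
        if len(medical):
            ys |= {d.year for d in medical["service_date"]}
        if len(pharmacy):
            ys |= {d.year for d in pharmacy["fill_date"]}
        years = sorted(ys)

    # --- diagnosis criterion, vectorized over all person-years -----------
    diag: dict[tuple[str, int], dict] = {}
    if len(medical):
        med = medical.reset_index(drop=True)
        cc = _code_class_series(med["icd9_codes"], config)
        cc["person_id"] = med["person_id"].reindex(cc.index).astype(str)
        cc["service_date"] = med["service_date"].reindex(cc.index)
        cc["year"] = [d.year for d in cc["service_date"]]
        cc = cc[cc["year"].isin(set(years))]

        likely = cc[cc["cls"] == "likely"]
        highly = cc[cc["cls"] == "highly_likely"]
        excl = cc[cc["cls"].isin(["excluded_headache", "cancer_pain"])]

        for (pid, yr), grp in highly.groupby(["person_id", "year"], sort=False):
            d = diag.setdefault((pid, yr), {})
            d["highly"] = True
            d.setdefault("evidence", []).extend(
                f"{r.service_date.isoformat()}:{r.code}" for r in grp.itertuples()
            )
        for (pid, yr), grp in likely.groupby(["person_id", "year"], sort=False):
            dates = grp["service_date"]
            span = (dates.max() - dates.min()).days
            if span >= policy.min_separation_days:
                d = diag.setdefault((pid, yr), {})
                d["pair"] = True
                dedup = grp.drop_duplicates(subset=["service_date", "code"])
                d.setdefault("evidence", []).extend(
                    f"{r.service_date.isoformat()}:{r.code}" for r in dedup.itertuples()
                )
        for (pid, yr) in excl.groupby(["person_id", "year"], sort=False).groups:
            diag.setdefault((pid, yr), {})["excluded"] = True

    # --- opioid criterion, per person with any opioid fill ----------------
    op: dict[tuple[str, int], ExposureTimeline] = {}
    if len(pharmacy):
        ph = pharmacy[[d in opioids for d in pharmacy["drug_id"].astype(str)]]
        for pid, grp in ph.groupby("person_id", sort=False):
            fill_years = {d.year for d in grp["fill_date"]}
            # a fill can only cover days in its own or the following year(s)
            candidate_years = set()
            for fy in fill_years:
                for r in grp[[d.year == fy for d in grp["fill_date"]]].itertuples():
                    end = r.fill_date + timedelta(days=int(r.days_supply) - 1)
                    candidate_years.update(range(fy, end.year + 1))
            for yr in sorted(candidate_years & set(years)):
                tl = build_exposure_timeline(grp, opioids, policy, yr)
                if evaluate_opioid_criterion(tl, policy):
                    op[(str(pid), yr)] = tl

    # --- assemble ---------------------------------------------------------
    rows = []
    for key in sorted(set(diag) | set(op)):
        pid, yr = key
        d = diag.get(key, {})
        icd_flag = bool(d.get("highly") or d.get("pair"))
        opioid_flag = key in op
        excluded_only = bool(d.get("excluded")) and not icd_flag
        if icd_flag and opioid_flag:
            cls = "both"
        elif icd_flag:
            cls = "icd_only"
        elif opioid_flag:
            cls = "opioid_only"
        else:
            cls = "none"
        if cls == "none" and not excluded_only:
            continue
        ev = sorted(set(d.get("evidence", []))) if icd_flag else []
        if opioid_flag:
            tl = op[key]
            ev.append(
                "opioid:" + ",".join(f"{s.isoformat()}..{e.isoformat()}"
                                     for s, e in tl.covered_intervals)
            )
        rows.append({
            "person_id": pid, "year": yr, "icd_flag": icd_flag,
            "opioid_flag": opioid_flag, "classification": cls,
            "excluded_only_flag": excluded_only, "evidence": ";".join(ev),
        })
    cols = ["person_id", "year", "icd_flag", "opioid_flag",
            "classification", "excluded_only_flag", "evidence"]
    return pd.DataFrame(rows, columns=cols)


def criterion_breakdown(records: pd.DataFrame, year: int) -> dict:
    """Count and percentage breakdown of identification routes for one year.

    Returns a dict with counts for ``icd_only`` / ``both`` / ``opioid_only``
    (disjoint, summing to the cohort size), the opioid-criterion total
    (``both + opioid_only``), and the matching percentages of cohort size.
    Percentages are ``None`` (absent) for an empty cohort.
    """
    sub = records[(records["year"] == year) & (records["classification"] != "none")]
    n = len(sub)
    counts = {
        k: int((sub["classification"] == k).sum())
        for k in ("icd_only", "both", "opioid_only")
    }
    out: dict = {"year": year, "cohort_size": n, **counts,
                 "opioid_criterion_total": counts["both"] + counts["opioid_only"]}
    if n:
        out["pct"] = {k: 100.0 * counts[k] / n for k in counts}
        out["pct"]["opioid_criterion_total"] = 100.0 * out["opioid_criterion_total"] / n
    else:
        out["pct"] = None
    return out
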