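"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the interval arithmetic of the package: coverage
is evaluated on an explicit boolean day grid, and the diagnosis criterion
by naive all-pairs date scanning, so that agreement is meaningful.
"""

from __future__ import annotations

from datetime import date

import numpy as np

from painclaims.claims import CodeConfig, OpioidList, match_icd9

PAD = 1000  # grid days kept on each side of the calendar year


def grid_max_run(
    fills: list[tuple[str, int, int]],
    year_days: int = 365,
    grace: int = 0,
    policy: str = "union",
    clip: bool = True,
) -> int:
    """Longest covered run (days) via an explicit boolean day grid.

    *fills* are (drug_id, start_day, days_supply) with start_day 1-based
    relative to Jan 1 of the target year (values outside [1, year_days]
    allowed).  Mirrors the full policy pipeline: overlap handling, grace-gap
    filling, then clipping to the year.
    """
    grid = np.zeros(year_days + 2 * PAD, dtype=bool)  # index = day + PAD - 1

    def mark(start: int, n: int) -> None:
        lo = max(start + PAD - 1, 0)
        hi = min(start + n + PAD - 1, len(grid))
        if hi > lo:
            grid[lo:hi] = True

    if policy == "stockpile":
        by_drug: dict[str, list[tuple[int, int]]] = {}
        for drug, s, ds in fills:
            by_drug.setdefault(drug, []).append((s, ds))
        for drug, lst in by_drug.items():
            prev_end = None
            for s, ds in sorted(lst):
                start = s if prev_end is None else max(s, prev_end + 1)
                mark(start, ds)
                prev_end = start + ds - 1
    else:
        for _, s, ds in fills:
            mark(s, ds)

    # grace: fill uncovered gaps of <= grace days between covered days
    if grace > 0:
        covered = np.flatnonzero(grid)
        for a, b in zip(covered[:-1], covered[1:]):
            if 1 < b - a <= grace + 1:
                grid[a:b] = True

    # maximal covered runs as [start, end) index pairs
    padded = np.concatenate([[False], grid, [False]])
    d = np.diff(padded.astype(int))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    y_lo, y_hi = PAD, PAD + year_days  # year window, [lo, hi); day d -> index d+PAD-1
    best = 0
    for s, e in zip(starts, ends):
        if e <= y_lo or s >= y_hi:
            continue
        length = (min(e, y_hi) - max(s, y_lo)) if clip else (e - s)
        best = max(best, int(length))
    return best


def naive_icd_flag(
    claims: list[tuple[date, str]],
    config: CodeConfig | None = None,
    min_sep: int = 30,
) -> tuple[bool, bool]:
    """(icd_flag, excluded_only_flag) by exhaustive scanning.

    *claims* are (service_date, code) pairs for one person-year.
    """
    config = config or CodeConfig()
    classes = [(d, match_icd9(c, config)) for d, c in claims]
    if any(cls == "highly_likely" for _, cls in classes):
        icd = True
    else:
        likely_dates = [d for d, cls in classes if cls == "likely"]
        icd = any(
            abs((a - b).days) >= min_sep
            for i, a in enumerate(likely_dates)
            for b in likely_dates[i + 1:]
        )
    has_excl = any(cls in ("excluded_headache", "cancer_pain") for _, cls in classes)
    return icd, has_excl and not icd


def naive_person_year_labels(medical, pharmacy, config=None, opioids=None):
    """Re-derive (person_id, year) -> classification by brute force.

    Day-grid opioid evaluation (union policy, no grace, year-clipped) and
    all-pairs diagnosis scanning; used to cross-validate planted truth.
    """
    from calendar import isleap

    config = config or CodeConfig()
    opioids = opioids or OpioidList()
    diag: dict[tuple[str, int], list[tuple[date, str]]] = {}
    for r in medical.itertuples():
        key = (str(r.person_id), r.service_date.year)
        for c in str(r.icd9_codes).split(";"):
            if c.strip():
                diag.setdefault(key, []).append((r.service_date, c.strip()))

    fills_by_person: dict[str, list[tuple[str, date, int]]] = {}
    years: set[int] = set()
    for r in pharmacy.itertuples():
        if str(r.drug_id) in opioids:
            fills_by_person.setdefault(str(r.person_id), []).append(
                (str(r.drug_id), r.fill_date, int(r.days_supply)))
        years.add(r.fill_date.year)
    years |= {y for _, y in diag}

    labels: dict[tuple[str, int], str] = {}
    for year in sorted(years):
        n_days = 366 if isleap(year) else 365
        jan1 = date(year, 1, 1)
        for pid, fills in fills_by_person.items():
            rel = [(d, (fd - jan1).days + 1, ds) for d, fd, ds in fills]
            if grid_max_run(rel, year_days=n_days) >= 90:
                labels[(pid, year)] = "opioid_only"
    for key, claims in diag.items():
        if key[1] not in years:
            continue
        icd, _ = naive_icd_flag(claims, config)
        if icd:
            labels[key] = "both" if labels.get(key) == "opioid_only" else "icd_only"
    return labels
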