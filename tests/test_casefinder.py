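"""Case-finding rules: diagnosis criterion, exposure timelines, cohort assembly."""

from __future__ import annotations

from datetime import date

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from painclaims.casefinder import (
    FinderPolicy,
    build_exposure_timeline,
    criterion_breakdown,
    evaluate_diagnosis_criterion,
    evaluate_opioid_criterion,
    identify_cohort,
)
from painclaims.claims import ValidationError, validate_table

from _oracles import grid_max_run
from conftest import fills_from_days, medical_frame, pharmacy_frame


def _med(rows):
    return validate_table(medical_frame(rows), "medical")


class TestDiagnosisCriterion:
    @pytest.mark.parametrize("rows,icd,excl", [
        # one highly-likely (338.xx) claim suffices
        ([("P1", "2010-06-15", "338.29", "public")], True, False),
        # likely pair 25 days apart: below the 30-day separation
        ([("P1", "2010-01-10", "724.2", "public"),
          ("P1", "2010-02-04", "724.2", "public")], False, False),
        # likely pair exactly 30 days apart: boundary of "at least 30 days"
        ([("P1", "2010-01-10", "724.2", "public"),
          ("P1", "2010-02-09", "723.1", "public")], True, False),
        # migraine codes only, 60 days apart: excluded-only
        ([("P1", "2010-01-10", "346.90", "public"),
          ("P1", "2010-03-11", "346.90", "public")], False, True),
        # cancer pain 338.3x does not trigger the highly-likely rule
        ([("P1", "2010-06-15", "338.30", "public")], False, True),
        # an include pattern beats the exclusion
        ([("P1", "2010-06-15", "338.29;346.90", "public")], True, False),
        # same-day likely codes: one distinct date, no pair
        ([("P1", "2010-06-15", "724.2;723.1", "public")], False, False),
    ])
    def test_rule_outcomes(self, rows, icd, excl):
        flag, evidence, excluded = evaluate_diagnosis_criterion(_med(rows))
        assert flag is icd
        assert excluded is excl
        assert bool(evidence) is icd

    def test_best_pair_across_three_dates(self):
        # closest pairs are < 30 apart but the extremes span 40 days
        rows = [("P1", f"2010-01-{d:02d}", "724.2", "public") for d in (1, 21)]
        rows.append(("P1", "2010-02-10", "724.2", "public"))
        flag, _, _ = evaluate_diagnosis_criterion(_med(rows))
        assert flag

    def test_multi_person_claims_rejected(self):
        rows = [("P1", "2010-01-01", "724.2", "public"),
                ("P2", "2010-02-05", "724.2", "public")]
        with pytest.raises(ValidationError):
            evaluate_diagnosis_criterion(_med(rows))

    def test_raising_separation_never_flips_false_to_true(self):
        rows = [("P1", "2010-01-10", "724.2", "public"),
                ("P1", "2010-03-01", "724.2", "public")]
        flags = [evaluate_diagnosis_criterion(
            _med(rows), policy=FinderPolicy(min_separation_days=s))[0]
            for s in (10, 30, 50, 51, 120)]
        # monotone non-increasing in the separation threshold
        assert flags == sorted(flags, reverse=True)


class TestExposureTimeline:
    def test_no_fills_gives_zero(self):
        tl = build_exposure_timeline(pharmacy_frame([]), year=2010)
        assert tl.max_consecutive_days == 0
        assert not evaluate_opioid_criterion(tl)

    @pytest.mark.parametrize("day_fills,expected", [
        # three back-to-back 30-day fills: one 90-day run
        ([("oxycodone", 1, 30), ("oxycodone", 31, 30), ("oxycodone", 61, 30)], 90),
        # one-day gap at day 31 splits the run
        ([("oxycodone", 1, 30), ("oxycodone", 32, 30)], 30),
        # overlap under union policy wastes the overlap
        ([("oxycodone", 1, 30), ("oxycodone", 15, 30)], 44),
    ])
    def test_union_examples(self, day_fills, expected):
        fills = fills_from_days("P1", 2010, day_fills)
        tl = build_exposure_timeline(fills, year=2010)
        assert tl.max_consecutive_days == expected
        assert tl.max_consecutive_days == grid_max_run(day_fills)

    def test_stockpile_shifts_early_refill(self):
        day_fills = [("oxycodone", 1, 30), ("oxycodone", 15, 30)]
        fills = fills_from_days("P1", 2010, day_fills)
        pol = FinderPolicy(overlap_policy="stockpile")
        tl = build_exposure_timeline(fills, policy=pol, year=2010)
        assert tl.max_consecutive_days == 60
        assert tl.covered_intervals == [(date(2010, 1, 1), date(2010, 3, 1))]

    def test_stockpile_is_per_drug(self):
        # different drugs overlap freely; no shifting between them
        day_fills = [("oxycodone", 1, 30), ("tramadol", 15, 30)]
        fills = fills_from_days("P1", 2010, day_fills)
        pol = FinderPolicy(overlap_policy="stockpile")
        tl = build_exposure_timeline(fills, policy=pol, year=2010)
        assert tl.max_consecutive_days == 44

    def test_grace_gap_merges_small_gaps(self):
        day_fills = [("oxycodone", 1, 30), ("oxycodone", 34, 30)]  # 3-day gap
        fills = fills_from_days("P1", 2010, day_fills)
        assert build_exposure_timeline(fills, year=2010).max_consecutive_days == 30
        pol = FinderPolicy(grace_gap_days=3)
        assert build_exposure_timeline(fills, policy=pol, year=2010) \
            .max_consecutive_days == 63

    def test_prior_year_fill_covers_january(self):
        day_fills = [("oxycodone", -19, 30)]  # Dec 12 2009, 30 days' supply
        fills = fills_from_days("P1", 2010, day_fills)
        tl = build_exposure_timeline(fills, year=2010)
        assert tl.covered_intervals == [(date(2010, 1, 1), date(2010, 1, 10))]
        assert tl.max_consecutive_days == 10

    def test_new_year_run_clipped_vs_unclipped(self):
        # 50 days in December + 50 in January: qualifies in neither year
        # under clipping, but counts 100 days when unclipped
        day_fills = [("oxycodone", -49, 100)]
        fills = fills_from_days("P1", 2010, day_fills)
        assert build_exposure_timeline(fills, year=2010).max_consecutive_days == 50
        assert build_exposure_timeline(fills, year=2009).max_consecutive_days == 50
        pol = FinderPolicy(clip_to_year=False)
        assert build_exposure_timeline(fills, policy=pol, year=2010) \
            .max_consecutive_days == 100

    def test_non_opioid_fills_ignored(self):
        fills = fills_from_days("P1", 2010, [("lisinopril", 1, 200)])
        assert build_exposure_timeline(fills, year=2010).max_consecutive_days == 0

    @pytest.mark.parametrize("max_days,expected", [(89, False), (90, True), (365, True)])
    def test_opioid_criterion_boundary(self, max_days, expected):
        fills = fills_from_days("P1", 2010, [("oxycodone", 1, max_days)])
        tl = build_exposure_timeline(fills, year=2010)
        assert evaluate_opioid_criterion(tl) is expected

    @given(
        fills=st.lists(
            st.tuples(st.sampled_from(["oxycodone", "tramadol"]),
                      st.integers(-120, 400), st.integers(1, 120)),
            min_size=0, max_size=40),
        grace=st.integers(0, 7),
        policy=st.sampled_from(["union", "stockpile"]),
        clip=st.booleans(),
    )
    @settings(max_examples=250, deadline=None)
    def test_equals_day_grid_oracle(self, fills, grace, policy, clip):
        frame = fills_from_days("P1", 2010, fills)
        pol = FinderPolicy(grace_gap_days=grace, overlap_policy=policy,
                           clip_to_year=clip)
        tl = build_exposure_timeline(frame, policy=pol, year=2010)
        assert tl.max_consecutive_days == grid_max_run(
            fills, year_days=365, grace=grace, policy=policy, clip=clip)

    @given(
        fills=st.lists(st.tuples(st.just("oxycodone"),
                                 st.integers(1, 330), st.integers(1, 60)),
                       min_size=1, max_size=15),
        extra=st.tuples(st.just("oxycodone"), st.integers(1, 330), st.integers(1, 60)),
    )
    @settings(max_examples=100, deadline=None)
    def test_adding_a_fill_never_decreases_coverage(self, fills, extra):
        before = build_exposure_timeline(
            fills_from_days("P1", 2010, fills), year=2010).max_consecutive_days
        after = build_exposure_timeline(
            fills_from_days("P1", 2010, fills + [extra]), year=2010).max_consecutive_days
        assert after >= before


class TestIdentifyCohort:
    def _cohort(self, med_rows, ph_rows, **kw):
        return identify_cohort(_med(med_rows) if med_rows else medical_frame([]),
                               validate_table(pharmacy_frame(ph_rows), "pharmacy")
                               if ph_rows else pharmacy_frame([]), **kw)

    def test_both_criteria_give_one_record_classified_both(self):
        med = [("P1", "2010-03-01", "338.29", "public")]
        ph = [("P1", "2010-05-01", "oxycodone", 90, "public")]
        out = self._cohort(med, ph)
        assert len(out) == 1
        rec = out.iloc[0]
        assert (rec["classification"], rec["icd_flag"], rec["opioid_flag"]) == \
               ("both", True, True)

    def test_yearly_cohorts_are_separate_records(self):
        med = [("P1", "2009-03-01", "338.29", "public"),
               ("P1", "2010-04-01", "338.29", "public")]
        out = self._cohort(med, [])
        assert sorted(out["year"]) == [2009, 2010]
        assert set(out["classification"]) == {"icd_only"}

    def test_pharmacy_only_person_is_evaluable(self):
        ph = [("P9", "2010-02-01", "oxycodone", 120, "private")]
        out = self._cohort([], ph)
        assert list(out["classification"]) == ["opioid_only"]

    def test_excluded_only_person_year_flagged_not_member(self):
        med = [("P1", "2010-01-10", "346.90", "public"),
               ("P1", "2010-04-10", "346.90", "public")]
        out = self._cohort(med, [])
        assert len(out) == 1
        rec = out.iloc[0]
        assert rec["classification"] == "none"
        assert rec["excluded_only_flag"]

    def test_opioid_criterion_overrides_excluded_diagnoses(self):
        med = [("P1", "2010-01-10", "346.90", "public")]
        ph = [("P1", "2010-02-01", "oxycodone", 100, "public")]
        out = self._cohort(med, ph)
        rec = out.iloc[0]
        assert rec["classification"] == "opioid_only"

    def test_december_fill_can_qualify_next_year(self):
        ph = [("P1", "2009-12-01", "oxycodone", 150, "private")]
        out = self._cohort([], ph, years=[2010])
        # 119 covered days fall in 2010 (Jan 1 .. Apr 29)
        assert list(out["year"]) == [2010]
        assert list(out["classification"]) == ["opioid_only"]

    def test_duplicate_persons_table_rejected(self):
        persons = pd.DataFrame({"person_id": ["P1", "P1"],
                                "sex": ["female", "female"],
                                "birth_year": [1950, 1950],
                                "county": ["York", "York"]})
        with pytest.raises(ValidationError):
            self._cohort([("P1", "2010-01-01", "338.29", "public")], [],
                         persons=persons)


class TestCriterionBreakdown:
    def _records(self, icd_only, both, opioid_only, year=2010):
        rows = (["icd_only"] * icd_only + ["both"] * both
                + ["opioid_only"] * opioid_only)
        return pd.DataFrame({
            "person_id": [f"P{i}" for i in range(len(rows))],
            "year": year, "classification": rows,
        })

    def test_percentages_of_cohort_size(self):
        b = criterion_breakdown(self._records(100, 14, 3), 2010)
        assert (b["cohort_size"], b["opioid_criterion_total"]) == (117, 17)
        assert round(b["pct"]["icd_only"], 1) == 85.5
        assert round(b["pct"]["both"], 1) == 12.0
        assert round(b["pct"]["opioid_only"], 1) == 2.6

    def test_partition_sums_to_cohort(self):
        b = criterion_breakdown(self._records(57, 13, 9), 2010)
        assert b["icd_only"] + b["both"] + b["opioid_only"] == b["cohort_size"]

    def test_all_icd_only(self):
        b = criterion_breakdown(self._records(25, 0, 0), 2010)
        assert (b["pct"]["icd_only"], b["pct"]["both"], b["pct"]["opioid_only"]) \
            == (100.0, 0.0, 0.0)

    def test_empty_cohort_reports_absent_percentages(self):
        b = criterion_breakdown(self._records(0, 0, 0), 2010)
        assert b["cohort_size"] == 0 and b["pct"] is None
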