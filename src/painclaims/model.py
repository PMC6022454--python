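"""Study-level modelling interface: build from claims tables, fit, summarize.

:class:`ChronicPainStudy` bundles the claims tables with the rule
configuration; :meth:`ChronicPainStudy.fit` applies the two-criterion
identification to every person-year and returns a
:class:`ChronicPainResults` carrying the cohort, yearly summaries,
stratified prevalence, insurance splits, the significance tests, and a
plain-text ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import prevalence as prev
from . import reporting, stats
from .casefinder import FinderPolicy, identify_cohort
from .claims import CodeConfig, OpioidList, read_claims

__all__ = ["ChronicPainStudy", "ChronicPainResults"]


class ChronicPainStudy:
    """Chronic-pain claims study: identification rule applied to one dataset.

    Parameters
    ----------
    medical, pharmacy, persons, census
        Validated claims tables (see :mod:`painclaims.claims` schemas).
    code_config, opioids, policy
        The identification rule sets and thresholds; package defaults
        implement the standard two-criterion definition (338.xx or paired
        likely codes >= 30 days apart; >= 90 consecutive covered opioid days).
    years
        Calendar years to analyse; default, every year present in the claims.
    """

    def __init__(
        self,
        medical: pd.DataFrame,
        pharmacy: pd.DataFrame,
        persons: pd.DataFrame,
        census: pd.DataFrame | None = None,
        *,
        code_config: CodeConfig | None = None,
        opioids: OpioidList | None = None,
        policy: FinderPolicy | None = None,
        years: Sequence[int] | None = None,
    ) -> None:
        self.medical = medical
        self.pharmacy = pharmacy
        self.persons = persons
        self.census = census
        self.code_config = code_config or CodeConfig()
        self.opioids = opioids or OpioidList()
        self.policy = policy or FinderPolicy()
        self.years = list(years) if years is not None else None

    @classmethod
    def from_directory(cls, path: str | Path, **kwargs) -> "ChronicPainStudy":
        """Build a study from a directory of interchange CSVs
        (medical_claims.csv, pharmacy_claims.csv, persons.csv, census.csv)."""
        path = Path(path)
        census_path = path / "census.csv"
        return cls(
            read_claims(path / "medical_claims.csv", "medical"),
            read_claims(path / "pharmacy_claims.csv", "pharmacy"),
            read_claims(path / "persons.csv", "person"),
            read_claims(census_path, "census") if census_path.exists() else None,
            **kwargs,
        )

    def fit(self) -> "ChronicPainResults":
        """Run the case-finding algorithm and assemble the results object."""
        cohort = identify_cohort(
            self.medical, self.pharmacy, self.persons,
            self.code_config, self.opioids, self.policy, self.years,
        )
        cohort_ins = prev.attribute_insurance(cohort, self.medical, self.pharmacy)
        return ChronicPainResults(self, cohort_ins)


@dataclass
class ChronicPainResults:
    """Fitted study results: cohort, summaries, prevalence and tests."""

    model: ChronicPainStudy
    cohort: pd.DataFrame  # cohort records + insurance column

    @property
    def years(self) -> list[int]:
        members = self.cohort[self.cohort["classification"] != "none"]
        return sorted(int(y) for y in members["year"].unique())

    @property
    def yearly_summary(self) -> pd.DataFrame:
        return reporting.yearly_summaries(self.cohort, self.years, insurance=self.cohort)

    @property
    def summary_with_average(self) -> pd.DataFrame:
        return reporting.multi_year_summary(self.yearly_summary)

    # ---- prevalence ------------------------------------------------------
    def prevalence(self, by: Sequence[str] = ("sex",)) -> pd.DataFrame:
        """Stratified prevalence against the census denominators."""
        if self.model.census is None:
            raise ValueError("a census table is required for prevalence")
        return prev.compute_prevalence(self.cohort, self.model.census, by,
                                       persons=self.model.persons)

    def insurance_split(self, by: str = "overall") -> pd.DataFrame:
        return prev.insurance_split(self.cohort, by=by)

    # ---- tests -----------------------------------------------------------
    def sex_difference_test(self) -> stats.TestResult:
        """Two-sample z test: female vs male prevalence over census denominators."""
        tab = self.prevalence(by=("sex",)).set_index("sex")
        return stats.two_sample_z(
            int(tab.loc["female", "cases"]), int(tab.loc["female", "population"]),
            int(tab.loc["male", "cases"]), int(tab.loc["male", "population"]),
        )

    def insurance_test(self, year: int | None = None) -> stats.TestResult:
        """One-sample z test of the public-insurance share against 50%."""
        df = self.cohort[self.cohort["classification"] != "none"]
        if year is not None:
            df = df[df["year"] == year]
        n = len(df)
        x = int((df["insurance"] == "public").sum())
        return stats.one_sample_z(x, n, 0.5)

    def county_table(self, year: int | None = None) -> pd.DataFrame:
        """Per-county outcome + covariate table for ecological correlations."""
        if self.model.census is None:
            raise ValueError("a census table is required")
        census = self.model.census
        covars = (census.groupby("county")[list(stats.COUNTY_COVARIATES)]
                  .first().reset_index())
        ptab = self.prevalence(by=("county",))
        ptab = ptab[ptab["county"] != "overall"][["county", "prevalence_pct"]]
        df = self.cohort[self.cohort["classification"] != "none"].merge(
            self.model.persons[["person_id", "county"]], on="person_id", how="left")
        if year is not None:
            df = df[df["year"] == year]
        ins = []
        for county, grp in df.groupby("county", sort=True):
            n = len(grp)
            n_pub = int((grp["insurance"] == "public").sum())
            ins.append({"county": county,
                        "public_pct": 100.0 * n_pub / n,
                        "private_pct": 100.0 * (n - n_pub) / n})
        out = covars.merge(ptab, on="county", how="left").merge(
            pd.DataFrame(ins), on="county", how="left")
        return out

    def county_correlations(self, outcome: str = "public_share",
                            year: int | None = None) -> pd.DataFrame:
        """r/t/p of the county outcome against income, poverty and education."""
        return stats.county_correlations(self.county_table(year), outcome)

    # ---- reporting -------------------------------------------------------
    def report(self, out_dir: str | Path, plots: bool = False) -> Path:
        """Write the full set of figure-equivalent tables + manifest."""
        tables = {
            "yearly_summary": self.summary_with_average,
            "insurance_by_year": self.insurance_split(by="year"),
        }
        if self.model.census is not None:
            tables["prevalence_by_sex_age"] = self.prevalence(by=("sex", "age_band"))
            tables["prevalence_by_county_sex"] = self.prevalence(by=("county", "sex"))
            tables["county_covariates"] = self.county_table()
            tables["county_correlations_public"] = self.county_correlations("public_share")
            tables["county_correlations_private"] = self.county_correlations("private_share")
        return reporting.render_report(tables, out_dir, plots=plots)

    def summary(self) -> str:
        """Human-readable study summary table."""
        lines = ["Chronic-pain claims study", "=" * 60]
        ys = self.summary_with_average
        lines.append("Cohort by year (identification-route breakdown):")
        cols = ["year", "cohort_size", "icd_only", "both", "opioid_only",
                "opioid_criterion_pct", "public_pct", "private_pct"]
        cols = [c for c in cols if c in ys.columns]
        with pd.option_context("display.float_format", lambda v: f"{v:.1f}"):
            lines.append(ys[cols].to_string(index=False))
        if self.model.census is not None:
            ptab = self.prevalence(by=("sex",))
            lines.append("")
            lines.append("Prevalence by sex (census-denominated):")
            with pd.option_context("display.float_format", lambda v: f"{v:.1f}"):
                lines.append(ptab.to_string(index=False))
            t = self.sex_difference_test()
            lines.append(f"female vs male two-sample z: z={t.statistic:.2f}, "
                         f"p={t.p_value:.3g}")
        t = self.insurance_test()
        lines.append(f"public-share one-sample z vs 50%: z={t.statistic:.2f}, "
                     f"p={t.p_value:.3g}")
        return "\n".join(lines)
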