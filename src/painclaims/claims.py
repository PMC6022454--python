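"""Claims data model: record schemas, invariant checks, tabular IO and ICD-9 matching.

All tabular data is carried as :class:`pandas.DataFrame` with fixed column
schemas (see :data:`SCHEMAS`).  Dates are ISO-8601 in text files and
``datetime.date``-valued object columns in memory; all day intervals are
closed on both ends.  Payer type is a per-claim attribute (person-level
insurance attribution is a separate step, see :mod:`painclaims.prevalence`).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "SCHEMAS",
    "PAYER_TYPES",
    "SEXES",
    "MAINE_COUNTIES",
    "ValidationError",
    "CodeConfig",
    "OpioidList",
    "match_icd9",
    "normalize_icd9",
    "is_valid_icd9",
    "read_claims",
    "write_claims",
    "validate_table",
    "load_config",
]

PAYER_TYPES = ("public", "private")
SEXES = ("female", "male")

#: The 16 Maine counties — the default region set for county-level analyses.
MAINE_COUNTIES = (
    "Androscoggin", "Aroostook", "Cumberland", "Franklin", "Hancock",
    "Kennebec", "Knox", "Lincoln", "Oxford", "Penobscot", "Piscataquis",
    "Sagadahoc", "Somerset", "Waldo", "Washington", "York",
)

#: Column schemas for the delimited-text interchange files.
SCHEMAS: dict[str, list[str]] = {
    "medical": ["person_id", "service_date", "icd9_codes", "payer_type"],
    "pharmacy": ["person_id", "fill_date", "drug_id", "days_supply", "payer_type"],
    "person": ["person_id", "sex", "birth_year", "county"],
    "census": ["county", "sex", "age_band", "population",
               "median_income", "pct_poverty", "pct_bachelors"],
    "truth": ["person_id", "year", "is_case", "planted_route"],
    "cohort": ["person_id", "year", "icd_flag", "opioid_flag",
               "classification", "excluded_only_flag", "evidence"],
}

# ICD-9-CM lexical pattern: numeric 3-digit root (or V2/E3 root) plus an
# optional 1-2 digit decimal extension, with or without the dot.
_ICD9_RE = re.compile(r"^(?:\d{3}|V\d{2}|E\d{3})(?:\.?\d{1,2})?$", re.IGNORECASE)


class ValidationError(ValueError):
    """Raised when a record violates a schema or domain invariant."""


def normalize_icd9(code: str) -> str:
    """Normalize an ICD-9 code for prefix matching: strip dots, uppercase."""
    return code.replace(".", "").upper().strip()


def is_valid_icd9(code: str) -> bool:
    return bool(_ICD9_RE.match(code.strip()))


# ---------------------------------------------------------------------------
# Rule-set configuration
# ---------------------------------------------------------------------------

# The published case definition defers its full "likely" include list and the
# opioid drug list to external sources; these defaults are documented,
# user-replaceable stand-ins covering the common chronic-pain diagnosis
# families (spine disorders, chronic joint pain, neuropathies, fibromyalgia).
DEFAULT_HIGHLY_LIKELY = frozenset({"338"})
DEFAULT_CANCER_PAIN = frozenset({"338.3"})
DEFAULT_LIKELY = frozenset({
    "721", "722", "723", "724",      # spondylosis, disc disorders, neck/back pain
    "719.4",                          # joint pain
    "729.1", "729.2",                 # myalgia/fibromyalgia, neuralgia
    "337.2",                          # reflex sympathetic dystrophy
    "353", "354", "355",              # nerve root and mononeuropathy syndromes
    "053.13",                         # postherpetic neuralgia
    "250.6",                          # diabetic neuropathy
    "715",                            # osteoarthrosis
})
DEFAULT_EXCLUDED = frozenset({
    "346",                            # migraine
    "339", "784.0", "307.81",         # other headache syndromes
    "350.2",                          # atypical facial pain
})

DEFAULT_OPIOIDS = frozenset({
    "buprenorphine", "codeine-acetaminophen", "fentanyl", "hydrocodone-acetaminophen",
    "hydromorphone", "meperidine", "methadone", "morphine",
    "oxycodone", "oxycodone-acetaminophen", "oxymorphone", "tapentadol", "tramadol",
})

Icd9Class = Literal["highly_likely", "likely", "excluded_headache", "cancer_pain", "none"]


@dataclass(frozen=True)
class CodeConfig:
    """ICD-9 prefix rule sets driving the diagnosis criterion.

    Matching is by normalized prefix (dots stripped, case-insensitive) with
    longest-prefix precedence, so ``338.3x`` (cancer pain) is carved out of
    the general ``338`` (chronic-pain) family.
    """

    highly_likely_prefixes: frozenset[str] = DEFAULT_HIGHLY_LIKELY
    likely_codes: frozenset[str] = DEFAULT_LIKELY
    excluded_codes: frozenset[str] = DEFAULT_EXCLUDED
    cancer_pain_prefixes: frozenset[str] = DEFAULT_CANCER_PAIN

    def __post_init__(self) -> None:
        sets = {
            "highly_likely": {normalize_icd9(c) for c in self.highly_likely_prefixes},
            "likely": {normalize_icd9(c) for c in self.likely_codes},
            "excluded_headache": {normalize_icd9(c) for c in self.excluded_codes},
            "cancer_pain": {normalize_icd9(c) for c in self.cancer_pain_prefixes},
        }
        names = list(sets)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                dup = sets[a] & sets[b]
                if dup:
                    raise ValidationError(
                        f"code prefix(es) {sorted(dup)} appear in both {a!r} and {b!r}"
                    )
        for p in sets["cancer_pain"]:
            if not any(p.startswith(h) for h in sets["highly_likely"]):
                raise ValidationError(
                    f"cancer-pain prefix {p!r} is not within the highly-likely range"
                )
        object.__setattr__(self, "_prefix_map", {
            p: cls for cls, ps in sets.items() for p in ps
        })

    @property
    def prefix_map(self) -> dict[str, str]:
        return self._prefix_map  # type: ignore[attr-defined]


@dataclass(frozen=True)
class OpioidList:
    """Set of drug identifiers (names or NDCs) counted as opioids."""

    drug_ids: frozenset[str] = DEFAULT_OPIOIDS

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "_norm", frozenset(d.strip().lower() for d in self.drug_ids)
        )

    def __contains__(self, drug_id: str) -> bool:
        return drug_id.strip().lower() in self._norm  # type: ignore[attr-defined]


def match_icd9(code: str, config: CodeConfig | None = None) -> Icd9Class:
    """Classify one ICD-9 code against the configured rule sets.

    Returns exactly one of ``highly_likely``, ``likely``, ``excluded_headache``,
    ``cancer_pain`` or ``none``.  The longest configured prefix that matches
    the normalized code wins, so a specific carve-out (e.g. cancer pain
    338.3x) takes precedence over its general family (338).

    Raises
    ------
    ValidationError
        If *code* is not lexically a valid ICD-9 code.
    """
    if not is_valid_icd9(code):
        raise ValidationError(f"not a lexically valid ICD-9 code: {code!r}")
    config = config or CodeConfig()
    norm = normalize_icd9(code)
    pm = config.prefix_map
    for k in range(len(norm), 0, -1):
        cls = pm.get(norm[:k])
        if cls is not None:
            return cls  # type: ignore[return-value]
    return "none"


# ---------------------------------------------------------------------------
# Tabular IO with validation
# ---------------------------------------------------------------------------

def _err(schema: str, row: int, fieldname: str, msg: str) -> ValidationError:
    return ValidationError(f"{schema} row {row}, field {fieldname!r}: {msg}")


def _check_dates(s: pd.Series, schema: str, fieldname: str) -> pd.Series:
    parsed = pd.to_datetime(s, format="%Y-%m-%d", errors="coerce")
    bad = parsed.isna() | s.isna()
    if bad.any():
        row = int(bad.idxmax())
        raise _err(schema, row, fieldname, f"malformed ISO-8601 date {s.iloc[row]!r}")
    return parsed.dt.date


def validate_table(df: pd.DataFrame, schema: str) -> pd.DataFrame:
    """Validate and coerce a raw table against one of the named schemas.

    Returns a copy with canonical dtypes (dates as ``datetime.date``,
    counts as integers).  Raises :class:`ValidationError` naming the first
    offending row and field.
    """
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; expected one of {sorted(SCHEMAS)}")
    cols = SCHEMAS[schema]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{schema} table is missing column(s) {missing}")
    df = df[cols].copy().reset_index(drop=True)

    if schema == "medical":
        df["service_date"] = _check_dates(df["service_date"], schema, "service_date")
        for i, raw in df["icd9_codes"].items():
            codes = [c for c in str(raw).split(";") if c.strip()]
            if not codes:
                raise _err(schema, i, "icd9_codes", "empty code list")
            for c in codes:
                if not is_valid_icd9(c):
                    raise _err(schema, i, "icd9_codes", f"invalid ICD-9 code {c!r}")
        df["icd9_codes"] = df["icd9_codes"].astype(str)
        _check_enum(df, schema, "payer_type", PAYER_TYPES)
    elif schema == "pharmacy":
        df["fill_date"] = _check_dates(df["fill_date"], schema, "fill_date")
        ds = pd.to_numeric(df["days_supply"], errors="coerce")
        bad = ds.isna() | (ds < 1) | (ds != ds.round())
        if bad.any():
            row = int(bad.idxmax())
            raise _err(schema, row, "days_supply",
                       f"must be a positive integer, got {df['days_supply'].iloc[row]!r}")
        df["days_supply"] = ds.astype(int)
        _check_enum(df, schema, "payer_type", PAYER_TYPES)
    elif schema == "person":
        if df["person_id"].duplicated().any():
            dup = df["person_id"][df["person_id"].duplicated()].iloc[0]
            raise ValidationError(f"person table: duplicate person_id {dup!r}")
        by = pd.to_numeric(df["birth_year"], errors="coerce")
        bad = by.isna() | (by < 1880) | (by > 2100)
        if bad.any():
            row = int(bad.idxmax())
            raise _err(schema, row, "birth_year",
                       f"implausible birth year {df['birth_year'].iloc[row]!r}")
        df["birth_year"] = by.astype(int)
        _check_enum(df, schema, "sex", SEXES)
    elif schema == "census":
        pop = pd.to_numeric(df["population"], errors="coerce")
        bad = pop.isna() | (pop < 0)
        if bad.any():
            row = int(bad.idxmax())
            raise _err(schema, row, "population", "must be a non-negative count")
        df["population"] = pop.astype(int)
        if df.duplicated(subset=["county", "sex", "age_band"]).any():
            raise ValidationError("census table: duplicate (county, sex, age_band) stratum")
        for c in ("median_income", "pct_poverty", "pct_bachelors"):
            df[c] = pd.to_numeric(df[c], errors="coerce")
            if df[c].isna().any():
                row = int(df[c].isna().idxmax())
                raise _err(schema, row, c, "missing or non-numeric covariate")
    elif schema == "truth":
        df["year"] = pd.to_numeric(df["year"], errors="coerce").astype(int)
        df["is_case"] = df["is_case"].map(_to_bool)
        _check_enum(df, schema, "planted_route", ("icd_only", "opioid_only", "both", "none"))
        if df.duplicated(subset=["person_id", "year"]).any():
            raise ValidationError("truth table: duplicate (person_id, year) label")
    elif schema == "cohort":
        df["year"] = pd.to_numeric(df["year"], errors="coerce").astype(int)
        for c in ("icd_flag", "opioid_flag", "excluded_only_flag"):
            df[c] = df[c].map(_to_bool)
        _check_enum(df, schema, "classification", ("icd_only", "opioid_only", "both", "none"))
        df["evidence"] = df["evidence"].fillna("").astype(str)
    return df


def _to_bool(v) -> bool:
    if isinstance(v, bool):
        return v
    s = str(v).strip().lower()
    if s in ("true", "1"):
        return True
    if s in ("false", "0"):
        return False
    raise ValidationError(f"not a boolean: {v!r}")


def _check_enum(df: pd.DataFrame, schema: str, fieldname: str, allowed: Iterable[str]) -> None:
    allowed = set(allowed)
    bad = ~df[fieldname].isin(allowed)
    if bad.any():
        row = int(bad.idxmax())
        raise _err(schema, row, fieldname,
                   f"{df[fieldname].iloc[row]!r} not in {sorted(allowed)}")


def read_claims(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate a delimited-text (CSV) or parquet claims table.

    Parameters
    ----------
    path
        File path; ``.parquet`` is read as columnar binary, anything else as
        comma-delimited text with a header row and ISO-8601 dates.
    schema
        One of ``medical``, ``pharmacy``, ``person``, ``census``, ``truth``,
        ``cohort``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".parquet":
        raw = pd.read_parquet(path)
    else:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    out = validate_table(raw, schema)
    logger.info("read %d %s record(s) from %s", len(out), schema, path)
    return out


def write_claims(records: pd.DataFrame, path: str | Path, schema: str | None = None) -> Path:
    """Write a validated table so that :func:`read_claims` round-trips it losslessly."""
    path = Path(path)
    df = records.copy()
    if schema is not None:
        df = df[SCHEMAS[schema]]
    if path.suffix == ".parquet":
        df.to_parquet(path, index=False)
    else:
        df.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Run configuration file (YAML/JSON contract)
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Parsed analysis configuration: rule sets plus case-finder policy knobs."""

    code_config: CodeConfig = field(default_factory=CodeConfig)
    opioids: OpioidList = field(default_factory=OpioidList)
    policy_kwargs: dict = field(default_factory=dict)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML (or JSON — YAML is a superset) analysis configuration.

    Recognized top-level keys: ``codes`` (with ``highly_likely``, ``likely``,
    ``excluded``, ``cancer_pain`` lists), ``opioids`` (list of drug ids) and
    ``policy`` (keyword arguments for the case-finder policy).  Absent keys
    fall back to package defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    codes = raw.get("codes", {})
    cc = CodeConfig(
        highly_likely_prefixes=frozenset(codes.get("highly_likely", DEFAULT_HIGHLY_LIKELY)),
        likely_codes=frozenset(codes.get("likely", DEFAULT_LIKELY)),
        excluded_codes=frozenset(codes.get("excluded", DEFAULT_EXCLUDED)),
        cancer_pain_prefixes=frozenset(codes.get("cancer_pain", DEFAULT_CANCER_PAIN)),
    )
    ops = OpioidList(frozenset(raw["opioids"])) if raw.get("opioids") else OpioidList()
    return RunConfig(code_config=cc, opioids=ops, policy_kwargs=dict(raw.get("policy", {})))
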