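"""Summary artifacts: yearly cohort tables, multi-year averages, report files.

Counts are rounded half-up to integers and percentages to one decimal in
display tables; machine-readable outputs keep full precision.  Year
selection is always an explicit input — which calendar years enter the
averages is an analysis decision, never hard-coded.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .casefinder import criterion_breakdown

__all__ = ["yearly_summaries", "multi_year_summary", "render_report"]

_SUMMARY_COLS = ["year", "cohort_size", "icd_only", "both", "opioid_only",
                 "opioid_criterion_total", "opioid_criterion_pct",
                 "public_pct", "private_pct"]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def yearly_summaries(
    records: pd.DataFrame,
    years: Sequence[int] | None = None,
    insurance: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-year cohort size and criterion breakdown from cohort records.

    *insurance*, if given, is the cohort with an ``insurance`` column
    (see :func:`painclaims.prevalence.attribute_insurance`); public/private
    percentages are then included.
    """
    if years is None:
        years = sorted(records.loc[records["classification"] != "none", "year"].unique())
    rows = []
    for year in years:
        b = criterion_breakdown(records, int(year))
        row = {
            "year": int(year), "cohort_size": b["cohort_size"],
            "icd_only": b["icd_only"], "both": b["both"],
            "opioid_only": b["opioid_only"],
            "opioid_criterion_total": b["opioid_criterion_total"],
            "opioid_criterion_pct": (b["pct"]["opioid_criterion_total"]
                                     if b["pct"] else float("nan")),
            "public_pct": float("nan"), "private_pct": float("nan"),
        }
        if insurance is not None:
            sub = insurance[(insurance["year"] == year)
                            & (insurance["classification"] != "none")]
            if len(sub):
                n_pub = int((sub["insurance"] == "public").sum())
                row["public_pct"] = 100.0 * n_pub / len(sub)
                row["private_pct"] = 100.0 * (len(sub) - n_pub) / len(sub)
        rows.append(row)
    return pd.DataFrame(rows, columns=_SUMMARY_COLS)


def multi_year_summary(
    yearly: pd.DataFrame | Mapping[int, int],
) -> pd.DataFrame:
    """Append the across-year averages row to a per-year summary table.

    *yearly* may be the frame from :func:`yearly_summaries`, or a plain
    ``{year: cohort_size}`` mapping (e.g. published counts).  The averages
    row carries the arithmetic mean over exactly the years present —
    counts rounded half-up to integers, percentages to full precision.
    The opioid-criterion share is averaged two ways, both reported:
    mean of the yearly shares (``opioid_criterion_pct``) and the pooled
    share, total opioid-criterion count over total cohort size
    (``opioid_criterion_pct_pooled``).
    """
    if isinstance(yearly, Mapping):
        yearly = pd.DataFrame(
            [{"year": int(y), "cohort_size": int(n)} for y, n in sorted(yearly.items())]
        )
    if not len(yearly):
        raise ValueError("at least one year of records is required")
    df = yearly.copy()
    if ({"opioid_criterion_total", "cohort_size"} <= set(df.columns)
            and "opioid_criterion_pct" not in df.columns):
        df["opioid_criterion_pct"] = (100.0 * df["opioid_criterion_total"]
                                      / df["cohort_size"])
    avg: dict = {"year": "average"}
    for col in df.columns:
        if col == "year":
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.notna().all():
            m = float(vals.mean())
            avg[col] = _round_half_up(m) if not col.endswith("pct") else m
    if {"opioid_criterion_total", "cohort_size"} <= set(df.columns):
        tot = df["opioid_criterion_total"].sum()
        size = df["cohort_size"].sum()
        avg["opioid_criterion_pct_pooled"] = 100.0 * tot / size if size else float("nan")
    out = df.copy()
    out["year"] = out["year"].astype(object)
    return pd.concat([out, pd.DataFrame([avg])], ignore_index=True)


def render_report(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    plots: bool = False,
) -> Path:
    """Write each table as CSV plus a manifest; optionally simple charts.

    Deterministic: identical inputs produce byte-identical CSVs and
    manifest.  Returns the manifest path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    produced: list[str] = []
    for name in sorted(tables):
        path = out / f"{name}.csv"
        tables[name].to_csv(path, index=False)
        produced.append(path.name)
    if plots:
        produced.extend(_render_charts(tables, out))
    manifest = out / "manifest.json"
    with open(manifest, "w") as fh:
        json.dump({"files": produced}, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _render_charts(tables: Mapping[str, pd.DataFrame], out: Path) -> list[str]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    produced = []
    for name in sorted(tables):
        df = tables[name]
        num = df.select_dtypes("number")
        if not len(num.columns) or not len(df):
            continue
        fig, ax = plt.subplots(figsize=(8, 4))
        label_col = next((c for c in df.columns if c not in num.columns), None)
        xticks = df[label_col].astype(str) if label_col is not None else df.index.astype(str)
        pct_cols = [c for c in num.columns if c.endswith("pct")]
        cols = pct_cols or list(num.columns[:3])
        for col in cols:
            ax.bar(xticks, df[col], label=col, alpha=0.6)
        ax.set_title(name)
        ax.legend(fontsize=7)
        ax.tick_params(axis="x", labelrotation=90, labelsize=6)
        fig.tight_layout()
        fname = f"{name}.png"
        fig.savefig(out / fname, dpi=100)
        plt.close(fig)
        produced.append(fname)
    return produced
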