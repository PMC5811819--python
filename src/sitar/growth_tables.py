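"""Survey-mean anthropometry tables and period/cohort curve construction.

Input data are national survey means of height (cm) or weight (kg) tabulated
by 1-year age group, sex, country and year of measurement.  One
:class:`GrowthTable` holds the curves entering a single model fit (one sex,
one measurement), either as *period* curves (all ages measured in one year)
or *cohort* curves (one birth year followed across measurement years).

Conventions
-----------
* "age group a" covers completed years [a, a+1); its mean age is a + 0.5,
  applied once by :func:`assign_midyear_ages`.
* The cohort for birth year b at age group a is drawn from measurement year
  b + a, so the period curve of year y pairs with the cohort born y - 11
  (in mid-year y that cohort's mean age is 11.0, the midpoint of ages 1-20).
* Annual series may be merged into 3-year groups centred on reference years
  to reduce sampling noise (as done for the Japanese annual surveys).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GrowthDataError",
    "GrowthTable",
    "read_growth_table",
    "write_growth_table",
    "assign_midyear_ages",
    "merge_triennia",
    "build_cohort_table",
    "match_period_to_cohort",
    "survey_metadata",
]

logger = logging.getLogger("sitar")

#: Columns every validated table carries, in emission order.
COLUMNS = ["survey", "country", "year", "sex", "measurement", "age", "value", "n"]

_SEXES = {"male", "female"}
_MEASUREMENTS = {"height", "weight"}


class GrowthDataError(ValueError):
    """Raised for malformed or inconsistent growth tables."""


@dataclass(frozen=True)
class GrowthTable:
    """Validated survey-mean observations for one sex and one measurement.

    ``data`` has columns ``survey, country, year, sex, measurement, age,
    value, n`` (``n`` may be all-NaN).  ``mode`` records whether curves are
    period or cohort slices.
    """

    data: pd.DataFrame = field(repr=False)
    mode: str = "period"

    def __post_init__(self) -> None:
        if self.mode not in ("period", "cohort"):
            raise GrowthDataError(f"mode must be 'period' or 'cohort', got {self.mode!r}")
        df = self.data
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise GrowthDataError(f"table is missing columns: {missing}")
        if len(df) == 0:
            return
        if df["sex"].nunique() > 1 or df["measurement"].nunique() > 1:
            raise GrowthDataError(
                "a GrowthTable holds one sex and one measurement; got "
                f"sexes {sorted(df['sex'].unique())}, "
                f"measurements {sorted(df['measurement'].unique())}"
            )
        bad_sex = set(df["sex"].unique()) - _SEXES
        if bad_sex:
            raise GrowthDataError(f"unknown sex value(s) {sorted(bad_sex)}")
        bad_meas = set(df["measurement"].unique()) - _MEASUREMENTS
        if bad_meas:
            raise GrowthDataError(f"unknown measurement value(s) {sorted(bad_meas)}")
        if (df["age"] <= 0).any() or (df["value"] <= 0).any():
            raise GrowthDataError("ages and values must be strictly positive")
        if (df["n"].dropna() <= 0).any():
            raise GrowthDataError("sample sizes n must be strictly positive where given")
        for survey, grp in df.groupby("survey"):
            ages = grp["age"].to_numpy()
            if np.any(np.diff(ages) <= 0):
                raise GrowthDataError(
                    f"ages within survey {survey!r} must be strictly increasing "
                    "and unique (sort rows by survey then age)"
                )

    # -- convenience accessors -------------------------------------------------

    @property
    def surveys(self) -> list[str]:
        return list(dict.fromkeys(self.data["survey"]))

    @property
    def n_obs(self) -> int:
        return len(self.data)

    def for_survey(self, survey: str) -> pd.DataFrame:
        out = self.data[self.data["survey"] == survey]
        if len(out) == 0:
            raise KeyError(f"no survey {survey!r} in table")
        return out

    def check_fittable(self) -> None:
        """Raise unless every curve has the >= 4 distinct ages a spline fit needs."""
        if len(self.data) == 0:
            raise GrowthDataError("empty table cannot be fitted")
        for survey, grp in self.data.groupby("survey"):
            if grp["age"].nunique() < 4:
                raise GrowthDataError(
                    f"survey {survey!r} has {grp['age'].nunique()} distinct ages; "
                    "at least 4 are required"
                )


def _finalize(df: pd.DataFrame, mode: str) -> GrowthTable:
    df = df.sort_values(["survey", "age"], kind="stable").reset_index(drop=True)
    return GrowthTable(data=df[COLUMNS], mode=mode)


def read_growth_table(
    path: str | Path,
    sex: str | None = None,
    measurement: str | None = None,
) -> GrowthTable:
    """Read a survey-mean CSV into a period-mode :class:`GrowthTable`.

    The CSV must have columns ``country, year, sex, measurement, age_group,
    value`` (``n`` optional); comma-separated, UTF-8, decimal point.  Ages
    are kept as the integer completed-years group; apply
    :func:`assign_midyear_ages` before fitting.  ``sex``/``measurement``
    select one stratum from a file holding several.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    raw = pd.read_csv(path, encoding="utf-8")
    required = ["country", "year", "sex", "measurement", "age_group", "value"]
    for col in required:
        if col not in raw.columns:
            raise GrowthDataError(f"input CSV {path} is missing required column {col!r}")
    if "n" not in raw.columns:
        raw["n"] = np.nan
    if sex is not None:
        raw = raw[raw["sex"] == sex]
    if measurement is not None:
        raw = raw[raw["measurement"] == measurement]
    for col in ("year", "age_group", "value", "n"):
        coerced = pd.to_numeric(raw[col], errors="coerce")
        bad = coerced.isna() & raw[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise GrowthDataError(
                f"non-numeric {col!r} value {raw.loc[row, col]!r} at row {row} of {path}"
            )
        raw[col] = coerced
    raw["survey"] = raw["country"].astype(str) + " " + raw["year"].astype(int).astype(str)
    dup = raw.duplicated(subset=["survey", "sex", "measurement", "age_group"])
    if dup.any():
        row = int(dup.idxmax())
        raise GrowthDataError(
            f"duplicate (survey, age) entry at row {row}: "
            f"{raw.loc[row, 'survey']} age {raw.loc[row, 'age_group']}"
        )
    df = raw.rename(columns={"age_group": "age"})
    df["age"] = df["age"].astype(float)
    return _finalize(df, "period")


def write_growth_table(table: GrowthTable, path: str | Path) -> None:
    """Re-emit a table in the input schema, with decimal ``age`` replacing
    ``age_group``."""
    out = table.data.rename(columns={"age": "age_group"})
    out.to_csv(path, index=False)


def assign_midyear_ages(table: GrowthTable) -> GrowthTable:
    """Replace each completed-years age group a by the group's mean age a + 0.5.

    Guarded against double application: already-fractional ages raise.
    """
    ages = table.data["age"].to_numpy()
    if len(ages) and not np.allclose(ages, np.round(ages)):
        raise GrowthDataError(
            "ages are already fractional; mid-year offsets appear to have been applied"
        )
    df = table.data.copy()
    df["age"] = df["age"] + 0.5
    return _finalize(df, table.mode)


def merge_triennia(annual: GrowthTable, center_years: Sequence[int]) -> GrowthTable:
    """Merge an annual period table into 3-year groups centred on ``center_years``.

    For each centre year c and age, the merged value averages years c-1, c,
    c+1 — weighted by n when n is available for all three, unweighted
    otherwise.  The output survey is labelled by the centre year.
    """
    df = annual.data
    if annual.mode != "period":
        raise GrowthDataError("triennial merging applies to period tables")
    rows = []
    for c in center_years:
        triple = df[df["year"].isin([c - 1, c, c + 1])]
        missing_years = sorted({c - 1, c, c + 1} - set(triple["year"].unique()))
        if missing_years:
            raise GrowthDataError(
                f"cannot merge around {c}: no data for year(s) {missing_years}"
            )
        for (country, age), grp in triple.groupby(["country", "age"]):
            if grp["year"].nunique() != 3:
                got = sorted(grp["year"].unique())
                gap = sorted({c - 1, c, c + 1} - set(got))
                raise GrowthDataError(
                    f"cannot merge around {c} at age {age}: missing year(s) {gap}"
                )
            if grp["n"].notna().all():
                w = grp["n"].to_numpy(dtype=float)
                value = float(np.average(grp["value"], weights=w))
                n_out = float(w.sum())
            else:
                value = float(grp["value"].mean())
                n_out = np.nan
            rows.append(
                {
                    "survey": f"{country} {c}",
                    "country": country,
                    "year": c,
                    "sex": grp["sex"].iloc[0],
                    "measurement": grp["measurement"].iloc[0],
                    "age": age,
                    "value": value,
                    "n": n_out,
                }
            )
    return _finalize(pd.DataFrame(rows, columns=COLUMNS), "period")


def match_period_to_cohort(period_year: int) -> int:
    """Birth year whose cohort curve pairs with the given period curve.

    In mid-year y the cohort born y - 11 has mean age 11.0, the midpoint of
    the 1-20 completed-years range, so period year y maps to birth year y - 11.
    """
    return period_year - 11


def build_cohort_table(
    annual: GrowthTable,
    birth_years: Iterable[int],
    age_groups: Sequence[int] = tuple(range(1, 20)),
) -> GrowthTable:
    """Assemble cohort curves from an annual period table.

    The cohort born in year b contributes, at age group a, the record of
    measurement year b + a.  Cohorts at the edges of the measurement span
    are kept as partial curves; cohorts with fewer than 4 available ages are
    dropped with a warning.  Expects completed-years ages (apply mid-year
    offsets afterwards, as usual).
    """
    df = annual.data
    ages = df["age"].to_numpy()
    if len(ages) and not np.allclose(ages, np.round(ages)):
        raise GrowthDataError(
            "cohort construction expects completed-years age groups "
            "(build cohorts before assigning mid-year ages)"
        )
    by_year_age = {
        (int(r.year), int(r.age)): r for r in df.itertuples(index=False)
    }
    rows = []
    for b in birth_years:
        hits = []
        for a in age_groups:
            rec = by_year_age.get((b + a, a))
            if rec is not None:
                hits.append((a, rec))
        if len(hits) < 4:
            logger.warning(
                "cohort %s excluded: only %d age(s) available in the data span",
                b,
                len(hits),
            )
            continue
        for a, rec in hits:
            rows.append(
                {
                    "survey": f"{rec.country} {b}",
                    "country": rec.country,
                    "year": b,
                    "sex": rec.sex,
                    "measurement": rec.measurement,
                    "age": float(a),
                    "value": rec.value,
                    "n": rec.n,
                }
            )
    return _finalize(pd.DataFrame(rows, columns=COLUMNS), "cohort")


def survey_metadata(table: GrowthTable) -> pd.DataFrame:
    """One row per survey: ``survey, country, year`` (year = birth year in
    cohort mode), for joining fitted effects back to calendar time."""
    meta = (
        table.data.groupby("survey", sort=False)[["country", "year"]]
        .first()
        .reset_index()
    )
    return meta
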