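"""Stratified descriptive outputs: per-axis count/frequency tables, batch
disproportionality over strata, the county distribution, and the
monthly/annual notification time series with a pandemic-period comparison.

Every emitted table reconciles with the cohort size (conservation), and all
outputs are bit-stable given a fixed input. Percentages are reported to one
decimal place with round-half-even.
"""
from __future__ import annotations

import dataclasses
import datetime
import math
from collections import Counter
from typing import Iterable, Sequence, Union

import pandas as pd

from .classify import ClassifiedRecord
from .disproportionality import (
    DegenerateTableError,
    analyze_table,
    build_contingency,
)
from .model import COUNTY_VOCABULARY, IcsrRecord, MqrcCategory

#: Stratification axes and how each reads off a record.
AXES = {
    "therapeutic_class": lambda r: r.therapeutic_class.value,
    "specific_product": lambda r: r.specific_product,
    "medicine_version": lambda r: r.medicine_version.value,
    "facility_sector": lambda r: r.facility_sector.value,
    "facility_level": lambda r: r.facility_level.value,
    "reporter_profession": lambda r: r.reporter_profession.value,
    "dosage_form": lambda r: r.dosage_form.value,
    "county": lambda r: r.county,
}

#: Default onset of the COVID-19 pandemic period used for the
#: before/after notification comparison (March 2020).
PANDEMIC_BREAK = datetime.date(2020, 3, 1)

Cohort = Iterable[ClassifiedRecord]


@dataclasses.dataclass(frozen=True)
class StratumSpec:
    """One stratum of interest: an axis and a value from its vocabulary."""

    axis: str
    selector_value: str

    def __post_init__(self):
        if self.axis not in AXES:
            raise ValueError(f"unknown axis {self.axis!r}; one of {sorted(AXES)}")
        if self.axis == "county" and self.selector_value not in COUNTY_VOCABULARY:
            raise ValueError(f"unknown county {self.selector_value!r}")

    def selector(self):
        getter = AXES[self.axis]
        value = self.selector_value
        return lambda rec: getter(rec) == value


@dataclasses.dataclass
class TrendSeries:
    """Contiguous per-period complaint counts with a break date."""

    period: str  # "monthly" | "annual"
    counts: list[tuple[datetime.date, int]]
    break_date: datetime.date


@dataclasses.dataclass
class TrendSummary:
    """Mean per-period counts before/after the break and relative change.

    The period containing the break date belongs to "after". When nothing
    precedes the break the relative change is undefined and ``degenerate``
    is set.
    """

    before_mean: float
    after_mean: float
    relative_change: float | None
    degenerate: bool = False


def _pct(n: int, total: int) -> float:
    return round(100.0 * n / total, 1) if total else 0.0


def stratum_table(cohort: Cohort, axis: str) -> pd.DataFrame:
    """Counts and cohort percentages per stratum × category for one axis.

    Columns: the axis, ``<CAT>_n`` and ``<CAT>_pct`` for each category,
    ``total_n``, ``total_pct``. Rows are sorted by descending total then
    stratum name; row totals sum to the cohort size.
    """
    if axis not in AXES:
        raise ValueError(f"unknown axis {axis!r}; one of {sorted(AXES)}")
    cohort = list(cohort)
    getter = AXES[axis]
    cells: Counter = Counter()
    for cr in cohort:
        cells[(getter(cr.record), cr.category)] += 1
    strata = sorted({k[0] for k in cells})
    total = len(cohort)
    rows = []
    for s in strata:
        row: dict = {axis: s}
        row_total = 0
        for cat in MqrcCategory:
            n = cells.get((s, cat), 0)
            row[f"{cat.value}_n"] = n
            row[f"{cat.value}_pct"] = _pct(n, total)
            row_total += n
        row["total_n"] = row_total
        row["total_pct"] = _pct(row_total, total)
        rows.append(row)
    rows.sort(key=lambda r: (-r["total_n"], str(r[axis])))
    return pd.DataFrame(rows)


def strata_for_axis(cohort: Cohort, axis: str) -> list[StratumSpec]:
    """One StratumSpec per stratum value observed in the cohort."""
    getter = AXES[axis]
    values = sorted({getter(cr.record) for cr in cohort})
    return [StratumSpec(axis, v) for v in values]


def batch_disproportionality(
    cohort: Cohort,
    strata: Sequence[StratumSpec],
) -> pd.DataFrame:
    """One disproportionality result per (stratum × category).

    Degenerate tables (no defined ROR or p) are flagged in the
    ``degenerate`` column with NaN statistics rather than dropped.
    """
    cohort = list(cohort)
    rows = []
    for spec in strata:
        selector = spec.selector()
        for cat in MqrcCategory:
            t = build_contingency(cohort, selector, cat)
            row = {
                "axis": spec.axis,
                "stratum": spec.selector_value,
                "category": cat.value,
                "a": t.a, "b": t.b, "c": t.c, "d": t.d,
                "ror": math.nan, "ci_low": math.nan, "ci_high": math.nan,
                "chi2": math.nan, "p_value": math.nan, "p_bucket": "",
                "zero_cell": "none", "signal": False, "degenerate": False,
            }
            try:
                res = analyze_table(t)
            except DegenerateTableError:
                row["degenerate"] = True
            else:
                row.update(
                    ror=res.ror,
                    ci_low=math.nan if res.ci_low is None else res.ci_low,
                    ci_high=math.nan if res.ci_high is None else res.ci_high,
                    chi2=res.chi2,
                    p_value=res.p_value,
                    p_bucket=res.p_bucket,
                    zero_cell=res.zero_cell.value,
                    signal=res.is_signal,
                )
            rows.append(row)
    return pd.DataFrame(rows)


def _period_start(day: datetime.date, period: str) -> datetime.date:
    if period == "monthly":
        return day.replace(day=1)
    if period == "annual":
        return day.replace(month=1, day=1)
    raise ValueError(f"unknown period {period!r}")


def _next_period(start: datetime.date, period: str) -> datetime.date:
    if period == "annual":
        return start.replace(year=start.year + 1)
    if start.month == 12:
        return datetime.date(start.year + 1, 1, 1)
    return start.replace(month=start.month + 1)


def trend_series(
    cohort: Cohort,
    period: str = "monthly",
    break_date: datetime.date = PANDEMIC_BREAK,
) -> tuple[TrendSeries, TrendSummary]:
    """Per-period complaint counts and the before/after break comparison.

    Bins are contiguous from the first to the last observed period (empty
    periods count 0) and sum to the cohort size. The summary compares mean
    per-period counts strictly before the break period against the break
    period onward; ``relative_change = (after - before) / before``.
    """
    cohort = list(cohort)
    undated = [cr.record.report_id for cr in cohort if cr.record.report_date is None]
    if undated:
        raise ValueError(f"undated records: {', '.join(undated)}")
    if not cohort:
        raise ValueError("empty cohort")
    tallies: Counter = Counter(
        _period_start(cr.record.report_date, period) for cr in cohort
    )
    start, stop = min(tallies), max(tallies)
    counts: list[tuple[datetime.date, int]] = []
    cur = start
    while cur <= stop:
        counts.append((cur, tallies.get(cur, 0)))
        cur = _next_period(cur, period)
    series = TrendSeries(period=period, counts=counts, break_date=break_date)

    break_start = _period_start(break_date, period)
    before = [n for p, n in counts if p < break_start]
    after = [n for p, n in counts if p >= break_start]
    before_mean = sum(before) / len(before) if before else 0.0
    after_mean = sum(after) / len(after) if after else 0.0
    if before and before_mean > 0:
        summary = TrendSummary(
            before_mean, after_mean, (after_mean - before_mean) / before_mean
        )
    else:
        summary = TrendSummary(before_mean, after_mean, None, degenerate=True)
    return series, summary


def trend_frame(series: TrendSeries) -> pd.DataFrame:
    return pd.DataFrame(series.counts, columns=["period_start", "count"])


def county_table(
    cohort: Cohort,
    rollup_threshold: float | None = None,
) -> pd.DataFrame:
    """County × year counts with row totals, percentages and a totals row.

    Counties reporting at least one complaint appear as rows (the explicit
    "Not Indicated" row included); ``rollup_threshold`` (a fraction of the
    cohort, e.g. 0.026) optionally aggregates low-reporting counties into a
    single "Counties reports <X%" row. Rows sort by descending total; the
    roll-up, "Not Indicated" and "Total" rows close the table.
    """
    cohort = list(cohort)
    cells: Counter = Counter()
    for cr in cohort:
        cells[(cr.record.county, cr.record.report_date.year)] += 1
    years = sorted({y for _, y in cells})
    grand = len(cohort)
    county_totals: Counter = Counter()
    for (county, _), n in cells.items():
        county_totals[county] += n

    rolled: list[str] = []
    label = None
    if rollup_threshold is not None:
        label = f"Counties reports <{rollup_threshold * 100:g}%"
        rolled = [
            c
            for c, tot in county_totals.items()
            if c != "Not Indicated" and tot / grand < rollup_threshold
        ]

    def year_counts(counties: list[str]) -> dict:
        return {y: sum(cells.get((c, y), 0) for c in counties) for y in years}

    named = [
        c for c in county_totals if c != "Not Indicated" and c not in rolled
    ]
    named.sort(key=lambda c: (-county_totals[c], c))
    rows = []
    for c in named:
        rows.append({"county": c, **year_counts([c])})
    if rolled:
        rows.append({"county": label, **year_counts(sorted(rolled))})
    if "Not Indicated" in county_totals:
        rows.append({"county": "Not Indicated", **year_counts(["Not Indicated"])})
    rows.append(
        {"county": "Total", **{y: sum(r[y] for r in rows) for y in years}}
    )
    df = pd.DataFrame(rows)
    df["total"] = df[years].sum(axis=1)
    df["pct"] = [_pct(t, grand) for t in df["total"]]
    return df
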