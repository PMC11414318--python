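"""Synthetic ICSR generation and exact-count fixtures.

Two kinds of data come out of this module:

* :func:`generate` draws a configurable synthetic complaint cohort by
  seeded categorical sampling — category mix, per-axis distributions
  conditional on category, an annual reporting trend, plus injected
  duplicates, "Test" rows and out-of-window rows to exercise
  preprocessing. Complaint texts are template sentences embedding defect
  lexicon trigger phrases verbatim, so the classifier can recover the
  intended category; realism of the prose is a non-goal,
  classifier-recoverability is the contract.

* :func:`fixture_from_counts` / :func:`paper_fixture` emit cohorts whose
  stratum × category counts match a stated count table *exactly*, so that
  every downstream table and disproportionality statistic is reproducible
  deterministically. The shipped fixture tables encode the published
  marginal count tables of a national complaint cohort of 2,767 reports
  (by medicine version, therapeutic class, facility sector/level, reporter
  profession, dosage form, and county × year).

Axis distributions are sampled independently per axis conditional on
category: the published tables are one-axis-at-a-time marginals, and a
joint distribution matching all of them at once is overconstrained, so
fixtures are per-table.
"""
from __future__ import annotations

import dataclasses
import datetime
import math
from typing import Iterable, Mapping, Optional

import numpy as np

from .classify import default_lexicon
from .model import (
    COUNTY_NOT_INDICATED,
    KENYAN_COUNTIES,
    DosageForm,
    FacilityLevel,
    FacilitySector,
    IcsrRecord,
    MedicineVersion,
    MqrcCategory,
    ReporterProfession,
    ReportType,
    Route,
    TherapeuticClass,
)
from .preprocess import WINDOW_END, WINDOW_START

_CATS = (MqrcCategory.SMQD, MqrcCategory.STF, MqrcCategory.SADR)
_YEARS = tuple(range(2014, 2022))


# ---------------------------------------------------------------------------
# Published marginal count tables (cohort of 2,767 complaint reports).
# Cell order in the 3-tuples is (SMQD, STF, SADR).
# ---------------------------------------------------------------------------

TABLE3_COUNTS: dict[str, tuple[int, int, int]] = {
    "branded": (325, 494, 6),
    "generic": (1015, 647, 167),
    "unstated": (101, 10, 2),
}

TABLE4_COUNTS: dict[str, tuple[int, int, int]] = {
    "antineoplastics": (227, 558, 5),
    "antivirals": (133, 89, 101),
    "antibacterials": (175, 111, 12),
    "analgesics": (203, 24, 1),
    "antihypertensives": (86, 42, 18),
    "medical_devices": (108, 14, 3),
    "antiprotozoals": (60, 39, 1),
    "gynaecological": (61, 24, 2),
    "antimycobacterial": (33, 48, 6),
    "blood_perfusion_solutions": (29, 57, 0),
    "anaesthetics": (53, 5, 0),
    "minerals_vitamins": (28, 31, 4),
    "diabetes_drugs": (8, 18, 1),
    "vaccines": (16, 6, 0),
    "other_therapeutic_products": (221, 85, 21),
}

TABLE8_COUNTS: dict[tuple[str, str], tuple[int, int, int]] = {
    ("government", "hospital"): (822, 296, 108),
    ("government", "dispensary_clinic_health_centre"): (255, 153, 20),
    ("government", "importer_distributor_wholesaler"): (5, 0, 0),
    ("private_for_profit", "hospital"): (48, 522, 9),
    ("private_for_profit", "pharmacy_chemist"): (70, 5, 0),
    ("private_for_profit", "dispensary_clinic_health_centre"): (43, 19, 2),
    ("private_for_profit", "importer_distributor_wholesaler"): (11, 3, 1),
    ("not_for_profit", "hospital"): (34, 48, 15),
    ("not_for_profit", "dispensary_clinic_health_centre"): (27, 18, 8),
    ("informal_unlicensed", "individual"): (14, 2, 1),
    ("informal_unlicensed", "unknown"): (112, 85, 10),
    ("informal_unlicensed", "research_institution"): (0, 0, 1),
}

TABLE10_COUNTS: dict[str, tuple[int, int, int]] = {
    "pharmacist": (952, 324, 0),
    "medical_doctor": (124, 374, 0),
    "pharmaceutical_technician": (274, 51, 0),
    "other_hcp": (10, 0, 0),
    "not_stated": (81, 402, 175),
}

TABLE11_COUNTS: dict[str, tuple[int, int, int]] = {
    "tablet": (777, 826, 159),
    "injection": (252, 166, 10),
    "oral_liquid": (194, 76, 0),
    "medical_device": (108, 14, 3),
    "capsule": (38, 44, 0),
    "dermal_implant": (16, 11, 1),
    "other": (56, 14, 2),
}

#: County × year counts for the named high-reporting counties and the
#: "Not Indicated" row; years 2014..2021.
TABLE12_NAMED_COUNTS: dict[str, tuple[int, ...]] = {
    "Nairobi": (39, 62, 160, 118, 157, 227, 184, 99),
    "Kiambu": (4, 20, 30, 40, 16, 31, 7, 14),
    "Mombasa": (8, 11, 8, 20, 13, 22, 17, 7),
    "Kilifi": (4, 6, 8, 9, 22, 17, 14, 13),
    "Nakuru": (6, 11, 10, 4, 11, 14, 18, 10),
    "Kisumu": (3, 4, 11, 7, 29, 10, 9, 4),
    COUNTY_NOT_INDICATED: (9, 20, 25, 39, 42, 45, 50, 22),
}

#: Aggregate row of all counties individually below 2.6% of the cohort.
TABLE12_REST_COUNTS: tuple[int, ...] = (42, 73, 117, 90, 186, 205, 152, 82)

#: Counties with zero complaint reports over the study window.
ZERO_REPORT_COUNTIES = ("Garissa", "Lamu", "Trans-Nzoia", "Wajir")

COHORT_TOTAL = 2767
CATEGORY_TOTALS = (1441, 1151, 175)


def _spread_rest() -> dict[tuple[str, int], int]:
    """Deterministically spread the aggregate low-reporting-county row.

    The source table aggregates 947 reports over every county below the
    2.6% threshold; individual attributions are not published. The mass is
    spread round-robin across the 37 eligible counties (all counties minus
    the six named rows and the four zero-report counties), which keeps
    every synthetic county well below the threshold so a 2.6% roll-up of
    the fixture reproduces the aggregate row exactly.
    """
    eligible = [
        c
        for c in KENYAN_COUNTIES
        if c not in TABLE12_NAMED_COUNTS and c not in ZERO_REPORT_COUNTIES
    ]
    cells: dict[tuple[str, int], int] = {}
    idx = 0
    for year, total in zip(_YEARS, TABLE12_REST_COUNTS):
        for _ in range(total):
            county = eligible[idx % len(eligible)]
            cells[(county, year)] = cells.get((county, year), 0) + 1
            idx += 1
    return cells


def table12_cells() -> dict[tuple[str, int], int]:
    """Full county × year counts including the spread aggregate row."""
    cells: dict[tuple[str, int], int] = {}
    for county, per_year in TABLE12_NAMED_COUNTS.items():
        for year, n in zip(_YEARS, per_year):
            if n:
                cells[(county, year)] = n
    for key, n in _spread_rest().items():
        cells[key] = cells.get(key, 0) + n
    return cells


# ---------------------------------------------------------------------------
# Fixture construction
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class FixtureCountTable:
    """Exact stratum × category counts a fixture cohort must reproduce.

    ``axes`` names the record fields fixed by each stratum key; ``cells``
    maps a stratum key tuple to per-category counts. The special axis
    ``year`` pins the report year instead of a categorical field (used by
    the county table, whose source publishes no category split; categories
    are then cycled in roughly the cohort's global proportions).
    """

    name: str
    axes: tuple[str, ...]
    cells: Mapping[tuple, tuple[int, int, int] | int]

    def __post_init__(self):
        for key, val in self.cells.items():
            counts = val if isinstance(val, tuple) else (val,)
            if any((not isinstance(v, int)) or v < 0 for v in counts):
                raise ValueError(f"negative or non-integer cell at {key}: {val}")

    @property
    def grand_total(self) -> int:
        return sum(
            sum(v) if isinstance(v, tuple) else v for v in self.cells.values()
        )


def _category_table(name: str, axis: str, counts: Mapping) -> FixtureCountTable:
    axes = ("facility_sector", "facility_level") if name == "table8" else (axis,)
    cells = {
        (k if isinstance(k, tuple) else (k,)): v for k, v in counts.items()
    }
    return FixtureCountTable(name=name, axes=axes, cells=cells)


def fixture_tables() -> dict[str, FixtureCountTable]:
    return {
        "table3": _category_table("table3", "medicine_version", TABLE3_COUNTS),
        "table4": _category_table("table4", "therapeutic_class", TABLE4_COUNTS),
        "table8": _category_table("table8", "facility_sector", TABLE8_COUNTS),
        "table10": _category_table("table10", "reporter_profession", TABLE10_COUNTS),
        "table11": _category_table("table11", "dosage_form", TABLE11_COUNTS),
        "table12": FixtureCountTable(
            name="table12",
            axes=("county", "year"),
            cells={k: v for k, v in sorted(table12_cells().items())},
        ),
    }


_ENUM_SETTERS = {
    "medicine_version": ("medicine_version", MedicineVersion),
    "therapeutic_class": ("therapeutic_class", TherapeuticClass),
    "facility_sector": ("facility_sector", FacilitySector),
    "facility_level": ("facility_level", FacilityLevel),
    "reporter_profession": ("reporter_profession", ReporterProfession),
    "dosage_form": ("dosage_form", DosageForm),
}

_ROUTE_FOR_FORM = {
    DosageForm.TABLET: Route.ORAL,
    DosageForm.CAPSULE: Route.ORAL,
    DosageForm.ORAL_LIQUID: Route.ORAL,
    DosageForm.INJECTION: Route.PARENTERAL,
    DosageForm.MEDICAL_DEVICE: Route.NOT_APPLICABLE,
    DosageForm.DERMAL_IMPLANT: Route.TOPICAL,
    DosageForm.OTHER: Route.OTHER,
}

# Category cycle used when a fixture table publishes no category split
# (~global proportions 52/42/6 per 16 records).
_T12_CYCLE = (
    [MqrcCategory.SMQD] * 8 + [MqrcCategory.STF] * 7 + [MqrcCategory.SADR]
)

_STF_TEXT = "Suspected therapeutic failure: no improvement after a full course."
_SADR_TEXT = "Patient developed an adverse reaction; suspected poor quality product."


def _smqd_text(form: DosageForm, cycle_idx: int) -> str:
    """Complaint sentence embedding one defect trigger phrase verbatim."""
    terms = [t for t in default_lexicon() if t.applies_to(form)]
    term = terms[cycle_idx % len(terms)]
    return f"Product received with {term.synonyms[0]} noted on inspection."


def _fixture_record(
    idx: int,
    category: MqrcCategory,
    axes: tuple[str, ...],
    key: tuple,
    smqd_cycle: int,
) -> IcsrRecord:
    fields: dict = {}
    year: Optional[int] = None
    for axis, value in zip(axes, key):
        if axis == "year":
            year = int(value)
        elif axis == "county":
            fields["county"] = value
        else:
            attr, cls = _ENUM_SETTERS[axis]
            fields[attr] = cls(value)
    if "dosage_form" not in fields:
        if fields.get("therapeutic_class") is TherapeuticClass.MEDICAL_DEVICES:
            fields["dosage_form"] = DosageForm.MEDICAL_DEVICE
        else:
            fields["dosage_form"] = DosageForm.TABLET
    form = fields["dosage_form"]
    fields["route"] = _ROUTE_FOR_FORM[form]
    if year is None:
        # deterministic spread over the study window
        report_date = WINDOW_START + datetime.timedelta(days=(idx * 193) % 2922)
    else:
        report_date = datetime.date(year, 1, 1) + datetime.timedelta(
            days=(idx * 97) % 365
        )
    if category is MqrcCategory.SMQD:
        text = _smqd_text(form, smqd_cycle)
        rtype = (
            ReportType.DEVICE_INCIDENT
            if form is DosageForm.MEDICAL_DEVICE
            else ReportType.SPQM
        )
    elif category is MqrcCategory.STF:
        text, rtype = _STF_TEXT, ReportType.SPQM
    else:
        text, rtype = _SADR_TEXT, ReportType.SADR
    version = fields.get("medicine_version", MedicineVersion.UNSTATED)
    return IcsrRecord(
        report_id=f"F{idx:06d}",
        report_date=report_date,
        report_type=rtype,
        trade_name="BRAND-F" if version is MedicineVersion.BRANDED else "",
        api_names=["fixture-api"],
        complaint_text=text,
        patient_key=f"PF{idx:06d}",
        **fields,
    )


def fixture_from_counts(table: FixtureCountTable, seed: int = 0) -> list[IcsrRecord]:
    """Emit a cohort reproducing the table's counts exactly.

    Each record is constructed so the classifier and stratifier recover
    its cell deterministically: the stratum attributes are set directly
    and the category is encoded through the report type and a template
    complaint text (a lexicon trigger phrase for quality defects, a
    therapeutic-failure phrase for inefficacy complaints, an
    adverse-reaction report with declared quality suspicion otherwise).
    ``seed`` is accepted for interface symmetry; fixture output is fully
    deterministic regardless.
    """
    del seed
    records: list[IcsrRecord] = []
    idx = 0
    smqd_cycle = 0
    for key, val in table.cells.items():
        if isinstance(val, tuple):
            per_cat = zip(_CATS, val)
        else:
            picks = [_T12_CYCLE[(idx + j) % len(_T12_CYCLE)] for j in range(val)]
            per_cat = ((cat, picks.count(cat)) for cat in _CATS)
        for category, count in per_cat:
            for _ in range(count):
                records.append(
                    _fixture_record(idx, category, table.axes, key, smqd_cycle)
                )
                idx += 1
                if category is MqrcCategory.SMQD:
                    smqd_cycle += 1
    assert len(records) == table.grand_total
    return records


def paper_fixture(name: str, seed: int = 0) -> list[IcsrRecord]:
    """Named exact-count fixture: table3|table4|table8|table10|table11|table12."""
    tables = fixture_tables()
    if name not in tables:
        raise KeyError(f"unknown fixture {name!r}; one of {sorted(tables)}")
    return fixture_from_counts(tables[name], seed=seed)


# ---------------------------------------------------------------------------
# Configurable generator
# ---------------------------------------------------------------------------

def _cond(counts: Mapping, totals=CATEGORY_TOTALS) -> dict[str, dict[str, float]]:
    """Per-category conditional distribution from a (SMQD,STF,SADR) table."""
    out: dict[str, dict[str, float]] = {}
    for i, cat in enumerate(_CATS):
        col = {key: val[i] / totals[i] for key, val in counts.items() if val[i]}
        out[cat.value] = col
    return out


def _sector_level_marginals():
    sector: dict[str, list[int]] = {}
    level: dict[str, list[int]] = {}
    for (sec, lev), val in TABLE8_COUNTS.items():
        sector.setdefault(sec, [0, 0, 0])
        level.setdefault(lev, [0, 0, 0])
        for i in range(3):
            sector[sec][i] += val[i]
            level[lev][i] += val[i]
    return (
        {k: tuple(v) for k, v in sector.items()},
        {k: tuple(v) for k, v in level.items()},
    )


def default_axis_distributions() -> dict:
    """Per-axis sampling distributions conditional on category.

    Derived from the published one-axis marginal tables; the county axis
    is unconditional (keyed ``"*"``) over the named reporting counties,
    with the aggregated low-reporting mass spread as in the county fixture.
    """
    sector, level = _sector_level_marginals()
    county_totals: dict[str, int] = {}
    for county, per_year in TABLE12_NAMED_COUNTS.items():
        if county != COUNTY_NOT_INDICATED:
            county_totals[county] = sum(per_year)
    for (county, _), n in _spread_rest().items():
        county_totals[county] = county_totals.get(county, 0) + n
    named_total = sum(county_totals.values())
    return {
        "therapeutic_class": _cond(TABLE4_COUNTS),
        "medicine_version": _cond(TABLE3_COUNTS),
        "facility_sector": _cond(sector),
        "facility_level": _cond(level),
        "reporter_profession": _cond(TABLE10_COUNTS),
        "dosage_form": _cond(TABLE11_COUNTS),
        "county": {
            "*": {c: n / named_total for c, n in sorted(county_totals.items())}
        },
    }


@dataclasses.dataclass
class SyntheticConfig:
    """Distributions, injection rates and seed governing the generator.

    ``category_probs`` defaults to the published category mix
    (52.1% / 41.6% / 6.3%); ``annual_weights`` to the published annual
    report totals 2014–2021; ``missing_county_rate`` to the published
    share of reports without a county (9.1%). The injection rates
    (duplicates 5%, test rows 1%, out-of-window rows 2%) are exercise
    parameters for the preprocessing stage, not published quantities.
    """

    n_records: int = 1000
    category_probs: tuple[float, float, float] = (0.521, 0.416, 0.063)
    axis_distributions: Optional[dict] = None
    duplicate_rate: float = 0.05
    test_rate: float = 0.01
    missing_county_rate: float = 0.091
    out_of_window_rate: float = 0.02
    annual_weights: tuple[float, ...] = (115, 207, 369, 327, 476, 571, 451, 251)
    seed: int = 0

    def __post_init__(self):
        if self.n_records < 0:
            raise ValueError("n_records must be nonnegative")
        self._check_probs("category_probs", self.category_probs)
        for name in ("duplicate_rate", "test_rate", "missing_county_rate",
                     "out_of_window_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if len(self.annual_weights) != len(_YEARS):
            raise ValueError(f"annual_weights must have {len(_YEARS)} entries")
        if any(w < 0 for w in self.annual_weights) or sum(self.annual_weights) <= 0:
            raise ValueError("annual_weights must be nonnegative with positive sum")
        dists = self.axis_distributions or default_axis_distributions()
        for axis, per_cat in dists.items():
            for key, dist in per_cat.items():
                self._check_probs(f"{axis}[{key}]", tuple(dist.values()))
        self._dists = dists

    @staticmethod
    def _check_probs(name: str, probs: tuple[float, ...]) -> None:
        if any(p < 0 for p in probs):
            raise ValueError(f"{name} has a negative probability")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError(f"{name} must sum to 1, got {sum(probs)!r}")


@dataclasses.dataclass
class InjectionLedger:
    """What the generator injected, for exact downstream oracles."""

    intended_category: dict[str, MqrcCategory]
    duplicate_ids: list[str]
    duplicate_source_ids: list[str]
    test_ids: list[str]
    out_of_window_ids: list[str]


def _sample_axis(rng, cats: np.ndarray, per_cat: Mapping, n: int) -> list[str]:
    out = [""] * n
    if "*" in per_cat:
        values = list(per_cat["*"])
        probs = np.array([per_cat["*"][v] for v in values])
        idx = rng.choice(len(values), size=n, p=probs / probs.sum())
        return [values[i] for i in idx]
    for ci, cat in enumerate(_CATS):
        dist = per_cat[cat.value]
        values = list(dist)
        probs = np.array([dist[v] for v in values])
        rows = np.flatnonzero(cats == ci)
        if rows.size:
            idx = rng.choice(len(values), size=rows.size, p=probs / probs.sum())
            for r, i in zip(rows, idx):
                out[r] = values[i]
    return out


def generate_with_ledger(
    config: SyntheticConfig,
) -> tuple[list[IcsrRecord], InjectionLedger]:
    """Generate a synthetic cohort plus the injection ledger.

    Output is deterministic for a given config (integer-sequence-based
    sampling, no locale dependence): the same seed yields byte-identical
    CSV output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_records
    dists = config._dists
    cats = rng.choice(3, size=n, p=np.asarray(config.category_probs, dtype=float))
    weights = np.asarray(config.annual_weights, dtype=float)
    year_idx = rng.choice(len(_YEARS), size=n, p=weights / weights.sum())
    day_frac = rng.random(n)
    missing_county = rng.random(n) < config.missing_county_rate

    axis_values = {
        axis: _sample_axis(rng, cats, per_cat, n) for axis, per_cat in dists.items()
    }

    records: list[IcsrRecord] = []
    intended: dict[str, MqrcCategory] = {}
    for i in range(n):
        category = _CATS[int(cats[i])]
        year = _YEARS[int(year_idx[i])]
        days = (datetime.date(year, 12, 31) - datetime.date(year, 1, 1)).days + 1
        report_date = datetime.date(year, 1, 1) + datetime.timedelta(
            days=int(day_frac[i] * days)
        )
        tclass = TherapeuticClass(
            axis_values.get("therapeutic_class", ["other_therapeutic_products"] * n)[i]
        )
        form = DosageForm(axis_values.get("dosage_form", ["tablet"] * n)[i])
        version = MedicineVersion(
            axis_values.get("medicine_version", ["generic"] * n)[i]
        )
        county = (
            COUNTY_NOT_INDICATED
            if missing_county[i]
            else axis_values.get("county", [COUNTY_NOT_INDICATED] * n)[i]
        )
        if category is MqrcCategory.SMQD:
            text = _smqd_text(form, i)
            rtype = (
                ReportType.DEVICE_INCIDENT
                if form is DosageForm.MEDICAL_DEVICE
                else ReportType.SPQM
            )
        elif category is MqrcCategory.STF:
            text, rtype = _STF_TEXT, ReportType.SPQM
        else:
            text, rtype = _SADR_TEXT, ReportType.SADR
        rid = f"S{i:07d}"
        intended[rid] = category
        records.append(
            IcsrRecord(
                report_id=rid,
                report_date=report_date,
                report_type=rtype,
                trade_name=(
                    f"BRAND-{tclass.value}" if version is MedicineVersion.BRANDED else ""
                ),
                api_names=[f"{tclass.value}-api"],
                medicine_version=version,
                therapeutic_class=tclass,
                dosage_form=form,
                route=_ROUTE_FOR_FORM[form],
                facility_sector=FacilitySector(
                    axis_values.get("facility_sector", ["unknown"] * n)[i]
                ),
                facility_level=FacilityLevel(
                    axis_values.get("facility_level", ["unknown"] * n)[i]
                ),
                reporter_profession=ReporterProfession(
                    axis_values.get("reporter_profession", ["not_stated"] * n)[i]
                ),
                county=county,
                complaint_text=text,
                patient_key=f"PT{i:07d}",
            )
        )

    next_id = n
    duplicate_ids, duplicate_source_ids = [], []
    n_dup = round(config.duplicate_rate * n)
    if n_dup and n:
        sources = rng.choice(n, size=n_dup, replace=n_dup > n)
        for s in sources:
            src = records[int(s)]
            rid = f"S{next_id:07d}"
            next_id += 1
            records.append(dataclasses.replace(src, report_id=rid))
            duplicate_ids.append(rid)
            duplicate_source_ids.append(src.report_id)

    test_ids = []
    for _ in range(round(config.test_rate * n)):
        rid = f"S{next_id:07d}"
        next_id += 1
        test_ids.append(rid)
        records.append(
            IcsrRecord(
                report_id=rid,
                report_date=WINDOW_START,
                report_type=ReportType.SPQM,
                api_names=["validation-api"],
                complaint_text="Test entry created during system validation.",
                patient_key=f"PT{rid}",
                is_test_entry=True,
            )
        )

    oow_ids = []
    for j in range(round(config.out_of_window_rate * n)):
        rid = f"S{next_id:07d}"
        next_id += 1
        oow_ids.append(rid)
        when = (
            WINDOW_START - datetime.timedelta(days=1 + j)
            if j % 2 == 0
            else WINDOW_END + datetime.timedelta(days=1 + j)
        )
        records.append(
            IcsrRecord(
                report_id=rid,
                report_date=when,
                report_type=ReportType.SPQM,
                api_names=["late-api"],
                complaint_text=_smqd_text(DosageForm.TABLET, j),
                dosage_form=DosageForm.TABLET,
                route=Route.ORAL,
                patient_key=f"PT{rid}",
            )
        )

    ledger = InjectionLedger(
        intended_category=intended,
        duplicate_ids=duplicate_ids,
        duplicate_source_ids=duplicate_source_ids,
        test_ids=test_ids,
        out_of_window_ids=oow_ids,
    )
    return records, ledger


def generate(config: SyntheticConfig) -> list[IcsrRecord]:
    """Generate a synthetic cohort (see :func:`generate_with_ledger`)."""
    return generate_with_ledger(config)[0]


# ---------------------------------------------------------------------------
# Self-validation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ValidationReport:
    ok: bool
    n_checked: int
    violations: list[str]


def validate_synthetic(
    records: Iterable[IcsrRecord],
    config: SyntheticConfig,
) -> ValidationReport:
    """Check empirical frequencies against the configured distributions.

    Test and out-of-window injections are dropped and duplicates collapsed
    first; every configured category and axis-value frequency must lie
    within 3 binomial standard errors of its target. Violations are listed,
    never raised.
    """
    from .classify import categorize_cohort
    from .preprocess import preprocess

    kept, _ = preprocess(list(records))
    classified, counts = categorize_cohort(kept)
    m = len(classified)
    violations: list[str] = []
    if m == 0:
        return ValidationReport(ok=False, n_checked=0, violations=["empty cohort"])

    def check(label: str, observed: float, expected: float) -> None:
        se = math.sqrt(max(expected * (1 - expected), 1e-12) / m)
        if abs(observed - expected) > 3 * se:
            violations.append(
                f"{label}: observed {observed:.4f}, expected {expected:.4f} "
                f"(3 SE = {3 * se:.4f})"
            )

    for cat, p in zip(_CATS, config.category_probs):
        check(f"category {cat.value}", counts.get(cat, 0) / m, p)

    from .reporting import AXES

    cat_probs = dict(zip((c.value for c in _CATS), config.category_probs))
    for axis, per_cat in config._dists.items():
        if axis == "county":
            continue  # modified by missing_county_rate; checked via category mix
        getter = AXES[axis]
        observed_counts: dict[str, int] = {}
        for cr in classified:
            v = getter(cr.record)
            observed_counts[v] = observed_counts.get(v, 0) + 1
        values = set()
        for dist in per_cat.values():
            values.update(dist)
        for v in sorted(values):
            if "*" in per_cat:
                expected = per_cat["*"].get(v, 0.0)
            else:
                expected = sum(
                    cat_probs[cv] * dist.get(v, 0.0) for cv, dist in per_cat.items()
                )
            check(f"{axis}={v}", observed_counts.get(v, 0) / m, expected)

    return ValidationReport(ok=not violations, n_checked=m, violations=violations)
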