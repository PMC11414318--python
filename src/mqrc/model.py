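"""Record schema, controlled vocabularies and CSV I/O for individual case
safety reports (ICSRs).

An ICSR is one spontaneous notification of a suspected medicine problem
submitted to a national pharmacovigilance database. The schema here mirrors
the fields such a system captures: the product (trade name, active
pharmaceutical ingredients, branded/generic status, therapeutic class,
dosage form, route), the reporting facility (sector and level within the
health system), the reporter's profession, the county of origin, a free-text
complaint description, and an opaque patient key used only for duplicate
detection.

All categorical fields are closed vocabularies. Blank or unparseable cells
map to an explicit ``unknown``/``not_stated`` member rather than a null,
because downstream tables report those strata as real rows. Dates are
ISO-8601 (``YYYY-MM-DD``) in files.
"""
from __future__ import annotations

import csv
import dataclasses
import datetime
import enum
import json
from collections import Counter
from pathlib import Path
from typing import Iterable, Optional, Sequence


# ---------------------------------------------------------------------------
# Controlled vocabularies
# ---------------------------------------------------------------------------

class ReportType(enum.Enum):
    """How the report was notified to the database."""

    SADR = "sADR"
    SPQM = "sPQM"
    MEDICATION_ERROR = "medication_error"
    DEVICE_INCIDENT = "device_incident"
    AEFI = "AEFI"
    BLOOD_PRODUCT_REACTION = "blood_product_reaction"


class MedicineVersion(enum.Enum):
    BRANDED = "branded"
    GENERIC = "generic"
    UNSTATED = "unstated"


class TherapeuticClass(enum.Enum):
    ANTINEOPLASTICS = "antineoplastics"
    ANTIVIRALS = "antivirals"
    ANTIBACTERIALS = "antibacterials"
    ANALGESICS = "analgesics"
    ANTIHYPERTENSIVES = "antihypertensives"
    MEDICAL_DEVICES = "medical_devices"
    ANTIPROTOZOALS = "antiprotozoals"
    GYNAECOLOGICAL = "gynaecological"
    ANTIMYCOBACTERIAL = "antimycobacterial"
    BLOOD_PERFUSION_SOLUTIONS = "blood_perfusion_solutions"
    ANAESTHETICS = "anaesthetics"
    MINERALS_VITAMINS = "minerals_vitamins"
    DIABETES_DRUGS = "diabetes_drugs"
    VACCINES = "vaccines"
    OTHER = "other_therapeutic_products"


class DosageForm(enum.Enum):
    TABLET = "tablet"
    INJECTION = "injection"
    ORAL_LIQUID = "oral_liquid"
    MEDICAL_DEVICE = "medical_device"
    CAPSULE = "capsule"
    DERMAL_IMPLANT = "dermal_implant"
    OTHER = "other"


class Route(enum.Enum):
    ORAL = "oral"
    PARENTERAL = "parenteral"
    TOPICAL = "topical"
    OTHER = "other"
    NOT_APPLICABLE = "not_applicable"


class FacilitySector(enum.Enum):
    GOVERNMENT = "government"
    PRIVATE_FOR_PROFIT = "private_for_profit"
    NOT_FOR_PROFIT = "not_for_profit"
    INFORMAL_UNLICENSED = "informal_unlicensed"
    UNKNOWN = "unknown"


class FacilityLevel(enum.Enum):
    HOSPITAL = "hospital"
    DISPENSARY_CLINIC_HEALTH_CENTRE = "dispensary_clinic_health_centre"
    PHARMACY_CHEMIST = "pharmacy_chemist"
    IMPORTER_DISTRIBUTOR_WHOLESALER = "importer_distributor_wholesaler"
    INDIVIDUAL = "individual"
    RESEARCH_INSTITUTION = "research_institution"
    UNKNOWN = "unknown"


class ReporterProfession(enum.Enum):
    PHARMACIST = "pharmacist"
    MEDICAL_DOCTOR = "medical_doctor"
    PHARMACEUTICAL_TECHNICIAN = "pharmaceutical_technician"
    OTHER_HCP = "other_hcp"
    NOT_STATED = "not_stated"


class MqrcCategory(enum.Enum):
    """The three-way medicine quality-related complaint class.

    SMQD — suspected medicine quality defect (an observable physical,
    packaging or labelling defect); STF — suspected therapeutic failure
    attributed to poor quality; SADR — suspected adverse drug reaction
    attributed to poor quality. The categories partition the complaint
    cohort: every complaint record belongs to exactly one.
    """

    SMQD = "SMQD"
    STF = "STF"
    SADR = "SADR"


#: The 47 Kenyan counties, plus the explicit "Not Indicated" member used when
#: the report does not state its county of origin.
KENYAN_COUNTIES: tuple[str, ...] = (
    "Baringo", "Bomet", "Bungoma", "Busia", "Elgeyo-Marakwet", "Embu",
    "Garissa", "Homa Bay", "Isiolo", "Kajiado", "Kakamega", "Kericho",
    "Kiambu", "Kilifi", "Kirinyaga", "Kisii", "Kisumu", "Kitui", "Kwale",
    "Laikipia", "Lamu", "Machakos", "Makueni", "Mandera", "Marsabit",
    "Meru", "Migori", "Mombasa", "Murang'a", "Nairobi", "Nakuru", "Nandi",
    "Narok", "Nyamira", "Nyandarua", "Nyeri", "Samburu", "Siaya",
    "Taita-Taveta", "Tana River", "Tharaka-Nithi", "Trans-Nzoia", "Turkana",
    "Uasin Gishu", "Vihiga", "Wajir", "West Pokot",
)

COUNTY_NOT_INDICATED = "Not Indicated"

COUNTY_VOCABULARY: tuple[str, ...] = KENYAN_COUNTIES + (COUNTY_NOT_INDICATED,)


def _norm_token(raw: str) -> str:
    return (
        raw.strip()
        .casefold()
        .replace("-", "_")
        .replace(" ", "_")
        .replace("'", "")
        .replace("/", "_")
    )


_COUNTY_LOOKUP = {_norm_token(c): c for c in COUNTY_VOCABULARY}

#: Fallback member used when a categorical cell is blank or unparseable.
ENUM_FALLBACKS = {
    MedicineVersion: MedicineVersion.UNSTATED,
    TherapeuticClass: TherapeuticClass.OTHER,
    DosageForm: DosageForm.OTHER,
    Route: Route.OTHER,
    FacilitySector: FacilitySector.UNKNOWN,
    FacilityLevel: FacilityLevel.UNKNOWN,
    ReporterProfession: ReporterProfession.NOT_STATED,
}


# ---------------------------------------------------------------------------
# Record
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class IcsrRecord:
    """One individual case safety report.

    ``trade_name`` and ``api_names`` are free text (empty when absent);
    every other categorical field holds a declared vocabulary member.
    ``extras`` preserves unknown CSV columns opaquely so that a file can be
    round-tripped without loss.
    """

    report_id: str
    report_date: datetime.date
    report_type: ReportType
    trade_name: str = ""
    api_names: list[str] = dataclasses.field(default_factory=list)
    medicine_version: MedicineVersion = MedicineVersion.UNSTATED
    therapeutic_class: TherapeuticClass = TherapeuticClass.OTHER
    specific_product: str = ""
    dosage_form: DosageForm = DosageForm.OTHER
    route: Route = Route.OTHER
    facility_sector: FacilitySector = FacilitySector.UNKNOWN
    facility_level: FacilityLevel = FacilityLevel.UNKNOWN
    reporter_profession: ReporterProfession = ReporterProfession.NOT_STATED
    county: str = COUNTY_NOT_INDICATED
    complaint_text: str = ""
    patient_key: str = ""
    is_test_entry: bool = False
    extras: dict[str, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.county not in COUNTY_VOCABULARY:
            raise ValueError(
                f"county {self.county!r} is not one of the 47 Kenyan counties "
                f"or {COUNTY_NOT_INDICATED!r}"
            )

    def has_product_identity(self) -> bool:
        """True when the report names either a trade name or ≥1 API."""
        return bool(self.trade_name) or bool(self.api_names)

    def violations(self) -> list[str]:
        """Soft-invariant check: messages for any violated record invariant."""
        out = []
        if (
            self.medicine_version in (MedicineVersion.BRANDED, MedicineVersion.GENERIC)
            and not self.has_product_identity()
        ):
            out.append(
                f"{self.report_id}: branded/generic record lacks both "
                "trade_name and api_names"
            )
        return out


# ---------------------------------------------------------------------------
# CSV schema
# ---------------------------------------------------------------------------

#: Documented column order of the interchange CSV. ``api_names`` is a
#: semicolon-separated list; ``is_test_entry`` is "true"/"false".
CSV_COLUMNS: tuple[str, ...] = (
    "report_id", "report_date", "report_type", "trade_name", "api_names",
    "medicine_version", "therapeutic_class", "specific_product",
    "dosage_form", "route", "facility_sector", "facility_level",
    "reporter_profession", "county", "complaint_text", "patient_key",
    "is_test_entry",
)

_ENUM_FIELDS = {
    "report_type": ReportType,
    "medicine_version": MedicineVersion,
    "therapeutic_class": TherapeuticClass,
    "dosage_form": DosageForm,
    "route": Route,
    "facility_sector": FacilitySector,
    "facility_level": FacilityLevel,
    "reporter_profession": ReporterProfession,
}


class SchemaError(ValueError):
    """The CSV header does not match the documented schema."""


@dataclasses.dataclass
class ParseReport:
    """Accounting of what happened while reading a CSV file."""

    n_rows: int = 0
    n_records: int = 0
    n_skipped: int = 0
    skipped: list[tuple[int, str]] = dataclasses.field(default_factory=list)
    coercions: Counter = dataclasses.field(default_factory=Counter)

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_records": self.n_records,
            "n_skipped": self.n_skipped,
            "skipped": [list(s) for s in self.skipped],
            "coercions": dict(self.coercions),
        }


class _RowSkip(Exception):
    pass


def _parse_enum(cls, raw: str, field: str, report: ParseReport):
    """Case-insensitive enum parse with fallback-member coercion."""
    token = _norm_token(raw)
    if not token:
        return ENUM_FALLBACKS[cls]
    for member in cls:
        if token in (_norm_token(member.value), _norm_token(member.name)):
            return member
    fallback = ENUM_FALLBACKS.get(cls)
    if fallback is None:
        # report_type declares no unknown member; treat like a bad date
        raise _RowSkip(f"unparseable {field} {raw!r}")
    report.coercions[field] += 1
    return fallback


def _parse_county(raw: str, report: ParseReport) -> str:
    token = _norm_token(raw)
    if not token:
        return COUNTY_NOT_INDICATED
    hit = _COUNTY_LOOKUP.get(token)
    if hit is None:
        # near-miss spellings are reported, not auto-corrected
        report.coercions["county"] += 1
        return COUNTY_NOT_INDICATED
    return hit


def _parse_bool(raw: str) -> bool:
    return raw.strip().casefold() in ("true", "1", "yes")


def read_icsr_csv(
    path: str | Path,
    dialect: str = "excel",
    **fmtparams,
) -> tuple[list[IcsrRecord], ParseReport]:
    """Read ICSR records from a CSV file.

    Returns the parsed records in file order together with a
    :class:`ParseReport` counting skipped rows (unparseable dates or report
    types) and coerced categorical cells. Unknown columns are preserved in
    each record's ``extras``. A missing mandatory column raises
    :class:`SchemaError` naming the column.
    """
    path = Path(path)
    report = ParseReport()
    records: list[IcsrRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, dialect=dialect, **fmtparams)
        header = reader.fieldnames or []
        missing = [c for c in CSV_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
        extra_cols = [c for c in header if c not in CSV_COLUMNS]
        for lineno, row in enumerate(reader, start=2):
            report.n_rows += 1
            try:
                records.append(_parse_row(row, extra_cols, report))
                report.n_records += 1
            except _RowSkip as exc:
                report.n_skipped += 1
                report.skipped.append((lineno, str(exc)))
    return records, report


def _parse_row(row: dict, extra_cols: Sequence[str], report: ParseReport) -> IcsrRecord:
    raw_date = (row.get("report_date") or "").strip()
    try:
        report_date = datetime.date.fromisoformat(raw_date)
    except ValueError:
        raise _RowSkip(f"unparseable date {raw_date!r}") from None
    kwargs = {
        "report_id": (row.get("report_id") or "").strip(),
        "report_date": report_date,
        "trade_name": row.get("trade_name") or "",
        "api_names": [
            s.strip() for s in (row.get("api_names") or "").split(";") if s.strip()
        ],
        "specific_product": (row.get("specific_product") or "").strip(),
        "county": _parse_county(row.get("county") or "", report),
        "complaint_text": row.get("complaint_text") or "",
        "patient_key": (row.get("patient_key") or "").strip(),
        "is_test_entry": _parse_bool(row.get("is_test_entry") or ""),
        # empty extra cells are treated as absent so mixed-extras files round-trip
        "extras": {c: row[c] for c in extra_cols if row.get(c)},
    }
    for field, cls in _ENUM_FIELDS.items():
        kwargs[field] = _parse_enum(cls, row.get(field) or "", field, report)
    return IcsrRecord(**kwargs)


def write_icsr_csv(records: Iterable[IcsrRecord], path: str | Path) -> None:
    """Write records to CSV in the documented column order.

    Round-trips exactly: ``read_icsr_csv(write_icsr_csv(x)) == x``
    field-for-field. Extra columns carried in ``extras`` are appended after
    the schema columns (union over all records, in first-seen order).
    """
    records = list(records)
    extra_cols: list[str] = []
    for rec in records:
        for c in rec.extras:
            if c not in extra_cols:
                extra_cols.append(c)
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(CSV_COLUMNS) + extra_cols)
        for rec in records:
            writer.writerow(
                [
                    rec.report_id,
                    rec.report_date.isoformat(),
                    rec.report_type.value,
                    rec.trade_name,
                    ";".join(rec.api_names),
                    rec.medicine_version.value,
                    rec.therapeutic_class.value,
                    rec.specific_product,
                    rec.dosage_form.value,
                    rec.route.value,
                    rec.facility_sector.value,
                    rec.facility_level.value,
                    rec.reporter_profession.value,
                    rec.county,
                    rec.complaint_text,
                    rec.patient_key,
                    "true" if rec.is_test_entry else "false",
                ]
                + [rec.extras.get(c, "") for c in extra_cols]
            )


def schema_dict() -> dict:
    """Machine-readable description of the interchange CSV schema."""
    vocab = {
        field: [m.value for m in cls] for field, cls in _ENUM_FIELDS.items()
    }
    vocab["county"] = list(COUNTY_VOCABULARY)
    return {
        "format": "mqrc-icsr-csv",
        "version": 1,
        "encoding": "utf-8",
        "columns": list(CSV_COLUMNS),
        "date_format": "YYYY-MM-DD",
        "list_separator": ";",
        "vocabularies": vocab,
    }


def write_schema_json(path: str | Path) -> None:
    Path(path).write_text(json.dumps(schema_dict(), indent=2) + "\n")
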