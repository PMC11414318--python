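"""Data preparation for complaint analysis: redaction, duplicate
elimination, the study-window filter, test-entry exclusion, and the
product-identity completeness requirement.

The preparation mirrors how a national spontaneous-report dataset is cleaned
before analysis. Duplicates are collapsed on the composite key (product
name, report type, county, report date, patient key); the surviving record
is the one with the lowest report id, an arbitrary but deterministic rule.
General inclusion requires a report date inside the study window (both ends
inclusive), at least one of trade name / API names (medical-device reports
are exempt), and that the entry is not a system-validation "Test" row.
Exclusion reasons are counted with fixed precedence test > window >
missing-product so each record is counted exactly once.
"""
from __future__ import annotations

import dataclasses
import datetime
import hashlib
import hmac
import re
from typing import Iterable

from .model import DosageForm, IcsrRecord

#: Default study window: 1 January 2014 – 31 December 2021, inclusive.
WINDOW_START = datetime.date(2014, 1, 1)
WINDOW_END = datetime.date(2021, 12, 31)

_TEST_WORD = re.compile(r"\btest\b", re.IGNORECASE)


@dataclasses.dataclass
class PreprocessReport:
    """Flow accounting for one preprocessing pass.

    Invariant: ``n_retained == n_input - n_duplicates_removed -
    n_test_removed - n_out_of_window - n_missing_product``.
    """

    n_input: int = 0
    n_duplicates_removed: int = 0
    n_test_removed: int = 0
    n_out_of_window: int = 0
    n_missing_product: int = 0
    n_retained: int = 0

    def check(self) -> None:
        expect = (
            self.n_input
            - self.n_duplicates_removed
            - self.n_test_removed
            - self.n_out_of_window
            - self.n_missing_product
        )
        if self.n_retained != expect:
            raise AssertionError(
                f"flow accounting broken: retained {self.n_retained} != {expect}"
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _token(value: str, salt: str) -> str:
    return hmac.new(salt.encode(), value.encode(), hashlib.sha256).hexdigest()[:16]


def redact(record: IcsrRecord, salt: str) -> IcsrRecord:
    """Replace identifying fields with stable keyed hash tokens.

    ``trade_name`` and ``patient_key`` become HMAC-SHA256 tokens keyed by
    ``salt``; all analytic fields are untouched. The same input value under
    the same salt always yields the same token, so joins and duplicate
    detection still work on redacted data. Empty fields stay empty.
    """
    return dataclasses.replace(
        record,
        trade_name=_token(record.trade_name, salt) if record.trade_name else "",
        patient_key=_token(record.patient_key, salt) if record.patient_key else "",
    )


def product_name_key(record: IcsrRecord) -> str:
    """Normalised product identity: trade name if present, else sorted APIs."""
    if record.trade_name:
        return record.trade_name.strip().casefold()
    return ";".join(sorted(a.strip().casefold() for a in record.api_names))


def dedup_key(record: IcsrRecord) -> tuple:
    return (
        product_name_key(record),
        record.report_type,
        record.county,
        record.report_date,
        record.patient_key,
    )


def deduplicate(
    records: Iterable[IcsrRecord],
) -> tuple[list[IcsrRecord], PreprocessReport]:
    """Collapse records sharing the composite duplicate key.

    The survivor of each duplicate group is the record with the lowest
    ``report_id``. Output preserves the input order of survivors. The
    operation is idempotent.
    """
    records = list(records)
    survivor: dict[tuple, IcsrRecord] = {}
    for rec in records:
        key = dedup_key(rec)
        cur = survivor.get(key)
        if cur is None or rec.report_id < cur.report_id:
            survivor[key] = rec
    keep_ids = {id(rec) for rec in survivor.values()}
    kept = [rec for rec in records if id(rec) in keep_ids]
    report = PreprocessReport(
        n_input=len(records),
        n_duplicates_removed=len(records) - len(kept),
        n_retained=len(kept),
    )
    report.check()
    return kept, report


def is_test_entry(record: IcsrRecord) -> bool:
    """Flagged test rows, or a whole-word 'Test' in the complaint text."""
    return record.is_test_entry or bool(_TEST_WORD.search(record.complaint_text))


def apply_general_criteria(
    records: Iterable[IcsrRecord],
    window_start: datetime.date = WINDOW_START,
    window_end: datetime.date = WINDOW_END,
) -> tuple[list[IcsrRecord], PreprocessReport]:
    """Apply the general inclusion criteria.

    Retains records dated within ``[window_start, window_end]`` (inclusive),
    with at least one of trade name / API names (medical-device reports
    exempt), and not marked as test entries. Exclusion counts use the fixed
    precedence test > window > missing-product.
    """
    if window_start > window_end:
        raise ValueError(f"inverted window: {window_start} > {window_end}")
    records = list(records)
    kept: list[IcsrRecord] = []
    report = PreprocessReport(n_input=len(records))
    for rec in records:
        if is_test_entry(rec):
            report.n_test_removed += 1
        elif not (window_start <= rec.report_date <= window_end):
            report.n_out_of_window += 1
        elif not (
            rec.has_product_identity()
            or rec.dosage_form is DosageForm.MEDICAL_DEVICE
        ):
            report.n_missing_product += 1
        else:
            kept.append(rec)
    report.n_retained = len(kept)
    report.check()
    return kept, report


def preprocess(
    records: Iterable[IcsrRecord],
    window_start: datetime.date = WINDOW_START,
    window_end: datetime.date = WINDOW_END,
    salt: str | None = None,
) -> tuple[list[IcsrRecord], PreprocessReport]:
    """Full preparation pass: optional redaction, dedup, general criteria."""
    records = list(records)
    if salt is not None:
        records = [redact(r, salt) for r in records]
    deduped, dedup_report = deduplicate(records)
    kept, crit_report = apply_general_criteria(deduped, window_start, window_end)
    report = PreprocessReport(
        n_input=dedup_report.n_input,
        n_duplicates_removed=dedup_report.n_duplicates_removed,
        n_test_removed=crit_report.n_test_removed,
        n_out_of_window=crit_report.n_out_of_window,
        n_missing_product=crit_report.n_missing_product,
        n_retained=crit_report.n_retained,
    )
    report.check()
    return kept, report
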