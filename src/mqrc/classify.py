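"""Three-way complaint categorization.

Every retained complaint record is assigned exactly one category:

* ``SMQD`` — suspected medicine quality defect: an observable physical,
  packaging or labelling defect, detected either by a declared quality
  issue on the report or by a defect-term lexicon match against the
  free-text complaint;
* ``STF`` — suspected therapeutic failure: the report notifies perceived
  inefficacy attributed to suspected poor quality;
* ``SADR`` — suspected adverse drug reaction attributed to poor quality:
  an adverse-reaction report where poor product quality is suspected.

Categories are mutually exclusive. For records carrying more than one cue
the precedence is STF > SADR > SMQD: how the report was notified is treated
as stronger evidence than a text match. Records matching no cue are not
medicine quality-related complaints and are excluded.

The defect lexicon is a closed list of controlled terms (caking, capping,
leakage, mislabelling, powdering, ...), each restricted to the dosage forms
it can physically occur in and carrying ≥3 case-insensitive trigger
phrases. It ships as a versioned, editable JSON config.
"""
from __future__ import annotations

import dataclasses
import enum
import json
from collections import Counter
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

from .model import DosageForm, IcsrRecord, MqrcCategory, ReportType

_CAUSE_CLASSES = {"poor_manufacturing_practice", "environmental_degradation", "both"}

#: Phrases marking a report notified as a suspected therapeutic failure.
TF_PHRASES: tuple[str, ...] = (
    "therapeutic failure",
    "treatment failure",
    "no therapeutic effect",
    "not effective",
    "lack of efficacy",
    "no improvement",
    "failed to achieve the expected",
)

#: Phrases marking that poor quality is suspected / a quality issue declared.
QUALITY_SUSPECT_PHRASES: tuple[str, ...] = (
    "suspected poor quality",
    "poor quality suspected",
    "suspected substandard",
    "quality issue declared",
)


@dataclasses.dataclass(frozen=True)
class DefectTerm:
    """One controlled defect term of the quality-defect lexicon."""

    name: str
    applicable_forms: frozenset[str]  # dosage_form values, or {"all"}
    cause_class: str
    synonyms: tuple[str, ...]

    def __post_init__(self):
        if not self.synonyms:
            raise ValueError(f"defect term {self.name!r} has no trigger phrase")
        if self.cause_class not in _CAUSE_CLASSES:
            raise ValueError(f"unknown cause_class {self.cause_class!r}")

    def applies_to(self, form: DosageForm) -> bool:
        return "all" in self.applicable_forms or form.value in self.applicable_forms


def load_lexicon(path: str | Path | None = None) -> list[DefectTerm]:
    """Load the defect-term lexicon (packaged default, or a custom file)."""
    if path is None:
        raw = (
            resources.files("mqrc").joinpath("data/defect_lexicon.json").read_text()
        )
    else:
        raw = Path(path).read_text()
    doc = json.loads(raw)
    terms = [
        DefectTerm(
            name=t["name"],
            applicable_forms=frozenset(t["applicable_forms"]),
            cause_class=t["cause_class"],
            synonyms=tuple(t["synonyms"]),
        )
        for t in doc["terms"]
    ]
    names = [t.name for t in terms]
    if len(names) != len(set(names)):
        raise ValueError("duplicate defect-term names in lexicon")
    return terms


_DEFAULT_LEXICON: list[DefectTerm] | None = None


def default_lexicon() -> list[DefectTerm]:
    global _DEFAULT_LEXICON
    if _DEFAULT_LEXICON is None:
        _DEFAULT_LEXICON = load_lexicon()
    return _DEFAULT_LEXICON


def match_defect_terms(
    text: str,
    dosage_form: DosageForm,
    lexicon: Iterable[DefectTerm] | None = None,
) -> list[str]:
    """Names of every lexicon term triggered by the complaint text.

    A term matches when at least one of its trigger phrases occurs
    (case-insensitively) in ``text`` and the term applies to the record's
    dosage form. Result order is lexicon order, so it is deterministic.
    """
    lexicon = default_lexicon() if lexicon is None else list(lexicon)
    folded = text.casefold()
    return [
        term.name
        for term in lexicon
        if term.applies_to(dosage_form)
        and any(syn.casefold() in folded for syn in term.synonyms)
    ]


def _contains_any(text: str, phrases: Iterable[str]) -> bool:
    folded = text.casefold()
    return any(p.casefold() in folded for p in phrases)


class Rationale(enum.Enum):
    """Which rule assigned the category."""

    REPORT_TYPE_TF = "report_type_tf"
    REPORT_TYPE_ADR = "report_type_adr"
    DEFECT_LEXICON = "defect_lexicon"
    DEFECT_DECLARED = "defect_declared"


@dataclasses.dataclass
class ClassifiedRecord:
    record: IcsrRecord
    category: MqrcCategory
    matched_terms: list[str]
    rationale: Rationale


def infer_declared_quality_issue(record: IcsrRecord) -> bool:
    """Default inference of the 'quality issue declared/suspected' flag.

    A suspected-poor-quality-medicine (sPQM) report type is itself a
    declaration; otherwise an explicit quality-suspicion phrase in the
    complaint text counts. The flag can always be supplied explicitly
    instead (its capture in real databases is system-specific).
    """
    return record.report_type is ReportType.SPQM or _contains_any(
        record.complaint_text, QUALITY_SUSPECT_PHRASES
    )


def assign_category(
    record: IcsrRecord,
    declared_quality_issue: Optional[bool] = None,
    lexicon: Iterable[DefectTerm] | None = None,
) -> Optional[ClassifiedRecord]:
    """Assign the record's complaint category, or None for non-complaints.

    Precedence for multiply-cued records:

    1. notified as therapeutic failure  -> STF
    2. adverse-reaction report with poor quality suspected -> SADR
    3. declared quality issue or ≥1 defect-lexicon match -> SMQD

    ``matched_terms`` always carries the lexicon matches, even when a
    higher-precedence rule decided the category.
    """
    if declared_quality_issue is None:
        declared_quality_issue = infer_declared_quality_issue(record)
    matched = match_defect_terms(record.complaint_text, record.dosage_form, lexicon)
    if _contains_any(record.complaint_text, TF_PHRASES):
        return ClassifiedRecord(record, MqrcCategory.STF, matched, Rationale.REPORT_TYPE_TF)
    if record.report_type is ReportType.SADR and declared_quality_issue:
        return ClassifiedRecord(record, MqrcCategory.SADR, matched, Rationale.REPORT_TYPE_ADR)
    if matched:
        return ClassifiedRecord(record, MqrcCategory.SMQD, matched, Rationale.DEFECT_LEXICON)
    if declared_quality_issue:
        return ClassifiedRecord(record, MqrcCategory.SMQD, [], Rationale.DEFECT_DECLARED)
    return None


def categorize_cohort(
    records: Iterable[IcsrRecord],
    lexicon: Iterable[DefectTerm] | None = None,
) -> tuple[list[ClassifiedRecord], dict[MqrcCategory, int]]:
    """Classify a preprocessed cohort.

    Returns the classified complaint records (non-complaints dropped) and
    the per-category counts, which always sum to the classified cohort
    size. Category frequencies are counts divided by that total.
    """
    lexicon = default_lexicon() if lexicon is None else list(lexicon)
    classified = []
    counts: Counter = Counter({cat: 0 for cat in MqrcCategory})
    for rec in records:
        cr = assign_category(rec, lexicon=lexicon)
        if cr is not None:
            classified.append(cr)
            counts[cr.category] += 1
    return classified, dict(counts)


def category_frequencies(
    counts: dict[MqrcCategory, int]
) -> dict[MqrcCategory, float]:
    """Per-category share of the complaint cohort (fractions, not %)."""
    total = sum(counts.values())
    if total == 0:
        return {cat: 0.0 for cat in MqrcCategory}
    return {cat: counts.get(cat, 0) / total for cat in MqrcCategory}
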