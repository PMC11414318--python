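import datetime

import pytest

from mqrc import (
    DosageForm,
    IcsrRecord,
    MedicineVersion,
    ReporterProfession,
    ReportType,
    Route,
    TherapeuticClass,
    categorize_cohort,
    paper_fixture,
    preprocess,
)


def make_record(report_id="R001", **kwargs):
    """A valid in-window record with sensible defaults for targeted edits."""
    defaults = dict(
        report_id=report_id,
        report_date=datetime.date(2018, 6, 15),
        report_type=ReportType.SPQM,
        trade_name="Acmecillin",
        api_names=["amoxicillin"],
        medicine_version=MedicineVersion.GENERIC,
        therapeutic_class=TherapeuticClass.ANTIBACTERIALS,
        dosage_form=DosageForm.TABLET,
        route=Route.ORAL,
        reporter_profession=ReporterProfession.PHARMACIST,
        county="Nairobi",
        complaint_text="Tablets arrived with broken tablets in the blister.",
        patient_key="P-0001",
    )
    defaults.update(kwargs)
    return IcsrRecord(**defaults)


def classified_fixture(name):
    records = paper_fixture(name)
    kept, report = preprocess(records)
    assert report.n_retained == len(records)
    classified, counts = categorize_cohort(kept)
    assert len(classified) == len(records)
    return classified, counts


@pytest.fixture(scope="session")
def table4_cohort():
    return classified_fixture("table4")


@pytest.fixture(scope="session")
def table8_cohort():
    return classified_fixture("table8")


@pytest.fixture(scope="session")
def table10_cohort():
    return classified_fixture("table10")


@pytest.fixture(scope="session")
def table11_cohort():
    return classified_fixture("table11")


@pytest.fixture(scope="session")
def table3_cohort():
    return classified_fixture("table3")


@pytest.fixture(scope="session")
def table12_cohort():
    return classified_fixture("table12")
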