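"""Reporting odds ratio, Wald CI, chi-square p and the signal rule."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mqrc import (
    ContingencyTable,
    DegenerateTableError,
    MqrcCategory,
    ZeroCell,
    analyze_table,
    build_contingency,
    chi_square_p,
    compute_ror,
    flag_signal,
    p_to_bucket,
)
from mqrc.classify import ClassifiedRecord, Rationale

from conftest import make_record

cells = st.integers(min_value=1, max_value=500)


# --- ROR and Wald CI -------------------------------------------------------

def test_ror_reproduces_published_medical_devices_row():
    r = compute_ror(ContingencyTable(108, 17, 1333, 1309))
    assert round(r.ror, 1) == 6.2
    assert round(r.ci_low, 2) == 3.72
    assert round(r.ci_high, 2) == 10.46
    assert r.zero_cell is ZeroCell.NONE


def test_balanced_table_gives_unit_ror():
    r = compute_ror(ContingencyTable(1, 1, 1, 1))
    assert r.ror == 1.0
    assert r.ci_low < 1.0 < r.ci_high


def test_zero_denominator_yields_infinite_ror_without_ci():
    r = compute_ror(ContingencyTable(5, 0, 100, 2000))
    assert math.isinf(r.ror)
    assert r.zero_cell is ZeroCell.DENOMINATOR_ZERO
    assert r.ci_low is None and r.ci_high is None


def test_zero_numerator_yields_zero_ror():
    r = compute_ror(ContingencyTable(0, 10, 100, 2000))
    assert r.ror == 0.0 and r.zero_cell is ZeroCell.NUMERATOR_ZERO


def test_doubly_degenerate_table_errors():
    with pytest.raises(DegenerateTableError):
        compute_ror(ContingencyTable(5, 0, 7, 0))


def test_haldane_anscombe_option_handles_zero_cells():
    r = compute_ror(ContingencyTable(5, 0, 100, 2000), continuity=True)
    assert math.isfinite(r.ror) and r.ci_low is not None


def test_invalid_cells_rejected():
    with pytest.raises(ValueError):
        ContingencyTable(-1, 2, 3, 4)


@settings(max_examples=100, deadline=None)
@given(a=cells, b=cells, c=cells, d=cells)
def test_reciprocity_swapping_categories_inverts_ror(a, b, c, d):
    t = ContingencyTable(a, b, c, d)
    assert compute_ror(t.swapped_categories()).ror == pytest.approx(
        1.0 / compute_ror(t).ror, rel=1e-12
    )


@settings(max_examples=100, deadline=None)
@given(a=cells, b=cells, c=cells, d=cells)
def test_monotonicity_in_a(a, b, c, d):
    t = ContingencyTable(a, b, c, d)
    bumped = ContingencyTable(a + 1, b, c, d)
    assert compute_ror(bumped).ror > compute_ror(t).ror


@settings(max_examples=50, deadline=None)
@given(a=cells, b=cells, c=cells, d=cells)
def test_wald_ci_matches_independent_epidemiology_oracle(a, b, c, d):
    statsmodels = pytest.importorskip("statsmodels.api")
    t = ContingencyTable(a, b, c, d)
    r = compute_ror(t)
    oracle = statsmodels.stats.Table2x2(
        np.array([[a, b], [c, d]]), shift_zeros=False
    )
    assert r.ror == pytest.approx(oracle.oddsratio, rel=1e-12)
    lo, hi = oracle.oddsratio_confint(alpha=0.05)
    assert r.ci_low == pytest.approx(lo, rel=1e-4)
    assert r.ci_high == pytest.approx(hi, rel=1e-4)


# --- chi-square ------------------------------------------------------------

def test_chi_square_independence_cases():
    assert chi_square_p(ContingencyTable(1, 1, 1, 1)) == (0.0, 1.0)
    chi2, _ = chi_square_p(ContingencyTable(50, 50, 50, 50))
    assert chi2 == 0.0


def test_chi_square_on_published_table_is_highly_significant():
    chi2, p = chi_square_p(ContingencyTable(558, 232, 593, 1384))
    assert p < 0.001 and chi2 > 0


def test_chi_square_matches_closed_formula():
    a, b, c, d = 23, 41, 57, 19
    n = a + b + c + d
    expect = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    chi2, _ = chi_square_p(ContingencyTable(a, b, c, d))
    assert chi2 == pytest.approx(expect, rel=1e-12)


def test_chi_square_zero_margin_errors():
    with pytest.raises(DegenerateTableError):
        chi_square_p(ContingencyTable(0, 0, 10, 20))


@settings(max_examples=100, deadline=None)
@given(a=cells, b=cells, c=cells, d=cells)
def test_chi_square_transposition_invariance(a, b, c, d):
    t = ContingencyTable(a, b, c, d)
    assert chi_square_p(t)[0] == pytest.approx(chi_square_p(t.transposed())[0], rel=1e-12)


# --- p-value buckets -------------------------------------------------------

@pytest.mark.parametrize(
    "p, bucket",
    [
        (0.0004, "<0.001"),
        (0.001, "0.002-0.001"),
        (0.003, "0.005-0.002"),
        (0.007, "0.01-0.005"),
        (0.015, "0.02-0.01"),
        (0.022, "0.025-0.02"),
        (0.03, "0.05-0.025"),
        (0.025, "0.05-0.025"),
        (0.07, "0.1-0.05"),
        (0.15, "0.2-0.1"),
        (0.5, "0.975-0.2"),
        (0.98, "0.995-0.975"),
        (0.999, ">0.995"),
        (1.0, ">0.995"),
    ],
)
def test_p_bucket_labels(p, bucket):
    assert p_to_bucket(p) == bucket


def test_p_bucket_rejects_out_of_range():
    with pytest.raises(ValueError):
        p_to_bucket(1.5)


# --- signal rule -----------------------------------------------------------

def test_signal_rule_threshold_and_alpha():
    strong = analyze_table(ContingencyTable(203, 25, 1238, 1301))
    assert round(strong.ror, 1) == 8.5 and strong.is_signal
    below_ror = analyze_table(ContingencyTable(120, 100, 100, 120))
    assert below_ror.ror < 2.0 and not below_ror.is_signal
    weak_p = analyze_table(ContingencyTable(6, 2, 10, 10))
    assert weak_p.ror >= 2.0 and weak_p.p_value >= 0.05 and not weak_p.is_signal


def test_infinite_ror_counts_as_above_threshold():
    r = compute_ror(ContingencyTable(40, 0, 100, 2000))
    r.chi2, r.p_value = chi_square_p(r.table)
    assert flag_signal(r)


# --- contingency construction ---------------------------------------------

def _mini_cohort():
    rows = [
        ("R1", "analgesics", MqrcCategory.SMQD),
        ("R2", "analgesics", MqrcCategory.STF),
        ("R3", "antivirals", MqrcCategory.SMQD),
        ("R4", "antivirals", MqrcCategory.SADR),
        ("R5", "antivirals", MqrcCategory.SADR),
    ]
    from mqrc.model import TherapeuticClass

    return [
        ClassifiedRecord(
            make_record(rid, therapeutic_class=TherapeuticClass(tc)),
            cat, [], Rationale.DEFECT_DECLARED,
        )
        for rid, tc, cat in rows
    ]


def test_build_contingency_counts_and_conservation():
    cohort = _mini_cohort()
    t = build_contingency(
        cohort,
        lambda r: r.therapeutic_class.value == "antivirals",
        MqrcCategory.SADR,
    )
    assert (t.a, t.b, t.c, t.d) == (2, 1, 0, 2)
    assert t.n == len(cohort)


def test_build_contingency_degenerate_selectors():
    cohort = _mini_cohort()
    nothing = build_contingency(cohort, lambda r: False, MqrcCategory.SMQD)
    assert (nothing.a, nothing.b) == (0, 0)
    everything = build_contingency(cohort, lambda r: True, MqrcCategory.SMQD)
    assert (everything.c, everything.d) == (0, 0)
    with pytest.raises(ValueError):
        build_contingency([], lambda r: True, MqrcCategory.SMQD)
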