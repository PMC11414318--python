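"""Generator determinism, injection ledgers and exact-count fixtures."""
import math

import pytest

from mqrc import (
    MqrcCategory,
    SyntheticConfig,
    categorize_cohort,
    county_table,
    deduplicate,
    fixture_from_counts,
    fixture_tables,
    generate,
    generate_with_ledger,
    paper_fixture,
    preprocess,
    stratum_table,
    validate_synthetic,
    write_icsr_csv,
)
from mqrc.synthetic import (
    COHORT_TOTAL,
    FixtureCountTable,
    TABLE4_COUNTS,
    TABLE8_COUNTS,
    table12_cells,
)


def test_same_seed_produces_byte_identical_files(tmp_path):
    cfg = SyntheticConfig(n_records=400, seed=7)
    p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
    write_icsr_csv(generate(cfg), p1)
    write_icsr_csv(generate(cfg), p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_different_seeds_differ():
    a = generate(SyntheticConfig(n_records=100, seed=1))
    b = generate(SyntheticConfig(n_records=100, seed=2))
    assert a != b


def test_degenerate_category_probs_classify_uniformly():
    cfg = SyntheticConfig(n_records=150, category_probs=(1.0, 0.0, 0.0), seed=3)
    kept, _ = preprocess(generate(cfg))
    _, counts = categorize_cohort(kept)
    assert counts[MqrcCategory.SMQD] == len(kept)
    assert counts[MqrcCategory.STF] == counts[MqrcCategory.SADR] == 0


def test_dedup_removes_exactly_the_injected_duplicates():
    cfg = SyntheticConfig(n_records=1000, duplicate_rate=0.1, seed=11)
    records, ledger = generate_with_ledger(cfg)
    assert len(ledger.duplicate_ids) == 100
    kept, report = deduplicate(records)
    assert report.n_duplicates_removed == len(ledger.duplicate_ids)
    kept_ids = {r.report_id for r in kept}
    assert kept_ids.isdisjoint(ledger.duplicate_ids)
    assert set(ledger.duplicate_source_ids) <= kept_ids


def test_preprocess_accounts_for_all_injections():
    cfg = SyntheticConfig(
        n_records=500, duplicate_rate=0.04, test_rate=0.02,
        out_of_window_rate=0.03, seed=5,
    )
    records, ledger = generate_with_ledger(cfg)
    _, report = preprocess(records)
    assert report.n_duplicates_removed == len(ledger.duplicate_ids) == 20
    assert report.n_test_removed == len(ledger.test_ids) == 10
    assert report.n_out_of_window == len(ledger.out_of_window_ids) == 15
    assert report.n_retained == 500


def test_classifier_recovers_intended_categories():
    records, ledger = generate_with_ledger(SyntheticConfig(n_records=2000, seed=9))
    kept, _ = preprocess(records)
    classified, _ = categorize_cohort(kept)
    agree = sum(
        cr.category is ledger.intended_category[cr.record.report_id]
        for cr in classified
    )
    assert agree / len(classified) >= 0.99


def test_invalid_configs_rejected():
    with pytest.raises(ValueError, match="sum to 1"):
        SyntheticConfig(n_records=10, category_probs=(0.5, 0.4, 0.2))
    with pytest.raises(ValueError, match="duplicate_rate"):
        SyntheticConfig(n_records=10, duplicate_rate=1.5)
    with pytest.raises(ValueError, match="annual_weights"):
        SyntheticConfig(n_records=10, annual_weights=(1, 2))


def test_validation_report_within_three_se_at_large_n():
    cfg = SyntheticConfig(n_records=10_000, seed=13)
    report = validate_synthetic(generate(cfg), cfg)
    assert report.n_checked == 10_000
    assert not [v for v in report.violations if v.startswith("category")]


def test_validation_report_well_formed_at_small_n():
    cfg = SyntheticConfig(n_records=50, seed=1)
    report = validate_synthetic(generate(cfg), cfg)
    assert report.n_checked == 50
    assert isinstance(report.violations, list)


def test_validation_flags_mislabeled_input():
    # cohort drawn with an inverted category mix, validated against default
    wrong = SyntheticConfig(n_records=2000, category_probs=(0.063, 0.416, 0.521), seed=2)
    records = generate(wrong)
    report = validate_synthetic(records, SyntheticConfig(n_records=2000, seed=2))
    assert not report.ok
    assert any(v.startswith("category") for v in report.violations)


def test_negative_fixture_cell_rejected():
    with pytest.raises(ValueError, match="negative"):
        FixtureCountTable("bad", ("dosage_form",), {("tablet",): (-1, 0, 0)})


def test_single_cell_fixture():
    table = FixtureCountTable("one", ("dosage_form",), {("tablet",): (5, 0, 0)})
    records = fixture_from_counts(table)
    assert len(records) == 5
    _, counts = categorize_cohort(records)
    assert counts[MqrcCategory.SMQD] == 5


@pytest.mark.parametrize("name", sorted(fixture_tables()))
def test_fixture_grand_totals(name):
    assert fixture_tables()[name].grand_total == COHORT_TOTAL


@pytest.mark.parametrize(
    "name, axis, counts",
    [
        ("table4", "therapeutic_class", TABLE4_COUNTS),
        ("table8", "facility_sector", None),
    ],
)
def test_fixture_round_trips_through_full_pipeline(name, axis, counts):
    """preprocess -> classify -> report reproduces the fixture's own table."""
    kept, report = preprocess(paper_fixture(name))
    assert report.n_retained == COHORT_TOTAL
    classified, _ = categorize_cohort(kept)
    df = stratum_table(classified, axis).set_index(axis)
    if name == "table8":
        counts = {}
        for (sector, _), (s, t, a) in TABLE8_COUNTS.items():
            cur = counts.setdefault(sector, [0, 0, 0])
            cur[0] += s; cur[1] += t; cur[2] += a
    for stratum, (smqd, stf, sadr) in counts.items():
        row = df.loc[stratum]
        assert (row["SMQD_n"], row["STF_n"], row["SADR_n"]) == (smqd, stf, sadr)


def test_table8_fixture_reproduces_published_government_cell(table8_cohort):
    classified, _ = table8_cohort
    df = stratum_table(classified, "facility_sector").set_index("facility_sector")
    assert df.loc["government", "SMQD_n"] == 1082
    assert df.loc["government", "SMQD_pct"] == 39.1


def test_table12_fixture_reproduces_county_year_cells(table12_cohort):
    classified, _ = table12_cohort
    observed = {}
    for cr in classified:
        key = (cr.record.county, cr.record.report_date.year)
        observed[key] = observed.get(key, 0) + 1
    assert observed == table12_cells()


def test_generator_recovers_configured_odds_ratio():
    """RORs on a large synthetic cohort converge to the configured odds.

    The facility-sector distribution is set so government facilities carry
    70% of quality-defect reports but only 30% of the rest; the implied
    odds ratio of the (government x SMQD) 2x2 table is recovered within
    3 standard errors of the log odds ratio.
    """
    from mqrc import StratumSpec, analyze_table, build_contingency

    p_sel = {"SMQD": 0.7, "STF": 0.3, "SADR": 0.3}
    dists = {
        "facility_sector": {
            cat: {"government": p, "private_for_profit": 1 - p}
            for cat, p in p_sel.items()
        }
    }
    cfg = SyntheticConfig(
        n_records=50_000, axis_distributions=dists,
        duplicate_rate=0.0, test_rate=0.0, out_of_window_rate=0.0, seed=17,
    )
    kept, _ = preprocess(generate(cfg))
    classified, _ = categorize_cohort(kept)
    t = build_contingency(
        classified,
        StratumSpec("facility_sector", "government").selector(),
        MqrcCategory.SMQD,
    )
    res = analyze_table(t)

    p_cat = dict(zip(("SMQD", "STF", "SADR"), cfg.category_probs))
    pa = p_cat["SMQD"] * p_sel["SMQD"]
    pb = sum(p_cat[c] * p_sel[c] for c in ("STF", "SADR"))
    pc = p_cat["SMQD"] * (1 - p_sel["SMQD"])
    pd = sum(p_cat[c] * (1 - p_sel[c]) for c in ("STF", "SADR"))
    expected_or = (pa * pd) / (pb * pc)
    assert abs(math.log(res.ror) - math.log(expected_or)) <= 3 * res.se_log_ror
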