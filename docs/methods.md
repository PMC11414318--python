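# Methods

## Setting and data model

The package models individual case safety reports (ICSRs) as captured by a
national pharmacovigilance electronic reporting system: one row per
spontaneous report, carrying the product (trade name, active
pharmaceutical ingredients, branded/generic status, therapeutic class,
dosage form, route), the notifying facility (sector and level within the
health system), the reporter's profession, the county of origin among the
47 Kenyan counties, a free-text complaint description and an opaque
patient key. All categorical fields are closed vocabularies; blank or
unparseable cells are coerced to explicit `unknown`/`not_stated` members
(and counted in a parse report) rather than stored as nulls, because the
descriptive tables report those strata as real rows ("Not Indicated",
"Professional not stated"). Near-miss county spellings are *reported*, not
auto-corrected, to keep counts auditable. Therapeutic class and specific
product are treated as pre-coded input columns: no free-text coding
algorithm for them is attempted. Files are UTF-8 CSV with ISO-8601 dates;
a machine-readable schema ships as `mqrc/data/icsr_schema.json`.

## Preprocessing

* **Redaction** replaces trade name and patient key with HMAC-SHA256
  tokens keyed by a caller-supplied salt. Tokens are stable per
  (value, salt), so duplicate detection and joins still work on redacted
  data; empty fields stay empty.
* **Duplicate elimination** collapses records sharing the composite key
  (normalised product name, report type, county, report date, patient
  key). The survivor is the record with the lowest report id — an
  arbitrary but deterministic stand-in for what is a manual judgement in
  practice. The operation is idempotent and never removes a record whose
  key is unique (property-tested against a brute-force pairwise oracle).
* **General criteria** retain reports dated within the study window
  (1 January 2014 – 31 December 2021, both ends inclusive), not marked as
  system-validation test rows, and naming at least one of trade name /
  APIs. Medical-device reports are exempt from the product-name
  requirement, since devices frequently lack both. Test rows are detected
  by an explicit flag *or* a case-insensitive whole-word "test" in the
  complaint text. Exclusion counts use the fixed precedence
  test > window > missing-product so each record is counted once; the flow
  report satisfies the arithmetic identity
  `retained = input − duplicates − test − window − missing` on every run
  and is invariant to input order.

## Three-way complaint classification

Complaints partition into suspected medicine quality defects (SMQD),
suspected therapeutic failures (STF) and suspected adverse drug reactions
attributed to poor quality (SADR). Cues:

* STF — the report is notified as a therapeutic failure, detected through
  a small phrase list ("therapeutic failure", "no improvement", "lack of
  efficacy", …) since report-type vocabularies rarely carry an explicit
  inefficacy member;
* SADR — an adverse-reaction report where poor quality is suspected. How
  that suspicion was recorded is system-specific, so it is modelled as an
  explicit boolean input, inferred by default from the report type (a
  suspected-poor-quality-medicine report is itself a declaration) or a
  quality-suspicion phrase in the text;
* SMQD — a declared quality issue, or ≥1 match of the defect-term lexicon
  against the complaint text.

For multiply-cued records the precedence is **STF > SADR > SMQD**: how the
report was notified is treated as stronger evidence than a text match.
This makes the categories mutually exclusive and exhaustive over complaint
records; records matching no cue are excluded as non-complaints (e.g.
ordinary medication errors — though labelling-related medication errors
route to SMQD via the mislabelling term). Falsified-medicine detection is
not attempted.

The lexicon holds 17 controlled defect terms (caking, capping/lamination,
chipping/breaking, cracking, incomplete package, leakage, mislabelling,
mottling/colour change, moulding, odour change, phase inversion,
powdering, sticking/picking/binding, taste change, uneven splitting,
unusual stains/spots, other quality defect), each with the dosage forms it
can physically occur in, a cause class (poor manufacturing practice,
environmental degradation, or both) and ≥3 case-insensitive trigger
phrases. Matching is plain substring search — no stemming, no NLP — and a
term is only eligible when the record's dosage form is in its list
("all dosage forms" terms are always eligible). The synonym lists are an
implementation artifact: they ship as an editable, versioned JSON config
(`mqrc/data/defect_lexicon.json`) because real free-text conventions vary
by database. Match order is lexicon order, so results are deterministic;
shuffling the lexicon changes ordering only, never membership.

## Disproportionality statistics

For stratum *S* and category *C* over a classified cohort of size *N*:
`a = |S∧C|`, `b = |S∧¬C|`, `c = |¬S∧C|`, `d = |¬S∧¬C|` (cells sum to *N*).
The reporting odds ratio is **ROR = ad/bc**, with

* 95% CI `exp(ln ROR ± z·√(1/a+1/b+1/c+1/d))`, `z = 1.959964` (using the
  exact quantile rather than 1.96 changes nothing at printed precision);
  the CI is defined only when all four cells are positive;
* significance from the Pearson chi-square statistic on the 2×2 table
  without Yates continuity correction (df = 1), computed via
  `scipy.stats.chi2_contingency`; a "non-exact" test, in contrast with
  Fisher's exact test;
* printed p-values bucketed into the conventional interval labels
  (`<0.001`, `0.002-0.001`, …, `>0.995`), half-open and inclusive on the
  smaller-p side;
* **signal rule**: ROR ≥ 2.0 (infinite RORs count as above threshold) and
  p < 0.05. No multiple-testing correction is applied — the method is a
  hypothesis-generating screen, not a confirmatory analysis.

Zero-cell conventions are single-sided: `bc = 0` with `ad > 0` yields
ROR = ∞ (the category is reported only for the stratum of interest),
`ad = 0` with `bc > 0` yields ROR = 0; both products zero (or a zero
margin for the chi-square) is degenerate and raises rather than silently
emitting 0 or ∞ — batch reporting flags such strata instead of dropping
them. A Haldane–Anscombe +0.5 correction is available but **off by
default**: the uncorrected form is what reproduces published confidence
intervals in this setting. Comparisons against printed values use
round-half-even at the printed number of decimals.

Tested invariants: reciprocity (swapping category columns maps
ROR → 1/ROR exactly), chi-square transposition invariance, strict
monotonicity in *a*, equality with an independent epidemiology oracle
(statsmodels `Table2x2`), agreement with brute-force record counting to
1e-12 relative tolerance, and ~95% (±2%) null coverage of the Wald CI over
10,000 simulated independence tables of size 200.

## Stratified reporting

Per-axis tables report counts and cohort percentages (one decimal,
round-half-even) per category; every table's totals reconcile with the
cohort size. The trend series bins complaints by month or year over a
contiguous range and compares mean per-period counts before and after a
break date defaulting to 1 March 2020 (the pandemic onset); the period
containing the break belongs to "after", and the relative change
`(after − before)/before` is flagged undefined when nothing precedes the
break. Both monthly and annual granularities are supported. The county
table includes the explicit "Not Indicated" row and an optional roll-up of
counties below a threshold share (2.6% of the cohort reproduces the
published aggregate row, which is defined only by its label).

## Synthetic data

The generator emulates the schema by seeded categorical sampling
(`numpy.random.default_rng`; integer-sequence based, no locale
dependence — same seed, byte-identical output):

* the category mix defaults to the published cohort's 52.1 / 41.6 / 6.3%;
* per-axis distributions are sampled **independently per axis,
  conditional on category**, with defaults read off the published
  one-axis marginal tables. The published tables are marginals, so a
  joint distribution matching all of them simultaneously is
  overconstrained — exact reproduction is therefore delegated to
  per-table fixtures;
* report dates follow the published annual totals (115, 207, 369, 327,
  476, 571, 451, 251 for 2014–2021), uniform within year; 9.1% of records
  carry no county;
* complaint texts are template sentences embedding a lexicon trigger
  phrase (quality defects), a therapeutic-failure phrase, or an
  adverse-reaction-with-quality-suspicion phrase, so the classifier
  recovers the intended category; defect terms cycle uniformly within a
  dosage form, since no within-category defect-term distribution is
  published. Prose realism is a non-goal — classifier-recoverability is
  the contract;
* duplicates (default 5% — clones of existing records with fresh ids, so
  the lowest-id survivor is the original), test rows (1%) and
  out-of-window rows (2%) are appended per configured rates, and an
  **injection ledger** records exactly what was injected, giving the
  preprocessing tests an exact oracle. Patient keys are unique except for
  injected duplicates. The injection rates are exercise parameters for
  the preprocessing stage, not published quantities.

`validate_synthetic` checks empirical category and axis frequencies
against the configuration within 3 binomial standard errors and lists any
violations. On large cohorts, pipeline RORs converge to the odds ratios
implied by the configured conditional distributions (checked at n=50,000
within 3 SE of the log odds ratio).

The exact-count fixtures (`paper_fixture("table3" | "table4" | "table8" |
"table10" | "table11" | "table12")`) each encode one published marginal
table of the 2,767-report cohort as records whose cells the pipeline
recovers identically. The county fixture's published aggregate row
("counties below 2.6%", 947 reports) has no per-county attribution, so its
mass is spread deterministically round-robin across the 37 reporting
counties outside the named rows, each staying below the roll-up threshold;
the four counties published as reporting nothing stay empty. Where a
fixture table publishes no category split (the county × year table),
categories are cycled in roughly the cohort's global proportions.

What passing fixture tests show — and what they do not: they demonstrate
that the statistical pipeline reproduces published results *given the
published counts*; they do not validate the free-text classifier against
real complaint prose, real duplicate structure, or real inter-axis
correlations, none of which are public.

## Known limitations and documented inconsistencies

* A small number of published ROR values do not follow from their own
  published marginal counts via the 2×2 construction (the branded×SMQD,
  efavirenz×SADR and metronidazole×SMQD rows). The test suite asserts
  these are *not* reproducible and they are excluded from the
  reproduction targets; no attempt is made to guess the original intent.
* The published flow counts (1,506 complaints identified among 9,914
  reports vs 2,767 fulfilling the criteria) are not mutually reconcilable,
  so no flow-count reproduction is attempted.
* Whole-word "test" matching can exclude genuine complaints that mention
  e.g. diagnostic test kits; the generator avoids the word outside
  injected test rows, but real data would need the explicit flag.
* Causality assessment, laboratory confirmation, MedDRA coding,
  prevalence estimation and geographic mapping are out of scope.

## Problem sizes

Fixture cohorts are 2,767 records; property tests use 1,000 random
tables, 10,000 null-coverage replicates and one 50,000-record generator
run — the full suite completes in well under a minute of compute on a
single core, and the reproduction script in about a second.
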