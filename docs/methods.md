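# Methods

This document describes the statistical model, the study pipeline, the
synthetic data generator, and the numerical and design choices made in
`pvsignal`.

## 1. Data model

### Input format

The pipeline reads FAERS-style quarterly ASCII extracts: `$`-delimited
text tables `DEMO`, `DRUG`, `REAC`, `INDI`, `OUTC`, `THER`, keyed by
`primaryid` (a case identifier concatenated with a version number) and
`caseid`. Files are parsed with pandas (`engine="python"`,
`quoting=csv.QUOTE_NONE`); lines with an inconsistent field count are
skipped and counted per table rather than aborting the run, because
FAERS extracts contain occasional malformed rows. Files are decoded as
UTF-8 with a Latin-1 fallback. A missing mandatory column is a hard
`FormatError` naming the file and column.

### Report assembly

Rows are grouped by `primaryid` into one `SafetyReport` per report
version: demographics, drug uses (role code, verbatim name, mapped
ingredient), reaction PTs, indication PTs, and outcome codes. Reports
with no parseable reaction are dropped — they cannot contribute to
either margin of a contingency table. Malformed demographic fields
degrade to `unknown` instead of dropping the report.

Age is converted to years using the FAERS unit codes:
`YR`×1, `DEC`×10, `MON`/12, `WK`/52.18, `DY`/365.25, `HR`/8766. A
missing unit code is treated as years when the value is plausible
(≤ 120). `DEC` means decades in FAERS data files, so it is multiplied
by 10 even though some secondary documentation paraphrases it as
"years".

### Deduplication

FAERS carries every submitted version of a case. The default rule keeps,
per `caseid`, the report with the highest `caseversion`, breaking ties
by latest receipt date and then by `primaryid`; an alternative
`latest_receipt_only` rule is available. Case identifiers on the
quarterly deleted-case list are removed entirely. Deduplication is a
deterministic function of the report set: it is idempotent and invariant
to input order (property-tested).

## 2. Exposure mapping

Verbatim drug names are normalised (uppercased, punctuation stripped,
dose/formulation/salt tokens removed) and looked up in a packaged
pattern dictionary covering the eight statins (simvastatin,
atorvastatin, rosuvastatin, pravastatin, fluvastatin, lovastatin,
pitavastatin, cerivastatin), colchicine, and common trade names. Only
primary-suspect (`PS`) drug roles count toward exposure by default;
`roles` is configurable (e.g. `("PS", "SS")`).

Each report is assigned exactly one mutually exclusive group:
`statin:<name>` (exactly one statin), `statin:multiple` (≥ 2 statins,
no colchicine), `colchicine` (no statin),
`colchicine+statin:<name>`, `colchicine+statin:multiple`, or `other`.
The groups partition the store, so group counts always sum to the
analysed total (tested as an invariant).

## 3. Event classification

The case definition is a narrow rhabdomyolysis/myopathy term set,
packaged as an editable CSV (PT name, code, scope) approximating the
narrow scope of the corresponding MedDRA standardised query. Matching is
case-insensitive on whitespace-normalised PT names. Reports whose
*indication* list contains a term from the same set are excluded before
analysis, as a proxy for pre-existing muscle disease; this is an
indication-PT approximation, not a medical-history review.

## 4. Statistics

For index group vs. comparator, the 2×2 table (a, b, c, d) yields:

- **ROR** `= ad/bc` with the Woolf interval
  `exp(ln ROR ± z·√(1/a+1/b+1/c+1/d))`, `z = 1.96`. When any cell is
  zero the Haldane–Anscombe correction (+0.5 to all four cells) is
  applied automatically and flagged in the output; requesting the
  uncorrected estimator on a zero-cell table raises.
- **IC** `= log₂((a+0.5)/(E+0.5))`, `E = (a+b)(a+c)/N`, with the Norén
  closed-form credible interval
  `IC025 = IC − 3.3(a+0.5)^−1/2 − 2(a+0.5)^−3/2`,
  `IC975 = IC + 2.4(a+0.5)^−1/2 − 0.5(a+0.5)^−3/2`. An alternative
  `bate_variance` method computes the interval from the closed-form
  posterior variance of the original BCPNN formulation (priors
  α₁ = β₁ = 1, α = β = 2, γ₁₁ = 1); the two agree at large counts
  (tested).
- **Signal rule**: `a ≥ 3 ∧ ROR025 > 1 ∧ IC025 > 0`. Both inequalities
  are strict; `min_cases` and `z` are configurable.

Two comparators are supported: `rest_of_store` (c, d counted from all
non-index reports) and `explicit_background` (c, d supplied directly,
for reproducing published tables).

**Counting units.** Drug-level and combination analyses count *reports*
(a report with two matching PTs is one case). PT-level analysis counts
*(report, PT) pairs*, so a report with two matching PTs contributes two
pairs; this matches the convention of PT-level disproportionality
tables and makes per-PT columns sum to the reaction total.

## 5. Study pipeline

`run_study(StudyConfig)` chains: read quarters → assemble → deduplicate
→ exclude prior myopathy → label (group + case flag per report) →
demographic tables, drug-count table, drug-level / combination /
PT-level signal tables, and annual counts. A case-flow table records the
report count after each stage; counts are non-increasing and the final
count equals the analysed population (tested against the generator
manifest).

Percentages in summary tables use `round(x, 1)` (Python banker's
rounding). When `output_dir` is set, all tables are written as CSV with
a `run_manifest.json` containing the analysis configuration and its
SHA-256 hash; the destination directory itself is excluded from the
hash so reruns are byte-identical regardless of where they are written.

## 6. Synthetic generator

`SyntheticTruth` specifies: the number of reports, exposure-group
weights, per-PT background event probabilities, planted associations
(group, PT, relative rate r — the event probability becomes
`min(1, r·p)` for exposed reports), and nuisance rates (duplicates,
deleted cases, pre-existing myopathy indications). Defaults mirror the
scale of a published colchicine–statin study (group weights proportional
to its report totals), but every parameter is overridable.

Given exposure group, events are independent Bernoulli draws per PT;
every report also receives one guaranteed non-myopathy base reaction so
that no report is empty. Duplicates are emitted as version-2 copies
with a shifted receipt date and a verbatim-name variant; deleted cases
go to `deleted_cases.txt`. Demographics (age, sex, occupation, country,
outcomes) are drawn from configurable marginals.

`generate()` writes FAERS-format files; `simulate_store()` produces the
equivalent in-memory labeled frame. Both consume the random draws in
the same fixed order from `numpy.random.default_rng(seed)`, so they
share realised counts and generation is byte-identical for a given
seed (tested). A manifest records expected and realised per-(group, PT)
counts and the post-deduplication/exclusion population.
`recover_parameters()` compares pipeline estimates against the planted
truth and applies the signal rule.

**Scope and limits of the generator.** It models exposure→event
disproportionality with independent events and uniform background rates;
it does not model reporting heterogeneity over time, drug–drug
interactions beyond the planted groups, MedDRA hierarchy effects,
correlated reactions within a report, or informative missingness.
Calibration results (interval coverage, null signal rate) therefore
validate the *estimators* under the stated model, not FAERS itself.

## 7. Validation and calibration

The test suite and `scripts/acceptance.py` check, with fixed seeds:

- **Published-table arithmetic**: feeding the published report counts
  through the summary operations reproduces the printed totals
  (1,029,987 included reaction records) and every printed percentage
  exactly at one-decimal rounding.
- **Oracle equivalence**: cells from the vectorised path equal a plain
  recount over raw records; ROR is exact, IC agrees to 1e-12; the odds
  ratio and Woolf interval agree with `statsmodels` `Table2x2`.
- **Null calibration**: over 1000 null stores the 95% ROR interval
  covers 1 with frequency in [93%, 97%]; over 2000 null drug–event
  tests the joint signal rule fires in well under 10%.
- **Recovery**: a planted relative rate of 5 run through file
  generation and the full pipeline (10⁵ reports, with duplicates,
  deletions and exclusions) is recovered within 25% by both ROR and
  2^IC; a planted rate of 10 with ~50 expected cases is detected in
  ≥ 95 of 100 replicates.

Problem sizes (10³–10⁵ reports, 100–1000 replicates) were chosen so the
full suite runs in well under a minute while keeping Monte-Carlo noise
small relative to the asserted margins.

## 8. Known limitations

- The term set is a packaged approximation of a MedDRA standardised
  query, not a licensed MedDRA distribution; users with a licence can
  supply their own CSV/YAML term file.
- 2^IC is a shrunk observed-to-expected *ratio*, not an odds ratio; for
  rare events and small exposed shares the two are close, but with a
  large planted rate and non-negligible exposed share 2^IC is biased
  toward the null relative to the true relative rate (visible in the
  recovery results, where ROR ≈ 5.3 and 2^IC ≈ 4.5 for a planted 5).
- Disproportionality statistics on spontaneous reports measure
  reporting behaviour, not incidence; confounding (e.g. by indication)
  and stimulated reporting are not addressed by the design.
- The prior-myopathy exclusion uses indication PTs only and will miss
  histories recorded as free text or absent from the report.
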