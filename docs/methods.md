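# Methods

## The classification rule

`asthmafinder` implements a deterministic case definition over four
EMR criterion categories. Matching semantics, in the order they are
applied:

* **Text normalisation.** All free text is lower-cased and runs of
  whitespace are collapsed to single spaces before any matching.
* **ICD-9 matching** is prefix-based on the trimmed code string after
  removing a leading `ICD-9:`-style tag, so `493`, `493.0` and
  `493.90` all match the asthma rubric. Billing entries are code-only;
  no text criterion applies to them.
* **Inclusion text** (`asth*`) is a token-initial prefix match:
  any whitespace-delimited token beginning with `asth` qualifies, with
  punctuation hugging a token ignored when locating its start
  (`(asthma)` matches, `masthead` does not).
* **Exclusion text** uses whole-field glob patterns
  (`*asthma*query*`, `*query*asthma*`, `*asthma*?*`, `*?*asthma*`)
  in which `*` matches any — possibly empty — character sequence and
  `?` is the **literal** question mark: the patterns target
  uncertainty notations such as "asthma query", "asthma?" and
  "?asthma", not single-character wildcards. Exclusion is local to the
  row it appears on: an "asthma query" encounter never cancels a
  qualifying hit on a different row.
* **Medications** qualify by ATC code membership in the 22-code set
  (relievers, inhaled/systemic corticosteroids, combination inhalers,
  leukotriene receptor antagonists, ipratropium); rows with an empty
  ATC code fall back to a case-insensitive drug-name substring match.
  A present but non-qualifying ATC code is trusted over the name.
* **Combination rule.** With `n` the number of qualifying prescription
  rows: case ⇔ eligible age ∧ (n ≥ 2 ∨ (n ≥ 1 ∧ any diagnosis hit)).
  Both thresholds are configurable
  (`min_prescriptions_alone`, `min_prescriptions_with_other_criterion`),
  as is the counting unit (`rows`, the default, versus
  `distinct_drug` or `distinct_date` for sensitivity analyses) and an
  opt-in `allow_diagnosis_only` arm. Counting rows reflects the
  operational reading that two refills of the same reliever are two
  prescriptions.
* **Eligibility.** Age is computed in completed years at the cohort
  reference date (default 2015-06-30, the extract cut-off); eligible
  ages are 1–17 inclusive. The age-reference convention is a package
  choice — extraction-date ageing — exposed via `--reference-date`
  since encounter-date ageing is equally defensible. Patients with a
  missing or unparseable birth date are flagged ineligible with a
  logged warning rather than silently classified.
* **No date window** is imposed on any criterion: all rows up to the
  reference date count ("any occurrence").

## Validation statistics

Confusion matrices cross-tabulate algorithm verdicts against
gold-standard labels over identical patient sets (a mismatch is an
error naming examples). Sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP), PPV = TP/(TP+FP), NPV = TN/(TN+FN), each
with a two-sided binomial interval: **Clopper–Pearson exact** (beta
quantiles, via `statsmodels`) by default, Wilson score by flag. We
recomputed the published three-stratum intervals with both methods;
each lands within about 0.2 percentage points of the printed bounds
but neither reproduces them exactly (the printed intervals are
slightly wider on both sides, suggesting a different recipe or
rounding chain), so point estimates — which reproduce exactly — are
the quantitative anchor and the exact method is retained as the
conventional default for diagnostic-accuracy tables. Percentages are
printed to one decimal, rounded half away from zero. Undefined metrics
(zero denominator) raise a named error when requested directly and are
reported as missing — never as 0 or 1 — inside stratified reports.

Stratified reports evaluate inclusive integer age bands (default 1–17,
3–17, 6–17) at the reference date; patients whose age falls outside a
band are simply excluded from that band.

Two-rater reliability: percent agreement is the fraction of identical
labels; Cohen's kappa is (p_o − p_e)/(1 − p_e) with chance agreement
p_e from the product of marginal proportions, returning 1 by
convention when observed agreement is perfect (including the
degenerate single-category case).

## The synthetic cohort generator

The generator emulates the *structure* of a cleaned primary-care
extract, not its clinical dynamics: per patient it draws a gold label
at the configured prevalence (default 0.143, matching a childhood
asthma prevalence of ~13–14%), an integer age uniform on 1–17 (birth
date back-computed with a random day offset so boundary ages are
exercised), and documentation rows from per-stratum profiles. All
randomness comes from a single seeded NumPy generator, so a config and
seed determine the written tables byte for byte.

Default documentation profiles (package assumptions, recorded in each
run's provenance file; the source data publishes no such
distributions):

* gold-positives: billing 493 with probability 0.55, encounter code
  0.30, encounter text 0.80, problem-list entry 0.45; prescription
  counts {0: 0.04, 1: 0.12, 2: 0.40, 3: 0.28, 4: 0.16} (mass
  concentrated at ≥2, the dominant criterion); uncertainty note 0.05,
  concurrent "acute bronchitis"-type label 0.20.
* gold-negatives: near-zero code/text rates, prescription counts
  {0: 0.90, 1: 0.085, 2: 0.015} (a lone-reliever tail for transient
  viral wheeze and a small two-script tail that produces realistic
  false positives), uncertainty note 0.08, distractor label 0.15.
* 6% of gold-positives are generated as sparse "suspected" records —
  1–2-year-olds carrying only an ambiguous note or a single reliever —
  mirroring the reviewer category of likely-but-thinly-documented
  cases; they count as gold-positive and are typically missed by the
  rule.

Diagnosis texts are sampled from variant lists covering
capitalisation, punctuation and all four exclusion-pattern shapes, so
the matcher's corners are exercised by default; ~10% of prescription
rows omit the ATC code to exercise the name fallback.

**Calibrated mode.** `calibrate_profiles(sens, spec, base)` sets
target operating points: gold-positives are generated fully documented
(guaranteed ≥2 qualifying scripts) with probability `sens` and
sub-threshold otherwise (label-only, lone script, or sparse-suspected);
gold-negatives get case-like documentation with probability
`1 − spec` and otherwise a draw constrained to be sub-threshold. Each
patient's classification is then an independent Bernoulli draw at the
target rate, so recovery tests have an exact sampling distribution. A
target is unreachable — and rejected before any sampling — when the
case prescription-count distribution has no mass at ≥2.

What passing simulation tests does **not** show: the generator has no
longitudinal visit dynamics, no co-medication plausibility, no
free-text beyond the variant lists, and no claim to CPCSSN
representativeness; recovery results validate the *pipeline*, not the
rule's real-world accuracy, which rests on the chart-review comparison.

## Problem sizes and numerical choices

The Monte-Carlo recovery check uses 5000-patient cohorts over 20
seeds, sized so that three binomial standard errors on sensitivity
(~700 gold-positives per replicate) span about ±3.7 percentage points;
the glob-matcher equivalence check uses 10,000 random strings over an
alphabet rich in `?`, spaces and "asthma"/"query" fragments against an
independently written dynamic-programming matcher. Dates are ISO-8601
throughout; tables are UTF-8 CSV with standard quoting, so free text
containing delimiters or quotes round-trips. CLI exit codes: 0
success, 2 input/validation error, 3 internal error; outputs are
written atomically so a failed run leaves no partial files.

## Known limitations

Only ICD-9 and ATC vocabularies are matched (no ICD-10/SNOMED
mapping); text matching is the stated glob/prefix semantics, not NLP;
referral documents and the other CPCSSN chronic-condition definitions
are out of scope. Whether same-day duplicate prescriptions should
count once or twice in the deployed rule is unknowable from the
source; the `rows` default counts them twice and the
`distinct_date` switch counts them once.
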