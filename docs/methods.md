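# Methods

`faersig` implements a complete spontaneous-reporting signal-detection
workflow for FAERS-style quarterly data: ingestion and deduplication,
drug–event disproportionality analysis with four algorithms, subgroup and
sensitivity reruns, and Weibull time-to-onset modelling. Because real FAERS
extracts are large and MedDRA is licensed, the package ships a synthetic
generator that reproduces the statistical structure of the data with known
ground truth; every stage is exercised and validated against it.

## Data model and ingestion

FAERS distributes quarterly dollar-delimited ASCII tables. Four are used:
DEMO (one row per report version: identifiers, receipt and onset dates,
demographics), DRUG (one row per drug per report, with the FAERS role codes
PS/SS/C/I), REAC (one MedDRA preferred term per row) and THER (therapy start
dates keyed by drug sequence number).

**Deduplication.** Reports are versioned: the same CASEID can appear with
several PRIMARYIDs. Following the FDA-recommended rule, we keep, per CASEID,
the row with the largest FDA receipt date (FDA_DT) and, among ties, the
largest PRIMARYID. PRIMARYID is compared numerically after stripping
non-digits; rows with no digits at all fall back to lexicographic comparison.
Unparseable FDA_DT sorts smallest, so a malformed version is never preferred
over a well-formed one. The operation is idempotent and independent of input
order (both property-tested).

**Partial dates.** FAERS dates are frequently YYYYMM or YYYY. These are
imputed (1st of month; July 1) but tagged with their original precision, and
time-to-onset analysis excludes imputed intervals by default
(`allow_imputed_dates` reverses this).

**Ages** are normalized to years from the unit code (DY/365.25, WK·7/365.25,
MON/12, DEC·10); unknown codes become missing rather than guessed.

**Drug matching** is case-insensitive exact matching after whitespace
normalization against a synonym list (default: the study drug's generic and
brand names). Substring matching is deliberately avoided — combination
products and salts make it a false-positive machine.

**Within-report duplicate PTs are collapsed**: a term counts at most once per
report, so counting is report-level throughout. This keeps the fourfold-table
margins interpretable as report counts; per-occurrence counting would let a
single verbose report inflate a cell.

## Disproportionality statistics

For target drug D and event X over N deduplicated reports the fourfold table
is a (D with X), b (D without X), c (other drugs with X), d (rest). The
expected count under independence is E = (a+b)(a+c)/N.

* **ROR** = ad/bc with the Wald 95% CI `exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d))`.
  Any zero cell makes the statistic undefined; no Haldane 0.5 correction is
  applied by default (togglable) so that reported values are never silently
  corrected.
* **PRR** = [a/(a+b)] / [c/(c+d)], with the Yates continuity-corrected
  chi-square `N·(|ad−bc|−N/2)²/[(a+b)(c+d)(a+c)(b+d)]` (uncorrected form
  togglable). The correction floors at zero for near-proportional tables.
* **MGPS / EBGM.** Counts are modelled as a ~ Poisson(λE) with a two-component
  gamma mixture prior on λ (shapes α₁, α₂, rates β₁, β₂, weight w). The five
  hyperparameters are fitted across all drug–event pairs by maximizing the
  negative-binomial mixture marginal likelihood with L-BFGS-B on
  log-transformed parameters (logit-transformed weight), from the canonical
  starting point (0.2, 0.1, 2.0, 4.0, 1/3); convergence at a relative
  function tolerance of 1e-8, failure raises with the iteration trace. The
  posterior of λ is again a two-component gamma mixture; EBGM = 2^E[log₂ λ]
  (the posterior geometric mean) and EBGM05 is the 5th posterior percentile,
  found by bracketed root finding on the mixture CDF between the component
  quantiles.
* **BCPNN / IC.** Default parameterization is the shrunk observed/expected
  ratio: IC = log₂[(a+0.5)/(E+0.5)], with IC025 the log₂ of the 2.5th
  percentile of the Gamma(a+0.5, rate E+0.5) posterior. This is the variant
  whose point values behave like log₂(EBGM) in published signal tables. The
  1998 moment approximation (Dirichlet pseudo-counts, normal interval on the
  IC scale) is available with `method="moment"`.

**A note on shrinkage.** EBGM is a posterior *geometric* mean, so it shrinks
the raw ratio a/E toward the prior's geometric mean, which for heavy-tailed
gamma mixtures lies well below the prior's arithmetic mean, and it sits below
the posterior arithmetic mean by the Jensen gap (bounded by exp(−1/(α+a)) per
component). The folklore statement "EBGM always lies between 1 and a/E" is
therefore false in general — it fails for pairs near independence and for any
prior whose geometric mean is not 1. The test suite asserts the exact
bounds instead: the posterior arithmetic mean (α+a)/(β+E) lies between the
prior mean and a/E, and EBGM lies within the Jensen gap below it.

**Thresholds.** Default positivity rules: ROR — a ≥ 3 and ROR₀₂.₅ > 1;
PRR — PRR ≥ 2, χ² ≥ 4, a ≥ 3; MGPS — EBGM05 > 2; BCPNN — IC025 > 0. The
boundary comparisons are inclusive for ≥-rules. A pair is a signal when at
least one enabled rule fires ("any-of"); an "all-of" mode and per-rule
toggles are provided. The minimum count of 3 is common ROR/PRR practice and
configurable.

**Levels.** SOC-level analysis reuses the same machinery with each report's
event set mapped through the PT→SOC table (one primary SOC per PT, so
SOC-level counts partition the mapped occurrences). Ranking for top-k tables
is by a descending with alphabetical tie-break.

## Subgroups and sensitivity

Subgroups are report-level filters: sex, and age bands <18, 18–65 (closed
interval) and >65 (open at 65) — the closure convention is pinned because
published table labels rarely state it. The stratum's background is
re-restricted to the same stratum by default so the contrast is not
confounded by stratum composition; full-background mode is available. The
sensitivity rerun removes target reports mentioning any excluded concomitant
drug (any role, normalized name match) from the whole database — they are
target reports, so leaving them among the comparators would contradict the
exclusion — and recomputes everything, logging before/after counts.

## Time to onset and Weibull modelling

TTO is EVENT_DT − START_DT in days, one interval per report, using the
earliest full-precision therapy start among the report's matching drug
entries; negatives are excluded, and tallies of missing/partial/negative
exclusions are kept. Same-day onsets are excluded by default because the
Weibull support is t > 0; `include_same_day=True` imputes them as half a day.

The retained onsets get a maximum-likelihood two-parameter Weibull fit
(scale α in days, shape β). 95% CIs come from the observed information:
the Hessian of the log-likelihood in (log α, log β) by central differences,
inverted and exponentiated, which keeps bounds positive and is equivariant
under rescaling of the data (property-tested). Failure classification uses
the CI of β, not the point estimate: entirely below 1 → "early failure"
(decreasing hazard), entirely above 1 → "wear-out failure", otherwise
"random failure". Quantiles everywhere use linear interpolation (type 7) so
medians and IQRs are bit-reproducible.

Day-rounding matters at this shape: for β ≈ 0.73 about 1.7% of onsets round
to day 0, and excluding them left-truncates the sample enough to bias β̂ up
by ~0.03 at large n. The parameter-recovery tests therefore use the half-day
imputation toggle, which is nearly unbiased; the default exclusion policy is
kept for analysis because an onset recorded as "same day" genuinely carries
no sub-day information.

## The synthetic generator

The generator emulates the features that make this pipeline hard to test on
real data: duplicate case versions (later FDA_DT, larger PRIMARYID,
sometimes re-reported demographics), per-field missingness, partial dates,
mixed age units, one-to-many drug and reaction rows, role codes, and
injected associations of known strength.

Each case draws one primary-suspect drug uniformly from the vocabulary and
1–5 reactions (geometric count, p = 0.55, truncated at 5) from a uniform
event distribution, so drug and event are independent in the background. For
an injected pair the event probability under the target drug is set to
rr·(1/n_events) exactly, and only the non-signal probabilities are rescaled
to sum to one; this keeps the per-draw rate ratio at exactly rr, and the
report-level odds ratio within a few percent of rr for the default
vocabulary sizes (n_drugs = 25, n_events = 300). Those sizes were chosen so
that a null pair still has ~10 expected target-drug reports at 50k cases —
enough for the Wald ROR interval to be usably calibrated — while the
injected-signal distortion from multiple draws per report stays under 10%.
Onset times for target-drug reports are Weibull(α = 138.2 d, β = 0.73) draws
rounded to whole days — an early-failure profile; other reports get uniform
onsets. Default missingness approximates large FAERS drug extracts (age 56%,
sex 7%, onset date 55%, start date 45%). Generation is vectorized and
bit-reproducible given the seed.

What the generator does *not* model: reporting waves and stimulated
reporting, country- and reporter-specific reporting propensities, correlated
event clusters (syndromes), masking/competition between drugs, and
indication confounding. Passing tests therefore demonstrate that the
statistics, filters and fits are computed correctly and are calibrated under
independence — not that the pipeline is robust to the biases of real
spontaneous-reporting data.

## Problem sizes used in the test suite

Calibration and detection checks run at 50,000 synthetic cases (~300
drug–event pairs for the target drug), injected-relative-risk recovery at
100,000, the empirical-Bayes prior recovery at 10,000 simulated pairs, and
Weibull coverage at 100 replicates of n = 1,411 onsets — sizes at which the
Monte-Carlo tolerances stated in each test are comfortably binding.

## Known limitations

* The Wald ROR interval is asymptotic; with expected cell counts below ~5 its
  calibration degrades and the null-calibration check would need exact
  intervals.
* The MGPS fit treats pairs as independent, as is standard; margins are in
  fact shared.
* No multiple-testing control is applied — signal tables are screening
  output, not confirmatory inference.
* Uncensored TTO only: spontaneous reports record realized onsets, so
  survival-style censoring is out of scope by construction.
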