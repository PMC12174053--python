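# Methods

This note records the statistical model, the numerical choices, and the
design decisions behind `faerspv`, in the spirit of a methods appendix.

## Study design being emulated

The package implements the standard spontaneous-report disproportionality
design: restrict a FAERS-style database to reports naming a target drug as
primary suspect, deduplicate report versions, and compare the reporting
frequency of each adverse-event term against the background of all other
drugs through a 2×2 table of case–term pairs. The counting unit is the
case–term pair: one deduplicated case contributes at most once per
distinct PT, and at SOC level at most once per distinct SOC. This is the
field convention; databases do not state it and results are sensitive to
it, so it is worth making explicit.

Deduplication keeps, per CASEID, the version with the latest FDA receipt
date, breaking ties by the largest PRIMARYID. The rule is a pure
two-key maximum, hence idempotent and independent of input row order.

Cohort selection matches the normalized drug name (upper-cased,
whitespace-collapsed) or active ingredient **exactly** against a synonym
list, only for role code PS. Substring matching was deliberately rejected:
it silently captures combination products and makes cohorts irreproducible
across synonym lists.

## Disproportionality statistics

ROR, PRR and the Yates-corrected Pearson χ² are computed in closed form
(see README for formulas). Zero cells get the Haldane–Anscombe correction:
when any of a, b, c, d is zero, 0.5 is added to all four cells for
ROR/PRR/χ². Degenerate tables (a zero margin) report χ² = 0 with p = 1 and
are flagged rather than raised.

The BCPNN information component uses the closed-form shrinkage estimate
`IC = log2((a+½)/(E+½))` with the (3.3, 2.0) credible-bound coefficients.
This variant is deterministic and exactly testable; the original
moment-expansion formulation is available via `bcpnn_ic(..., variant="bate")`
for comparison but is not the default.

### MGPS / empirical Bayes

The relative reporting rate λ of each term has the five-parameter mixture
prior λ ~ P·Gamma(α₁, β₁) + (1−P)·Gamma(α₂, β₂) (shape/rate), with
a | λ ~ Poisson(λE) and E = (a+b)(a+c)/N the count expected under
independence. Marginally a is a two-component negative-binomial mixture;
the prior is fitted by maximizing the summed marginal log-likelihood with
L-BFGS-B on log-transformed shapes/rates and a logit-transformed weight,
box-constrained to [1e-6, 1e6] (weight to [1e-6, 1−1e-6]). Five fixed
starting points are tried — including the canonical
(α₁, β₁, α₂, β₂, P) = (0.2, 0.1, 2, 4, 1/3) — and the best converged fit
wins, making the fit deterministic. At least 10 (a, E) pairs with E > 0
are required; below that the fit refuses rather than returning an
unidentified prior.

The posterior of λ is the updated mixture Q·Gamma(α₁+a, β₁+E) +
(1−Q)·Gamma(α₂+a, β₂+E); EBGM = exp(E[ln λ]) via the digamma function and
EBGM05 solves the mixture CDF = 0.05 by Brent root-finding (bracketed by
the 99.9th percentiles of the components, tolerance 1e-12).

With a small event vocabulary (tens of terms rather than the thousands of
a full database), the fitted prior adapts to mostly-null data and shrinks
isolated strong signals substantially; they still clear the EBGM05 > 2
threshold at realistic counts, but EBGM should not be read as an unbiased
rate estimate in small vocabularies.

### Positive-signal conjunction

positive ⇔ (n ≥ 3 and ROR lower 95% bound > 1) and (n ≥ 3 and PRR ≥ 2 and
χ² ≥ 4) and (IC025 > 0) and (EBGM05 > 2). Every constant is configurable
(`SignalThresholds`). The conjunction is by construction never more
permissive than its strictest member; negatives carry a reason string
naming the failing methods.

### Background

The comparator for c and d is the set of non-target cases in the ingested
corpus. When a dataset contains only target cases (a target-only extract),
an explicit background count table must be supplied; the package refuses
to use the target set as its own background silently.

## Subgroup analysis

Within the target cohort, each term gets a per-case 2×2 (event vs no
event) between two strata: F vs M for sex, consumer vs healthcare
professional (MD, PH, HP, RN, OT) for reporter occupation, and one-vs-rest
for each age band. Cases with a missing stratum value are excluded here
(they remain in the descriptive tables as an explicit Missing category).
P-values come from the same Yates χ²; Benjamini–Hochberg FDR adjustment is
applied within each comparison. Volcano coordinates are x = log2(ROR),
y = −log10(p_adj).

Enrichment calls use the conventional direction p_adj < α (α = 0.05
default). A reversed reading (p_adj > α) circulates in some published
descriptions of this design; it is selectable (`rule="greater"`) so the
two behaviors can be compared, but it is documented as non-standard and is
not the default.

## Time to onset

TTO = event date − earliest full-precision target-drug therapy start
date, in calendar days. Partial dates (YYYYMM, YYYY) are excluded from TTO
— using them would fabricate day-level intervals — but retained for
descriptive tables and quarter-of-year tabulations (which need only the
month). Negative intervals are excluded with a reason; zero is a valid
onset. Quantiles use linear interpolation (type 7). The survival curve is
the empirical survival function S(t) = P(T > t): every report is an
observed event, so a censoring model would have nothing to estimate.
Onset bins are [0,30], [31,60], [61,90], [91,120], [121,150], [151,180],
[181,360], >360 days.

## Synthetic cohorts

The generator emulates the structure of FAERS quarterly archives: DEMO,
DRUG, REAC, THER, INDI and OUTC tables in the '$'-delimited ASCII dialect,
with demographics, one PS drug plus concomitants, multi-PT reaction sets,
therapy/event dates, outcome codes and duplicate CASEID versions.

**Reaction model.** Each report includes each vocabulary PT independently
with its baseline probability; a planted signal multiplies one PT's
probability by RR for target-drug reports (optionally within one sex).
Reports that come up empty are redrawn whole until non-empty. The
rejection step rescales all of a row's inclusion probabilities by the same
factor, so the population reporting odds ratio of a planted PT equals its
RR *exactly* — this is what makes confidence-interval coverage of the
planted RR a sharp test (measured coverage of the 95% ROR interval is
≈ 95.7% over 600 replicates). Replacing the rejection step with a single
forced draw from the baseline distribution would dilute planted signals
by roughly 5% and break coverage; this was measured and is why the
per-report PT count is Bernoulli-sum (mean ≈ 2 under the default
42-term vocabulary) rather than a shifted-Poisson draw.

**Defaults as study conditions.** The demographic mixes (sex 64/29/7%
F/M/missing, age bands, occupation codes, countries, weight bands,
indications) follow the marginal composition of a large published
methotrexate reporting cohort; the onset model is log-normal(μ=4.0, σ=1.5)
days truncated to [0, 8000], giving the heavy right tail characteristic of
spontaneous-report onset histograms; the target-drug probability defaults
to 0.2 so that both target and background cohorts are well populated at
desk scale (a real database has a far smaller target share; only the
relative 2×2 structure matters for the estimators). Dates are emitted as
YYYYMMDD integers with a configurable fraction partial (YYYYMM or YYYY)
and missing, to exercise the ingest policy.

**Duplicates.** With probability `duplicate_rate` a case emits one or two
extra versions sharing its CASEID, with strictly larger PRIMARYIDs and FDA
dates 0–180 days later. The truth table records every version and the one
the retention rule must keep, so deduplication is testable exactly.

**What the generator does not model:** MedDRA hierarchies beyond a toy
one-SOC-per-PT table, correlated reactions within a report, country- or
time-varying reporting dynamics, dose information, and report narratives.
Passing tests on synthetic data therefore validate the *pipeline
arithmetic and calibration*, not the clinical plausibility of any signal
in real data.

**Determinism.** One root seed; every stage draws from its own child of a
single `SeedSequence`, so any stage is replayable and identical configs
give byte-identical output files.

## Problem sizes in the test and acceptance runs

Calibration and power checks use the sizes a desk study can afford: null
calibration on one 50,000-report cohort (~10⁵ case–PT pairs), CI coverage
over 200 cohorts of 10,000 reports, subgroup power over 100 cohorts of
50,000 reports, MGPS recovery from 2,000 simulated terms, and dedup
recovery at duplicate rates 0/0.3/0.6. A fast in-memory assembly path
(`cohort_case_data`) builds the joined dataset directly from generated
tables for these simulation studies; its equivalence with the full
write-read-join path is itself under test.

## Known limitations

- The MGPS prior is fitted unstratified; DuMouchel-style stratification by
  age/sex/year is out of scope.
- The BCPNN default is the closed-form shrinkage variant, not an MCMC
  posterior; credible bounds are approximate for very small E.
- Drug-name normalization is synonym-list based; no ingredient ontology
  (RxNorm-style) resolution.
- Pre-2012 legacy AERS column layouts are not parsed.
- The dialect writer rejects fields containing '$' (the format has no
  escape mechanism) rather than attempting lossy escaping.
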