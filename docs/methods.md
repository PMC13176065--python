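# Methods

## Data model and protocol

The pipeline consumes the public FAERS quarterly ASCII dialect:
`$`-delimited text, one header line, schemas DEMO (report versions,
demographics, dates), DRUG (drugs per report with role codes PS/SS/C/I), REAC
(MedDRA PTs per report) and THER (therapy start dates per drug). Partial
dates (YYYY, YYYYMM) are kept as typed partial dates and never imputed;
downstream stages decide usability. Unknown columns pass through untouched.

**Deduplication.** Spontaneous cases are re-versioned as follow-up arrives.
One version per CASEID is kept: the latest FDA receipt date, ties broken by
the highest PRIMARYID (compared numerically when all contenders are
all-digit, else lexicographically — FAERS ids are numeric in practice).
Duplicate detection is exact CASEID match only; probabilistic record linkage
is out of scope. Deduplication runs on the full ingest, before cohort
restriction.

**Cohort.** A report enters the target-drug cohort when at least one DRUG row
has the required role (default PS, primary suspect) and a name — verbatim or
active ingredient — matching a synonym list after case-folding and whitespace
collapsing. Matching is exact-after-normalization, not fuzzy: cohorts must be
auditable. A report with several matching rows counts once.

**Demographic plausibility.** Reports with age outside [0, 120] years
(converted from the FAERS unit codes DEC/YR/MON/WK/DY/HR), missing age, or
unreported sex are excluded from *descriptive* tabulations only. They remain
in every 2×2 table: disproportionality needs the full background, and the
tests assert the screen never changes a cell.

**PT→SOC mapping.** MedDRA is licensed, so the mapping (PT → single primary
SOC) is a user-supplied TSV. Lookups are case-insensitive; unmapped PTs are
tagged, counted under an `<unmapped>` pseudo-SOC, and reported — counts always
reconcile exactly.

## Contingency tables

Cells count either drug–event records — (report, term) pairs, the default —
or distinct reports; both at PT and SOC level, with within-report duplicate
terms collapsed to one (a report contributes each SOC once, however many of
its PTs map there). The record unit is the default because the published
SOC-level case counts partition the cohort's record total under it (the
drug margin is the sum of the SOC case counts), which is also what makes the
published CI bounds reproducible from printed margins. The comparator is
always the full remaining database; no drug-class restriction. Terms need
a ≥ 3 cases for signal scoring; descriptive outputs keep all terms.

## The four algorithms

*ROR and PRR/χ²* are the classical frequentist measures (formulas in the
README). χ² is Pearson without continuity correction by default — Yates is an
option — because back-computation from the published COVID-19 row matches the
uncorrected statistic. Zero cells make ROR/PRR undefined (flagged, never
silently Haldane-corrected): with the a ≥ 3 eligibility floor a zero cell
signals a data problem, not a statistic to rescue.

*BCPNN.* The information component uses the standard closed-form posterior
approximation with priors α = β = 2, α₁ = β₁ = γ₁₁ = 1 and the joint-cell
prior total γ calibrated to the margins, so the prior IC is centred at zero:

    IC    = log₂[(a+γ₁₁)(N+α)(N+β) / ((N+γ)(a+b+α₁)(a+c+β₁))]
    V(IC) = (1/ln2)²·[(N−a+γ−γ₁₁)/((a+γ₁₁)(1+N+γ))
            + (N−a−b+α−α₁)/((a+b+α₁)(1+N+α))
            + (N−a−c+β−β₁)/((a+c+β₁)(1+N+β))]

and IC025 = IC − 2√V(IC). The closed form carries an O(1/a) bias relative to
the exact posterior mean (≈0.12 bit at a = 5 with large margins); the
Monte-Carlo agreement test therefore samples tables with a ≥ 10, where the
measured disagreement stays below 0.06 bit.

*MGPS.* The two-component gamma mixture prior on λ = a/E (five
hyperparameters: two shape/rate pairs and a mixing weight) is fitted by
maximizing the marginal likelihood — a mixture of negative binomials — over
all (a, E) pairs of the run, from DuMouchel's conventional start
(0.2, 0.1, 2.0, 4.0, 1/3). The optimizer works in log space for shapes/rates
and logit space for the weight: the natural-scale surface is badly
conditioned (near-null databases push shapes toward infinity) and aborts
L-BFGS-B line searches. A stalled search is retried from two fixed alternate
starts; pairs are sorted before summation so the fit is exactly invariant to
table order. Scoring uses the conjugate posterior (component j: shape αⱼ+a,
rate βⱼ+E, weight ∝ prior weight × marginal negative-binomial mass):
EBGM = exp(Σⱼ Qⱼ[ψ(αⱼ+a) − ln(βⱼ+E)]), and EB05 solves mixture-CDF = 0.05 by
Brent root search to 1e−8 relative tolerance (no normal approximation).
A *simplified* mode — EBGM = a/E with a log-normal-style EB05 sharing the
ROR's Wald standard error — is provided because many published FAERS analyses
use that family (their printed EBGM₀₅/EBGM ratios equal the ROR's lower/point
ratio, which no genuine shrinkage posterior reproduces).

*Classification.* ROR lower CI > 1 (strict); PRR ≥ 2 **and** χ² ≥ 4 (both
non-strict); IC − 2 SD > 0 (strict); EB05 > 2 (strict). Consensus = all four.
Terms under the case floor get all-false flags with an eligibility marker.

## Time-to-onset

Onset = event date − earliest *complete* start date among the report's
matching primary-suspect therapy rows (first exposure). Records with missing
or partial dates, or negative intervals, are excluded with per-reason tallies
that reconcile to the cohort size. Quartiles use inclusive linear
interpolation (conventions differ by up to a day; this one is pinned by
regression tests); the within-one-year cutoff is ≤ 365 days inclusive;
histogram bins are 0–30, 31–90, 91–180, 181–365, 366–730, > 730 days.

## Subgroups

Strata are age < 18 / age ≥ 18 (18-year-olds are adults) and sex M / F.
Each stratum restricts **both** cohort and background to its members
(children compared to children — the epidemiologically defensible default;
full-background mode is available) and reruns the whole scoring stack,
including a fresh MGPS prior fit, on the stratum's tables. Reports on which
the stratum predicate cannot be evaluated (unknown age, unknown sex) drop out
of that stratification only.

## The synthetic generator

`synthetic.generate` emulates the statistical structure the analysis assumes,
with every quantity controlled by `SyntheticConfig` and a single integer
seed:

- versioned duplicate cases (default 8% re-versioned with later receipt
  dates and higher PRIMARYIDs);
- drug exposures with primary-suspect vs secondary/concomitant roles;
- events as independent Bernoulli draws per configured PT, multiplied by a
  planted relative risk (capped at 1) when the planted drug is the report's
  primary suspect — independence is exactly the assumption the 2×2 statistics
  make, so planted RRs are directly comparable to pipeline RORs;
- a per-report filler draw (zero-truncated Poisson, mean 1.2) from a disjoint
  background PT vocabulary, guaranteeing ≥ 1 reaction per report (as in
  FAERS) while scaling both cohort and background record margins equally —
  configured events keep their exact probabilities and the ROR of a planted
  pair stays centred on the planted RR;
- demographics emulating a pediatric, heavily male cohort: 98.5% male, 0.3%
  female, 62% under 18, 4% missing age, 1% implausible age (> 120 years);
- onsets from a log-normal parameterized directly by its median (default
  253 days, σ = 1) with configurable missing/partial-date rates (defaults
  leave roughly a third of cohort reports with complete onset data) and a
  2% rate of negative intervals to exercise exclusions. Note the published
  onset figures this emulates are mutually inconsistent (a 253-day median
  implies > 50% of onsets within a year, yet 36.04% is printed); the median
  is taken as the direct input, so the generator's within-year fraction is
  ≈ 64%.

What it does **not** emulate: reporting dynamics over calendar time (Weber
effect, stimulated reporting), correlated event clusters beyond the planted
effects, drug–drug interactions, or free-text name noise. Passing calibration
tests therefore show the pipeline recovers known disproportion under the
statistics' own assumptions — not that FAERS data satisfy those assumptions.

`synthetic.worked_example` is a ten-case hand-enumerable dataset whose
contingency tables, ROR/PRR/χ² values and onset exclusions were computed by
hand and frozen; the pipeline's outputs on it are golden-filed.

## Problem sizes and numerical choices

Default analyses simulate 20,000 reports; the calibration scenario plants
RR = 20 at background 0.005 with 2% exposure in 50,000 reports, replicated
50× in the acceptance suite (10× in the narrative driver), with CI coverage
of the planted RR ≥ 90% required. Null-data positive rates are measured on a
50,000-report database with ~50 eligible terms. Oracle equivalence uses 200
random tables (1e−10 relative for closed forms), 2×10⁵-draw Monte-Carlo
posteriors for IC, and 10⁶-draw posterior quantiles for EB05. MGPS recovery
uses 5,000 simulated (a, E) pairs from a well-separated truth (component
means 1 and 10), compared after ordering components by mean — mixture labels
are arbitrary. All randomness flows from explicit integer seeds; generated
dates derive from integer day offsets, so outputs are byte-reproducible
across platforms.

## Known limitations

- Disproportionality measures reporting association only; no causal or
  incidence interpretation, and no multiple-comparison adjustment (matching
  standard practice for these four criteria).
- The BCPNN closed form is an approximation; its known small-count bias is
  documented above rather than patched.
- Crude (unstratified) expected counts; year- or covariate-adjusted E is out
  of scope.
- Published IC025 and EBGM values from analyses whose exact formula variants
  are unpublished cannot be reproduced bound-for-bound; the package documents
  its variants precisely so users can match alternatives.
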