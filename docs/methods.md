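# Methods

## Data model

A panel is a long-format table of (reporting unit, indicator, month)
cells.  Months are a contiguous 1-based index 1..T (T = 24 by default,
two calendar years); calendar systems (Gregorian, Ethiopian, Nepali
fiscal) are reconciled once at ingest via a schema map and never
downstream.  Units may be facilities or districts that aggregate small
facilities; every metric treats both identically as "reporting units",
which also means the per-unit outlier SDs of a mixed-level panel pool
heterogeneous unit sizes — a caveat the run log surfaces rather than
resolves.  A cell holds a non-negative integer count or is missing;
a reported 0 and a missing cell are distinct states throughout.

## Cleaning rules

**Death zero-imputation.**  Small facilities often leave death cells
blank in months with no deaths.  A missing death count at (unit, month)
is imputed to 0 iff the linked service count at the same (unit, month)
is reported and strictly positive; otherwise it stays missing, and
reported values are never altered.  The strict-positive condition is a
deliberate reading: a reported service count of exactly 0 means the
service was not provided that month, so a zero death count cannot be
distinguished from non-observation.  A `strict` switch imputes whenever
the linked service is non-missing, for sensitivity analyses.  The rule
applies to every death indicator that has a linked service in the
registry; which deaths link to which services is registry data, not
code.

**C-section non-provider exclusion.**  Units whose c-section values sum
to 0 over the whole period (including all-missing series) have the
entire series set to missing, removing structural zeros from facilities
without surgical capacity.  Both rules are idempotent, change only cell
values (never keys), and emit change logs into the run metadata.

Imputation runs before exclusion and before all metrics, since
completeness is assessed on the imputed panel.

## Completeness

Expected units for an indicator = the maximum number of units reporting
it in any single month of the period (no master-list denominator).
Monthly completeness = 100 × reporters / expected; at least one month
scores exactly 100 by construction (several can, under ties).  A
reported zero counts as reporting.  An indicator never reported at all
has an undefined denominator and is dropped with a warning rather than
scored 0%, distinguishing "not collected" from "collected but
unreported".

The period contrast treats monthly percentages as observations (15 pre
vs 9 pandemic by default) and uses Welch's two-sided t-test; the pooled
variant is a config switch.  Months are treated as independent
observations — the natural reading of a 15-vs-9 comparison — and no
multiple-testing adjustment is applied across the indicator grid, with
per-cell significance flagged at 0.05.  Degenerate cases: with < 2
months in a period the p-value is reported missing; two zero-variance
samples give p = 1 (equal means) or 0 (unequal), where the t statistic
is 0/0.

## Outliers

Per (unit, indicator), mean and sample SD (ddof = 1) are computed over
the unit's non-missing months, candidate point included — the plain
full-series screening convention of routine data-quality review
tooling; a leave-one-out variant is available (`mask_candidate=True`).
A value is flagged iff it lies strictly beyond mean ± z·SD (z = 3.5).
Units with SD = 0 or fewer than 4 observed months produce no flags (a
configurable stability floor; SDs over very short series are too noisy
to screen against).  Frequencies use non-missing unit-months as
denominators, overall and per period; period counts partition the
overall count exactly.  Flagging is invariant to scaling and shifting a
unit's series and monotone non-increasing in z.

## Internal consistency

Annual (reference-year, default months 1–12) totals of BCG,
pneumococcal-3, oral-polio-3 and rotavirus-2 are expressed as
percentages of the pentavalent-3 total.  The comparator set is data
(a vaccine role map), not code, because antigen availability differs by
country; roles missing from an extract are skipped, never zero-filled,
and a panel without the anchor yields no row.  Display percentages are
rounded half-up to integers (97.502 → 98); full precision is retained
internally.  Cross-row summaries (min, max, max pairwise gap) are
computed on display values; the gap excludes BCG by default because the
birth dose legitimately diverges from the 6-week series.  Reference
totals are summed over whatever months are configured, with no
completed-period filtering.

## External consistency

With `d` annual HMIS deliveries, `c` annual HMIS c-sections and survey
facility-delivery rate `q`: estimated births `B = d/q`, HMIS c-section
rate `100·c/B = 100·c·q/d`, compared to the survey c-section rate in
percentage points.  Assumptions: the HMIS captures all facility
deliveries and all c-sections within its scope, and the survey rates
are accurate and scope-matched (the benchmark carries a mandatory
provenance label and scope note; a public-sector HMIS needs a
public-facility delivery rate).  The sensitivity interval recomputes
the rate at `q ± δ` (δ = 3 pp default); since a higher `q` implies
fewer estimated births, the +δ arm is the upper end.  Perturbed rates
are clipped into (0, 1] with a warning.  The significance test is the
standard large-sample two-proportion z-test, with estimated births and
the survey birth-sample size as denominators — the denominators are an
explicit input because published comparisons rarely state them; without
a survey sample size the difference is reported and the test skipped.
Only reference-year (pre-pandemic) totals feed the estimator.

## Synthetic generator

The generator emulates the structure of a two-year DHIS2 extract, with
defaults chosen once as the study conditions:

| parameter | default | rationale |
|---|---|---|
| reporting probability (pre, pandemic) | 0.95, 0.95 | routine reporting is high and was largely stable at the pandemic onset |
| pandemic volume multiplier | 0.9 | modest service disruption in months 16–24 |
| unit scale distribution | lognormal, σ = 0.5 | right-skewed facility sizes |
| month noise | Poisson (NB optional) | count data; overdispersion opt-in |
| spike planting rate / magnitude | 0.002 / 8 SD, half positive | observed positive-outlier frequencies are 0–0.6% |
| antigen completion probs | BCG .95, penta3 .90, pneumo3 .89, polio3 .88, rota2 .87 | anchor ratios in the realistic 91–110% band |
| death probabilities | 0.003–0.02 of linked service | order-of-magnitude institutional mortality |
| facility delivery / c-section proportion | 0.60 / 0.05 | typical LMIC magnitudes |
| c-section provider fraction | 0.3 | only hospitals perform surgery |
| zero-as-missing corruption | 0 (off) | enabled explicitly in tests probing the 0-vs-blank ambiguity |

Counts are generated first (planted spikes included), corruption —
missingness, zero-as-missing — second, so `GroundTruth` refers to
pre-corruption counts.  Death counts are binomial thinnings of their
linked service and are reported exactly in the months the service is
reported, which is what gives the imputation rule realistic work.
C-sections are drawn per provider unit from catchment births;
facility deliveries are the c-sections plus a binomial share of
remaining births.  The survey truth (facility-delivery rate, c-section
rate) is the *realized* ratio of generated totals, which makes the
external-consistency loop close exactly under complete capture — the
configured `csection_prop` applies within provider catchments, so the
realized population rate is lower by the provider birth share.  Each
indicator consumes its own CRC32-keyed substream of the seed, so adding
an indicator never perturbs another's draws; identical (seed, config)
give byte-identical panels.

What the generator does **not** emulate — and hence what passing tests
do not establish about real extracts: seasonality and secular trends,
spatial or administrative hierarchy, correlated unit-level reporting
shocks (strikes, stock-outs), digitisation-driven completeness ramps,
and private-sector undercapture.  Tests against it validate the
*metrics*, not any country's data quality.

## Numerical choices

- Percentages are computed in float64 and display-rounded half-up to
  integers only at report writing.
- The completeness t-test handles zero-variance arms explicitly (see
  above) instead of propagating NaN.
- Outlier comparisons use strict inequalities; band-edge values are not
  flagged.
- Proportion-test counts are rounded to integers; a degenerate table
  (no events, or all events) reports p = 1 for equal rates and skips
  otherwise.
- Problem sizes in the validation suite (10³ series for the brute-force
  screen, ~10⁵ unit-months for spike recovery, 10³ replicates for test
  size) were chosen to bound Monte-Carlo error well below the asserted
  tolerances while keeping the suite quick on a laptop.

## Known limitations

- Timeliness of reporting and population-denominator consistency are
  out of scope.
- The expected-units denominator is data-derived: a unit that never
  reports is invisible, so completeness is relative to the observed
  reporting universe, not the true facility roster.
- Mixing facility- and district-level units within one indicator pools
  heterogeneous scales into the outlier SDs (logged, not corrected).
- Units drawing two planted spikes can have both absorbed by their own
  inflated SD — an inherent property of include-the-candidate
  screening, visible in the recovery tests.
- The external-consistency test's p-value depends on the supplied
  denominators; treat it as indicative, not inferential, when the
  survey sample size is approximate.
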