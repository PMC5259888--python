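# Methods

## Model

`prev2inc` estimates the incidence of an irreversible chronic condition
from two cross-sectional prevalence measurements taken `T` years apart in
an open population, stratified by sex × age band. The model is a
closed-form two-compartment balance: of the people standing at the first
survey, a fraction `SP·p0` are prevalent cases that survive the interval
and `SN·(1 − p0)` are disease-free survivors; the whole-stratum survival is
`F = SP·p0 + SN·(1 − p0)`. Any excess of the second-survey prevalent share
`F·pT` over the surviving baseline cases `SP·p0` must be incident cases, and
dividing by the person-years at risk — the trapezoid
`T·(1 − p0 + F·(1 − pT))/2` of the disease-negative share at the two
endpoints — gives the rate

    I = 2 (F·pT − SP·p0) / ( T (1 − p0 + F (1 − pT)) ).

Assumptions: the condition is irreversible (no remission flow back to the
negative compartment); prevalence and mortality are constant within each
inter-survey interval; each stratum is closed over one interval (no aging
across band boundaries, no migration); the two surveys sample the same
population.

### Survivor attrition: what the estimator actually recovers

The numerator counts only incident cases **alive at the second survey**.
An incident case converts at a roughly uniform time over the interval and
must then survive, at relative survival `ρ = SP/SN` per interval, to be
counted. Integrating over a uniform conversion time, the estimator's
population value is not the true hazard `h` but

    I ≈ h · κ(ρ),    κ(ρ) = (ρ − 1) / ln ρ    (κ → 1 as SP → SN).

This is verified numerically against the package's own continuous-time
propagator: the κ law holds within ~1.5 % at typical cardiovascular
parameter values and within ~8 % over an extreme grid (baseline prevalence
up to 0.3, survival gaps up to 40 points). Consequences:

- With mild differential mortality (`ρ ≥ 0.95`, e.g. 2-year SP ≥ 0.95
  against SN ≈ 0.99) the raw bias is under ~3 % and the estimator recovers
  the hazard within 5 %.
- At MI-like survival (SP ≈ 0.81, SN ≈ 0.98, so ρ ≈ 0.83, κ ≈ 0.91) the
  estimator under-states true incidence by ≈ 9 %. Hospital-based
  comparison statistics share much of this attrition (fatal incident cases
  never appear in either), which is why the method still tracks observed
  hospitalized series well; but as an estimate of the true event hazard the
  raw value should be read as `h·κ`.

The test suite asserts the κ-corrected recovery; the uncorrected 5 % claim
is only true in the mild-mortality regime and is tested there.

## Parameters

| parameter | units / scale | default | rationale |
|---|---|---|---|
| `T` | years | 2 | biennial national survey cycles |
| `SP`, `SN` | proportion over `T` | — | built from case fatality / vital statistics |
| `annual_decline` | proportion per calendar year | 0.03 | published secular decline in MI case mortality |
| `baseline_year` | calendar year | 1999 | first survey cycle of the motivating application |
| `w_MI, w_AG, w_HF` | proportions, sum 1 | 1, 0, 0 | component weights of the composite outcome (validated, never computed from microdata) |
| fatal, silent fractions | proportion of events | 0.30, 0.20 | literature shares of fatal and unrecognized MI; hospitalized share (1−f)(1−s) = 0.56 |
| `ci_level` | proportion | 0.95 | convention |
| `min_age` | years | none | study-population filter (35+ for MI-style, 12+ for heart-disease-style analyses) |
| `m_substeps` | count | 100 | propagator discretization; end prevalence changes < 1e−5 beyond this |

All proportions in files and APIs are on the [0, 1] scale; the per-100,000
scale exists only in reports and presentation columns.

## Design choices

**Survival construction.** The interval MI mortality is composed as
`M_MI = M_in + (1 − M_in)·M_out` (independent sequential risks; equivalently
survival multiplies). The secular decline applies to the *combined* `M_MI`,
per calendar year from `baseline_year`, not separately to the components.
Composite heart-disease survival mixes component mortalities linearly with
prevalence weights. `SN = 1 − (MV_all − MV_dis)` requires both vital
statistics already cumulated over `T`; the builder refuses
`MV_dis > MV_all` rather than clamping, because that signals inconsistent
sources. Sex-only case-fatality rows broadcast across that sex's age bands.

**Negative estimates.** When prevalence falls faster than mortality
attrition explains (sampling noise in small strata), the raw negative rate
is preserved and flagged, and it enters standardization as-is; flooring at
zero would bias every standardized rate upward. Standardized outputs carry
the count of negative-flagged strata. Confidence intervals are refused for
negative point estimates (the Poisson model has no parameter there).

**Confidence intervals.** Exact Garwood limits on the implied event count
`rate × n × person-years-per-respondent`, with `n` the first-wave stratum
respondent count (the natural at-risk base; the method itself does not
prescribe one). The lower limit is 0 at zero events. These intervals model
only the Poisson noise of the implied count and *ignore the binomial
sampling error of the first-wave prevalence*; simulation shows nominal 95 %
intervals cover the estimand ≥ 95 % when baseline prevalence is near zero
but can drop toward ~60 % when `p0` is large relative to the prevalence
change. They should be read as lower bounds on uncertainty for established
diseases.

**Zero-prevalence substitution.** Within each sex, ordered by age, a zero
prevalence borrows the first non-zero value from the next-older band; zeros
older than the last non-zero band stay zero; an all-zero sex group warns
and passes through. Substitution is applied per wave, before pairing.

**Interval dating and trend convention.** A wave whose label spans two
years ("1999–2000") is dated January 1 of its second year; a single-year
label ("2001") is dated January 1 of that year. An estimate from
consecutive waves is attributed to [Jan 1 ref0, Jan 1 refT). This single
rule reproduces the presented interval labels of both motivating surveys
and, with trend `x = interval start year − 2000`, reproduces the published
trend coefficients for both. Trend fits consume the *presented integer*
rates (the published coefficients are only reproducible at printed
precision); full-precision values are kept alongside. Percent summaries
use the fitted value at `x = 0` as denominator: annual percent decline
`100·|slope|/intercept`, horizon reduction `100·years·|slope|/intercept`
capped at 100.

**Standardization.** Weights are the standard population's stratum shares
after truncation to `min_age`; the filter must align with band edges (a cut
inside a band is a configuration error, not a silent re-weight). Every
standard-population stratum must have a matching rate; extra rate strata
outside the standard are ignored.

## The simulator

`simulate` forward-propagates per-stratum prevalence through the same
two-compartment bookkeeping the estimator assumes, in `m` sub-steps per
interval: survive (positives at `SP^(1/m)`, negatives at `SN^(1/m)`), then
convert surviving negatives with probability `1 − exp(−h·T/m)`. Expected-
value mode is deterministic; binomial mode draws each wave's observed
prevalence as `Binomial(n, p)/n` per stratum from a seeded generator.

What it emulates: an open population (deaths replaced implicitly by the
prevalence-among-survivors bookkeeping), differential mortality, constant
hazards, biennial waves, survey sampling noise. What it does not: aging
across strata and migration (an individual keeps its stratum for an
interval — adequate at `T = 2` with 5-year bands and exactly matching the
estimator's own constancy assumption), survey design effects and weights
(draws are simple binomial), secular change within an interval, recall or
diagnostic misclassification. Passing recovery tests therefore validates
the estimator's internal consistency under its own assumptions, not
robustness to the measurement problems of real surveys.

The default scenario (`mi_like_scenario`) is fixed at MI-like era-2000
magnitudes: 2 sexes × 5 bands (35+), hazards 0.4–15 per 1,000 person-years
rising with age, baseline prevalence 0.5–18 %, SP 0.95→0.78 and SN
0.997→0.88 with age, 7 waves, 300 respondents per stratum per wave in
binomial mode (the order of a national examination survey's cell counts).

## Numerical choices

- Garwood limits use chi-square quantiles `χ²(α/2, 2k)/2` and
  `χ²(1−α/2, 2k+2)/2`, valid for non-integer implied counts.
- The propagator's conversion probability uses `expm1` for small-hazard
  accuracy; a stratum whose compartments both reach zero returns
  prevalence 0.
- Degenerate strata (non-positive person-time, i.e. universal prevalence
  at both surveys) raise rather than return ±inf.
- Tables round-trip CSV at 12 significant digits (`%.12g`); equality in
  tests is asserted at rtol 1e−11.
- OLS is ordinary least squares via statsmodels; trend fits require ≥ 3
  points with all-distinct years.

## Problem sizes used in the test suite

Property tests run the propagator at `m = 200` sub-steps over ≤ 80
hypothesis examples (derandomized); the CI-coverage check uses 300
replicates at `n = 5,000`; the binomial-convergence check uses one draw at
`n = 10⁶`. The full suite completes in well under a minute on one CPU.
These sizes were chosen so the whole suite stays desk-scale while leaving
the asserted tolerances comfortably non-binding.

## Known limitations

- Survivor attrition (above): raw estimates are `h·κ(SP/SN)`, a ≈ 9 %
  understatement at MI-like survival; users comparing against true event
  hazards should divide by κ.
- CIs understate uncertainty when baseline prevalence is substantial.
- The approximation in the incidence formula is first-order in the
  interval; no error analysis exists for long intervals, and `T = 2` years
  is the tested regime.
- Self-reported prevalence carries recall and diagnostic biases the model
  cannot correct; it inherits whatever bias the survey instrument has.
- The hospitalization adjustment applies one fatal/silent split to all
  years and strata.
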