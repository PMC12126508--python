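# Methods

## Scope and model

`spiritrisk` implements a deterministic chronic-exposure assessment for
metal contaminants in spirits, of the kind used in unrecorded-alcohol
surveillance. It is not a fitted statistical model: given a sample table,
per-element toxicological constants, and drinker scenarios, every output is
an exact function of the inputs. The `RiskAssessment`/`RiskAssessmentResults`
pair presents this computation in the model/results idiom for convenience
(`fit()` runs the pipeline; results carry cell accessors, tidy frames and a
text summary), not because any estimation takes place.

The exposure chain is:

1. **Screening scale.** Concentrations are expressed in mg per litre of
   pure alcohol (p.a.). Beverage-scale inputs are divided by ABV/100; the
   measured (GC/MS) ethanol strength is used for this normalisation rather
   than the producer-reported one, since reported strengths are unverified.
2. **Censoring.** Entries below the limit of detection are replaced by
   LOD/2, the conventional substitution for left-censored trace-element
   data. Censoring flags are retained, so detection and exceedance counts
   are computed from the raw flags, never from substituted values. A
   censored entry can never count as exceeding a threshold.
3. **Summary levels.** The median and 99th percentile of each element's
   substituted column are the two concentration summary levels (MCS). The
   percentile convention is linear interpolation between closest ranks,
   h = (n−1)p + 1 (numpy's `"linear"`); other numpy conventions can be
   selected, but the default is the one under which the packaged study data
   reproduce their published summary and risk tables.
4. **Exposure and risk.** MCS is converted to mg per gram of pure alcohol
   (division by 789 g/l, ethanol density 0.789 g/cm³, not
   temperature-corrected) and combined with a scenario:
   EDI = MDI·MCS/BW; THQ = (MCS·MDI·EF·ED)/(RfD·BW·AET); MOE = BMDLx/EDI.
   With AET = 365·ED and EF = 365 d/y the THQ algebraically equals EDI/RfD;
   both routes are computed in tests and agree to machine precision.
   Elements with an oral reference dose get a THQ; elements with only
   benchmark-dose lower bounds (lead) get one MOE per health endpoint.
   Classification: THQ > 1.0 "elevated"; MOE < 100 "public health concern".
5. **Element selection.** By default an element enters the risk stage iff
   at least one sample exceeds its AMPHORA screening threshold (for the
   packaged data: Cu, Fe, Ni, Pb). An explicit element list overrides this.
   No hazard index is summed across metals; each is assessed separately.

## Parameters and defaults

| Parameter | Default | Units | Rationale |
|---|---|---|---|
| AMPHORA thresholds | Al 2.0, Cu 2.0, Fe 2.0, Mn 0.5, Ni 0.2, Pb 0.2, Zn 5.0 | mg/l p.a. | project limits for unrecorded alcohol |
| LOD | Cu 1.0e-4, Fe 2.0e-4, Ni 5.0e-4, Pb 2.2e-3 | mg/l | ICP-OES detection limits of the packaged survey |
| RfD | Cu 0.04, Fe 0.7, Ni 0.011 | mg/kg bw/day | oral reference doses |
| Pb BMDL | cardiovascular 0.0015 (BMDL01), nephrotoxicity 0.00063 (BMDL10) | mg/kg bw/day | EFSA endpoints for lead in adults |
| MDI | average 1.62, heavy 60 | g ethanol/day | average: mean neighbouring-country per-capita unrecorded volume, 0.75 l p.a./yr × 789 g/l ÷ 365; heavy: conventional heavy-drinking dose |
| BW | 73.9 | kg | average adult body weight, both sexes |
| EF | 365 | days/year | daily consumption assumed |
| ED | 65.4 | years | remaining life expectancy at age 15 |
| AET | 365 × ED | days | non-carcinogenic averaging time |

All constants are data, not code: element constants can be overridden with a
YAML/JSON file (`load_reference`), scenarios with a YAML list (CLI
`--scenarios`) or by constructing `ConsumptionScenario` objects.

Scenario constants are used exactly as stated (MDI = 1.62, not the unrounded
0.75·789/365 = 1.6212…): the assessment treats the published scenario dose
as the definition, and `scenario_from_annual_volume` exists for deriving new
scenarios from per-capita volumes.

The LOD constants are on the mg/l beverage scale as measured; the packaged
concentration table is on the mg/l p.a. scale, and the LOD/2 substitution is
applied to the values as given without back-converting each sample's LOD to
the beverage scale. This is deliberate: the substituted values are an
imputation convention, not measurements, and this convention is the one
under which the packaged data reproduce their published percentile tables.
Callers normalising beverage-scale data themselves should convert the LOD by
the same factor; substitution and a linear unit change commute (tested).

## Statistical procedures

**Wilcoxon signed-rank** (reported vs measured ethanol): differences are
measured − reported over pairs where both exist; zero differences are
dropped; tied absolute differences receive mid-ranks. For ≤ 15 nonzero pairs
the two-sided p-value is exact, from the full 2ⁿ sign-assignment null built
by subset-sum convolution over doubled (integer) ranks; beyond that a normal
approximation with tie-corrected variance and 0.5 continuity correction is
used. The exact mode agrees with a brute-force enumeration oracle to
machine precision; the approximation sits within about 0.01 of the exact
p-value at n = 15 (slightly more in unfavourable tie patterns). scipy's
`wilcoxon(..., method="approx", correction=True, zero_method="wilcox")` is
the independent cross-check in the test suite.

**Prices** are summarised as arithmetic mean ± sample (n−1) SD over known
values; the SD is absent for fewer than two.

**Ethanol descriptives** report both mean and median with IQR explicitly,
since survey write-ups sometimes label one as the other.

## Synthetic data

The generator (`spiritrisk.simulate`) emulates the structure the analysis
assumes: independent per-element log-normal concentrations (median and
geometric SD parametrised; log-normality is the standard model for trace
contaminants and matches the heavy right tails seen in real surveys),
censored against the element's LOD *after* the draw so ground truth is
available to tests; measured ABV from a normal(45, 5) truncated to
(30, 70) % v/v; reported ABV = measured − 1.6 + N(0, 3.5), occasionally
missing; prices uniform on 2.5–10 EUR/l; ~10 % missing metadata. Defaults
mirror the packaged survey: a dominant copper signal (median 11.5 mg/l
p.a.), mostly-censored nickel with a heavy tail (median below its LOD,
GSD 8), partially censored lead (median 0.0655 mg/l p.a., GSD 4).

What it does *not* model: between-element correlation (e.g. copper and lead
both tracking still quality), covariates such as raw material or
distillation year, measurement error, or rounding of reported strengths to
label values. Passing parameter-recovery and end-to-end tests on synthetic
data therefore demonstrates the pipeline's arithmetic and its behaviour
under censoring, not robustness to those real-data features.

Parameter-recovery tests use n = 10,000 synthetic samples (pipeline median
within 5 % of the generator median, and an end-to-end check that a lead
median placed at the MOE = 100 intake boundary yields MOE ≈ 100); this size
keeps Monte-Carlo error well inside the tolerance while the whole suite
runs in seconds.

## Numerical and formatting conventions

- All statistics are carried at full double precision; MCS values feed the
  risk formulas unrounded (several published-style table cells, e.g. a
  copper THQ of 8.0e-3, only emerge from the unrounded median). Display
  rounding (2 significant digits, scientific notation) happens exclusively
  at reporting time.
- Tests that compare against published-style rounded values accept one unit
  in the last printed digit, under either rounding or truncation of that
  digit (band [printed − ulp, printed + 2·ulp)): printed risk tables in this
  field mix both conventions, and a handful of reference cells are
  demonstrably truncations of intermediate-rounded quotients.
- Degenerate inputs: empty percentile input raises; all-zero difference sets
  give p = 1 with a warning; an EDI of zero yields an infinite MOE ("no
  concern"); an element with censored entries but no LOD raises rather than
  silently dropping; an element with neither RfD nor BMDL is reported with
  EDI only, with a warning.
- Exceedance is strict (value > threshold); equality does not exceed.

## Limitations

- LOD/2 is a crude imputation; maximum-likelihood estimation for censored
  log-normals would be the natural extension and is intentionally out of
  scope.
- No carcinogenic (slope-factor) risk route and no uncertainty propagation
  (Monte-Carlo over concentration and consumption distributions is an
  extension point).
- The assessment assumes all unrecorded alcohol is consumed as the analysed
  spirit type and that scenario doses are constant over the exposure
  duration.
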