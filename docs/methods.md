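# Methods

This note documents the modelling assumptions, numerical choices and
limitations of the package; the README sketches the calculation chain
itself.

## Study design emulated

The assessment targets the adult (15+) general population of South
Africa in 2015. All quantities are computed per subgroup defined by SES
tertile (low/middle/high), sex, and age — 20-year bands (15–34, 35–54,
55+) for exposure and AAFs, 5-year groups (15–19 … 85+) for mortality.
The 5-year groups map onto exposure bands by their lower bound (85+ →
55+). Three calculation steps: exposure → AAFs; hazard-ratio-based SES
splitting of national death counts and application of AAFs; population
splitting and WHO age standardisation. Sex is coded {male, female}, SES
{low, middle, high}; all tables are long-format CSV with explicit key
columns.

## Synthetic data: what it emulates, and what it does not

The survey and cohort inputs of the original study are restricted, so
`sescra.synthetic` generates stand-ins whose *generating truth* is the
published population table: adult population counts per (SES, sex),
prevalences of lifetime abstention, current drinking and binge drinking,
and mean grams/day among drinkers. Defaults worth knowing:

- **Asset indicators**: 10 binary items; ownership probability is
  logistic in the latent SES tertile (intercepts spread over ±2, slope
  3.0 per tertile step). The slope is chosen so the MCA score recovers
  the generating tertile for >90% of records at survey scale — the
  planted-gradient condition the scoring stage is tested against.
  Misclassification is therefore small but real, and Cox hazard ratios
  estimated on scored (rather than latent) SES are mildly attenuated,
  as they would be with a real asset index.
- **Quantity-frequency reporting**: frequency ∈ {never, <weekly, 1–2/wk,
  3–4/wk, 5–6/wk, daily}, quantity ∈ {1–2, …, 13+} drinks of 12 g.
  A drinker's latent grams/day is gamma distributed; the *reported*
  value is shrunk by an underreporting factor (default 0.4, reflecting
  the low coverage of quantity-frequency instruments relative to
  per-capita sales — national surveys in the region capture roughly a
  third of recorded consumption). Categories are then assigned by
  randomising between the two frequency categories bracketing the
  required occasions/week, so the category-implied mean is unbiased for
  the shrunken value; the pipeline's triangulation step scales it back
  up (factor ≈ 1/0.4).
- **Binge status** is the upper tail of the consumption distribution:
  the threshold is the (1 − binge share) gamma quantile, which matches
  the published binge prevalences and keeps quantity categories
  consistent with the 5+-drinks definition. An independently drawn
  binge flag cannot coexist with both the published means and strict
  category arithmetic, so tail membership is the coherent choice.
- **Rural/urban**: records are rural with probability 0.6/0.4/0.2 for
  low/middle/high SES; the cohort is drawn from the rural stratum.
  This is what makes the projection step consequential, mirroring the
  rural surveillance area of the real cohort.
- **Cohort mortality**: exponential event times with subject hazard =
  cause baseline × HR(SES); competing causes resolved by multinomial
  allocation; administrative censoring at follow-up end. Baseline
  hazards are calibrated so the implied national death total equals the
  published ~529,400 all-cause envelope; cause shares follow an
  HIV-dominant pattern. The national death table is the deterministic
  expectation (not a Poisson draw), with a Gompertz-like age gradient
  (slope 0.055/year) normalised against the age distribution.
- **Ages**: drawn uniformly within 5-year groups with a young-skewed
  geometric band distribution (ratio e^-0.25 per 5-year step).

Not emulated: household clustering and design effects, item
non-response, verbal-autopsy misclassification, migration, and any
correlation between drinking and asset ownership beyond their common
dependence on SES. Passing tests therefore demonstrate correctness of
the estimators under the stated generating model, not robustness to
those real-data features.

## Numerical choices

- **MCA**: correspondence analysis of the disjunctive matrix via SVD of
  the standardised residual matrix. The MCA itself is unweighted by
  default (survey weights enter only the tertile cutoffs), since the
  weighting convention of the original score is not documented; the
  score sign is fixed by positive correlation with asset count. When
  the leading non-trivial singular values tie (symmetric toy designs),
  the axis within the tied subspace is the combination most correlated
  with asset count — a deterministic tie-break. Categories with <1%
  mass in multi-category indicators are merged with their nearest
  neighbour; constant indicators are rejected.
- **Weighted quantiles**: one convention package-wide — the cutoff is
  the largest observed value whose weighted CDF does not exceed the
  target rank, and records exactly at a cutoff fall in the lower group.
  A mass atom larger than a tertile therefore sits *above* the cutoff.
- **Quantity-frequency midpoints**: open-ended categories are assigned
  0.5 occasions/week (<weekly) and 14 drinks (13+); a standard drink is
  12 g (South African convention) and ethanol density 789.24 g/L — all
  configurable.
- **Triangulation** uses a single global scale factor (not sex- or
  SES-specific): the minimal assumption that preserves all relative
  subgroup differences. Binge prevalence is not rescaled.
- **AAF quadrature**: fixed 128-node Gauss–Legendre rule on (0.1, 150]
  g/day, with the truncated gamma density normalised by its own
  quadrature mass so that RR ≡ 1 yields exactly AAF = 0; an adaptive
  quadrature cross-check (`check_quadrature=True`) validates the fixed
  rule to 1e-8 relative. Binge and non-binge drinkers share the gamma
  density and differ only in the pattern modification, since no
  separate binge consumption distribution is documented.
- **Cox fits** use lifelines' partial-likelihood estimator with SES
  indicators (reference high), baseline age and sex as covariates;
  deaths from other causes are censored at their event time. Event
  times are continuous, so tie-handling conventions are immaterial
  here. Hazard ratios are applied uniformly across age and sex within a
  cause category (they are adjusted for, not stratified by, age and
  sex).
- **Sparse survey cells**: SES population shares per (sex, 5-year age)
  fall back to sex-level shares below 10 records, keeping the split
  well defined at small survey sizes.
- **Monte Carlo**: parameters are drawn independently (no correlation
  structure — a documented simplification); prevalence draws are
  renormalised if abstainer + current exceeds 1, and binge is clipped
  to current. National death counts are fixed (no sampling) by
  default. The point estimate is the chain evaluated at central
  parameters, not the draw median, so percentile intervals need not
  bracket it; violations are reported, never hidden. Draws failing with
  numerical errors are excluded and counted; >1% failures aborts. All
  randomness flows from a single root seed split per stage.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| per-capita consumption | 9.5 | L ethanol/adult/year | recorded 2015 figure |
| coverage factor | 0.8 | — | share of per-capita consumption assumed consumed |
| gamma SD/mean ratio | 1.171 / 1.258 | — | men / women, from the published table's SD columns |
| consumption window | (0.1, 150] | g/day | standard CRA integration bounds |
| HIV low-SES multiplier | 1.5 | — | placeholder; the source interaction estimate is not printed |
| underreporting factor | 0.4 | — | synthetic survey coverage of true quantities |
| MC draws | 100,000 | — | study scale; analyses here default lower |

## Problem sizes used

The analysis drivers default to the real studies' sample sizes (22,741
survey respondents; 87,029 cohort subjects). The test suite and the
acceptance script run the same estimators at 10,000–50,000 records and
1,000–2,000 Monte Carlo draws — sizes at which every law-of-large-numbers
and recovery check already holds at its stated tolerance.

## Known limitations

- RR curve coefficients are placeholders with provenance notes, not a
  vetted meta-analytic set; absolute AAF levels should not be quoted.
- Exposure profiles use constant drinking parameters across age bands
  (the published table is resolved by SES × sex only); age variation in
  AAFs enters through sampling noise and the age-specific death counts.
- Average-volume risk curves are used for injuries as for chronic
  causes; no occasion-based acute model.
- Uncertainty intervals inherit the assumed sampling distributions and
  draw-level independence.
- Attributable counts are kept real-valued throughout; rounding is a
  display concern, conservation a computational one.
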