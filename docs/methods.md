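# Methods

## Regression model

Daily non-accidental death counts per city × age group are modelled as
quasi-Poisson: Poisson mean structure with log link, variance inflated by a
dispersion φ estimated from the Pearson chi-square over residual degrees of
freedom. Coefficient covariance is φ·(XᵀWX)⁻¹. Fitting is IRLS (via
statsmodels' GLM), accepted only when the relative score norm
‖Xᵀ(y − μ)‖ / (1 + ‖Xᵀy‖) falls below 1e-8; rank-deficient designs are
rejected with the offending columns named. On a saturated design there are
no residual degrees of freedom, and φ defaults to 1.

The temperature term is a DLNM cross-basis over lags 0–21 days. Both
marginal bases are natural cubic splines built from the truncated-power
construction, which is linear beyond its boundary knots by construction;
columns are rescaled by the squared boundary span for conditioning (a pure
column scaling, invisible to the fit). Defaults, all configurable:

* **Exposure basis** — internal knots at the 10th/50th/75th/90th percentiles
  of the city's fitting-period temperatures, boundary knots at the observed
  min/max. The median knot is load-bearing: without it the central span of
  the temperature distribution is a single cubic piece, and the smooth
  approximation of a V-shaped log-RR drifts its minimum ~3 °C toward the
  shallow cold side, which would make the MMT systematically wrong.
* **Lag basis** — natural cubic spline on lags 0–21 with an intercept,
  2 internal knots equally spaced on the log(lag+1) scale, concentrating
  flexibility at short lags where the hot-side response lives.
* **Confounders** — six day-of-week indicators (Sunday reference), two
  annual Fourier harmonic pairs on a 365.25-day period, and a centered
  linear year trend. Harmonics rather than a day-of-year spline keep the
  seasonal term strictly periodic and cheap; two pairs are enough for the
  synthetic seasonality, and the count is a parameter.
* The first 21 rows (incomplete lag history) are excluded from the
  likelihood rather than padded.

One percentile convention is used everywhere (knots, MMT window, extreme
thresholds): linear interpolation between order statistics on the
(n−1)-based scale, i.e. numpy's default.

## RR curve and MMT

The fitted cross-basis coefficients are reduced to the cumulative
(lag-summed) log-RR on a 0.1 °C grid spanning the observed range; consumers
interpolate linearly between grid points, and beyond the grid the log-RR is
extrapolated linearly with a logged warning. The MMT is the argmin of the
uncentered curve restricted to the 1st–99th percentile window of the
fitting-period temperatures (boundary grid points rest on single days and
are extrapolation-dominated); exact ties break toward the warmer
temperature, and an all-flat curve returns the window midpoint with a
warning. The curve is then centered at the MMT, so RR(MMT) = 1 exactly.

## Attribution

The forward two-step form is used: baseline deaths are the mean observed
count on days within ±0.5 °C of the MMT (the window doubles, at most five
times, until ≥30 days qualify), and daily excess is baseline·(RR(T)−1).
Days above/below the MMT are heat/cold; a day exactly at the MMT belongs to
neither (its excess is zero). Extreme categories restrict to days strictly
beyond the 97.5th/2.5th percentiles of the historical reference
temperatures, computed once and frozen for all future series. The
alternative attributable-fraction form N·(1 − 1/RR) is deliberately not
used; the forward form keeps attribution exactly linear in the baseline,
which the scenario engine exploits.

## Adaptation

Vulnerability scalars are OLS slopes of RR vs T on each side of the MMT
(cold side reported as a magnitude). Across cities, each side's slope is
regressed on the matching seasonal climate coordinate: hot ↔ trailing JJA
median, cold ↔ trailing DJF median (a winter is labeled by its January, so
December 2019 belongs to DJF 2020). Under strong adaptation, a city's hot
slope in year y is the hot regression line evaluated at the city's trailing
10-year JJA median, clipped at zero — extrapolating the line beyond the
fitted range is intentional, since the warmest cities have no present-day
analogue. The scaling ratio r_hot divides by the line's value at the
trailing median ending in record year 10, so the ratio is exactly 1
throughout the baseline decade; from year 11 the slope updates annually.
By default r_hot is capped at 1 (adaptation never increases vulnerability);
the cap is configurable.

The cold side is tied to the hot side through ρ, the ratio of the two
regression-line slope magnitudes: the cold-side fractional change is ρ times
the hot-side fractional change, r_cold = max(0, 1 − ρ·(1 − r_hot)). The
alternative literal reading r_cold = ρ·r_hot is available behind
`cold_rule="literal"`, but it is not the default because it fails the
no-adaptation fixed point: with r_hot = 1 it would still cut cold risk by
1 − ρ. The MMT never moves under adaptation; shifting it would require an
extra assumption about how the cold side follows, with no principled basis
for choosing one.

## Scenarios, decomposition, warming levels

Future baselines are per-capita historical rates (historical baseline deaths
over mean fitting-period population, per age group) times the scenario's
annual population. Fixing rules: *fixed climate* tiles the reference-decade
(2011–2020) daily block forward and backward, a target Feb 29 without a
source counterpart reusing Feb 28; *fixed demographics* freezes each city's
over/under-75 split at the reference-decade average while keeping the total
trajectory; *fixed population* freezes each group at its reference-decade
average. Strong adaptation uses the scenario's own temperature stream for
trailing medians, so fixing climate also fixes the adaptation trajectory.

The scenario engine is vectorised: because adaptation scaling is affine in
(RR − 1) on each side of the MMT, per-year category sums of (RR − 1) split
by side are precomputed once and multiplied by the year's (r_hot, r_cold)
and baseline; the tests assert equality with the per-year attribution loop.

Factor contributions are all-factor minus fixed-run totals per category and
year. These differences need not sum to the total change; the interaction
residual is always computed and reported. Global warming is the two-stage
mean of synthetic ensemble members (members averaged within each pseudo
climate model, then across models), expressed as anomalies against the
1850–1859 preindustrial decade. Mortality at a warming level is the mean
over years whose 10-year centered rolling warming mean lies within ±0.05 °C
of the level; the rolling mean suppresses interannual noise that would
otherwise scramble the level assignment. Latitude aggregation uses half-open
5° bins.

## Synthetic data

The generator emulates the structure of the multi-city observational data
this kind of analysis runs on:

* **Temperature** — seasonal sinusoid (day-of-year on a 365.25-day cycle, so
  leap days cause no phase jump) + optional linear warming trend +
  stationary AR(1) noise (innovation SD `noise_sd`, coefficient `ar1_coef`).
* **Deaths** — E[count] = baseline · dow-effect · exp(Σ_l w_l · logRR(T_{d−l})),
  the exact inverse of the fitted model family, with a V-shaped point
  exposure-response (piecewise linear in RR around a known MMT) distributed
  across lags by fixed nonnegative weights summing to one (geometric decay,
  5-day scale). Counts are negative-binomial with variance φ·mean (φ = 1 is
  Poisson); the default φ = 1.3 is a typical mild overdispersion for daily
  city mortality counts. The first 21 days reuse the series' leading values
  as lag history.
* **Population** — compound total growth plus a linear shift of share into
  the over-75 group.
* **Multi-city ensemble** — city mean temperatures drawn over a climate
  range; true hot slopes follow a linear law in the city's noise-free JJA
  median (negative slope: hot-summer cities are heat-adapted) and cold
  slopes a linear law in the DJF median (positive slope: cold-winter cities
  are cold-adapted), plus Gaussian scatter, clipped at zero.

Default study conditions (12 cities, 1987–2000 fitting period, horizon
2100, reference decade 2011–2020, baseline 20/21 deaths/day per age group,
population 1M growing 0.8 %/yr with the over-75 share rising from 5% by
0.12 points/yr, city warming 0.033 °C/yr) are sized so the full pipeline and
its tests run in seconds while keeping the qualitative structure of a large
historical study: mortality dominated by moderate cold, extreme heat a
~20% share of heat deaths, demographics and population the largest drivers
of projected change, and a negative climate contribution in the
cold-dominated regime.

What the generator does **not** emulate — and hence what passing recovery
tests do not establish about real data: differential lag structure between
hot and cold effects (one lag-weight vector serves both sides), humidity
and air-pollution confounding, harvesting/mortality displacement, day-to-day
death-count autocorrelation beyond what temperature induces, reporting
artifacts, urban heat islands, and within-city spatial heterogeneity.

## Numerical notes and limitations

* The spline approximation of the generator's sharp V rounds the corner at
  the MMT; single-city recovery at realistic counts locates the MMT with a
  median error ≈1.4 °C and the cumulative RR at MMT+10 °C within a few
  percent. A city whose true hot slope clips to zero has a flat hot side
  and an intrinsically ill-identified MMT.
* The zero-clip in the ensemble truncates the slope-climate law; recovery
  experiments for the law keep the climate range in the linear regime.
* Quasi-Poisson IRLS can oscillate at machine precision on the deviance;
  convergence is therefore judged on the relative score norm.
* All generators take an explicit integer seed; nothing uses global random
  state, and identical config + seed reproduces every output byte for byte.
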