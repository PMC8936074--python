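# Methods

## The demand model and its assumptions

The core assumption is that the total rate of energy release during cycling,
expressed in O₂-equivalent units (mmol s⁻¹), is linear in mechanical power:
Y = a + b·P. The relation is identified on submaximal steady-state
measurements and extrapolated beyond the power at V̇O₂max, where anaerobic
processes supply the shortfall. Two empirical violations of linearity shape
the implementation:

* **Low-power excess.** Below roughly 75 W at 1.5 Hz pedaling (30 W at
  0.75 Hz) measured V̇O₂ exceeds the linear prediction, plausibly from
  accelerating/decelerating the legs and compensatory upper-body work.
  Measurements below the threshold are excluded from every fit except M4,
  which exists precisely to quantify the damage of including them. A power
  exactly at the threshold is kept (the excess is modeled as vanishing
  there); `FitConfig.include_boundary` flips this.
* **Slow component.** V̇O₂ keeps rising between 4 and 10 min of constant
  power (≈ +1.8 % below the lactate threshold, ≈ +4.9 % at or above it), so
  relations fitted on 3–4-min windows (M1–M3) are systematically shallow.

Canonical internal units are V̇O₂ in mmol s⁻¹, power in W, slope in μmol J⁻¹
(`slope·P/1000` gives mmol s⁻¹); conversions to L_STPD min⁻¹ (molar volume
22.4 L mol⁻¹, configurable) live only at the I/O edge.

## The nine estimators

M0, M1, M3 and M4 are free ordinary least squares on different data subsets;
M2 is constrained least squares with the intercept forced to the cohort mean
of the M1 intercepts; M5–M8 draw a line from a fixed intercept (common mean /
zero / resting V̇O₂ / loadless V̇O₂) through the mean of the
`n_high_points` highest-power steady-state points (default 1; 2–3 is the
recommended safeguard, several bouts tied at the top power are averaged
first). Two interpretations were genuinely open and are decided here:

* **M2 as constrained least squares** rather than a re-anchored average —
  the minimiser of Σ(y − a₀ − bP)², b = ΣP(y − a₀)/ΣP². With a₀ equal to the
  free-fit intercept this reproduces the free-fit slope exactly, which is
  the property the tests pin.
* **M5's common intercept** is the mean of the individual reference-method
  intercepts, M2's the mean of the M1 intercepts; both overridable via
  `FitConfig.common_intercept`.

The lactate threshold is the power at which blood lactate first reaches
4.0 mmol L⁻¹, linearly interpolated between bracketing measurements; a
subject who never reaches the criterion has all bouts classed below
threshold. Frequencies are never pooled: one relation per (subject,
frequency), because the intercept varies strongly (cubically) with pedaling
rate.

## The AOD engine

The five exercise models (100/120/150/200/250 % of the V̇O₂max intensity;
217/120/60/30/10 s to exhaustion; aerobic fractions 0.75/0.63/0.47/0.30/0.10
from pooled exhaustive-exercise data) define the comparison grid. Aerobic
fractions at intermediate durations interpolate linearly in log(time); only
the five canonical rows enter any reported table.

The deliberately asymmetric anchoring: accumulated demand is each test
method's relation evaluated at the **common** modeled power times *t*, while
accumulated uptake is `aerobic_fraction × demand_ref × t` — the *reference*
total — identically for every method. All methods are thus compared under
the same power, duration and accumulated uptake, so deficit differences
isolate the demand relation. The reference method's own row uses
`demand_ref` directly, making it immune to coefficient rounding; on
unrounded self-consistent inputs the two routes coincide exactly (tested).
A negative deficit is returned flagged, not raised — it diagnoses a too-low
demand relation. Per-kg values use the cohort mean mass for cohort-mean
tables and each subject's own mass for per-subject residuals. Method
contrasts use the one-sample matched-pair t-test; a Bonferroni option covers
the eight contrasts (no Dunnett post-hoc).

When reproducing the published grid, the printed (rounded) demands and
powers are injected verbatim (`--use-printed-model`); default behaviour
recomputes both from the fitted reference relation. With rounded
coefficients the selected worked-example cells agree to ±0.02 mmol kg⁻¹;
full-grid agreement is not expected since the original computation averaged
unrounded per-subject values.

## The synthetic-cohort generator

Thirteen subjects (3 women, 10 men) by default, each with a true linear
relation (intercept 0.50 ± 0.05 mmol s⁻¹, slope 8.8 ± 0.8 μmol J⁻¹), V̇O₂max
2.9 ± 0.6 mmol s⁻¹, resting V̇O₂ 0.26 ± 0.03 mmol s⁻¹, body mass 74 ± 7 kg
(women) / 82 ± 7 kg (men). Draws are truncated normals; the V̇O₂max draw is
additionally floored so the power at V̇O₂max stays ≥ 150 W (config
`min_vo2max_power`) — a physiological bound for subjects completing the
protocol, and a structural guarantee that at least two bouts clear the 75 W
inclusion threshold.

The noise-free expectation is

    steady(P, f) = a + b·P/1000 + e(f)·max(0, 1 − P/P_nl(f))²

with the low-power excess decaying quadratically (the smoothest
sign-definite shape vanishing with zero slope at the threshold
P_nl(f)). The excess amplitude anchors loadless V̇O₂ exactly to
`resting + k·f³` with k = 0.1185 mmol s⁻¹ Hz⁻³, i.e.
e(f) = max(0, resting + k·f³ − a): at defaults loadless V̇O₂ at 1.5 Hz is
0.26 + 0.40 = 0.66 mmol s⁻¹, reproducing both the resting and
loadless-pedaling anchors simultaneously (an alternative parameterisation
drawing the excess independently at ≈ 0.18 ± 0.04 cannot satisfy both).
Early-window values divide the steady state by (1 + drift), with the drift
fraction switching at the subject's lactate-threshold power (default 75 % of
the V̇O₂max power); the stepwise protocol adds +0.015 mmol s⁻¹ at 1.5 Hz and
nothing at 0.75 Hz. Blood lactate follows a logistic in power centred at the
threshold power (asymptote 8 mmol L⁻¹, scale 15 W) — only the 4.0-crossing
matters downstream. Gaussian noise (SD 0.03 mmol s⁻¹, chosen so the pooled
drift's standard error at n ≈ 155 has the reported order ±0.005) is added
independently per recorded window; lactate noise SD 0.2 mmol L⁻¹. Bout
powers span 30–95 % of the V̇O₂max power in ≤ 22 W steps, both the 3–4 and
8–10-min windows recorded; plus a stepwise series (22 W steps for men, 11 W
for women, starting at twice the step), loadless pedaling per frequency, and
seated rest. Everything is reproducible bit-for-bit from (config, master
seed) via spawned per-subject bit streams.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: breath-by-breath on-transient kinetics, day-to-day
biological variability, correlated measurement error within a session, the
occasional outlier subject that dominated the real M1-vs-M2 contrast, and
heart rate beyond a plausible placeholder column. One known divergence: with
the piecewise multiplicative drift, the early-window OLS intercept is pulled
*above* the steady-state intercept (≈ +0.06 at defaults) while real data
showed near-equal M0/M1 intercepts; the slope ordering (M1 < M0), which is
what the comparison turns on, is unaffected.

## Numerical choices and problem sizes

Free and constrained fits are closed-form normal equations (no iterative
optimisation); polynomial frequency fits use a Vandermonde least-squares
solve. Singular designs (identical powers; all-zero powers with a forced
intercept) raise typed errors, as do methods left with fewer than the
required points after inclusion rules, naming the rule responsible.
Ties at the top power are averaged. The uptake integral is trapezoidal on
the union of the series grid and the bout endpoints.

Test and reproduction workloads are sized for quick routine runs: the
parameter-recovery check uses 200 cohorts × 13 subjects (≈ 2 s), the
directional-bias and comparison checks one default cohort, and the
worked-example reproduction is pure arithmetic on the published summary. All
reported numbers are produced by these computations at run time.

## Known limitations

* Linear extrapolation is itself the modeled assumption; the package
  deliberately refuses non-linear demand extrapolation (numerically fragile
  for out-of-range prediction).
* The 217-s time to exhaustion at 100 % intensity is a model convention
  carried for comparability, not a physiological claim.
* Exercise-model powers are cohort-level; per-subject AOD ordering between
  fixed-intercept methods can invert for subjects whose own anchor power
  exceeds the cohort-modeled power (the cohort-mean ordering is the tested
  claim).
* Douglas-bag gas arithmetic, V̇O₂max protocol modeling and heart-rate
  analysis are upstream/out of scope.
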