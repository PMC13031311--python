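# Methods

This note documents the statistical model, the synthetic data-generating
process, numerical conventions, and the design decisions behind `periclim`.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The exposure construction

**Daily means and day-of-year.** A station's daily mean is the midpoint of
the reported minimum and maximum, the standard convention for historical
daily temperature archives. Day-of-year indices run 1–365; Feb 29 shares
index 59 with Feb 28 and later dates in a leap year shift down by one, so
no day is discarded and every calendar date maps into the climatology's
domain.

**Climatology.** Each station's long-run expected temperature is a degree-4
polynomial in day-of-year, fitted by pooled OLS over all daily observations
in the reference period (default 1933–1971; a station is eligible with at
least 30 calendar years having ≥ 180 valid records — the "year with data"
notion is otherwise underdetermined and both thresholds are configurable).
The day index is affinely rescaled to [−1, 1] before powering purely for
conditioning; a test verifies predictions are invariant to the rescaling.
Pooled OLS and per-day-of-year averaging followed by smoothing coincide for
balanced data; the pooled reading is implemented. The polynomial is not
constrained to be periodic at the year boundary — a degree-4 polynomial
cannot be — and the Dec 31 → Jan 1 discontinuity is accepted. A degree-4
approximation to a sinusoidal annual cycle of 7 °C amplitude carries a
worst-case error below 0.6 °C (verified against an independent dense-grid
solve), small relative to daily weather variability of a few °C.

**Anomalies.** `deviation = observed daily mean − climatological
expectation`. Because the fit is OLS with an intercept, per-station
anomalies average to zero over the fit period (asserted to 1e−8 °C), which
is what makes them non-seasonal, quasi-random exposure variation.

**Linkage.** Distances are inverse Vincenty geodesics on WGS84, iterated to
|Δλ| < 1e−12 (≤ 200 iterations) with a great-circle fallback for
near-antipodal pairs (logged; never triggered at regional scale). The
implementation is vectorised and was checked to the metre against an
independent Vincenty implementation and against the exact equatorial closed
form a·Δλ. Stations within 200 km (inclusive) contribute with weights
∝ 1/max(d, 1e−6 km)^p, normalized to 1; the clamp means a birthplace on top
of a station receives that station's value. The default power p = 1 reads
"inverse distance" literally; p is configurable (`--idw-power`) and a
nearest-neighbor mode (ties to the smallest station id) is the robustness
alternative. Interpolation is per day with weights renormalized over the
stations actually reporting that day, then averaged over the window
("interpolate, then average"); with complete data this commutes with
averaging station series first, and with gaps it uses all information.

**Windows.** Estimated conception = birth − 266 days. Windows are whole
weeks, half-open at the conception day ("till DOC" excludes the DOC day),
giving lengths 1/14/28/42/56 days for DOC, −2w;DOC, −3w;+1w, −4w;+2w,
−5w;+3w. This is the only convention under which a +1 °C anomaly confined
to the 14 pre-conception days averages to exactly +0.25 °C over the 8-week
window, which anchors the dilution arithmetic; the alternative 15-day
reading of "−2w;DOC" is available by constructing a custom window. Days
with no in-radius reporting station are skipped and the mean renormalized;
an exposure is set missing when coverage falls below 0.8 (the floor exists
because real archives have gaps; the synthetic world is complete).

## The regression model

Linear models absorb area-by-birth-month fixed effects via the within
transformation; a test asserts numerical equality (1e−8) with brute-force
dummy-variable OLS. Sex enters as a dummy; year of birth and year of
assessment enter as categorical dummies (flexible trends, matching the
fixed-effects style, where only "controlling for" is specified). Standard
errors are CR1 cluster-robust at the area level —
(X'X)⁻¹[Σ_g X_g'e_g e_g'X_g](X'X)⁻¹ scaled by G/(G−1)·(N−1)/(N−K), with K
counting the absorbed fixed effects — and p-values use a t distribution on
G−1 degrees of freedom (the common econometric default; the small-sample
correction is not otherwise pinned down). With each observation its own
cluster the estimator reduces exactly to HC1, which doubles as a test.
Singleton fixed-effect cells are retained in linear fits (they self-absorb
and contribute nothing to α's identification).

Binary outcomes use maximum-likelihood logit with explicit fixed-effect
dummy columns (statsmodels MLE) and the clustered sandwich, accepting
incidental-parameter bias as the stated estimand — a warning is logged when
the average cell size drops below 20. Cells with a constant outcome carry
no likelihood information once their dummy is free and are dropped with a
logged count. The independent check here is the 2×2 single-cell design,
which must reduce to the contingency-table log-odds-ratio.

Holm correction is applied per exposure window across the five outcomes of
a family (step-down: sort ascending, multiply p_(j) by m−j+1, cap at 1,
enforce monotonicity, map back), cross-checked against
`statsmodels.stats.multitest`.

Scenario translations are linear: %SD = 100·α/SD (displayed half-up to 2
decimals; raw values retained in machine output), weight change =
α_BMI·ΔT·height²·1000 g, and ΔT-scaling multiplies a 2 °C reference effect
by ΔT/2 — confidence-interval endpoints scale the same way, and no further
uncertainty propagation is attempted.

## The synthetic world

The generator emulates the *statistical structure* the analysis assumes,
not real geography: stations are uniform in a UK-sized lat/lon box
(50–55.5°N, 5.5°W–1.5°E), areas are a 5×5 grid partition, and no real
station metadata or disease prevalences are reproduced.

Daily mean temperature at station *s*:
`base + lat_gradient·(lat_s − lat₀) + season(doy) + a_t + e_st`, emitted as
(tmin, tmax) = mean ∓ diurnal_range/2. Defaults: base 9.5 °C, gradient
−0.6 °C per degree latitude, seasonal amplitude 7 °C peaking mid-July,
diurnal range 8 °C, regional anomaly `a_t` AR(1) with marginal SD 2 °C and
lag-1 autocorrelation 0.7 (the few-day persistence of mid-latitude weather
systems), station noise SD 1 °C (instrument and microclimate error). One
shared regional anomaly plus i.i.d. station noise — rather than a
distance-decaying spatial covariance — is deliberately minimal: it is
sufficient to exercise inverse-distance weighting and the fixed-effects
estimator, and keeps repetitions cheap.

The seasonal curve is generated as the degree-4 polynomial (in the same
rescaled day-of-year basis the climatology uses) that best approximates the
cosine harmonic. Generating the seasonal truth inside the climatology model
class makes the ground-truth anomaly exactly `a_t + e_st`: a noiseless
world then has identically zero anomalies and exposures, a limit the tests
rely on. With a raw cosine, a deterministic ±0.5 °C seasonal remainder
would be conflated with the anomaly and the "true anomaly" would be
ill-defined.

Cohort: participants get a uniform birthplace within a uniformly assigned
area; conception day-of-year follows an area-specific von-Mises-style
weighting `exp(κ_a·cos(2π(doy − peak_a)/365))` with per-area peaks near
late December (UK births historically peak in early autumn) and
κ_a = fertility_season_strength·U(0.5, 1.5); gestation is
Normal(266, gestation_sd) rounded to whole days and truncated at ±6 SD
(calendar arithmetic needs integers; default SD 10 days, matching observed
gestational-age dispersion); sex is Bernoulli(1/2) and assessment year
uniform on 2006–2010. Each continuous outcome is

    intercept + area effect + season-of-birth effect + sex effect
    + birth-year trend + α·(true-window mean anomaly at conception) + noise

with intercepts and noise SDs matching published cohort descriptives (BMI
27.44 ± 4.79 kg/m², WC 90.34 ± 13.51 cm, HbA1c 35.97 ± 6.52 mmol/mol,
triglycerides 1.76 ± 1.03, cholesterol 5.71 ± 1.14 mmol/l). True effects
default to 10% of an outcome SD per °C — far larger than the
epidemiological scale, deliberately, so a desk-scale cohort of 20,000 has
power comparable to a biobank-scale analysis of hundreds of thousands. The
causal window defaults to −2w;DOC (the biologically favoured
pre-conception fortnight) and is configurable; the attenuation experiment
uses the DOC-day window so conception-date error acts directly.

The **season-of-birth confounder** is a step function of calendar birth
month, `strength·SD·cos(2π(month − peak)/12)`, phased 266 days after the
fertility peak. Keying it to birth month — the granularity the
area-by-month fixed effects are designed to absorb, and the classic
season-of-birth effect in the epidemiological literature — makes the
fixed-effects model exactly correctly specified, so its type-I error is
nominal at any cohort size. A smooth conception-day effect would instead
leave a within-cell remainder, shared across areas by all participants
conceived on the same date, that area-clustered errors cannot represent;
the fixed-effects model's size then degrades as within-date sharing grows,
which is a (real, documented) inference limitation of the design rather
than a confounding failure. The ground truth (true effects, true conception
dates, true-window anomalies, per-area fertility weights) is written to
sidecar files suffixed `ground_truth_test_only` and is never read by the
estimation path.

What the generator does *not* emulate — spatially correlated weather beyond
one regional factor, station moves and quality flags, migration between
conception and birth, gestational-age-dependent selection, realistic effect
sizes — bounds what passing tests show: they validate the estimator's
arithmetic and its sampling behaviour under the stated assumptions, not the
epidemiological finding itself.

## Calibration experiments

Three experiments (in `periclim.calibration`, shared by the test suite and
the acceptance script) repeatedly run the full pipeline — simulate network,
fit climatologies, link, expose, regress — on fresh seeds:

* **Recovery** (100 reps, n = 20,000, gestation_sd = 0): mean relative bias
  of α̂ for the causal window and empirical coverage of the 95%
  cluster-robust CI (t on G−1 df). The small negative bias that remains is
  classical errors-in-variables attenuation from station noise and
  climatology estimation error in the constructed exposure; it is part of
  the estimand's behaviour, not a defect, and stays well inside the 5%
  band.
* **Confounding removal** (200 reps, n = 45,000, strength 2, null effect):
  type-I error of the area-by-month fixed-effects model versus a naive
  pooled regression. The naive comparator uses conventional HC1 errors —
  obtained as the one-observation-per-cluster degenerate case of the CR1
  sandwich — because an analysis that ignores the area-month structure
  would not cluster on it either; area-clustered errors on the pooled model
  would largely absorb the seasonal common shock (all cluster scores shift
  together) and mask the over-rejection the experiment measures. The
  experiment is sized at 45,000 because the naive model's excess rejection
  operates through month-level shared exposure realizations, so its power
  grows with within-date sharing of the cohort.
* **Attenuation** (100 reps × 4 conditions, n = 4,000, causal window =
  DOC): mean |α̂| for the conception-day window across gestation-length SDs
  0/5/10/15 days. Under the AR(1) weather model the expected attenuation
  factor is E[ρ^|Δ|] for a Normal(0, SD·√2…) day shift Δ, so the means
  should fall steeply and monotonically.

Problem sizes were chosen so each experiment completes in minutes on one
CPU while leaving the acceptance margins wide; they are stated here as the
package's own operating points.

## Numerical conventions and degenerate inputs

Records with tmin > tmax are rejected with a logged warning wherever they
appear; duplicate station-dates keep the first row. Fewer than five
distinct day-of-year values (or a rank-deficient basis) is a fitting error
naming the station. An exposure coefficient constant within every
fixed-effect cell raises an identification error; a single cluster raises
an error advising the HC1 fallback. Empty radius queries are a value
(missing), not an error. All pipeline randomness derives from one seed via
`numpy.random.SeedSequence` substreams (stations / cohort), so stages rerun
identically in isolation; rerunning a manifest reproduces results files
byte for byte.

## Known limitations

Logit fixed effects by unconditional MLE are inconsistent for small cells
(incidental parameters); conditional logit is out of scope. The CR1/t(G−1)
combination is approximate with few clusters (25 areas by default). The
linkage treats birthplaces as exact points; coordinate snapping resolution
is upstream. Scenario arithmetic scales point estimates and CI endpoints
linearly and ignores estimation uncertainty in the SD denominators.
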