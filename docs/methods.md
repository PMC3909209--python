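# Methods

## Data reduction

Survey tows arrive as station-level rows (cruise, station, date, position,
species, abundance in ind m⁻³, upper-3 m temperature).  Because cruises do
not cover the shelf on a fixed schedule, a "complete survey" is
operationalised as all tows sharing a `cruise_id`; the survey midpoint is
halfway between its first and last tow date, and the whole cruise is
assigned to the midpoint's two-month bin (bin = ceil(month/2), six bins
per year).  The bin value is the unweighted arithmetic mean over tows — no
volume weighting, since abundances are already flowmeter-standardised to
ind m⁻³.  A bin with no qualifying survey is missing, never zero.

Sub-region boundaries are nowhere canonically defined, so they are
configuration: the shipped defaults are rectangles (GOM north of 42°N east
of 70°W; GB 40.5–42°N east of 69°W; SNE 39–41°N between 72 and 69°W; MAB
south of 39°N west of 72°W) that tile the shelf without interior overlap.
Config order is the tie-break for boundary points, overlap is rejected at
validation time, and every pipeline manifest records the region definition
used.  Latitude bands are half-open `[lower, lower+2)` — the 2°-wide
reading; the alternative 1°-wide labeling that sometimes appears in survey
summaries is internally inconsistent, so the half-open 2° convention is
fixed and documented here.

## The structural model

Each series is decomposed as `y_t = mu_t + gamma_t + eps_t` with an AR(1)
local trend `mu_t = phi mu_{t-1} + eta_t`, `phi ∈ (0,1]` (`phi = 1` is a
random walk), and a deterministic trigonometric seasonal with a 12-month
period.  With time indexed in bins (Δt = 1 bin = 2 months) the seasonal
period is 6 steps, giving three harmonics: full sine/cosine pairs at j =
1, 2 and a cosine-only Nyquist term at j = 3 — five coefficients, exactly
periodic and zero-mean over any six consecutive bins.  The harmonic phase
is anchored to the calendar (absolute bin index), so coefficients are
comparable across sub-series.

Fits operate on the raw abundance scale; the seasonal component is a
deviation from the trend and is frequently negative, which is expected,
not an error.  A `log1p` scale option exists for robustness studies.

**Estimation.**  The Gaussian prediction-error-decomposition likelihood is
computed by a Kalman filter over the scalar trend state; missing bins skip
the measurement update.  The five seasonal coefficients enter the
observation equation linearly and are concentrated out exactly: the data
column and the five harmonic regressor columns are passed through the same
innovations recursion and the coefficients solve the weighted normal
equations in innovation space (GLS on the whitened problem).  This is
algebraically equivalent to carrying five constant diffuse states in a
six-dimensional filter — the full six-state representation is still
constructed (`build_state_space`) and its dimensions and diffuse flags are
part of the tested contract — but the reduced form is faster and
numerically simpler.  For `phi = 1` the trend prior is diffuse: the first
observed bin initialises the state exactly and its innovation is dropped,
so the reported value is the log density of the remaining observations
given the first.  For `phi < 1` the stationary prior is used.

The remaining parameters are optimised as (logit `phi`, log variances) by
Nelder–Mead from five seeded starts, plus a dedicated branch with `phi`
fixed at 1 (the boundary is otherwise unreachable through the logistic
transform); the best likelihood wins and the `converged` flag is honest.
Variances carry an additive floor of 1e-12 so the noiseless limit stays
finite.  Smoothed components come from the fixed-interval (RTS) smoother;
bins before a diffuse first observation are back-filled with the
random-walk conditional expectation (constant).

Two cross-checks guard the filter: a dense O(n³) evaluation of the same
likelihood from the model's full joint covariance matrix, and the
generalised-least-squares projection for the smoothed trend.  Tests
require agreement to 1e-8 relative tolerance on small instances with
missing values; in practice agreement is at machine precision.

**The alternative reading.**  The decomposition prose admits a second
parsing — random-walk trend with AR(1) *observation* error.  Both are
implemented; the AR(1)-trend reading is the default and the variant is the
`error_ar1` model-spec flag (a two-state filter with an exact-diffuse step
for the random-walk component).  Outputs are labeled with the variant
used.

**Period splitting.**  The southern regions (SNE, MAB) carry no samples in
1989–1991, so their series are fit separately for 1977–1988 and 1992–2009;
the northern regions (GOM, GB) are fit over the whole span by default.
Both behaviours are configurable.

## Phenology

Annual peaks are read from the fitted (trend + seasonal) series so missing
observed bins do not bite: `peak_value` is the maximum over the six fitted
bins of a calendar year and `peak_bin` its argmax, ties to the earliest
bin.  Years are calendar years (Nov–Dec is bin 6 of its own year; no
wrap-around), and years with fewer than six fitted bins at period edges
are flagged partial.  The era cross-tabulation counts `peak_bin` by era
around a split year and reports the modal bin per era; no formal
change-point inference is attempted — the shift is a descriptive quantity.

## Forcing indices

The transport path sits on the grid row nearest 39.3°N (the figure-quality
value; the text's rounded 39°N is reachable by configuration).  The path
is geometric: the six 1/3° cells starting at the first ocean cell from the
coast (2° extent), the two nearest the coast discarded against land
contamination, the remaining four averaged per week.  An all-missing cell
inside the path is an error that lists the offending longitudes — no
silent in-fill.  "Alongshore" is the northward (meridional) component,
positive = northward.  Bi-monthly means average the weeks falling in each
bin; annual cumulative northward/southward components are the sums of
positive and negative bi-monthly values respectively (weekly input also
accepted), and they add up to the plain annual sum by construction.

The GSNWI standardizes each of the six north-wall latitude series over the
fitting span, takes first-principal-component loadings, fixes the sign so
the mean loading is positive (PCA sign is arbitrary), rescales the
loadings to sum to one, and averages.  Standardization makes the index
invariant to affine rescaling of any input series; constant inputs are
rejected.

## Associations

Plain OLS with Pearson r and the two-sided t-test p-value on n−2 df — the
simplest reading of "regression analysis" with fitted-line panels.  The
suite crosses each species × (region + pooled "entire") response with
annual alongshore velocity, annual GSNWI and regional annual temperature,
and adds GSNWI ~ velocity at the bi-monthly and annual scales.  The annual
velocity covariate is the annual mean of bi-monthly values by default
(cumulative components optional).  Incomplete pairs are dropped; nothing
is filtered by significance and no multiple-testing correction is applied
— the full p-value table is returned so users can correct as they see fit.

## The synthetic world

The generator reproduces the statistical structure the pipeline assumes,
not shelf physics: no tides, eddies or mesoscale structure.

* **Abundance.**  Per species × region, bin-mean signal = smooth trend
  (level + optional linear drift + multi-year sine) + calendar-anchored
  harmonic seasonal + AR(1) bin noise (`phi_true = 0.95`,
  `sigma_eta = 5 ind m⁻³`).  Station samples add mean-zero
  *shifted-lognormal* noise with SD `sigma_eps = 30 ind m⁻³` (right-skewed
  like tow counts; exactly zero when `sigma_eps = 0`) and are truncated at
  zero — a deliberate deviation from a pure Gaussian observation model,
  chosen to preserve non-negativity.  The observation-noise distribution of
  real tow counts is unknown; the lognormal shape is a stand-in.  Default
  levels follow the published order of magnitude (e.g. *C. finmarchicus*
  233 ind m⁻³ in the GOM, *Cen. typicus* 493 ind m⁻³ in the MAB) without
  claiming to reproduce the real shelf; seasonal amplitudes are 70–80 % of
  the level, peaking in May–June for *C. finmarchicus* and Nov–Dec for
  *Cen. typicus*, with the MAB *Cen. typicus* argmax moving to Jan–Feb in
  1985.  Default span 1977–2009 with the southern 1989–1991 gap and six
  stations per bin.
* **Velocity.**  Weekly fields on a 1/3° grid, 35–45°N, 1993–2010: mean
  alongshore flow −5 cm s⁻¹ (southward), i.i.d. yearly anomalies
  (SD 1.5 cm s⁻¹), the GSNWI common signal injected at the monthly scale
  with coupling −1.5 cm s⁻¹ per unit index, and white noise
  (SD 2 cm s⁻¹).  Land is every cell west of a configurable coast
  longitude.
* **North wall.**  Six monthly latitude series sharing one common signal —
  an i.i.d. yearly level (SD 1) plus monthly white noise — scaled by 0.5°
  per unit and perturbed by independent noise (SD 0.3°).  Yearly i.i.d.
  structure is what makes the annual-scale null-calibration experiment
  exact: under zero coupling both annual series are i.i.d. normal, so the
  regression p-value is exactly uniform.
* **Biology ← physics.**  By default the abundance world is *independent*
  of the physical world (so the association table on the default run is a
  null table apart from GSNWI ~ velocity).  The
  `coupling_velocity_abundance` knob adds the yearly velocity anomaly to a
  species' signal with a chosen coefficient; the sign-recovery experiments
  use it.

Everything is driven by per-purpose `numpy` Generator streams derived from
one seed, so identical seed + parameters give bit-identical tables and the
pipeline manifest hashes are reproducible.

## Verification experiments and problem sizes

* Filter-vs-dense oracle: 24 random instances, n ≤ 24, up to 4 missing.
* Parameter recovery: 200 replicates at n = 198 under the reference truth
  (`phi = 0.95`, `sigma_eta = 5`, `sigma_eps = 30`, first-harmonic seasonal
  amplitude 100 ind m⁻³).  Median |phî − phi| ≈ 0.05 and median relative
  amplitude error ≈ 2 % in the shipped runs.  `phi` is weakly identified
  in this regime (stationary trend SD ≈ 16 against observation SD 30), so
  individual estimates often sit at the random-walk boundary; the median
  error is the meaningful summary.
* Null calibration: 500 fresh zero-coupling worlds, annual GSNWI ~ velocity
  regression, rejection rate compared with 5 % within three binomial
  standard errors.
* Phenology shift: low-noise world (`sigma_eta = 1`, `sigma_eps = 5`),
  eras fit separately around the shift year, modal bins compared exactly.

What passing these shows — and does not.  The experiments demonstrate that
the estimator recovers the structure the generator puts in: linear-Gaussian
trend/seasonal signals, i.i.d. yearly physics, a clean seasonal-argmax
shift.  Real survey data add patchy station coverage, species-dependent
catchability, non-stationary seasonal shapes and serially correlated
physics, none of which the generator emulates; passing here validates the
machinery, not conclusions about the real shelf.  In particular the
published regional grand means (233±213, 493±468 ind m⁻³) and the
GSNWI-explains-12–15 % figure are properties of the original survey data
and are only reproducible with those downloads; the pipeline computes the
corresponding summaries from any supplied table in the same layout.

## Known limitations

* No multivariate or hierarchical coupling across regions; each series is
  fit independently.
* The transport operator assumes a west coast on a regular grid row;
  along-isobath projection is limited to the meridional-component reading.
* `error_ar1` is functional but lightly exercised compared with the
  default variant.
* Optimiser multi-starts are finite; pathological series could in
  principle defeat all starts, which is reported honestly via
  `converged = False` rather than a silent success.
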