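# Methods

This note records the models, conventions and numerical choices behind
`planktonmet`, in the spirit of a model-description chapter: what is
computed, under which assumptions, and where the design was genuinely open.

## Rates from bottle replicates

Each sampled depth carries three replicate sets of dissolved-O₂
concentrations (mmol O₂ m⁻³): zero-time, 24-h light and 24-h dark.  With
treatment means Z̄, L̄, D̄:

- NCP = L̄ − Z̄, R = Z̄ − D̄, and P is *computed as* NCP + R, so the identity
  P − NCP − R = 0 holds to machine precision by construction (numerically it
  also equals L̄ − D̄).
- Rates are normalised to per-day by 24 h / incubation duration.
- Standard errors treat the treatment means as independent:
  se(NCP) = √(sem_L² + sem_Z²), se(R) = √(sem_Z² + sem_D²), and
  se(P) = √(sem_L² + sem_D²) — the zero-time term cancels in P because
  P = L̄ − D̄.  `sem_t = sd_t/√n_t` uses the sample (ddof=1) standard
  deviation.  Whether analytical and biological replication should be pooled
  differently when quoting a survey-wide mean s.e. is not defined by the
  measurement itself; we report the difference-of-means s.e. throughout.

Quality control ("significantly negative P or R, or anomalously high
replicate variance") requires two operationalisations that field reports
usually leave implicit:

- *significantly negative*: a one-sided z criterion — exclude when
  rate + z(1−α/2)·se < 0, default α = 0.05.  This matches the normal-theory
  style of the rest of the toolchain; no distributional refinement is
  warranted for n = 4–6.
- *anomalously high variance*: any treatment replicate CV above 1%,
  i.e. ten times the ~0.1% analytical CV that automated Winkler titration
  achieves.  Configurable.
- Exclusion is applied at the **station** level (one bad depth discards the
  station from integration and statistics), because at-sea QC is reported
  per station; excluded stations go to a QC report, not silently away.

## Depth integration and error propagation

Integrals to the 1% light depth are trapezoidal sums written as weights on
the samples: w₁ = (z₂−z₁)/2 (+ z₁ when the shallowest sample is extended to
the surface), wᵢ = (zᵢ₊₁−zᵢ₋₁)/2, w_n = (z_n−z_{n−1})/2.  Two conventions
needed fixing:

- *Surface*: the shallowest bottle (~97% light, a few metres deep) is
  extended to 0 m at constant value by default — the standard oceanographic
  treatment; a flag starts the integral at the sample instead.  At typical
  geometries the choice moves integrals by <5%.
- *Bottom*: the integral never extrapolates downward.  A deepest sample
  between 0.8 and 1.0 of the euphotic depth truncates the integral there
  (logged); shallower raises an error.

The s.d. of an integral is √(Σ(wᵢ·seᵢ)²), treating levels as independent.
Unit tests check the trapezoid against `numpy.trapezoid` and analytic
integrals (exact for linear profiles to 1e−10), and the propagated s.d.
against a 10⁴-draw Monte-Carlo perturbation oracle (5%).

## Hydrographic classification

- *DCM*: depth of the maximum of the chlorophyll profile after a 3-point
  running mean; ties break shallow.
- *Thermocline*: there is no single community definition; the default is
  the depth of maximum |dT/dz| (centred differences on the possibly
  irregular grid, after 3-point smoothing, ties shallow), with an
  alternative ("0.5 °C below the 10 m temperature") selectable.  Profiles
  with max |dT/dz| < 0.005 °C m⁻¹ are declared isothermal.
- *Province*: NAST iff latitude ∈ [20, 38]°N and both criterion depths
  strictly exceed 100 m; SATL iff latitude ∈ [−32, −10]; else OTHER.  The
  bands are configurable since gyre boundaries are approximate.
- *Season*: boreal astronomical seasons with fixed boundaries (Mar 20,
  Jun 21, Sep 22, Dec 21; the boundary day starts the season), applied
  regardless of hemisphere so that whole cruises carry one label.

## Regional statistics

- Confidence intervals for means use the z multiplier (1.959964 at 95%) by
  default rather than Student's t — the convention under which published
  oceanographic rate tables of this kind reproduce (half-width/s.e.m. ≈
  1.96 at n ≈ 47); a t multiplier can be passed explicitly.
- Two-sample comparisons are Student pooled-variance t with
  df = n₁ + n₂ − 2 (not Welch), again matching the reporting convention of
  the field.  Degenerate inputs are handled explicitly: zero pooled
  variance gives t = 0, p = 1 for equal means and an infinite-t sentinel
  with p = 0 otherwise.
- The fraction of net-heterotrophic observations counts strictly negative
  values; zeros are neither auto- nor heterotrophic.
- *Lilliefors normality test*: D = sup|F̂ − Φ((x−m̂)/ŝ)| with the p-value
  from a seeded Monte-Carlo null (default 10⁴ standard-normal samples of
  the same n, each standardised by its own estimates).  This is exact at
  any n, bit-reproducible under a fixed seed, and testable: the suite
  checks D against the `statsmodels` implementation, type-I error
  0.05 ± 0.01 at n = 30 over 10⁴ simulations, and power > 0.9 against
  exponential samples at n = 100.
- *Carbon conversion*: annual flux (mol C m⁻² yr⁻¹) = volumetric NCP ×
  layer depth × 365 × RQ / 1000, RQ the respiratory quotient (default
  0.8).  Note that a mean NCP of −0.07 mmol O₂ m⁻³ d⁻¹ over 50 m gives
  −1.02 mol C m⁻² yr⁻¹; published figures computed from unrounded means can
  differ in the last digit.

## P:R scaling

R is regressed on P by ordinary least squares — the orientation in which
such relationships are printed — with no errors-in-variables correction,
because the published lines are plain OLS.  Consequences worth knowing:

- the net-heterotrophy threshold is P* = b₀/(1 − b₁) when b₁ < 1 and the
  crossing is positive; otherwise the relation never predicts net
  heterotrophy from P alone (reported as a non-interpretable threshold, not
  an error).  Algebraically, predicted NCP at P* is exactly zero, which the
  suite asserts.
- when both P and R are *measured* integrals (each carrying ~10–15 mmol O₂
  m⁻² d⁻¹ of propagated error), the fitted slope is attenuated below the
  generating value and the correlated dark-bottle error leaks into both
  axes.  This is visible in the worked example (fitted NAST slope ≈ 0.63
  against a generating 0.76) and is a property of the method as practised,
  not a defect of the fit.  The regression-recovery checks therefore put
  noise only on R, which is the setting in which the published slopes are
  recovered without bias.
- slope-vs-1 and between-fit comparisons use normal-theory t tests
  (df = n − 2 and n_a + n_b − 4).  At the published sample sizes and R²
  the two gyre relations differ with high power in the *intercept*
  (gap ≈ 3.7 s.e.) but only moderate power in the slope (gap ≈ 1.5 s.e.);
  the suite asserts exactly that.
- `cross_region_bias` reports mean error, RMSE and the strict-sign
  misclassification fraction of predicting one region's NCP with the other
  region's fit; exact zeros are tallied separately.

## The synthetic transect

The generator emulates a meridional oxygen-metabolism survey: two gyre
bands plus equatorial stations, five light depths per station
(97/33/14/7/1% surface PAR), five replicates per treatment, baseline O₂
210 mmol O₂ m⁻³.  Its defaults are the survey conditions, not free dials.

Generative order (single `numpy` Generator from one seed; same seed ⇒
byte-identical dataset):

1. integrated P per station: truncated normal per zone — NAST mean 57.5,
   range 19.8–118.9; SATL mean 68.3, range 16.8–103.4 (s.d. back-computed
   from the published s.e.m. × √n); equatorial stations use a broader,
   more productive model (mean 120, range 60–220) that only exercises the
   OTHER class.
2. integrated R from the zonal linear relation (NAST R = 0.76 P + 28.25;
   SATL R = 0.98 P − 8.56; OTHER R = 0.85 P + 5) plus a Gaussian residual
   with s.d. = |b₁|·sd(P)·√((1−R²)/R²) so the expected R² matches the
   zonal value (0.59 / 0.64 / 0.70); draws outside the zone's plausible R
   range are redrawn, which keeps true respiration positive everywhere.
3. vertical distribution: p(z) and r(z) are fixed piecewise-linear shapes
   in normalised depth with mild subsurface maxima (P knots 0.705, 1.10,
   1.00, 0.80, 0.45; R knots 0.920, 1.05, 1.00, 0.95, 0.80 at the standard
   light depths), renormalised per station so that trapezoidal integration
   of the sampled values — surface extension included — reproduces the
   integrated truth *exactly* on the sample grid.  The knots are solved so
   that the equal-weight mean over the five standard depths equals the
   depth-averaged rate: the five light depths are then depth-representative
   samples, and sample statistics of volumetric rates line up with
   integrated statistics divided by the euphotic depth.  The subsurface
   production maximum at the ~33% light depth mirrors the photoinhibited
   surface typical of oligotrophic gyres.
4. bottles: zero-time ~ N(210, 0.21) (0.1% analytical CV); light and dark
   add the rate signal over 24 h and an extra biological/experimental
   component of 0.2943 mmol O₂ m⁻³ d⁻¹ in quadrature.  That constant was
   tuned once, by bisection (`scripts/tune_biological_sd.py`), so the
   grand-mean rate standard error is 0.18 mmol O₂ m⁻³ d⁻¹ at n = 5 — the
   survey-level precision the generator emulates — and then frozen.
5. hydrography: euphotic depth ~ truncated N(112, 10) on [108, 145] m in
   gyres (the floor keeps the gyre DCM safely below the 100 m criterion
   after 5-m CTD-grid quantisation, so classifier labels match the
   generating zone exactly) and N(60, 10) on [35, 85] outside; the CTD
   carries a tanh thermocline (centre > 108 m in gyres, < 80 m outside,
   width 18 m, 0.02 °C noise) and a Gaussian chlorophyll maximum at the
   euphotic depth (width 20 m, amplitude 0.25–0.45 mg m⁻³ over a 0.05
   background) on a 0–300 m grid at 5 m.
6. metadata: latitudes uniform in the zone band, dates advancing half a
   day per station from late September (a boreal-autumn cruise window).

What the generator does *not* emulate: seasonality of the rate fields,
fronts and mesoscale structure, depth-varying replicate precision,
light-field modelling (light fractions are taken as exact), and any
correlation between hydrography and rates beyond zone membership.  Passing
tests therefore demonstrate that the *pipeline arithmetic and statistics*
behave correctly under realistic survey geometry and noise — not that the
generator is an ocean model.

A deliberate tension is worth recording: with integrated statistics
calibrated as above, the sampled-mean volumetric NCP is ≈ NCP_int/Z_eu —
about −0.12 mmol O₂ m⁻³ d⁻¹ in the NAST but ≈ +0.08 in the SATL, whereas
surveys report ≈ +0.06 for the southern gyre from a sample that differs
from the integrated-station set.  No fixed vertical shape reconciles both
gyres simultaneously (it would require rates increasing with depth), so the
generator stays calibrated to the integrated scale and the southern
volumetric mean sits a few hundredths high.

## Problem sizes and runtime

Defaults were chosen so the whole suite runs comfortably on a laptop: the
Monte-Carlo oracles use 10⁴ draws (s.e. of a s.d. ratio ≈ 0.7%), regression
recovery uses 500 replicates (s.e. of the mean slope ≈ 0.005), calibration
checks average 20 generated transects (~113 stations each), and the
Lilliefors calibration uses 10⁴ simulated samples against a 10⁴-sample null
(s.e. of the rejection rate ≈ 0.3%).  The complete test suite runs in
about 40 s; the reproduction script in about 25 s.
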