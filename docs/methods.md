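# Methods

## Scientific setting

Facultative nitrogen-fixing trees adjust symbiotic nitrogen fixation (SNF) to
the balance of nitrogen supply and demand, but not instantly. This package
implements the inference chain that turns repeated, nondestructive
closed-chamber measurements of whole-plant nitrogenase activity into
quantitative regulation timescales: how many days a seedling needs to shut
SNF down after nitrogen becomes plentiful, or to ramp it up after nitrogen is
withdrawn.

The chain has two halves: (1) per-incubation flux inversion — from raw
analyzer traces to substrate-saturated acetylene reduction (Vmax), SNF and
whole-plant CO2 exchange, each with parametric-bootstrap uncertainty; and
(2) longitudinal regulation fitting — a lagged sigmoid fit by maximum
likelihood to each plant's SNF trajectory, with parameter sharing across
plants selected by AICc, and timescales derived in closed form from the fits.

## Chamber flux inversion

A plant is sealed in a stirred chamber (default volume 40.5 l) that leaks
with first-order rate constant `keff` (default 0.0045 h^-1, 95% CI
0.0010–0.0105 h^-1, shared by ethylene, acetylene and CO2). Acetylene is
injected to ~2% (A0 = 20,000 ppm); nitrogenase reduces it to ethylene at a
Michaelis–Menten rate in the acetylene concentration, which itself decays as
`A(t) = A0 exp(-keff t)`. Inverting this model:

    Vmax(t) = (dE/dt + keff E(t)) · (Km / (A0 e^(-keff t)) + 1) · n

with `Km` the species-specific half-saturation acetylene concentration and
`n = PV/RT` the molar content of the chamber (mole fractions in ppm, time in
hours), giving Vmax in µmol C2H4 h^-1. Net plant CO2 exchange uses the same
leak correction, `NPE(t) = (dCO2/dt + keff (CO2 - CO2_ambient)) · n`, with
the chamber-source sign convention (positive = the plant adds CO2 to the
chamber, i.e. respiration; negative = net uptake). Dark-phase NPE is
whole-symbiosis respiration; apparent photosynthesis is the light-minus-dark
difference (negative under this convention when the plant photosynthesises).

Processing order per incubation: (i) water-dilution correction
(`x_dry = x_wet/(1 - h2o)`, guarded against double application); (ii)
subtraction of the plant's background ethylene production, fitted as an OLS
slope over the pre-injection phase and removed as a linear-in-time term —
a slope rather than a constant, because what is reported and physically
meaningful is a background *rate*; (iii) slope estimation over the last
5 min of the acetylene phase (ordinary least squares, standard error from
the residuals), or — for species whose nitrogenase activity declines under
acetylene exposure — a 480-point moving regression over the
post-equilibration phase whose maximum-slope window is taken as the
pre-decline rate. The flux equations are evaluated at the slope window's
midpoint, where the OLS slope approximates the instantaneous derivative to
second order; E(t) and CO2(t) at that time are taken from the window's
fitted intercept.

### Uncertainty

Parametric bootstrap: the slope and A0 are drawn from normals (slope SE from
OLS; A0 relative SD configurable, default 2%, since only the nominal
injection is known), and keff and Km from gamma distributions. The gammas
are published only as mean + 95% CI, so shape/rate are recovered by quantile
matching: the rate is pinned at shape/mean (mean exact) and the shape chosen
to minimize the squared relative error of the 2.5%/97.5% quantiles. For the
default keff this yields shape ≈ 3.23, rate ≈ 717 h, with quantiles within
1% of the stated CI. Fluxes are evaluated per draw (10,000 draws by default,
seeded); the point estimate is the all-means evaluation and the 95% CI the
2.5/97.5 percentile of the draws. Conversion from acetylene reduction to SNF
divides by a species-specific mol-ethylene-per-mol-N factor — a pure
rescaling that provably cannot move the regulation parameters r and tL.

Negative or near-zero Vmax values are reported as-is; exclusion of
non-fixing plants is a separate, logged, threshold rule applied to the
assembled measurement table (threshold configurable; no default is claimed
to reproduce the original study's unpublished criteria).

## Regulation model

Each plant's SNF, divided by whole-symbiosis respiration to factor out
growth, is modelled as a lagged sigmoid in days `t` since the nitrogen
switch:

    SNF(t) = K / (1 + exp(-r (t - tL)))

`K` is the saturated rate, `tL` the day SNF crosses K/2, and `r` (d^-1) the
steepness; r > 0 is upregulation, r < 0 downregulation (enforced as a bound
from the experiment's switch direction). Observation error is Gaussian, iid,
with a single σ per fitted data set (per-group σ optional); the error model
is a package choice, stated here because the original analysis does not
publish one.

Fitting is bounded quasi-Newton (L-BFGS-B) maximum likelihood on the
internal scale (log K, tL, r, log σ) with an analytic gradient. Starting
values are deterministic functions of the data: K from the trajectory
maximum (upregulation) or initial value (downregulation), tL from the
linear-interpolated half-maximum crossing, r from ±2·ln(19) divided by the
observed 5-to-95% span; 20 multi-starts perturb r (×0.25–×4) and tL (±30% of
the day span) on a fixed grid, so fits are reproducible without a seed. A
fit whose best start ends in an abnormal line search is accepted only if a
restart cannot improve it; otherwise it is flagged non-converged and
excluded from model selection with a logged reason.

### Parameter sharing and structure selection

Every plant gets its own K and tL by default; r is shared at a configurable
level of organisation (global, by symbiosis, by growing temperature, by
biome of origin, their two-way combinations, by species, or per plant). K,
tL and σ accept the same vocabulary. Candidate structures are ranked by
AICc = 2·NLL + 2k + 2k(k+1)/(n−k−1); when the top two differ by ΔAICc < 2
and are nested (every sharing partition of the simpler coarsens the
richer's), a likelihood-ratio test at 95% decides whether the extra
parameters are retained, ties breaking toward parsimony.

### Timescales and their uncertainty

From a fitted (K, r, tL), SNF crosses the fraction f of K at
`t = tL − ln(1/f − 1)/r`; the 5-to-95% transition is `2 ln(19)/|r|` —
independent of K and tL. Direction-aware reporting: for downregulation the
"initial response" (5% reduction) is the crossing of 0.95·K and the
"near-complete shutdown" (95% reduction) the crossing of 0.05·K. Per-plant
timescales use that plant's fitted K, so they can differ from naive
readings of the raw day-0 rate. Confidence intervals for any functional of
the parameters come from a parametric bootstrap: parameter vectors drawn
from a multivariate normal centred at the MLE with the inverse
finite-difference Hessian as covariance (falling back, with a warning, to
independent normals if the Hessian is not positive definite), pushed through
the functional, percentile 95% interval.

### Cross-plant inference

Per-plant tL estimates are extracted from the per-plant-tL fit family and
compared across factors with ordinary linear models (statsmodels OLS +
type-II ANOVA), ranked by the same AICc, and regressed on continuous
covariates (plant size proxied by day-0 whole-symbiosis respiration;
maximum SNF), reporting the slope in days per covariate unit and the implied
tL change across the observed covariate range.

## Synthetic-data generator

The generator exists so every stage is testable without the original data
set; its defaults are the study conditions.

*Incubations*: the forward chamber ODEs (ethylene production from decaying
acetylene, CO2 relaxation toward ambient under a plant source/sink, both
leaking) are integrated with adaptive RK at tolerance 1e-9 — tight enough
that round-trip error lives in the estimator, not the simulator — then
resampled at 1 Hz, re-wetted by a linear humidity ramp (default 0 → 2%) so
the dilution correction is exercised, and given Gaussian channel noise
(defaults 0.5 ppb ethylene, 0.3 ppm CO2, instrument-order realism).
Optional: plant-background ethylene production and an exponential
nitrogenase decline after an onset time, exercising the moving-regression
path.

*Cohorts*: 4 species (2 rhizobial, 2 actinorhizal; 2 tropical, 2 temperate)
× 2 growing temperatures, 4 plants per cell by default, sampled at the
study cadence (day 0, day 3, then every 1–2 weeks). Per-plant K is
log-normal (σ_log 0.3 around 0.1 — SNF per unit respiration is a small
dimensionless ratio), per-plant tL normal, r fixed per group. Group truth
emulates the observed scales: upregulation r by symbiosis (5-to-95%
transitions of 57 d rhizobial / 21 d actinorhizal, with tL placed so SNF
becomes detectable near day 51 / 117); downregulation r by biome ×
temperature with 95% shutdown near 35/31/51/36 d (temperate-cold /
temperate-warm / tropical-cold / tropical-warm) and 5-to-95% transitions in
the observed 29–50 d band. Measurement noise defaults to 5% of the plant's
K. Down-direction tL spread is 3 d and up-direction 12 d, reflecting the
much larger individual variation seen in upregulation onset. Optional
non-fixing plants (near-zero noise trajectories) exercise the exclusion
rule.

What the generator does *not* emulate: acetylene/ethylene toxicity dynamics
beyond an imposed exponential decline, diurnal physiology, drift or
autocorrelation in analyzer noise, plant death or missed measurement days,
and any dependence of measurement error on SNF magnitude. Passing recovery
tests therefore certify the estimators under the stated error model, not
robustness to these departures.

## Numerical choices and degenerate inputs

- Sigmoid evaluation uses the logistic `expit`, safe for |r(t−tL)| ≫ 700.
- Internal optimiser bounds: |r| ∈ [1e-4, 10] d^-1 (sign by direction), tL
  within the observed day range ± 2 spans, log K within ±12 nats of the data
  scale, log σ within [−20, +6] nats of it.
- AICc requires n − k − 1 > 0; it raises rather than returning a value
  outside its domain.
- The LRT raises on non-nested pairs and on deviances more negative than
  numerical tolerance (a sign of failed optimisation), and clamps tiny
  negative deviances to zero.
- Noiseless data drive σ to its lower bound; the restart-based convergence
  rule (above) accepts such fits.
- A slope window needs ≥ 3 points; a background phase ≥ 10 min (configurable
  to a hard error instead of a warned zero-correction).
- All randomness flows from one root seed, split per stage via
  `numpy.random.SeedSequence.spawn`.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run entirely on synthetic data:
15-minute incubations at 1 Hz; 500-replicate bootstrap-coverage studies at
2,000 draws; 200-replicate recovery/selection studies on 2-group × 8-plant
cohorts at 1,000-scale bootstrap sizes; study-scale cohorts of 32 plants.
These sizes give Monte-Carlo error comfortably below the asserted
tolerances while keeping a full run to a few minutes.

## Known limitations

- The CO2-concentration response correction applied to photosynthesis
  fluxes in the original workflow is out of scope here; apparent
  photosynthesis is reported uncorrected.
- Nonlinear mixed-effects variants (random plant effects) are deliberately
  absent — the fixed-effects-with-sharing structure is the supported path.
- Species Km values and ethylene→SNF conversion factors must be supplied in
  the config; the defaults shipped with the generator are order-of-magnitude
  placeholders, not measured values.
- Exclusion thresholds for non-fixing plants are configurable inputs; no
  default reproduces the original study's unpublished criteria.
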