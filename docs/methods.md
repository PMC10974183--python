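# Methods

## Scope and model

`mixtox` analyses algal growth-inhibition assays of chemical mixtures. The
measured endpoint is the 96 h growth inhibition derived from optical
densities,

    I = 1 − (OD_t,96 − OD_t,0) / (OD_c,96 − OD_c,0),

where the denominator is the control growth delta (we use the mean over
control replicates). Because the formula uses within-arm deltas, a constant
blank offset within an arm cancels.

Concentration–response curves (CRCs) are fitted with the two classical
two-parameter families:

* **Weibull** `E = 1 − exp(−exp(α + β·log10 x))`, with α a location and β a
  slope on the log10 concentration axis;
* **Hill** `E = α·x/(β + x)`, with α ∈ (0, 1] the maximum effect and β > 0
  the EC50 in mol/L.

Model selection keeps the family with maximum R²; ties within 10⁻⁶ are
broken by minimum RMSE and then by family order (Weibull first). R² uses the
total sum of squares about the mean of the observed effects and is reported
as NaN when all effects are identical (SStot = 0). RMSE uses denominator `n`
(not `n − p`), the commonest convention in the mixture-toxicology
literature; users comparing against `n − p` variants should rescale.
Effects outside [0, 1] (hormesis / stimulation) are not clipped before
fitting — clipping would bias the slope estimate.

Fitting is plain least squares (`scipy.optimize.least_squares`, LM for the
unbounded Weibull problem, TRF with box bounds 0 < α ≤ 1, β > 0 for Hill)
with tight tolerances (1e−15) so that noise-free data are recovered to
optimizer precision. Starting values: Weibull from a linearised
`ln(−ln(1−E))` vs `log10 x` regression on interior effects; Hill from the
maximum observed effect (clipped to (0, 1]) and the concentration nearest
half-max. Both choices keep the optimiser away from flat (β → 0) solutions.
Non-convergence is flagged on the result, never silently replaced.

## Mixture reference models

A fixed-ratio **ray** holds molar fractions `p_i` (Σp_i = 1) of the total
mixture concentration fixed while diluting the total geometrically.

* **Concentration addition (CA)**: Σ c_i/EC_x,i = 1, giving the mixture
  effect concentration as the fraction-weighted harmonic mean
  `EC_x,CA = 1/Σ(p_i/EC_x,i)`. The CA *curve* at a given total concentration
  is obtained by monotone root-finding (Brent on the log-concentration
  scale) for the effect level whose CA effect concentration equals it.
* **Independent action (IA)**: `E(c_mix) = 1 − Π(1 − E_i(p_i·c_mix))`,
  inverted by geometric bracketing (factor 10, starting from the CA scale)
  plus Brent bisection in log10 concentration to a relative concentration
  tolerance of 1e−10. No derivative-based root-finding is used, avoiding
  slope pathologies at extreme effect levels.

The 0.20:0.80 ratio is interpreted as molar fractions of the total mixture
molar concentration (`c_i = p_i·c_mix`). A Hill component with ceiling
α < 1 truncates the attainable effect range; requesting a level at or above
the ceiling raises rather than extrapolating. Single-component "rays" are
accepted as the degenerate m = 1 case.

## Interaction classification

The mixture deviation ratio compares prediction with observation:
`MDR = EC_x,pred/EC_x,obs`, with `EC_x,obs` from a CRC fitted to the
mixture's own data. Its bounds come from the 95% observed confidence
interval (OCI) of the observed effect concentration:
`MDR_lower = EC_x,low/EC_x,obs ≤ 1 ≤ MDR_upper = EC_x,up/EC_x,obs`.
`MDR > MDR_upper` is called synergism, `MDR < MDR_lower` antagonism,
anything in between (including boundary equality, which the strict
inequalities leave undefined) additive. MDR is reported against both CA and
IA references at effect levels {0.10, 0.25, 0.50} by default, with 0.50 as
the headline level.

The dose-reduction index uses the standard definition
`DRI_i = EC_x,i/(p_i·EC_x,mix)` — the fold-reduction in component i's dose
achievable inside the mixture at equal effect.

## Bootstrap confidence intervals

The 95% OCI on an effect concentration is a seeded nonparametric
**pooled residual bootstrap**: the centred residuals of the point fit are
resampled with replacement across all wells, added back to the fitted
values, the curve is refit (same family, warm-started at the point
estimate), and inverted; the 2.5th/97.5th percentiles over `n_boot`
(default 1000) resamples form the interval. Resamples whose refitted curve
cannot attain the requested level (e.g. a Hill ceiling below it) are
dropped. The interval is widened, if necessary, to contain the point
estimate, so `ec_low ≤ ec ≤ ec_up` always holds; noise-free data give a
degenerate zero-width interval.

Residuals are pooled rather than resampled within concentration groups
deliberately: with triplicate designs, a 3-point group's empirical scatter
systematically underestimates the group-mean variability and the resulting
intervals under-cover badly (we measured ~65% coverage of the true EC50
for a nominal 95% interval in simulation). Pooling the 21 residuals of the
7 × 3 design restores ~92% coverage at the default study conditions. The
pooled scheme assumes homoscedastic noise on the effect scale, which
matches the generator's instrument-scale noise model.

## Synthetic data generator

The generator emulates the assay design: a 7-level geometric dilution
series with dilution factor 0.4, triplicate wells, OD read at 0 h and
96 h, controls growing from OD 0.1 to 0.5 (arbitrary but fixed). For each
treatment well, `od_96 = od_0 + (1 − E_truth(c))·Δ_control + ε` with
`ε ~ N(0, noise_sd)` — noise lives on the instrument (OD) scale, not on
the derived effect; the default `noise_sd = 0.01` on a control growth
delta of 0.4 corresponds to ~2.5% effect-scale noise. Control wells carry
the nominal ODs exactly. Negative simulated ODs are clipped at zero with a
warning (rare at the defaults). Everything is deterministic given the
scenario seed.

Default truth curves are Weibull with EC50s 1.18 × 10⁻⁴ and
1.99 × 10⁻⁴ mol/L (the single-compound potencies of the two β-lactams the
stock scenario represents) mixed 0.20:0.80, sharing a common log10-slope of
3.0. The common slope encodes the similar mode of action of the two
compounds, and has a useful structural consequence: the CA composition of
equal-slope Weibull curves is itself exactly a Weibull curve, so the
noise-free generate → fit → assess loop is an exact identity (recovered
pEC50s to 1e−6, MDR to 1e−3) rather than an approximation limited by
family mismatch. The default top concentration of a series is 3× the
relevant EC50 (placing the series across ~1–95% effect); explicit
`top_conc` overrides are available for designs that, like real studies
often do, truncate the upper range.

Mixture truth surfaces: exact CA, exact IA, or a potency-shift synergy
factor `s` on the CA surface (`E(c) = E_CA(s·c)`), chosen because it maps
directly onto the expected CA-referenced MDR (≈ s): s = 1 reduces to CA,
s > 1 is synergy, s < 1 antagonism.

Biomarker tables (pigment and TBARS absorbances, enzyme activities) are
generated by a linear index response to the truth effect,
`value = control·(1 − slope·E)`, back-converted through the inverted
pigment/MDA equations so the endpoint calculators recover the targets
exactly at zero noise. Control index levels are fixed package constants on
realistic scales (e.g. chlorophyll a 4 µg/mL, MDA at 10⁶ cells/mL).

What the generator does **not** emulate: mechanistic algal growth (logistic
growth, nutrient/light dynamics), hormesis-shaped truth curves,
between-replicate systematic drift, heteroscedastic or non-Gaussian
instrument noise, and noisy control wells. Passing the simulation tests
therefore shows correctness of the estimators under the stated noise
model, not robustness to every feature of real plate data.

## Endpoint calculators

Growth inhibition, MDA content
(`[6.45(OD532 − OD600) − 0.56·OD450]·M/(1000·N)`), and the chlorophyll
a/b / carotenoid equations
(`Chla = 13.59·OD665 − 6.88·OD649`, `Chlb = 24.96·OD649 − 7.32·OD665`,
`Car = (1000·OD470 − 2.05·OD665 − 114.8·OD649)/245`) are evaluated exactly
as printed; pigment values are reported in the formula-native µg/mL-scale
units with no extra normalisation, and MDA in its formula-native per-cell
units. Negative MDA values from pathological absorbances are reported, not
clipped. Relative change versus control is inhibition-positive:
`100·(control − treatment)/control`. The correlation panel is the ordinary
Pearson matrix across concentration-level index means; zero-variance
indices yield NaN sentinels. Replicate dispersion in the panel is
summarised as the sample standard deviation.

## Numerical choices and degenerate inputs

* Effect-level padding for CA curve evaluation: 1e−9 away from 0 and from
  the attainable ceiling; grid concentrations outside the representable
  range clamp to the padded boundary levels.
* Fitting requires ≥ 3 observations and ≥ 2 distinct concentrations;
  constant effects give R² = NaN.
* pEC50s are reported rounded to 2 decimals; internal values keep full
  precision.
* Boundary MDR ties classify as additive.
* All randomness flows through `numpy.random.default_rng(seed)`; identical
  seeds give bit-identical outputs.

## Problem sizes used in the test and acceptance runs

Simulation-based checks use the default 7 × 3 design. Classification
recovery uses 50 seeds per truth scenario with 500 bootstrap resamples at
OD noise 0.02; the EC50 coverage check uses 100 simulated experiments with
300 resamples each. These sizes give Monte Carlo standard errors
comfortably below the margins being asserted.

## Known limitations

* Only two-parameter CRC families; no floor/ceiling log-logistic variants,
  Box–Cox transforms, or weighted least squares.
* No generalized concentration addition for partial agonists: a Hill
  component with α < 1 simply truncates the attainable CA range.
* No isobologram/response-surface interaction analysis; the MDR is a
  single-ray summary.
* The bootstrap OCI reflects mixture-fit uncertainty only; uncertainty in
  the single-compound fits propagates into the MDR point value but not
  into its bounds, which is the main driver of the residual false-positive
  rate in the additive-truth simulations.
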