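# Methods

## Headspace correction and its central property

A spot sample drawn from the rumen headspace through the cannula is modelled
as true rumen gas diluted by an air fraction `f`:
`raw_g = true_g * (1 - f) + air_g * f`.  Since the contaminating air is
essentially N2 and O2, the correction assumes CO2 + CH4 + N2O = 100 vol% in
the undiluted gas and renormalises the three measured fractions.  When the
air carries none of the three gases this is an exact inverse for every
`f < 1` (dilution invariance, property-tested over random compositions and
`f` up to 0.9).  Real air carries ~0.04 vol% CO2; with that composition the
correction is biased by `f * 0.04` vol% of CO2 — under 0.1% of the rumen CO2
proportion even at 50% contamination — and the package deliberately ignores
it, matching the N2/O2-only assumption under which the field applies this
correction.  Argon is folded into N2 (air = 79.01 / 20.95 / 0.04 vol%
N2 / O2 / CO2); atmospheric CH4 and N2O are zero.

## The N2O:CH4 anchor ratio

N2O production is quantified as daily CH4 production (L/d) times the
headspace N2O:CH4 volume ratio (L/L), regrammed via the ideal gas law.
Equal molar volumes cancel, leaving `n2o_g = ch4_g / M_CH4 * ratio * M_N2O`;
the configured molar volume (default 22.414 L/mol at 0 degC, 101.325 kPa)
affects only the diagnostic L/d intermediates, and a test asserts the mass
result is bit-identical at 0 degC and 39 degC references.

How the 16 spot samples aggregate into one ratio per cow x period is a
genuinely open choice; three methods are implemented:

* `per-sample-mean` — arithmetic mean of per-sample N2O/CH4;
* `ratio-of-means` — mean N2O proportion over mean CH4 proportion;
* `time-weighted` (default) — trapezoidal time average of per-sample ratios
  over the cyclic 24-h day, per sampling day, then averaged across days.

The default is time-weighted because the schedule is deliberately
front-loaded after the morning feeding; an unweighted mean over-represents
the post-feeding window.  Ratios are computed per cow x period first and
only then averaged across animals, matching the mixed models' unit of
analysis.

## Stoichiometry and GWP accounting

Nitrate reduction to ammonium and methanogenesis are both 8-electron
(4 mol H2) sinks, so 1 mol NO3- fully reduced prevents at most 1 mol CH4:
theoretical potential = `dose / M_NO3 * M_CH4` g CH4 per kg DMI.  Molar
masses default to 4 significant figures (CH4 16.04, N2O 44.01, NO3- 62.00
g/mol) — the precision at which this literature reports the derived
quantities — and are config-overridable for higher-precision work.
Efficacy is the observed CH4-yield reduction as a percentage of the
potential; values above 100% are meaningful (direct toxicity of nitrate to
methanogens adds to the H2-competition effect).

The GWP offset weights the N2O increase and the CH4 reduction by their
100-year GWPs (defaults 273 and 27 g CO2-eq/g, config-overridable since
horizons differ across assessment reports) and reports their ratio as a
percentage.  It is computed from treatment LSMEANS differences.  All
percentages are carried at full precision and rounded only at reporting,
half away from zero.

## Mixed models

Both study models are fitted by restricted maximum likelihood through one
engine (`mixedlm.MixedModel`): `y = Xb + sum_g Z_g u_g + e`, random effects
`u_g ~ N(0, s2_g I)`, residuals `e ~ N(0, s2_e C(rho))` with `C` the
blocked AR(1) correlation over declared cow x period x day series (identity
when no serial correlation is requested).

Numerics: the restricted log-likelihood is evaluated via the Woodbury
identity, with the AR(1) inverse's tridiagonal structure reduced to three
precomputed Gram matrices so each evaluation costs only O(K^3) in the
number of random-effect levels; the response is centred internally (exactly
neutral for a design with an intercept) to avoid cancellation on large
baselines.  Optimisation is bounded L-BFGS-B on (log variances, atanh rho)
from a fixed lattice of deterministic restarts (3 for the 2-parameter
crossover problem, 5 for the 4-parameter repeated problem), so fits are
run-to-run reproducible.  Variances are bounded within 1e-8 to 1e4 times
the response variance; estimates at the floor report as zero.  Constant
responses short-circuit to OLS with all variances zero.  Non-convergence
raises an error carrying the best point and gradient norm.

Design and inference choices:

* Crossover model: treatment and period as dummies, cow random.  In the
  balanced 2x2 design the GLS treatment estimate must equal the classical
  sequence-contrast estimator (half the difference between the sequence
  groups' period-1 minus period-2 means); the fit verifies this identity
  internally and errors on unbalanced designs rather than silently
  degrading.  The treatment t-test uses n_cows - 2 denominator df.
* Repeated model: sum-to-zero coding for treatment, time, their
  interaction and period, giving type-III-style Wald F-tests for effect
  blocks.  Denominator df follow a containment-style two-stratum rule,
  recorded in every result: effects constant within a cow x period series
  are tested against the between-series stratum
  (`n_series - n_cows - 1`), within-series effects against the residual
  stratum (`n - rank(X) - (n_cows - 1) - (n_day_levels - 1)`).  This is a
  deliberate, reproducible simplification; Kenward-Roger-style adjustments
  are out of scope.
* AR(1) applies over observation order within a series by default
  (`rho^|index gap|), which treats the unequally spaced 16-point schedule
  as a sequence; a continuous-time option (`rho^|dt|`) is provided because
  the spacing is unequal and either convention is defensible.
* Log transform (N2O proportions): values <= 0 are rejected with an error —
  no offset is invented silently; `RepeatedModelSpec.log_offset` makes an
  offset explicit when zeros are expected.  LSMEANS are computed on the
  model scale over the balanced treatment x time grid and back-transformed
  by exponentiation (geometric means, no bias correction), with
  delta-method standard errors.
* Two SEM flavours are reported and labelled (SE of a treatment LS mean and
  SE of the treatment difference), since summary tables in this literature
  print a single pooled "SEM" without saying which it is.

Validation: the engine's likelihood is checked against an independent
dense-matrix implementation in the tests (agreement to 1e-7), optimiser
solutions must dominate brute-force grid searches, and the AR(1) model is
cross-checked against R `nlme::lme` with `corAR1`.  On one test dataset
`lme` converges to a local optimum with a restricted log-likelihood 0.37
below ours (verified through the independent dense likelihood); the
cross-check therefore asserts "at least as good as lme" rather than exact
parameter equality.

## Synthetic-study generator

The generator's defaults are the study conditions: 4 cows in a balanced
2x2 crossover (2 per treatment sequence), 4 chamber days and 2 headspace
sampling days (16 spot samples each) per period, feedings at 0540 and
1650 h.

* Diurnal model: additive baseline plus two feeding-anchored exponential
  decay peaks, `curve(t) = m (1 + a (g(t) - mean(g)))` with
  `g(t) = exp(-k dt_morning) + exp(-k dt_evening)`, normalised on the
  sampling grid so the grid mean of the noise-free curve is exactly `m`.
  Decay constant 0.5/h (~1.4 h half-life).  Nitrate flattens the CH4 peak
  (`a` 0.35 -> 0.15), matching the observed persistent-suppression pattern.
* Calibration: hourly means per treatment are the reported values — CH4
  17.4/15.1, H2 0.06/0.19 g/h, CO2 and O2 from daily values / 24; DMI
  22.9/23.0 kg/d; milk composition 4.54/3.91/4.71% (urea arm).  Milk yield
  defaults to 24.5 kg/d so that computed ECM matches the reported
  27.2 kg/d (the 29.4 kg/d herd figure is a pre-trial average inconsistent
  with ECM 27.2 under the reported composition).  Dietary gross energy
  18.9 MJ/kg DM is back-computed from CH4/GEI 5.31% at 412 g CH4/d and
  22.9 kg DMI; CH4 gross energy 55.65 kJ/g.
* Headspace truth: CH4 proportion follows the same diurnal form around
  20.5/18.7 vol%; N2O is log-normal around 0.001/0.008 vol%; CO2 is the
  complement to 100.  Air contamination per sample is uniform on 0-40% —
  the study reports contamination "considerably higher" than the 2-4% of
  earlier work without quantifying it, so the upper bound is a package
  choice, flagged in the parameters.
* Noise structure mirrors the repeated model: cow effects, sampling-day
  effects shared across cows, stationary AR(1) residuals (rho 0.5) along
  each within-day trace.  All randomness flows from one seed through named
  substreams, so regenerating any single stage never perturbs another.

What the generator does not emulate: rumen fermentation kinetics (VFA,
pH, nitrite intermediates), feeding-behaviour feedback on the diurnal
shape, instrument drift, or between-day non-stationarity.  Passing tests
therefore demonstrate correctness of the analysis chain under the model's
own assumptions, not robustness to real-data pathologies.

## Problem sizes used in the checks

Monte-Carlo checks use 200 cows for generator calibration and the
end-to-end reduction reproduction, 500 cows for trait-mean recovery, 2,000
simulated 4-cow crossovers for type-I error, and 200 replicates of the
4-cow x 2-period x 2-day x 16-time design for AR(1) recovery; grid oracles
use 10 small random datasets.  These sizes keep every check's Monte-Carlo
error well inside its assertion band.

## Known limitations

* Only the two study designs (and their degenerate reductions) are
  supported; this is not a general mixed-model engine.
* Containment-style df are approximate for unbalanced data; the fitter
  refuses unbalanced crossovers outright.
* The headspace correction inherits the N2/O2-only contamination
  assumption; heavy CO2 contamination (e.g. expired air) would bias it.
* No multiple-testing adjustment is applied, matching practice in these
  tables.
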