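# Methods

This note records the models implemented in `foxcache`, the choices
made where the design was genuinely open, and what the synthetic data
do and do not establish about real collar data.

## Sampling model

A collar records a 30-s tri-axial acceleration burst (50 Hz; sway =
lateral, surge = longitudinal, heave = vertical, all in g) every
4.5 min and one GPS fix every 4 min. Each burst partitions into ten
contiguous 3-s windows, the classification unit. Window length is a
config knob (`SimConfig.window_s`, must divide the burst); 3 s is the
default because shorter windows multiply the training sample and
improve precision for the rare focal behaviour, while longer windows
increasingly mix behaviours.

## Synthetic signal models

No quantitative field waveforms are available, so the generator fixes
qualitative contrasts with explicit parameters (all in `SimConfig`,
units g and Hz):

- **motionless** — static gravity vector (0, 0.05, 0.98) plus white
  noise (SD 0.02);
- **walking** — 2 Hz sinusoid with a 2f harmonic, moderate amplitude
  (0.08, 0.12, 0.22), noise SD 0.04;
- **running** — 3.5 Hz gait at roughly 3x walking amplitude
  (0.25, 0.35, 0.65), noise SD 0.06;
- **digging** — amplitude-modulated noise bursts (on 0.4–0.9 s, off
  0.2–0.6 s, carrier 4–5 Hz, amplitude jitter 0.6–1.3x) with the surge
  static component shifted to −0.30 (head down), noise SD 0.08.

Every bout additionally receives a random per-axis baseline offset
with the same SD as the sample noise, representing collar-posture
variability; this makes the single `noise_scale` knob blur both the
dynamic and the quasi-static contrasts, so classification accuracy
degrades as noise is inflated (a property the tests assert) instead of
being rescued by sample averaging.

## Behaviour and movement processes

Locomotor behaviour follows a semi-Markov process over
(running, walking, motionless) with exponential dwell times (means 80,
20, 115 s) and a uniform embedded jump chain. The long-run time
fractions are the embedded stationary distribution weighted by dwell
means (~37/9/54%), chosen to reproduce a realistic budget ordering
(motionless most, then running, walking least) without asserting any
field value. The fox moves by a correlated random walk on a 3-s step
grid: heading increments N(0, 0.6 rad), speed by state (3.0, 0.8,
0 m/s), reflection at the landscape boundary.

Digging is overlaid per burst, not simulated as a fourth dwell state:
the burst's digging indicator is drawn from the cloglog model below,
and a positive draw converts 1 + Binomial(9, 0.25) of the ten windows
to digging. This makes the indicator exactly consistent with its
definition (1 iff ≥ 1 digging window) and puts the caching process
under the analyst's model by construction, which is what parameter
recovery requires.

Each fox-year records two deployment sessions of half the configured
duration each — one starting just before incubation (default offset
−0.05 d, producing a few pre-season bursts that exercise the phenology
filter) and one a day into brooding — so both period levels occur even
in short simulated campaigns. A single continuous session is available
via `include_brooding_session=False`.

## Landscape

The goose-density surface is a sum of Gaussian patches on a 100×100
grid of 1-ha cells (values in geese/ha, peaks 15–40), written and read
as an ESRI ASCII grid. Coordinates are planar metres throughout: the
quantities of interest (50-m den buffer, den distances) are metric and
a map projection would add nothing testable. Dens are uniform over the
interior, at least one cell from the boundary. Raster lookup returns
the containing cell's value with no interpolation — density is a
survey-block proxy, not a smooth field.

## Features (52)

Per axis (13 × 3): mean, SD, skewness, kurtosis, min, max, range, mean
absolute deviation, RMS, mean-crossing count, 25th/75th percentiles,
mean absolute first difference. Per axis pair (2 × 3): Pearson
correlation and covariance. Whole-signal (7): ODBA mean/SD/max, VeDBA
mean/SD, vector-magnitude mean/SD, with ODBA = Σ_axes |a − ā| and
VeDBA the Euclidean analogue. Conventions are pinned so an independent
reference implementation reproduces every value exactly: population
(÷n) normalisation for SD/covariance/moments, kurtosis as raw m4/m2²,
linear-interpolation percentiles, crossings as sign changes of
(x − mean) > 0, and zero-variance axes reporting correlation,
skewness and kurtosis as 0 so classifiers always see finite inputs.
The exact membership of the set is a declared implementation choice
spanning the families standard in accelerometry classification
(moments, extrema, dynamic body acceleration, cross-axis association);
the cardinality is fixed at 52.

## Classification

Eight classifiers with fixed hyperparameters: 3-nearest neighbours;
linear and RBF SVMs; decision tree; random forest (500 trees);
Gaussian naive Bayes; LDA; one-hidden-layer (32-unit) neural network.
Distance- and gradient-based learners get train-fold standardization;
trees, forest, NB and LDA take raw features. Cross-validation is
5-fold, stratified by category (with 49 digging sequences, unstratified
folds can lack the class entirely; plain splitting remains available),
with identical fold assignments across algorithms so comparisons are
paired. Out-of-fold predictions pool into a single confusion matrix
per algorithm. Metrics are one-vs-rest accuracy/precision/recall per
category with count-weighted averages; weighted recall is identically
the micro-accuracy (trace/total). Values are carried at full precision
and rounded half-up to two decimals only in reports. Selection
maximizes weighted precision, breaking ties by digging precision and
then weighted accuracy — precision on the rare focal behaviour is what
downstream spatial inference depends on. The selected algorithm is
refit on the full training set before annotating the complete dataset.

## Burst–GPS fusion and filters

A burst is matched to the closest same-fox fix whose time distance to
the interval [start, start + 30 s] is ≤ 30 s; the fix with the minimal
distance wins and exact ties go to the earlier fix. Matching never
crosses foxes; unmatched bursts are dropped with logged counts.
Covariates: raster density at the fix; period from year-specific dates
(incubation start ≤ t < brooding start → incubation; brooding start ≤
t through the brooding end *date*, inclusive as a calendar day →
brooding); minimum Euclidean den distance; sex and reproductive status
from metadata; year from the burst timestamp.

The exclusion cascade runs in a fixed order — (capture) within 48 h
after any capture of that fox, (off-map) outside the raster or on
NODATA, (pre-season) before that year's incubation start, (near-den)
strictly < 50 m from a den — attributing each dropped record to the
first matching rule. The retained set is provably order-invariant
(each record is dropped iff it violates ≥ 1 rule); only the
attribution counts depend on order, and a permuted order is available
to verify exactly that. The identity
`retained + Σ exclusions + unmatched = all bursts` is asserted in
tests and logged on every run.

## The caching model

Binomial GLMM, cloglog link: P(y = 1) = 1 − exp(−exp(η)), the natural
link for "≥ 1 event in a 30-s interval" and deliberately asymmetric
(P = 1 − 1/e ≈ 0.632 at η = 0). Fixed effects: standardized goose
density, period (reference incubation), their interaction, sex
(reference male), reproductive status (reference reproductive), their
interaction, intercept. Random intercepts: fox identity and year,
crossed — a fox tracked in both years keeps one intercept, and both
effects enter one joint penalized system with no nesting assumption.

Estimation: for fixed (σ_fox, σ_year) the joint mode of (β, u, v) is
found by penalized IRLS (Fisher scoring on the working model;
step-halving guards the penalized objective; group-indicator structure
reduces every crossproduct to `bincount` aggregations, O(n) per
iteration). The Laplace log-likelihood — conditional log-likelihood at
the mode, minus the Gaussian penalty, minus ½ log det of the
random-effects information (2π factors cancel) — is maximized over
(log σ_fox, log σ_year) by Nelder-Mead with warm-started inner solves,
optionally polished by coordinate-wise golden-section refinement. σ is
bounded below at 10⁻⁴; estimates collapsing there are reported as
boundary values (expected for the 2-level year effect), never treated
as errors. With both variances fixed at zero the random effects drop
out and the fit is an ordinary cloglog GLM; tests verify agreement
with the statsmodels IRLS implementation to 10⁻⁴ and equality of the
maximized log-likelihood.

Inference is Wald only: SEs from the (β, β) block of the inverse joint
information at the mode, z = β̂/SE, normal p-values, CI = β̂ ± 1.96 SE.
Density standardization divides by one sample SD (ddof = 1) by
default; a 2-SD convention is a flag. The constants are stored on the
fit so prediction grids can be given on the raw geese/ha scale.
Predictions are population-level (random effects at zero) at the
reference levels; the optional band is a delta-method Wald interval on
the linear predictor, transformed — hence asymmetric in probability —
and is labelled as such because nothing stronger (profile or
simulation bands) is claimed.

Numerical guards: η is clipped at 3.6 before exponentiation
(μ within 10⁻¹⁶ of 1), μ at [10⁻¹², 1 − 10⁻¹²], and log μ computed via
expm1 to keep the extreme tails finite.

## Problem sizes used in the test suite

Classifier calibration uses 660 sequences at class counts
146/126/49/339. Mixed-model recovery uses 20 replicates of 23
fox-years × 2410 bursts (~55,000 rows); confidence-interval coverage
uses 100 replicates of 20 fox-years × 120 bursts. Pipeline round-trips
run a 3-fox, 2-h-per-fox campaign (156 bursts) through every stage
including file I/O. These sizes make each property cheap to re-verify
while keeping Monte-Carlo error well below the asserted tolerances.

## What the synthetic data do not show

The generator's behaviours are cleanly separable by construction at
default noise (per-behaviour accuracies near 100%, comfortably above
the 96% calibration bound); real collar data include transitional and
rare behaviours, inter-individual signal differences and sensor drift,
so field accuracies will be lower and must be estimated from real
annotation. Field-scale summary numbers — the activity budget split,
the GPS match fraction, the digging rate and the full fitted
coefficient table — depend on the field data and are represented here
only by their structural identities (metric identities, partition
identities, oracle equivalence, coverage calibration, monotone
density–digging response), which is what the test suite asserts. The
movement model has no territory structure, no terrain, and GPS error
is optional Gaussian jitter only.

## Known limitations

- The annotation clock is reduced to a single signed offset; real
  video synchronization drift within an observation is not modelled.
- Crossed random intercepts only; no random slopes, no spatial or
  temporal autocorrelation between consecutive bursts.
- Wald inference throughout; with 2 year levels the year variance is
  weakly identified and routinely lands at the boundary.
- The dense fox×year cross-term in the joint information is built as a
  dense block; fine for tens of foxes and a few years, not for
  thousands of grouping levels.
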