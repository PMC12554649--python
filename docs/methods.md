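# Methods

This note documents the models, the synthetic data-generating process, the
numerical choices and the known limitations of `ruralcoord`.

## Data model

All stages share one balanced long-format panel: one row per (unit, year)
carrying 11 development indicators, 4 DEA inputs, 2 DEA outputs, 6 driver
covariates and a region label (default region set East/Central/West).
Balance is enforced — a missing (unit, year) cell rejects the dataset with
the offending pairs named — and DEA blocks must be strictly positive.
Missing values are never imputed: the upstream sources for such panels are
curated yearbook tables, and silent imputation would contaminate every
downstream stage. Spatial structure enters through a symmetric binary
contiguity matrix; isolated units are warned about and excluded from
spatial operations only.

## Composite index (CRITIC)

Indicators are range-normalized (`(x − min)/(max − min)`, reversed for
cost-type indicators). Normalization is pooled over all unit-years so U1 is
comparable across years — cross-year comparison of levels is the point of
the analysis; per-year normalization is available behind a flag for
sensitivity. Weights use the sample standard deviation (n − 1 denominator)
of the normalized columns and Pearson correlations for the conflict term
`R_j = Σ_i (1 − r_ij)`; they are computed once from the pooled panel, not
per year. All default indicators are benefit-type; directions are
configurable. A constant column or a perfectly correlated indicator set is
an error, not a silent fill.

## DEA efficiency (SBM and super-efficiency)

The non-oriented SBM model is solved per unit-year through the
Charnes–Cooper fractional-to-linear transformation (scalar t normalizes
the denominator; all variables are rescaled by t), with HiGHS as the LP
solver. Defaults: constant returns to scale and a contemporaneous
(per-year) frontier — year-by-year efficiencies that can rise and fall are
the behaviour of interest; VRS and a pooled frontier are flags. A unit is
"efficient" when ρ ≥ 1 − 1e-6; efficient units are re-scored with the
super-efficiency model, whose output-reduction slacks are capped at
(1 − 1e-9)·y_rk to keep the objective denominator positive. Under VRS the
reduced reference set can make the super problem infeasible; the score then
falls back to 1.0 with status `infeasible` and the count is recorded in the
run manifest. The contract is the score, not the peer weights: LP
degeneracy may admit multiple optimal λ.

## Coupling coordination

`C = 2√(U1·U2)/(U1+U2)`, `N = αU1 + βU2` with α = β = 0.5 by default (the
two systems are treated as symmetric), and `D = √(C·N)` by default. The
plain product `D = C·N` is selectable (`form="product"`), and the manifest
records which form a run used; the square-root form is the default because
it is the conventional scaling whose magnitudes match the ten-tier grading
(a balanced pair at level 0.5 grades "intermediate" under the root form
but "proximity" under the product form, which compresses the scale).
Because super-efficiency allows U2 > 1, U2 is clipped at 1.0 for the CCD
computation by default (the grading assumes D ≤ 1); clipped rows are
flagged and counted. Tier intervals are right-closed; boundary values go
to the lower tier. Regional D values are means of provincial D, not D of
regional mean scores.

## Dagum Gini decomposition

Only the total Gini has a single canonical formula; the three-way split
follows Dagum's subgroup scheme: within = population-share × value-share
weighted group Ginis; the cross-group inequality of each region pair is
split into net between-group and transvariation parts by the relative
affluence `D_jh = (d_jh − p_jh)/(d_jh + p_jh)` computed from the empirical
mean positive and negative cross-group differences, with groups ordered by
ascending mean. The identity `G = G_w + G_nb + G_t` is exact and enforced
by property tests at 1e-10. Contribution rates are reported as fractions
(multiply by 100 for percentages).

## Kernel density and shape calls

Plain Gaussian KDE with Silverman's rule bandwidth
`0.9·min(sd, IQR/1.34)·n^(−1/5)` (no bandwidth is prescribed by
convention for these curves), evaluated on an even grid spanning the data
± 4 bandwidths so the trapezoid integral is ≈ 1. "Single/double/multi
peak" calls count strict local maxima with prominence above 5% of the
maximum density — below that floor, ripples are numerical, not
distributional. Tail masses integrate beyond main peak ± one bandwidth.
Zero-variance samples are rejected.

## Markov dynamics and Moran's I

D is discretised at the pooled 25/50/75 percentiles (one classification
for the whole window, so "moving up a state" means the same thing in every
year); ties at a cut point go to the lower state. Transition matrices at
lags 1–3 use overlapping L-step pairs. The spatial variant computes each
unit's lag value as the row-standardized neighbour mean of D at the
transition's start year, classifies it with the same thresholds, and bins
the transition by that lag state; conditional counts partition the
traditional counts exactly, and never-observed conditions yield all-zero
rows. Global Moran's I uses row-standardized weights; inference is by
random permutation (default 999, observed arrangement included in the null
count, one-sided greater) with a normal-approximation z also reported.

## Quantile regression of drivers

Each τ-fit minimises the pinball loss as an explicit LP (variables β free,
residual split u⁺/u⁻ ≥ 0), giving an exact, deterministic vertex solution;
the optimality contract is the attained loss and the subgradient condition
(share of negative residuals ≤ τ ≤ share of non-positive residuals, up to
p/n), not uniqueness of β under ties. Separate per-τ fits mean quantile
crossing is possible by design. The default covariate transform is natural
log of the monetary drivers (LED, HNL, GOV) followed by z-standardisation
of all six — coefficient magnitudes are then comparable across drivers.
Inference is xy-pair bootstrap (default 1000 replicates; the pipeline
default is 200, which stabilises t statistics to well under the
significance thresholds used) with percentile intervals and stars at the
10/5/1% levels; pair resampling is robust to heteroscedasticity, which the
panel structure makes likely. The panel is pooled across years (one
232-observation stack on the default panel); year dummies are not fitted.

## Synthetic data-generating process

One latent development factor per unit-year drives everything:

    latent = 0.5 + region_shift + unit_effect + 0.015·t + Σ β_k z_k + ε

followed by one pass of spatial mixing with the neighbour mean at strength
ρ = 0.3. Defaults: 29 units split 11/8/10 into East/Central/West, 8 years,
region shifts +0.08/0/−0.08, unit effects N(0, 0.05²), year noise
N(0, 0.03²). Driver processes z_k are standard-normal with a persistent
unit component (weight 0.95) and a region-aligned mean (±0.35, sign-matched
to the driver's effect: prosperous regions have higher GDP and government
spending, less urbanised ones more rural health staff per capita), with
effects β = (0.10, 0.07, 0.06, 0.08, −0.09, −0.12) for LED, HNL, DIN, GOV,
HHC, URB. These sizes were chosen so that the designed properties hold
with margin: regional mean gaps are large against region-mean noise (the
East > Central > West ordering holds every year), median-quantile t
statistics on 232 observations are ≳ 4 (signs recover reliably), and
year-to-year jitter is small against the cross-sectional spread (units
mostly keep their quartile state, so transition matrices are diagonally
dominant).

Indicators are affine maps of the latent factor plus positive half-normal
noise — correlated but not collinear, which is what makes CRITIC's
conflict term meaningful. DEA inputs are a Cobb–Douglas bundle (unit size
× input-mix noise); outputs are the CRS frontier of those inputs times a
true efficiency multiplier in (0, 1.2], a fixed monotone map of the unit's
mean latent level (overridable per unit for frontier-recovery tests).
Covariates are written on realistic scales (lognormal GDP etc.) such that
the default log-z transform recovers the underlying z. The blocks
adjacency scheme makes regions internally dense with sparse bridges;
combined with spatial mixing this produces strongly positive Moran's I.

What the generator does **not** emulate: the marginal distributions of
real yearbook variables, serial correlation in the noise, measurement
error, policy shocks (e.g. pandemic-style dips), or China's actual
contiguity graph. Passing tests therefore demonstrate that the methods
recover known structure of the assumed form, not that any substantive
finding about real provinces is reproduced.

## Problem sizes and runtime choices

The default panel (29 × 8) needs 232 SBM LPs plus super-efficiency
re-scores per pipeline run (~1 s) and a full run with 200 bootstrap
replicates per quantile completes in well under a minute. The acceptance
tests use 200 generator seeds for driver-sign recovery, 1000 null
replicates with 199 permutations each for the Moran type-I rate, and 100
random grouped vectors for the decomposition identity.

## Known limitations

* Fixed-effects or penalised quantile estimators are out of scope; the
  pooled stack conflates within- and between-unit variation.
* Super-efficiency VRS infeasibility is handled by a flagged fallback, not
  by the two-stage modifications proposed in the DEA literature.
* The Dagum decomposition requires strictly positive group means; D values
  of exactly zero in a whole region would need a different inequality
  index.
* Moran's I uses binary contiguity only; distance- or flow-based weights
  are not implemented.
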