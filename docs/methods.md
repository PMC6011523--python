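# Methods

This note documents the models implemented in `seascapes`, their
assumptions, the numerical choices behind them, and what the synthetic
data generator does and does not emulate.

## Activity model: 2-state HMM on ODBA

**Observation model.** One-second ODBA values are strictly positive,
right-skewed, and punctuated by activity bursts; each behavioural state
carries a gamma density parameterized by (shape, rate). States are
labelled so that state 1 has the smaller mean ODBA ("relatively low
activity"); this convention breaks the label-swap symmetry of the
likelihood deterministically after fitting. Zero ODBA values (possible
after block averaging of quantized sensors) are outside the gamma
support; `fit_hmm` replaces them with half the smallest positive
observation and reports the count.

**State process.** The hidden chain has two states and covariate-driven
transition probabilities: each off-diagonal entry is logit-linear in an
intercept, `harmonic_order` sin/cos pairs of hour-of-day (default 2;
the pipeline's generating model uses 1), and dummies for the tidal
phases {high, ebb, low, flood} with "high" as reference. The transition
matrix applied on the step from t−1 into t is evaluated at the
covariates of the destination time t; the simulator, likelihood,
decoder, and all test oracles share this convention (the alternative —
origin-time covariates — is equally defensible; what matters is
internal consistency).

**Fitting.** The exact likelihood is computed by the scaled forward
recursion (per-observation log-density rows are rescaled by their
maximum so the recursion never underflows at plausible parameters; a
hard underflow returns −∞ and the optimizer moves away). Working
parameters are log shape/rate and unconstrained transition
coefficients; the initial distribution is not free but set to the
stationary distribution of the first transition matrix, so the AIC
parameter count is k = 4 + 2p. Optimisation is L-BFGS-B from
`n_restarts` seeded random starts (moment-based density starts from a
median split, switching-probability intercepts drawn in [0.02, 0.3]);
the best restart wins and the same data + seed reproduce the fit
bit-for-bit. The parameter covariance is the inverse of a
central-difference Hessian of the negative log-likelihood. The forward,
forward–backward, Viterbi and chain-simulation inner loops are
numba-compiled with a no-op fallback decorator.

**Diel activity curve.** With time-varying transitions the chain has no
single stationary distribution; we use the periodically stationary
distribution: discretize the cycle at 10-min resolution, hold tide
fixed, form the one-cycle product of transition matrices, take its
stationary vector, and propagate it around the cycle. A homogeneous
model collapses to the ordinary stationary distribution (flat curve).
95 % CIs come from `n_boot` (default 1000) draws from the asymptotic
normal on working parameters (covariance eigenvalue-clipped at zero),
re-deriving the curve per draw and taking percentile bands. The
curve is evaluated at bin midpoints and interpolated cyclically.

**Decoding and summaries.** Global decoding by Viterbi; local state
probabilities by forward–backward (both returned, since bout-length
summaries want the global path while the seascape wants probabilities).
Dwell times are mean lengths of maximal runs; a state that never occurs
reports its mean as absent rather than zero.

## Accelerometry

Gravity is separated with a centred box-car moving average per axis,
default 3 s — long relative to shark tail-beat periods (~0.5–1 s),
short relative to postural change; the window is configurable because
the optimal length is species-dependent. At the edges the window
shrinks (`min_periods=1`) rather than padding, so no fabricated samples
enter and static + dynamic reconstructs the input exactly. ODBA is the
sum of absolute dynamic accelerations; block averaging to 1 s drops a
trailing partial block; the first 4 h are trimmed by default
(post-tagging stress).

## Movement model

**Motion variance.** σ_m² is estimated by leave-one-out maximum
likelihood: every odd-indexed detection is predicted by the bridge
joining its two neighbours. The residual variance used in this
likelihood is the bridge variance *plus the held-out detection's own
location error* (α(1−α)Tσ_m² + ((1−α)²+α²+1)σ_loc²): omitting the last
term biases σ̂_m² upward by σ_loc²/(α(1−α)T), which at telemetry scales
dominates the signal. The mapping (density) variance remains the
two-term bridge formula. Optimisation is bounded scalar minimisation;
coincident detections push the estimate to the zero boundary.

**Voxel deposition.** For each detection pair with 0 < gap ≤ `max_gap`
(default 12 h — bridges across longer absences are uninformative), the
bridge Gaussian is evaluated at the midpoint of its overlap with every
10-min absolute time bin, weighted by the overlap duration, truncated
at ±5σ, and integrated over cells exactly (per-axis normal-CDF
differences, outer product). Absolute bins fold modulo 24 h, so months
of data stack onto one diel cycle and shifting all timestamps by 24 h
leaves the volume unchanged. Normalization is over the whole volume —
one probability distribution over space × time-of-day, so bins with
more bridge occupancy carry more mass; per-slice normalization is
available as an option since either convention is defensible.

**Contours.** The p % contour is the greedy smallest cell set by
descending mass (stable flat-index tie-break), which is exactly the
minimal-cardinality set for any level.

## Seascape analyses

Displacement scores a detection 0 inside the central-place region and
the Euclidean distance to the region boundary outside (boundary, not
centroid, matching the reading of displacement *from* a place; the
inside-zero convention is a choice — distances within the core are not
meaningful displacement). The 80 %-receiver rule is inclusive at
exactly 0.80 and ties break lexicographically by receiver id; both are
logged on the resulting object. Group volumes are unweighted individual
means renormalized to mass 1 (robust to unequal detection counts).
Fusion multiplies each voxel by the activity probability of its time
bin with **no renormalization** — the seascape is bounded by the UD
voxelwise, and the within-bin seascape/UD ratio is constant.

## Bioenergetics

The length–mass allometry W = 0.0045 L^3.21 is evaluated in grams and
reported in kg, the standard length–weight convention; read in raw kg
the formula would give a 37-tonne 143-cm shark, irreconcilable with the
38.3-kg population average it is meant to reproduce. Metabolic rate
units follow the source allometry (mg O₂ h⁻¹). Speed scaling applies to
the full routine metabolic rate (an "active-component-only" variant is
a matter of bookkeeping and can be emulated via `min_fraction`); the
multiplier is floored at 0.5 so near-zero speeds cannot produce
non-physical rates. The diel temperature amplitude is a scenario
parameter, not a constant, because reported values for the source
system span roughly 0.3–0.5 °C peak-to-trough. With Q10 = 3 a 0.5 °C
peak-to-trough cycle moves the rate by ±2.8 % about the mean
(3^±0.025), while a 7 % speed swing moves it by 7 % peak-to-trough —
the speed-dominance conclusion is robust across Q10 ∈ [1, 3] and both
range conventions.

## Diel profiles with AR(1) errors

Hourly sensor series are regressed on a harmonic basis (K sin/cos
pairs, default 2), cyclic with period 24 h by construction, with AR(1)
Gaussian errors estimated by full joint maximum likelihood: the exact
AR(1) likelihood is concentrated over coefficients and innovation
variance via the Prais–Winsten transform and maximised over ρ by
bounded scalar optimisation. A harmonic basis replaces penalized cyclic
splines deliberately: it is fully specified, dependency-light, exactly
periodic, and adequate for single-peaked diel patterns; K is the
resolution knob. Model support requires ΔAIC = AIC_null − AIC_fit
strictly greater than 3 against the intercept-only (same-error) null.
AIC counts coefficients + ρ + σ². A noiseless harmonic is interpolated
exactly; the σ² floor of 1e−300 only guards the log in that degenerate
case.

## Synthetic data: what it does and does not emulate

The generator reproduces the *statistical structure* the pipeline
assumes: mean-reverting daytime residence within `day_radius` of the
central place (OU walk, relaxation time 600 s, step scale set by
`speed_mean`, deviation hard-capped at `day_radius`); nightly
excursions to `night_excursion_dist` along a fresh random heading per
night with a trapezoidal out/plateau/back profile (ramps over the first
and last quarter of the excursion window); hard-cutoff detection by the
nearest in-range receiver with optional binomial thinning; HMM-driven
ODBA; sinusoid-plus-noise sensor channels; and a four-phase tide on the
12.42-h M2 period. Defaults (3-km excursions, 0.6 m/s mean speed,
300-m detection range, 19:00–05:00 excursion window) mirror the study
conditions.

It does **not** emulate: habitat-dependent detection ranges or diel
acoustic noise (real arrays detect worse at night), depth-resolved
movement, tidal currents or tide-height realism, individual
heterogeneity, or autocorrelated sensor noise beyond the HMM state
process. Passing tests therefore certify the estimators and the
pipeline plumbing under the assumed data-generating process, not
robustness to these field complications.

The pipeline's demonstration accelerometer record synthesises 20-Hz
tri-axial data whose per-second expected ODBA equals an HMM-simulated
target (sinusoidal dynamic components at tail-beat-scale frequencies,
gravity on z), so the accel → HMM chain is exercised end to end; the
block-averaged ODBA is then only approximately gamma, which is why the
pipeline's density-recovery diagnostic is looser than the direct
simulation-recovery tolerance.

## Problem sizes and determinism

Default analysis sizes: 30-day tracks at 60-s steps, 120-s ping
interval on a 15 × 15 receiver grid, 14 h of 1-s ODBA (36 000
observations after the 4-h trim) for the pipeline fit, 50 000
observations and 3 restarts for simulation-recovery checks, 10⁶ steps
for the activity-curve Monte Carlo, 10⁵ samples for the bridge-moment
Monte Carlo. Every stochastic routine takes an explicit seed and
derives all randomness from it; reruns are numerically identical.
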