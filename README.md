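# seascapes

**Activity seascapes for central-place-foraging marine predators.**

Many reef predators — blacktip and grey reef sharks are the motivating
case — behave like central place foragers: they rest-by-swimming in a
small daytime core area and range over a much larger area at night. But
their space use (months-to-years of acoustic telemetry detections) and
their activity (days of high-resolution accelerometry) are measured on
different time scales and usually on different individuals. `seascapes`
implements a pipeline that fuses the two into a single diel space–time
picture, the *activity seascape*, and adds the companion analyses:
central-place definition, diel displacement, and a simple ectotherm
bioenergetics model that weighs swim speed against body temperature as
drivers of the daily energy budget.

## What it computes

**Activity HMM.** Raw tri-axial acceleration (20 Hz) is gravity-filtered
(centred moving average per axis), converted to overall dynamic body
acceleration ODBA = |dx| + |dy| + |dz|, averaged to 1 s, and trimmed of
the first 4 h (post-tagging stress). A 2-state hidden Markov model with
gamma state densities is fit by direct numerical maximum likelihood:
state 1 = relatively low activity, state 2 = relatively high activity.
The two off-diagonal transition probabilities are logit-linear in
hour-of-day harmonics and tidal-phase dummies:

    γ12(t) = logit⁻¹(η12ᵀ x_t),   γ21(t) = logit⁻¹(η21ᵀ x_t)

The diel activity curve P(state 2 | hour, tide) is the periodically
stationary distribution of the one-cycle product of transition matrices
at 10-min resolution, with 95 % CIs from a parametric bootstrap on the
asymptotic parameter distribution.

**Space–time UD.** Consecutive acoustic detections (located at receiver
coordinates) are linked by Brownian bridges with location error
σ_loc = 300 m (average receiver detection range) and motion variance
σ_m² estimated by leave-one-out maximum likelihood. At time fraction α
between detections a and b the bridge is Gaussian per axis:

    mean = (1−α) z_a + α z_b
    var  = α(1−α) T σ_m² + ((1−α)² + α²) σ_loc²

Bridge mass is folded modulo 24 h into a voxel grid (100 m × 100 m ×
10 min) and normalized to total probability 1.

**Fusion.** The activity seascape multiplies each voxel by the activity
probability of its time bin: `seascape(x, y, τ) = UD(x, y, τ) ·
P(state 2 | τ)`. Central places are the 50 % contour of the planar UD,
or the receiver holding ≥ 80 % of detections plus a 1000-m buffer;
displacement is the hourly mean distance to the central-place boundary.
Individuals with fewer than 100 detections are excluded.

**Bioenergetics.** For a shark of total length L (cm): mass
W = 0.0045 L^3.21 (g), routine metabolic rate
log₁₀M = 0.79 log₁₀W + 2.31 (mg O₂ h⁻¹, W in kg), temperature-corrected
by Q10^((T_b−T_ref)/10) with Q10 ∈ {1.65, 3.0} and T_ref = 28 °C, and
speed-scaled 1 % per 1 % deviation from the mean (optimal travel)
speed. Hourly scenario profiles are compared with a paired t-test.

A `dielprofiles` module fits cyclic harmonic regressions with AR(1)
errors (joint ML) to hourly sensor series, judging diel structure by
ΔAIC > 3 against an intercept-only null. A `synthetic` module generates
everything the pipeline consumes — CPF tracks, range-limited
detections, HMM-driven ODBA, sinusoidal sensor channels, tidal phases —
so every stage is testable without field data.

## Worked example

```python
import numpy as np
from seascapes import energetics as en, hmm, movement as mv, seascape as sc, synthetic as syn

# 1. central-place forager + receiver array + detections
track = syn.simulate_cpf_track(syn.CPFParams(night_excursion_dist=3000.0, seed=0), 30)
receivers = syn.make_receiver_grid(spacing=500.0, extent=3500.0, detection_range=300.0)
det = syn.simulate_detections(track, receivers, ping_interval=120.0, seed=1)

# 2. space-time Brownian-bridge UD and 50 % central place
grid = mv.VoxelGrid.from_extent(-4000, 4000, -4000, 4000)
sigma_m2 = mv.estimate_motion_variance(det, sigma_loc=300.0)
volume = mv.spacetime_ud(det, grid, mv.BridgeParams(300.0, sigma_m2, 12 * 3600))
place = sc.central_place_udcontour(mv.planar_ud(volume))

# 3. night-active 2-state HMM, fit + diel activity curve
design = hmm.CovariateDesign(harmonic_order=1, tidal_levels=())
spec = hmm.HMMSpec(
    hmm.StateDensities(np.array([2.0, 3.0]), np.array([40.0, 15.0])),
    hmm.TransitionModel(np.array([-2.2, 0.3, 1.0]), np.array([-1.2, -0.3, -0.8])),
    design,
)
t = np.arange(50_000.0)
series, _ = syn.simulate_odba_hmm(spec, (t / 3600) % 24, seed=2, timestamps=t)
fit = hmm.fit_hmm(series.odba, (t / 3600) % 24, design=design, n_restarts=3, seed=0)
curve = hmm.activity_curve(fit, seed=0)

# 4. fuse and summarize
seascape = sc.fuse_activity(volume, curve)
disp = sc.displacement_series(det, place)
```

Output of the full script (see also `seascapes run-all`):

```
detections: 21120
sigma_m^2 = 6.27e-06 m^2/s, central place = 50 cells
P(state 2): min 0.09 (hour 13), max 0.68 (hour 2)
daytime seascape mass inside central place: 82 %
displacement 02:00 = 2.5 km, 12:00 = 0.0 km
shark: 38.2 kg, RMR 3626 mg O2/h; observed vs static temperature: t = 0.165, p = 0.87
```

Reading it: the simulated shark's movement probability by day is
overwhelmingly (82 %) inside its 50 % UD central place; activity peaks
at 02:00 when it is ~2.5 km out on nocturnal excursions; and for a
38-kg shark the realistic ±0.25 °C diel body-temperature cycle is
energetically negligible (paired t ≈ 0.17) next to the diel swim-speed
cycle.

## Command line

`seascapes` exposes the stages as subcommands: `simulate`, `odba`,
`fit-hmm`, `ud`, `seascape`, `displacement`, `energetics`, and
`run-all` (YAML-configured end-to-end run writing the full artifact
bundle: ODBA CSV, HMM fit JSON, activity-curve CSV, UD and seascape
netCDF volumes, displacement CSV, energetics report, provenance JSON).

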