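# Methods

## Model and assumptions

The pipeline treats a dilute liposome suspension as a two-component medium:
a solvent with measured density ρ₀(T) and sound velocity u₀(T), plus a small
mass fraction of lipid at concentration c. In this dilute limit the excess
sound velocity and excess density are linear in c, so the concentration
increment [u] = (u − u₀)/(u₀·c) and the apparent specific partial volume
φ_v = [1 − (ρ − ρ₀)/c]/ρ₀ are intensive properties of the vesicles. The
specific adiabatic compressibility φ_k/β₀ = −2[u] − 1/ρ₀ + 2φ_v compares
the solute's volume compressibility with the solvent's; the lipid
compressibility β_lipid = β₀·(2 − [u]/φ_v) and its reciprocal, the bulk
modulus K_lipid, summarise membrane elasticity without any contact-mechanics
model. Key assumptions: dilute, non-interacting vesicles; adiabatic
(ultrasonic) rather than isothermal compressibility; solvent and suspension
scanned under identical thermal protocol.

The solvent compressibility β₀ is always computed from the measured solvent
scan, never from literature water tables, so buffer composition is handled
automatically.

### The β_lipid equation and its alternative

Two readings of the lipid-compressibility relation circulate, differing in
whether the factor applied to β₀ is (2 − [u]/φ_v) or (φ_k/β₀)/φ_v. The
default here is β_lipid = β₀·(2 − [u]/φ_v), which yields bulk moduli near
1.1–1.2 GPa in the dilute-vesicle regime (the magnitude reported for
model-membrane work); the alternative, selectable as
`parse="phik_over_phiv"`, yields roughly half the compressibility scale.
Every derived output records which parse produced it in its metadata, so
results are never silently mixed.

## Units

Inputs follow instrument conventions: ρ in g·cm⁻³, u in m·s⁻¹, c in
mg·mL⁻¹. Internally ρ is converted to kg·m⁻³ wherever a Pa⁻¹
compressibility is formed, and c to g·mL⁻¹ so that [u], φ_v and φ_k/β₀
come out in mL·g⁻¹. The conversions are recorded in the derivation
metadata.

## Uncertainty propagation

`InstrumentPrecision` holds the 1-σ repeatability of one reading
(defaults: 10⁻⁵ g·cm⁻³, 0.01 m·s⁻¹, 0.01 °C). `derive_scan` propagates
them by a first-order delta method treating the four readings
(u, u₀, ρ, ρ₀) as independent; the Jacobian of the full chain is evaluated
by central differences at a relative step of 10⁻⁷, which is exact to
first order for these smooth formulas. The temperature repeatability
enters through the local slope of the interpolated solvent baselines
(du₀/dT ≈ 2–3 m·s⁻¹·K⁻¹ near room temperature, which in fact dominates
the effective u₀ uncertainty). Propagated σ therefore scale exactly
linearly in the instrument σ. No error correlation between solvent and
suspension runs is modelled; temperatures of the suspension readings are
taken as exact.

Non-physical derived points (β_lipid ≤ 0, possible for noisy edge points)
are flagged in a `nonphysical` column and warned about, never raised, so a
single bad point cannot abort a scan.

## Solvent/suspension pairing

Solvent values are linearly interpolated onto suspension temperatures.
Suspension temperatures outside the solvent range by more than the
pairing tolerance (default 0.05 °C) raise an error listing the offending
rows; within the tolerance the query is clamped to the range boundary
(refusing extrapolation).

## Transition-dip detection

The chain-melting transition appears as a dip in [u](T). The detector
(1) smooths by local quadratic least squares over an odd point window
(default 5; valid for non-uniform temperature grids, reducing to
Savitzky–Golay on uniform ones), (2) finds interior local minima of the
smoothed curve, (3) measures each minimum's depth against the straight
line joining its flanking smoothed maxima (or series endpoints) and keeps
those exceeding `min_depth_sigma` (default 3) times the median point σ,
and (4) reports the vertex of a least-squares parabola fit to the smoothed
window around the minimum — exact for a locally quadratic dip. When
several minima qualify, the deepest is reported and all candidates are
returned. Detection is invariant under value offsets and under joint
rescaling of values and sigmas. A rising baseline biases the located
minimum of a symmetric (Gaussian) dip slightly downslope — about
slope·width²/depth, ≈0.15 °C at the default synthetic settings — which is
a property of the composite curve, not an estimator defect.

`monotone_trend` reports the majority direction of consecutive
differences and the fraction of pairs concordant with it (invariant under
series reversal; for i.i.d. noise its expectation sits slightly above 0.5
by order n^(−1/2) because the direction is itself estimated). No p-value
is attached.

## Group statistics

Welch's unequal-variance t = (m₁ − m₂)/√(v₁/N₁ + v₂/N₂) with
Welch–Satterthwaite degrees of freedom, used fractionally (unrounded) in
Student's t distribution for two-tailed p-values. Confidence intervals
follow the reporting convention mean ± c·S/√N with c the standard-normal
0.975 quantile (1.96 to the printed precision) regardless of N — a
deliberate fidelity choice to the field's reporting convention; a t-based
interval is available via `use_t=True`. No multiple-testing correction is
applied anywhere, matching common practice in this literature; callers
making many comparisons should correct externally.

## Morphology

Roundness is 4·area/(π·major_axis²), with "major axis" the full axis
length so that a circle scores exactly 1 and an ellipse scores its
minor/major semi-axis ratio. Mask inputs are measured with second-moment
equivalent-ellipse axes (scikit-image regionprops) at a user-supplied
pixel size; because moment-based axes can undershoot the true extent by a
fraction of a pixel, the bounding-circle invariant is checked with a 2%
relative tolerance for mask-derived records and the area is capped at the
bounding circle, keeping roundness ≤ 1. Rasterisation error at a 50 px
radius is below 0.01 and decreases with resolution.

DLS number→intensity conversion uses the pure Rayleigh d⁶ weighting
(weights ∝ w·d⁶, renormalised). For vesicles of 100–500 nm this is an
approximation — Mie corrections are not applied — and is flagged as such;
converting an already intensity-weighted distribution is an error rather
than a silent double-weighting.

## Synthetic data generator

The generator inverts the derivation chain: given prescribed [u](T) and
φ_v(T), it emits u(T) = u₀(T)·(1 + [u]·c′) and
ρ(T) = ρ₀(T) + c′·(1 − φ_v·ρ₀(T)), then adds independent Gaussian noise at
the instrument repeatability to each emitted reading. Ground truth is
recorded noise-free and is internally consistent with the chain under the
configured β_lipid parse, making `derive_scan ∘ generate_scans` the
identity on ground truth in the noise-free limit (verified to ≲10⁻¹¹
relative; the floor is the u − u₀ cancellation in float64, which is why
the default [u] baseline stays bounded away from zero except at the
transition itself).

Default conditions (chosen once as a realistic regime, then frozen):
10–45 °C in 1 °C steps; c = 2 mg·mL⁻¹; solvent baselines are quadratics
fit to handbook water ρ/u at 10/25/37 °C; [u] baseline 0.038 mL·g⁻¹ at
25 °C rising 0.001 mL·g⁻¹·K⁻¹; a negative Gaussian dip at Tm = 22.5 °C of
depth 0.065 mL·g⁻¹ and width 2 °C (a muted, cholesterol-broadened
transition; [u] transiently crosses zero at the dip, as real vesicle
scans do); φ_v = 1.018 mL·g⁻¹ at 25 °C with slope 4×10⁻⁴. These place the
derived φ_k/β₀(37 °C) near 0.94 mL·g⁻¹ and K_lipid near 1.18 GPa, the
windows expected for multi-component cholesterol-containing membranes.
Particle ensembles draw roundness from a Beta distribution with
configurable mean (default 0.83) and concentration 40, and lognormal
major axes (mean diameter 104 nm, shape 0.45, matching TEM-scale
dispersion at n = 220). DLS diameters are lognormal (median 100 nm, shape
0.25); the ground-truth intensity-weighted mean uses the exact lognormal
moment ratio E[d⁷]/E[d⁶] = exp(μ + 6.5σ²). Zeta-potential fixtures are
plain Gaussian replicate groups (default −55 ± 8 mV, n = 12); no
electrokinetic physics is simulated.

What the generator does *not* emulate: thermal drift or autocorrelated
instrument noise (the instrument is Peltier-stabilised), scattering
artifacts in DLS, multimodal size distributions, staining artifacts or
touching particles in TEM, and concentration errors. Passing round-trip
tests therefore demonstrates correctness of the analysis chain and its
error model, not robustness to every real-world artifact.

All generation is deterministic per seed, and CSV emission is
byte-identical across runs (floats are written with round-trip precision
and read back with round-trip parsing).

## Problem sizes

The test-suite and acceptance-script simulation sizes — 100 seeds for
noisy round-trip recovery, 200 replicates for dip localization, 10,000
null replicates (n = 12 per group) for the empirical type-I error, 60
replicates of 4,000 lognormal diameters for the Rayleigh check, 1,000
random summaries for the Welch oracles — were chosen so each Monte-Carlo
standard error sits well below the property's acceptance margin while the
whole suite runs in seconds.

## Known limitations

- The dilute-limit formulas ignore vesicle–vesicle interactions; do not
  use above ~10 mg·mL⁻¹.
- The delta-method σ are first-order; near the non-physical boundary
  ([u]/φ_v → 2) they understate the true spread.
- Dip localization assumes a single dominant transition inside the scanned
  range; overlapping transitions return multiple candidates but only the
  deepest as T_min.
- The normal-critical-value CI undercovers slightly at small N (by design,
  matching the reporting convention); use `use_t=True` for calibrated
  coverage.
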