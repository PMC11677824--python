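# liposonics

Molecular acoustics of liposome suspensions: derive the mechanical
properties of lipid vesicle membranes — specific adiabatic compressibility
and bulk elastic modulus — from non-invasive density and ultrasound-velocity
temperature scans, together with transition-dip detection, Welch group
statistics, and vesicle morphology analysis (TEM roundness, Rayleigh-weighted
DLS size distributions).

## Who this is for

Membrane biophysicists and physical chemists characterising model membranes
(e.g. multi-component grey-matter-mimicking vesicles with phosphatidylcholines,
sphingomyelin, phosphatidylserine, cholesterol and ω-3 polyunsaturated
lipids) with a vibrating-tube densimeter / sound-velocity analyser, DLS /
zeta-potential instrumentation and TEM.

## The derivation chain

Given a solvent scan (ρ₀, u₀)(T) and a dilute suspension scan (ρ, u)(T) at
lipid concentration c (mg·mL⁻¹, converted internally to g·mL⁻¹):

- adiabatic compressibility β = 1/(u²ρ) (Pa⁻¹, ρ in SI units),
- sound-velocity concentration increment [u] = (u − u₀)/(u₀·c) (mL·g⁻¹),
- apparent specific partial volume φ_v = [1 − (ρ − ρ₀)/c]·(1/ρ₀) (mL·g⁻¹),
- specific adiabatic compressibility φ_k/β₀ = −2[u] − 1/ρ₀ + 2φ_v (mL·g⁻¹),
- lipid compressibility β_lipid = β₀·(2 − [u]/φ_v) (Pa⁻¹; an alternative
  reading β_lipid = β₀·(φ_k/β₀)/φ_v is selectable and recorded in output
  metadata),
- bulk elastic modulus K_lipid = 1/β_lipid (Pa).

Instrument repeatability (σ_ρ = 10⁻⁵ g·cm⁻³, σ_u = 0.01 m·s⁻¹,
σ_T = 0.01 °C by default) is propagated to every derived quantity by
first-order delta-method propagation. The gel/fluid transition shows as a
dip in [u](T); `detect_dip` locates it by local quadratic smoothing and
parabolic vertex interpolation. Group comparisons use Welch's
unequal-variance t-test with Welch–Satterthwaite fractional degrees of
freedom; intervals are reported as mean ± 1.96·S/√N.

A fully deterministic synthetic-data generator (`liposonics.synthetic`)
inverts the chain to emit paired scans, particle ensembles and DLS
distributions with recorded ground truth, so every stage is testable
without instrument data.

## Worked example

```python
import liposonics as lp

scan, truth = lp.generate_scans(lp.SyntheticConfig(seed=1))
derived = lp.derive_scan(scan)
row = derived.table.query("temperature_C == 37").iloc[0]
print(f"phi_k/beta0(37 C) = {row.phi_k_over_beta0_mL_per_g:.4f} "
      f"+/- {row.sigma_phi_k_over_beta0_mL_per_g:.4f} mL/g")
print(f"K_lipid(37 C)     = {row.K_lipid_Pa/1e9:.4f} +/- {row.sigma_K_lipid_Pa/1e9:.4f} GPa")

series = lp.ThermalSeries(
    derived.table["temperature_C"].to_numpy(),
    derived.table["u_increment_mL_per_g"].to_numpy(),
    derived.table["sigma_u_increment_mL_per_g"].to_numpy())
dip = lp.detect_dip(series)
print(f"dip found: {dip.dip_found}, T_min = {dip.T_min:.2f} C (true Tm = {truth.Tm} C)")

a = lp.GroupSummary.from_sample(lp.generate_zeta(lp.SyntheticConfig(seed=2, zeta_mean=-59.5)))
b = lp.GroupSummary.from_sample(lp.generate_zeta(lp.SyntheticConfig(seed=3, zeta_mean=-46.4)))
res = lp.compare(a, b)
print(f"Welch t = {res.t:.3f}, df = {res.df:.2f}, p = {res.p_two_tailed:.3e}")
```

prints

```
phi_k/beta0(37 C) = 0.9416 +/- 0.0209 mL/g
K_lipid(37 C)     = 1.1787 +/- 0.0044 GPa
dip found: True, T_min = 22.65 C (true Tm = 22.5 C)
Welch t = -2.677, df = 19.56, p = 1.467e-02
```

The specific compressibility near 0.94 mL·g⁻¹ and bulk modulus near
1.18 GPa are the expected regime for cholesterol-containing vesicle
membranes at physiological temperature; the dip at ≈22.5 °C is the
(cholesterol-muted) chain-melting transition of the simulated membrane;
the Welch comparison shows the two zeta-potential groups differ at α = 0.05.

## Command line

```
liposonics simulate  --seed 3 --outdir sim/          # synthetic dataset + ground truth
liposonics derive    --solvent sim/solvent.csv --suspension sim/suspension.csv \
                     --out derived.csv --meta derived.json
liposonics transition --input derived.csv             # dip report JSON
liposonics compare   groupA.csv groupB.csv            # Welch comparison JSON
liposonics morphology --particles sim/particles.csv --dls sim/dls.csv \
                     --to-intensity --outdir morph/
liposonics report    --seed 2 --out report.json       # three-condition summary table
```

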