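# ocutherm

Thermo-viscoelastic simulation of the human cornea under ultrasonic loading.

`ocutherm` is aimed at researchers in ocular biomechanics and ultrasound
elastography who want a transparent, fully scripted model of (i) how the
cornea deforms when pushed by a constant or transient acoustic load, and
(ii) how much the eye heats up while being pushed. It combines three
self-contained physics stages behind one configuration and CLI layer:

1. **Lumped viscoelastic creep models** (`ocutherm.visco`). The cornea is a
   single viscoelastic element with elastic modulus *E* and viscosity *η*
   (retardation time τ_R = η/E). The driving stress is the resultant of the
   applied load, the tear-film pressure and the intra-ocular pressure,
   σ_res = σ_applied + P_tear − IOP. Step (creep) responses:

   - Kelvin–Voigt: ε(t) = σ₀/E · (1 − e^(−t/τ_R)) — creeps monotonically to
     σ₀/E and never recovers;
   - standard linear solid (product form): ε(t) = σ₀/E · (1 − e^(−t/τ_R)) ·
     e^(−t/τ_R) — peaks at σ₀/(4E) when t = τ_R ln 2 and recovers fully;
   - Maxwell: J(t) = 1/E + t/η, kept only as the baseline with unbounded
     ("indefinite") creep.

   Arbitrary load histories (e.g. a truncated sinusoidal burst) are handled
   by Boltzmann superposition over the creep kernel, ε(t) = ∫ J(t−s) dσ(s),
   with a direct ODE integration of σ = Eε + η ε̇ available as a
   Kelvin–Voigt cross-check. Strain is dimensionless; the conventional
   "deformation reading" reports it as millimetres (ε × 1000).

2. **Transducer pressure fields** (`ocutherm.acoustic`). On-axis
   Rayleigh–Sommerfeld closed forms for a flat circular piston,
   p(z) = ρcv₀ (e^{ikz} − e^{ik√(z²+a²)}), and for a spherically focused
   cap, p(z) = ρcv₀/(1 − z/R₀) · (e^{ikz} − e^{ik r_e}) with
   r_e = √((z−h)² + a²), the focal singularity evaluated by its analytic
   limit |p(R₀)| = k·h·ρcv₀. Off-axis fields come from direct numerical
   quadrature of the Rayleigh surface integral over the spherical cap.

3. **Pennes bioheat solver** (`ocutherm.bioheat`). Finite-volume solution of
   ρ_t C_t ∂T/∂t = ∇·(k∇T) + W_b C_pb (T_a − T) + Q_m + H on a layered
   axial eye model (saline standoff, cornea, aqueous, lens, vitreous) and on
   an axisymmetric (r, z) grid, with a convective + radiative anterior
   boundary −k ∂T/∂z = h_c (T − T_amb) + εσ_SB (T⁴ − T_amb⁴). The heat
   source is absorbed acoustic power, H = duty · α p²/(ρc), and a
   calibration utility pins the simulated peak temperature rise to a target
   so profile shapes and ratios can be compared across assumptions.

## Worked example

Run the standard-linear-solid constant-load scenario (800 Pa applied load,
550 Pa tear film, 2050 Pa IOP ⇒ |σ_res| = 700 Pa; E = 150 kPa,
η = 100 Pa·s):

```text
$ ocutherm run sls-constant --out out
sls-constant: metrics written to out/sls-constant-report.json
  peak_deformation_mm = 1.1666666413904765
  t_peak_s = 0.00046199999999999995
  t_settle_99_s = None
  resultant_peak_pa = 700.0
  resultant_sign = -1.0
```

The peak reading 1.167 mm is σ₀/(4E) = 700/(4·150 000) interpreted as a
millimetre deformation, reached at t = τ_R ln 2 ≈ 0.462 ms; the settle time
is undefined because the response is unimodal (the tissue recovers). The
resultant sign −1 records that Eq.-level bookkeeping gives −700 Pa and the
creep kernels are driven by its magnitude.

The calibrated axial temperature-rise scenario:

```text
$ ocutherm thermal axial --out out
thermal-axial: metrics written to out/thermal-axial-report.json
  peak_delta_T_C = 0.8999424081251135
  z_peak_m = 0.0004
  corneal_delta_T_C = 0.04317182661309005
  z_cornea_m = 0.028
  rate_pre_cornea_per_m = 111.25547281574542
  rate_post_cornea_per_m = 149.7473994578843
  v0_scale_factor = 6.155311471893133
```

After calibrating the surface velocity so the peak ΔT is 0.9 °C, the rise is
maximal 0.4 mm from the transducer face, decays with a slow rate through the
saline standoff (111 m⁻¹) and a faster rate beyond the cornea (150 m⁻¹),
and the corneal-surface value (0.043 °C here) depends strongly on the
assumed absorption profile — the per-key provenance block in the JSON report
marks exactly which inputs are assumptions.

Every preset (`kv-constant`, `sls-constant`, `kv-burst`, `sls-burst`,
`sweep-modulus`, `field-axial`, `field-map`, `thermal-axial`,
`thermal-map`) writes full-precision CSV traces/maps plus a JSON report, and
reruns are byte-identical for a given configuration. `ocutherm show-config
<preset>` prints the editable YAML configuration.

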