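# Methods

This note records the models implemented in `ocutherm`, the assumptions
behind them, the numerical schemes, and the design decisions taken where
the underlying study left the formulation open. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Viscoelastic stage

### Model

The cornea is reduced to one lumped viscoelastic element. Three creep
kernels J(t) (strain per unit step stress) are provided:

| kernel | J(t) | behaviour |
|---|---|---|
| Kelvin–Voigt | (1 − e^(−t/τ_R))/E | monotone creep to 1/E, no recovery |
| standard linear solid (product form) | (1 − e^(−t/τ_R)) e^(−t/τ_R)/E | unimodal: peak 1/(4E) at τ_R ln 2, full recovery |
| Maxwell | 1/E + t/η | unbounded creep; baseline only |

τ_R = η/E is the retardation time. The product-form SLS kernel is
implemented exactly as the source formulation prints it. It is *not* the
classical three-element SLS compliance ε = σ₀[1/E₁ + (1 − e^(−t/τ))/E₂]
(the extra series spring of the classical model has no separate modulus in
the printed form; a single E appears). We implement the printed product
verbatim because the headline numbers — peak σ₀/(4E) at τ_R ln 2 — follow
from it and from nothing else.

**Units of strain.** The source text calls ε a length in mm while its
formulas produce dimensionless values three orders of magnitude smaller
than the quoted deformations. We resolve this by keeping ε dimensionless
and defining the *deformation reading* as ε interpreted in metres and
reported in mm (×1000). This reconciles σ₀/(4E) = 1.167e−3 with the quoted
"about 1.1 mm" exactly.

**Resultant load and its sign.** The driving stress is
σ_res = σ_applied + P_tear − IOP with P_tear = 550 Pa and IOP = 2050 Pa
(the conventional rounded Pa values for 4.15 and 15 mmHg; exact conversion
is available via `PressureEnvironment.from_mmhg`). For the 800 Pa constant
load this gives −700 Pa while the reported deformations are positive, so
the creep kernels are driven by the magnitude and the sign is recorded in
the trace metadata. For time-varying loads the whole resultant signal is
flipped when σ_res evaluated at the peak applied amplitude is negative;
a pointwise absolute value would distort the burst waveform.

**Burst truncation.** The transient scenario asks for 3 cycles at 1 kHz
inside a window of 40% of 5 ms. Three cycles need 3 ms but the window is
2 ms; the window is treated as authoritative and the burst is truncated at
its edge (ending, for these numbers, at a zero crossing after 2 full
cycles). During the remainder of the simulation the static tear-film/IOP
offset continues to act.

### Numerics

* Uniform time grid, default dt = 1 µs (5001 points over 5 ms).
* **Boltzmann superposition** (default, all kernels): discrete hereditary
  sum ε_n = Σ_m J(t_n − t_m) Δσ_m with the t = 0 jump assigned its own
  increment, evaluated as a linear convolution. Step loads are reproduced
  *exactly* (the sum telescopes to σ₀ J(t)); smooth loads converge first
  order in dt (verified by a halving test against a fine ODE reference).
* **ODE mode** (Kelvin–Voigt only): fixed-step RK4 on
  dε/dt = (σ(t) − Eε)/η with mid-step stress taken as the endpoint
  average — exact stage values for constant stress, second order for
  time-varying stress. dt > τ_R is rejected; burst loads additionally
  require dt ≤ 1/(50 f) so the sinusoid is resolved. No governing ODE is
  defined for the product-form SLS kernel, so that combination is rejected
  rather than guessed.
* The 99% settle time of monotone traces is measured against an
  Aitken-extrapolated asymptote of the trace tail (exact for exponential
  approach), so it equals τ_R ln 100 up to one grid step rather than being
  biased by the finite 5 ms horizon.
* The modulus sweep reports peak × E; for step loads the peak is taken
  from the closed form (the grid maximum carries an O((dt/τ_R)²) bias that
  varies across the sweep and would mask the exact 1/E scaling). Under the
  product-form kernel the peak scales exactly as 1/E — the sweep is linear
  in this sense, and the summary records that as a diagnostic rather than
  asserting the source's "non-linear" characterisation.

## Acoustic stage

On-axis closed forms use the physically standard edge-wave path lengths
√(z² + a²) (piston) and √((z−h)² + a²) (focused cap, cap depth
h = R₀ − √(R₀² − a²)). The source prints minus signs under these roots,
which would make the edge term complex over part of the axis; we default to
the "+" form and keep an `as_printed=True` mode (restricted to the domain
where the printed root is real) for auditability.

The focused form has a removable singularity at the geometric focus; for
|1 − z/R₀| < 1e−9 it is replaced by the analytic limit
p(R₀) = −i k h ρcv₀ e^{ikR₀}. Direct evaluation just outside that window is
numerically stable (the phasor difference loses only ~1e−12 relative
precision at |q₀| = 1e−6), so no grid-dodging is needed.

Off-axis fields integrate the Rayleigh integral
p = (−i ρck v₀ / 2π) ∫_S e^{ikd}/d dS over the spherical cap:
Gauss–Legendre in the cap polar angle (`n_quad` nodes, default 96 in the
library, 48 in the preset pipelines) and a uniform azimuthal grid
(4 × n_quad nodes; spectrally accurate for the periodic integrand). The
sign of the prefactor follows the e^{+ikz} phase convention so the on-axis
column reproduces the closed form (to ~1e−12 at convergence). Doubling
n_quad changes results by far less than the 0.1% contract at the default
resolutions. The field is single-frequency and lossless; absorption enters
only in the heat-source step.

Defaults a = 9.5 mm, R₀ = 38 mm, f = 4 MHz, v₀ = 0.01 m/s are package
assumptions (the source states only the 28 mm standoff); v₀ is anyway
rescaled by the thermal calibration.

## Thermal stage

### Model

Pennes bioheat equation on a layered axial model with the printed corneal
parameters (C_t = 4178 J/(kg·K), k = 0.58 W/(m·K), W_b = 0, Q_m = 0,
T_a = 36.7 °C) and boundary parameters (h_c = 14 W/(m²·K), T_amb = 30 °C,
ϵ = 0.975). The printed boundary equation omits the emissivity factor while
tabulating ϵ; we take the radiation term as ϵσ_SB(T⁴ − T_amb⁴) with the
quartic in kelvin.

**Where the Robin boundary applies.** The convective/radiative exchange is
applied at the anterior (z = 0) end of whatever layer stack is supplied.
For a bare-cornea stack that is the corneal anterior surface — the
textbook reading of the boundary condition. For the preset stack, which
starts with the 28 mm saline standoff, z = 0 is the transducer face; an
ambient exchange at an interior (saline-covered) corneal node would be
unphysical. The posterior boundary is clamped to the body-core 36.7 °C by
default (insulated optional); the vitreous is long enough that this choice
moves the corneal ΔT by far less than the solver's 1% grid-convergence
band.

**Heat source.** H = duty · α p²/(ρc) per node — time-averaged plane-wave
absorption heating (equivalently 2αI with I = p²/2ρc), with duty = 0.4
from the 40% excitation window. The pressure amplitude fed to the 1D solve
is the *aperture-averaged* |p| over r ∈ [0, a] (the dimensional reduction
the source describes feeding its bioheat equation), multiplied by the
accumulated absorption e^(−∫α dz) along the path. Feeding the raw on-axis
focused amplitude instead would concentrate essentially all deposition at
the geometric focus inside the lens, which contradicts every qualitative
feature of the reported axial profile.

**Layer stack and absorption (assumptions).** Thicknesses: saline 28 mm,
cornea 0.55 mm, aqueous 3.05 mm, lens 4 mm, vitreous 16.3 mm. Thermal
properties of the non-corneal layers are standard literature-order values.
Amplitude absorption: saline 30, cornea 60, aqueous 3, lens 40, vitreous
3 Np/m. The saline value is deliberately *not* water-like: with waterlike
saline absorption (~0.1 Np/m) the deposition maximum sits in the
cornea/lens region and the reported regime — rise maximal at the
transducer face, ~5× amplitude-squared decay across the cup, fluids acting
as heat sinks — cannot occur under any drive level (scaling H only scales
ΔT). The stack therefore encodes the regime the study reports, with an
absorbing cup, more strongly absorbing cornea/lens, and weakly absorbing
ocular fluids; every one of these values is marked `assumption` in the
emitted provenance and is config-exposed.

**Exposure.** The thermal presets integrate 60 s of sustained pushing at
duty 0.4 with the implicit solver (dt = 1 s) — a realistic elastography
push-train duration; the calibration to the 0.9 °C peak absorbs the
overall drive scale, so the reported profile *shape* and rate ratio are
the meaningful outputs. The corneal-surface ΔT is reported alongside, not
asserted: it depends directly on the assumed absorption split between cup
and eye.

### Numerics

* Vertex-centred finite volumes; nodes on every layer interface; each
  layer subdivided uniformly (≥ 5 nodes in the thinnest layer, default
  target spacing 0.1 mm in the library, 0.2 mm in the presets — halving it
  moves the final profile by < 1%, verified in the suite). Interface
  coupling via series (harmonic) conductances, so heat flux is continuous
  across material jumps by construction.
* Default time stepping: backward Euler (unconditionally stable), with the
  radiation term linearised about the previous step
  (h_rad = 4ϵσ_SB T_K³). An explicit forward-Euler scheme is retained for
  the conservation and maximum-principle tests and refuses steps above its
  computed bound min(ρC ΔV / ΣG).
* Initial condition: the source-free steady state (Newton iteration on the
  radiation term), so ΔT isolates the acoustic push and is provably
  nonnegative for nonnegative H.
* 2D: axisymmetric finite volumes on annular cells, symmetry at r = 0,
  insulated (default) or ambient-clamped rim, sparse LU factorisation
  reused across steps while the linearised radiation coefficient is
  unchanged. With a laterally uniform source and insulated rim every
  radial ring reduces algebraically to the 1D scheme (the suite checks
  agreement to ~1e−12).
* Two-regime decay rates: least-squares slopes of log ΔT over the saline
  window (profile peak → corneal surface) and an intra-ocular window
  (default 8 mm past the corneal surface, chosen to exclude the posterior
  Dirichlet node where ΔT = 0 by construction). Exact on piecewise
  exponential input.
* Calibration: secant iteration on the H scale factor to relative
  tolerance 1e−4 (the ΔT–H map is linear except for the mild radiation
  nonlinearity, so convergence takes a few solves); `free="v0"` reports
  the square root of the H scale.

The 2D temperature map uses the pointwise |p(r, z)|² deposition (the honest
two-dimensional counterpart of the field, scaled by the 1D calibration).
Because the pointwise field retains the focal gain that lateral averaging
suppresses, the 2D hot spot sits near the geometric focus rather than at
the face; the map's metrics report its location rather than asserting one.
This difference between the averaged-1D and pointwise-2D reductions is
inherent to the modelling chain, not a numerical artefact.

## What the pipelines do and do not show

The viscoelastic stage is exact physics for its stated model: closed forms,
an independent ODE route, and a superposition route agree to 1e−6 or
better, so its outputs are as trustworthy as the lumped model itself. The
lumped model, in turn, ignores corneal geometry, anisotropy and rate
dependence of the modulus — it cannot predict absolute deformations of a
real cornea, only the scaling behaviour of the chosen element.

The thermal chain's *absolute* temperatures are not predictions: the drive
level and absorption profile are assumptions, and the peak is pinned by
calibration. What the pipeline does establish is conditional structure —
given face-dominant deposition, the profile shape, the two-regime decay
ordering, and the conservation/maximum-principle properties of the solver
are all verified. Safety conclusions about real exposures require measured
absorption coefficients and drive levels.

## Known limitations

* No Prony/generalised-Kelvin chains; no parameter fitting to measured
  creep data; no 3D corneal finite-element geometry.
* No nonlinear acoustics, no attenuation inside the field solver (path
  absorption applies only in the heat-source step), no broadband transient
  field synthesis.
* No thermal dose (CEM43), no perfused choroid/retina, no acoustic
  streaming.
* The product-form SLS kernel is a faithful implementation of an
  unconventional formulation; comparisons with classical SLS fits should
  use the classical compliance instead.
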