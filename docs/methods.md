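# Methods

## Scope and model

`chiralprop` implements the overdamped ("Smoluchowski") picture of a rigid
dipolar chiral molecule in a rotating electric field. Inertia is neglected:
rotational relaxation (~100 ps in low-viscosity solvents) is far faster than
the ~µs field period, so the orientational distribution is the equilibrium
Boltzmann density ρ(α) ∝ exp(x cos α) in the angle α between dipole and
field, with x = μE/kT. Everything downstream — responding fraction,
escape/effective frequency, angular correction, the factorized propulsion
velocity, and the 1-D drift–diffusion separation model — follows from this
equilibrium assumption plus the deterministic driven-rotor equation. A full
time-dependent orientational PDE solver is deliberately out of scope; the
stochastic simulator covers the dynamic content instead.

## Closed-form theory (`theory`)

**Responding fraction.** The non-responding population is defined by the
minimum of the orientation density (dipoles antiparallel to the field)
spread uniformly over the sphere, giving F = 1 − 2x/(e²ˣ − 1) ≈ x − x²/3.
An alternative reading, F = 1 − e⁻²ˣ, is selectable via
`responding_fraction(x, formula="exponential")` but is not the default: only
the baseline-subtraction form is consistent with the factorized velocity
chain that yields 25 and ~44 nm/s at the experimental parameters. The two
conventions differ by a factor ~2 at small x; we do not attempt to
reconcile them silently.

**Escape and effective frequency.** ν_esc = μE/(2πξ) with ξ = kT/D_r from
the Einstein relation (user-facing D_r in deg² s⁻¹, converted internally to
rad² s⁻¹). The deterministic phase equation dψ/dt = 2πν_esc sin(2πνt − ψ)
is the Adler equation; its rotation number gives ν_eff = ν when ν ≤ ν_esc
and ν − √(ν² − ν_esc²) above. `effective_frequency_ode` integrates the
equation directly with fixed-step classical Runge–Kutta (200 steps per field
period) as an independent oracle. Because the phase-lag flow is strictly
monotone on the circle in the slipping regime, its return period
T = 1/√(ν² − ν_esc²) is exact for every trajectory; the measured rate is
therefore averaged over a window snapped to an integer number of slip
periods (after discarding the first 20%), which removes the bounded phase
oscillation from the estimate and gives agreement with the closed form to
~10⁻⁴ already at 150 field cycles.

**Angular correction.** The azimuthal average of the Boltzmann factor over
dipole rotation β about I₁ is recognised analytically as a modified Bessel
function: B(x,θ) = (1/2π)∫e^{x sinθ cosβ}dβ = I₀(x sinθ). The |cos φ|
factor of the projection integrates to 4, so

A_cor(x) = (2/π)·∫sin²θ·I₀(x sinθ)dθ / ∫sinθ·I₀(x sinθ)dθ,

evaluated by adaptive quadrature (relative tolerance 10⁻¹², needed to
resolve 0.5000003 at the experimental coupling) with `i0e` exponential
scaling so the strong-field limit (x = 10⁴ → 0.6366 ≈ 2/π) does not
overflow. Limits: A_cor(0) = ½ exactly; small-x expansion ½(1 + x²/48).
The default velocity uses the weak-field value A_cor = ½
(`a_cor_mode="fixed_half"`), since the correction at practical couplings is
below 10⁻⁶; `"field_dependent"` evaluates the quadrature.

**Sign conventions.** The rotation sense is defined looking along the flow
axis from injection toward collection; by the right-hand rule the clockwise
sense has its angular-velocity vector along that axis (+x). The reported
velocity is sense_sign·L_rev·ν_eff·A_cor·F along +x, so mirroring the
rotor (L_rev → −L_rev) or reversing the sense each negate v. This places
the S enantiomer of a positive-L_rev rotor in the leading fraction under
the clockwise field.

## Brownian-dynamics generator (`simulate`)

The simulator is the package's synthetic-data source, standing in for
all-atom MD. It evolves a rigid body frame by composing small rotations
about the body axes,

Δθᵢ = (τᵢ/ξ)Δt + √(2 D_r Δt)·N(0,1),

with τ = μ×E(t) (dipole carried along I₂) and a fixed composition order
I₁→I₂→I₃; the O(Δθ²) ordering error is far below the stochastic noise at
the enforced step bound D_r Δt ≤ 0.01 rad². A single scalar D_r is applied
to all three axes by default (the principal-axis coefficients of compact
binaphthyls are similar); a per-axis override exists. The centre of mass
advances by (L_rev/2π)·Δθ₁ along the instantaneous I₁ — the propeller
coupling is injected by construction — plus isotropic translational noise
√(2 D Δt) per coordinate. Frames are re-orthonormalised every 100 steps
(Gram–Schmidt, right-handed); recorded triads stay orthonormal to ~10⁻¹⁴.
Noise streams are pre-generated from a single seeded numpy generator, so
trajectories are bit-reproducible; the stepping kernel is numba-compiled
(~10⁶ steps/s).

The `four_phase_square` waveform steps the field direction through exactly
four orientations per period (z → ∓y → −z → ±y), emulating the four-electrode
drive; the hardware's brief diagonal transients during the ~π/4 phase
overlap of adjacent electrodes are not modelled.

What the generator does *not* emulate: solvent structure and hydrodynamic
memory, internal conformational motion, field inhomogeneity (the ~4% radial
falloff in the real chamber), and any coupling between thermal orientation
noise and the deterministic phase-slip dynamics beyond their independent
superposition. Passing recovery tests therefore show the estimators are
correct for a rigid rotor with ideal white-noise baths, not that real MD or
experiment would match the injected parameters.

## Trajectory estimators (`trajectory_analysis`)

D_r is half the least-squares slope of the mean square angular displacement
(MSAD) of the unwrapped cumulative angle versus lag. Lags are capped at 10%
of the trajectory by default (bias control); for quantitative recovery the
tests use 0.2%, because the single-trajectory MSAD error grows as
√(lag/T) — at 10⁶ records this yields D_r within ~5–10%.

L_rev is the OLS slope of *increments* of the axial centre-of-mass
displacement (each COM increment projected on the instantaneous body axis)
against increments of the rotation angle, rescaled to Å/rev. Increments
make the regression errors independent between records, so the
block-sampling standard error (s.d. of 10 contiguous block slopes / √10)
is a faithful uncertainty — ~0.05 Å/rev at 10⁶ records under the bundled
molecule I parameters. Regressing the accumulated series instead leaves a
random-walk error whose variance never averages down with trajectory
length; this is why the increment form was chosen. Angles are unwrapped
throughout; nothing is re-wrapped at ±180°.

## Separation transport (`transport`)

Concentrations live on a uniform 1-D grid in cm; velocities enter in m/s
(the theory layer's unit) and are converted internally. ee is computed on
concentrations — absorbance is proportional to total concentration at a
single wavelength, so the two are interchangeable here. The centre-split
kinetics ee = |v|√(t/πD) is the small-drift limit of the exact
erf(v√t/2√D) for two drifting Gaussians; it is capped at 1. The bounded
solver is explicit flux-form finite differences: upwind advection applied
only inside the electrode-covered active region (drift ceases where the
field ends, diffusion continues), reflecting far boundaries (valves
closed), diffusive CFL bound D Δt/Δx² ≤ 0.4. Flux form conserves mass to
machine precision; the upwind numerical diffusivity vΔx/2 is ~10⁻⁸ cm²/s
at experimental parameters, three orders below the physical D. The
closed-box steady state is evaluated in an overflow-safe scaled form and
returns the uniform profile for |vL/D| < 10⁻¹².

## Chromatography (`chromatography`)

Position maps to elution time through the volumetric flow rate and
capillary cross-section; material nearer the detector elutes first. FWHM
uses linear interpolation of the half-maximum crossings and refuses traces
whose above-half region is not contiguous. Diffusion from spreading uses
FWHM² = FWHM₀² + 16 ln2·D·t with a free intercept. The CD calibration is a
fitted straight line (the calibration's functional form is not otherwise
specified; linearity of CD and absorbance in concentration implies a linear
ratio–ee map), with an identity line through the origin as the synthetic
default. The default fraction cut is the absorbance centre of mass;
a cut at a user-supplied time is available.

## Bundled parameters

| quantity | molecule I | molecule II | note |
|---|---|---|---|
| dipole (D) | 5.3 | 10.9 | from quantum chemistry; treated as inputs here |
| L_rev (Å/rev) | 1.22 | 0.18 | II = mean magnitude of the S/R slopes 0.19/0.17 |
| D_r about I₁ (deg²/s) | 3.988×10¹² | 8.2×10¹² | I is *inferred*: back-solved from ν_esc = 0.507 MHz |
| D (cm²/s) | 8.3×10⁻⁶ | 1.4×10⁻⁵ | measured by peak spreading |
| field | 6×10⁵ V/m, 0.9 MHz, 293 K, η = 0.0065 N s m⁻² | | |

Molecule I's rotational diffusion coefficient is not tabulated anywhere
in the source measurements; the bundled value is the unique one reproducing the quoted escape
frequency and is flagged as inferred. Temperature defaults to 293 K (the
simulation bath; the physical chamber ran at 16 ± 2 °C) and is configurable
per `FieldProtocol`. The Debye→SI constant is fixed at 3.33564×10⁻³⁰ C·m.

## Numerical and test-size choices

Acceptance-level recovery runs use five seeds × 10⁶ steps of 2 ps (2 µs of
rotor time each), which bounds the whole statistical suite to a few seconds
while leaving comfortable margins (D_r within 10%, L_rev within 3 block
s.e.). The drift–diffusion comparisons use grids of ~4000 points spanning
±8σ so Gaussian tail truncation is negligible at the 0.05-ee-point level.
Known limitations: the factorization of v into F(E)·ν_eff treats the
responding fraction and phase-slip dynamics as independent, which is exact
in neither limit — the simulator can probe their interplay but the theory
layer does not; enrichment beyond ee ≈ 0.3 leaves the validity of the
√t formula (the erf form and the bounded solver take over there); and the
chromatography layer ignores detector optics and solvent-recovery losses.
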