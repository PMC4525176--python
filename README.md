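# chiralprop

Modelling and analysis of the **molecular propeller effect**: a dipolar
chiral molecule in a rotating electric field (REF) rotates with the field
and, like a propeller, couples that rotation into directed translation —
in opposite directions for opposite enantiomers. The effect separates
enantiomers in free solution, without chiral selectors, and predicts the
drift direction from absolute configuration. This package is for physical
chemists and separation scientists who want to predict the effect for a
candidate molecule, simulate the underlying rotational Brownian dynamics,
and model or analyse the resulting enantiomeric enrichment and
chromatograms.

## The model

A molecule with dipole moment μ (⊥ to its propeller axis I₁) in a field of
magnitude E rotating at frequency ν experiences the dimensionless coupling
x = μE/kT. The propulsion velocity factorizes as

```
v = L_rev · ν_eff · A_cor · F(E)
```

- **L_rev** — *hydrodynamic chirality*: signed axial displacement per full
  revolution about I₁ (Å/rev); mirror enantiomers have opposite sign.
- **ν_eff** — effective rotation frequency of the overdamped driven rotor:
  ν below the escape frequency ν_esc = μE/2πξ (ξ = kT/D_r the rotational
  friction), and ν − √(ν² − ν_esc²) above it, where the rotor phase-slips.
- **A_cor** — angular correction for random orientation of I₁ relative to
  the field-rotation axis: exactly ½ at weak coupling, 2/π at strong.
- **F(E)** — responding fraction of molecules that follow the field,
  1 − 2x/(e²ˣ − 1) ≈ x for the weak couplings (~10⁻³) of practical fields.

Two enantiomers drifting apart at ±v while diffusing (coefficient D) give a
centre-split enantiomeric excess ee(t) = |v|·√(t/πD); in a closed box of
length L the steady state is the exponential profile
C(x) = C_ave·(vL/D)·e^(vx/D)/(e^(vL/D) − 1), with D/v the characteristic
length of the drift–diffusion balance.

## Worked example

```python
from chiralprop import DEFAULT_FIELD, MOLECULE_I, MOLECULE_II, predict_report

for rotor in (MOLECULE_I, MOLECULE_II):
    r = predict_report(rotor, DEFAULT_FIELD)
    print(rotor.name, f"nu_esc={r['nu_esc_hz']/1e6:.3f} MHz",
          f"nu_eff={r['nu_eff_hz']/1e3:.0f} kHz",
          f"v={r['velocity_nm_s']:.1f} nm/s")
```

prints

```
molecule_I nu_esc=0.507 MHz nu_eff=156 kHz v=25.0 nm/s
molecule_II nu_esc=2.144 MHz nu_eff=900 kHz v=43.6 nm/s
```

Molecule I (5.3 D) cannot keep up with the 0.9-MHz field — it slips, and
its effective rotation collapses to 156 kHz, giving 25 nm/s of drift.
Molecule II (10.9 D) stays phase-locked at the full 900 kHz; despite a
seven-fold weaker propeller coupling it drifts faster, ~44 nm/s. Fed into
the drift–diffusion model, these velocities predict ~20% and ~28%
enantiomeric excess after the two-day exposures used in practice.

The `examples/` scripts walk through each capability — theory prediction,
Brownian-dynamics simulation with parameter recovery, separation kinetics
in the bounded chamber, and chromatogram synthesis/analysis — each printing
the numbers it computes and what they mean. The same functionality is
scriptable from the shell:

```
chiralprop make-fixtures --out-dir fixtures
chiralprop predict --rotor fixtures/molecule_I.json --field fixtures/field.json
chiralprop simulate-rotor --rotor fixtures/molecule_I.json --n-steps 100000 --out traj.csv
chiralprop analyze-trajectory traj.csv --axis I1
```

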