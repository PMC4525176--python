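"""Simulate a chiral rotor's Brownian dynamics and re-measure its parameters.

Generates a field-free rotational-diffusion trajectory of molecule I with its
built-in displacement-per-revolution coupling, then closes the loop: the MSAD
slope returns the injected D_r and the displacement-vs-angle regression
returns the injected L_rev with a block-sampling error bar.
"""

from chiralprop import MOLECULE_I, SimulationConfig, simulate
from chiralprop.trajectory_analysis import (
    estimate_L_rev,
    fit_rotational_diffusion,
    msad,
)

config = SimulationConfig(rotor=MOLECULE_I, field=None, dt=2e-12,
                          n_steps=1_000_000, seed=42)
traj = simulate(config)
print(f"simulated {len(traj) - 1} steps of {config.dt * 1e12:.0f} ps "
      f"({traj.times[-1] * 1e6:.1f} us of rotor time)")

lags, curve = msad(traj, axis="I1", max_lag_frac=0.002)
d_r = fit_rotational_diffusion(lags, curve)
print(f"D_r injected : {MOLECULE_I.d_r:.2e} deg^2/s")
print(f"D_r recovered: {d_r.d_r:.2e} deg^2/s  (MSAD slope / 2)")

est = estimate_L_rev(traj, axis="I1")
print(f"L_rev injected : {MOLECULE_I.l_rev:+.2f} A/rev")
print(f"L_rev recovered: {est.slope:+.2f} +- {est.stderr:.2f} A/rev "
      f"({est.n_blocks} blocks)")

mirror = estimate_L_rev(traj.mirrored(), axis="I1")
print(f"mirror image   : {mirror.slope:+.2f} A/rev  (sign flips with handedness)")
print()
print("The recovered coupling within its error bar of the injected value is")
print("the propeller signature; the mirrored trajectory reverses it exactly.")
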