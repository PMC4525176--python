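"""Overdamped rotational Brownian dynamics of a rigid chiral rotor.

This is the package's synthetic-data generator: it stands in for all-atom MD
of a binaphthyl "molecular propeller" in solvent.  The rotor is a rigid body
whose frame (body axes I1, I2, I3) diffuses rotationally with coefficient
``D_r``; an optional rotating electric field exerts the torque ``mu x E`` on
the dipole (carried along I2, perpendicular to the propeller axis I1).  The
built-in rotational-translational coupling displaces the centre of mass by
``L_rev / 360 deg`` along the instantaneous I1 for every degree of rotation
about I1, on top of isotropic translational diffusion.

Integration is a per-step composition of small rotations about the body axes

    dtheta_i = (tau_i / xi) dt + sqrt(2 D_r dt) N(0,1)

(Euler-Maruyama in the body frame; composition order I1, I2, I3 is fixed,
with O(dtheta^2) ordering error far below the stochastic noise at the
mandated step size dt * D_r <= 0.01 rad^2).  Trajectories are bit-reproducible
from the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional, Tuple, Union

import numpy as np
import pandas as pd
from numba import njit

from .constants import CM2_TO_A2, DEBYE, DEG2_TO_RAD2, K_B
from .params import ChiralRotor, FieldProtocol, ParameterError

__all__ = [
    "SimulationConfig",
    "RotorTrajectory",
    "simulate",
    "field_at",
    "write_trajectory_csv",
    "read_trajectory_csv",
]

_TRAJ_COLUMNS = [
    "t_s",
    "e11", "e12", "e13",
    "e21", "e22", "e23",
    "e31", "e32", "e33",
    "ang1_deg", "ang2_deg", "ang3_deg",
    "x_A", "y_A", "z_A",
]

_WAVEFORMS = {"ideal_circular": 0, "four_phase_square": 1}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one Brownian-dynamics run.

    ``record_every`` emulates the MD practice of saving coordinates at a
    coarser interval than the integration step.  ``rotational_noise`` /
    ``translational_noise`` switch the stochastic terms off for deterministic
    limit checks.  ``d_r_per_axis`` optionally overrides the scalar ``rotor.d_r``
    with distinct coefficients about I1, I2, I3.
    """

    rotor: ChiralRotor
    field: Optional[FieldProtocol] = None
    dt: float = 1e-12
    n_steps: int = 100_000
    record_every: int = 1
    seed: int = 0
    waveform: str = "ideal_circular"
    rotational_noise: bool = True
    translational_noise: bool = True
    d_r_per_axis: Optional[Tuple[float, float, float]] = None

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ParameterError("dt must be > 0")
        if self.n_steps < 1 or self.record_every < 1:
            raise ParameterError("n_steps and record_every must be >= 1")
        if self.waveform not in _WAVEFORMS:
            raise ParameterError(f"unknown waveform {self.waveform!r}")
        if max(self.d_r_axes) * DEG2_TO_RAD2 * self.dt > 0.01:
            raise ParameterError(
                "dt * D_r exceeds 0.01 rad^2 per step; reduce dt to stay in the "
                "small-rotation regime"
            )

    @property
    def d_r_axes(self) -> Tuple[float, float, float]:
        """Rotational diffusion about (I1, I2, I3), deg^2 s^-1."""
        if self.d_r_per_axis is not None:
            return self.d_r_per_axis
        return (self.rotor.d_r, self.rotor.d_r, self.rotor.d_r)


@dataclass
class RotorTrajectory:
    """Recorded rigid-rotor trajectory.

    Attributes
    ----------
    times : (n,) array, s — uniform, strictly increasing.
    frames : (n, 3, 3) array — columns are the body axes I1, I2, I3 expressed
        in the lab frame; each triad orthonormal.
    cum_angle : (n, 3) array, deg — cumulative unwrapped rotation angle about
        each body axis.
    com : (n, 3) array, Å — centre-of-mass position in the lab frame.
    """

    times: np.ndarray
    frames: np.ndarray
    cum_angle: np.ndarray
    com: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.times)
        if not (self.frames.shape == (n, 3, 3) and self.cum_angle.shape == (n, 3)
                and self.com.shape == (n, 3)):
            raise ValueError("inconsistent trajectory array shapes")
        if n > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def check_orthonormal(self, tol: float = 1e-8) -> float:
        """Max deviation of any recorded triad from orthonormality."""
        eye = np.eye(3)
        dev = np.abs(np.einsum("nij,nik->njk", self.frames, self.frames) - eye)
        return float(dev.max())

    def mirrored(self) -> "RotorTrajectory":
        """The trajectory of the mirror enantiomer under the same noise.

        Mirror symmetry of the coupling flips the sign of the axial drift;
        for the recorded data this negates the centre of mass.
        """
        return RotorTrajectory(
            times=self.times.copy(),
            frames=self.frames.copy(),
            cum_angle=self.cum_angle.copy(),
            com=-self.com,
        )


def field_at(t, field: FieldProtocol, waveform: str = "ideal_circular") -> np.ndarray:
    """Lab-frame electric field vector(s) at time(s) ``t``, V m^-1.

    The field rotates in the zy plane about the lab x axis (the flow /
    propulsion axis).  ``ideal_circular`` rotates uniformly;
    ``four_phase_square`` steps through exactly four orientations
    (z, -/+y, -z, +/-y) per period, emulating the four-electrode drive.
    The magnitude is the configured ``field.e`` in both dialects.
    """
    if waveform not in _WAVEFORMS:
        raise ParameterError(f"unknown waveform {waveform!r}")
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    s = field.sense_sign
    if waveform == "ideal_circular":
        a = s * 2.0 * math.pi * field.nu * t
    else:
        quarter = np.floor(4.0 * field.nu * t) % 4.0
        a = s * quarter * (math.pi / 2.0)
    out = np.zeros(t.shape + (3,))
    out[..., 1] = -field.e * np.sin(a)
    out[..., 2] = field.e * np.cos(a)
    return out[0] if scalar else out


@njit(cache=True)
def _bd_kernel(n_steps, dt, record_every,
               rot_sigma, trans_sigma, drift_coeff, l_rev_per_rad,
               mu_cm, e_mag, nu, sense_sign, waveform_code, has_field,
               rot_noise, trans_noise,
               frames_out, ang_out, com_out):  # pragma: no cover - jit
    R = np.eye(3)
    ang = np.zeros(3)
    com = np.zeros(3)
    E = np.zeros(3)
    tau_body = np.zeros(3)
    dth = np.zeros(3)
    rec = 1
    for i in range(n_steps):
        t = i * dt
        if has_field:
            if waveform_code == 0:
                a = sense_sign * 2.0 * math.pi * nu * t
            else:
                quarter = math.floor(4.0 * nu * t) % 4.0
                a = sense_sign * quarter * (math.pi / 2.0)
            E[0] = 0.0
            E[1] = -e_mag * math.sin(a)
            E[2] = e_mag * math.cos(a)
            # torque = (mu * I2) x E, then into body components
            mx = mu_cm * (R[1, 1] * E[2] - R[2, 1] * E[1])
            my = mu_cm * (R[2, 1] * E[0] - R[0, 1] * E[2])
            mz = mu_cm * (R[0, 1] * E[1] - R[1, 1] * E[0])
            for j in range(3):
                tau_body[j] = R[0, j] * mx + R[1, j] * my + R[2, j] * mz
        else:
            tau_body[0] = 0.0
            tau_body[1] = 0.0
            tau_body[2] = 0.0
        for j in range(3):
            dth[j] = tau_body[j] * drift_coeff[j] + rot_sigma[j] * rot_noise[i, j]
            if abs(dth[j]) > 0.5:
                raise ValueError(
                    "unstable rotation step (|dtheta| > 0.5 rad); reduce dt")
        # coupling displacement along the current I1, plus translational noise
        for r in range(3):
            com[r] += (l_rev_per_rad * dth[0] * R[r, 0]
                       + trans_sigma * trans_noise[i, r])
        ang[0] += dth[0]
        ang[1] += dth[1]
        ang[2] += dth[2]
        # rotate frame about body axes: R <- R Rx(dth1) Ry(dth2) Rz(dth3)
        c1 = math.cos(dth[0]); s1 = math.sin(dth[0])
        c2 = math.cos(dth[1]); s2 = math.sin(dth[1])
        c3 = math.cos(dth[2]); s3 = math.sin(dth[2])
        # combined body rotation B = Rx Ry Rz
        b00 = c2 * c3
        b01 = -c2 * s3
        b02 = s2
        b10 = c1 * s3 + s1 * s2 * c3
        b11 = c1 * c3 - s1 * s2 * s3
        b12 = -s1 * c2
        b20 = s1 * s3 - c1 * s2 * c3
        b21 = s1 * c3 + c1 * s2 * s3
        b22 = c1 * c2
        for r in range(3):
            r0 = R[r, 0]; r1 = R[r, 1]; r2 = R[r, 2]
            R[r, 0] = r0 * b00 + r1 * b10 + r2 * b20
            R[r, 1] = r0 * b01 + r1 * b11 + r2 * b21
            R[r, 2] = r0 * b02 + r1 * b12 + r2 * b22
        if (i + 1) % 100 == 0:
            # re-orthonormalize columns (Gram-Schmidt, right-handed)
            n0 = math.sqrt(R[0, 0]**2 + R[1, 0]**2 + R[2, 0]**2)
            for r in range(3):
                R[r, 0] /= n0
            d01 = R[0, 0] * R[0, 1] + R[1, 0] * R[1, 1] + R[2, 0] * R[2, 1]
            for r in range(3):
                R[r, 1] -= d01 * R[r, 0]
            n1 = math.sqrt(R[0, 1]**2 + R[1, 1]**2 + R[2, 1]**2)
            for r in range(3):
                R[r, 1] /= n1
            R[0, 2] = R[1, 0] * R[2, 1] - R[2, 0] * R[1, 1]
            R[1, 2] = R[2, 0] * R[0, 1] - R[0, 0] * R[2, 1]
            R[2, 2] = R[0, 0] * R[1, 1] - R[1, 0] * R[0, 1]
        if (i + 1) % record_every == 0:
            for r in range(3):
                for c in range(3):
                    frames_out[rec, r, c] = R[r, c]
                ang_out[rec, r] = ang[r]
                com_out[rec, r] = com[r]
            rec += 1


def simulate(config: SimulationConfig) -> RotorTrajectory:
    """Run the rotational Brownian dynamics and return the recorded trajectory.

    Fully reproducible: identical config (including seed) gives a
    bit-identical trajectory.
    """
    rotor = config.rotor
    n_rec = config.n_steps // config.record_every + 1
    frames = np.empty((n_rec, 3, 3))
    ang = np.zeros((n_rec, 3))
    com = np.zeros((n_rec, 3))
    frames[0] = np.eye(3)

    d_r_rad = np.array(config.d_r_axes) * DEG2_TO_RAD2
    rot_sigma = (np.sqrt(2.0 * d_r_rad * config.dt)
                 if config.rotational_noise else np.zeros(3))
    trans_sigma = (math.sqrt(2.0 * rotor.d_trans * CM2_TO_A2 * config.dt)
                   if config.translational_noise else 0.0)

    has_field = config.field is not None
    if has_field:
        fld = config.field
        xi = np.array([K_B * fld.temperature / dr for dr in d_r_rad])  # per-axis friction
        drift_coeff = config.dt / xi
        mu_cm = rotor.dipole_moment * DEBYE
        e_mag, nu, sense_sign = fld.e, fld.nu, float(fld.sense_sign)
    else:
        drift_coeff = np.zeros(3)
        mu_cm = e_mag = nu = 0.0
        sense_sign = 1.0

    rng = np.random.default_rng(config.seed)
    rot_noise = (rng.standard_normal((config.n_steps, 3))
                 if config.rotational_noise else np.zeros((config.n_steps, 3)))
    trans_noise = (rng.standard_normal((config.n_steps, 3))
                   if config.translational_noise else np.zeros((config.n_steps, 3)))

    _bd_kernel(config.n_steps, config.dt, config.record_every,
               rot_sigma, trans_sigma, drift_coeff,
               rotor.l_rev / (2.0 * math.pi),
               mu_cm, e_mag, nu, sense_sign,
               _WAVEFORMS[config.waveform], has_field,
               rot_noise, trans_noise,
               frames, ang, com)

    times = np.arange(n_rec) * (config.dt * config.record_every)
    return RotorTrajectory(times=times, frames=frames,
                           cum_angle=np.degrees(ang), com=com)


def write_trajectory_csv(traj: RotorTrajectory, path: Union[str, Path]) -> None:
    """Write a trajectory as CSV (columns t_s, e11..e33, ang1_deg..ang3_deg, x_A..z_A).

    ``eij`` is row i, column j of the body-to-lab frame matrix (columns are
    the body axes I1..I3 in lab coordinates).
    """
    n = len(traj)
    data = np.empty((n, 16))
    data[:, 0] = traj.times
    data[:, 1:10] = traj.frames.reshape(n, 9)
    data[:, 10:13] = traj.cum_angle
    data[:, 13:16] = traj.com
    pd.DataFrame(data, columns=_TRAJ_COLUMNS).to_csv(path, index=False)


def read_trajectory_csv(path: Union[str, Path]) -> RotorTrajectory:
    df = pd.read_csv(path)
    missing = set(_TRAJ_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory CSV is missing columns: {sorted(missing)}")
    n = len(df)
    return RotorTrajectory(
        times=df["t_s"].to_numpy(),
        frames=df[_TRAJ_COLUMNS[1:10]].to_numpy().reshape(n, 3, 3),
        cum_angle=df[_TRAJ_COLUMNS[10:13]].to_numpy(),
        com=df[_TRAJ_COLUMNS[13:16]].to_numpy(),
    )
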