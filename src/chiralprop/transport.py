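"""1-D drift-diffusion model of enantiomer separation in the capillary.

Opposite enantiomers drift with velocities +/-v along the flow axis while
spreading diffusively.  For a point-like racemic slug split in half at the
centre of its absorbance profile, the enantiomeric excess grows as

    ee(t) = |v| sqrt(t / (pi D))

(the small-drift limit of the overlapping-Gaussian model; the exact value is
erf(v sqrt(t) / (2 sqrt(D)))).  In a closed chamber of length L the long-time
steady state is the exponential profile C(x) = C_ave (vL/D) e^{vx/D} /
(e^{vL/D} - 1), inverted for the opposite enantiomer; D/v is the
characteristic length separating drift- from diffusion-dominated behaviour.

Velocities are in m s^-1 (as produced by the theory layer), diffusion
coefficients in cm^2 s^-1 and positions in cm (the chamber scale).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .params import ParameterError

__all__ = [
    "ConcentrationProfile",
    "ee_vs_time",
    "gaussian_pair_profile",
    "split_ee",
    "evolve_bounded",
    "steady_state_profile",
    "characteristic_length",
    "enrichment_from_ee",
    "fit_propulsion_velocity",
    "write_profile_csv",
    "read_profile_csv",
]

_M_TO_CM = 100.0


@dataclass
class ConcentrationProfile:
    """S- and R-enantiomer concentrations on a uniform 1-D grid.

    ``grid`` is in cm; concentrations are non-negative, arbitrary units.
    ``active_region`` is the interval where the rotating field acts (drift is
    applied only there); ``None`` means the whole grid.
    """

    grid: np.ndarray
    c_s: np.ndarray
    c_r: np.ndarray
    active_region: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.c_s = np.asarray(self.c_s, dtype=float)
        self.c_r = np.asarray(self.c_r, dtype=float)
        if not (len(self.grid) == len(self.c_s) == len(self.c_r)):
            raise ValueError("grid and concentration arrays must have equal length")
        dx = np.diff(self.grid)
        if len(dx) and not np.allclose(dx, dx[0], rtol=1e-8):
            raise ValueError("grid must be uniform")
        if np.any(self.c_s < -1e-12) or np.any(self.c_r < -1e-12):
            raise ValueError("concentrations must be >= 0")

    @property
    def dx(self) -> float:
        return float(self.grid[1] - self.grid[0])

    def mass(self) -> Tuple[float, float]:
        """Total (S, R) mass by the trapezoidal rule."""
        return (float(np.trapezoid(self.c_s, self.grid)),
                float(np.trapezoid(self.c_r, self.grid)))

    def total(self) -> np.ndarray:
        """Total concentration c_S + c_R (proportional to absorbance)."""
        return self.c_s + self.c_r

    def copy(self) -> "ConcentrationProfile":
        return ConcentrationProfile(self.grid.copy(), self.c_s.copy(),
                                    self.c_r.copy(), self.active_region)


def ee_vs_time(v: float, d: float, t: float) -> float:
    """Predicted enantiomeric excess (fraction) of a centre-split sample.

    ``ee = |v| sqrt(t / (pi D))`` with ``v`` in m/s, ``d`` in cm^2/s, ``t`` in
    seconds; capped at 1 (the formula is a small-drift approximation).
    """
    if d <= 0:
        raise ParameterError("diffusion coefficient must be > 0")
    if t < 0:
        raise ParameterError("time must be >= 0")
    ee = abs(v) * _M_TO_CM * math.sqrt(t / (math.pi * d))
    return min(ee, 1.0)


def gaussian_pair_profile(v: float, d: float, t: float, x0: float,
                          grid: Sequence[float],
                          active_region: Optional[Tuple[float, float]] = None,
                          ) -> ConcentrationProfile:
    """Two drifting Gaussians: S centred at x0 + v t, R at x0 - v t.

    Both have variance 2 D t and unit mass on the grid.  At t = 0 the peaks
    coincide (represented at the grid resolution).
    """
    grid = np.asarray(grid, dtype=float)
    v_cm = v * _M_TO_CM
    sigma = math.sqrt(2.0 * d * t) if t > 0 else 0.0
    dx = float(grid[1] - grid[0])
    sigma = max(sigma, dx)  # narrow slugs are representable only at grid scale

    def _gauss(centre: float) -> np.ndarray:
        g = np.exp(-0.5 * ((grid - centre) / sigma) ** 2)
        m = np.trapezoid(g, grid)
        if m <= 0:
            raise ValueError("Gaussian mass vanished on the grid; enlarge the grid")
        return g / m

    return ConcentrationProfile(grid, _gauss(x0 + v_cm * t), _gauss(x0 - v_cm * t),
                                active_region)


def split_ee(profile: ConcentrationProfile, cut_position: float) -> Tuple[float, float]:
    """ee (percent) of the leading (x > cut) and trailing (x < cut) fractions.

    ee = (int c_S - int c_R) / (int c_S + int c_R) over each side; positive
    means S-enriched.  For a symmetric drifting pair the two sides have
    opposite signs.
    """
    g = profile.grid
    if not (g[0] <= cut_position <= g[-1]):
        raise ValueError("cut position outside the grid")
    lead = g >= cut_position
    trail = ~lead

    def _side_ee(mask: np.ndarray) -> float:
        s = float(np.trapezoid(np.where(mask, profile.c_s, 0.0), g))
        r = float(np.trapezoid(np.where(mask, profile.c_r, 0.0), g))
        tot = s + r
        if tot <= 0:
            raise ValueError("empty fraction: ee undefined")
        return 100.0 * (s - r) / tot

    return _side_ee(lead), _side_ee(trail)


def evolve_bounded(profile: ConcentrationProfile, v: float, d: float,
                   dt: float, n_steps: int) -> ConcentrationProfile:
    """Explicit finite-difference drift-diffusion evolution in the chamber.

    Drift +/-v (m/s; + for S, - for R) acts only inside ``active_region``
    (material that diffuses past the electrodes stops drifting); diffusion
    acts everywhere; the far domain ends are reflecting (valves closed).
    Flux-form upwind advection conserves mass to machine precision.

    Requires the diffusive CFL condition D dt / dx^2 <= 0.4.
    """
    if d <= 0 or dt <= 0 or n_steps < 0:
        raise ParameterError("need d > 0, dt > 0, n_steps >= 0")
    dx = profile.dx
    if d * dt / dx**2 > 0.4:
        raise ParameterError(
            f"unstable step: D dt/dx^2 = {d * dt / dx**2:.3f} > 0.4")
    g = profile.grid
    lo, hi = profile.active_region if profile.active_region else (g[0], g[-1])
    # drift velocity at cell interfaces, zero outside the active region
    x_iface = 0.5 * (g[1:] + g[:-1])
    active = (x_iface >= lo) & (x_iface <= hi)
    v_cm = v * _M_TO_CM

    c_s = profile.c_s.copy()
    c_r = profile.c_r.copy()
    for _ in range(n_steps):
        for c, vel in ((c_s, v_cm), (c_r, -v_cm)):
            flux = -d * np.diff(c) / dx
            if vel >= 0:
                flux += np.where(active, vel * c[:-1], 0.0)
            else:
                flux += np.where(active, vel * c[1:], 0.0)
            dc = np.zeros_like(c)
            dc[:-1] -= flux
            dc[1:] += flux
            c += dt / dx * dc
        if min(c_s.min(), c_r.min()) < -1e-9 * max(c_s.max(), c_r.max()):
            raise ArithmeticError("instability: negative concentrations detected")
    np.clip(c_s, 0.0, None, out=c_s)
    np.clip(c_r, 0.0, None, out=c_r)
    return ConcentrationProfile(g, c_s, c_r, profile.active_region)


def steady_state_profile(v: float, d: float, length: float, c_ave: float,
                         grid: Sequence[float]) -> ConcentrationProfile:
    """Long-time exponential profile in a closed chamber of length L.

    C_S(x) = C_ave (vL/D) e^{vx/D} / (e^{vL/D} - 1) on [0, L]; the R profile
    is the x -> L - x mirror.  Spatial mean equals C_ave; satisfies zero net
    flux v C - D dC/dx = 0 everywhere.  v -> 0 returns the uniform profile.
    """
    if length <= 0:
        raise ParameterError("chamber length must be > 0")
    if d <= 0:
        raise ParameterError("diffusion coefficient must be > 0")
    grid = np.asarray(grid, dtype=float)
    a = v * _M_TO_CM * length / d  # dimensionless vL/D
    if abs(a) < 1e-12:
        c = np.full_like(grid, c_ave)
        return ConcentrationProfile(grid, c.copy(), c.copy(), (0.0, length))
    # scaled form, overflow-safe for either sign of v
    c_s = c_ave * a * np.exp(a * (grid / length - 1.0)) / -np.expm1(-a)
    c_r = c_ave * a * np.exp(-a * grid / length) / -np.expm1(-a)  # x -> L - x mirror
    return ConcentrationProfile(grid, c_s, c_r, (0.0, length))


def characteristic_length(d: float, v: float) -> float:
    """Drift-diffusion balance length D/|v| in cm (v in m/s, D in cm^2/s)."""
    if v == 0:
        return math.inf
    return d / abs(v * _M_TO_CM)


def enrichment_from_ee(ee_percent: float) -> float:
    """Majority-enantiomer enrichment level (percent) from ee (percent)."""
    if not -100.0 <= ee_percent <= 100.0:
        raise ParameterError("ee must be between -100 and 100 percent")
    return (100.0 + abs(ee_percent)) / 2.0


def fit_propulsion_velocity(times: Sequence[float], ee_values: Sequence[float],
                            d: float) -> Tuple[float, float]:
    """Least-squares |v| (m/s, with s.e.) from measured ee(t) (fractions).

    Fits ee = v sqrt(t/(pi D)), the model linear in v, exactly as one fits an
    enrichment-versus-exposure-time curve.
    """
    t = np.asarray(times, dtype=float)
    ee = np.asarray(ee_values, dtype=float)
    if d <= 0:
        raise ParameterError("diffusion coefficient must be > 0")
    s = np.sqrt(t / (math.pi * d)) * _M_TO_CM  # d(ee)/dv
    denom = float(np.dot(s, s))
    if denom == 0:
        raise ValueError("degenerate fit: all times are zero")
    v_hat = float(np.dot(s, ee)) / denom
    resid = ee - v_hat * s
    dof = max(len(t) - 1, 1)
    stderr = math.sqrt(float(np.dot(resid, resid)) / dof / denom)
    return v_hat, stderr


def write_profile_csv(profile: ConcentrationProfile, path: Union[str, Path]) -> None:
    pd.DataFrame({"x_cm": profile.grid, "c_S": profile.c_s,
                  "c_R": profile.c_r}).to_csv(path, index=False)


def read_profile_csv(path: Union[str, Path],
                     active_region: Optional[Tuple[float, float]] = None,
                     ) -> ConcentrationProfile:
    df = pd.read_csv(path)
    return ConcentrationProfile(df["x_cm"].to_numpy(), df["c_S"].to_numpy(),
                                df["c_R"].to_numpy(), active_region)
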