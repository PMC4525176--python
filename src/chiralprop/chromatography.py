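"""Chromatogram synthesis and analysis for the in-line and CD detectors.

The separation chamber's contents elute past a fixed detector, so a spatial
concentration profile maps linearly onto elution time through the volumetric
flow rate and capillary cross-section.  Absorbance is proportional to total
concentration; the circular-dichroism (CD) channel is proportional to the
S-R concentration difference, so the CD/absorbance ratio calibrates to ee
independently of concentration.  Diffusion coefficients are read off from the
growth of squared peak widths: for a Gaussian peak FWHM^2 = FWHM_0^2 +
16 ln2 D t.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .params import ParameterError
from .transport import ConcentrationProfile

__all__ = [
    "Chromatogram",
    "CalibrationCurve",
    "profile_to_chromatogram",
    "fwhm",
    "estimate_D_from_spreading",
    "ee_from_cd",
    "split_fractions",
    "write_chromatogram_csv",
    "read_chromatogram_csv",
]

_16LN2 = 16.0 * math.log(2.0)


@dataclass
class Chromatogram:
    """Elution-time series of absorbance (>= 0) and signed CD signal (a.u.)."""

    time: np.ndarray
    absorbance: np.ndarray
    cd: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        self.cd = np.asarray(self.cd, dtype=float)
        if not (len(self.time) == len(self.absorbance) == len(self.cd)):
            raise ValueError("channel lengths differ")
        if len(self.time) > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("elution times must be strictly increasing")
        if np.any(self.absorbance < -1e-12):
            raise ValueError("baseline-subtracted absorbance must be >= 0")

    def centre_of_mass(self) -> float:
        """Absorbance-weighted mean elution time."""
        w = float(np.trapezoid(self.absorbance, self.time))
        if w <= 0:
            raise ValueError("empty chromatogram")
        return float(np.trapezoid(self.time * self.absorbance, self.time)) / w


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear map between ee (percent) and the CD/absorbance ratio.

    Fitted from standards of known ee; must be strictly monotone (nonzero
    slope).  ``ratio = slope * ee_pct + intercept``.
    """

    slope: float
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ParameterError("calibration slope must be nonzero (monotone map)")

    @classmethod
    def identity(cls) -> "CalibrationCurve":
        """Synthetic-detector default: ratio = ee fraction (slope 0.01/percent)."""
        return cls(slope=0.01, intercept=0.0)

    @classmethod
    def fit(cls, ee_percent: Sequence[float], ratio: Sequence[float]) -> "CalibrationCurve":
        res = stats.linregress(np.asarray(ee_percent, float), np.asarray(ratio, float))
        return cls(slope=float(res.slope), intercept=float(res.intercept))

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "CalibrationCurve":
        df = pd.read_csv(path)
        return cls.fit(df["ee_pct"], df["ratio"])

    def ee_of_ratio(self, ratio: float) -> float:
        return (ratio - self.intercept) / self.slope


def profile_to_chromatogram(profile: ConcentrationProfile, flow_rate: float,
                            capillary_id: float, detector_position: float,
                            cd_per_ee: float = 1.0) -> Chromatogram:
    """Map a spatial profile to the elution-time domain of an in-line detector.

    Parameters
    ----------
    flow_rate : µl min^-1 volumetric pump rate (> 0).
    capillary_id : µm inner diameter.
    detector_position : cm; must be at or beyond the leading edge of the
        profile.  Material at larger x (closer to the detector) elutes first.
    cd_per_ee : CD signal per unit (c_S - c_R), a.u.
    """
    if flow_rate <= 0:
        raise ParameterError("flow rate must be > 0")
    if capillary_id <= 0:
        raise ParameterError("capillary inner diameter must be > 0")
    if detector_position < profile.grid[-1]:
        raise ValueError("detector lies behind part of the profile")
    area_cm2 = math.pi * (capillary_id * 1e-4 / 2.0) ** 2
    u = (flow_rate * 1e-3 / 60.0) / area_cm2  # linear flow speed, cm/s
    t = (detector_position - profile.grid) / u
    order = np.argsort(t)
    return Chromatogram(
        time=t[order],
        absorbance=(profile.c_s + profile.c_r)[order],
        cd=cd_per_ee * (profile.c_s - profile.c_r)[order],
    )


def fwhm(chrom: Chromatogram) -> float:
    """Full width at half maximum of a single-peak absorbance trace, seconds.

    Half-max crossings are located by linear interpolation.  A trace whose
    above-half-maximum region is not contiguous (two peaks) is rejected.
    """
    y = chrom.absorbance
    t = chrom.time
    peak = y.max()
    if peak <= 0:
        raise ValueError("no peak in chromatogram")
    half = 0.5 * peak
    above = y >= half
    idx = np.flatnonzero(above)
    if len(idx) == 0:
        raise ValueError("no half-maximum crossing found")
    if np.any(np.diff(idx) != 1):
        raise ValueError("multiple peaks above half maximum; fwhm undefined")
    i0, i1 = idx[0], idx[-1]
    if i0 == 0 or i1 == len(y) - 1:
        raise ValueError("peak is cut off by the record edge")

    def _cross(ia: int, ib: int) -> float:
        return t[ia] + (half - y[ia]) * (t[ib] - t[ia]) / (y[ib] - y[ia])

    return _cross(i1, i1 + 1) - _cross(i0, i0 - 1)


def estimate_D_from_spreading(wait_times: Sequence[float],
                              widths: Sequence[float]) -> Tuple[float, float]:
    """Diffusion coefficient (with s.e.) from peak spreading, cm^2 s^-1.

    ``widths`` are FWHM values in cm (convert detector-time widths via the
    flow speed first).  For a Gaussian peak FWHM^2 = FWHM_0^2 + 16 ln2 D t,
    so D is the slope of the least-squares line through (t, FWHM^2) divided
    by 16 ln2; the intercept (injection width) is free.
    """
    t = np.asarray(wait_times, dtype=float)
    w = np.asarray(widths, dtype=float)
    if len(t) < 3:
        raise ParameterError("need at least 3 (time, FWHM) pairs")
    res = stats.linregress(t, w**2)
    if res.slope < 0:
        raise ValueError("negative spreading slope: widths shrink with time")
    return res.slope / _16LN2, res.stderr / _16LN2


def ee_from_cd(chrom: Chromatogram, calibration: CalibrationCurve,
               window: Optional[Tuple[float, float]] = None) -> float:
    """ee (percent) of the material in an elution-time window.

    The CD/absorbance integral ratio is concentration-independent; the
    calibration maps it to ee.
    """
    t = chrom.time
    if window is None:
        mask = np.ones_like(t, dtype=bool)
    else:
        t0, t1 = window
        if t0 < t[0] - 1e-12 or t1 > t[-1] + 1e-12:
            raise ValueError("window outside the recorded elution range")
        mask = (t >= t0) & (t <= t1)
    total = float(np.trapezoid(chrom.absorbance, t))
    absorb = float(np.trapezoid(np.where(mask, chrom.absorbance, 0.0), t))
    if absorb <= max(1e-9 * total, 1e-300):
        raise ValueError("absorbance integral is ~0: ee undefined")
    cd = float(np.trapezoid(np.where(mask, chrom.cd, 0.0), t))
    return calibration.ee_of_ratio(cd / absorb)


def split_fractions(chrom: Chromatogram,
                    cut_time: Optional[float] = None,
                    ) -> Tuple[Chromatogram, Chromatogram]:
    """Partition into (leading, trailing) fractions at ``cut_time``.

    The default cut is the absorbance centre of mass (the experiment's
    "split into two halves at the centre of the absorption profile").  The
    leading fraction is the earlier-eluting material.
    """
    if cut_time is None:
        cut_time = chrom.centre_of_mass()
    t = chrom.time
    if not (t[0] <= cut_time <= t[-1]):
        raise ValueError("cut time outside the record")
    lead = t <= cut_time
    if lead.sum() < 2 or (~lead).sum() < 2:
        raise ValueError("cut leaves an empty fraction")
    return (
        Chromatogram(t[lead], chrom.absorbance[lead], chrom.cd[lead]),
        Chromatogram(t[~lead], chrom.absorbance[~lead], chrom.cd[~lead]),
    )


def write_chromatogram_csv(chrom: Chromatogram, path: Union[str, Path]) -> None:
    pd.DataFrame({"t_s": chrom.time, "abs_au": chrom.absorbance,
                  "cd_au": chrom.cd}).to_csv(path, index=False)


def read_chromatogram_csv(path: Union[str, Path]) -> Chromatogram:
    df = pd.read_csv(path)
    return Chromatogram(df["t_s"].to_numpy(), df["abs_au"].to_numpy(),
                        df["cd_au"].to_numpy())
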