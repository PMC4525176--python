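"""Domain parameter types: the chiral rotor and the rotating-field protocol.

A :class:`ChiralRotor` bundles the per-enantiomer physical constants that enter
the propeller-effect theory: the electric dipole moment ``mu`` (Debye), the
hydrodynamic chirality ``L_rev`` (signed axial displacement in Å per full
revolution about the propeller axis I1), the rotational diffusion coefficient
``D_r`` about I1 (deg^2 s^-1) and the translational diffusion coefficient
(cm^2 s^-1).  A :class:`FieldProtocol` describes the rotating electric field
(REF): magnitude, rotation frequency, sense, temperature and solvent viscosity.

Both types round-trip through the JSON config schema used by the CLI
(keys ``dipole_debye``, ``l_rev_angstrom``, ``d_r_deg2_s``, ``d_trans_cm2_s``,
``handedness``; ``e_v_m``, ``nu_hz``, ``sense``, ``temperature_k``,
``eta_pa_s``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Union

__all__ = [
    "ChiralRotor",
    "FieldProtocol",
    "MOLECULE_I",
    "MOLECULE_II",
    "DEFAULT_FIELD",
]


class ParameterError(ValueError):
    """Raised for physically invalid rotor/field parameters."""


@dataclass(frozen=True)
class ChiralRotor:
    """One enantiomer's physical parameters.

    Parameters
    ----------
    name : str
        Identifier (e.g. ``"molecule_I"``).
    handedness : {"S", "R"}
        Absolute configuration.
    dipole_moment : float
        Electric dipole moment, Debye (>= 0).
    l_rev : float
        Hydrodynamic chirality: displacement in Å per 360 deg revolution about
        the propeller axis I1.  Signed; opposite for mirror enantiomers; zero
        means an achiral propeller axis.
    d_r : float
        Rotational diffusion coefficient about I1, deg^2 s^-1 (> 0).
    d_trans : float
        Translational diffusion coefficient, cm^2 s^-1 (> 0).
    """

    name: str
    handedness: str
    dipole_moment: float
    l_rev: float
    d_r: float
    d_trans: float

    def __post_init__(self) -> None:
        if self.handedness not in ("S", "R"):
            raise ParameterError(f"handedness must be 'S' or 'R', got {self.handedness!r}")
        if self.dipole_moment < 0:
            raise ParameterError("dipole_moment must be >= 0 Debye")
        if self.d_r <= 0:
            raise ParameterError("d_r must be > 0 deg^2/s")
        if self.d_trans <= 0:
            raise ParameterError("d_trans must be > 0 cm^2/s")

    def mirror(self) -> "ChiralRotor":
        """Return the mirror-image enantiomer: handedness flipped, L_rev negated."""
        return replace(
            self,
            handedness="R" if self.handedness == "S" else "S",
            l_rev=-self.l_rev,
        )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "handedness": self.handedness,
            "dipole_debye": self.dipole_moment,
            "l_rev_angstrom": self.l_rev,
            "d_r_deg2_s": self.d_r,
            "d_trans_cm2_s": self.d_trans,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChiralRotor":
        return cls(
            name=d.get("name", "rotor"),
            handedness=d["handedness"],
            dipole_moment=float(d["dipole_debye"]),
            l_rev=float(d["l_rev_angstrom"]),
            d_r=float(d["d_r_deg2_s"]),
            d_trans=float(d["d_trans_cm2_s"]),
        )

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "ChiralRotor":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


@dataclass(frozen=True)
class FieldProtocol:
    """Rotating electric field (REF) protocol and bath conditions.

    The sense of rotation is defined looking along the propulsion (flow) axis
    from injection toward collection; by the right-hand rule a CW rotation has
    its angular-velocity vector pointing along that axis.

    Parameters
    ----------
    e : float
        Electric field magnitude, V m^-1 (>= 0).
    nu : float
        Field rotation frequency, Hz (>= 0).
    sense : {"CW", "CCW"}
        Rotation sense viewed from injection toward collection.
    temperature : float
        Bath temperature, K (> 0).
    eta : float
        Solvent viscosity, N s m^-2 (> 0).
    """

    e: float
    nu: float
    sense: str = "CW"
    temperature: float = 293.0
    eta: float = 0.0065

    def __post_init__(self) -> None:
        if self.sense not in ("CW", "CCW"):
            raise ParameterError(f"sense must be 'CW' or 'CCW', got {self.sense!r}")
        if self.e < 0:
            raise ParameterError("field magnitude must be >= 0 V/m")
        if self.nu < 0:
            raise ParameterError("rotation frequency must be >= 0 Hz")
        if self.temperature <= 0:
            raise ParameterError("temperature must be > 0 K")
        if self.eta <= 0:
            raise ParameterError("viscosity must be > 0 N s/m^2")

    @property
    def omega(self) -> float:
        """Angular frequency 2*pi*nu, rad s^-1."""
        import math

        return 2.0 * math.pi * self.nu

    @property
    def sense_sign(self) -> int:
        """+1 for CW (angular velocity along +x, the flow axis), -1 for CCW."""
        return 1 if self.sense == "CW" else -1

    def to_dict(self) -> dict:
        return {
            "e_v_m": self.e,
            "nu_hz": self.nu,
            "sense": self.sense,
            "temperature_k": self.temperature,
            "eta_pa_s": self.eta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FieldProtocol":
        return cls(
            e=float(d["e_v_m"]),
            nu=float(d["nu_hz"]),
            sense=d.get("sense", "CW"),
            temperature=float(d.get("temperature_k", 293.0)),
            eta=float(d.get("eta_pa_s", 0.0065)),
        )

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "FieldProtocol":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


# Bundled parameter sets for the two binaphthyl test molecules.
# Molecule I: 1,1'-bi-2-naphthol bis(trifluoromethanesulfonate).
# Its D_r about I1 is not tabulated anywhere; the value below is back-solved
# from the escape frequency 0.507 MHz and is flagged as inferred.
MOLECULE_I = ChiralRotor(
    name="molecule_I",
    handedness="S",
    dipole_moment=5.3,
    l_rev=1.22,
    d_r=3.988e12,  # inferred from nu_esc = 0.507 MHz at 6e5 V/m, 293 K
    d_trans=8.3e-6,
)

# Molecule II: 2,2'-(1,4-butylenedioxy)-6,6'-dinitro-1,1'-binaphthalene.
# L_rev = 0.18 Å is the mean magnitude of the S/R slopes (0.19 / -0.17 Å).
MOLECULE_II = ChiralRotor(
    name="molecule_II",
    handedness="S",
    dipole_moment=10.9,
    l_rev=0.18,
    d_r=8.2e12,
    d_trans=1.4e-5,
)

#: The experimental REF: 6e5 V/m at 0.9 MHz, CW, 293 K, benzene.
DEFAULT_FIELD = FieldProtocol(e=6.0e5, nu=0.9e6, sense="CW", temperature=293.0, eta=0.0065)
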