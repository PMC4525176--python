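"""Bundled parameter fixtures and small synthetic data files.

``make_fixtures`` writes the two binaphthyl parameter sets, the experimental
field protocol and small synthetic trajectory / chromatogram / calibration
CSVs — everything needed to exercise the full pipeline from a shell.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .chromatography import write_chromatogram_csv, profile_to_chromatogram
from .params import DEFAULT_FIELD, MOLECULE_I, MOLECULE_II
from .simulate import SimulationConfig, simulate, write_trajectory_csv
from .transport import gaussian_pair_profile
from . import theory

__all__ = ["make_fixtures"]


def make_fixtures(out_dir: Union[str, Path], seed: int = 0) -> list:
    """Write fixture files into ``out_dir`` and return the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    for rotor, fname in ((MOLECULE_I, "molecule_I.json"), (MOLECULE_II, "molecule_II.json")):
        path = out / fname
        rotor.to_json(path)
        written.append(path)
    field_path = out / "field.json"
    DEFAULT_FIELD.to_json(field_path)
    written.append(field_path)

    # Short synthetic free-diffusion trajectory of molecule I (2000 records).
    config = SimulationConfig(rotor=MOLECULE_I, field=None, dt=2e-12,
                              n_steps=2000, record_every=1, seed=seed)
    traj_path = out / "trajectory_molecule_I.csv"
    write_trajectory_csv(simulate(config), traj_path)
    written.append(traj_path)

    # Synthetic chromatogram: molecule II after 21 h of drift at the
    # theory-predicted velocity, seen by the in-line detector.
    v = theory.propulsion_velocity(MOLECULE_II, DEFAULT_FIELD)
    t_exp = 21 * 3600.0
    grid = np.linspace(-5.0, 5.0, 1001)
    profile = gaussian_pair_profile(v, MOLECULE_II.d_trans, t_exp, 0.0, grid)
    chrom = profile_to_chromatogram(profile, flow_rate=0.050, capillary_id=75.0,
                                    detector_position=20.0)
    chrom_path = out / "chromatogram_molecule_II.csv"
    write_chromatogram_csv(chrom, chrom_path)
    written.append(chrom_path)

    # Identity-slope CD calibration standards.
    ee = np.linspace(-100.0, 100.0, 9)
    calib_path = out / "calibration.csv"
    pd.DataFrame({"ee_pct": ee, "ratio": 0.01 * ee}).to_csv(calib_path, index=False)
    written.append(calib_path)
    return written
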