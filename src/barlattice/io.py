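"""File I/O: MRC2014 maps/stacks via gemmi, TSV metadata, JSON config."""

from __future__ import annotations

import json
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "write_mrc",
    "read_mrc",
    "write_tsv",
    "read_tsv",
    "default_config",
    "load_config",
    "save_config",
]


def write_mrc(path, array: np.ndarray, voxel_size: float) -> None:
    """Write a 2D/3D array as an MRC/CCP4 map (mode 2, Å voxel size).

    Stacks are stored as 3D grids with the slowest axis enumerating images.
    """
    arr = np.ascontiguousarray(array, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError("expect 2D or 3D array")
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(arr)
    nz, ny, nx = arr.shape  # gemmi grid dims follow the numpy shape
    m.grid.unit_cell = gemmi.UnitCell(
        nz * voxel_size, ny * voxel_size, nx * voxel_size, 90, 90, 90
    )
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


def read_mrc(path) -> tuple[np.ndarray, float]:
    """Read an MRC/CCP4 map; returns (array, voxel_size_Å)."""
    m = gemmi.read_ccp4_map(str(path))
    arr = np.array(m.grid, copy=True)
    voxel = m.grid.unit_cell.a / m.grid.nu
    return arr, float(voxel)


def write_tsv(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# Shared JSON configuration: study-condition defaults of the major tube
# class.  Every pipeline stage reads the subset of keys it needs.
_DEFAULTS = {
    "rise_A": 3.81,
    "twist_deg": 55.92,
    "diameters_A": {
        "inner_leaflet": 182.0,
        "outer_leaflet": 248.0,
        "protein_shell": 280.0,
    },
    "area_per_lipid_A2": 50.0,
    "mean_lipid_mw_kDa": 0.7384,
    "dimer_mass_kDa": 56.0,
    "tube_mpl_kDa_per_A": 28.0,
    "calibrant_mpl_kDa_per_A": 13.1,
    "reference_tube_diameter_A": 300.0,
    "pixel_size_A": 3.0,
    "box_px": 96,
    "defocus_um": 1.5,
    "voltage_kV": 300.0,
    "spherical_aberration_mm": 2.0,
    "amplitude_contrast": 0.07,
    "stem_pixel_size_nm": 2.0,
    "stem_dose_per_A2": 10.0,
}

_NUMERIC_KEYS = [
    "rise_A",
    "twist_deg",
    "area_per_lipid_A2",
    "mean_lipid_mw_kDa",
    "dimer_mass_kDa",
    "tube_mpl_kDa_per_A",
    "calibrant_mpl_kDa_per_A",
    "reference_tube_diameter_A",
    "pixel_size_A",
    "defocus_um",
    "voltage_kV",
    "spherical_aberration_mm",
    "amplitude_contrast",
    "stem_pixel_size_nm",
    "stem_dose_per_A2",
]


def default_config() -> dict:
    return json.loads(json.dumps(_DEFAULTS))  # deep copy


def load_config(path=None) -> dict:
    """Load a JSON config, fill missing keys with defaults, validate."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = json.load(fh)
        for k, v in user.items():
            if k == "diameters_A":
                cfg["diameters_A"].update(v)
            else:
                cfg[k] = v
    _validate(cfg)
    return cfg


def _validate(cfg: dict) -> None:
    for k in _NUMERIC_KEYS:
        v = cfg.get(k)
        if not isinstance(v, (int, float)) or not v > 0:
            raise ValueError(f"config key {k!r} must be a positive number, got {v!r}")
    d = cfg["diameters_A"]
    if not d["inner_leaflet"] < d["outer_leaflet"] <= d["protein_shell"]:
        raise ValueError("diameters_A must satisfy inner < outer <= shell")
    if not isinstance(cfg["box_px"], int) or cfg["box_px"] < 16:
        raise ValueError("box_px must be an integer >= 16")


def save_config(path, cfg: dict) -> None:
    _validate(cfg)
    Path(path).write_text(json.dumps(cfg, indent=2, sort_keys=True) + "\n")
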