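"""Radial-profile analysis, model-lattice building, and run reports.

The transverse structure of a reconstruction is summarized by its
cylindrically averaged density profile: tubes show up to three peaks from
the axis outward — inner leaflet, outer leaflet, and the attached protein
shell.  Diameters are always reported with an explicit radial convention
because "tube diameter" is ambiguous between the protein shell and the
membrane leaflets.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .lattice import HelicalSymmetry, TubeGeometry
from .reconstruct import DensityMap, symmetrize
from .simulate import ProtomerModel, TubeModel, build_tube_volume

logger = logging.getLogger(__name__)

__all__ = [
    "RadialProfile",
    "LatticeModelMap",
    "DiameterConvention",
    "radial_profile",
    "leaflet_separation",
    "build_lattice_model",
    "protomer_contacts",
    "report",
]

#: explicit radial conventions for any reported diameter
DiameterConvention = ("protein_shell", "outer_leaflet", "inner_leaflet")


@dataclass
class RadialProfile:
    radii: np.ndarray  # Å, ascending
    density: np.ndarray  # mean density per radial bin
    peaks: list[tuple[float, str]]  # (radius Å, label)

    def peak_radius(self, label: str) -> float:
        for r, lab in self.peaks:
            if lab == label:
                return r
        raise KeyError(label)


@dataclass
class LatticeModelMap:
    map: DensityMap
    protomer: ProtomerModel
    symmetry: HelicalSymmetry
    n_copies: int


def radial_profile(dmap: DensityMap, min_prominence: float = 0.1) -> RadialProfile:
    """Cylindrical average over (φ, z) with labeled density peaks.

    Peaks are local maxima with prominence above ``min_prominence`` of the
    profile span; the two innermost are labeled inner/outer leaflet and
    any further peak is protein.  Missing peaks are logged, not fatal.
    """
    box = dmap.box
    c = box // 2
    yy, xx = np.indices((box, box))
    r_px = np.hypot(yy - c, xx - c)
    r_bin = np.round(r_px).astype(int)
    n_bins = c
    sel = r_bin < n_bins
    counts = np.bincount(r_bin[sel], minlength=n_bins)
    sums = np.zeros(n_bins)
    for plane in dmap.grid.astype(np.float64):
        sums += np.bincount(r_bin[sel], weights=plane[sel], minlength=n_bins)
    density = sums / np.maximum(counts * box, 1)
    radii = np.arange(n_bins) * dmap.voxel_size
    span = float(density.max() - density.min())
    labels = ["inner_leaflet", "outer_leaflet", "protein"]
    peaks_out: list[tuple[float, str]] = []
    if span > 0:
        idx, _ = find_peaks(density, prominence=min_prominence * span)
        for j, p in enumerate(idx[:3]):
            rp = float(p)
            if 0 < p < n_bins - 1:
                y0, y1, y2 = density[p - 1 : p + 2]
                denom = y0 - 2 * y1 + y2
                if denom < 0:
                    rp += float(np.clip(0.5 * (y0 - y2) / denom, -0.5, 0.5))
            peaks_out.append((rp * dmap.voxel_size, labels[j]))
    if len(peaks_out) < 2:
        logger.warning("radial profile: only %d peaks found", len(peaks_out))
    return RadialProfile(radii, density, peaks_out)


def leaflet_separation(profile: RadialProfile) -> float:
    """Radial distance (Å) between the outer and inner leaflet peaks."""
    try:
        return profile.peak_radius("outer_leaflet") - profile.peak_radius(
            "inner_leaflet"
        )
    except KeyError as exc:
        raise ValueError("both leaflet peaks are required") from exc


def build_lattice_model(
    protomer: ProtomerModel,
    sym: HelicalSymmetry,
    geom: TubeGeometry,
    n_copies: int,
    voxel_size: float = 3.0,
    box: int = 96,
) -> LatticeModelMap:
    """Rasterize `n_copies` symmetry-related protomers into a density map.

    Copy k is placed at azimuth k·twist and height k·rise (k centered on
    zero) at the tube geometry's protein radius — the model-lattice
    counterpart of imposing the reconstruction's symmetry on a fitted
    protomer.
    """
    if n_copies < 1:
        raise ValueError("n_copies must be >= 1")
    model = TubeModel(
        geometry=geom,
        symmetry=sym,
        protomer=protomer,
        tube_length=max(n_copies, 1) * sym.rise,
    )
    dmap = build_tube_volume(model, voxel_size, box, with_membrane=False)
    return LatticeModelMap(dmap, protomer, sym, n_copies)


def protomer_contacts(
    model: TubeModel, neighbors: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7)
) -> pd.DataFrame:
    """Minimal pseudo-atom distances between protomer 0 and its neighbors.

    For each neighbor index k, reports the closest atom pair, whether the
    closest atom of each protomer is a tip (immersed/protruding) or a
    central atom, and the distance in Å.
    """
    from .simulate import _protomer_world_coords

    p0, _ = _protomer_world_coords(model, 0)
    prot = model.protomer
    arc = prot.pseudo_atoms[:, 0]  # local along-arc coordinate
    half_span = float(np.abs(arc).max())

    def zone(i: int) -> str:
        t = arc[i] / half_span  # -1 immersed tip ... +1 protruding tip
        if t <= -0.85:
            return "immersed_tip"
        if t >= 0.85:
            return "protruding_tip"
        return "central" if abs(t) <= 0.5 else "arm"

    rows = []
    for k in neighbors:
        pk, _ = _protomer_world_coords(model, k)
        d = np.linalg.norm(p0[:, None, :] - pk[None, :, :], axis=2)
        i, j = np.unravel_index(np.argmin(d), d.shape)
        rows.append(
            {
                "neighbor_k": k,
                "min_distance_A": float(d[i, j]),
                "atom_self": zone(int(i)),
                "atom_neighbor": zone(int(j)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# run report
# ---------------------------------------------------------------------------

_STAGE_FILES = {
    "config": "config.json",
    "symmetry": "symmetry.tsv",
    "layer_lines": "layer_lines.tsv",
    "diameters": "diameters.json",
    "mass": "mass_decomposition.json",
    "mpl": "mpl_summary.json",
    "fsc": "fsc.tsv",
}


def report(run_dir) -> dict:
    """Aggregate pipeline outputs in a run directory into one summary.

    Reads whichever stage outputs exist (JSON/TSV dialects written by the
    analysis drivers), lists the missing ones, and writes
    ``report.json`` plus a human-readable ``report.txt``.  Pure function
    of the directory contents.
    """
    run_dir = Path(run_dir)
    summary: dict = {"missing_stages": []}
    for stage, fname in _STAGE_FILES.items():
        path = run_dir / fname
        if not path.exists():
            summary["missing_stages"].append(stage)
            continue
        if fname.endswith(".json"):
            summary[stage] = json.loads(path.read_text())
        else:
            df = pd.read_csv(path, sep="\t")
            summary[stage] = df.to_dict(orient="list")
    if "symmetry" in summary:
        rises = summary["symmetry"].get("rise_A", [])
        twists = summary["symmetry"].get("twist_deg", [])
        if rises:
            summary["converged_symmetry"] = {
                "rise_A": rises[-1],
                "twist_deg": twists[-1],
            }
    out_json = json.dumps(summary, indent=2, sort_keys=True, default=float)
    (run_dir / "report.json").write_text(out_json + "\n")
    lines = ["BAR-lattice pipeline report", "=" * 27]
    for stage in _STAGE_FILES:
        status = "missing" if stage in summary["missing_stages"] else "ok"
        lines.append(f"{stage:12s} {status}")
    if "converged_symmetry" in summary:
        cs = summary["converged_symmetry"]
        lines.append(
            f"converged symmetry: rise {cs['rise_A']:.2f} Å, "
            f"twist {cs['twist_deg']:.2f}°"
        )
    (run_dir / "report.txt").write_text("\n".join(lines) + "\n")
    return summary
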