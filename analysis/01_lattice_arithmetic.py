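"""Printed-input lattice arithmetic: layer lines, area, mass decomposition.

Everything here is closed-form, computed from the converged helical
parameters of the major tube class (rise 3.81 Å, twist 55.92°) and the
printed geometry/composition constants.  Writes results/layer_lines.tsv
and results/mass_decomposition.json.
"""

import json
from pathlib import Path

import pandas as pd

from barlattice.lattice import (
    MAJOR_CLASS_GEOMETRY,
    MAJOR_CLASS_SYMMETRY,
    LipidModel,
    TubeGeometry,
    area_per_subunit,
    decompose_mass,
    layer_lines,
    lipids_per_angstrom,
    pitch,
    units_per_turn,
)

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

sym, geom = MAJOR_CLASS_SYMMETRY, MAJOR_CLASS_GEOMETRY

print(f"symmetry: rise {sym.rise} Å, twist {sym.twist}°")
print(f"  -> {units_per_turn(sym):.4f} subunits/turn, pitch {pitch(sym):.2f} Å")

lines = [
    {
        "n": L.n,
        "m": L.m,
        "Z_invA": L.axial_frequency,
        "spacing_A": L.axial_spacing,
    }
    for L in layer_lines(sym, 8, 1)
    if L.n > 0 or (L.n == 0 and L.m > 0)  # one line per conjugate pair
]
df = pd.DataFrame(lines)
df.to_csv(OUT / "layer_lines.tsv", sep="\t", index=False)
d7 = df.query("n == 7 and m == -1").spacing_A.iloc[0]
d6 = df.query("n == 6 and m == -1").spacing_A.iloc[0]
print(f"major layer-line families: (7,-1) {d7:.1f} Å, (6,-1) {d6:.1f} Å")
print(f"  (the two spacings visible as the diagonal moiré pattern)")

area = area_per_subunit(geom, sym)
area_312 = area_per_subunit(
    TubeGeometry(214, 280, 312), 3.83
)
print(f"area per dimer: {area:.0f} Å² (280 Å class), {area_312:.0f} Å² (312 Å class)")

lipid = LipidModel(reference_diameter=300.0)
n_lip = lipids_per_angstrom(lipid)
dec = decompose_mass(28.0, lipid, dimer_mass=56.0)
print(
    f"mass decomposition of 28 kDa/Å: {n_lip:.2f} lipids/Å "
    f"(~{int(n_lip)}), lipid {dec.lipid_mpl:.2f} kDa/Å, protein "
    f"{dec.protein_mpl:.2f} kDa/Å -> one 56 kDa dimer per "
    f"{dec.axial_extent_per_dimer:.2f} Å of tube axis"
)

(OUT / "mass_decomposition.json").write_text(
    json.dumps(
        {
            "total_mpl_kDa_per_A": dec.total_mpl,
            "lipids_per_A": n_lip,
            "lipid_mpl_kDa_per_A": dec.lipid_mpl,
            "protein_mpl_kDa_per_A": dec.protein_mpl,
            "axial_extent_per_dimer_A": dec.axial_extent_per_dimer,
            "area_per_dimer_A2_280": area,
            "area_per_dimer_A2_312": area_312,
        },
        indent=2,
    )
    + "\n"
)
print(f"wrote {OUT/'layer_lines.tsv'} and {OUT/'mass_decomposition.json'}")
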