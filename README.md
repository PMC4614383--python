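# barlattice

Desk-scale analysis pipeline for the helical protein lattices that N-BAR
domains (amphiphysin/BIN1) form on membrane tubes.  BAR-domain proteins
polymerize into spiral lattices around lipid tubes; cryo-EM images of
such tubes show an interwoven moiré pattern whose layer lines encode the
lattice, and scanning transmission EM (STEM) dark-field intensity gives
the tube's mass per unit length (MPL).  This package implements, with
fully synthetic data, every computational step of that characterization:

* **Helical-lattice arithmetic** — the selection rule
  `Z(n, m) = (n·Δφ/360 + m)/Δz` connecting the rise/twist pair
  (Δz, Δφ) to layer-line spacings, per-subunit lattice area π·D·Δz,
  and the lipid/protein decomposition of a measured MPL.
* **Synthetic data generation** — pseudo-atom tube models (bilayer
  leaflet shells + crescent BAR-dimer protomers on the helical lattice),
  phase-contrast CTF projection images with noise, and Poisson-count
  STEM dark-field fields with TMV-like calibration rods.
* **2D processing** — segment extraction, CTF phase flipping,
  reference-free alignment/classification, power-spectrum layer-line and
  diameter measurement.
* **IHRSR reconstruction** — projection matching, R-weighted
  back-projection, helical symmetrization, local (rise, twist) search
  ("hsearch"), layer-line indexing for initial parameters, and FSC
  resolution at the 0.5 criterion.
* **STEM MPL** — internal-standard calibration against TMV (13.1 kDa/Å)
  and per-box mass measurement with background annuli.

The code lives under `src/barlattice/` (one module per pipeline stage),
with narrative drivers under `analysis/` and the scientific details in
`docs/methods.md`.

## Worked example

The central arithmetic, from printed inputs only (also available as
`analysis/01_lattice_arithmetic.py`):

```python
>>> from barlattice.lattice import (MAJOR_CLASS_SYMMETRY, LipidModel,
...     layer_lines, decompose_mass, lipids_per_angstrom)
>>> sym = MAJOR_CLASS_SYMMETRY          # rise 3.81 Å, twist 55.92°
>>> {(L.n, L.m): round(L.axial_spacing, 1)
...  for L in layer_lines(sym, 8, 1) if (L.n, L.m) in [(6, -1), (7, -1)]}
{(6, -1): 56.0, (7, -1): 43.6}
>>> lip = LipidModel(reference_diameter=300.0)   # 50 Å²/lipid
>>> round(lipids_per_angstrom(lip), 2)
18.85
>>> dec = decompose_mass(28.0, lip, dimer_mass=56.0)
>>> round(dec.lipid_mpl, 2), round(dec.protein_mpl, 2), round(dec.axial_extent_per_dimer, 2)
(13.92, 14.08, 3.98)
```

Reading: a lattice with 3.81 Å rise and 55.92° twist produces its two
major layer lines at 56.0 and 43.6 Å — the diagonal stripe spacings of
the tube images.  A 300 Å tube carries ~18.85 lipids per axial Å
(≈ 13.9 kDa/Å of lipid), so a measured 28 kDa/Å leaves ≈ 14.1 kDa/Å of
protein: one 56 kDa BAR dimer per ≈ 4 Å of tube axis — a tightly packed
scaffold.

The simulation-based stages print, for example (`analysis/05_stem_mpl.py`):

```
tube MPL: 28.24 ± 2.85 kDa/Å over 750 boxes (rounds to 28)
held-out calibrant: 13.06 ± 1.38 kDa/Å over 375 boxes (rounds to 13; true 13.1)
```

and the reconstruction driver (`analysis/04_reconstruct.py`) recovers the
generating rise/twist from noisy synthetic segments started 0.4 Å / 3°
off-truth:

```
converged symmetry: rise 3.78 Å, twist 55.90° (generation values: 3.81 Å, 55.92°)
```

## Analysis scripts

| script | what it does |
| --- | --- |
| `analysis/01_lattice_arithmetic.py` | selection-rule table, per-dimer area, mass decomposition |
| `analysis/02_tube_model.py` | radial profile, leaflet separation, measured vs predicted layer lines, protomer contacts |
| `analysis/03_class_averages.py` | two-diameter segment mixture → phase flip → 2D classes → spectra |
| `analysis/04_reconstruct.py` | IHRSR symmetry recovery on 300 noisy segments (~10 min) |
| `analysis/05_stem_mpl.py` | calibrated STEM MPL recovery + decomposition chain |
| `analysis/06_report.py` | aggregate everything under `results/` into one report |

Each writes TSV/JSON tables under `results/`.

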