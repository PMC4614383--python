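# Methods

`barlattice` is a desk-scale reimplementation of the computational
analysis used to characterize the helical protein lattice that N-BAR
domains (amphiphysin/BIN1) form on membrane tubes: a synthetic-data
generator standing in for the raw cryo-EM and STEM data, helical-lattice
arithmetic, an IHRSR-style reconstruction loop with symmetry search, and
calibrated mass-per-length (MPL) estimation.  This note records the
models, the parameters that matter, and the design decisions taken where
the procedure was genuinely open.

## The lattice model

A 1-start helical lattice is parameterized by the rise Δz (Å) and twist
Δφ (degrees) per subunit.  The study conditions are the converged values
of the most populated tube class: Δz = 3.81 Å, Δφ = 55.92°, giving
360/55.92 ≈ 6.44 subunits per turn and a pitch of 24.5 Å.  Layer lines
follow the helical selection rule

    Z(n, m) = (n·Δφ/360 + m) / Δz

with Bessel order n and axial repeat index m.  For the study symmetry the
(7,−1) and (6,−1) families fall at 43.6 Å and 56.0 Å — the "44 and 55 Å"
diagonal moiré spacings visible in tube images.  Handedness is not
observable in projection; twist is stored signed (positive by default)
and all derived spacings use |Δφ|.

Per-subunit area on the unrolled cylinder is π·D·Δz at the lattice
diameter D.  With the class diameter 280 Å this gives 3351 Å² (3754 Å²
for the 312 Å class at Δz = 3.83 Å) — within 2 % of the ~3300/~3700 Å²
usually quoted; the exact radial convention behind those round numbers is
not recoverable, so every diameter in this package carries an explicit
convention (`protein_shell`, `outer_leaflet`, `inner_leaflet`).

Mass decomposition: lipid count per axial Å uses the single-cylindrical-
surface convention π·D/A (D = 300 Å, A = 50 Å²/lipid → 18.85, truncated
to 18 for reporting; truncation rather than rounding is the convention
that reproduces the published count).  The mean lipid molecular weight
defaults to 0.7384 kDa — the mole-fraction-weighted mean of POPG
(749 Da) and POPE (718 Da) at 2:1 w/w.  The lipid MPL (13.9 kDa/Å)
subtracted from a 28 kDa/Å total leaves 14.1 kDa/Å of protein, i.e. one
56 kDa BAR dimer per 3.98 Å of tube axis.

## The synthetic tube generator

The generator emulates — it does not reproduce — the raw data.  A tube is
two Gaussian-shell leaflets (inner/outer diameters 182/248 Å, headgroup
shells of 6 Å FWHM) plus one protomer per lattice point.  The protomer is
a pseudo-atom crescent standing in for the BAR dimer: 21 arc positions ×
3 strands, 170 Å tip to tip, ~26 Å axial width, mass weighted toward the
dimerization center, with one tip dipping 16 Å below the placement radius
(the membrane-immersed tip reaching into the acyl region) and the other
protruding 7 Å above it, and a small axial slope (0.05) along the 1-start
row direction.  These dimensions were chosen from the known shape of BAR
dimers and from the qualitative features of the published data the
generator must reproduce: the dominant 44/55 Å layer lines (a thin or
untilted crescent instead produces a dominant 24.5 Å pitch line), the
three-peak radial profile (inner leaflet, outer leaflet, protein), and
nearest-neighbour contacts between the protruding tip of one dimer and
the central body of its adjacent-turn neighbour.  Pseudo-atoms are
rasterized as σ = 5 Å Gaussians normalized so that integrated protein
density per axial Å equals (dimer mass)/Δz exactly.

Cryo-EM segments are line-integral projections at a uniform random
azimuth, out-of-plane tilt uniform in ±10°, and small in-plane offsets
(±3 Å), multiplied in Fourier space by a phase-contrast CTF (300 kV,
Cs = 2 mm, 7 % amplitude contrast, defocus drawn from 0.5–3.2 μm), plus
white Gaussian noise with variance var(signal)/SNR.  Working scale is a
96-pixel box at 3 Å/pixel (288 Å of tube per segment) — the published
300-pixel boxes at ~1.8 Å emulated at reduced scale so that full
reconstructions run in minutes on one CPU.  What the generator does not
model: solvent/ice background, detector MTF, beam-induced motion,
flexibility/disorder of the lattice, and astigmatism.  Passing recovery
tests therefore demonstrates correctness of the pipeline's inference
machinery under the stated noise model, not performance on real
micrographs.

STEM dark-field fields are Poisson-count images: expected counts =
dose·A_px·background + dose·mass_contrast·(projected mass per pixel),
with rods rasterized as semicircular (projected-cylinder) cross-profiles.
Defaults: 2 nm pixels, dose 10 counts/Å², mass_contrast 0.05,
background 0.02.  The instrument proportionality is arbitrary — it
cancels exactly in the internal-standard calibration, which the tests
verify.  Tubes carry 10 % per-100 Å occupancy jitter emulating the
non-uniform packing that widens the tube MPL histogram relative to the
rigid TMV control; with these defaults the simulated tube spread is
≈ ±3 kDa/Å, matching the reported distribution width.

## 2D processing

CTF correction is by phase flipping (multiply Fourier terms by
sign(CTF)), which preserves amplitudes exactly and is an involution.
Reference-free 2D classification replaces maximum-likelihood
classification at this scale: segments are rotationally aligned by a
coarse search (sharpness of the transverse profile), centered on their
mirror axis by autocorrelation, and clustered by k-means on transverse
profiles with order-invariant quantile initialization along the first
principal axis.  This separates tube diameter classes cleanly at SNR 0.5
and is fully deterministic.

Tube diameters are read from class averages by folding the transverse
line scan about the tube axis and inverting it to a radial density
profile (onion-peeling inverse Abel transform); the diameter is twice the
outermost radial peak.  Reading peaks on the raw projected profile
instead would be biased a few Å inward by the projection geometry of a
shell.

Layer lines are measured on the axially collapsed power spectrum:
local maxima above a prominence threshold (relative to the spectrum
median), equator band excluded, positions refined parabolically.  Note
the (6,−1)/(7,−1) pair is separated by only ~1.5 Fourier pixels in a
288 Å box; measurement tests use longer synthetic images (512 Å), and
stack-level indexing averages zero-padded per-segment spectra.

## IHRSR reconstruction

The loop is the classic cycle: project the current volume on an
(azimuth, tilt) grid → assign each segment its best reference by
normalized cross-correlation with sub-pixel translation search →
back-project → refine (rise, twist) on the unsymmetrized volume
("hsearch") → impose the symmetry → repeat, on a coarse-to-fine schedule
(2×-binned images with a 4° azimuth grid first, unbinned with ±10° tilt
search later).  Back-projection is R-weighted (1D ramp filter per z-row
before trilinear scattering); the unweighted scatter is the exact adjoint
of the projector, which the tests verify to 1e-6.

Three design points were forced by desk scale and are worth recording:

1. **Initial symmetry comes from indexing, not from trust in the input
   values.**  The stack's own layer lines are measured and inverted
   through the selection rule (adjacent-Bessel-order assignment); the
   candidate closest to the caller's initial estimate, within a trust
   window (±0.5 Å, ±4°), becomes the working symmetry.  This mirrors the
   original protocol, where initial parameters were computed from class
   averages and their Fourier transforms and the local search was used
   only to converge.  Starting the full loop from a symmetry several
   degrees off instead either stalls or locks onto grid-commensurate
   false lattices (an exact 6-fold is a spurious attractor of the
   self-consistency score on a 4° reference grid).

2. **The noise-cylinder initial model is low-pass filtered** (25 Å
   correlation length).  With white voxel noise the first matching rounds
   cannot discriminate azimuths and the alternating iteration converges
   to a featureless fixed point; noise features at the lattice scale
   break the azimuthal degeneracy within one or two iterations.

3. **hsearch scores a mean over multi-step symmetry transforms**
   (k = 2, 6, 12): the candidate (Δz, Δφ) is applied k times and the
   transformed map is correlated with the original inside a cylindrical
   shell mask whose axial margin excludes everything a k-step transform
   would sample from outside the box.  A single-step score barely
   constrains the rise (sliding along a nearly continuous helical strand
   is a flat valley); longer baselines amplify rise sensitivity roughly
   as k².  Search is a coarse grid then shrinking grids with a final
   parabolic fit, deterministic throughout; results pinned to the window
   edge are rejected (the previous estimate is kept), and the symmetry is
   only searched during unbinned phases — binned grids bias the optimum.

Resolution is the FSC 0.5 crossing between even/odd half-set
reconstructions symmetrized independently.  At SNR 0.5 with 300 segments
the symmetrized half maps are strongly denoised by symmetry averaging,
so the desk-scale FSC is close to Nyquist and is not a reproduction
target.

Numerical conventions: (z, y, x) volumes, helical axis z, beam along y,
right-handed rotations in degrees, Å everywhere, rotation center at voxel
`box // 2`; trilinear interpolation with zero padding (`grid-constant`)
for all map transforms; ties in projection matching resolved by grid
order; divergence declared after three consecutive mean-score drops
greater than 0.01.

## STEM mass-per-length

Measurement boxes tile each rod (length 150 Å, width 1.5× the rod's
apparent width, so the full semicircular profile is integrated); local
background is the mean over rectangular side strips 2–4 box-widths from
the rod (the mean, not the median: the discrete skew of a Poisson-count
median biases the integrated mass by ~1 %, measurable in simulation).
The calibration factor is the known TMV line density divided by the mean
background-subtracted counts per Å over calibrant boxes; held-out
calibrant rods (not used for calibration) provide the control
measurement.  The estimator is exact in the noise-free limit and unbiased
to < 2 % at the default dose.

## Problem sizes

Default experiment sizes were chosen so every pipeline stage runs in
minutes on a single CPU: 300 segments in 96³ boxes for recovery runs
(five binned rounds plus one unbinned round), 160³ grids at 2 Å for
radial measurements, three 1024² STEM fields (≈ 750 tube boxes).  The
published data set (26 754 segments, 300-pixel boxes, 1° azimuth grids
with 21 tilt values) is emulated in structure, not in size.

## Known limitations

* Recovered rise at the working scale is accurate to ~0.05 Å, limited by
  layer-line sharpness in a 288 Å box (the direct 3.81 Å meridional
  repeat lies beyond Nyquist at 3 Å/pixel), and recovered twist to
  ~0.05°; two-decimal agreement with the published values is at the edge
  of what this scale determines.
* The 2D classifier separates diameter classes but does not model
  continuous flexibility; bad-segment rejection is a plain
  cross-correlation threshold.
* FSC resolutions at this scale reflect symmetry-averaged synthetic
  noise, not the disorder-limited ~11 Å of the real data set.
* Indexing assumes the two major layer lines are adjacent-Bessel-order
  (n, −1)/(n+1, −1) families of a dense 1-start lattice, which is the
  relevant regime here; sparse lattices would need a wider candidate
  search.
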