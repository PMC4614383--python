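"""Synthetic data: tube volumes, cryo-EM segments with CTF, STEM fields.

The generator emulates the study conditions of the N-BAR/amphiphysin tube
data set: protein-coated bilayer tubes with 1-start helical symmetry
(rise ≈ 3.8 Å, twist ≈ 56°, leaflet diameters 182/248 Å, protein shell
≈ 280 Å), imaged as phase-contrast projections with additive Gaussian
noise, and STEM dark-field fields of tubes plus TMV-like calibration rods
(13.1 kDa/Å) with Poisson counting noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .lattice import (
    HelicalSymmetry,
    TubeGeometry,
    MAJOR_CLASS_GEOMETRY,
    MAJOR_CLASS_SYMMETRY,
    units_per_turn,
)
from .reconstruct import DensityMap, project, fourier_shift_image
from .segments import CTFParams, SegmentStack, ctf_2d, METADATA_COLUMNS

import pandas as pd

__all__ = [
    "ProtomerModel",
    "TubeModel",
    "StemRod",
    "StemField",
    "build_protomer",
    "default_tube_model",
    "build_tube_volume",
    "render_segments",
    "render_stem_field",
    "lattice_projection_image",
]


@dataclass(frozen=True)
class ProtomerModel:
    """Pseudo-atom model of the repeating unit (one BAR dimer).

    Local frame: x = along the crescent (maps to the lattice-row
    direction, mostly circumferential), y = radial offset from the
    placement radius (outward positive), z = axial.  pseudo_atoms is an
    (n, 4) array of (x, y, z, weight_kDa); tip flags mark the
    membrane-immersed and protruding ends.
    """

    pseudo_atoms: np.ndarray
    total_mass: float
    descriptor: str = ""
    immersed_tip: int = -1  # atom index flagged membrane-immersed
    protruding_tip: int = -1

    def __post_init__(self) -> None:
        atoms = np.asarray(self.pseudo_atoms, dtype=float)
        object.__setattr__(self, "pseudo_atoms", atoms)
        if atoms.ndim != 2 or atoms.shape[1] != 4:
            raise ValueError("pseudo_atoms must be (n, 4)")
        if not np.isclose(atoms[:, 3].sum(), self.total_mass, rtol=1e-9):
            raise ValueError("weights must sum to total_mass")

    @property
    def tip_span(self) -> float:
        """Tip-to-tip distance in the local frame, Å."""
        a = self.pseudo_atoms
        return float(
            np.linalg.norm(a[self.protruding_tip, :3] - a[self.immersed_tip, :3])
        )


def build_protomer(
    style: str = "crescent",
    total_mass: float = 56.0,
    span: float = 170.0,
    n_arc: int = 21,
    axial_half_width: float = 8.0,
    radial_offsets: tuple[float, float, float] = (-16.0, 3.0, 7.0),
    axial_slope: float = 0.05,
    mass_sigma: float = 0.45,
) -> ProtomerModel:
    """Build a pseudo-atom protomer.

    'crescent': a BAR-dimer-like body of ``n_arc`` ≥ 20 pseudo-atoms per
    strand spanning ~`span` Å tip to tip, three parallel strands at axial
    offsets 0, ±axial_half_width giving the dimer its ~25 Å axial width.
    Mass is weighted toward the center (Gaussian in the arc parameter,
    width `mass_sigma`).  The radial offset varies quadratically along the
    arc through `radial_offsets` = (immersed tip, center, protruding tip):
    one tip dips below the placement radius (into the membrane), the other
    protrudes above it.  A small axial slope follows the 1-start row
    direction.  'sphere': a single pseudo-atom.
    """
    if total_mass <= 0:
        raise ValueError("total_mass must be > 0")
    if style == "sphere":
        return ProtomerModel(
            np.array([[0.0, 0.0, 0.0, total_mass]]),
            total_mass,
            "single pseudo-atom",
            immersed_tip=0,
            protruding_tip=0,
        )
    if style != "crescent":
        raise ValueError(f"unknown protomer style {style!r}")
    if n_arc < 20:
        raise ValueError("crescent needs >= 20 pseudo-atoms per strand")
    t = np.linspace(-1.0, 1.0, n_arc)
    x = 0.5 * span * t
    lo, mid, hi = radial_offsets
    a = (hi - lo) / 2.0
    b = (hi + lo) / 2.0 - mid
    y = mid + a * t + b * t * t
    z = axial_slope * x
    w = np.exp(-0.5 * (t / mass_sigma) ** 2)
    w /= w.sum()
    strands = (
        (0.0, 0.40),
        (-axial_half_width, 0.30),
        (+axial_half_width, 0.30),
    )
    parts = [
        np.column_stack([x, y, z + dz, total_mass * frac * w])
        for dz, frac in strands
    ]
    atoms = np.concatenate(parts)
    return ProtomerModel(
        atoms,
        total_mass,
        f"crescent, {n_arc} pseudo-atoms x 3 strands, {span:.0f} Å tip-to-tip",
        immersed_tip=0,
        protruding_tip=n_arc - 1,
    )


@dataclass(frozen=True)
class TubeModel:
    """Forward model of a protein-coated membrane tube."""

    geometry: TubeGeometry
    symmetry: HelicalSymmetry
    protomer: ProtomerModel
    leaflet_thickness: float = 6.0  # Å, Gaussian FWHM of each headgroup shell
    tube_length: float = 0.0  # Å; 0 -> fill the box
    leaflet_amplitude: float = 0.0012  # kDa/Å^3 peak density of each leaflet
    protomer_radius: float = 0.0  # Å placement radius; 0 -> midway shell

    def placement_radius(self) -> float:
        if self.protomer_radius > 0:
            return self.protomer_radius
        g = self.geometry
        return 0.5 * (g.protein_shell_diameter / 2 + g.outer_leaflet_radius)


def default_tube_model(
    geometry: TubeGeometry = MAJOR_CLASS_GEOMETRY,
    symmetry: HelicalSymmetry = MAJOR_CLASS_SYMMETRY,
    protomer: ProtomerModel | None = None,
) -> TubeModel:
    """Tube model of the major class with the default crescent protomer."""
    return TubeModel(
        geometry=geometry,
        symmetry=symmetry,
        protomer=protomer if protomer is not None else build_protomer(),
    )


def _protomer_world_coords(
    model: TubeModel, k: int
) -> tuple[np.ndarray, np.ndarray]:
    """World (x, y, z in Å) positions and weights of protomer copy k.

    The local x coordinate is wrapped as arc length around the cylinder at
    the placement radius; copy k sits at azimuth k*twist, height k*rise.
    """
    atoms = model.protomer.pseudo_atoms
    r0 = model.placement_radius()
    phi0 = math.radians(k * model.symmetry.twist)
    r = r0 + atoms[:, 1]
    phi = phi0 + atoms[:, 0] / r0
    x = r * np.cos(phi)
    y = r * np.sin(phi)
    z = k * model.symmetry.rise + atoms[:, 2]
    return np.column_stack([x, y, z]), atoms[:, 3]


def _rasterize_gaussians(
    grid: np.ndarray,
    voxel: float,
    points: np.ndarray,
    weights: np.ndarray,
    sigma: float,
) -> None:
    """Add normalized 3D Gaussians (integral = weight, kDa) to the grid.

    Grid is (z, y, x); world origin at voxel box//2 of each axis; density
    units kDa/Å³.
    """
    box = grid.shape[0]
    c = box // 2
    s_vox = sigma / voxel
    half = int(math.ceil(3.5 * s_vox))
    amp = 1.0 / ((2 * math.pi) ** 1.5 * sigma**3)
    win = np.arange(-half, half + 1)
    for (x, y, z), w in zip(points, weights):
        px, py, pz = x / voxel + c, y / voxel + c, z / voxel + c
        ix, iy, iz = int(round(px)), int(round(py)), int(round(pz))
        if not (
            -half <= ix <= box + half
            and -half <= iy <= box + half
            and -half <= iz <= box + half
        ):
            continue
        gx = np.exp(-0.5 * ((ix + win - px) / s_vox) ** 2)
        gy = np.exp(-0.5 * ((iy + win - py) / s_vox) ** 2)
        gz = np.exp(-0.5 * ((iz + win - pz) / s_vox) ** 2)
        zs = slice(max(iz - half, 0), min(iz + half + 1, box))
        ys = slice(max(iy - half, 0), min(iy + half + 1, box))
        xs = slice(max(ix - half, 0), min(ix + half + 1, box))
        oz = slice(zs.start - (iz - half), zs.stop - (iz - half))
        oy = slice(ys.start - (iy - half), ys.stop - (iy - half))
        ox = slice(xs.start - (ix - half), xs.stop - (ix - half))
        grid[zs, ys, xs] += (
            w
            * amp
            * gz[oz][:, None, None]
            * gy[oy][None, :, None]
            * gx[ox][None, None, :]
        )


def build_tube_volume(
    model: TubeModel,
    voxel_size: float,
    box: int,
    atom_sigma: float = 5.0,
    with_membrane: bool = True,
    with_protein: bool = True,
) -> DensityMap:
    """Rasterize the tube model on a cubic grid (kDa/Å³ for the protein).

    Two Gaussian-shell leaflets at the configured leaflet radii plus one
    protomer copy at (k·twist, k·rise) for every k whose center lies in
    the covered tube length.  The box must accommodate the protein shell.
    """
    if box * voxel_size < model.geometry.protein_shell_diameter:
        raise ValueError(
            "box too small for the protein shell "
            f"({box * voxel_size:.0f} Å < "
            f"{model.geometry.protein_shell_diameter:.0f} Å)"
        )
    grid = np.zeros((box, box, box), dtype=np.float64)
    c = box // 2
    extent = box * voxel_size
    length = model.tube_length if model.tube_length > 0 else extent
    half_len = min(length, extent + 4 * atom_sigma) / 2

    if with_membrane:
        yy, xx = np.indices((box, box), dtype=np.float64)
        r = np.hypot(yy - c, xx - c) * voxel_size
        sig = model.leaflet_thickness / 2.355
        shell = np.zeros_like(r)
        for radius in (
            model.geometry.inner_leaflet_radius,
            model.geometry.outer_leaflet_radius,
        ):
            shell += model.leaflet_amplitude * np.exp(
                -0.5 * ((r - radius) / sig) ** 2
            )
        z_abs = np.abs(np.arange(box) - c) * voxel_size
        zmask = (z_abs <= half_len).astype(np.float64)
        grid += zmask[:, None, None] * shell[None]

    if with_protein:
        k_max = int(math.floor(half_len / model.symmetry.rise))
        for k in range(-k_max, k_max + 1):
            pts, w = _protomer_world_coords(model, k)
            _rasterize_gaussians(grid, voxel_size, pts, w, atom_sigma)

    return DensityMap(grid, voxel_size)


def render_segments(
    model: TubeModel,
    ctf: CTFParams,
    n_segments: int,
    snr: float,
    seed: int,
    box: int = 96,
    tilt_range: float = 10.0,
    max_shift_A: float = 3.0,
    defocus_range: tuple[float, float] | None = None,
    volume: DensityMap | None = None,
) -> SegmentStack:
    """Simulate boxed micrograph segments of the tube.

    Each segment is the projection of the tube volume at a uniform random
    azimuth and an out-of-plane tilt uniform in ±tilt_range, shifted by a
    small random in-plane offset, convolved with the phase-contrast CTF,
    plus white Gaussian noise with variance = var(signal)/snr.  A pure
    function of (parameters, seed).
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    if not snr > 0:
        raise ValueError("snr must be > 0")
    rng = np.random.default_rng(seed)
    if volume is None:
        volume = build_tube_volume(model, ctf.pixel_size, box)
    box = volume.box
    rows = []
    images = np.empty((n_segments, box, box), dtype=np.float32)
    for i in range(n_segments):
        azimuth = float(rng.uniform(0.0, 360.0))
        tilt = float(rng.uniform(-tilt_range, tilt_range)) if tilt_range else 0.0
        sz = float(rng.uniform(-max_shift_A, max_shift_A)) if max_shift_A else 0.0
        sx = float(rng.uniform(-max_shift_A, max_shift_A)) if max_shift_A else 0.0
        if defocus_range is not None:
            defocus = float(rng.uniform(*defocus_range))
        else:
            defocus = ctf.defocus
        img = project(volume, azimuth, tilt, shifts=(sz, sx))
        h = ctf_2d((box, box), ctf, defocus_um=defocus)
        img = np.real(np.fft.ifft2(np.fft.fft2(img) * h))
        if np.isfinite(snr):
            sigma = math.sqrt(float(np.var(img)) / snr)
            img = img + rng.normal(0.0, sigma, img.shape)
        images[i] = img.astype(np.float32)
        rows.append(
            {
                "id": i,
                "azimuth_deg": azimuth,
                "tilt_deg": tilt,
                "in_plane_deg": 0.0,
                "shift_x_A": sx,
                "shift_y_A": sz,
                "defocus_um": defocus,
                "tube_id": 0,
                "seed": seed,
            }
        )
    meta = pd.DataFrame(rows, columns=METADATA_COLUMNS)
    return SegmentStack(images, ctf.pixel_size, meta, ctf)


def lattice_projection_image(
    model: TubeModel,
    pixel_size: float,
    shape: tuple[int, int],
    atom_sigma: float = 5.0,
    with_membrane: bool = False,
) -> np.ndarray:
    """Noise-free projection of the helical lattice onto the (z, x) plane.

    Cheap analytic rendering (no 3D volume): every protomer pseudo-atom of
    every symmetry copy contributes a projected 2D Gaussian.  Used for
    layer-line oracles where only axial frequencies matter.
    """
    ny, nx = shape
    img = np.zeros(shape, dtype=np.float64)
    cz, cx = ny // 2, nx // 2
    half_len = ny * pixel_size / 2
    k_max = int(math.floor((half_len + 50) / model.symmetry.rise))
    pts = []
    wts = []
    for k in range(-k_max, k_max + 1):
        p, w = _protomer_world_coords(model, k)
        pts.append(p)
        wts.append(w)
    pts = np.concatenate(pts)
    wts = np.concatenate(wts)
    s_px = atom_sigma / pixel_size
    half = int(math.ceil(3.5 * s_px))
    win = np.arange(-half, half + 1)
    amp = 1.0 / (2 * math.pi * atom_sigma**2)
    for (x, y, z), w in zip(pts, wts):
        px, pz = x / pixel_size + cx, z / pixel_size + cz
        ix, iz = int(round(px)), int(round(pz))
        if not (-half <= ix <= nx + half and -half <= iz <= ny + half):
            continue
        gx = np.exp(-0.5 * ((ix + win - px) / s_px) ** 2)
        gz = np.exp(-0.5 * ((iz + win - pz) / s_px) ** 2)
        zs = slice(max(iz - half, 0), min(iz + half + 1, ny))
        xs = slice(max(ix - half, 0), min(ix + half + 1, nx))
        oz = slice(zs.start - (iz - half), zs.stop - (iz - half))
        ox = slice(xs.start - (ix - half), xs.stop - (ix - half))
        img[zs, xs] += w * amp * gz[oz][:, None] * gx[ox][None, :]
    if with_membrane:
        xx = (np.arange(nx) - cx) * pixel_size
        prof = np.zeros(nx)
        sig = 8.0 / 2.355
        for radius in (
            model.geometry.inner_leaflet_radius,
            model.geometry.outer_leaflet_radius,
        ):
            # projection of a thin shell: 2R/sqrt(R^2-x^2), smoothed
            with np.errstate(invalid="ignore", divide="ignore"):
                p = np.where(
                    np.abs(xx) < radius - 1,
                    2 * radius / np.sqrt(np.maximum(radius**2 - xx**2, 1.0)),
                    0.0,
                )
            prof += np.convolve(p, np.exp(-0.5 * (np.arange(-8, 9) / sig) ** 2), "same")
        img += model.leaflet_amplitude * prof[None, :]
    return img


# ---------------------------------------------------------------------------
# STEM dark-field simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StemRod:
    """A straight vertical rod in a STEM field.

    x_px: center column; y0_px/y1_px: axial extent (rows); line_density in
    kDa/Å; width_A: physical diameter (projected as a semicircular
    profile); kind: 'tube' or 'calibrant'.  occupancy_sd adds per-stretch
    packing variance (fractional sd of the local line density) for tubes.
    """

    x_px: float
    y0_px: int
    y1_px: int
    line_density: float
    kind: str = "tube"
    width_A: float = 300.0
    occupancy_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.line_density <= 0:
            raise ValueError("line_density must be > 0")
        if self.y1_px <= self.y0_px:
            raise ValueError("empty rod extent")
        if self.kind not in ("tube", "calibrant"):
            raise ValueError("kind must be 'tube' or 'calibrant'")


@dataclass
class StemField:
    """Dark-field STEM image with known ground-truth rods."""

    image: np.ndarray  # counts
    pixel_size_nm: float
    rods: list[StemRod]
    dose: float  # incident counts per Å^2
    mass_contrast: float  # counts per kDa per unit dose
    background: float  # scattered fraction of the dose per Å^2

    def __post_init__(self) -> None:
        if not (0.5 <= self.pixel_size_nm <= 4.0):
            raise ValueError("pixel_size_nm outside plausible range")
        if np.any(self.image < 0):
            raise ValueError("counts must be >= 0")

    @property
    def pixel_size_A(self) -> float:
        return self.pixel_size_nm * 10.0


def _rod_profile(width_px: float, x_center: float, n_cols: int) -> np.ndarray:
    """Projected semicircular cross-profile, unit sum, anti-aliased."""
    sub = 8
    xs = (np.arange(n_cols * sub) + 0.5) / sub - 0.5
    half = width_px / 2.0
    vals = np.sqrt(np.maximum(half**2 - (xs - x_center) ** 2, 0.0))
    prof = vals.reshape(n_cols, sub).mean(axis=1)
    s = prof.sum()
    return prof / s if s > 0 else prof


def render_stem_field(
    rods: list[StemRod],
    dose: float,
    field: int,
    seed: int,
    pixel_size_nm: float = 2.0,
    mass_contrast: float = 0.05,
    background: float = 0.02,
    occupancy_stretch_A: float = 100.0,
    poisson_noise: bool = True,
) -> StemField:
    """Simulate a dark-field STEM micrograph.

    Expected counts per pixel = dose·A_px·background + dose·mass_contrast·
    (projected mass in the pixel); Poisson noise on top.  Tube rods with
    occupancy_sd > 0 get per-axial-stretch occupancy jitter emulating
    non-uniform lattice packing.  Pure function of (parameters, seed).
    """
    if dose <= 0:
        raise ValueError("dose must be > 0")
    rng = np.random.default_rng(seed)
    px_A = pixel_size_nm * 10.0
    expected = np.full((field, field), dose * background * px_A**2, dtype=np.float64)
    for rod in rods:
        prof = _rod_profile(rod.width_A / px_A, rod.x_px, field)
        rows = np.arange(rod.y0_px, min(rod.y1_px, field))
        occ = np.ones(len(rows))
        if rod.occupancy_sd > 0:
            stretch_px = max(1, int(round(occupancy_stretch_A / px_A)))
            n_stretch = int(np.ceil(len(rows) / stretch_px))
            jitter = np.clip(
                1.0 + rod.occupancy_sd * rng.standard_normal(n_stretch), 0.1, None
            )
            occ = np.repeat(jitter, stretch_px)[: len(rows)]
        mass_per_row = rod.line_density * px_A * occ  # kDa in each pixel row
        expected[rows] += dose * mass_contrast * mass_per_row[:, None] * prof[None, :]
    image = rng.poisson(expected).astype(np.float64) if poisson_noise else expected
    return StemField(image, pixel_size_nm, list(rods), dose, mass_contrast, background)
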