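"""Iterative helical real-space reconstruction (IHRSR-style).

The cycle is the classic one: project the current volume on an orientation
grid, assign each segment the best-matching reference by normalized
cross-correlation, back-project, refine the helical symmetry by local
search on the unsymmetrized volume ("hsearch"), impose the symmetry, and
repeat on a coarse-to-fine schedule (binned images and a coarse azimuth
grid first).  Resolution is estimated by Fourier shell correlation of
independently symmetrized half-set maps at the 0.5 criterion.

Conventions: volumes are (z, y, x) arrays, helical axis = z, beam along y,
images are (z, x); rotations are right-handed, angles in degrees, lengths
in Å; the rotation center is voxel ``box // 2`` on every axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numba
import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from .lattice import HelicalSymmetry, LayerLine, layer_lines
from .segments import SegmentStack

logger = logging.getLogger(__name__)

__all__ = [
    "DensityMap",
    "OrientationAssignment",
    "HsearchResult",
    "ReconstructionResult",
    "Phase",
    "project",
    "backproject",
    "make_reference_library",
    "projection_match",
    "match_stack",
    "symmetrize",
    "hsearch",
    "run_ihrsr",
    "fsc",
    "resolution_at",
    "amplitude_correct",
    "index_layer_lines",
    "rank_candidates",
    "noise_cylinder",
]


@dataclass
class DensityMap:
    """Cubic voxel grid with physical voxel size (Å); helical axis = z."""

    grid: np.ndarray
    voxel_size: float

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float32)
        if self.grid.ndim != 3 or len(set(self.grid.shape)) != 1:
            raise ValueError("grid must be a cubic 3D array")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be > 0")

    @property
    def box(self) -> int:
        return self.grid.shape[0]

    @property
    def center(self) -> int:
        return self.box // 2


@dataclass(frozen=True)
class OrientationAssignment:
    """Best-matching orientation of one segment against a reference grid."""

    azimuth: float  # deg about z
    tilt: float  # deg out-of-plane (about x)
    in_plane: float  # deg in image plane
    shift_z: float  # Å, reference shifted by this matches the segment
    shift_x: float  # Å
    score: float  # normalized cross-correlation in [-1, 1]


@dataclass(frozen=True)
class HsearchResult:
    symmetry: HelicalSymmetry
    score: float
    flat: bool = False  # score surface uninformative; symmetry == init


@dataclass
class ReconstructionResult:
    map: DensityMap
    symmetry: HelicalSymmetry
    fsc: pd.DataFrame  # columns freq_invA, fsc
    resolution_A: float
    iterations: int
    trajectory: pd.DataFrame  # iter, rise_A, twist_deg, mean_score
    diverged: bool = False


# ---------------------------------------------------------------------------
# rotation matrices in (z, y, x) component order
# ---------------------------------------------------------------------------

def _rot_z(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[1, 0, 0], [0, c, s], [0, -s, c]], dtype=float)


def _rot_x(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, s, 0], [-s, c, 0], [0, 0, 1]], dtype=float)


def _rot_y(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)


def _orientation_matrix(azimuth: float, tilt: float, in_plane: float) -> np.ndarray:
    """Rotation applied to the object: azimuth about z, then tilt about x,
    then in-plane about the beam (y)."""
    return _rot_y(in_plane) @ _rot_x(tilt) @ _rot_z(azimuth)


def _gather_map(shape: tuple[int, int, int], azimuth, tilt, in_plane):
    """(matrix, offset) such that rotated(p) = map[M p + offset]."""
    m = _orientation_matrix(azimuth, tilt, in_plane).T  # inverse rotation
    c = np.array([shape[0] // 2] * 3, dtype=float)
    return m, c - m @ c


def fourier_shift_image(image: np.ndarray, shift_z: float, shift_x: float) -> np.ndarray:
    """Shift an image by (shift_z, shift_x) pixels via the Fourier transform."""
    f = np.fft.fft2(image)
    return np.real(
        np.fft.ifft2(ndi.fourier_shift(f, (shift_z, shift_x)))
    ).astype(image.dtype)


def project(
    dmap: DensityMap,
    azimuth: float,
    tilt: float = 0.0,
    in_plane: float = 0.0,
    shifts: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Line-integral projection along the beam after rotating the map.

    Returns a (box, box) image in (z, x) with pixel values equal to the
    integral of density along y (Å units).  `shifts` = (Δz, Δx) in Å is
    applied to the projected image by Fourier shift, so `project` and
    `backproject` remain exact adjoints.
    """
    m, off = _gather_map(dmap.grid.shape, azimuth, tilt, in_plane)
    rot = ndi.affine_transform(
        dmap.grid.astype(np.float64), m, off, order=1, mode="grid-constant",
        cval=0.0, prefilter=False,
    )
    img = rot.sum(axis=1) * dmap.voxel_size
    if shifts != (0.0, 0.0):
        img = fourier_shift_image(
            img, shifts[0] / dmap.voxel_size, shifts[1] / dmap.voxel_size
        )
    return img


@numba.njit(cache=True)
def _scatter_kernel(acc, wacc, image, m, off, voxel):  # pragma: no cover
    nz, ny, nx = acc.shape
    for pz in range(nz):
        for py in range(ny):
            base_z = m[0, 0] * pz + m[0, 1] * py + off[0]
            base_y = m[1, 0] * pz + m[1, 1] * py + off[1]
            base_x = m[2, 0] * pz + m[2, 1] * py + off[2]
            for px in range(nx):
                val = image[pz, px] * voxel
                qz = base_z + m[0, 2] * px
                qy = base_y + m[1, 2] * px
                qx = base_x + m[2, 2] * px
                iz0 = int(np.floor(qz))
                iy0 = int(np.floor(qy))
                ix0 = int(np.floor(qx))
                fz = qz - iz0
                fy = qy - iy0
                fx = qx - ix0
                for dz in range(2):
                    iz = iz0 + dz
                    if iz < 0 or iz >= nz:
                        continue
                    wz = fz if dz else 1.0 - fz
                    for dy in range(2):
                        iy = iy0 + dy
                        if iy < 0 or iy >= ny:
                            continue
                        wy = fy if dy else 1.0 - fy
                        for dx in range(2):
                            ix = ix0 + dx
                            if ix < 0 or ix >= nx:
                                continue
                            w = wz * wy * (fx if dx else 1.0 - fx)
                            acc[iz, iy, ix] += w * val
                            wacc[iz, iy, ix] += w


def _scatter_one(
    acc: np.ndarray,
    wacc: np.ndarray,
    image: np.ndarray,
    azimuth: float,
    tilt: float,
    in_plane: float,
    voxel_size: float,
) -> None:
    """Adjoint of `project` for one image: trilinear scatter-add."""
    m, off = _gather_map(acc.shape, azimuth, tilt, in_plane)
    _scatter_kernel(
        acc, wacc, np.ascontiguousarray(image, dtype=np.float64), m, off,
        voxel_size,
    )


def _ramp_filter(image: np.ndarray) -> np.ndarray:
    """1D ramp (|f|) filter along x — the R-weighting of parallel-beam
    filtered back-projection about the z axis."""
    n = image.shape[1]
    f = np.abs(np.fft.rfftfreq(n))
    return np.fft.irfft(np.fft.rfft(image, axis=1) * f[None, :], n=n, axis=1)


def backproject(
    segments: np.ndarray | SegmentStack,
    assignments: list[OrientationAssignment],
    box: int,
    voxel_size: float | None = None,
    normalize: bool = True,
    half_sets: bool = False,
    weighting: str = "ramp",
):
    """Real-space back-projection of segments at assigned orientations.

    ``weighting='ramp'`` (default) applies the R-weighting of filtered
    back-projection (1D ramp along x per z-row) before scattering, which
    undoes the 1/ρ low-frequency pile-up of plain back-projection.  With
    ``weighting='none'`` and ``normalize=False`` and zero shifts this is
    the exact adjoint of `project` (trilinear scatter with identical
    mapping).  Shifts recorded in the assignments are removed from each
    image by Fourier shift before scattering.  ``half_sets=True``
    additionally returns even/odd-index half volumes for FSC.
    """
    if weighting not in ("ramp", "none"):
        raise ValueError("weighting must be 'ramp' or 'none'")
    if isinstance(segments, SegmentStack):
        if voxel_size is None:
            voxel_size = segments.pixel_size
        images = segments.images
    else:
        images = np.asarray(segments)
        if images.ndim == 2:
            images = images[None]
    if voxel_size is None:
        raise ValueError("voxel_size required for raw arrays")
    if len(images) == 0:
        raise ValueError("no segments to backproject")
    if len(assignments) != len(images):
        raise ValueError("one assignment per segment required")

    shape = (box, box, box)
    accs = [np.zeros(shape), np.zeros(shape)]
    waccs = [np.zeros(shape), np.zeros(shape)]
    for i, (img, a) in enumerate(zip(images, assignments)):
        img = np.asarray(img, dtype=np.float64)
        if a.shift_z != 0.0 or a.shift_x != 0.0:
            img = fourier_shift_image(
                img, -a.shift_z / voxel_size, -a.shift_x / voxel_size
            )
        if weighting == "ramp":
            img = _ramp_filter(img)
        _scatter_one(
            accs[i % 2], waccs[i % 2], img, a.azimuth, a.tilt, a.in_plane,
            voxel_size,
        )
    acc = accs[0] + accs[1]
    wacc = waccs[0] + waccs[1]
    eps = 1e-8

    def _norm(a, w):
        out = a / np.maximum(w, eps)
        out[w < 0.05] = 0.0
        return DensityMap(out, voxel_size)

    full = _norm(acc, wacc) if normalize else DensityMap(acc, voxel_size)
    if half_sets:
        return full, _norm(accs[0], waccs[0]), _norm(accs[1], waccs[1])
    return full


def make_reference_library(
    dmap: DensityMap,
    azimuth_step: float,
    tilt_range: float = 0.0,
    tilt_step: float = 1.0,
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Project the map on an (azimuth, tilt) grid.

    Azimuths cover [0, 360) at `azimuth_step`; tilts are inclusive
    −tilt_range…+tilt_range at `tilt_step` (a single 0 when tilt_range=0).
    Returns (references (n, box, box), [(azimuth, tilt), ...]).
    """
    if azimuth_step <= 0 or tilt_step <= 0:
        raise ValueError("steps must be > 0")
    azimuths = np.arange(0.0, 360.0, azimuth_step)
    if tilt_range > 0:
        tilts = np.arange(-tilt_range, tilt_range + tilt_step / 2, tilt_step)
    else:
        tilts = np.array([0.0])
    orientations = [(float(a), float(t)) for a in azimuths for t in tilts]
    refs = np.stack([project(dmap, a, t) for a, t in orientations])
    return refs.astype(np.float32), orientations


def _normalize_images(images: np.ndarray) -> np.ndarray:
    flat = images.reshape(len(images), -1).astype(np.float64)
    flat = flat - flat.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(flat, axis=1)
    norm[norm == 0] = 1.0
    return (flat / norm[:, None]).reshape(images.shape)


def _parabolic(y0: float, y1: float, y2: float) -> float:
    """Sub-sample offset of a parabola through three equidistant points."""
    denom = y0 - 2 * y1 + y2
    if denom >= 0 or abs(denom) < 1e-12:
        return 0.0
    return float(np.clip(0.5 * (y0 - y2) / denom, -0.5, 0.5))


def match_stack(
    stack: SegmentStack,
    references: np.ndarray,
    orientations: list[tuple[float, float]],
    max_shift_A: float = 12.0,
) -> list[OrientationAssignment]:
    """Assign every segment its best reference and sub-pixel shift.

    Normalized cross-correlation over circular translations (limited to
    ±max_shift), grid search over all references; ties resolved by the
    first reference in grid order.
    """
    box = stack.box
    max_shift = max(1, int(round(max_shift_A / stack.pixel_size)))
    refs = _normalize_images(np.asarray(references, dtype=np.float64))
    segs = _normalize_images(stack.images)
    ref_f = np.conj(np.fft.rfft2(refs))
    # window of allowed circular shifts
    sl = np.r_[0 : max_shift + 1, box - max_shift : box]
    out: list[OrientationAssignment] = []
    for seg in segs:
        seg_f = np.fft.rfft2(seg)
        cc = np.fft.irfft2(seg_f[None] * ref_f, s=(box, box))
        win = cc[:, sl][:, :, sl]
        k = int(np.argmax(win))
        r, iz, ix = np.unravel_index(k, win.shape)
        tz, tx = int(sl[iz]), int(sl[ix])
        # parabolic sub-pixel refinement on the circular correlation map
        c = cc[r]
        dz = _parabolic(c[(tz - 1) % box, tx], c[tz, tx], c[(tz + 1) % box, tx])
        dx = _parabolic(c[tz, (tx - 1) % box], c[tz, tx], c[tz, (tx + 1) % box])
        # centered shift in pixels: positive = segment content sits at +z/+x
        # relative to the reference, i.e. reference shifted by +s matches
        sz = (tz + dz + box // 2) % box - box // 2
        sx = (tx + dx + box // 2) % box - box // 2
        az, tilt = orientations[r]
        out.append(
            OrientationAssignment(
                azimuth=az,
                tilt=tilt,
                in_plane=0.0,
                shift_z=sz * stack.pixel_size,
                shift_x=sx * stack.pixel_size,
                score=float(c[tz, tx]),
            )
        )
    return out


def projection_match(
    segment: np.ndarray,
    references: np.ndarray,
    orientations: list[tuple[float, float]],
    pixel_size: float,
    max_shift_A: float = 12.0,
) -> OrientationAssignment:
    """Match a single segment (see `match_stack`)."""
    stack = SegmentStack(np.asarray(segment)[None], pixel_size)
    return match_stack(stack, references, orientations, max_shift_A)[0]


# ---------------------------------------------------------------------------
# symmetry operations
# ---------------------------------------------------------------------------

def _helical_transform(
    grid: np.ndarray, voxel_size: float, twist: float, rise_A: float
) -> np.ndarray:
    """Sample the grid at points rotated by −twist and shifted by −rise.

    For a density with subunit k at (k·twist, k·rise) this maps subunit
    k+1 onto subunit k, i.e. it is the symmetry operator of the lattice.
    """
    m = _rot_z(-twist)
    c = np.array([grid.shape[0] // 2] * 3, dtype=float)
    shift = np.array([rise_A / voxel_size, 0.0, 0.0])
    off = m @ (-shift - c) + c
    return ndi.affine_transform(
        grid, m, off, order=1, mode="grid-constant", cval=0.0, prefilter=False
    )


def symmetrize(
    dmap: DensityMap, sym: HelicalSymmetry, k_range: int | None = None
) -> DensityMap:
    """Impose helical symmetry by averaging over lattice translations.

    Each voxel is replaced by the mean over k = −K…K of the map sampled at
    (rotate by k·twist, shift by k·rise); axial slices that a given k
    would sample from outside the box are excluded from that k's average.
    """
    nz = dmap.box
    extent = nz * dmap.voxel_size
    if sym.rise >= extent:
        raise ValueError("rise exceeds the box extent")
    if k_range is None:
        k_range = min(int((extent / 4) / sym.rise), 40)
    grid = dmap.grid.astype(np.float64)
    acc = grid.copy()
    weight = np.ones(nz)
    z = np.arange(nz)
    for k in range(1, k_range + 1):
        for s in (+1, -1):
            sk = s * k
            sampled = _helical_transform(
                grid, dmap.voxel_size, sk * sym.twist, sk * sym.rise
            )
            zsrc = z - sk * sym.rise / dmap.voxel_size
            ok = (zsrc >= 0) & (zsrc <= nz - 1)
            acc[ok] += sampled[ok]
            weight[ok] += 1.0
    out = acc / weight[:, None, None]
    return DensityMap(out, dmap.voxel_size)


def _cyl_mask(
    box: int, voxel: float, r_in_A: float, r_out_A: float, z_margin_A: float
) -> np.ndarray:
    c = box // 2
    zz, yy, xx = np.indices((box, box, box))
    r = np.hypot(yy - c, xx - c) * voxel
    zok = np.abs(zz - c) * voxel <= box * voxel / 2 - z_margin_A
    return (r >= r_in_A) & (r <= r_out_A) & zok


def _masked_ncc(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    x = a[mask].astype(np.float64)
    y = b[mask].astype(np.float64)
    x -= x.mean()
    y -= y.mean()
    d = np.linalg.norm(x) * np.linalg.norm(y)
    if d == 0:
        return 0.0
    return float(np.dot(x, y) / d)


def hsearch(
    dmap: DensityMap,
    init: HelicalSymmetry,
    window: tuple[float, float] = (0.5, 4.0),
    coarse_step: tuple[float, float] = (0.1, 0.5),
    mask_radii_A: tuple[float, float] | None = None,
    n_refine: int = 2,
    k_steps: tuple[int, ...] = (2, 6, 12),
) -> HsearchResult:
    """Locally refine (rise, twist) by maximizing self-consistency.

    The score of a candidate symmetry is the normalized cross-correlation,
    inside a cylindrical shell mask, between the map and its copies
    transformed by `k_steps` symmetry steps (averaged).  Multi-step
    transforms amplify the sensitivity to the rise, which a single step
    barely constrains when the lattice strands are nearly continuous.
    The axial mask margin excludes every slice a k-step transform would
    sample from outside the box, so edge truncation cannot bias the
    search.  Coarse grid search over the window, then progressively finer
    grids, then a final parabolic fit.  Deterministic; a flat coarse
    surface returns the initial values with ``flat=True``.
    """
    if window[0] < 0 or window[1] < 0:
        raise ValueError("window must be non-negative")
    box, voxel = dmap.box, dmap.voxel_size
    if mask_radii_A is None:
        half = box * voxel / 2
        mask_radii_A = (0.15 * half, 0.94 * half)
    k_max = max(k_steps)
    z_margin = k_max * (init.rise + window[0]) + 2 * voxel
    mask = _cyl_mask(box, voxel, *mask_radii_A, z_margin)
    if not mask.any():
        raise ValueError("box too short for the requested k_steps")
    grid = dmap.grid.astype(np.float64)

    def score(rise: float, twist: float) -> float:
        vals = [
            _masked_ncc(
                grid, _helical_transform(grid, voxel, -k * twist, -k * rise), mask
            )
            for k in k_steps
        ]
        return float(np.mean(vals))

    if window == (0.0, 0.0):
        return HsearchResult(init, score(init.rise, init.twist))

    def grid_search(center, steps, half_counts):
        rises = center[0] + steps[0] * np.arange(-half_counts[0], half_counts[0] + 1)
        twists = center[1] + steps[1] * np.arange(-half_counts[1], half_counts[1] + 1)
        rises = rises[rises > 0.05]
        table = np.array([[score(r, t) for t in twists] for r in rises])
        i, j = np.unravel_index(np.argmax(table), table.shape)
        return rises, twists, table, i, j

    h_r = max(1, int(np.ceil(window[0] / coarse_step[0])))
    h_t = max(1, int(np.ceil(window[1] / coarse_step[1])))
    rises, twists, table, i, j = grid_search(
        (init.rise, init.twist), coarse_step, (h_r, h_t)
    )
    if table.max() - table.min() < 1e-6:
        logger.warning("hsearch: flat score surface, returning initial symmetry")
        return HsearchResult(init, float(table.max()), flat=True)
    lo = (init.rise - window[0], init.twist - window[1])
    hi = (init.rise + window[0], init.twist + window[1])

    def clamp(b):
        return (
            float(np.clip(b[0], lo[0], hi[0])),
            float(np.clip(b[1], lo[1], hi[1])),
        )

    best = clamp((float(rises[i]), float(twists[j])))
    steps = list(coarse_step)
    for _ in range(n_refine):
        steps = [steps[0] / 4, steps[1] / 4]
        rises, twists, table, i, j = grid_search(best, steps, (3, 3))
        best = clamp((float(rises[i]), float(twists[j])))
    # parabolic interpolation along each axis at the optimum
    dr = dt = 0.0
    if 0 < i < len(rises) - 1:
        dr = -_parabolic(-table[i - 1, j], -table[i, j], -table[i + 1, j])
    if 0 < j < len(twists) - 1:
        dt = -_parabolic(-table[i, j - 1], -table[i, j], -table[i, j + 1])
    rise = best[0] + dr * steps[0]
    twist = best[1] + dt * steps[1]
    return HsearchResult(HelicalSymmetry(rise, twist), float(table[i, j]))


# ---------------------------------------------------------------------------
# FSC and amplitude correction
# ---------------------------------------------------------------------------

def _shell_indices(shape: tuple[int, ...], voxel: float):
    freqs = [np.fft.fftfreq(n, d=voxel) for n in shape]
    f2 = np.zeros(shape)
    for ax, f in enumerate(freqs):
        sh = [1] * len(shape)
        sh[ax] = -1
        f2 = f2 + f.reshape(sh) ** 2
    fmag = np.sqrt(f2)
    df = 1.0 / (shape[0] * voxel)
    shell = np.round(fmag / df).astype(np.int64)
    return shell, df


def fsc(map_a: DensityMap, map_b: DensityMap) -> pd.DataFrame:
    """Fourier shell correlation between two maps on the same grid."""
    if map_a.grid.shape != map_b.grid.shape or map_a.voxel_size != map_b.voxel_size:
        raise ValueError("maps must share the same grid")
    fa = np.fft.fftn(map_a.grid.astype(np.float64))
    fb = np.fft.fftn(map_b.grid.astype(np.float64))
    shell, df = _shell_indices(map_a.grid.shape, map_a.voxel_size)
    n_shell = map_a.box // 2 + 1
    sel = shell < n_shell
    num = np.bincount(shell[sel], weights=np.real(fa * np.conj(fb))[sel], minlength=n_shell)
    da = np.bincount(shell[sel], weights=np.abs(fa[sel]) ** 2, minlength=n_shell)
    db = np.bincount(shell[sel], weights=np.abs(fb[sel]) ** 2, minlength=n_shell)
    denom = np.sqrt(da * db)
    vals = np.divide(num, denom, out=np.ones_like(num), where=denom > 0)
    return pd.DataFrame(
        {"freq_invA": np.arange(n_shell) * df, "fsc": vals}
    )


def resolution_at(curve: pd.DataFrame, threshold: float = 0.5) -> float:
    """Resolution (Å) at the first downward crossing of the threshold.

    Linear interpolation between shells; returns the Nyquist resolution if
    the curve never drops below the threshold.
    """
    f = curve["freq_invA"].to_numpy()
    v = curve["fsc"].to_numpy()
    for i in range(1, len(v)):
        if v[i] < threshold <= v[i - 1]:
            frac = (v[i - 1] - threshold) / (v[i - 1] - v[i])
            fc = f[i - 1] + frac * (f[i] - f[i - 1])
            return float(1.0 / fc) if fc > 0 else np.inf
    return float(1.0 / f[-1]) if f[-1] > 0 else np.inf


def amplitude_correct(dmap: DensityMap, reference: DensityMap) -> DensityMap:
    """Scale the map's rotationally averaged Fourier amplitudes to match a
    reference map, leaving all phases untouched."""
    if dmap.grid.shape != reference.grid.shape:
        raise ValueError("maps must share the same grid")
    f = np.fft.fftn(dmap.grid.astype(np.float64))
    fr = np.fft.fftn(reference.grid.astype(np.float64))
    shell, _ = _shell_indices(dmap.grid.shape, dmap.voxel_size)
    n_shell = shell.max() + 1
    counts = np.bincount(shell.ravel(), minlength=n_shell)
    amp = np.bincount(shell.ravel(), weights=np.abs(f).ravel(), minlength=n_shell) / counts
    amp_r = np.bincount(shell.ravel(), weights=np.abs(fr).ravel(), minlength=n_shell) / counts
    scale = np.ones(n_shell)
    ok = amp > 0
    if not ok.all():
        logger.warning("amplitude_correct: %d empty shells skipped", (~ok).sum())
    scale[ok] = amp_r[ok] / amp[ok]
    out = np.real(np.fft.ifftn(f * scale[shell]))
    return DensityMap(out, dmap.voxel_size)


# ---------------------------------------------------------------------------
# initial model and the full IHRSR loop
# ---------------------------------------------------------------------------

def noise_cylinder(
    box: int,
    voxel_size: float,
    diameter_A: float,
    seed: int = 0,
    lowpass_A: float = 25.0,
) -> DensityMap:
    """Gaussian-noise-filled cylinder used as the reference-free start.

    The noise is low-pass filtered to a correlation length of
    ``lowpass_A`` (0 disables).  Giving the initial model features at the
    lattice scale makes the first rounds of projection matching
    discriminative; with white voxel noise the azimuthal degeneracy of a
    tube breaks far more slowly.
    """
    rng = np.random.default_rng(seed)
    c = box // 2
    yy, xx = np.indices((box, box))
    r = np.hypot(yy - c, xx - c) * voxel_size
    mask = (r <= diameter_A / 2).astype(np.float64)
    grid = rng.standard_normal((box, box, box))
    if lowpass_A > 0:
        grid = ndi.gaussian_filter(grid, lowpass_A / (2.355 * voxel_size))
    return DensityMap(grid * mask[None], voxel_size)


def _bin_stack(stack: SegmentStack, factor: int) -> SegmentStack:
    if factor == 1:
        return stack
    n, ny, nx = stack.images.shape
    ny2, nx2 = ny // factor, nx // factor
    imgs = stack.images[:, : ny2 * factor, : nx2 * factor]
    imgs = imgs.reshape(n, ny2, factor, nx2, factor).mean(axis=(2, 4))
    return SegmentStack(imgs, stack.pixel_size * factor, stack.metadata, stack.ctf)


def _resample_map(dmap: DensityMap, box: int, voxel: float) -> DensityMap:
    """Resample a map onto a new cubic grid, preserving the center voxel."""
    zoom = dmap.voxel_size / voxel
    c_old = dmap.box // 2
    c_new = box // 2
    m = np.eye(3) / zoom
    off = np.full(3, c_old - c_new / zoom)
    out = ndi.affine_transform(
        dmap.grid.astype(np.float64), m, off, output_shape=(box, box, box),
        order=1, mode="grid-constant", cval=0.0, prefilter=False,
    )
    return DensityMap(out, voxel)


def _soft_cyl_mask(box: int, voxel: float, diameter_A: float) -> np.ndarray:
    c = box // 2
    yy, xx = np.indices((box, box))
    r = np.hypot(yy - c, xx - c) * voxel
    edge = 10.0  # Å soft edge
    m = np.clip((diameter_A / 2 + edge - r) / edge, 0.0, 1.0)
    return m[None].astype(np.float64)


def estimate_initial_symmetry(
    stack: SegmentStack,
    init: HelicalSymmetry,
    window: tuple[float, float] = (0.6, 4.0),
    pad: int = 4,
    spacing_range_A: tuple[float, float] = (25.0, 100.0),
    min_prominence: float = 0.3,
    tilt_range_deg: float = 10.0,
) -> HelicalSymmetry:
    """Initial helical parameters from the stack's own layer lines.

    The axially collapsed power spectra of all segments (zero-padded for
    sub-pixel line positions) are averaged, divided by a median-filtered
    baseline, and the two strongest peaks in `spacing_range_A` (between
    the pitch line and the equator) are indexed as adjacent-Bessel-order
    moiré families via `index_layer_lines`.  Among the resulting
    candidates, those inside the trust window around `init` are kept and
    the one closest to `init` is returned; if none can be indexed the
    initial values are returned unchanged.

    Out-of-plane tilt foreshortens axial spacings by cos(tilt); measured
    spacings are divided by the mean foreshortening of a uniform
    ±`tilt_range_deg` tilt distribution (sin r / r) before inversion.
    The correction moves the rise by ~0.5 % at ±10° and leaves the twist
    unchanged (the inversion's twist is scale-invariant).
    """
    from scipy.ndimage import median_filter
    from scipy.signal import find_peaks

    box = stack.box
    spec = np.zeros(box * pad)
    for img in stack.images:
        padded = np.zeros((box * pad, box))
        padded[:box] = img - img.mean()
        spec += (np.abs(np.fft.fft2(padded)) ** 2).sum(axis=1)
    spec = spec[: box * pad // 2]
    df = 1.0 / (box * pad * stack.pixel_size)
    base = median_filter(spec, size=8 * pad - 1)
    ratio = spec / np.maximum(base, 1e-300)
    pk, props = find_peaks(ratio, prominence=min_prominence)
    found = []
    for i, p in enumerate(pk):
        if p <= 0 or p >= len(ratio) - 1:
            continue
        y0, y1, y2 = ratio[p - 1 : p + 2]
        denom = y0 - 2 * y1 + y2
        dp = 0.5 * (y0 - y2) / denom if denom < 0 else 0.0
        freq = (p + float(np.clip(dp, -0.5, 0.5))) * df
        spacing = 1.0 / freq
        if spacing_range_A[0] < spacing < spacing_range_A[1]:
            found.append((spacing, props["prominences"][i]))
    found.sort(key=lambda t: -t[1])
    if len(found) < 2:
        logger.warning(
            "initial-symmetry indexing found %d usable layer lines; "
            "keeping the provided initial values", len(found),
        )
        return init
    r = np.radians(tilt_range_deg)
    mean_cos = float(np.sin(r) / r) if r > 0 else 1.0
    spacings = (found[0][0] / mean_cos, found[1][0] / mean_cos)
    cands = [
        c
        for c in index_layer_lines(spacings)
        if abs(c.rise - init.rise) <= window[0]
        and abs(abs(c.twist) - abs(init.twist)) <= window[1]
    ]
    if not cands:
        logger.warning(
            "no indexing of layer lines %.1f/%.1f Å falls inside the trust "
            "window; keeping the provided initial values", *spacings,
        )
        return init
    best = min(
        cands,
        key=lambda c: (c.rise - init.rise) ** 2 / window[0] ** 2
        + (abs(c.twist) - abs(init.twist)) ** 2 / window[1] ** 2,
    )
    logger.info(
        "indexed layer lines %.1f/%.1f Å -> initial symmetry "
        "rise %.3f Å twist %.3f°", spacings[0], spacings[1], best.rise, best.twist,
    )
    return best


@dataclass(frozen=True)
class Phase:
    """One stage of the coarse-to-fine refinement schedule.

    ``refine_symmetry`` controls whether hsearch runs during the phase;
    binned maps bias the (rise, twist) optimum, so by default only the
    unbinned refinement phase searches the symmetry — the coarse phase
    imposes the (indexed) starting values, as in the original protocol.
    """

    n_iter: int
    binning: int = 1
    azimuth_step: float = 4.0
    tilt_range: float = 0.0
    tilt_step: float = 1.0
    refine_symmetry: bool = True


DEFAULT_SCHEDULE = (
    Phase(n_iter=4, binning=2, azimuth_step=4.0, refine_symmetry=False),
    Phase(n_iter=1, binning=1, azimuth_step=4.0, tilt_range=10.0,
          tilt_step=5.0, refine_symmetry=False),
    Phase(n_iter=1, binning=1, azimuth_step=4.0, tilt_range=10.0, tilt_step=5.0),
)


def run_ihrsr(
    stack: SegmentStack,
    init_sym: HelicalSymmetry,
    schedule: tuple[Phase, ...] = DEFAULT_SCHEDULE,
    seed: int = 0,
    diameter_A: float | None = None,
    hsearch_window: tuple[float, float] = (0.5, 4.0),
    refine_window: tuple[float, float] = (0.1, 0.3),
    compute_fsc: bool = True,
    reindex_init: bool = True,
    hsearch_start: int = 3,
) -> ReconstructionResult:
    """Full IHRSR loop: match → backproject → hsearch → symmetrize.

    Following the original recipe, the initial helical parameters are not
    trusted blindly: with ``reindex_init`` the layer lines of the segment
    spectra are indexed first (`estimate_initial_symmetry`) and the
    indexing closest to `init_sym` replaces it, using `hsearch_window` as
    the trust region around the provided initial values.  Early
    iterations impose the indexed symmetry unchanged while the map
    bootstraps from the noise cylinder; from iteration ``hsearch_start``
    on, `hsearch` refines (rise, twist) on each unsymmetrized
    back-projection inside the tighter `refine_window` around the indexed
    anchor.  A result pinned to the window edge is rejected (the previous
    estimate is kept): reference grids quantized to the azimuth step make
    grid-commensurate twists (e.g. exact 6-fold at a 4° step) spurious
    attractors of the self-consistency score on noisy early maps, and a
    genuine local optimum near the anchor is interior.  Divergence (mean
    match score decreasing for 3 consecutive iterations) aborts with
    ``diverged=True``.
    """
    if len(stack) == 0:
        raise ValueError("empty stack")
    box = stack.box
    if diameter_A is None:
        diameter_A = 0.75 * box * stack.pixel_size
    total_iters = sum(p.n_iter for p in schedule)
    anchor = (
        estimate_initial_symmetry(stack, init_sym, window=hsearch_window)
        if reindex_init
        else init_sym
    )
    sym = anchor
    current = noise_cylinder(box, stack.pixel_size, diameter_A, seed=seed)
    current = symmetrize(current, sym)
    if total_iters == 0:
        empty = pd.DataFrame(columns=["iter", "rise_A", "twist_deg", "mean_score"])
        return ReconstructionResult(
            current, sym, pd.DataFrame(columns=["freq_invA", "fsc"]),
            np.inf, 0, empty,
        )

    traj: list[dict] = []
    it = 0
    diverged = False
    decreasing = 0
    last_score = -np.inf
    halves = None
    for phase in schedule:
        ph_stack = _bin_stack(stack, phase.binning)
        ph_map = (
            current
            if current.box == ph_stack.box
            else _resample_map(current, ph_stack.box, ph_stack.pixel_size)
        )
        mask2d = _soft_cyl_mask(ph_stack.box, ph_stack.pixel_size, diameter_A)
        for _ in range(phase.n_iter):
            it += 1
            refs, orients = make_reference_library(
                ph_map, phase.azimuth_step, phase.tilt_range, phase.tilt_step
            )
            assigns = match_stack(ph_stack, refs, orients)
            mean_score = float(np.mean([a.score for a in assigns]))
            is_last = it == total_iters
            bp = backproject(
                ph_stack, assigns, ph_stack.box, half_sets=is_last and compute_fsc
            )
            if is_last and compute_fsc:
                bp, *halves = bp
            if phase.refine_symmetry and it >= hsearch_start:
                hs = hsearch(
                    bp, anchor, window=refine_window,
                    coarse_step=(refine_window[0] / 5, refine_window[1] / 5),
                )
                s = hs.symmetry
                interior = (
                    abs(s.rise - anchor.rise) < 0.98 * refine_window[0]
                    and abs(s.twist - anchor.twist) < 0.98 * refine_window[1]
                )
                if interior and not hs.flat:
                    sym = s
                else:
                    logger.info(
                        "iter %d: hsearch result %.3f/%.3f at window edge, "
                        "keeping %.3f/%.3f", it, s.rise, s.twist,
                        sym.rise, sym.twist,
                    )
            sym_map = symmetrize(bp, sym)
            sym_map.grid *= mask2d.astype(np.float32)
            ph_map = sym_map
            traj.append(
                {
                    "iter": it,
                    "rise_A": sym.rise,
                    "twist_deg": sym.twist,
                    "mean_score": mean_score,
                }
            )
            logger.info(
                "iter %d: rise %.3f Å twist %.3f° score %.4f",
                it, sym.rise, sym.twist, mean_score,
            )
            if mean_score < last_score - 0.01:
                decreasing += 1
                if decreasing >= 3:
                    logger.warning("score decreasing for 3 iterations; aborting")
                    diverged = True
                    break
            else:
                decreasing = 0
            last_score = mean_score
        current = ph_map
        if diverged:
            break

    if halves is not None and not diverged:
        half_maps = [symmetrize(h, sym) for h in halves]
        curve = fsc(half_maps[0], half_maps[1])
        res = resolution_at(curve, 0.5)
    else:
        curve = pd.DataFrame(columns=["freq_invA", "fsc"])
        res = np.inf
    return ReconstructionResult(
        map=current,
        symmetry=sym,
        fsc=curve,
        resolution_A=res,
        iterations=it,
        trajectory=pd.DataFrame(traj),
        diverged=diverged,
    )


# ---------------------------------------------------------------------------
# initial symmetry from layer-line indexing
# ---------------------------------------------------------------------------

def index_layer_lines(
    spacings_A: tuple[float, float],
    n_pairs: list[tuple[int, int]] | None = None,
    rise_bounds: tuple[float, float] = (2.0, 6.0),
) -> list[HelicalSymmetry]:
    """Invert the selection rule for two measured layer-line spacings.

    Treats the two major lines as the (n, −1) and (n+1, −1) families of a
    dense 1-start lattice (adjacent-row moiré pair) and solves
    ``Z(n, m) = (n·twist/360 + m)/rise`` for every candidate Bessel-order
    assignment and sign combination, returning all solutions with a rise
    inside `rise_bounds` and |twist| ≤ 180.
    """
    z1, z2 = sorted(1.0 / s for s in spacings_A)  # |Z| of the two lines
    if n_pairs is None:
        n_pairs = [(n, n + 1) for n in range(3, 12)]
    out: list[HelicalSymmetry] = []
    for n_lo, n_hi in n_pairs:
        for s_lo in (+1, -1):
            for s_hi in (+1, -1):
                # s_lo*z1*rise = n_lo*t - 1 ; s_hi*z2*rise = n_hi*t - 1
                denom = s_lo * z1 * n_hi - s_hi * z2 * n_lo
                if abs(denom) < 1e-12:
                    continue
                rise = (n_hi * -1 - n_lo * -1) / denom
                if not (rise_bounds[0] <= rise <= rise_bounds[1]):
                    continue
                t = (s_lo * z1 * rise + 1) / n_lo
                twist = t * 360.0
                if not (0 < abs(twist) <= 180):
                    continue
                out.append(HelicalSymmetry(round(rise, 4), round(twist, 4)))
    # deduplicate
    uniq: dict[tuple[float, float], HelicalSymmetry] = {}
    for s in out:
        uniq[(round(s.rise, 3), round(abs(s.twist), 3))] = s
    return list(uniq.values())


def rank_candidates(
    candidates: list[HelicalSymmetry],
    spectrum_1d: np.ndarray,
    length_A: float,
    n_max: int = 8,
    m_max: int = 1,
) -> list[tuple[HelicalSymmetry, float]]:
    """Rank candidate symmetries by agreement with a measured spectrum.

    `spectrum_1d` is the axially collapsed power spectrum (FFT row order).
    Peaks are picked from it; a candidate earns the prominence of every
    measured peak lying within one Fourier pixel of one of its allowed
    layer lines, and pays a penalty for every allowed line in the
    measurable band that matches no peak (a lattice that predicts lines
    where the data show none is a bad indexing).
    """
    from scipy.signal import find_peaks

    n = len(spectrum_1d)
    half = spectrum_1d[: n // 2]
    med = float(np.median(half[2:]))
    peaks, props = find_peaks(half, prominence=max(med, 1e-300))
    peak_f = peaks / length_A
    peak_w = props["prominences"] / max(med, 1e-300)
    df = 1.0 / length_A
    scored = []
    for cand in candidates:
        zs = np.array(
            sorted(
                {
                    abs(L.axial_frequency)
                    for L in layer_lines(cand, n_max, m_max)
                    if 2 * df < abs(L.axial_frequency) < (n // 2 - 1) * df
                }
            )
        )
        gain = 0.0
        for f, w in zip(peak_f, peak_w):
            if len(zs) and np.min(np.abs(zs - f)) <= df:
                gain += float(w)
        unmatched = sum(
            1 for z in zs if len(peak_f) == 0 or np.min(np.abs(peak_f - z)) > df
        )
        mean_w = float(peak_w.mean()) if len(peak_w) else 1.0
        scored.append((cand, gain - 0.5 * mean_w * unmatched))
    scored.sort(key=lambda x: -x[1])
    return scored
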