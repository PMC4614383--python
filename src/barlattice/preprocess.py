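"""Segment extraction, CTF phase flipping, 2D averaging, layer-line search.

Reference-free 2D classification replaces maximum-likelihood methods at
desk scale: segments are centered and rotationally aligned with a coarse
search, then clustered by k-means on their transverse density profiles,
which separates tube diameters cleanly and deterministically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from scipy.signal import find_peaks

from .segments import CTFParams, SegmentStack, ctf_2d

__all__ = [
    "ClassAverage",
    "SpectrumMeasurement",
    "MeasurementError",
    "segment_tube",
    "phase_flip",
    "align_and_classify",
    "collapsed_power_spectrum",
    "measure_layer_lines",
    "measure_diameter",
]


class MeasurementError(RuntimeError):
    """Raised when a measurement cannot be made on the given image."""


@dataclass
class ClassAverage:
    """Aligned mean of one 2D class."""

    image: np.ndarray
    member_ids: list[int]
    pixel_size: float
    diameter_estimate: float = float("nan")  # Å

    def __post_init__(self) -> None:
        if len(self.member_ids) < 1:
            raise ValueError("a class must have at least one member")


@dataclass
class SpectrumMeasurement:
    """Axially collapsed power spectrum and its non-equatorial peaks."""

    power_spectrum: np.ndarray  # 2D |FFT|^2, unshifted order
    axial_peaks: list[tuple[float, float]]  # (spacing Å, prominence), by prominence


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def segment_tube(
    trace: np.ndarray, box: int, overlap_fraction: float
) -> list[tuple[int, int]]:
    """Box centers along a traced tube axis.

    Centers are spaced ``step = round(box * (1 - overlap))`` pixels of arc
    length apart, starting half a box from the trace start, keeping every
    center whose box lies fully inside the trace.  Sub-pixel positions are
    rounded half-up.  A trace shorter than one box yields no centers.
    """
    if box < 2:
        raise ValueError("box must be >= 2")
    if not (0 <= overlap_fraction < 1):
        raise ValueError("overlap_fraction must be in [0, 1)")
    pts = np.asarray(trace, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        return []
    seg = np.diff(pts, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    length = float(seg_len.sum())
    if length < box:
        return []
    step = max(1, _round_half_up(box * (1.0 - overlap_fraction)))
    n = int(math.floor((length - box) / step)) + 1
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    centers = []
    for i in range(n):
        s = box / 2.0 + i * step
        j = int(np.searchsorted(cum, s, side="right") - 1)
        j = min(j, len(seg) - 1)
        frac = (s - cum[j]) / seg_len[j] if seg_len[j] > 0 else 0.0
        p = pts[j] + frac * seg[j]
        centers.append((_round_half_up(p[0]), _round_half_up(p[1])))
    return centers


def phase_flip(image: np.ndarray, ctf: CTFParams, defocus_um: float | None = None) -> np.ndarray:
    """Correct CTF phase inversions: multiply Fourier terms by sign(CTF).

    Amplitudes (and hence total spectral power) are preserved exactly;
    applying the operation twice is the identity.
    """
    h = ctf_2d(image.shape, ctf, defocus_um=defocus_um)
    s = np.sign(h)
    s[s == 0] = 1.0
    return np.real(np.fft.ifft2(np.fft.fft2(image) * s))


def phase_flip_stack(stack: SegmentStack) -> SegmentStack:
    """Phase-flip every segment with its own recorded defocus."""
    if stack.ctf is None:
        raise ValueError("stack carries no CTF parameters")
    defoci = (
        stack.metadata["defocus_um"].to_numpy()
        if "defocus_um" in stack.metadata
        else np.full(len(stack), stack.ctf.defocus)
    )
    out = np.stack(
        [
            phase_flip(img, stack.ctf, defocus_um=float(d))
            for img, d in zip(stack.images, defoci)
        ]
    ).astype(np.float32)
    return SegmentStack(out, stack.pixel_size, stack.metadata, stack.ctf)


def _center_x(image: np.ndarray) -> float:
    """Sub-pixel x offset of the tube axis from the mirror-symmetry center."""
    prof = image.mean(axis=0)
    prof = prof - prof.mean()
    f = np.fft.rfft(prof)
    cc = np.fft.irfft(f * f, n=len(prof))  # correlation with mirrored profile
    k = int(np.argmax(cc))
    y0, y1, y2 = cc[(k - 1) % len(cc)], cc[k], cc[(k + 1) % len(cc)]
    denom = y0 - 2 * y1 + y2
    dk = 0.5 * (y0 - y2) / denom if denom < 0 else 0.0
    center2 = k + dk  # mirror center*2 (mod n)
    n = len(prof)
    c = center2 / 2.0
    # choose the candidate center (c or c + n/2) closer to the middle
    cands = [(c + off) % n for off in (0.0, n / 2.0)]
    return min(cands, key=lambda v: abs(v - n / 2)) - n / 2


def _align_one(
    image: np.ndarray, rotation_range: float, rotation_step: float
) -> tuple[np.ndarray, float, float]:
    """Rotate to make the tube axis vertical, then center in x."""
    best_img, best_ang, best_score = image, 0.0, -np.inf
    if rotation_range > 0:
        for ang in np.arange(-rotation_range, rotation_range + 1e-9, rotation_step):
            rot = (
                image
                if ang == 0.0
                else ndi.rotate(image, ang, reshape=False, order=1, mode="constant")
            )
            score = float(np.var(rot.mean(axis=0)))  # sharpest column profile
            if score > best_score:
                best_img, best_ang, best_score = rot, float(ang), score
    dx = _center_x(best_img)
    out = ndi.shift(best_img, (0.0, -dx), order=1, mode="constant")
    return out, best_ang, dx


def align_and_classify(
    stack: SegmentStack,
    n_classes: int,
    n_iter: int = 10,
    seed: int = 0,
    rotation_range: float = 6.0,
    rotation_step: float = 1.0,
) -> list[ClassAverage]:
    """Reference-free alignment followed by deterministic k-means.

    Each segment is rotationally aligned (coarse search maximizing the
    sharpness of its transverse profile) and centered on its mirror axis;
    k-means then clusters the transverse profiles.  Initial centers are
    data-derived quantile members along the first principal axis, making
    assignments deterministic and independent of input order.
    """
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    if n_classes > len(stack):
        raise ValueError("more classes than segments")
    aligned = np.stack(
        [_align_one(img, rotation_range, rotation_step)[0] for img in stack.images]
    )
    feats = aligned.mean(axis=1)  # transverse profiles
    feats = feats - feats.mean(axis=1, keepdims=True)

    if n_classes == 1:
        labels = np.zeros(len(stack), dtype=int)
    else:
        centered = feats - feats.mean(axis=0, keepdims=True)
        # first principal axis, sign-fixed for order invariance
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        pc = vt[0]
        if pc.sum() < 0:
            pc = -pc
        scores = centered @ pc
        order = np.argsort(scores, kind="stable")
        qs = [order[int(round(q * (len(order) - 1)))] for q in np.linspace(0, 1, n_classes)]
        centers = feats[qs].copy()
        labels = np.zeros(len(stack), dtype=int)
        for _ in range(max(n_iter, 1)):
            d = ((feats[:, None, :] - centers[None]) ** 2).sum(axis=2)
            new_labels = np.argmin(d, axis=1)
            if np.array_equal(new_labels, labels):
                labels = new_labels
                break
            labels = new_labels
            for c in range(n_classes):
                sel = labels == c
                if sel.any():
                    centers[c] = feats[sel].mean(axis=0)

    ids = (
        stack.metadata["id"].to_numpy()
        if "id" in stack.metadata
        else np.arange(len(stack))
    )
    out = []
    for c in range(n_classes):
        sel = np.flatnonzero(labels == c)
        if len(sel) == 0:
            continue
        avg = aligned[sel].mean(axis=0)
        ca = ClassAverage(avg, [int(ids[i]) for i in sel], stack.pixel_size)
        try:
            ca.diameter_estimate = measure_diameter(ca)
        except MeasurementError:
            pass
        out.append(ca)
    return out


def collapsed_power_spectrum(image: np.ndarray) -> np.ndarray:
    """1D axial power: |FFT2|^2 summed over the transverse frequency axis."""
    p = np.abs(np.fft.fft2(image - image.mean())) ** 2
    return p.sum(axis=1)


def measure_layer_lines(
    avg: "ClassAverage | np.ndarray",
    min_prominence: float = 20.0,
    pixel_size: float | None = None,
    max_peaks: int = 10,
) -> SpectrumMeasurement:
    """Find axial layer-line spacings in a class average's power spectrum.

    Peaks are local maxima of the axially collapsed power spectrum with
    prominence above ``min_prominence ×`` the spectrum median; an equator
    band |Z| ≤ max(1/(4·L), one Fourier pixel) is excluded.  Peak
    positions are refined parabolically; spacings are reported in Å,
    sorted by descending prominence (ties toward lower frequency).
    """
    if isinstance(avg, ClassAverage):
        image, px = avg.image, avg.pixel_size
    else:
        image = np.asarray(avg)
        if pixel_size is None:
            raise ValueError("pixel_size required for raw arrays")
        px = pixel_size
    ny = image.shape[0]
    length = ny * px
    power2d = np.abs(np.fft.fft2(image - image.mean())) ** 2
    spec = power2d.sum(axis=1)[: ny // 2 + 1]
    df = 1.0 / length
    excl = max(int(math.ceil((1.0 / (4.0 * length)) / df)), 1)
    med = float(np.median(spec[excl:]))
    if med <= 0:
        med = 1.0
    peaks, props = find_peaks(spec, prominence=min_prominence * med)
    # spacings approaching the box length are dominated by the tube's
    # shape transform; require at least ~3 periods inside the image
    peaks_l = [
        (int(p), float(pr))
        for p, pr in zip(peaks, props["prominences"])
        if max(excl, 2) < p < ny // 2
    ]
    # descending prominence, ties by lower frequency
    peaks_l.sort(key=lambda t: (-t[1], t[0]))
    out = []
    for p, pr in peaks_l[:max_peaks]:
        y0, y1, y2 = spec[p - 1], spec[p], spec[p + 1] if p + 1 < len(spec) else spec[p]
        denom = y0 - 2 * y1 + y2
        dp = 0.5 * (y0 - y2) / denom if denom < 0 else 0.0
        freq = (p + float(np.clip(dp, -0.5, 0.5))) * df
        out.append((1.0 / freq, pr / med))
    return SpectrumMeasurement(power2d, out)


def _abel_invert(profile: np.ndarray) -> np.ndarray:
    """Onion-peeling inverse Abel transform of a half-profile.

    profile[i] is the line integral at impact parameter i (pixel units);
    returns the radial density f(r) at integer radii.  Solves the
    triangular system P(x_i) = Σ_j A_ij f(r_j) with annulus chord weights
    A_ij = 2(√(r_{j+1}²−x_i²) − √(r_j²−x_i²)) from the outside in.
    """
    n = len(profile)
    f = np.zeros(n)
    r = np.arange(n + 1, dtype=float)
    for i in range(n - 1, -1, -1):
        acc = 0.0
        for j in range(i + 1, n):
            a = 2.0 * (
                math.sqrt(max(r[j + 1] ** 2 - i**2, 0.0))
                - math.sqrt(max(r[j] ** 2 - i**2, 0.0))
            )
            acc += a * f[j]
        a_ii = 2.0 * math.sqrt(max(r[i + 1] ** 2 - i**2, 0.0))
        f[i] = (profile[i] - acc) / a_ii if a_ii > 0 else 0.0
    return f


def measure_diameter(avg: "ClassAverage | np.ndarray", pixel_size: float | None = None) -> float:
    """Tube diameter (Å) at the outermost density shell of a class average.

    The transverse line scan (mean over rows) is folded about the tube
    axis and inverted back to a radial density profile (inverse Abel
    transform); the diameter is twice the radius of the outermost
    prominent radial peak.  Reading the peak on the inverted profile
    avoids the inward bias that projection geometry imprints on the raw
    line-scan wall peaks.
    """
    if isinstance(avg, ClassAverage):
        image, px = avg.image, avg.pixel_size
    else:
        image = np.asarray(avg)
        if pixel_size is None:
            raise ValueError("pixel_size required for raw arrays")
        px = pixel_size
    prof = image.mean(axis=0).astype(np.float64)
    prof = prof - np.median(prof)
    span = float(prof.max() - prof.min())
    if span <= 0:
        raise MeasurementError("uniform image: no wall peaks")
    if abs(prof.min()) > abs(prof.max()):
        prof = -prof  # density sign convention of CTF-corrected averages
    n = len(prof)
    c = n / 2.0 + _center_x(image)
    ci = int(round(c))
    half = min(ci, n - 1 - ci)
    if half < 4:
        raise MeasurementError("tube axis too close to the box edge")
    folded = 0.5 * (prof[ci : ci + half + 1] + prof[ci : ci - half - 1 : -1])
    radial = _abel_invert(folded)
    span_r = float(radial.max() - radial.min())
    peaks, _ = find_peaks(radial, prominence=0.15 * span_r)
    if len(peaks) == 0:
        raise MeasurementError("no radial density peak found")
    p = int(peaks[-1])
    rp = float(p)
    if 0 < p < len(radial) - 1:
        y0, y1, y2 = radial[p - 1 : p + 2]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            rp += float(np.clip(0.5 * (y0 - y2) / denom, -0.5, 0.5))
    return 2.0 * rp * px
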