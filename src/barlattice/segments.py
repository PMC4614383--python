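"""Shared containers: boxed tube segments and phase-contrast CTF parameters."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CTFParams", "SegmentStack", "electron_wavelength", "ctf_2d"]

#: metadata columns every segment stack carries
METADATA_COLUMNS = [
    "id",
    "azimuth_deg",
    "tilt_deg",
    "in_plane_deg",
    "shift_x_A",
    "shift_y_A",
    "defocus_um",
    "tube_id",
    "seed",
]


@dataclass(frozen=True)
class CTFParams:
    """Phase-contrast CTF of the microscope.

    defocus is positive for underfocus, in μm; the study's data span
    0.5–3.2 μm.  pixel_size is the image sampling in Å.
    """

    defocus: float = 1.5  # μm
    spherical_aberration: float = 2.0  # mm
    voltage: float = 300.0  # kV
    amplitude_contrast: float = 0.07
    pixel_size: float = 3.0  # Å

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if not (0 <= self.amplitude_contrast < 1):
            raise ValueError("amplitude_contrast must be in [0, 1)")
        if not (0.1 <= self.defocus <= 10):
            raise ValueError("defocus (μm) outside plausible 0.1–10 range")


def electron_wavelength(voltage_kV: float) -> float:
    """Relativistic electron wavelength in Å."""
    v = voltage_kV * 1e3
    return 12.2643 / np.sqrt(v * (1.0 + 0.978476e-6 * v))


def ctf_2d(
    shape: tuple[int, int],
    ctf: CTFParams,
    defocus_um: float | None = None,
) -> np.ndarray:
    """Evaluate the CTF on the (unshifted) 2D FFT frequency grid.

    CTF(f) = -( sqrt(1-A^2) sin χ + A cos χ ),
    χ(f) = π λ Δf f² − (π/2) Cs λ³ f⁴.
    """
    dz = (ctf.defocus if defocus_um is None else defocus_um) * 1e4
    cs = ctf.spherical_aberration * 1e7
    lam = electron_wavelength(ctf.voltage)
    fy = np.fft.fftfreq(shape[0], d=ctf.pixel_size)
    fx = np.fft.fftfreq(shape[1], d=ctf.pixel_size)
    f2 = fy[:, None] ** 2 + fx[None, :] ** 2
    chi = np.pi * lam * dz * f2 - 0.5 * np.pi * cs * lam**3 * f2**2
    a = ctf.amplitude_contrast
    return -(np.sqrt(1.0 - a * a) * np.sin(chi) + a * np.cos(chi))


@dataclass
class SegmentStack:
    """Boxed tube segments plus per-segment metadata.

    images: (n, box, box) array, axial direction along rows (axis 0 of each
    image); pixel_size in Å; metadata: one row per segment with the
    METADATA_COLUMNS dialect.
    """

    images: np.ndarray
    pixel_size: float
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)
    ctf: CTFParams | None = None

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images)
        if self.images.ndim != 3:
            raise ValueError("images must be (n, ny, nx)")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if len(self.metadata) and len(self.metadata) != len(self.images):
            raise ValueError("metadata rows must match image count")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def box(self) -> int:
        return self.images.shape[1]
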