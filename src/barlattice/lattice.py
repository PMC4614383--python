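"""Analytic helical-lattice mathematics for protein-coated membrane tubes.

A 1-start helical lattice is described by the rise :math:`\\Delta z` (axial
translation per subunit, Å) and twist :math:`\\Delta\\varphi` (azimuthal
rotation per subunit, degrees).  This module relates that symmetry to the
layer lines of the tube's diffraction pattern through the helical selection
rule

.. math:: Z(n, m) = (n \\,\\Delta\\varphi/360 + m) / \\Delta z

(axial frequency of the line carrying Bessel order *n* and axial repeat
index *m*), to the per-subunit area of the lattice on the unrolled
cylinder, and to the lipid/protein decomposition of a measured mass per
unit length (MPL).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "InvalidSymmetryError",
    "DecompositionError",
    "HelicalSymmetry",
    "LayerLine",
    "TubeGeometry",
    "LipidModel",
    "MassDecomposition",
    "units_per_turn",
    "pitch",
    "layer_lines",
    "area_per_subunit",
    "lipids_per_angstrom",
    "decompose_mass",
    "unrolled_lattice_vectors",
    "row_spacing",
    "MAJOR_CLASS_SYMMETRY",
    "MAJOR_CLASS_GEOMETRY",
]


class InvalidSymmetryError(ValueError):
    """Raised for helical parameters outside the valid domain."""


class DecompositionError(ValueError):
    """Raised when a measured MPL cannot accommodate the lipid contribution."""


@dataclass(frozen=True)
class HelicalSymmetry:
    """Rise/twist pair of a 1-start helical lattice.

    Parameters
    ----------
    rise : float
        Axial translation per subunit, Å.  Must be positive.
    twist : float
        Azimuthal rotation per subunit, degrees, signed; positive means
        right-handed about the tube axis.  Handedness is not observable in
        projection, so all derived spacings use ``abs(twist)``.
    """

    rise: float
    twist: float

    def __post_init__(self) -> None:
        if not (self.rise > 0):
            raise InvalidSymmetryError(f"rise must be > 0, got {self.rise}")
        if not (0 < abs(self.twist) <= 360):
            raise InvalidSymmetryError(
                f"twist must satisfy 0 < |twist| <= 360, got {self.twist}"
            )


@dataclass(frozen=True)
class LayerLine:
    """One allowed layer line (n, m) of a helical diffraction pattern."""

    n: int
    m: int
    axial_frequency: float  # Å^-1, signed

    @property
    def axial_spacing(self) -> float:
        """Real-space spacing 1/|Z| in Å (inf on the equator)."""
        if self.axial_frequency == 0:
            return math.inf
        return 1.0 / abs(self.axial_frequency)


@dataclass(frozen=True)
class TubeGeometry:
    """Radial geometry of a protein-coated bilayer tube (all Å, diameters)."""

    inner_leaflet_diameter: float
    outer_leaflet_diameter: float
    protein_shell_diameter: float
    lattice_radius: float = 0.0  # 0 -> default to protein_shell_diameter / 2

    def __post_init__(self) -> None:
        if not (
            0
            < self.inner_leaflet_diameter
            < self.outer_leaflet_diameter
            <= self.protein_shell_diameter
        ):
            raise ValueError(
                "require 0 < inner_leaflet < outer_leaflet <= protein_shell"
            )
        if self.lattice_radius == 0.0:
            object.__setattr__(
                self, "lattice_radius", self.protein_shell_diameter / 2.0
            )
        if self.lattice_radius < 0:
            raise ValueError("lattice_radius must be >= 0")

    @property
    def inner_leaflet_radius(self) -> float:
        return self.inner_leaflet_diameter / 2.0

    @property
    def outer_leaflet_radius(self) -> float:
        return self.outer_leaflet_diameter / 2.0

    @property
    def leaflet_separation(self) -> float:
        """Radial distance between leaflet peaks, Å."""
        return self.outer_leaflet_radius - self.inner_leaflet_radius


# POPG 749.0 Da, POPE 718.0 Da at 2:1 w/w -> mole-fraction-weighted mean.
_POPG_MW, _POPE_MW = 0.7490, 0.7180  # kDa
_x_pg = (2 / _POPG_MW) / (2 / _POPG_MW + 1 / _POPE_MW)
DEFAULT_MEAN_LIPID_MW = round(_x_pg * _POPG_MW + (1 - _x_pg) * _POPE_MW, 4)


@dataclass(frozen=True)
class LipidModel:
    """Bilayer composition model used in the MPL decomposition."""

    reference_diameter: float  # Å, tube width at which lipids are counted
    area_per_lipid: float = 50.0  # Å^2
    mean_lipid_mw: float = DEFAULT_MEAN_LIPID_MW  # kDa

    def __post_init__(self) -> None:
        if self.reference_diameter <= 0:
            raise ValueError("reference_diameter must be > 0")
        if self.area_per_lipid <= 0:
            raise ValueError("area_per_lipid must be > 0")
        if self.mean_lipid_mw <= 0:
            raise ValueError("mean_lipid_mw must be > 0")


@dataclass(frozen=True)
class MassDecomposition:
    """Lipid/protein split of a total mass per length."""

    total_mpl: float  # kDa/Å
    lipid_mpl: float  # kDa/Å
    protein_mpl: float  # kDa/Å
    dimer_mass: float  # kDa
    axial_extent_per_dimer: float  # Å


def units_per_turn(sym: HelicalSymmetry) -> float:
    """Number of subunits per full 360° turn of the 1-start helix."""
    return 360.0 / abs(sym.twist)


def pitch(sym: HelicalSymmetry) -> float:
    """Axial repeat (Å) of one full turn of the 1-start helix."""
    return sym.rise * units_per_turn(sym)


def layer_lines(
    sym: HelicalSymmetry, n_max: int, m_max: int
) -> list[LayerLine]:
    """Enumerate allowed layer lines by the helical selection rule.

    Returns every (n, m) with |n| <= n_max, |m| <= m_max, excluding
    (0, 0), at axial frequency ``Z = (n*twist/360 + m)/rise``, sorted by
    |Z| (ascending), ties by (|n|, n, m).
    """
    if n_max < 0 or m_max < 0:
        raise ValueError("n_max and m_max must be >= 0")
    t = sym.twist / 360.0
    lines = [
        LayerLine(n, m, (n * t + m) / sym.rise)
        for n in range(-n_max, n_max + 1)
        for m in range(-m_max, m_max + 1)
        if not (n == 0 and m == 0)
    ]
    lines.sort(key=lambda L: (abs(L.axial_frequency), abs(L.n), L.n, L.m))
    return lines


def area_per_subunit(
    geom: TubeGeometry, sym: "HelicalSymmetry | float"
) -> float:
    """Cylinder-surface area per lattice subunit, Å².

    Equal to circumference at the lattice radius times the rise:
    ``pi * (2*lattice_radius) * rise``.  `sym` may be a HelicalSymmetry or
    a plain non-negative rise in Å.
    """
    rise = sym.rise if isinstance(sym, HelicalSymmetry) else float(sym)
    if rise < 0:
        raise ValueError("rise must be >= 0")
    if geom.lattice_radius <= 0:
        raise ValueError("lattice_radius must be > 0")
    return math.pi * (2.0 * geom.lattice_radius) * rise


def lipids_per_angstrom(
    lipid: LipidModel, mode: str = "exact"
) -> float:
    """Lipids per axial Å on a tube of the model's reference diameter.

    Uses the single-cylindrical-surface convention ``pi * D / A``.
    ``mode='truncate'`` floors the count to an integer for reporting.
    """
    value = math.pi * lipid.reference_diameter / lipid.area_per_lipid
    if mode == "truncate":
        return float(math.floor(value))
    if mode != "exact":
        raise ValueError(f"unknown mode {mode!r}")
    return value


def decompose_mass(
    total_mpl: float,
    lipid: "LipidModel | None",
    dimer_mass: float = 56.0,
) -> MassDecomposition:
    """Split a measured MPL into lipid and protein contributions.

    lipid_mpl = lipids/Å × mean lipid MW; protein_mpl is the remainder;
    the axial extent occupied by one protein dimer is
    dimer_mass / protein_mpl.  `lipid=None` means a bare (lipid-free) rod.
    """
    if total_mpl <= 0:
        raise ValueError("total_mpl must be > 0")
    lipid_mpl = 0.0
    if lipid is not None:
        lipid_mpl = lipids_per_angstrom(lipid) * lipid.mean_lipid_mw
    protein_mpl = total_mpl - lipid_mpl
    if protein_mpl <= 0:
        raise DecompositionError(
            f"lipid contribution {lipid_mpl:.2f} kDa/Å exhausts the "
            f"measured {total_mpl:.2f} kDa/Å"
        )
    return MassDecomposition(
        total_mpl=total_mpl,
        lipid_mpl=lipid_mpl,
        protein_mpl=protein_mpl,
        dimer_mass=dimer_mass,
        axial_extent_per_dimer=dimer_mass / protein_mpl,
    )


def _wrap_deg(angle: float) -> float:
    """Wrap an angle to (-180, 180]."""
    a = math.fmod(angle, 360.0)
    if a > 180.0:
        a -= 360.0
    elif a <= -180.0:
        a += 360.0
    return a


def unrolled_lattice_vectors(
    geom: TubeGeometry, sym: HelicalSymmetry, k_max: int
) -> list[tuple[float, float]]:
    """Displacements to the k-th subunit on the unrolled cylinder.

    For k = 1..k_max, returns (circumferential Å, axial Å) of the shortest
    wrapped displacement at the lattice radius: the azimuth k*twist is
    wrapped to (-180°, 180°] before converting to arc length.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    r = geom.lattice_radius
    out = []
    for k in range(1, k_max + 1):
        ang = _wrap_deg(k * sym.twist)
        out.append((r * math.radians(ang), k * sym.rise))
    return out


def row_spacing(
    vector: tuple[float, float], geom: TubeGeometry, sym: HelicalSymmetry
) -> float:
    """Perpendicular spacing of the lattice-row family along `vector`.

    On the unrolled lattice the unit-cell area is the area per subunit, so
    the family of rows parallel to a lattice vector v is spaced
    area_per_subunit / |v| apart.
    """
    norm = math.hypot(*vector)
    if norm == 0:
        raise ValueError("zero lattice vector")
    return area_per_subunit(geom, sym) / norm


#: Converged symmetry of the most populated tube class (Δz = 3.81 Å,
#: Δφ = 55.92°) — the pipeline's canonical ground truth.
MAJOR_CLASS_SYMMETRY = HelicalSymmetry(rise=3.81, twist=55.92)

#: Leaflet and protein-shell geometry of the same class (182/248/280 Å).
MAJOR_CLASS_GEOMETRY = TubeGeometry(
    inner_leaflet_diameter=182.0,
    outer_leaflet_diameter=248.0,
    protein_shell_diameter=280.0,
)
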