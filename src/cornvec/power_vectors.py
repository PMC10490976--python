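"""Conversions between meridional (spherocylindrical) notation and power vectors.

A corneal surface, a refraction, or a toric implant is conventionally written
as two principal powers (or radii of curvature) along two perpendicular
meridians.  That notation is awkward for statistics: powers at different axes
cannot be added or averaged.  The power-vector representation fixes this by
projecting the astigmatism onto the 0°/90° and 45°/135° meridians at twice
the axis angle, giving three components

    EQ   equivalent (mean) power, dioptres
    C0   astigmatism projected onto 0°/90°, dioptres
    C45  astigmatism projected onto 45°/135°, dioptres

which form a vector space: componentwise sums and differences are physically
meaningful (e.g. surgically induced astigmatism = postop − preop).

Radii in millimetres are converted to dioptres through a refractive-index
step ``delta_n = n2 - n1`` across the interface: a single meridian of radius
``R`` mm has paraxial power ``1000 * delta_n / R`` dpt.  Named presets carry
the index steps of the Liou-Brennan schematic eye (cornea 1.376, aqueous
1.336) and the Zeiss keratometer index 1.332.

Sign conventions: astigmatism is stored signed "steep minus flat", so
with-the-rule astigmatism (steep meridian near vertical) has C0 > 0.  The
flat-meridian axis drives the double angle; axes live in [0, 180) degrees.
Left-eye (OS) vectors are pooled with right eyes by flipping the sign of C45
("mirroring"), reflecting the mirror symmetry of ocular anatomy.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = [
    "MediaInterface",
    "FRONT_SURFACE",
    "BACK_SURFACE",
    "KERATOMETRIC",
    "SurfaceMeasurement",
    "PowerMeridians",
    "PowerVector",
    "RefractionRecord",
    "TIOLRecord",
    "InvalidMeasurementError",
    "power_from_radius",
    "radii_to_power_vector",
    "powers_to_power_vector",
    "refraction_to_power_vector",
    "tiol_to_power_vector",
    "mirror_for_left_eye",
    "pv_add",
    "pv_subtract",
    "power_vector_to_polar",
    "power_vector_to_radii",
]


class InvalidMeasurementError(ValueError):
    """Raised for physically impossible or inconsistent meridional input."""


def _norm_axis(axis_deg: float) -> float:
    """Map an axis in degrees into [0, 180)."""
    a = float(axis_deg) % 180.0
    return a if a >= 0.0 else a + 180.0


@dataclass(frozen=True)
class MediaInterface:
    """Refractive-index step ``delta_n = n2 - n1`` across an optical interface."""

    delta_n: float
    name: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.delta_n) or self.delta_n == 0.0:
            raise InvalidMeasurementError(
                f"delta_n must be finite and nonzero, got {self.delta_n}"
            )


#: Corneal front surface: aqueous-to-cornea step of the Liou-Brennan eye, 1.376 - 1.000.
FRONT_SURFACE = MediaInterface(0.376, "front")
#: Corneal back surface: 1.336 - 1.376 (cornea to aqueous humour).
BACK_SURFACE = MediaInterface(-0.040, "back")
#: Fictitious keratometer index 1.332 applied to front-surface radii.
KERATOMETRIC = MediaInterface(0.332, "keratometric")


@dataclass
class SurfaceMeasurement:
    """Two perpendicular meridional radii of curvature with the flat-meridian axis.

    ``R_flat >= R_steep`` by convention (flat = larger radius = lower power for a
    positive index step).  Mislabelled flat/steep input is auto-normalised with a
    warning; non-perpendicular meridians are rejected.
    """

    R_flat: float
    A_flat: float
    R_steep: float
    A_steep: float

    _AXIS_TOL = 1e-6  # degrees

    def __post_init__(self) -> None:
        for r in (self.R_flat, self.R_steep):
            if not math.isfinite(r) or r <= 0.0:
                raise InvalidMeasurementError(f"radius must be finite and > 0, got {r}")
        self.A_flat = _norm_axis(self.A_flat)
        self.A_steep = _norm_axis(self.A_steep)
        sep = (self.A_steep - self.A_flat) % 180.0
        if abs(sep - 90.0) > self._AXIS_TOL:
            raise InvalidMeasurementError(
                f"meridians must be perpendicular: axes {self.A_flat}, {self.A_steep}"
            )
        if self.R_flat < self.R_steep:
            warnings.warn(
                "flat/steep meridians mislabelled (R_flat < R_steep); swapping",
                stacklevel=3,
            )
            self.R_flat, self.R_steep = self.R_steep, self.R_flat
            self.A_flat, self.A_steep = self.A_steep, self.A_flat


@dataclass
class PowerMeridians:
    """Two perpendicular meridional powers in dioptres with the flat-meridian axis.

    ``axis_undefined`` marks polar output derived from a zero-cylinder vector,
    where the axis is reported as 0° purely by convention.
    """

    P_flat: float
    P_steep: float
    A_flat: float
    axis_undefined: bool = False

    def __post_init__(self) -> None:
        if not (math.isfinite(self.P_flat) and math.isfinite(self.P_steep)):
            raise InvalidMeasurementError("meridional powers must be finite")
        self.A_flat = _norm_axis(self.A_flat)
        if self.P_flat > self.P_steep:
            warnings.warn(
                "flat/steep powers mislabelled (P_flat > P_steep); swapping",
                stacklevel=3,
            )
            self.P_flat, self.P_steep = self.P_steep, self.P_flat
            self.A_flat = _norm_axis(self.A_flat + 90.0)

    @property
    def A_steep(self) -> float:
        return _norm_axis(self.A_flat + 90.0)

    @property
    def cylinder(self) -> float:
        return self.P_steep - self.P_flat


@dataclass(frozen=True)
class PowerVector:
    """Power vector (EQ, C0, C45) in dioptres; supports + and -."""

    EQ: float
    C0: float
    C45: float

    @property
    def cylinder(self) -> float:
        """Astigmatism magnitude sqrt(C0**2 + C45**2), dioptres."""
        return math.hypot(self.C0, self.C45)

    def __add__(self, other: "PowerVector") -> "PowerVector":
        return PowerVector(self.EQ + other.EQ, self.C0 + other.C0, self.C45 + other.C45)

    def __sub__(self, other: "PowerVector") -> "PowerVector":
        return PowerVector(self.EQ - other.EQ, self.C0 - other.C0, self.C45 - other.C45)

    def mirror(self) -> "PowerVector":
        """Flip the oblique component, mapping OS anatomy onto OD orientation."""
        return PowerVector(self.EQ, self.C0, -self.C45)

    def scale(self, factor: float) -> "PowerVector":
        return PowerVector(self.EQ * factor, self.C0 * factor, self.C45 * factor)


@dataclass(frozen=True)
class RefractionRecord:
    """Spectacle refraction: sphere REFS, cylinder REFC, axis REFA (degrees)."""

    REFS: float
    REFC: float
    REFA: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "REFA", _norm_axis(self.REFA))


@dataclass(frozen=True)
class TIOLRecord:
    """Toric IOL label data: equivalent power IOLP, toricity IOLT >= 0, axis IOLA."""

    IOLP: float
    IOLT: float
    IOLA: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.IOLT) or self.IOLT < 0.0:
            raise InvalidMeasurementError(f"toricity must be >= 0, got {self.IOLT}")
        object.__setattr__(self, "IOLA", _norm_axis(self.IOLA))


# ---------------------------------------------------------------------------
# conversions


def power_from_radius(radius_mm: float, media: MediaInterface) -> float:
    """Paraxial power of a single meridian: ``1000 * delta_n / R`` dpt for R in mm."""
    if not math.isfinite(radius_mm) or radius_mm <= 0.0:
        raise InvalidMeasurementError(f"radius must be finite and > 0, got {radius_mm}")
    return 1000.0 * media.delta_n / radius_mm


def radii_to_power_vector(s: SurfaceMeasurement, media: MediaInterface) -> PowerVector:
    """Decompose a radii-based surface measurement into a power vector.

    EQ = 500 * delta_n * (1/R_steep + 1/R_flat); the signed cylinder
    1000 * delta_n * (1/R_steep - 1/R_flat) is projected at twice the
    flat-meridian axis.  For a negative index step (back surface) the cylinder
    comes out negative at the front-flat axis, i.e. the back surface
    astigmatism opposes the front's, as anatomy dictates.
    """
    eq = 500.0 * media.delta_n * (1.0 / s.R_steep + 1.0 / s.R_flat)
    cyl = 1000.0 * media.delta_n * (1.0 / s.R_steep - 1.0 / s.R_flat)
    ang = math.radians(2.0 * s.A_flat)
    return PowerVector(eq, cyl * math.cos(ang), cyl * math.sin(ang))


def powers_to_power_vector(p: PowerMeridians) -> PowerVector:
    """Decompose meridional powers (already in dioptres) into a power vector."""
    eq = 0.5 * (p.P_flat + p.P_steep)
    cyl = p.P_steep - p.P_flat
    ang = math.radians(2.0 * p.A_flat)
    return PowerVector(eq, cyl * math.cos(ang), cyl * math.sin(ang))


def refraction_to_power_vector(r: RefractionRecord) -> PowerVector:
    """Decompose a spectacle refraction (sphere/cylinder/axis) into a power vector.

    The refraction is read as two meridional powers, REFS at REFA and
    REFS + REFC at REFA + 90°; transposed cylinder notation therefore maps to
    the same vector.
    """
    p1, a1 = r.REFS, r.REFA
    p2 = r.REFS + r.REFC
    if p1 <= p2:
        merid = PowerMeridians(p1, p2, a1)
    else:
        merid = PowerMeridians(p2, p1, _norm_axis(a1 + 90.0))
    return powers_to_power_vector(merid)


def tiol_to_power_vector(t: TIOLRecord) -> PowerVector:
    """Thin-lens split of a toric IOL: IOLP -/+ 0.5*IOLT at IOLA / IOLA + 90°."""
    merid = PowerMeridians(t.IOLP - 0.5 * t.IOLT, t.IOLP + 0.5 * t.IOLT, t.IOLA)
    return powers_to_power_vector(merid)


def mirror_for_left_eye(v: PowerVector) -> PowerVector:
    """Reverse the sign of C45 so left-eye data pools with right eyes."""
    return v.mirror()


def pv_add(a: PowerVector, b: PowerVector) -> PowerVector:
    return a + b


def pv_subtract(a: PowerVector, b: PowerVector) -> PowerVector:
    return a - b


def power_vector_to_polar(v: PowerVector) -> PowerMeridians:
    """Invert the decomposition back to meridional powers (flat @ axis, steep).

    The cylinder is sqrt(C0**2 + C45**2) >= 0 and the flat axis is half the
    double angle atan2(C45, C0), mapped into [0, 180).  A zero-cylinder vector
    gets axis 0° with ``axis_undefined`` set.
    """
    cyl = math.hypot(v.C0, v.C45)
    if cyl == 0.0:
        return PowerMeridians(v.EQ, v.EQ, 0.0, axis_undefined=True)
    axis = _norm_axis(math.degrees(0.5 * math.atan2(v.C45, v.C0)))
    return PowerMeridians(v.EQ - 0.5 * cyl, v.EQ + 0.5 * cyl, axis)


def power_vector_to_radii(v: PowerVector, media: MediaInterface) -> SurfaceMeasurement:
    """Invert a power vector to meridional radii for the given index step.

    For a negative index step the meridian with the lower (more negative)
    power is the one with the smaller radius, so the flat-by-radius meridian
    sits 90° from the flat-by-power axis.  Radii must come out positive.
    """
    polar = power_vector_to_polar(v)
    r_at_flat_power = 1000.0 * media.delta_n / polar.P_flat if polar.P_flat != 0 else math.inf
    r_at_steep_power = 1000.0 * media.delta_n / polar.P_steep if polar.P_steep != 0 else math.inf
    if not (0.0 < r_at_flat_power < math.inf and 0.0 < r_at_steep_power < math.inf):
        raise InvalidMeasurementError(
            f"power vector {v} has no positive-radius representation for delta_n={media.delta_n}"
        )
    if r_at_flat_power >= r_at_steep_power:
        return SurfaceMeasurement(
            R_flat=r_at_flat_power,
            A_flat=polar.A_flat,
            R_steep=r_at_steep_power,
            A_steep=polar.A_steep,
        )
    return SurfaceMeasurement(
        R_flat=r_at_steep_power,
        A_flat=polar.A_steep,
        R_steep=r_at_flat_power,
        A_steep=polar.A_flat,
    )
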