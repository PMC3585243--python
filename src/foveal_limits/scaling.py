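"""Retinal magnification chain: spectacle magnification, Bennett scaling, units.

Converting between angular units on the retina (arcmin, degrees) and linear
units in AOSLO imagery (µm, pixels) requires two pieces of per-eye optics:

* **Spectacle magnification** — a trial lens of power ``F`` diopters placed a
  vertex distance ``d`` (m) in front of the entrance pupil rescales retinal
  image size by ``SM = 1 / (1 - d * F)``.
* **Bennett's adjusted axial length method** — the retinal extent of one
  degree of visual angle is ``q * (AL - 1.82)`` mm with ``q = 0.01306``
  mm/deg, where ``AL`` is the optically measured axial length in mm and
  1.82 mm is the distance from the corneal vertex to the eye's second nodal
  point.

The product ``m = 1000 * q * (AL - 1.82) * SM`` µm/degree is the single
scale factor that the rest of the pipeline uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

BENNETT_Q_MM_PER_DEG = 0.01306
BENNETT_NODAL_OFFSET_MM = 1.82
DEFAULT_VERTEX_MM = 14.0

_UNITS = ("arcmin", "degree", "um", "pixel")


@dataclass(frozen=True)
class EyeBiometry:
    """Per-eye optical biometry.

    Parameters
    ----------
    axial_length : float
        Axial length of the eye in mm (IOLMaster-style optical measurement).
    spectacle_sphere_equiv : float
        Spherical equivalent (sphere + cyl/2, computed by the caller) of the
        trial lenses worn during imaging, in diopters.
    vertex_distance : float
        Distance from the spectacle plane to the entrance pupil, mm.
    """

    axial_length: float
    spectacle_sphere_equiv: float
    vertex_distance: float = DEFAULT_VERTEX_MM

    def __post_init__(self) -> None:
        if not 15.0 < self.axial_length < 40.0:
            raise ValueError(
                f"axial_length {self.axial_length} mm outside the plausible "
                "human range (15, 40)"
            )
        if not abs(self.spectacle_sphere_equiv) < 25.0:
            raise ValueError(
                f"|spectacle power| {self.spectacle_sphere_equiv} D >= 25 D"
            )


@dataclass(frozen=True)
class ScaleModel:
    """Magnification chain for one eye/imaging session.

    ``um_per_pixel`` ties the angular field size to the pixel raster through
    ``m``; consistency between the three is checked at construction.
    """

    sm: float
    m_um_per_deg: float
    field_arcmin: tuple[float, float] = (48.0, 54.0)
    pixels: tuple[int, int] = (384, 432)
    um_per_pixel: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.sm <= 0 or self.m_um_per_deg <= 0:
            raise ValueError("sm and m_um_per_deg must be positive")
        implied = (self.field_arcmin[0] / 60.0) * self.m_um_per_deg / self.pixels[0]
        if self.um_per_pixel == 0.0:
            object.__setattr__(self, "um_per_pixel", implied)
        elif abs(self.um_per_pixel - implied) > 0.05 * implied:
            raise ValueError(
                f"um_per_pixel {self.um_per_pixel:.4f} inconsistent with field/"
                f"pixel geometry (implied {implied:.4f})"
            )

    @property
    def pixels_per_arcmin(self) -> float:
        return self.pixels[0] / self.field_arcmin[0]

    @classmethod
    def from_biometry(
        cls,
        biometry: EyeBiometry,
        field_arcmin: tuple[float, float] = (48.0, 54.0),
        pixels: tuple[int, int] = (384, 432),
    ) -> "ScaleModel":
        return cls(
            sm=spectacle_magnification(biometry),
            m_um_per_deg=retinal_magnification(biometry),
            field_arcmin=field_arcmin,
            pixels=pixels,
        )


def spectacle_magnification(biometry: EyeBiometry) -> float:
    """Magnification induced by a spectacle-plane trial lens.

    ``SM = 1 / (1 - d*F)`` with ``d`` the vertex distance in meters and ``F``
    the spherical-equivalent power in diopters.  Minus lenses (myopes) give
    SM < 1 (minification).
    """
    d_m = biometry.vertex_distance / 1000.0
    denom = 1.0 - d_m * biometry.spectacle_sphere_equiv
    if denom <= 0:
        raise ValueError(
            f"nonphysical spectacle power: 1 - d*F = {denom:.3f} <= 0"
        )
    return 1.0 / denom


def retinal_magnification(biometry: EyeBiometry) -> float:
    """Retinal scale ``m`` in µm per degree of visual angle.

    Bennett's adjusted axial length method,
    ``m = 1000 * q * (AL - 1.82) * SM``, with the unrounded spectacle
    magnification applied for eyes imaged through trial lenses.
    """
    adjusted = biometry.axial_length - BENNETT_NODAL_OFFSET_MM
    if adjusted <= 0:
        raise ValueError(
            f"axial length {biometry.axial_length} mm <= nodal offset "
            f"{BENNETT_NODAL_OFFSET_MM} mm"
        )
    return 1000.0 * BENNETT_Q_MM_PER_DEG * adjusted * spectacle_magnification(biometry)


def convert(value: float, from_unit: str, to_unit: str, scale: ScaleModel) -> float:
    """Convert between angular/linear/pixel units through a ScaleModel.

    Supported units: ``arcmin``, ``degree``, ``um``, ``pixel``.  Conversions
    chain through degrees, so round trips are exact to floating precision.
    """
    for u in (from_unit, to_unit):
        if u not in _UNITS:
            raise ValueError(f"unknown unit {u!r}; expected one of {_UNITS}")
    # to degrees
    if from_unit == "degree":
        deg = value
    elif from_unit == "arcmin":
        deg = value / 60.0
    elif from_unit == "um":
        deg = value / scale.m_um_per_deg
    else:  # pixel
        deg = value * scale.um_per_pixel / scale.m_um_per_deg
    # from degrees
    if to_unit == "degree":
        return deg
    if to_unit == "arcmin":
        return deg * 60.0
    if to_unit == "um":
        return deg * scale.m_um_per_deg
    return deg * scale.m_um_per_deg / scale.um_per_pixel


def table_row(biometry: EyeBiometry) -> dict:
    """Biometry-table-style row: SM (%), m (µm/deg), µm/pixel."""
    sm = spectacle_magnification(biometry)
    m = retinal_magnification(biometry)
    scale = ScaleModel(sm=sm, m_um_per_deg=m)
    return {
        "axial_length_mm": biometry.axial_length,
        "spherical_equivalent_D": biometry.spectacle_sphere_equiv,
        "spectacle_magnification_pct": round(sm * 100.0, 1),
        "m_um_per_deg": round(m, 2),
        "um_per_pixel": round(scale.um_per_pixel, 4),
    }
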